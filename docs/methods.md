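# Methods

## The annotation model

A study variable is represented as a *personal data element* (PDE): a term
minted for one dataset, carrying the variable's local name
(`sourceVariable`), a label, a free-text description, a value
representation (`valueType`, drawn from a controlled XSD-style vocabulary),
optional units (`unitCode`), an optional ordered range
(`minValue`/`maxValue`), and — for categorical variables — a `choices` list
mapping codes (often integers) to meanings. *Common data elements* (CDEs)
are the same structure without the requirement of a local source variable.
*Concepts* are higher-order ideas identified by URL; an element's `isAbout`
links name the concepts it measures. Cross-dataset discovery rests entirely
on those links: two datasets that call the same measurement `handedness`
and `ehi` are both found by querying the shared handedness-assessment
concept, and renaming variables can never change a query result (this
name-independence is asserted as a property test).

Identifiers are absolute URIs; CURIEs with a registered prefix (e.g.
`ILX:0104886` for the InterLex handedness-assessment term) are expanded on
construction, so equality is always on expanded URI text. PDE identifiers
are minted deterministically as
`<base-namespace>/<dataset-id>/<normalized-variable-name>`, making
re-annotation stable. The shipped JSON-LD context maps property names to
stable URIs, reusing RDFS/Dublin Core/SKOS where a well-known predicate
exists and the NIDM namespace otherwise.

Unordered link sets (`isAbout`, `subtypeCDEs`, `supertypeCDEs`,
`associatedWith`) are canonically sorted at construction. This is what
makes the RDF round trip an exact identity — RDF graphs carry no list
order — while `choices`, whose order is meaningful, is serialized as an RDF
collection. Unknown keys met when importing a JSON-LD document are kept on
a side mapping (`extra`) and reported as a warning, never silently dropped:
the model assumes an open world in which others may say more about a term
than this package models.

## Choices text

Two textual dialects of categorical mappings are accepted besides JSON
objects: brace-wrapped and bare `code = meaning` lists, separated by commas
or semicolons, whitespace-insensitive around `=`. Numeric-looking codes
become numbers, others stay text. Duplicate codes and fragments without a
`=` are hard errors naming the offender. `format_choices` emits the
canonical brace-wrapped form and `parse_choices` is its left inverse
(property-tested).

## Shape validation

Each element type has a shape: per-property constraints with `minCount`,
`maxCount` (or unbounded), a value kind (`text`, `number`, `conceptRef`,
`choiceList`, `identifier`, `controlledText`) and, for controlled
properties, an allowed-value list. The engine is an explicit scan — count
occurrences, check kinds, check membership — deliberately small rather than
a general SHACL processor, and its soundness is tested against an
independently written brute-force scan on randomized elements.

Shipped defaults: a PDE requires label, description, sourceVariable and
valueType; a CDE drops the sourceVariable requirement; a concept requires
identifier, label and definition. `valueType` is constrained to
`xsd:int/float/string/bool/date/dateTime`. Two engine rules go beyond plain
cardinality: a categorical element's `valueType` must be `xsd:int` or
`xsd:string` (codes are integers or strings), reported against `valueType`
so that property removal stays monotone; and a non-categorical numeric
element without `unitCode` draws a *warning*, not a violation — missing
units make data hard to reuse, but demanding them would reject too many
real dictionaries. Violations are sorted by element identifier, property
name and constraint kind so reports are deterministic. Shapes are loadable
from a JSON file with the same structure as the defaults, so communities
can override them.

Construction is permissive by design (only internally inconsistent states —
inverted ranges, duplicate choice codes, duplicate subject ids — are
constructor errors); completeness is always validation's job. One
consequence: an element without an identifier is unrepresentable, so the
identifier requirement of the concept shape can only fire on records read
from malformed external files.

## Ingestion

`participants.tsv` and phenotype tables are read with a strict line-level
parser: a missing subject-identifier column or a ragged row is an error
naming the line, and the `n/a` marker (case-insensitive; configurable)
becomes an explicit missing value. Sidecar JSON keys map onto element
properties (`Description` → description, `Levels` → choices, `Units` →
unitCode, `isAbout` — object or list — → concept links); the package's
sidecar dialect additionally admits `MinValue`, `MaxValue` and `ValueType`,
because BIDS has no standard key for numeric ranges and without them an
inventory's bounds could not survive a BIDS round trip. Dictionary
assembly precedence is: externally supplied dictionary > sidecar > bare
stub — a master dictionary exists precisely to override per-site
heterogeneity.

Variable names are normalized by case-folding and collapsing runs of
spaces/dashes/underscores; distinct alphanumeric tokens are never merged
(`age` ≠ `agemonths`). Normalized names are the dictionary keys, so sites
whose headers differ only in surface convention land on identical key sets.

Imaging files are recognized purely by BIDS entity naming
(`sub-<id>[/ses-<id>]/<datatype>/..._<suffix>.nii[.gz]`); contents are
never read, so fixtures use zero-byte files. The suffix table maps
`T1w`→(T1-weighted, Anatomical), `T2w`→(T2-weighted, Anatomical),
`bold`→(T2*-weighted, Functional), `dwi`→(Diffusion-weighted, Diffusion),
`FLAIR`→(FLAIR, Anatomical), and is extensible per call. Unparseable paths
are skipped with a logged warning: a stray file must not abort a dataset
conversion.

Dataset graphs serialize to JSON-LD (embedded term documents, subjects,
acquisitions) and to N-Quads (an RDF graph in which each acquisition
carries `nidm:hadImageContrastType`/`nidm:hadImageUsageType` statements).
Both serializations round-trip to equality; subject-row cell values are
kept as text (what a TSV can carry) to make that identity exact.

## Concept suggestion

Similarity is a token-set ratio: both names are normalized and tokenized,
and the score is the best `SequenceMatcher` ratio among the sorted-token
combinations of shared and distinct tokens. A name whose tokens contain the
other's scores 1.0 — which is exactly why `age_months` matches the concept
label "age" perfectly. The suggestion threshold defaults to 0.5 and is a
keyword argument; ranking is two-tiered (previously used concepts first),
then score-descending with label and identifier tie-breaks for determinism.
The prior-use list mirrors curated practice: once a concept has been chosen
for an annotation, routine variables collapse to a single obvious
suggestion. Remote terminology services can implement the same
`search(text)` interface; everything shipped works from a local JSON-LD
registry file.

## Query engine

Queries run against an in-memory index (concept URI → (dataset, variable)
pairs; contrast type → dataset ids) — no triple store is required at this
scale. AND is satisfied at dataset level: every queried concept must be
matched by *some* variable of the dataset, not one variable carrying all
concepts; this matches the discovery use case ("which datasets have
both age and a depression measure?"). Concept matching is by exact expanded
URI; labels never enter queries. Combined criteria intersect the concept
and image-type results. Matched dataset lists are sorted for determinism.
`emit_sparql` prints the equivalent SPARQL for users moving to a
server-backed archive; it is illustrative output and is never executed
here.

## Synthetic fixtures

The generator emulates a multi-site study: each site is a BIDS directory
with `participants.tsv`, a sidecar, and zero-byte imaging files, and the
variable headers are surface-perturbed (case forms, space/dash/underscore
swaps, optional stray leading/trailing separators) variants of canonical
names, drawn from a fixed catalog with a seeded generator — every
perturbation normalizes back to the canonical key, and identical specs
produce byte-identical trees. Defaults: 3 sites, 4 subjects per site, three
variables (age in months, sex, handedness with the 1/5/10 Right/Left/
Ambidextrous coding), T1w and bold images per subject, 10% missingness.
Values are uniform draws: the fixtures exercise structure (names,
annotations, layout), not statistics — passing tests say nothing about
distributional properties of real phenotype data, about DICOM-level
metadata, or about imaging file contents. Fixture concepts live in a
reserved example namespace; real terminology URIs (such as the InterLex
handedness term) appear only in documentation and tests of CURIE handling.

The two-dataset worked example is fixed content, not seeded: a categorical
`handedness` variable (1 = Right, 5 = Left, 10 = Ambidextrous) in dataset
one and an integer `ehi` in −40..40 in dataset two, both `isAbout` the same
handedness-assessment concept.

## Problem sizes and numerical choices

Randomized suites use seeded `random.Random` instances (plus derandomized
`hypothesis` for string properties): validation soundness is checked on 200
randomized elements against the brute-force oracle, query/oracle
equivalence on 50 randomized collections of up to 20 datasets with up to 15
variables each — sizes at which the brute-force scans are still trivially
fast and exhaustive comparison is exact. There are no tolerances anywhere:
every compared quantity (codes, bounds, dataset lists, violation multisets)
is discrete and checked for exact equality.

## Known limitations

* Only the constraint kinds above are validated — no SHACL paths, logical
  combinators or SPARQL constraints.
* Dataset-level discovery only: no subject-level cohort filters (e.g. age
  ranges) and no remote SPARQL endpoints.
* No DICOM parsing, no ReproSchema conversion, and no live terminology
  services; the registry interface is the extension point.
* Subject/session/acquisition linkage is the only provenance modeled;
  scanner protocols and full PROV activity chains are out of scope.
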