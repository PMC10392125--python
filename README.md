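# neuroterms

Terminology management and concept-based discovery for neuroimaging
metadata.

Neuroimaging studies describe the same measurements under different local
variable names: one dataset stores a categorical `handedness` column, a
second stores the Edinburgh handedness inventory as an integer `ehi` score
from −40 (left handed) to 40 (right handed). No query over variable names
can find both. `neuroterms` implements the annotation model that makes such
queries possible:

* **data elements** — each study variable becomes a *personal data element*
  (PDE) carrying a small, well-defined property set (label, description,
  value type, units, min/max, categorical choices); community-adopted terms
  are *common data elements* (CDEs);
* **concepts** — higher-order ideas ("handedness assessment", "age")
  identified by URL; an element's `isAbout` links tie local variables to
  shared concepts, so queries operate on meaning instead of spelling;
* **shape validation** — per-type constraint sets (required properties,
  value kinds, cardinalities) that reject under-annotated terms before they
  enter a shared terminology;
* **BIDS/tabular annotation** — ingest a BIDS directory (`participants.tsv`,
  JSON sidecars, `phenotype/` tables, entity-named imaging files) or a
  standalone CSV/TSV into one annotated dataset graph per site, with
  acquisition records typed by image contrast (`T2-weighted`,
  `T2*-weighted`, …) and usage (`Anatomical`, `Functional`, `Diffusion`)
  via `nidm:hadImageContrastType` / `nidm:hadImageUsageType`;
* **concept suggestion** — fuzzy (token-set) matching of variable names
  against a local concept registry, with previously used concepts ranked
  first;
* **cross-dataset query** — AND/OR concept queries and image-contrast-type
  queries over a collection of annotated datasets, plus a SPARQL emitter
  showing the equivalent triple-store query.

It is intended for data curators and researchers preparing multi-site or
archive-scale collections for reuse, and for anyone who needs to answer
"which of these datasets measured X and acquired a T1-weighted scan?"
without a server.

## Worked example

```python
from pathlib import Path
from neuroterms import build_index, ingest_bids, query_concepts
from neuroterms.fixtures import HANDEDNESS_URI, generate_worked_example
from neuroterms.query_engine import scan_variable_name

ds1, ds2 = generate_worked_example(Path("example"))
index = build_index([ingest_bids(ds1), ingest_bids(ds2)])

print(query_concepts(index, [HANDEDNESS_URI], "OR").matchedDatasets)
print(scan_variable_name(index, "handedness"))
ehi = index.datasets["dataset2"].dataDictionary["ehi"]
print(ehi.minValue, ehi.maxValue)
```

prints

```
['dataset1', 'dataset2']
['dataset1']
-40 40
```

The concept query finds both datasets because both variables are annotated
`isAbout` the same handedness-assessment concept; the literal name scan
finds only the dataset that happens to call its variable `handedness`; and
the `ehi` element carries the inventory's −40..40 bounds recovered from its
sidecar annotation.

The same flows are available from the shell:

```sh
terms simulate --sites 3 --subjects 4 --seed 1 --out sim/
terms annotate bids --root sim/site-01 --out site-01.jsonld
terms suggest --var age_months --registry sim/registry.jsonld
terms query --datasets . --concepts <concept-uri> --mode and --contrast T1-weighted
terms validate --in my_terms/
terms export --format markdown --in my_terms/ --out terms.md
```

## Layout

| Module | Role |
| --- | --- |
| `neuroterms.term_model` | data-element/concept model, JSON-LD and RDF serialization, 5-format export |
| `neuroterms.schema_validation` | per-type shapes and the constraint engine |
| `neuroterms.dataset_ingest` | BIDS/tabular ingestion, image typing, dataset graphs |
| `neuroterms.concept_service` | local registry, fuzzy suggestion, prior-use ranking |
| `neuroterms.query_engine` | cross-dataset concept/image-type queries |
| `neuroterms.fixtures` | deterministic synthetic multi-site BIDS generator |
| `neuroterms.cli` | the `terms` command line |
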