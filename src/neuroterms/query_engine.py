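"""Cross-dataset discovery by concept and image contrast type.

Because data elements carry ``isAbout`` links to shared concepts, a query
for "handedness assessment" finds a dataset whose variable is called
``handedness`` and another whose variable is called ``ehi`` — the variable
names never enter the query.  An in-memory index over a collection of
annotated datasets supports:

* concept queries with AND/OR combinators (AND is satisfied at dataset
  level: each queried concept must be matched by *some* variable of the
  dataset, not necessarily the same one);
* image-type queries over the acquisitions' contrast types;
* combined queries (intersection of both).

A SPARQL emitter mirrors what the equivalent triple-store query would look
like, for users moving to a server-backed archive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dataset_ingest import AnnotatedDataset, CONTRAST_TYPES
from .term_model import ConceptRef, TermError, TermIdentifier

__all__ = [
    "DatasetIndex",
    "QueryCriteria",
    "QueryResult",
    "QueryError",
    "build_index",
    "available_concepts",
    "query_concepts",
    "query_image_type",
    "query_combined",
    "scan_variable_name",
    "emit_sparql",
]


class QueryError(ValueError):
    pass


@dataclass
class DatasetIndex:
    datasets: dict[str, AnnotatedDataset] = field(default_factory=dict)
    #: concept URI → {(datasetId, variableKey)}
    conceptIndex: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    #: contrast type → {datasetId}
    contrastIndex: dict[str, set[str]] = field(default_factory=dict)


@dataclass(frozen=True)
class QueryCriteria:
    concepts: frozenset[TermIdentifier] = frozenset()
    combinator: str = "AND"
    contrastTypes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.combinator not in ("AND", "OR"):
            raise QueryError(f"combinator must be AND or OR, got {self.combinator!r}")
        if not self.concepts and not self.contrastTypes:
            raise QueryError("criteria must name at least one concept or contrast type")


@dataclass
class QueryResult:
    matches: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    matchedDatasets: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matchedDatasets = sorted(self.matches)
        for ds in self.matches:
            self.matches[ds] = sorted(set(self.matches[ds]))


def build_index(datasets: list[AnnotatedDataset]) -> DatasetIndex:
    """Index a dataset collection by concept URI and contrast type."""
    index = DatasetIndex()
    for ds in datasets:
        if ds.datasetId in index.datasets:
            raise QueryError(f"duplicate dataset id {ds.datasetId!r}")
        index.datasets[ds.datasetId] = ds
        for key, element in ds.dataDictionary.items():
            for ref in element.isAbout:
                index.conceptIndex.setdefault(ref.url.uri, set()).add((ds.datasetId, key))
        for acq in ds.acquisitions:
            index.contrastIndex.setdefault(acq.imageContrastType, set()).add(ds.datasetId)
    return index


def available_concepts(index: DatasetIndex) -> list[ConceptRef]:
    """Every concept used in any ``isAbout`` link, once per URI, sorted by
    label (URI where no label is recorded)."""
    by_uri: dict[str, str | None] = {}
    for ds in index.datasets.values():
        for element in ds.dataDictionary.values():
            for ref in element.isAbout:
                if by_uri.get(ref.url.uri) is None:
                    by_uri[ref.url.uri] = ref.label
    refs = [
        ConceptRef(url=TermIdentifier(uri), label=label) for uri, label in by_uri.items()
    ]
    return sorted(refs, key=lambda r: (r.label or r.url.uri, r.url.uri))


def _normalize_concepts(concepts) -> list[str]:
    out = []
    for c in concepts:
        ident = c if isinstance(c, TermIdentifier) else TermIdentifier(str(c))
        out.append(ident.uri)
    return out


def query_concepts(index: DatasetIndex, concepts, combinator: str = "AND") -> QueryResult:
    """Datasets annotated with the queried concepts.

    OR returns datasets where at least one queried concept is linked by some
    variable; AND requires every queried concept to be linked (dataset-level
    conjunction).  ``matches`` lists each contributing (variable key,
    concept URI) pair.
    """
    uris = _normalize_concepts(concepts)
    if not uris:
        raise QueryError("empty concept set")
    if combinator not in ("AND", "OR"):
        raise QueryError(f"combinator must be AND or OR, got {combinator!r}")
    per_concept: dict[str, dict[str, list[tuple[str, str]]]] = {}
    for uri in uris:
        hits: dict[str, list[tuple[str, str]]] = {}
        for ds_id, key in index.conceptIndex.get(uri, ()):
            hits.setdefault(ds_id, []).append((key, uri))
        per_concept[uri] = hits
    dataset_sets = [set(hits) for hits in per_concept.values()]
    if combinator == "AND":
        selected = set.intersection(*dataset_sets)
    else:
        selected = set.union(*dataset_sets)
    matches: dict[str, list[tuple[str, str]]] = {ds: [] for ds in selected}
    for hits in per_concept.values():
        for ds_id, pairs in hits.items():
            if ds_id in selected:
                matches[ds_id].extend(pairs)
    return QueryResult(matches=matches)


def query_image_type(index: DatasetIndex, contrast_types) -> QueryResult:
    """Datasets with at least one acquisition of a queried contrast type."""
    requested = set(contrast_types)
    if not requested:
        raise QueryError("empty contrast-type set")
    unknown = requested - set(CONTRAST_TYPES)
    if unknown:
        raise QueryError(
            f"unknown contrast type(s) {sorted(unknown)}; valid values: "
            f"{list(CONTRAST_TYPES)}"
        )
    matches: dict[str, list[tuple[str, str]]] = {}
    for ds_id, ds in index.datasets.items():
        contributing = sorted(
            {
                (acq.filePath, acq.imageContrastType)
                for acq in ds.acquisitions
                if acq.imageContrastType in requested
            }
        )
        if contributing:
            matches[ds_id] = contributing
    return QueryResult(matches=matches)


def query_combined(index: DatasetIndex, criteria: QueryCriteria) -> QueryResult:
    """Concept and image-type criteria together: a dataset must satisfy
    both (when both are present)."""
    concept_result = (
        query_concepts(index, criteria.concepts, criteria.combinator)
        if criteria.concepts
        else None
    )
    contrast_result = (
        query_image_type(index, criteria.contrastTypes) if criteria.contrastTypes else None
    )
    if concept_result is None:
        return contrast_result
    if contrast_result is None:
        return concept_result
    keep = set(concept_result.matches) & set(contrast_result.matches)
    matches = {
        ds: concept_result.matches[ds] + contrast_result.matches[ds] for ds in keep
    }
    return QueryResult(matches=matches)


def scan_variable_name(index: DatasetIndex, name: str) -> list[str]:
    """Literal variable-name scan, provided for contrast with concept
    queries: returns dataset ids whose dictionary contains *name* as a key
    (exact key match, no normalization beyond the dictionary's own)."""
    return sorted(
        ds_id for ds_id, ds in index.datasets.items() if name in ds.dataDictionary
    )


def emit_sparql(criteria: QueryCriteria) -> str:
    """The SPARQL text an equivalent triple-store query would use.

    Educational output only — the in-memory engine never executes it.
    """
    lines = [
        "PREFIX nidm: <http://purl.org/nidash/nidm#>",
        "SELECT DISTINCT ?dataset WHERE {",
    ]
    uris = sorted(_normalize_concepts(criteria.concepts))
    if uris:
        if criteria.combinator == "AND":
            for i, uri in enumerate(uris):
                lines.append(f"  ?dataset nidm:hasDataElement ?el{i} .")
                lines.append(f"  ?el{i} nidm:isAbout <{uri}> .")
        else:
            lines.append("  ?dataset nidm:hasDataElement ?el .")
            lines.append("  ?el nidm:isAbout ?concept .")
            values = " ".join(f"<{u}>" for u in uris)
            lines.append(f"  VALUES ?concept {{ {values} }}")
    if criteria.contrastTypes:
        lines.append("  ?dataset nidm:hasAcquisition ?acq .")
        lines.append("  ?acq nidm:hadImageContrastType ?contrast .")
        values = " ".join(f'"{c}"' for c in sorted(criteria.contrastTypes))
        lines.append(f"  VALUES ?contrast {{ {values} }}")
    lines.append("}")
    return "\n".join(lines)
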