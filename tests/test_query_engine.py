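"""Cross-dataset queries: index construction, AND/OR semantics, oracles."""

from __future__ import annotations

import copy
import random

import pytest

from conftest import CONCEPT_POOL, random_annotated_dataset
from neuroterms.dataset_ingest import AnnotatedDataset, CONTRAST_TYPES
from neuroterms.query_engine import (
    QueryCriteria,
    QueryError,
    available_concepts,
    build_index,
    emit_sparql,
    query_combined,
    query_concepts,
    query_image_type,
    scan_variable_name,
)
from neuroterms.term_model import ConceptRef, TermIdentifier, build_data_element

HANDEDNESS = "https://terms.example.org/concepts/handedness-assessment"
AGE = "https://terms.example.org/concepts/age"


def make_dataset(ds_id: str, variables: dict[str, str | None], suffix_contrasts=()):
    """Tiny dataset: variable key → concept URI (or None), plus contrasts."""
    from neuroterms.dataset_ingest import AcquisitionRecord, SUFFIX_TABLE

    dictionary = {}
    for key, uri in variables.items():
        props = {"isAbout": [ConceptRef(url=TermIdentifier(uri))]} if uri else {}
        dictionary[key] = build_data_element(key, props, dataset_id=ds_id)
    acquisitions = []
    for i, suffix in enumerate(suffix_contrasts):
        contrast, usage = SUFFIX_TABLE[suffix]
        acquisitions.append(
            AcquisitionRecord(
                subjectId=f"{i:02d}",
                sessionId=None,
                filePath=f"sub-{i:02d}/anat/sub-{i:02d}_{suffix}.nii.gz",
                imageContrastType=contrast,
                imageUsageType=usage,
            )
        )
    return AnnotatedDataset(datasetId=ds_id, dataDictionary=dictionary, acquisitions=acquisitions)


@pytest.fixture()
def pair_index():
    """Two datasets naming the same handedness concept differently."""
    a = make_dataset("A", {"handedness": HANDEDNESS, "age": AGE}, ("T1w", "T2w"))
    b = make_dataset("B", {"ehi": HANDEDNESS}, ("bold",))
    return build_index([a, b])


class TestBuildIndex:
    def test_concept_index_counts_annotated_variables(self, pair_index):
        assert pair_index.conceptIndex[HANDEDNESS] == {("A", "handedness"), ("B", "ehi")}

    def test_contrast_index_from_acquisitions(self, pair_index):
        assert pair_index.contrastIndex["T2-weighted"] == {"A"}
        assert pair_index.contrastIndex["T2*-weighted"] == {"B"}

    def test_empty_collection(self):
        index = build_index([])
        assert index.datasets == {} and index.conceptIndex == {}

    def test_duplicate_dataset_id_rejected(self):
        ds = make_dataset("A", {})
        with pytest.raises(QueryError, match="duplicate"):
            build_index([ds, ds])


class TestAvailableConcepts:
    def test_deduplicated_by_uri(self, pair_index):
        uris = [ref.url.uri for ref in available_concepts(pair_index)]
        assert sorted(uris) == sorted({AGE, HANDEDNESS})

    def test_empty_when_nothing_annotated(self):
        index = build_index([make_dataset("A", {"x": None})])
        assert available_concepts(index) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_equals_linear_scan(self, seed):
        rng = random.Random(seed)
        datasets = [random_annotated_dataset(rng, f"ds-{i}") for i in range(rng.randint(1, 10))]
        index = build_index(datasets)
        expected = {
            ref.url.uri
            for ds in datasets
            for el in ds.dataDictionary.values()
            for ref in el.isAbout
        }
        assert {r.url.uri for r in available_concepts(index)} == expected


class TestConceptQueries:
    def test_shared_concept_returns_both_datasets(self, pair_index):
        result = query_concepts(pair_index, [HANDEDNESS], "OR")
        assert result.matchedDatasets == ["A", "B"]
        assert ("ehi", HANDEDNESS) in result.matches["B"]

    def test_and_requires_every_concept(self, pair_index):
        result = query_concepts(pair_index, [HANDEDNESS, AGE], "AND")
        assert result.matchedDatasets == ["A"]

    def test_or_is_union_of_singles(self, pair_index):
        union = set(query_concepts(pair_index, [HANDEDNESS], "OR").matchedDatasets) | set(
            query_concepts(pair_index, [AGE], "OR").matchedDatasets
        )
        assert set(query_concepts(pair_index, [HANDEDNESS, AGE], "OR").matchedDatasets) == union

    def test_empty_concept_set_rejected(self, pair_index):
        with pytest.raises(QueryError):
            query_concepts(pair_index, [], "AND")


class TestImageTypeQueries:
    def test_selective(self, pair_index):
        assert query_image_type(pair_index, {"T1-weighted"}).matchedDatasets == ["A"]

    def test_exhaustive_set_returns_every_dataset_with_scans(self, pair_index):
        result = query_image_type(pair_index, set(CONTRAST_TYPES))
        assert result.matchedDatasets == ["A", "B"]

    def test_unknown_contrast_type_names_valid_values(self, pair_index):
        with pytest.raises(QueryError, match="T1-weighted"):
            query_image_type(pair_index, {"X-ray"})


class TestCombinedQueries:
    def test_intersection_with_contrast(self, pair_index):
        criteria = QueryCriteria(
            concepts=frozenset([TermIdentifier(HANDEDNESS)]),
            combinator="AND",
            contrastTypes=frozenset({"T1-weighted"}),
        )
        assert query_combined(pair_index, criteria).matchedDatasets == ["A"]

    def test_contrast_only_degenerates_to_image_query(self, pair_index):
        criteria = QueryCriteria(contrastTypes=frozenset({"T2*-weighted"}))
        assert (
            query_combined(pair_index, criteria).matchedDatasets
            == query_image_type(pair_index, {"T2*-weighted"}).matchedDatasets
        )

    def test_empty_criteria_rejected(self):
        with pytest.raises(QueryError):
            QueryCriteria()

    def test_sparql_emission_mentions_criteria(self):
        criteria = QueryCriteria(
            concepts=frozenset([TermIdentifier(HANDEDNESS)]),
            contrastTypes=frozenset({"T1-weighted"}),
        )
        text = emit_sparql(criteria)
        assert HANDEDNESS in text and "hadImageContrastType" in text


# ---------------------------------------------------------------------------
# oracle equivalence and structural properties over randomized collections


def oracle_concept_query(datasets, uris, combinator):
    matched = []
    for ds in datasets:
        linked = {
            ref.url.uri
            for el in ds.dataDictionary.values()
            for ref in el.isAbout
        }
        hit = (
            all(u in linked for u in uris)
            if combinator == "AND"
            else any(u in linked for u in uris)
        )
        if hit:
            matched.append(ds.datasetId)
    return sorted(matched)


def oracle_contrast_query(datasets, types):
    return sorted(
        ds.datasetId
        for ds in datasets
        if any(a.imageContrastType in types for a in ds.acquisitions)
    )


@pytest.mark.parametrize("seed", range(12))
def test_queries_match_linear_scan_oracle(seed):
    rng = random.Random(seed)
    datasets = [random_annotated_dataset(rng, f"ds-{i:02d}") for i in range(rng.randint(1, 20))]
    index = build_index(datasets)
    uris = rng.sample(CONCEPT_POOL, rng.randint(1, 3))
    types = set(rng.sample(CONTRAST_TYPES, rng.randint(1, 2)))
    for combinator in ("AND", "OR"):
        got = query_concepts(index, uris, combinator).matchedDatasets
        assert got == oracle_concept_query(datasets, uris, combinator)
    assert query_image_type(index, types).matchedDatasets == oracle_contrast_query(
        datasets, types
    )
    criteria = QueryCriteria(
        concepts=frozenset(TermIdentifier(u) for u in uris),
        combinator="AND",
        contrastTypes=frozenset(types),
    )
    combined = query_combined(index, criteria).matchedDatasets
    assert combined == sorted(
        set(oracle_concept_query(datasets, uris, "AND")) & set(oracle_contrast_query(datasets, types))
    )
    # combined ⊆ each sub-result
    assert set(combined) <= set(query_concepts(index, uris, "AND").matchedDatasets)
    assert set(combined) <= set(query_image_type(index, types).matchedDatasets)


@pytest.mark.parametrize("seed", range(6))
def test_monotonicity_in_query_size(seed):
    rng = random.Random(seed)
    datasets = [random_annotated_dataset(rng, f"ds-{i:02d}") for i in range(8)]
    index = build_index(datasets)
    base = rng.sample(CONCEPT_POOL, 2)
    extra = base + [rng.choice([u for u in CONCEPT_POOL if u not in base])]
    assert set(query_concepts(index, extra, "AND").matchedDatasets) <= set(
        query_concepts(index, base, "AND").matchedDatasets
    )
    assert set(query_concepts(index, extra, "OR").matchedDatasets) >= set(
        query_concepts(index, base, "OR").matchedDatasets
    )


@pytest.mark.parametrize("seed", range(4))
def test_variable_names_never_affect_results(seed):
    """Renaming every variable (isAbout links unchanged) leaves the matched
    dataset set identical — queries act on concepts, not names."""
    rng = random.Random(seed)
    datasets = [random_annotated_dataset(rng, f"ds-{i:02d}") for i in range(6)]
    renamed = []
    for ds in datasets:
        clone = copy.deepcopy(ds)
        mapping = {k: f"renamed_{j:03d}" for j, k in enumerate(sorted(clone.dataDictionary))}
        clone.dataDictionary = {mapping[k]: v for k, v in clone.dataDictionary.items()}
        clone.subjectRows = [
            (sid, {mapping[k]: v for k, v in row.items()}) for sid, row in clone.subjectRows
        ]
        renamed.append(clone)
    uris = rng.sample(CONCEPT_POOL, 2)
    for combinator in ("AND", "OR"):
        assert (
            query_concepts(build_index(datasets), uris, combinator).matchedDatasets
            == query_concepts(build_index(renamed), uris, combinator).matchedDatasets
        )


def test_name_scan_is_name_dependent(pair_index):
    assert scan_variable_name(pair_index, "handedness") == ["A"]
    assert scan_variable_name(pair_index, "ehi") == ["B"]
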