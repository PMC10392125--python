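"""Shared fixtures and randomized-model builders for the test suite."""

from __future__ import annotations

import random
import string

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from neuroterms.dataset_ingest import AcquisitionRecord, AnnotatedDataset, SUFFIX_TABLE
from neuroterms.term_model import (
    ChoiceLevel,
    Concept,
    ConceptRef,
    DataElement,
    TermIdentifier,
)

WORDS = (
    "age", "sex", "handedness", "score", "months", "years", "iq", "memory",
    "depression", "anxiety", "total", "raw", "left", "right", "index",
)

CONCEPT_POOL = tuple(
    f"https://terms.example.org/concepts/c{i:02d}" for i in range(8)
)


def random_identifier(rng: random.Random) -> TermIdentifier:
    token = "".join(rng.choices(string.ascii_lowercase, k=8))
    return TermIdentifier(f"https://terms.example.org/terms/t/{token}")


def random_data_element(rng: random.Random, element_type: str | None = None) -> DataElement:
    """A randomized element covering arbitrary subsets of the optional
    properties; may or may not conform to the default shapes."""
    etype = element_type or rng.choice(("PDE", "CDE"))
    label = rng.choice(WORDS)
    kwargs: dict = {}
    if rng.random() < 0.8:
        kwargs["description"] = f"{label} of participant"
    if etype == "PDE" and rng.random() < 0.85:
        kwargs["sourceVariable"] = label + rng.choice(("", "_raw", "_total"))
    if rng.random() < 0.85:
        kwargs["valueType"] = rng.choice(
            ("xsd:int", "xsd:float", "xsd:string", "xsd:bool", "banana")
        )
    if rng.random() < 0.4:
        kwargs["unitCode"] = rng.choice(("years", "months", "mm"))
    if rng.random() < 0.4:
        lo, hi = sorted(rng.sample(range(-50, 200), 2))
        kwargs["minValue"], kwargs["maxValue"] = lo, hi
    if rng.random() < 0.4:
        n = rng.randint(1, 4)
        kwargs["choices"] = [
            ChoiceLevel(code=i, meaning=rng.choice(WORDS) + str(i)) for i in range(n)
        ]
    if rng.random() < 0.5:
        kwargs["isAbout"] = [
            ConceptRef(url=TermIdentifier(uri), label=None)
            for uri in rng.sample(CONCEPT_POOL, rng.randint(1, 2))
        ]
    if rng.random() < 0.2:
        kwargs["associatedWith"] = rng.sample(("BIDS", "NIDM", "local"), rng.randint(1, 2))
    return DataElement(
        identifier=random_identifier(rng),
        elementType=etype,
        label=label,
        **kwargs,
    )


def random_concept(rng: random.Random) -> Concept:
    label = " ".join(rng.sample(WORDS, rng.randint(1, 2)))
    return Concept(
        identifier=random_identifier(rng),
        label=label,
        definition=f"{label} is a notion measured in studies." if rng.random() < 0.9 else "",
    )


def random_annotated_dataset(rng: random.Random, dataset_id: str) -> AnnotatedDataset:
    """An in-memory dataset with random concept annotations and acquisitions."""
    n_vars = rng.randint(1, 15)
    dictionary = {}
    for i in range(n_vars):
        key = f"var_{i:02d}"
        element = random_data_element(rng, "PDE")
        dictionary[key] = element
    n_subj = rng.randint(0, 4)
    rows = [
        (f"sub-{j:02d}", {k: (str(rng.randint(0, 9)) if rng.random() < 0.8 else None) for k in dictionary})
        for j in range(n_subj)
    ]
    suffixes = list(SUFFIX_TABLE)
    acquisitions = []
    for j in range(rng.randint(0, 4)):
        suffix = rng.choice(suffixes)
        contrast, usage = SUFFIX_TABLE[suffix]
        sub = f"{j:02d}"
        acquisitions.append(
            AcquisitionRecord(
                subjectId=sub,
                sessionId=None,
                filePath=f"sub-{sub}/anat/sub-{sub}_{suffix}.nii.gz",
                imageContrastType=contrast,
                imageUsageType=usage,
            )
        )
    return AnnotatedDataset(
        datasetId=dataset_id,
        dataDictionary=dictionary,
        subjectRows=rows,
        acquisitions=acquisitions,
    )


@pytest.fixture()
def worked_example(tmp_path):
    from neuroterms.fixtures import generate_worked_example

    return generate_worked_example(tmp_path / "worked")


@pytest.fixture()
def registry_path(tmp_path):
    from neuroterms.fixtures import generate_registry

    return generate_registry(tmp_path / "registry.jsonld")
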