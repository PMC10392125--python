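"""Deterministic generator of synthetic multi-site BIDS datasets.

Emulates the situation the annotation tooling exists for: several sites of
one study each publish their own BIDS dataset, collecting the same
phenotype variables but spelling the headers differently (capitalization,
space/dash/underscore separators, stray leading or trailing separators).
Imaging files are zero-byte placeholders with valid BIDS names — ingestion
identifies images by name only, so no NIfTI payload is ever needed.  A
given spec and seed reproduce the output byte for byte.

The generator exercises structure (names, annotations, file layout), not
statistics: phenotype values are drawn uniformly and carry no covariance,
site effects or realistic distributions.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "VariableSpec",
    "FixtureSpec",
    "CONCEPT_NS",
    "HANDEDNESS_URI",
    "AGE_URI",
    "SEX_URI",
    "DEFAULT_VARIABLES",
    "perturb_name",
    "generate_sites",
    "generate_registry",
    "generate_worked_example",
]

#: Reserved example namespace for fixture concepts (real terminology URIs —
#: e.g. the InterLex handedness-assessment term — belong to documentation,
#: not fixtures).
CONCEPT_NS = "https://terms.example.org/concepts"
HANDEDNESS_URI = f"{CONCEPT_NS}/handedness-assessment"
AGE_URI = f"{CONCEPT_NS}/age"
SEX_URI = f"{CONCEPT_NS}/sex"


@dataclass(frozen=True)
class VariableSpec:
    canonicalName: str
    valueType: str = "xsd:int"
    unitCode: str | None = None
    choices: tuple[tuple[int | str, str], ...] = ()
    conceptURI: str | None = None
    conceptLabel: str | None = None
    minValue: int | None = None
    maxValue: int | None = None


DEFAULT_VARIABLES: tuple[VariableSpec, ...] = (
    VariableSpec("age months", valueType="xsd:int", unitCode="months",
                 conceptURI=AGE_URI, conceptLabel="age",
                 minValue=0, maxValue=1200),
    VariableSpec("sex", valueType="xsd:string",
                 choices=(("M", "male"), ("F", "female")),
                 conceptURI=SEX_URI, conceptLabel="sex"),
    VariableSpec("handedness", valueType="xsd:int",
                 choices=((1, "Right"), (5, "Left"), (10, "Ambidextrous")),
                 conceptURI=HANDEDNESS_URI, conceptLabel="handedness assessment"),
)


@dataclass(frozen=True)
class FixtureSpec:
    nSites: int = 3
    nSubjectsPerSite: int = 4
    variables: tuple[VariableSpec, ...] = DEFAULT_VARIABLES
    imageSuffixes: tuple[str, ...] = ("T1w", "bold")
    heterogeneity: frozenset[str] = frozenset({"case", "separator"})
    seed: int = 0
    missingRate: float = 0.1


# --------------------------------------------------------------------------
# name perturbation

_CASE_FORMS = (
    lambda s: s,
    lambda s: s.upper(),
    lambda s: s.title(),
)
_SEPARATORS = ("_", "-", " ")


def perturb_name(name: str, heterogeneity: frozenset[str], rng: random.Random) -> str:
    """A surface variant of *name* that normalizes back to the same key.

    Only separators, case and leading/trailing separator decoration are
    touched; alphanumeric tokens are never altered, so
    ``normalize_variable_name`` maps every variant onto the canonical name.
    """
    tokens = [t for t in name.replace("-", " ").replace("_", " ").split() if t]
    sep = rng.choice(_SEPARATORS) if "separator" in heterogeneity else "_"
    variant = sep.join(tokens)
    if "case" in heterogeneity:
        variant = rng.choice(_CASE_FORMS)(variant)
    if "spelling-suffix" in heterogeneity and rng.random() < 0.5:
        variant = variant + rng.choice(("_", " ", "-"))
    return variant


_USAGE_DIR = {"Anatomical": "anat", "Functional": "func", "Diffusion": "dwi"}


def _sidecar_entry(var: VariableSpec) -> dict:
    entry: dict = {
        "Description": f"{var.canonicalName} measurement",
        "ValueType": var.valueType,
    }
    if var.unitCode:
        entry["Units"] = var.unitCode
    if var.choices:
        entry["Levels"] = {str(code): meaning for code, meaning in var.choices}
    if var.minValue is not None:
        entry["MinValue"] = var.minValue
    if var.maxValue is not None:
        entry["MaxValue"] = var.maxValue
    if var.conceptURI:
        entry["isAbout"] = {"url": var.conceptURI}
        if var.conceptLabel:
            entry["isAbout"]["label"] = var.conceptLabel
    return entry


def _value_for(var: VariableSpec, rng: random.Random) -> str:
    if var.choices:
        return str(rng.choice([code for code, _ in var.choices]))
    low = var.minValue if var.minValue is not None else 0
    high = var.maxValue if var.maxValue is not None else 100
    return str(rng.randint(low, high))


def _write_site(
    site_dir: Path, spec: FixtureSpec, rng: random.Random
) -> None:
    from .dataset_ingest import SUFFIX_TABLE

    site_dir.mkdir(parents=True, exist_ok=True)
    headers = {
        var.canonicalName: perturb_name(var.canonicalName, spec.heterogeneity, rng)
        for var in spec.variables
    }
    lines = ["participant_id\t" + "\t".join(headers[v.canonicalName] for v in spec.variables)]
    for i in range(1, spec.nSubjectsPerSite + 1):
        sid = f"sub-{i:02d}"
        cells = [
            "n/a" if rng.random() < spec.missingRate else _value_for(var, rng)
            for var in spec.variables
        ]
        lines.append(sid + "\t" + "\t".join(cells))
    (site_dir / "participants.tsv").write_text("\n".join(lines) + "\n")

    sidecar = {
        headers[var.canonicalName]: _sidecar_entry(var) for var in spec.variables
    }
    (site_dir / "participants.json").write_text(json.dumps(sidecar, indent=2) + "\n")

    for i in range(1, spec.nSubjectsPerSite + 1):
        sub = f"sub-{i:02d}"
        for suffix in spec.imageSuffixes:
            _, usage = SUFFIX_TABLE[suffix]
            datatype = _USAGE_DIR.get(usage, "anat")
            img_dir = site_dir / sub / datatype
            img_dir.mkdir(parents=True, exist_ok=True)
            (img_dir / f"{sub}_{suffix}.nii.gz").touch()


def generate_sites(spec: FixtureSpec, out_dir: str | Path) -> list[Path]:
    """Write ``nSites`` BIDS directories under *out_dir*; returns their paths.

    Each site's variable headers are heterogeneity-perturbed variants of the
    canonical names; the whole tree is a pure function of the spec
    (including its seed).
    """
    out_dir = Path(out_dir)
    paths = []
    for site in range(1, spec.nSites + 1):
        rng = random.Random(f"{spec.seed}:{site}")
        site_dir = out_dir / f"site-{site:02d}"
        _write_site(site_dir, spec, rng)
        paths.append(site_dir)
    return paths


# --------------------------------------------------------------------------
# concept registry


_REGISTRY_CONCEPTS = (
    (HANDEDNESS_URI, "handedness assessment",
     "A handedness assessment is a measurement that determines the dominant hand."),
    (AGE_URI, "age",
     "Age is a duration of time from a predetermined starting point to the current moment."),
    (SEX_URI, "sex",
     "Sex is a biological characteristic distinguishing male and female organisms."),
    (f"{CONCEPT_NS}/diagnosis", "clinical diagnosis",
     "A clinical diagnosis is a determination identifying a disease or condition."),
)


def generate_registry(out_path: str | Path) -> Path:
    """Write the fixture concept registry (JSON-LD array) and return its path."""
    from .context import JSONLD_CONTEXT

    docs = [
        {
            "@context": dict(JSONLD_CONTEXT),
            "@id": uri,
            "@type": "Concept",
            "label": label,
            "definition": definition,
        }
        for uri, label, definition in _REGISTRY_CONCEPTS
    ]
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(json.dumps(docs, indent=2) + "\n")
    return out_path


# --------------------------------------------------------------------------
# the two-dataset worked example


def generate_worked_example(out_dir: str | Path) -> tuple[Path, Path]:
    """Two datasets measuring handedness under different variable names.

    Dataset one stores a categorical ``handedness`` variable (1 = Right,
    5 = Left, 10 = Ambidextrous); dataset two stores the Edinburgh
    handedness inventory as an integer ``ehi`` from −40 (left handed) to 40
    (right handed).  Both sidecars link their variable ``isAbout`` the same
    handedness-assessment concept, so a concept query finds both while a
    literal variable-name scan finds only one.
    """
    out_dir = Path(out_dir)
    ds1 = out_dir / "dataset1"
    ds1.mkdir(parents=True, exist_ok=True)
    (ds1 / "participants.tsv").write_text(
        "participant_id\thandedness\nsub-01\t1\nsub-02\t5\nsub-03\t10\n"
    )
    (ds1 / "participants.json").write_text(
        json.dumps(
            {
                "handedness": {
                    "Description": "dominant hand category",
                    "ValueType": "xsd:int",
                    "Levels": {"1": "Right", "5": "Left", "10": "Ambidextrous"},
                    "isAbout": {"url": HANDEDNESS_URI, "label": "handedness assessment"},
                }
            },
            indent=2,
        )
        + "\n"
    )
    anat = ds1 / "sub-01" / "anat"
    anat.mkdir(parents=True, exist_ok=True)
    (anat / "sub-01_T1w.nii.gz").touch()

    ds2 = out_dir / "dataset2"
    ds2.mkdir(parents=True, exist_ok=True)
    (ds2 / "participants.tsv").write_text(
        "participant_id\tehi\nsub-01\t-40\nsub-02\t40\nsub-03\t15\n"
    )
    (ds2 / "participants.json").write_text(
        json.dumps(
            {
                "ehi": {
                    "Description": "Edinburgh handedness inventory",
                    "ValueType": "xsd:int",
                    "MinValue": -40,
                    "MaxValue": 40,
                    "isAbout": {"url": HANDEDNESS_URI, "label": "handedness assessment"},
                }
            },
            indent=2,
        )
        + "\n"
    )
    anat = ds2 / "sub-01" / "anat"
    anat.mkdir(parents=True, exist_ok=True)
    (anat / "sub-01_T1w.nii.gz").touch()
    return ds1, ds2
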