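"""Local concept registry with fuzzy suggestion and prior-use ranking.

Annotators link study variables to concepts (higher-order ideas such as
"handedness assessment").  Picking the right concept out of a large
terminology is the slow step, so two devices narrow the choice:

* **fuzzy matching** — candidate concepts are ranked by a token-set
  similarity between the normalized variable name and each concept label
  (``age_months`` matches the label "age" with score 1.0, because the
  label's tokens are a subset of the variable's);
* **prior use** — concepts already chosen in earlier annotations form a
  first tier that always outranks never-used concepts, effectively reducing
  routine variables (age, sex, handedness) to a single obvious choice.

Remote terminology services can back the same interface through
:class:`ConceptSource`; the shipped implementation is a local JSON-LD
registry and needs no network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from pathlib import Path
from typing import Protocol

from .naming import tokenize
from .term_model import Concept, FormatError, TermError, TermIdentifier, element_from_dict

__all__ = [
    "ConceptRegistry",
    "Suggestion",
    "ConceptSource",
    "DEFAULT_THRESHOLD",
    "token_set_ratio",
    "load_registry",
    "save_used_concepts",
    "suggest_concepts",
    "record_used_concept",
]

#: Minimum similarity for a concept to be suggested at all.
DEFAULT_THRESHOLD = 0.5


class ConceptSource(Protocol):
    """Anything that can search concepts by text (local registry, remote
    terminology service)."""

    def search(self, text: str) -> list[Concept]: ...


@dataclass
class ConceptRegistry:
    concepts: dict[TermIdentifier, Concept] = field(default_factory=dict)
    usedConcepts: list[TermIdentifier] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for ident in self.usedConcepts:
            if ident in seen:
                raise TermError(f"duplicate used-concept entry {ident}")
            if ident not in self.concepts:
                raise TermError(f"used concept {ident} not in registry")
            seen.add(ident)

    def search(self, text: str) -> list[Concept]:
        return [
            s.concept
            for s in suggest_concepts(text, self, limit=len(self.concepts) or 1)
        ]


@dataclass(frozen=True)
class Suggestion:
    concept: Concept
    score: float
    fromUsedList: bool


# --------------------------------------------------------------------------
# similarity


def token_set_ratio(a: str, b: str) -> float:
    """Token-set similarity in [0, 1] between two names.

    Both names are case-folded and split on separators; the score is the
    best sequence ratio among the sorted-token combinations of the shared
    and distinct tokens, so token order is irrelevant and a name whose
    tokens include the other's scores 1.0.
    """
    try:
        ta, tb = set(tokenize(a)), set(tokenize(b))
    except ValueError:
        return 0.0
    if not ta or not tb:
        return 0.0
    inter = " ".join(sorted(ta & tb))
    sa = (inter + " " + " ".join(sorted(ta - tb))).strip()
    sb = (inter + " " + " ".join(sorted(tb - ta))).strip()
    if ta & tb:
        if inter == sa or inter == sb:
            return 1.0
    return max(
        SequenceMatcher(None, inter, sa).ratio() if inter else 0.0,
        SequenceMatcher(None, inter, sb).ratio() if inter else 0.0,
        SequenceMatcher(None, sa, sb).ratio(),
    )


# --------------------------------------------------------------------------
# registry IO


def load_registry(path: str | Path, used_path: str | Path | None = None) -> ConceptRegistry:
    """Load a JSON-LD concept registry (an array of concept documents, or an
    object with an ``@graph`` array).

    A used-concepts file — JSON array of identifier URIs — is read from
    *used_path*, or from ``<stem>_used.json`` next to the registry when one
    exists.  Duplicate identifiers are an error.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except (json.JSONDecodeError, ValueError) as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    docs = doc.get("@graph", []) if isinstance(doc, dict) else doc
    if not isinstance(docs, list):
        raise FormatError(f"{path}: expected an array of concept documents")
    concepts: dict[TermIdentifier, Concept] = {}
    for entry in docs:
        element = element_from_dict(entry)
        if not isinstance(element, Concept):
            continue
        if element.identifier in concepts:
            raise TermError(f"{path}: duplicate concept identifier {element.identifier}")
        concepts[element.identifier] = element

    if used_path is None:
        candidate = path.with_name(path.stem + "_used.json")
        used_path = candidate if candidate.is_file() else None
    used: list[TermIdentifier] = []
    if used_path is not None:
        used = [TermIdentifier(u) for u in json.loads(Path(used_path).read_text())]
    return ConceptRegistry(concepts=concepts, usedConcepts=used)


def save_used_concepts(registry: ConceptRegistry, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([i.uri for i in registry.usedConcepts], indent=2)
    )


# --------------------------------------------------------------------------
# suggestion


def suggest_concepts(
    variable_name: str,
    registry: ConceptRegistry,
    limit: int = 5,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[Suggestion]:
    """Ranked concept suggestions for a study variable name.

    Previously used concepts scoring at or above *threshold* form the first
    tier; remaining registry concepts the second.  Within a tier the order
    is score descending, ties broken by label.  Returns at most *limit*
    suggestions; an unmatchable name yields an empty list.
    """
    if not variable_name:
        raise TermError("variable name must be non-empty")
    if limit < 1:
        raise TermError("limit must be positive")
    used = set(registry.usedConcepts)
    scored = []
    for ident, concept in registry.concepts.items():
        score = token_set_ratio(variable_name, concept.label)
        if score >= threshold:
            scored.append(
                Suggestion(concept=concept, score=score, fromUsedList=ident in used)
            )
    scored.sort(
        key=lambda s: (not s.fromUsedList, -s.score, s.concept.label, s.concept.identifier.uri)
    )
    return scored[:limit]


def record_used_concept(
    registry: ConceptRegistry, concept: TermIdentifier | str
) -> ConceptRegistry:
    """Append *concept* to the used list (idempotent); it must exist in the
    registry."""
    ident = concept if isinstance(concept, TermIdentifier) else TermIdentifier(concept)
    if ident not in registry.concepts:
        raise TermError(f"concept {ident} not in registry")
    if ident not in registry.usedConcepts:
        registry.usedConcepts.append(ident)
    return registry
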