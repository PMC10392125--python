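"""Shape-based validation of term records.

Each element type (personal data element, common data element, concept) has
a shape: a set of per-property constraints giving minimum/maximum
cardinality, the kind of value expected, and — for controlled properties
such as ``valueType`` — the list of allowed values.  The engine is a small,
explicit constraint checker over the in-memory model (the constraint kinds
are required properties, value kinds and cardinalities; it is not a general
SHACL processor).

Shapes are data, not code: :func:`default_shapes` builds the shipped
defaults and :func:`load_shapes` reads a user-supplied JSON shapes file with
the same structure, so communities can tighten or relax the requirements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

from .term_model import ChoiceLevel, Concept, ConceptRef, DataElement, TermIdentifier

__all__ = [
    "PropertyConstraint",
    "ValidationShape",
    "Violation",
    "ValidationReport",
    "ShapeConfigurationError",
    "CONTROLLED_VALUE_TYPES",
    "CATEGORICAL_VALUE_TYPES",
    "default_shapes",
    "load_shapes",
    "shapes_to_json",
    "validate_element",
    "validate_collection",
]

#: Controlled vocabulary for the ``valueType`` property.
CONTROLLED_VALUE_TYPES = (
    "xsd:int",
    "xsd:float",
    "xsd:string",
    "xsd:bool",
    "xsd:date",
    "xsd:dateTime",
)

#: Value types compatible with a categorical (choices-bearing) element.
CATEGORICAL_VALUE_TYPES = ("xsd:int", "xsd:string")

VALUE_KINDS = ("text", "number", "conceptRef", "choiceList", "identifier", "controlledText")


class ShapeConfigurationError(ValueError):
    """No shape available for an element's type, or a malformed shapes file."""


@dataclass(frozen=True)
class PropertyConstraint:
    propertyName: str
    minCount: int = 0
    maxCount: int | None = 1  # None = unbounded
    valueKind: str = "text"
    allowedValues: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.minCount < 0:
            raise ShapeConfigurationError("minCount must be non-negative")
        if self.maxCount is not None and self.minCount > self.maxCount:
            raise ShapeConfigurationError(
                f"minCount {self.minCount} exceeds maxCount {self.maxCount} "
                f"for {self.propertyName}"
            )
        if self.valueKind not in VALUE_KINDS:
            raise ShapeConfigurationError(f"unknown value kind {self.valueKind!r}")


@dataclass
class ValidationShape:
    targetType: str  # "PDE" | "CDE" | "Concept"
    constraints: list[PropertyConstraint] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.propertyName for c in self.constraints]
        if len(set(names)) != len(names):
            raise ShapeConfigurationError(
                f"duplicate constraints in shape for {self.targetType}"
            )


class Violation(NamedTuple):
    elementIdentifier: str
    propertyName: str
    constraintKind: str  # minCount | maxCount | valueKind | allowedValues | configuration
    message: str


@dataclass
class ValidationReport:
    conforms: bool
    violations: list[Violation] = field(default_factory=list)
    warnings: list[Violation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.conforms = not self.violations


def default_shapes() -> list[ValidationShape]:
    """The three shipped shapes, one per element type.

    A personal data element must say what variable it came from and how its
    values are represented (label, description, source variable, value
    type); a community element needs the same minus the source variable; a
    concept needs an identifier, a label and a definition.  ``valueType``
    values are constrained to the controlled vocabulary.
    """
    value_type = PropertyConstraint(
        "valueType", minCount=1, maxCount=1, valueKind="controlledText",
        allowedValues=CONTROLLED_VALUE_TYPES,
    )
    optional_common = [
        PropertyConstraint("unitCode", 0, 1, "text"),
        PropertyConstraint("minValue", 0, 1, "number"),
        PropertyConstraint("maxValue", 0, 1, "number"),
        PropertyConstraint("choices", 0, 1, "choiceList"),
        PropertyConstraint("isAbout", 0, None, "conceptRef"),
        PropertyConstraint("measureOf", 0, 1, "conceptRef"),
        PropertyConstraint("datumType", 0, 1, "conceptRef"),
        PropertyConstraint("isPartOf", 0, 1, "conceptRef"),
        PropertyConstraint("subtypeCDEs", 0, None, "identifier"),
        PropertyConstraint("supertypeCDEs", 0, None, "identifier"),
        PropertyConstraint("associatedWith", 0, None, "text"),
    ]
    pde = ValidationShape(
        "PDE",
        [
            PropertyConstraint("label", 1, 1, "text"),
            PropertyConstraint("description", 1, 1, "text"),
            PropertyConstraint("sourceVariable", 1, 1, "text"),
            value_type,
            *optional_common,
        ],
    )
    cde = ValidationShape(
        "CDE",
        [
            PropertyConstraint("label", 1, 1, "text"),
            PropertyConstraint("description", 1, 1, "text"),
            value_type,
            PropertyConstraint("sourceVariable", 0, 1, "text"),
            *optional_common,
        ],
    )
    concept = ValidationShape(
        "Concept",
        [
            PropertyConstraint("identifier", 1, 1, "identifier"),
            PropertyConstraint("label", 1, 1, "text"),
            PropertyConstraint("definition", 1, 1, "text"),
        ],
    )
    return [pde, cde, concept]


# --------------------------------------------------------------------------
# shapes file IO


def shapes_to_json(shapes: list[ValidationShape]) -> str:
    docs = [
        {
            "targetType": s.targetType,
            "constraints": [
                {
                    "propertyName": c.propertyName,
                    "minCount": c.minCount,
                    "maxCount": c.maxCount,
                    "valueKind": c.valueKind,
                    "allowedValues": list(c.allowedValues) if c.allowedValues else None,
                }
                for c in s.constraints
            ],
        }
        for s in shapes
    ]
    return json.dumps(docs, indent=2)


def load_shapes(path: str | Path) -> list[ValidationShape]:
    """Read a declarative JSON shapes file (same structure as the defaults)."""
    try:
        docs = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, ValueError) as exc:
        raise ShapeConfigurationError(f"malformed shapes file {path}: {exc}") from exc
    if not isinstance(docs, list):
        raise ShapeConfigurationError("shapes file must hold a JSON array of shapes")
    shapes = []
    for doc in docs:
        constraints = [
            PropertyConstraint(
                propertyName=c["propertyName"],
                minCount=c.get("minCount", 0),
                maxCount=c.get("maxCount", 1),
                valueKind=c.get("valueKind", "text"),
                allowedValues=tuple(c["allowedValues"]) if c.get("allowedValues") else None,
            )
            for c in doc.get("constraints", [])
        ]
        shapes.append(ValidationShape(doc["targetType"], constraints))
    return shapes


# --------------------------------------------------------------------------
# the engine


def property_values(element: DataElement | Concept, name: str) -> list:
    """The occurrences of property *name* on *element*, as a flat list.

    Empty strings count as absent; list-valued properties contribute one
    occurrence per entry, except ``choices`` which is one occurrence (one
    choice list) when non-empty.
    """
    if name == "identifier":
        return [element.identifier]
    value = getattr(element, name, None)
    if value is None or value == "":
        return []
    if name == "choices":
        return [value] if value else []
    if isinstance(value, list):
        return list(value)
    return [value]


def _kind_ok(value, kind: str) -> bool:
    if kind == "text" or kind == "controlledText":
        return isinstance(value, str) and bool(value)
    if kind == "number":
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if kind == "conceptRef":
        return isinstance(value, ConceptRef)
    if kind == "identifier":
        return isinstance(value, TermIdentifier)
    if kind == "choiceList":
        return isinstance(value, list) and all(isinstance(c, ChoiceLevel) for c in value)
    return False


def _element_type(element: DataElement | Concept) -> str:
    return "Concept" if isinstance(element, Concept) else element.elementType


def _check(element: DataElement | Concept, shape: ValidationShape) -> tuple[list, list]:
    ident = element.identifier.uri
    violations: list[Violation] = []
    warns: list[Violation] = []
    for constraint in shape.constraints:
        values = property_values(element, constraint.propertyName)
        n = len(values)
        if n < constraint.minCount:
            violations.append(
                Violation(
                    ident,
                    constraint.propertyName,
                    "minCount",
                    f"{constraint.propertyName}: {n} occurrence(s), "
                    f"at least {constraint.minCount} required",
                )
            )
        if constraint.maxCount is not None and n > constraint.maxCount:
            violations.append(
                Violation(
                    ident,
                    constraint.propertyName,
                    "maxCount",
                    f"{constraint.propertyName}: {n} occurrence(s), "
                    f"at most {constraint.maxCount} allowed",
                )
            )
        for value in values:
            if not _kind_ok(value, constraint.valueKind):
                violations.append(
                    Violation(
                        ident,
                        constraint.propertyName,
                        "valueKind",
                        f"{constraint.propertyName}: {value!r} is not of kind "
                        f"{constraint.valueKind}",
                    )
                )
            elif constraint.allowedValues is not None and value not in constraint.allowedValues:
                violations.append(
                    Violation(
                        ident,
                        constraint.propertyName,
                        "allowedValues",
                        f"{constraint.propertyName}: {value!r} not in "
                        f"{list(constraint.allowedValues)}",
                    )
                )
    if isinstance(element, DataElement):
        # a categorical element's codes must be representable by its value type
        if element.choices and element.valueType not in (None, *CATEGORICAL_VALUE_TYPES):
            violations.append(
                Violation(
                    ident,
                    "valueType",
                    "valueKind",
                    f"valueType {element.valueType!r} incompatible with categorical "
                    f"choices (expected one of {list(CATEGORICAL_VALUE_TYPES)})",
                )
            )
        # missing units on a non-categorical numeric element hinders reuse
        if (
            element.valueType in ("xsd:int", "xsd:float")
            and not element.choices
            and not element.unitCode
        ):
            warns.append(
                Violation(
                    ident,
                    "unitCode",
                    "recommended",
                    "numeric element without unitCode; units are needed to reuse values",
                )
            )
    return violations, warns


_SORT_KEY = lambda v: (v.elementIdentifier, v.propertyName, v.constraintKind, v.message)


def validate_element(
    element: DataElement | Concept, shapes: list[ValidationShape] | None = None
) -> ValidationReport:
    """Check one element against the shape for its type.

    The report lists one violation per breached constraint, in a
    deterministic order (element identifier, then property name, then
    constraint kind).  Raises :class:`ShapeConfigurationError` when *shapes*
    holds no shape for the element's type.
    """
    shapes = default_shapes() if shapes is None else shapes
    etype = _element_type(element)
    matching = [s for s in shapes if s.targetType == etype]
    if not matching:
        raise ShapeConfigurationError(f"no shape for element type {etype}")
    violations: list[Violation] = []
    warns: list[Violation] = []
    for shape in matching:
        v, w = _check(element, shape)
        violations.extend(v)
        warns.extend(w)
    return ValidationReport(
        conforms=not violations,
        violations=sorted(violations, key=_SORT_KEY),
        warnings=sorted(warns, key=_SORT_KEY),
    )


def validate_collection(
    elements: list, shapes: list[ValidationShape] | None = None
) -> ValidationReport:
    """Concatenated per-element reports; conforms iff every element does.

    A missing shape for some element's type becomes a ``configuration``
    violation rather than an exception, so one bad record cannot hide the
    rest of the report.
    """
    shapes = default_shapes() if shapes is None else shapes
    violations: list[Violation] = []
    warns: list[Violation] = []
    for element in elements:
        try:
            report = validate_element(element, shapes)
        except ShapeConfigurationError as exc:
            violations.append(
                Violation(element.identifier.uri, "", "configuration", str(exc))
            )
            continue
        violations.extend(report.violations)
        warns.extend(report.warnings)
    return ValidationReport(
        conforms=not violations,
        violations=sorted(violations, key=_SORT_KEY),
        warnings=sorted(warns, key=_SORT_KEY),
    )
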