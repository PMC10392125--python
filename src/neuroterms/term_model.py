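"""Domain model for annotated data elements and concepts.

The model distinguishes three kinds of terms:

* **personal data elements (PDEs)** — study-specific variables named and
  annotated locally (e.g. an ``ehi`` column holding Edinburgh handedness
  inventory scores from −40 to 40);
* **common data elements (CDEs)** — elements adopted by a community or
  standards body;
* **concepts** — higher-order ideas (e.g. "handedness assessment")
  identified by a URL and used as the target of ``isAbout`` links, which is
  what makes variables with different local names discoverable together.

Every element carries a small property set (label, description, value type,
units, range, categorical choices, concept links, …) and serializes to a
self-contained JSON-LD document with the package's fixed context, to an RDF
graph, and to tabular export formats.
"""

from __future__ import annotations

import csv
import io
import json
import re
import warnings
from dataclasses import dataclass, field

from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, URIRef
from rdflib.collection import Collection
from rdflib.namespace import DCTERMS, SKOS

from .context import CURIE_PREFIXES, DEFAULT_BASE_NAMESPACE, JSONLD_CONTEXT, NIDM
from .naming import normalize_variable_name

__all__ = [
    "TermIdentifier",
    "ConceptRef",
    "ChoiceLevel",
    "DataElement",
    "Concept",
    "TermError",
    "UnknownPropertyError",
    "RangeError",
    "ChoicesError",
    "FormatError",
    "build_data_element",
    "parse_choices",
    "format_choices",
    "to_jsonld",
    "from_jsonld",
    "export_terms",
    "element_to_graph",
    "elements_to_graph",
    "EXPORT_FORMATS",
]


class TermError(ValueError):
    """Base class for term-model errors."""


class UnknownPropertyError(TermError):
    pass


class RangeError(TermError):
    pass


class ChoicesError(TermError):
    pass


class FormatError(TermError):
    pass


# --------------------------------------------------------------------------
# identifiers


@dataclass(frozen=True, order=True)
class TermIdentifier:
    """An absolute URI naming a term.

    CURIEs with a registered prefix (``ILX:0104886``) are expanded before
    storage; two identifiers are equal iff their expanded URI texts are.
    """

    uri: str

    def __post_init__(self) -> None:
        if not self.uri or not isinstance(self.uri, str):
            raise TermError("term identifier must be non-empty text")
        if "://" not in self.uri:
            prefix, sep, local = self.uri.partition(":")
            expansion = CURIE_PREFIXES.get(prefix.lower())
            if not (sep and local and expansion):
                raise TermError(
                    f"identifier {self.uri!r} is neither an absolute URI nor a "
                    f"CURIE with a registered prefix ({sorted(CURIE_PREFIXES)})"
                )
            object.__setattr__(self, "uri", expansion + local)

    def __str__(self) -> str:
        return self.uri


@dataclass(frozen=True, order=True)
class ConceptRef:
    """A link target: the concept's URL plus an optional display label."""

    url: TermIdentifier
    label: str | None = None

    def __post_init__(self) -> None:
        if isinstance(self.url, str):
            object.__setattr__(self, "url", TermIdentifier(self.url))


@dataclass(frozen=True)
class ChoiceLevel:
    """One categorical level: a code (often an integer) and its meaning."""

    code: int | float | str
    meaning: str

    def __post_init__(self) -> None:
        if not self.meaning:
            raise ChoicesError("choice meaning must be non-empty")


def _as_concept_ref(value) -> ConceptRef:
    if isinstance(value, ConceptRef):
        return value
    if isinstance(value, TermIdentifier):
        return ConceptRef(url=value)
    if isinstance(value, str):
        return ConceptRef(url=TermIdentifier(value))
    if isinstance(value, dict):
        url = value.get("url") or value.get("@id")
        if not url:
            raise FormatError(f"concept reference {value!r} lacks a url")
        return ConceptRef(url=TermIdentifier(url), label=value.get("label"))
    raise FormatError(f"cannot interpret {value!r} as a concept reference")


# --------------------------------------------------------------------------
# elements


@dataclass
class DataElement:
    """One annotated study variable (PDE) or community term (CDE)."""

    identifier: TermIdentifier
    elementType: str  # "PDE" | "CDE"
    label: str
    description: str = ""
    sourceVariable: str | None = None
    valueType: str | None = None
    unitCode: str | None = None
    minValue: int | float | None = None
    maxValue: int | float | None = None
    choices: list[ChoiceLevel] = field(default_factory=list)
    isAbout: list[ConceptRef] = field(default_factory=list)
    measureOf: ConceptRef | None = None
    datumType: ConceptRef | None = None
    isPartOf: ConceptRef | None = None
    subtypeCDEs: list[TermIdentifier] = field(default_factory=list)
    supertypeCDEs: list[TermIdentifier] = field(default_factory=list)
    associatedWith: list[str] = field(default_factory=list)
    #: unknown keys met on import; preserved, reported, never compared
    extra: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.elementType not in ("PDE", "CDE"):
            raise TermError(f"elementType must be PDE or CDE, got {self.elementType!r}")
        if (
            self.minValue is not None
            and self.maxValue is not None
            and self.minValue > self.maxValue
        ):
            raise RangeError(
                f"minValue {self.minValue} exceeds maxValue {self.maxValue}"
            )
        codes = [c.code for c in self.choices]
        if len(set(codes)) != len(codes):
            raise ChoicesError(f"duplicate choice codes in {codes!r}")
        # unordered link sets are kept sorted so RDF round trips are identities
        self.isAbout = sorted(self.isAbout)
        self.subtypeCDEs = sorted(self.subtypeCDEs)
        self.supertypeCDEs = sorted(self.supertypeCDEs)
        self.associatedWith = sorted(self.associatedWith)


@dataclass
class Concept:
    """A higher-order idea used as an annotation target."""

    identifier: TermIdentifier
    label: str
    definition: str = ""
    extra: dict = field(default_factory=dict, compare=False, repr=False)


#: Table of recognised data-element properties (lowerCamelCase canonical form).
PROPERTY_NAMES = (
    "description",
    "label",
    "valueType",
    "unitCode",
    "maxValue",
    "minValue",
    "choices",
    "isAbout",
    "sourceVariable",
    "measureOf",
    "datumType",
    "isPartOf",
    "subtypeCDEs",
    "supertypeCDEs",
    "associatedWith",
)

_CANONICAL = {re.sub(r"[^a-z0-9]", "", n.lower()): n for n in PROPERTY_NAMES}


def canonical_property_name(name: str) -> str:
    """Normalize property-name casing: ``Source_variable`` → ``sourceVariable``.

    Raises :class:`UnknownPropertyError` for names outside the property set.
    """
    key = re.sub(r"[^a-z0-9]", "", name.lower())
    # legacy spellings seen in the wild
    aliases = {"units": "unitCode", "levels": "choices", "hasunits": "unitCode"}
    key = aliases.get(key, key)
    try:
        return _CANONICAL[key]
    except KeyError:
        raise UnknownPropertyError(f"unknown property {name!r}") from None


def build_data_element(
    source_variable: str,
    properties: dict | None = None,
    *,
    element_type: str = "PDE",
    dataset_id: str = "local",
    base_namespace: str = DEFAULT_BASE_NAMESPACE,
) -> DataElement:
    """Assemble a data element from a variable name and a property mapping.

    Identifiers are minted deterministically as
    ``<base-namespace>/<dataset-id>/<normalized-variable-name>`` so that
    re-annotating the same dataset always produces the same term URI.
    Construction is permissive: completeness (required properties, controlled
    value types) is the job of shape validation, not of this constructor.
    """
    if element_type == "PDE" and not source_variable:
        raise TermError("a personal data element needs a source variable name")
    props: dict = {}
    for name, value in (properties or {}).items():
        props[canonical_property_name(name)] = value

    choices = props.pop("choices", [])
    if isinstance(choices, str):
        choices = parse_choices(choices)
    elif isinstance(choices, dict):
        choices = [ChoiceLevel(code=_coerce_code(k), meaning=str(v)) for k, v in choices.items()]
    else:
        choices = [c if isinstance(c, ChoiceLevel) else ChoiceLevel(**c) for c in choices]

    is_about = props.pop("isAbout", [])
    if not isinstance(is_about, list):
        is_about = [is_about]
    is_about = [_as_concept_ref(c) for c in is_about]

    for ref_field in ("measureOf", "datumType", "isPartOf"):
        if props.get(ref_field) is not None:
            props[ref_field] = _as_concept_ref(props[ref_field])
    for id_field in ("subtypeCDEs", "supertypeCDEs"):
        props[id_field] = [
            i if isinstance(i, TermIdentifier) else TermIdentifier(i)
            for i in props.get(id_field, [])
        ]

    key = normalize_variable_name(source_variable) if source_variable else props.get("label", "term")
    identifier = TermIdentifier(f"{base_namespace.rstrip('/')}/{dataset_id}/{key}")
    return DataElement(
        identifier=identifier,
        elementType=element_type,
        label=props.pop("label", source_variable),
        sourceVariable=source_variable if element_type == "PDE" else props.pop("sourceVariable", None),
        choices=choices,
        isAbout=is_about,
        **{k: v for k, v in props.items() if k not in ("label", "sourceVariable")},
    )


# --------------------------------------------------------------------------
# choices text


def _coerce_code(text) -> int | float | str:
    if isinstance(text, (int, float)):
        return text
    s = str(text).strip()
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        return s


_PAIR_SPLIT = re.compile(r"[,;]")


def parse_choices(text: str) -> list[ChoiceLevel]:
    """Parse a categorical value mapping written as text.

    Accepted dialects: brace-wrapped or bare ``code = meaning`` lists
    separated by commas or semicolons (``{1 = Right, 5 = Left, 10 =
    Ambidextrous}``), and JSON objects mapping codes to meanings.
    Numeric-looking codes become numbers; order is preserved.
    """
    if text is None:
        return []
    stripped = text.strip()
    if not stripped:
        return []
    try:
        doc = json.loads(stripped)
    except (json.JSONDecodeError, ValueError):
        doc = None
    if isinstance(doc, dict):
        pairs = [(_coerce_code(k), str(v)) for k, v in doc.items()]
    else:
        if stripped.startswith("{") and stripped.endswith("}"):
            stripped = stripped[1:-1]
        pairs = []
        for fragment in _PAIR_SPLIT.split(stripped):
            fragment = fragment.strip()
            if not fragment:
                continue
            code_text, eq, meaning = fragment.partition("=")
            if not eq or not code_text.strip() or not meaning.strip():
                raise ChoicesError(f"cannot parse choices fragment {fragment!r}")
            pairs.append((_coerce_code(code_text), meaning.strip()))
    codes = [c for c, _ in pairs]
    dupes = {c for c in codes if codes.count(c) > 1}
    if dupes:
        raise ChoicesError(f"duplicate choice codes: {sorted(map(str, dupes))}")
    return [ChoiceLevel(code=c, meaning=m) for c, m in pairs]


def format_choices(levels: list[ChoiceLevel]) -> str:
    """Canonical textual form of a choices list; inverse of :func:`parse_choices`."""
    return "{" + ", ".join(f"{lvl.code} = {lvl.meaning}" for lvl in levels) + "}"


# --------------------------------------------------------------------------
# JSON-LD


def _element_to_dict(element: DataElement | Concept, with_context: bool = True) -> dict:
    doc: dict = {}
    if with_context:
        doc["@context"] = dict(JSONLD_CONTEXT)
    doc["@id"] = element.identifier.uri
    if isinstance(element, Concept):
        doc["@type"] = "Concept"
        doc["label"] = element.label
        if element.definition:
            doc["definition"] = element.definition
        return doc
    doc["@type"] = (
        "PersonalDataElement" if element.elementType == "PDE" else "CommonDataElement"
    )
    doc["label"] = element.label
    if element.description:
        doc["description"] = element.description
    if element.sourceVariable is not None:
        doc["sourceVariable"] = element.sourceVariable
    for name in ("valueType", "unitCode", "minValue", "maxValue"):
        value = getattr(element, name)
        if value is not None:
            doc[name] = value
    if element.choices:
        doc["choices"] = [{"code": c.code, "meaning": c.meaning} for c in element.choices]
    if element.isAbout:
        doc["isAbout"] = [
            {"@id": ref.url.uri, **({"label": ref.label} if ref.label else {})}
            for ref in element.isAbout
        ]
    for name in ("measureOf", "datumType", "isPartOf"):
        ref = getattr(element, name)
        if ref is not None:
            doc[name] = {"@id": ref.url.uri, **({"label": ref.label} if ref.label else {})}
    if element.subtypeCDEs:
        doc["subtypeCDEs"] = [{"@id": i.uri} for i in element.subtypeCDEs]
    if element.supertypeCDEs:
        doc["supertypeCDEs"] = [{"@id": i.uri} for i in element.supertypeCDEs]
    if element.associatedWith:
        doc["associatedWith"] = list(element.associatedWith)
    return doc


def to_jsonld(element: DataElement | Concept) -> str:
    """Serialize one element to a self-contained JSON-LD document."""
    return json.dumps(_element_to_dict(element), indent=2, ensure_ascii=False)


_KNOWN_DOC_KEYS = {
    "@context",
    "@id",
    "@type",
    "label",
    "description",
    "definition",
    "sourceVariable",
    "valueType",
    "unitCode",
    "minValue",
    "maxValue",
    "choices",
    "isAbout",
    "measureOf",
    "datumType",
    "isPartOf",
    "subtypeCDEs",
    "supertypeCDEs",
    "associatedWith",
}


def element_from_dict(doc: dict) -> DataElement | Concept:
    """Build an element from a parsed JSON-LD document (see :func:`from_jsonld`)."""
    if not isinstance(doc, dict):
        raise FormatError("a term document must be a JSON object")
    if "@type" not in doc or "@id" not in doc:
        raise FormatError("term document lacks @id/@type")
    extra = {k: v for k, v in doc.items() if k not in _KNOWN_DOC_KEYS}
    if extra:
        warnings.warn(
            f"unknown keys in term document {doc['@id']}: {sorted(extra)}",
            stacklevel=3,
        )
    kind = doc["@type"]
    identifier = TermIdentifier(doc["@id"])
    if kind == "Concept":
        return Concept(
            identifier=identifier,
            label=doc.get("label", ""),
            definition=doc.get("definition", ""),
            extra=extra,
        )
    if kind not in ("PersonalDataElement", "CommonDataElement"):
        raise FormatError(f"unknown term document type {kind!r}")
    return DataElement(
        identifier=identifier,
        elementType="PDE" if kind == "PersonalDataElement" else "CDE",
        label=doc.get("label", ""),
        description=doc.get("description", ""),
        sourceVariable=doc.get("sourceVariable"),
        valueType=doc.get("valueType"),
        unitCode=doc.get("unitCode"),
        minValue=doc.get("minValue"),
        maxValue=doc.get("maxValue"),
        choices=[
            ChoiceLevel(code=c["code"], meaning=c["meaning"]) for c in doc.get("choices", [])
        ],
        isAbout=[_as_concept_ref(c) for c in doc.get("isAbout", [])],
        measureOf=_opt_ref(doc.get("measureOf")),
        datumType=_opt_ref(doc.get("datumType")),
        isPartOf=_opt_ref(doc.get("isPartOf")),
        subtypeCDEs=[TermIdentifier(d["@id"]) for d in doc.get("subtypeCDEs", [])],
        supertypeCDEs=[TermIdentifier(d["@id"]) for d in doc.get("supertypeCDEs", [])],
        associatedWith=list(doc.get("associatedWith", [])),
        extra=extra,
    )


def _opt_ref(value) -> ConceptRef | None:
    return None if value is None else _as_concept_ref(value)


def from_jsonld(text: str) -> DataElement | Concept:
    """Parse a JSON-LD term document back into its element.

    Inverse of :func:`to_jsonld`.  Unknown keys are preserved on the
    element's ``extra`` mapping and reported as a warning, never dropped
    silently.
    """
    try:
        doc = json.loads(text)
    except (json.JSONDecodeError, ValueError) as exc:
        raise FormatError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "@context" not in doc:
        raise FormatError("term document lacks a @context")
    return element_from_dict(doc)


# --------------------------------------------------------------------------
# RDF graph form


def element_to_graph(element: DataElement | Concept, graph: Graph | None = None) -> Graph:
    """Add one element's statements to *graph* (created if missing)."""
    g = graph if graph is not None else Graph()
    g.bind("nidm", NIDM)
    node = URIRef(element.identifier.uri)
    if isinstance(element, Concept):
        g.add((node, RDF.type, NIDM.Concept))
        g.add((node, RDFS.label, Literal(element.label)))
        if element.definition:
            g.add((node, SKOS.definition, Literal(element.definition)))
        return g
    type_uri = (
        NIDM.PersonalDataElement if element.elementType == "PDE" else NIDM.CommonDataElement
    )
    g.add((node, RDF.type, type_uri))
    g.add((node, RDFS.label, Literal(element.label)))
    if element.description:
        g.add((node, DCTERMS.description, Literal(element.description)))
    scalar = {
        "sourceVariable": NIDM.sourceVariable,
        "valueType": NIDM.valueType,
        "unitCode": NIDM.unitCode,
        "minValue": NIDM.minValue,
        "maxValue": NIDM.maxValue,
    }
    for name, pred in scalar.items():
        value = getattr(element, name)
        if value is not None:
            g.add((node, pred, Literal(value)))
    if element.choices:
        items = []
        for choice in element.choices:
            b = BNode()
            g.add((b, NIDM.choiceCode, Literal(choice.code)))
            g.add((b, NIDM.choiceMeaning, Literal(choice.meaning)))
            items.append(b)
        head = BNode()
        Collection(g, head, items)
        g.add((node, NIDM.choices, head))
    for ref in element.isAbout:
        target = URIRef(ref.url.uri)
        g.add((node, NIDM.isAbout, target))
        if ref.label:
            g.add((target, RDFS.label, Literal(ref.label)))
    single_ref = {
        "measureOf": NIDM.measureOf,
        "datumType": NIDM.datumType,
        "isPartOf": DCTERMS.isPartOf,
    }
    for name, pred in single_ref.items():
        ref = getattr(element, name)
        if ref is not None:
            target = URIRef(ref.url.uri)
            g.add((node, pred, target))
            if ref.label:
                g.add((target, RDFS.label, Literal(ref.label)))
    for ident in element.subtypeCDEs:
        g.add((node, NIDM.subtypeCDE, URIRef(ident.uri)))
    for ident in element.supertypeCDEs:
        g.add((node, NIDM.supertypeCDE, URIRef(ident.uri)))
    for community in element.associatedWith:
        g.add((node, NIDM.associatedWith, Literal(community)))
    return g


def elements_to_graph(elements: list) -> Graph:
    g = Graph()
    for element in elements:
        element_to_graph(element, g)
    return g


def _ref_from_node(g: Graph, node) -> ConceptRef:
    label = g.value(node, RDFS.label)
    return ConceptRef(url=TermIdentifier(str(node)), label=str(label) if label else None)


def element_from_graph(g: Graph, node: URIRef) -> DataElement | Concept:
    """Reconstruct an element from its statements in *g*; inverse of
    :func:`element_to_graph`."""
    rdf_type = g.value(node, RDF.type)
    identifier = TermIdentifier(str(node))
    if rdf_type == NIDM.Concept:
        definition = g.value(node, SKOS.definition)
        return Concept(
            identifier=identifier,
            label=str(g.value(node, RDFS.label) or ""),
            definition=str(definition) if definition else "",
        )
    if rdf_type not in (NIDM.PersonalDataElement, NIDM.CommonDataElement):
        raise FormatError(f"node {node} is not a typed term")

    def scalar(pred):
        value = g.value(node, pred)
        return value.toPython() if value is not None else None

    choices = []
    head = g.value(node, NIDM.choices)
    if head is not None:
        for item in Collection(g, head):
            choices.append(
                ChoiceLevel(
                    code=g.value(item, NIDM.choiceCode).toPython(),
                    meaning=str(g.value(item, NIDM.choiceMeaning)),
                )
            )
    description = g.value(node, DCTERMS.description)
    measure_of = g.value(node, NIDM.measureOf)
    datum_type = g.value(node, NIDM.datumType)
    is_part_of = g.value(node, DCTERMS.isPartOf)
    return DataElement(
        identifier=identifier,
        elementType="PDE" if rdf_type == NIDM.PersonalDataElement else "CDE",
        label=str(g.value(node, RDFS.label) or ""),
        description=str(description) if description else "",
        sourceVariable=scalar(NIDM.sourceVariable),
        valueType=scalar(NIDM.valueType),
        unitCode=scalar(NIDM.unitCode),
        minValue=scalar(NIDM.minValue),
        maxValue=scalar(NIDM.maxValue),
        choices=choices,
        isAbout=[_ref_from_node(g, o) for o in g.objects(node, NIDM.isAbout)],
        measureOf=None if measure_of is None else _ref_from_node(g, measure_of),
        datumType=None if datum_type is None else _ref_from_node(g, datum_type),
        isPartOf=None if is_part_of is None else _ref_from_node(g, is_part_of),
        subtypeCDEs=[TermIdentifier(str(o)) for o in g.objects(node, NIDM.subtypeCDE)],
        supertypeCDEs=[TermIdentifier(str(o)) for o in g.objects(node, NIDM.supertypeCDE)],
        associatedWith=[str(o) for o in g.objects(node, NIDM.associatedWith)],
    )


# --------------------------------------------------------------------------
# multi-format export

EXPORT_FORMATS = ("markdown", "json", "jsonld", "csv", "nquads")

_TABLE_COLUMNS = (
    "identifier",
    "type",
    "label",
    "description",
    "sourceVariable",
    "valueType",
    "unitCode",
    "minValue",
    "maxValue",
    "choices",
    "isAbout",
)


def _table_row(element: DataElement | Concept) -> list[str]:
    if isinstance(element, Concept):
        return [
            element.identifier.uri,
            "Concept",
            element.label,
            element.definition,
            "", "", "", "", "", "", "",
        ]
    return [
        element.identifier.uri,
        element.elementType,
        element.label,
        element.description,
        element.sourceVariable or "",
        element.valueType or "",
        element.unitCode or "",
        "" if element.minValue is None else str(element.minValue),
        "" if element.maxValue is None else str(element.maxValue),
        format_choices(element.choices) if element.choices else "",
        "; ".join(ref.url.uri for ref in element.isAbout),
    ]


def export_terms(elements: list, format: str) -> str:
    """Export terms as ``markdown``, ``json``, ``jsonld``, ``csv`` or ``nquads``.

    Every format yields exactly one record (row / document / statement
    group) per input element.
    """
    if format not in EXPORT_FORMATS:
        raise TermError(
            f"unsupported export format {format!r}; supported formats: "
            + ", ".join(EXPORT_FORMATS)
        )
    if not elements:
        raise TermError("nothing to export: empty element list")
    if format == "markdown":
        lines = ["| " + " | ".join(_TABLE_COLUMNS) + " |"]
        lines.append("|" + "|".join(" --- " for _ in _TABLE_COLUMNS) + "|")
        for element in elements:
            cells = [c.replace("|", "\\|") for c in _table_row(element)]
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines) + "\n"
    if format == "csv":
        buffer = io.StringIO()
        writer = csv.writer(buffer, lineterminator="\n")
        writer.writerow(_TABLE_COLUMNS)
        for element in elements:
            writer.writerow(_table_row(element))
        return buffer.getvalue()
    if format == "json":
        docs = [_element_to_dict(e, with_context=False) for e in elements]
        return json.dumps(docs, indent=2, ensure_ascii=False)
    if format == "jsonld":
        docs = [_element_to_dict(e) for e in elements]
        return json.dumps(docs, indent=2, ensure_ascii=False)
    # nquads: serialize the union graph through a quad-aware store
    from rdflib import Dataset

    ds = Dataset(default_union=True)
    default = ds.default_graph
    for triple in elements_to_graph(elements):
        default.add(triple)
    return ds.serialize(format="nquads")
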