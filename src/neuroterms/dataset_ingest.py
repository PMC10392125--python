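"""Turn a BIDS dataset (or a standalone phenotype table) into an annotated
dataset graph.

A BIDS dataset contributes three things: the subject rows of
``participants.tsv`` (plus any tables under ``phenotype/``), a data
dictionary assembled from JSON sidecars and/or an externally supplied
dictionary, and acquisition records inferred from imaging file names.  Image
files are identified by name only — contents are never read — and each BIDS
suffix maps to a (contrast type, usage type) pair: the physics mechanism
behind the image contrast (``T2-weighted``, ``T2*-weighted``, …) is recorded
separately from how the image is used (``Anatomical``, ``Functional``,
``Diffusion``), since images with different contrasts are routinely stored
under the same usage.

Variable names are normalized (case folding, separator unification) before
they become dictionary keys, so multi-site data whose headers differ only in
spelling conventions ("Age Months" vs ``age_months``) land on one key.
"""

from __future__ import annotations

import copy
import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path, PurePosixPath

from rdflib import Dataset as RdfDataset
from rdflib import Graph, Literal, RDF, URIRef

from .context import DEFAULT_BASE_NAMESPACE, JSONLD_CONTEXT, NIDM
from .naming import normalize_variable_name
from .term_model import (
    ChoiceLevel,
    DataElement,
    FormatError,
    TermError,
    build_data_element,
    element_from_graph,
    element_to_graph,
    _element_to_dict,
    element_from_dict,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AcquisitionRecord",
    "AnnotatedDataset",
    "DatasetError",
    "SUFFIX_TABLE",
    "CONTRAST_TYPES",
    "MISSING_MARKERS",
    "normalize_variable_name",
    "read_participants_table",
    "read_sidecar",
    "infer_image_annotations",
    "ingest_bids",
    "ingest_tabular",
    "write_dataset_graph",
    "read_dataset_graph",
]


class DatasetError(ValueError):
    pass


#: BIDS suffix → (image contrast type, image usage type).  Extensible: pass
#: ``extra_suffixes`` to :func:`infer_image_annotations` / :func:`ingest_bids`.
SUFFIX_TABLE: dict[str, tuple[str, str]] = {
    "T1w": ("T1-weighted", "Anatomical"),
    "T2w": ("T2-weighted", "Anatomical"),
    "bold": ("T2*-weighted", "Functional"),
    "dwi": ("Diffusion-weighted", "Diffusion"),
    "FLAIR": ("FLAIR", "Anatomical"),
}

CONTRAST_TYPES = tuple(sorted({c for c, _ in SUFFIX_TABLE.values()}))
USAGE_TYPES = tuple(sorted({u for _, u in SUFFIX_TABLE.values()}))

#: Cell values treated as missing (case-insensitive).
MISSING_MARKERS = ("n/a",)


@dataclass(frozen=True, order=True)
class AcquisitionRecord:
    subjectId: str
    sessionId: str | None
    filePath: str  # dataset-relative, POSIX separators
    imageContrastType: str
    imageUsageType: str


@dataclass
class AnnotatedDataset:
    """One dataset's graph: dictionary, subject rows, acquisitions."""

    datasetId: str
    dataDictionary: dict[str, DataElement] = field(default_factory=dict)
    subjectRows: list[tuple[str, dict[str, str | None]]] = field(default_factory=list)
    acquisitions: list[AcquisitionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.subjectRows]
        if len(set(ids)) != len(ids):
            raise DatasetError(f"duplicate subject ids in {self.datasetId}")
        self.subjectRows = sorted(self.subjectRows, key=lambda r: r[0])
        self.acquisitions = sorted(self.acquisitions)

    def check_invariants(self) -> None:
        for sid, row in self.subjectRows:
            unknown = set(row) - set(self.dataDictionary)
            if unknown:
                raise DatasetError(
                    f"subject {sid} carries variables missing from the "
                    f"dictionary: {sorted(unknown)}"
                )


# --------------------------------------------------------------------------
# tabular readers


def _is_missing(cell: str, markers=MISSING_MARKERS) -> bool:
    return cell.strip().casefold() in {m.casefold() for m in markers}


def _read_table(path: Path, delimiter: str, subject_column: str):
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        if subject_column not in header:
            raise FormatError(f"{path}: no {subject_column!r} column in header {header}")
        rows = []
        for lineno, cells in enumerate(reader, start=2):
            if not cells or (len(cells) == 1 and not cells[0].strip()):
                continue
            if len(cells) != len(header):
                raise FormatError(
                    f"{path}: line {lineno} has {len(cells)} cells, "
                    f"header has {len(header)}"
                )
            rows.append(
                {
                    name: (None if _is_missing(cell) else cell.strip())
                    for name, cell in zip(header, cells)
                }
            )
    return header, rows


def read_participants_table(path: str | Path) -> tuple[list[str], list[dict]]:
    """Read a BIDS ``participants.tsv``.

    Returns the header's variable names (including ``participant_id``) and
    one mapping per data line; the BIDS missing marker ``n/a`` becomes an
    explicit missing value (``None``).
    """
    return _read_table(Path(path), "\t", "participant_id")


_SIDECAR_KEYS = {
    "description": "description",
    "levels": "choices",
    "units": "unitCode",
    "isabout": "isAbout",
    "minvalue": "minValue",
    "maxvalue": "maxValue",
    "valuetype": "valueType",
    "label": "label",
}


def read_sidecar(path: str | Path) -> dict[str, dict]:
    """Read a BIDS JSON sidecar into partial data-element properties.

    Sidecar keys map onto element properties: ``Description`` →
    description, ``Levels`` → choices, ``Units`` → unitCode, ``isAbout``
    (single object or list of ``{url, label}``) → concept links; the
    package's own sidecar dialect additionally admits ``MinValue``,
    ``MaxValue`` and ``ValueType`` so numeric ranges survive a round trip.
    Unrecognized keys are kept verbatim under ``_extra``.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, ValueError) as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: sidecar must be a JSON object keyed by variable")
    out: dict[str, dict] = {}
    for variable, annotation in doc.items():
        if not isinstance(annotation, dict):
            continue  # e.g. a bare "LongName" string; nothing usable
        props: dict = {}
        extra: dict = {}
        for key, value in annotation.items():
            mapped = _SIDECAR_KEYS.get(key.replace("_", "").replace("-", "").lower())
            if mapped is None:
                extra[key] = value
            elif mapped == "choices":
                props["choices"] = [
                    ChoiceLevel(code=_sidecar_code(k), meaning=str(v))
                    for k, v in value.items()
                ]
            elif mapped == "isAbout":
                props["isAbout"] = value if isinstance(value, list) else [value]
            else:
                props[mapped] = value
        if extra:
            props["_extra"] = extra
        out[variable] = props
    return out


def _sidecar_code(key):
    try:
        return int(key)
    except (TypeError, ValueError):
        try:
            return float(key)
        except (TypeError, ValueError):
            return str(key)


# --------------------------------------------------------------------------
# imaging files

_BIDS_PATH = re.compile(
    r"^sub-(?P<sub>[A-Za-z0-9]+)"
    r"(?:/ses-(?P<ses>[A-Za-z0-9]+))?"
    r"/(?P<datatype>[a-z0-9]+)/"
    r"(?P<stem>[A-Za-z0-9_\-]+)_(?P<suffix>[A-Za-z0-9]+)"
    r"\.(?P<ext>nii(?:\.gz)?)$"
)


def infer_image_annotations(
    relative_paths: list[str],
    extra_suffixes: dict[str, tuple[str, str]] | None = None,
) -> list[AcquisitionRecord]:
    """One acquisition record per BIDS-named imaging file.

    Subject and session come from the path entities; contrast and usage
    types from the suffix table.  Unparseable paths (or suffixes outside
    the table) are skipped with a logged warning, never fatal.
    """
    table = {**SUFFIX_TABLE, **(extra_suffixes or {})}
    records = []
    for raw in relative_paths:
        path = str(PurePosixPath(str(raw).replace("\\", "/")))
        match = _BIDS_PATH.match(path)
        if not match:
            logger.warning("skipping non-BIDS imaging path %r", raw)
            continue
        suffix = match.group("suffix")
        if suffix not in table:
            logger.warning("skipping %r: unknown suffix %r", raw, suffix)
            continue
        contrast, usage = table[suffix]
        records.append(
            AcquisitionRecord(
                subjectId=match.group("sub"),
                sessionId=match.group("ses"),
                filePath=path,
                imageContrastType=contrast,
                imageUsageType=usage,
            )
        )
    return records


# --------------------------------------------------------------------------
# ingestion


def _stub_or_annotated(
    header: str,
    key: str,
    sidecar_props: dict | None,
    dictionary: dict[str, DataElement] | None,
    dataset_id: str,
) -> DataElement:
    """Dictionary-entry precedence: supplied dictionary > sidecar > stub."""
    if dictionary:
        normalized = {normalize_variable_name(k): v for k, v in dictionary.items()}
        if key in normalized:
            return normalized[key]
    props = dict(sidecar_props or {})
    props.pop("_extra", None)
    return build_data_element(header, props, dataset_id=dataset_id)


def ingest_bids(
    root: str | Path,
    dictionary: dict[str, DataElement] | None = None,
    dataset_id: str | None = None,
    extra_suffixes: dict[str, tuple[str, str]] | None = None,
) -> AnnotatedDataset:
    """Convert a BIDS directory into an :class:`AnnotatedDataset`.

    Requires ``participants.tsv`` at *root*; also reads the
    ``participants.json`` sidecar, any tables under ``phenotype/`` (with
    their sidecars), and every ``*.nii[.gz]`` path under subject
    directories.  The data dictionary is keyed by normalized variable name;
    entries from *dictionary* override sidecar annotations, which override
    bare stubs.
    """
    root = Path(root)
    participants = root / "participants.tsv"
    if not participants.is_file():
        raise DatasetError(f"{root}: no participants.tsv — not a BIDS dataset root")
    ds_id = dataset_id or root.name

    tables: list[tuple[list[str], list[dict], dict[str, dict]]] = []
    sidecar = {}
    if (participants.with_suffix(".json")).is_file():
        sidecar = read_sidecar(participants.with_suffix(".json"))
    header, rows = read_participants_table(participants)
    tables.append((header, rows, sidecar))

    for pheno_dir in (root / "phenotype", root / "phenotypes"):
        if not pheno_dir.is_dir():
            continue
        for table_path in sorted(pheno_dir.glob("*.tsv")):
            side_path = table_path.with_suffix(".json")
            side = read_sidecar(side_path) if side_path.is_file() else {}
            p_header, p_rows = read_participants_table(table_path)
            tables.append((p_header, p_rows, side))

    data_dictionary: dict[str, DataElement] = {}
    merged_rows: dict[str, dict] = {}
    for t_header, t_rows, t_sidecar in tables:
        side_by_key = {normalize_variable_name(k): v for k, v in t_sidecar.items()}
        keys = {}
        for name in t_header:
            if name == "participant_id":
                continue
            key = normalize_variable_name(name)
            keys[name] = key
            if key not in data_dictionary:
                data_dictionary[key] = _stub_or_annotated(
                    name, key, side_by_key.get(key), dictionary, ds_id
                )
        for row in t_rows:
            sid = row["participant_id"]
            if sid is None:
                raise FormatError(f"{root}: row with missing participant_id")
            target = merged_rows.setdefault(sid, {})
            for name, key in keys.items():
                value = row[name]
                if target.get(key) is not None and value is not None and target[key] != value:
                    raise DatasetError(
                        f"{root}: conflicting values for subject {sid} variable "
                        f"{key}: {target[key]!r} vs {value!r}"
                    )
                if value is not None or key not in target:
                    target[key] = value

    image_paths = [
        p.relative_to(root).as_posix()
        for pattern in ("sub-*/**/*.nii", "sub-*/**/*.nii.gz")
        for p in sorted(root.glob(pattern))
    ]
    acquisitions = infer_image_annotations(image_paths, extra_suffixes)

    all_keys = set(data_dictionary)
    subject_rows = [
        (sid, {k: row.get(k) for k in all_keys}) for sid, row in merged_rows.items()
    ]
    dataset = AnnotatedDataset(
        datasetId=ds_id,
        dataDictionary=data_dictionary,
        subjectRows=subject_rows,
        acquisitions=acquisitions,
    )
    dataset.check_invariants()
    return dataset


def ingest_tabular(
    path: str | Path,
    dictionary: dict[str, DataElement] | None = None,
    existing: AnnotatedDataset | None = None,
    subject_column: str = "participant_id",
    dataset_id: str | None = None,
) -> AnnotatedDataset:
    """Ingest a standalone phenotype CSV/TSV, optionally merging into an
    existing dataset by subject id.

    Re-ingesting the same file with identical values is idempotent;
    conflicting non-missing values for the same subject/variable raise a
    :class:`DatasetError` listing them.
    """
    path = Path(path)
    delimiter = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    header, rows = _read_table(path, delimiter, subject_column)
    ds_id = existing.datasetId if existing is not None else (dataset_id or path.stem)

    dataset = (
        copy.deepcopy(existing)
        if existing is not None
        else AnnotatedDataset(datasetId=ds_id)
    )
    keys = {}
    for name in header:
        if name == subject_column:
            continue
        key = normalize_variable_name(name)
        keys[name] = key
        if key not in dataset.dataDictionary:
            dataset.dataDictionary[key] = _stub_or_annotated(
                name, key, None, dictionary, ds_id
            )

    by_subject = {sid: row for sid, row in dataset.subjectRows}
    for row in rows:
        sid = row[subject_column]
        if sid is None:
            raise FormatError(f"{path}: row with missing {subject_column}")
        target = by_subject.setdefault(sid, {})
        for name, key in keys.items():
            value = row[name]
            old = target.get(key)
            if old is not None and value is not None and old != value:
                raise DatasetError(
                    f"{path}: conflicting values for subject {sid} variable "
                    f"{key}: existing {old!r} vs incoming {value!r}"
                )
            if value is not None or key not in target:
                target[key] = value

    all_keys = set(dataset.dataDictionary)
    dataset.subjectRows = sorted(
        ((sid, {k: row.get(k) for k in all_keys}) for sid, row in by_subject.items()),
        key=lambda r: r[0],
    )
    dataset.check_invariants()
    return dataset


# --------------------------------------------------------------------------
# graph serialization

GRAPH_FORMATS = ("jsonld", "nquads")


def _dataset_uri(dataset_id: str) -> URIRef:
    return URIRef(f"{DEFAULT_BASE_NAMESPACE.rstrip('/')}/dataset/{dataset_id}")


def write_dataset_graph(dataset: AnnotatedDataset, format: str = "jsonld") -> str:
    """Serialize a dataset (dictionary + rows + acquisitions) to text.

    ``jsonld`` embeds one term document per dictionary entry;  ``nquads``
    produces an RDF graph in which every acquisition carries
    ``nidm:hadImageContrastType`` / ``nidm:hadImageUsageType`` statements.
    :func:`read_dataset_graph` inverts both.
    """
    if format not in GRAPH_FORMATS:
        raise TermError(
            f"unsupported graph format {format!r}; supported: {', '.join(GRAPH_FORMATS)}"
        )
    dataset.check_invariants()
    if format == "jsonld":
        doc = {
            "@context": dict(JSONLD_CONTEXT),
            "@id": str(_dataset_uri(dataset.datasetId)),
            "datasetId": dataset.datasetId,
            "dataDictionary": {
                key: _element_to_dict(el, with_context=False)
                for key, el in sorted(dataset.dataDictionary.items())
            },
            "subjects": [
                {
                    "id": sid,
                    "values": {k: v for k, v in sorted(row.items()) if v is not None},
                }
                for sid, row in dataset.subjectRows
            ],
            "acquisitions": [
                {
                    "subject": a.subjectId,
                    **({"session": a.sessionId} if a.sessionId else {}),
                    "filePath": a.filePath,
                    "hadImageContrastType": a.imageContrastType,
                    "hadImageUsageType": a.imageUsageType,
                }
                for a in dataset.acquisitions
            ],
        }
        return json.dumps(doc, indent=2, ensure_ascii=False)

    ds_node = _dataset_uri(dataset.datasetId)
    store = RdfDataset(default_union=True)
    g = store.default_graph
    g.bind("nidm", NIDM)
    g.add((ds_node, RDF.type, NIDM.Dataset))
    g.add((ds_node, NIDM.datasetId, Literal(dataset.datasetId)))
    for key, element in dataset.dataDictionary.items():
        el_node = URIRef(element.identifier.uri)
        element_to_graph(element, g)
        g.add((ds_node, NIDM.hasDataElement, el_node))
        g.add((el_node, NIDM.variableKey, Literal(key)))
    for sid, row in dataset.subjectRows:
        subj = URIRef(f"{ds_node}/subject/{sid}")
        g.add((ds_node, NIDM.hasSubject, subj))
        g.add((subj, NIDM.subjectId, Literal(sid)))
        for key, value in row.items():
            if value is None:
                continue
            g.add((subj, URIRef(dataset.dataDictionary[key].identifier.uri), Literal(value)))
    for i, acq in enumerate(dataset.acquisitions):
        node = URIRef(f"{ds_node}/acquisition/{i}")
        g.add((ds_node, NIDM.hasAcquisition, node))
        g.add((node, RDF.type, NIDM.AcquisitionObject))
        g.add((node, NIDM.subjectId, Literal(acq.subjectId)))
        if acq.sessionId:
            g.add((node, NIDM.sessionId, Literal(acq.sessionId)))
        g.add((node, NIDM.filePath, Literal(acq.filePath)))
        g.add((node, NIDM.hadImageContrastType, Literal(acq.imageContrastType)))
        g.add((node, NIDM.hadImageUsageType, Literal(acq.imageUsageType)))
    return store.serialize(format="nquads")


def read_dataset_graph(text: str, format: str = "jsonld") -> AnnotatedDataset:
    """Parse a serialized dataset graph back; inverse of
    :func:`write_dataset_graph`."""
    if format not in GRAPH_FORMATS:
        raise TermError(
            f"unsupported graph format {format!r}; supported: {', '.join(GRAPH_FORMATS)}"
        )
    if format == "jsonld":
        try:
            doc = json.loads(text)
        except (json.JSONDecodeError, ValueError) as exc:
            raise FormatError(f"not valid JSON: {exc}") from exc
        dictionary = {
            key: element_from_dict(el_doc)
            for key, el_doc in doc.get("dataDictionary", {}).items()
        }
        all_keys = set(dictionary)
        rows = [
            (s["id"], {k: s.get("values", {}).get(k) for k in all_keys})
            for s in doc.get("subjects", [])
        ]
        acquisitions = [
            AcquisitionRecord(
                subjectId=a["subject"],
                sessionId=a.get("session"),
                filePath=a["filePath"],
                imageContrastType=a["hadImageContrastType"],
                imageUsageType=a["hadImageUsageType"],
            )
            for a in doc.get("acquisitions", [])
        ]
        return AnnotatedDataset(
            datasetId=doc["datasetId"],
            dataDictionary=dictionary,
            subjectRows=rows,
            acquisitions=acquisitions,
        )

    store = RdfDataset(default_union=True)
    store.parse(data=text, format="nquads")
    g = Graph()
    for s, p, o, _ in store.quads((None, None, None, None)):
        g.add((s, p, o))
    ds_node = g.value(predicate=RDF.type, object=NIDM.Dataset)
    if ds_node is None:
        raise FormatError("no dataset node in graph")
    dataset_id = str(g.value(ds_node, NIDM.datasetId))
    dictionary: dict[str, DataElement] = {}
    uri_to_key: dict[str, str] = {}
    for el_node in g.objects(ds_node, NIDM.hasDataElement):
        key = str(g.value(el_node, NIDM.variableKey))
        element = element_from_graph(g, el_node)
        dictionary[key] = element
        uri_to_key[str(el_node)] = key
    all_keys = set(dictionary)
    rows = []
    for subj in g.objects(ds_node, NIDM.hasSubject):
        sid = str(g.value(subj, NIDM.subjectId))
        row: dict[str, str | None] = {k: None for k in all_keys}
        for pred, obj in g.predicate_objects(subj):
            key = uri_to_key.get(str(pred))
            if key is not None:
                row[key] = str(obj)
        rows.append((sid, row))
    acquisitions = []
    for node in g.objects(ds_node, NIDM.hasAcquisition):
        session = g.value(node, NIDM.sessionId)
        acquisitions.append(
            AcquisitionRecord(
                subjectId=str(g.value(node, NIDM.subjectId)),
                sessionId=str(session) if session is not None else None,
                filePath=str(g.value(node, NIDM.filePath)),
                imageContrastType=str(g.value(node, NIDM.hadImageContrastType)),
                imageUsageType=str(g.value(node, NIDM.hadImageUsageType)),
            )
        )
    return AnnotatedDataset(
        datasetId=dataset_id,
        dataDictionary=dictionary,
        subjectRows=rows,
        acquisitions=acquisitions,
    )
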