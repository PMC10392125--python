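"""The fixed JSON-LD context shipped with the package.

Every term document this package writes carries this context, which maps
the data-element property names to stable URIs.  ``hadImageContrastType``
and ``hadImageUsageType`` live in the NIDM namespace; generic annotation
properties reuse RDFS/Dublin Core/SKOS where a well-known URI exists.
"""

from __future__ import annotations

from rdflib import Namespace

NIDM = Namespace("http://purl.org/nidash/nidm#")
RDFS_NS = "http://www.w3.org/2000/01/rdf-schema#"
DCT_NS = "http://purl.org/dc/terms/"
SKOS_NS = "http://www.w3.org/2004/02/skos/core#"

#: Default namespace under which personal-data-element identifiers are minted:
#: ``<base>/<dataset-id>/<normalized-variable-name>``.
DEFAULT_BASE_NAMESPACE = "https://terms.example.org/terms"

#: Registered CURIE prefixes expanded before a term identifier is stored.
CURIE_PREFIXES: dict[str, str] = {
    "ilx": "http://uri.interlex.org/base/ilx_",
    "nidm": str(NIDM),
    "cogatlas": "https://www.cognitiveatlas.org/concept/id/",
}

JSONLD_CONTEXT: dict[str, str] = {
    "nidm": str(NIDM),
    "rdfs": RDFS_NS,
    "dct": DCT_NS,
    "skos": SKOS_NS,
    "label": "rdfs:label",
    "description": "dct:description",
    "definition": "skos:definition",
    "valueType": "nidm:valueType",
    "unitCode": "nidm:unitCode",
    "minValue": "nidm:minValue",
    "maxValue": "nidm:maxValue",
    "choices": "nidm:choices",
    "code": "nidm:choiceCode",
    "meaning": "nidm:choiceMeaning",
    "isAbout": "nidm:isAbout",
    "sourceVariable": "nidm:sourceVariable",
    "measureOf": "nidm:measureOf",
    "datumType": "nidm:datumType",
    "isPartOf": "dct:isPartOf",
    "subtypeCDEs": "nidm:subtypeCDE",
    "supertypeCDEs": "nidm:supertypeCDE",
    "associatedWith": "nidm:associatedWith",
    "PersonalDataElement": "nidm:PersonalDataElement",
    "CommonDataElement": "nidm:CommonDataElement",
    "Concept": "nidm:Concept",
    "hadImageContrastType": "nidm:hadImageContrastType",
    "hadImageUsageType": "nidm:hadImageUsageType",
}


def expand_context_key(key: str) -> str:
    """Expand a context key (e.g. ``isAbout``) to its absolute URI."""
    value = JSONLD_CONTEXT[key]
    prefix, _, local = value.partition(":")
    if prefix in JSONLD_CONTEXT and not local.startswith("//"):
        return JSONLD_CONTEXT[prefix] + local
    return value
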