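"""Variable-name normalization shared by ingestion, minting and matching.

Study variable names for the same measure commonly differ across sites only
in capitalization and in the separators used between words ("Age Months",
"age_months", "AGE-MONTHS").  Normalization unifies exactly those surface
features and nothing else: distinct alphanumeric tokens are never merged,
so "age" and "agemonths" remain different keys.
"""

from __future__ import annotations

import re

_SEPARATOR_RUN = re.compile(r"[\s_\-]+")


def normalize_variable_name(name: str) -> str:
    """Case-fold *name* and collapse runs of spaces/dashes/underscores.

    Returns the canonical key under which a variable is stored in a data
    dictionary.  Idempotent.  Raises ``ValueError`` on empty input or input
    that normalizes to nothing (pure separators).
    """
    if not isinstance(name, str) or not name:
        raise ValueError("variable name must be non-empty text")
    collapsed = _SEPARATOR_RUN.sub("_", name.casefold()).strip("_")
    if not collapsed:
        raise ValueError(f"variable name {name!r} contains no usable characters")
    return collapsed


def tokenize(name: str) -> list[str]:
    """Split a (possibly unnormalized) name into lower-case word tokens."""
    return [t for t in normalize_variable_name(name).split("_") if t]
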