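"""Small DNA-string helpers shared across modules."""

from __future__ import annotations

from .exceptions import FormatError

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def validate_dna(seq: str, context: str = "") -> str:
    """Uppercase ``seq`` and reject characters outside A/C/G/T/N."""
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        where = f" ({context})" if context else ""
        raise FormatError(f"non-DNA characters {sorted(bad)}{where}")
    return seq


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
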