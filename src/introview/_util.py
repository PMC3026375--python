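"""Small shared helpers."""

from __future__ import annotations

import re

_CHUNK = re.compile(r"(\d+)")


def natural_key(text: str):
    """Sort key treating digit runs as numbers ("chr2" < "chr10")."""
    return tuple(
        (0, int(part)) if part.isdigit() else (1, part)
        for part in _CHUNK.split(str(text))
        if part != ""
    )


def format_number(x: float) -> str:
    """Render a cM coordinate without a spurious decimal part.

    Integers print as integers ("37", not "37.0"); fractional values keep
    up to six decimals with trailing zeros trimmed.
    """
    if x == int(x):
        return str(int(x))
    return f"{x:.6f}".rstrip("0").rstrip(".")
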