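"""Shared string normalization for terminology lookup and name matching."""

from __future__ import annotations

import re

_WS = re.compile(r"\s+")


def normalize(s: str) -> str:
    """Lowercase, trim, and collapse internal whitespace. No stemming."""
    return _WS.sub(" ", s.strip().lower())
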