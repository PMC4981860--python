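"""MR protocol tags and series-description matching.

Four axial abdominal protocols are recognised: single-shot fast spin echo
T2 (SSFSE-T2), fast short-tau inversion recovery (FAST-STIR), in/out-phase
gradient echo, and the non-enhanced dynamic series.  Series whose
description matches none of the aliases are tagged UNKNOWN and excluded
from biomarker scoring.
"""

from __future__ import annotations

import enum


class Protocol(enum.Enum):
    SSFSE_T2 = "SSFSE_T2"
    FAST_STIR = "FAST_STIR"
    IN_OUT_PHASE = "IN_OUT_PHASE"
    DYNAMIC = "DYNAMIC"
    UNKNOWN = "UNKNOWN"

    def __str__(self) -> str:  # keeps CSV/JSON output compact
        return self.value


#: Default case-insensitive substring aliases for DICOM SeriesDescription.
#: Users can pass their own table to :func:`match_protocol` / load_series.
DEFAULT_ALIASES: dict[str, Protocol] = {
    "ssfse": Protocol.SSFSE_T2,
    "stir": Protocol.FAST_STIR,
    "phase": Protocol.IN_OUT_PHASE,
    "dyn": Protocol.DYNAMIC,
}


def match_protocol(series_description: str | None,
                   aliases: dict[str, Protocol] | None = None) -> Protocol:
    """Map a DICOM series description to a :class:`Protocol`.

    Matching is case-insensitive substring containment; the longest
    matching alias wins so specific aliases can shadow generic ones.
    """
    if not series_description:
        return Protocol.UNKNOWN
    table = DEFAULT_ALIASES if aliases is None else aliases
    desc = series_description.lower()
    best: Protocol = Protocol.UNKNOWN
    best_len = -1
    for alias, proto in table.items():
        a = alias.lower()
        if a in desc and len(a) > best_len:
            best, best_len = proto, len(a)
    return best


def parse_protocol(name: str) -> Protocol:
    """Parse an exact protocol name (as serialised by ``str``)."""
    try:
        return Protocol(name)
    except ValueError as exc:
        raise ValueError(f"unknown protocol name: {name!r}") from exc
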