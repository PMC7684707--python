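"""Assembly and annotation summary statistics.

N50, chromosome anchoring rate and repeat-class composition percentages —
the ratios a genome paper prints from its length tables.  Percent values are
rounded half-even at the precision of the printed figure being matched, and
megabase inputs convert at 1 Mb = 1e6 bp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CompositionEntry",
    "n50",
    "anchoring_rate",
    "composition_percent",
    "assembly_summary",
    "MB",
]

MB = 1_000_000


@dataclass(frozen=True)
class CompositionEntry:
    name: str
    component_bp: float
    total_bp: float

    def __post_init__(self) -> None:
        if not 0 <= self.component_bp <= self.total_bp:
            raise ValueError(f"{self.name}: component_bp must be in [0, total_bp]")


def n50(lengths) -> int:
    """Smallest length L such that sequences >= L cover half the total."""
    arr = np.asarray(list(lengths), dtype=np.int64)
    if arr.size == 0:
        raise ValueError("empty length set")
    if (arr <= 0).any():
        raise ValueError("lengths must be positive")
    ordered = np.sort(arr)[::-1]
    half = arr.sum() / 2.0
    cum = np.cumsum(ordered)
    return int(ordered[np.searchsorted(cum, half)])


def anchoring_rate(anchored_bp: float, total_bp: float, ndigits: int = 1) -> float:
    """Percent of assembled bases placed on chromosomes, to one decimal."""
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    if anchored_bp > total_bp:
        raise ValueError("anchored_bp exceeds total_bp")
    return round(100.0 * anchored_bp / total_bp, ndigits)


def composition_percent(entry: CompositionEntry, ndigits: int = 1) -> float:
    """Percent of the genome a component occupies, at the printed precision."""
    return round(100.0 * entry.component_bp / entry.total_bp, ndigits)


def assembly_summary(lengths, anchored_bp: float | None = None) -> dict:
    """Total length, sequence count, N50 and optional anchoring rate."""
    arr = np.asarray(list(lengths), dtype=np.int64)
    out = {
        "total_bp": int(arr.sum()),
        "n_sequences": int(arr.size),
        "n50_bp": n50(arr),
        "longest_bp": int(arr.max()),
    }
    if anchored_bp is not None:
        out["anchoring_rate_pct"] = anchoring_rate(anchored_bp, out["total_bp"])
    return out
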