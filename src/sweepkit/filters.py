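"""Hard filtering and LD pruning of variant records.

A record passes the hard filters iff every inequality holds, all strict:

    QUAL > 30, QD > 2, DP > 5, FS < 60, MQ > 40, SOR < 4.0

A record missing one of the INFO metrics fails that specific filter — the
conservative reading, so unannotated records cannot leak through.  Failed
filter names are written into the FILTER column.

LD pruning is the standard windowed greedy scheme: within a sliding window of
sites, the later site of any pair with genotype correlation r^2 above the
threshold is dropped, scanning left to right, which makes the retained set
deterministic.  Genotype r is the Pearson correlation of 0/1/2 alt-allele
counts over pairwise-complete samples; a monomorphic site has undefined r and
is treated as r^2 = 0 (never pruned for LD).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .simulate import MISSING, GenotypeMatrix
from .vcf_io import VariantRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FilterThresholds",
    "LDPruneParams",
    "apply_hard_filters",
    "ld_prune",
    "mask_low_depth_calls",
]

# (filter name, INFO key or QUAL, comparison, threshold attribute)
_FILTERS = (
    ("lowQUAL", "QUAL", "gt", "qual_min"),
    ("lowQD", "QD", "gt", "qd_min"),
    ("lowDP", "DP", "gt", "dp_min"),
    ("highFS", "FS", "lt", "fs_max"),
    ("lowMQ", "MQ", "gt", "mq_min"),
    ("highSOR", "SOR", "lt", "sor_max"),
)


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter cutoffs; the defaults are the GATK-style thresholds above."""

    qual_min: float = 30.0
    qd_min: float = 2.0
    dp_min: float = 5.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    sor_max: float = 4.0

    def __post_init__(self) -> None:
        for name in ("qual_min", "qd_min", "dp_min", "mq_min"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        for name in ("fs_max", "sor_max"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class LDPruneParams:
    r2_max: float = 0.8
    window_size: int = 50  # sites
    step: int = 5  # sites
    min_depth: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.r2_max <= 1:
            raise ValueError("r2_max must be in (0,1]")
        if self.step < 1 or self.window_size < 1:
            raise ValueError("window_size and step must be >= 1")
        if self.step > self.window_size:
            raise ValueError("step must be <= window_size")


def failed_filters(
    record: VariantRecord, thresholds: FilterThresholds | None = None
) -> list[str]:
    """Names of the hard filters the record fails (empty = PASS)."""
    thresholds = thresholds or FilterThresholds()
    failed = []
    for name, key, op, attr in _FILTERS:
        value = record.qual if key == "QUAL" else record.info.get(key)
        cut = getattr(thresholds, attr)
        if value is None:
            failed.append(name)  # missing metric fails its filter
        elif op == "gt" and not value > cut:
            failed.append(name)
        elif op == "lt" and not value < cut:
            failed.append(name)
    return failed


def apply_hard_filters(
    records: Sequence[VariantRecord],
    thresholds: FilterThresholds | None = None,
    annotate: bool = True,
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Partition records by the hard filters.

    Returns the passing records and a per-filter failure count (a record
    failing several filters increments each).  When ``annotate`` is set the
    records' ``filter_status`` is rewritten in place.
    """
    thresholds = thresholds or FilterThresholds()
    counts = {name: 0 for name, *_ in _FILTERS}
    passing = []
    for rec in records:
        failed = failed_filters(rec, thresholds)
        if annotate:
            rec.filter_status = failed if failed else ["PASS"]
        if failed:
            for name in failed:
                counts[name] += 1
        else:
            passing.append(rec)
    return passing, counts


def _pairwise_r2(calls: np.ndarray, i: int, j: int) -> float:
    """r^2 between two sites on pairwise-complete 0/1/2 calls."""
    gi, gj = calls[:, i], calls[:, j]
    ok = (gi != MISSING) & (gj != MISSING)
    if ok.sum() < 2:
        return 0.0
    x = gi[ok].astype(float)
    y = gj[ok].astype(float)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0  # monomorphic: r undefined, treated as no LD
    r = float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))
    return r * r


def ld_prune(
    matrix: GenotypeMatrix, params: LDPruneParams | None = None
) -> np.ndarray:
    """Indices of sites retained after windowed greedy r^2 pruning."""
    params = params or LDPruneParams()
    n = matrix.n_sites
    keep = np.ones(n, dtype=bool)
    for start in range(0, max(n - 1, 1), params.step):
        window = range(start, min(start + params.window_size, n))
        idx = [i for i in window if keep[i]]
        for a in range(len(idx)):
            if not keep[idx[a]]:
                continue
            for b in range(a + 1, len(idx)):
                if not keep[idx[b]]:
                    continue
                if _pairwise_r2(matrix.calls, idx[a], idx[b]) > params.r2_max:
                    keep[idx[b]] = False
        if start + params.window_size >= n:
            break
    return np.flatnonzero(keep)


def mask_low_depth_calls(
    matrix: GenotypeMatrix, depths: np.ndarray | None, min_depth: int = 5
) -> GenotypeMatrix:
    """Set calls with per-sample depth below ``min_depth`` to missing.

    ``depths`` is (n_samples, n_sites); when per-sample depth is unavailable
    the mask is skipped with a warning, matching pipelines whose VCFs lack a
    per-genotype DP.
    """
    if depths is None:
        logger.warning("no per-sample depths available; min_depth mask skipped")
        return matrix
    if depths.shape != matrix.calls.shape:
        raise ValueError("depths shape must match calls")
    calls = matrix.calls.copy()
    calls[depths < min_depth] = MISSING
    return GenotypeMatrix(
        sample_ids=matrix.sample_ids,
        pop_labels=matrix.pop_labels,
        chrom=matrix.chrom,
        pos=matrix.pos,
        ref=matrix.ref,
        alt=matrix.alt,
        calls=calls,
    )
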