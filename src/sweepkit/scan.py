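"""Z(Fst) / log2 diversity-ratio outlier calling and gene annotation.

Window Fst values are standardized genome-wide,

    Z(Fst) = (Fst - mu_Fst) / sigma_Fst,

with the sample standard deviation, and the per-window diversity contrast is
log2(pi_A / pi_B).  A window is called an outlier under the default
INTERSECTION rule when it lies in the top ``q`` (default 1%) of Z(Fst) AND in
the top ``q`` of the diversity-ratio tail, each tail evaluated separately:
a high ratio (pi_A >> pi_B) points to reduced diversity — a sweep — in
population B, a low ratio to a sweep in population A.  Quantile cutoffs are
empirical with ties at the cutoff included, so calls are deterministic and
order-independent.  A UNION rule (either statistic extreme) is available.

Windows where either population has zero diversity are excluded from the
ratio ranking (the count is logged) rather than patched with a pseudocount
that would dominate the tail.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vcf_io import GeneInterval

logger = logging.getLogger(__name__)

__all__ = [
    "ScanStats",
    "OutlierCall",
    "z_transform",
    "log2_pi_ratio",
    "call_outliers",
    "annotate_genes",
    "compare_scans",
    "scan_windows",
    "plot_scan",
]


@dataclass
class ScanStats:
    mu_fst: float
    sigma_fst: float
    n_windows: int
    z_cut: float
    ratio_cut_high: float
    ratio_cut_low: float


@dataclass
class OutlierCall:
    chrom: str
    start: int
    end: int
    zfst: float
    log2_ratio: float
    direction: str  # population with reduced diversity
    genes: list[str] = field(default_factory=list)


def z_transform(fst: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Standardize window Fst by the genome-wide mean and sample sd (N-1)."""
    fst = np.asarray(fst, dtype=float)
    fst = fst[~np.isnan(fst)]
    if len(fst) < 2:
        raise ValueError("need at least 2 windows to Z-transform")
    mu = float(fst.mean())
    sigma = float(fst.std(ddof=1))
    if sigma <= 1e-12 * max(1.0, abs(mu)):  # constant up to float rounding
        raise ValueError("constant Fst across windows: sigma is 0, Z undefined")
    return (fst - mu) / sigma, mu, sigma


def log2_pi_ratio(pi_a: np.ndarray, pi_b: np.ndarray) -> np.ndarray:
    """log2(pi_A / pi_B) per window; NaN where either pi is 0 or undefined."""
    pi_a = np.asarray(pi_a, dtype=float)
    pi_b = np.asarray(pi_b, dtype=float)
    valid = (pi_a > 0) & (pi_b > 0)
    n_excluded = int((~valid & ~(np.isnan(pi_a) | np.isnan(pi_b))).sum())
    if n_excluded:
        logger.info("%d windows with zero diversity excluded from the ratio", n_excluded)
    out = np.full(len(pi_a), np.nan)
    out[valid] = np.log2(pi_a[valid] / pi_b[valid])
    return out


def _tail_cutoff(values: np.ndarray, q: float, tail: str) -> float:
    """Empirical top-q cutoff: the k-th most extreme value, k = ceil(q*N)."""
    values = values[~np.isnan(values)]
    k = max(1, math.ceil(q * len(values)))
    ordered = np.sort(values)
    return float(ordered[-k] if tail == "high" else ordered[k - 1])


def scan_windows(
    stats: pd.DataFrame,
    pop_a: str = "popA",
    pop_b: str = "popB",
) -> pd.DataFrame:
    """Add zfst and log2_ratio columns to a window-stats table."""
    df = stats.copy()
    fst = df["fst"].to_numpy(dtype=float)
    ok = ~np.isnan(fst)
    z, mu, sigma = z_transform(fst[ok])
    zcol = np.full(len(df), np.nan)
    zcol[ok] = z
    df["zfst"] = zcol
    df["log2_ratio"] = log2_pi_ratio(
        df["pi_a"].to_numpy(dtype=float), df["pi_b"].to_numpy(dtype=float)
    )
    df.attrs["mu_fst"] = mu
    df.attrs["sigma_fst"] = sigma
    df.attrs["pop_a"] = pop_a
    df.attrs["pop_b"] = pop_b
    return df


def call_outliers(
    df: pd.DataFrame,
    q: float = 0.01,
    rule: str = "intersection",
    pop_a: str | None = None,
    pop_b: str | None = None,
) -> tuple[list[OutlierCall], ScanStats]:
    """Call top-q outlier windows from a table produced by :func:`scan_windows`.

    ``rule``: "intersection" (default) requires a window to be extreme in both
    Z(Fst) and the ratio; "union" accepts either.  Both ratio tails are
    scanned; the direction field names the population whose diversity is
    reduced.
    """
    if not 0 < q < 0.5:
        raise ValueError("q must be in (0, 0.5)")
    if rule not in ("intersection", "union"):
        raise ValueError("rule must be 'intersection' or 'union'")
    pop_a = pop_a or df.attrs.get("pop_a", "popA")
    pop_b = pop_b or df.attrs.get("pop_b", "popB")
    z = df["zfst"].to_numpy(dtype=float)
    ratio = df["log2_ratio"].to_numpy(dtype=float)
    z_cut = _tail_cutoff(z, q, "high")
    hi_cut = _tail_cutoff(ratio, q, "high")
    lo_cut = _tail_cutoff(ratio, q, "low")
    z_top = z >= z_cut
    ratio_hi = ratio >= hi_cut
    ratio_lo = ratio <= lo_cut
    with np.errstate(invalid="ignore"):
        if rule == "intersection":
            called = z_top & (ratio_hi | ratio_lo)
        else:
            called = z_top | ratio_hi | ratio_lo
    called &= ~np.isnan(z)
    calls = []
    for i in np.flatnonzero(called):
        if not np.isnan(ratio[i]) and ratio_lo[i] and not ratio_hi[i]:
            direction = pop_a  # low pi_A/pi_B: A's diversity reduced
        else:
            direction = pop_b
        calls.append(
            OutlierCall(
                chrom=str(df["chrom"].iloc[i]),
                start=int(df["start"].iloc[i]),
                end=int(df["end"].iloc[i]),
                zfst=float(z[i]),
                log2_ratio=float(ratio[i]) if not np.isnan(ratio[i]) else float("nan"),
                direction=direction,
            )
        )
    fst = df["fst"].to_numpy(dtype=float)
    stats = ScanStats(
        mu_fst=float(np.nanmean(fst)),
        sigma_fst=float(np.nanstd(fst, ddof=1)),
        n_windows=int((~np.isnan(fst)).sum()),
        z_cut=z_cut,
        ratio_cut_high=hi_cut,
        ratio_cut_low=lo_cut,
    )
    return calls, stats


def annotate_genes(
    calls: list[OutlierCall], genes: list[GeneInterval]
) -> dict[str, list[OutlierCall]]:
    """Map each gene to the outlier windows it overlaps (half-open, any bp).

    Sorted sweep-line per chromosome: windows are sorted by start, and for
    each gene only the windows whose start lies within one maximum window
    length of the gene are examined, so the pass is near-linear.  Calls' gene
    lists are filled in place.
    """
    import bisect

    call_chroms = {c.chrom for c in calls}
    gene_chroms = {g.chrom for g in genes}
    if calls and genes and not call_chroms & gene_chroms:
        logger.warning(
            "no shared chromosome names between %d calls and %d genes",
            len(calls), len(genes),
        )
    by_gene: dict[str, list[OutlierCall]] = {}
    for chrom in sorted(call_chroms & gene_chroms):
        wins = sorted((c for c in calls if c.chrom == chrom), key=lambda c: c.start)
        starts = [w.start for w in wins]
        max_len = max(w.end - w.start for w in wins)
        for gene in sorted((g for g in genes if g.chrom == chrom), key=lambda g: g.start):
            lo = bisect.bisect_left(starts, gene.start - max_len + 1)
            hi = bisect.bisect_left(starts, gene.end)
            for w in wins[lo:hi]:
                if w.end > gene.start:  # overlap under half-open semantics
                    by_gene.setdefault(gene.gene_id, []).append(w)
                    w.genes.append(gene.gene_id)
    return by_gene


def compare_scans(gene_sets: dict[str, set[str]]) -> pd.DataFrame:
    """Membership table of candidate genes across scan comparisons.

    Rows are genes, one boolean column per comparison, plus the count of
    comparisons sharing the gene — the set-Venn of candidate gene lists.
    """
    all_genes = sorted(set().union(*gene_sets.values()) if gene_sets else set())
    data = {name: [g in s for g in all_genes] for name, s in gene_sets.items()}
    df = pd.DataFrame(data, index=pd.Index(all_genes, name="gene"))
    df["n_shared"] = df.sum(axis=1)
    return df


def plot_scan(df: pd.DataFrame, path: str, q: float = 0.01) -> None:
    """Manhattan-style Z(Fst) plot with the top-q cutoff line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    z = df["zfst"].to_numpy(dtype=float)
    mid = (df["start"].to_numpy() + df["end"].to_numpy()) / 2
    fig, ax = plt.subplots(figsize=(9, 3))
    for i, chrom in enumerate(pd.unique(df["chrom"])):
        sel = df["chrom"] == chrom
        ax.scatter(mid[sel.to_numpy()], z[sel.to_numpy()], s=4,
                   color=["#4477aa", "#ee6677"][i % 2], label=str(chrom))
    ax.axhline(_tail_cutoff(z, q, "high"), color="black", lw=0.8, ls="--")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("Z(Fst)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
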