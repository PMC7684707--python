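"""Windowed nucleotide diversity, Hudson Fst and genotype PCA.

Per-site diversity uses the unbiased pairwise estimator: with ``n`` called
allele copies of which ``a`` are the alternate allele,

    pi_site = 2 a (n - a) / (n (n - 1)),

the probability that two copies drawn without replacement differ.  Window
theta-pi sums pi over the variant sites in the window and divides by the
window's effective length in bp, so invariant positions dilute diversity as
they should.

Between two populations the Hudson Fst estimator is used.  Per site, with
sample frequencies p1 = a1/n1 and p2 = a2/n2,

    num = (p1 - p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    den = p1(1-p2) + p2(1-p1)

and a window's Fst is the ratio of sums over its sites.  ``den`` is the mean
between-population pairwise difference and ``den - num`` the average of the two
unbiased within-population diversities, so the window value equals
1 - pi_within / pi_between — the property the tests verify against a
brute-force pairwise comparison.  Hudson's form is insensitive to unequal
sample sizes, which matters when populations of 11 and 6 individuals are
compared.  Negative values (possible when true differentiation is ~0) are kept,
so the downstream Z-transform sees the real empirical distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

MIN_ALLELE_COPIES = 4  # site dropped for a pop below this many called copies

__all__ = [
    "Window",
    "make_windows",
    "site_pi",
    "window_pi",
    "hudson_fst_site",
    "window_fst",
    "window_stats",
    "pca_genotypes",
]


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("window must have start < end")

    @property
    def effective_bp(self) -> int:
        return self.end - self.start


def make_windows(
    chrom_lengths: dict[str, int], size: int = 1000, step: int | None = None
) -> list[Window]:
    """Half-open tiling (or sliding, if step < size) of each chromosome.

    The trailing partial window is kept with its true length so per-bp
    normalization stays honest at chromosome ends.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    step = size if step is None else step
    if step < 1:
        raise ValueError("step must be >= 1")
    windows = []
    for chrom, length in chrom_lengths.items():
        start = 0
        while start < length:
            windows.append(Window(chrom, start, min(start + size, length)))
            start += step
    return windows


def site_pi(n: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Unbiased per-site pairwise diversity; NaN where n < 2 (site unusable)."""
    n = np.asarray(n, dtype=float)
    a = np.asarray(a, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * a * (n - a) / (n * (n - 1.0))
    return np.where(n >= 2, pi, np.nan)


def hudson_fst_site(
    n1: np.ndarray, a1: np.ndarray, n2: np.ndarray, a2: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson numerator and denominator (NaN where a pop has n < 2)."""
    n1 = np.asarray(n1, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    a2 = np.asarray(a2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = a1 / n1, a2 / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    usable = (n1 >= 2) & (n2 >= 2)
    num = np.where(usable, num, np.nan)
    den = np.where(usable, den, np.nan)
    # both monomorphic for the same allele: uninformative, contributes (0, 0)
    zero = usable & (den == 0)
    num = np.where(zero, 0.0, num)
    return num, den


def _sites_in_window(matrix: GenotypeMatrix, window: Window) -> np.ndarray:
    on_chrom = matrix.chrom == window.chrom
    pos0 = matrix.pos - 1
    return np.flatnonzero(on_chrom & (pos0 >= window.start) & (pos0 < window.end))


def window_pi(
    matrix: GenotypeMatrix,
    windows: list[Window],
    pop: str,
    min_copies: int = MIN_ALLELE_COPIES,
) -> np.ndarray:
    """Theta-pi per bp for each window; sites with too few called copies excluded."""
    n, a = matrix.allele_counts(pop)
    pi = site_pi(n, a)
    pi = np.where(n >= min_copies, pi, np.nan)
    out = np.empty(len(windows))
    for w, window in enumerate(windows):
        idx = _sites_in_window(matrix, window)
        vals = pi[idx]
        out[w] = np.nansum(vals) / window.effective_bp
    return out


def window_fst(
    matrix: GenotypeMatrix,
    windows: list[Window],
    pop_a: str,
    pop_b: str,
    min_copies: int = MIN_ALLELE_COPIES,
) -> np.ndarray:
    """Ratio-of-sums Hudson Fst per window; NaN where no informative site."""
    n1, a1 = matrix.allele_counts(pop_a)
    n2, a2 = matrix.allele_counts(pop_b)
    num, den = hudson_fst_site(n1, a1, n2, a2)
    usable = (n1 >= min_copies) & (n2 >= min_copies) & ~np.isnan(den)
    out = np.full(len(windows), np.nan)
    for w, window in enumerate(windows):
        idx = _sites_in_window(matrix, window)
        idx = idx[usable[idx]]
        if len(idx) == 0:
            continue
        d = den[idx].sum()
        if d > 0:
            out[w] = num[idx].sum() / d
    return out


def window_stats(
    matrix: GenotypeMatrix,
    windows: list[Window],
    pop_a: str,
    pop_b: str,
    min_copies: int = MIN_ALLELE_COPIES,
) -> pd.DataFrame:
    """Per-window site counts, per-population theta-pi and Hudson Fst."""
    n_sites = np.array([len(_sites_in_window(matrix, w)) for w in windows])
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "n_sites": n_sites,
            "pi_a": window_pi(matrix, windows, pop_a, min_copies),
            "pi_b": window_pi(matrix, windows, pop_b, min_copies),
            "fst": window_fst(matrix, windows, pop_a, pop_b, min_copies),
        }
    )


def pca_genotypes(
    matrix: GenotypeMatrix, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the genotype matrix with allele-frequency standardization.

    Each polymorphic site is centered by twice its sample allele frequency and
    scaled by sqrt(2 p (1-p)), the binomial standard deviation, the standard
    normalization for genotype PCA; missing calls are mean-imputed per site.
    Returns sample coordinates (n_samples, k) and the fraction of variance on
    each axis.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    G = matrix.calls.astype(float)
    G[matrix.calls == MISSING] = np.nan
    p = np.nanmean(G, axis=0) / 2.0
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if poly.sum() < 2:
        raise ValueError("need at least 2 polymorphic sites")
    G = G[:, poly]
    p = p[poly]
    mu = 2.0 * p
    G = np.where(np.isnan(G), mu, G)
    X = (G - mu) / np.sqrt(2.0 * p * (1.0 - p))
    X = X - X.mean(axis=0)  # imputation can shift the column means slightly
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    k = min(n_components, len(s))
    coords = U[:, :k] * s[:k]
    return coords, frac[:k]
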