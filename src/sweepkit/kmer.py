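"""Genome-size estimation from a k-mer depth spectrum.

The estimator is the classical k-mer identity: a genome of size G sequenced to
depth C with reads of length L yields an expected k-mer depth of
``C_kmer = C * (L - k + 1) / L``, so

    G = (L - k + 1) * n_base / (C_kmer * L)

where ``n_base`` is the total count of sequenced bases.  Low-depth k-mers
(frequency < 3 by default) are dominated by sequencing errors and are trimmed
before locating the coverage peak.  An optionally supplied error rate revises
the estimate as ``G_revised = G * (1 - error_rate)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "KmerSpectrum",
    "SizeEstimate",
    "trim_spectrum",
    "estimate_ckmer",
    "estimate_genome_size",
    "revise_genome_size",
    "estimate_from_spectrum",
]


@dataclass(frozen=True)
class KmerSpectrum:
    """A depth histogram of distinct k-mers plus the read-set bookkeeping.

    ``histogram`` maps depth -> number of distinct k-mers observed at that
    depth.  ``n_base`` is the total sequenced bases of the read set the
    spectrum came from (reads shorter than k still count), and ``read_len``
    the (modal) read length.
    """

    k: int
    read_len: int
    n_base: int
    histogram: dict[int, int]
    trimmed: bool = False

    def __post_init__(self) -> None:
        if self.read_len < 1:
            raise ValueError("read length must be >= 1")
        if self.n_base <= 0:
            raise ValueError("n_base must be positive")
        if any(d < 1 for d in self.histogram):
            raise ValueError("depths must be >= 1")
        if any(c < 0 for c in self.histogram.values()):
            raise ValueError("counts must be >= 0")

    @property
    def total_distinct(self) -> int:
        return sum(self.histogram.values())

    @property
    def total_instances(self) -> int:
        return sum(d * c for d, c in self.histogram.items())


@dataclass(frozen=True)
class SizeEstimate:
    c_kmer: float
    genome_size: float
    error_rate: float = 0.0
    genome_size_revised: float | None = None


def trim_spectrum(spectrum: KmerSpectrum, min_freq: int = 3) -> KmerSpectrum:
    """Drop k-mers below ``min_freq`` depth (the sequencing-error peak).

    ``n_base`` is untouched: total bases come from the reads, not from which
    k-mers survive.
    """
    hist = {d: c for d, c in spectrum.histogram.items() if d >= min_freq and c > 0}
    if not hist:
        raise ValueError(f"no k-mers left after trimming depths < {min_freq}")
    return replace(spectrum, histogram=hist, trimmed=True)


def _smooth(depths: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """3-bin moving average on the dense depth grid, truncated at the edges."""
    padded = np.concatenate([[0.0], counts, [0.0]])
    window_sum = padded[:-2] + padded[1:-1] + padded[2:]
    n_bins = np.full(len(counts), 3.0)
    n_bins[0] -= 1
    n_bins[-1] -= 1
    return window_sum / n_bins


def estimate_ckmer(spectrum: KmerSpectrum, method: str = "mode") -> float:
    """Peak depth of the (trimmed) spectrum — the C_kmer of the size formula.

    ``mode`` (default) locates the depth maximizing the 3-bin smoothed
    histogram, then returns the count-weighted mean depth over the window
    [mode/2, 2*mode] around it — a local first moment that estimates the
    expectation of the coverage peak to sub-integer precision while ignoring
    residual error mass below and repeat mass above.  (The raw integer mode of
    a Poisson-shaped peak sits about half a bin below the expected depth,
    which alone is a 2–3% bias at 20–30x.)  A tie between smoothed bins
    returns the lower depth with a warning.  ``method="mean"`` is the global
    count-weighted mean depth.
    """
    if not spectrum.histogram:
        raise ValueError("empty spectrum")
    depths = np.array(sorted(spectrum.histogram))
    counts = np.array([spectrum.histogram[d] for d in depths], dtype=float)
    if method == "mean":
        return float((depths * counts).sum() / counts.sum())
    if method != "mode":
        raise ValueError(f"unknown method {method!r}")
    # dense grid so the moving average sees the gaps
    lo, hi = int(depths[0]), int(depths[-1])
    grid = np.arange(lo, hi + 1)
    dense = np.zeros(len(grid))
    dense[depths - lo] = counts
    smooth = _smooth(grid, dense)
    peak = int(np.argmax(smooth))
    ties = np.flatnonzero(smooth == smooth[peak])
    if len(ties) > 1:
        logger.warning(
            "multimodal spectrum: smoothed ties at depths %s; using the lowest",
            (grid[ties]).tolist(),
        )
        return float(grid[ties[0]])
    mode = int(grid[peak])
    sel = (grid >= np.ceil(mode / 2)) & (grid <= np.floor(2.0 * mode))
    return float((grid[sel] * dense[sel]).sum() / dense[sel].sum())


def estimate_genome_size(spectrum: KmerSpectrum, c_kmer: float) -> float:
    """G = (L - k + 1) * n_base / (C_kmer * L); pure arithmetic."""
    if c_kmer <= 0:
        raise ValueError("C_kmer must be positive")
    L, k = spectrum.read_len, spectrum.k
    if L <= k:
        raise ValueError("read length must exceed k for the size formula")
    return (L - k + 1) * spectrum.n_base / (c_kmer * L)


def revise_genome_size(genome_size: float, error_rate: float) -> float:
    """Revised size = G * (1 - error_rate)."""
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0,1)")
    return genome_size * (1.0 - error_rate)


def estimate_from_spectrum(
    spectrum: KmerSpectrum,
    min_freq: int = 3,
    error_rate: float = 0.0,
    method: str = "mode",
) -> SizeEstimate:
    """Trim, locate the peak, apply the size formula and the error revision."""
    trimmed = trim_spectrum(spectrum, min_freq=min_freq)
    c_kmer = estimate_ckmer(trimmed, method=method)
    g = estimate_genome_size(spectrum, c_kmer)
    return SizeEstimate(
        c_kmer=c_kmer,
        genome_size=g,
        error_rate=error_rate,
        genome_size_revised=revise_genome_size(g, error_rate),
    )
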