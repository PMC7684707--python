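"""Synthetic structured-population genotypes and idealized k-mer spectra.

Every downstream stage of the pipeline (filtering, windowed diversity and
differentiation scans, genome-size estimation) is validated against data
generated here, where the ground truth — the per-deme drift parameter, the
location of the sweep regions, the true genome size — is known exactly.

Allele frequencies follow the Balding–Nichols model: an ancestral frequency
``p`` is drawn per site from a Beta distribution, and each deme's frequency is
drawn from ``Beta(p(1-F)/F', (1-p)(1-F)/F')`` parametrized so that its mean is
``p`` and its variance is ``F p (1-p)``.  The drift parameter ``F`` then equals
the expected fixation index between demes, which is what makes parameter
recovery by the Hudson estimator a meaningful end-to-end check.

A selective sweep is emulated by its two observable footprints only: elevated
differentiation (a larger drift parameter ``F_sweep`` inside the region for the
swept deme) and reduced diversity (sites in the region monomorphized in the
swept deme with probability ``1 - pi_reduction``).  No selection dynamics are
simulated — the scan only ever sees differentiation and diversity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel for a missing genotype call

__all__ = [
    "MISSING",
    "SweepSpec",
    "SimParams",
    "GenotypeMatrix",
    "simulate_frequencies",
    "sample_genotypes",
    "simulate_genotype_matrix",
    "simulate_kmer_spectrum",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SweepSpec:
    """A localized sweep footprint.

    Parameters
    ----------
    start, end:
        Half-open region [start, end) in bp on the simulated chromosome.
    target_deme:
        Index of the deme carrying the sweep.
    f_sweep:
        Drift parameter used inside the region for the target deme; must
        exceed the deme's background ``F``.
    pi_reduction:
        Multiplicative diversity factor in (0, 1]: each site in the region is
        left polymorphic in the target deme with this probability and
        monomorphized otherwise.
    """

    start: int
    end: int
    target_deme: int
    f_sweep: float
    pi_reduction: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.f_sweep < 1:
            raise ValueError(f"f_sweep must be in (0,1), got {self.f_sweep}")
        if not 0 < self.pi_reduction <= 1:
            raise ValueError(
                f"pi_reduction must be in (0,1], got {self.pi_reduction}"
            )
        if self.start >= self.end:
            raise ValueError("sweep region must have start < end")


@dataclass(frozen=True)
class SimParams:
    """Contract of the structured-population generator.

    Defaults emulate the three-population sampling design the pipeline is
    meant for: two demes connected by frequent gene flow (low drift) plus one
    diverged deme, with 11/11/6 diploid individuals.
    """

    n_demes: int = 3
    deme_sizes: tuple[int, ...] = (11, 11, 6)
    F: tuple[float, ...] = (0.02, 0.02, 0.15)
    n_sites: int = 5000
    chrom_length: int = 1_000_000
    chrom: str = "chr1"
    ancestral_beta: tuple[float, float] = (1.0, 1.0)
    sweeps: tuple[SweepSpec, ...] = ()
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.deme_sizes) != self.n_demes or len(self.F) != self.n_demes:
            raise ValueError("deme_sizes and F must have one entry per deme")
        if any(s < 2 for s in self.deme_sizes):
            raise ValueError("each deme needs at least 2 samples")
        for f in self.F:
            if not 0 < f < 1:
                raise ValueError(f"drift parameter F must be in (0,1), got {f}")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.chrom_length < self.n_sites:
            raise ValueError("chrom_length must be >= n_sites for distinct positions")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0,1)")
        for sw in self.sweeps:
            if sw.target_deme >= self.n_demes:
                raise ValueError("sweep target_deme out of range")
            if sw.f_sweep <= self.F[sw.target_deme]:
                raise ValueError("f_sweep must exceed the target deme's F")
            if sw.end > self.chrom_length:
                raise ValueError("sweep region outside chromosome")

    @property
    def pop_labels(self) -> list[str]:
        return [f"deme{d}" for d in range(self.n_demes)]


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotypes for labelled samples.

    ``calls`` is (n_samples, n_sites) int8 with entries in {0, 1, 2} counting
    alternate-allele copies, or ``MISSING`` (-1).  Positions are 1-based and
    strictly increasing within a chromosome.
    """

    sample_ids: list[str]
    pop_labels: list[str]
    chrom: np.ndarray  # (n_sites,) object/str
    pos: np.ndarray  # (n_sites,) int, 1-based
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray  # (n_samples, n_sites) int8

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.pop_labels):
            raise ValueError("every sample needs a population label")
        if self.calls.shape != (len(self.sample_ids), len(self.pos)):
            raise ValueError("calls shape mismatch")
        valid = np.isin(self.calls, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("calls must be in {0,1,2,missing}")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.pop_labels:
            seen.setdefault(lab, None)
        return list(seen)

    def pop_mask(self, pop: str) -> np.ndarray:
        mask = np.array([lab == pop for lab in self.pop_labels])
        if not mask.any():
            raise KeyError(f"unknown population {pop!r}")
        return mask

    def allele_counts(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-site called allele copies ``n`` and alt copies ``a`` for a pop."""
        sub = self.calls[self.pop_mask(pop)]
        called = sub != MISSING
        n = 2 * called.sum(axis=0)
        a = np.where(called, sub, 0).sum(axis=0)
        return n, a

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=self.sample_ids,
            pop_labels=self.pop_labels,
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            calls=self.calls[:, idx],
        )


# ---------------------------------------------------------------------------
# frequency and genotype simulation
# ---------------------------------------------------------------------------

def _site_positions(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    pos = rng.choice(params.chrom_length, size=params.n_sites, replace=False)
    pos.sort()
    return pos + 1  # 1-based


def simulate_frequencies(
    params: SimParams, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw per-site ancestral and per-deme allele frequencies.

    Returns ``(pos, p_anc, deme_freqs)`` where ``deme_freqs`` has shape
    (n_demes, n_sites).  Inside a sweep region the target deme's frequency is
    drawn with ``f_sweep`` instead of its background drift parameter.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    pos = _site_positions(params, rng)
    a, b = params.ancestral_beta
    p_anc = rng.beta(a, b, size=params.n_sites)

    deme_freqs = np.empty((params.n_demes, params.n_sites))
    for d in range(params.n_demes):
        f_site = np.full(params.n_sites, params.F[d])
        for sw in params.sweeps:
            if sw.target_deme == d:
                in_region = (pos - 1 >= sw.start) & (pos - 1 < sw.end)
                f_site[in_region] = sw.f_sweep
        # Balding–Nichols: Beta with mean p, variance F p (1-p)
        scale = (1.0 - f_site) / f_site
        alpha = np.maximum(p_anc * scale, 1e-12)
        beta = np.maximum((1.0 - p_anc) * scale, 1e-12)
        deme_freqs[d] = rng.beta(alpha, beta)
    return pos, p_anc, deme_freqs


def sample_genotypes(
    pos: np.ndarray,
    deme_freqs: np.ndarray,
    params: SimParams,
    rng: np.random.Generator | None = None,
) -> GenotypeMatrix:
    """Draw diploid calls Binomial(2, p_deme) and apply sweep diversity thinning.

    Thinning: each site in a sweep region is, with probability
    ``1 - pi_reduction``, monomorphized in the target deme — every call set to
    the homozygote nearest the deme frequency.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    if deme_freqs.min() < 0 or deme_freqs.max() > 1:
        raise ValueError("frequencies must lie in [0,1]")
    n_sites = deme_freqs.shape[1]
    sample_ids: list[str] = []
    pop_labels: list[str] = []
    blocks = []
    for d, size in enumerate(params.deme_sizes):
        calls = rng.binomial(2, deme_freqs[d][None, :], size=(size, n_sites))
        for sw in params.sweeps:
            if sw.target_deme != d:
                continue
            in_region = (pos - 1 >= sw.start) & (pos - 1 < sw.end)
            mono = in_region & (rng.random(n_sites) > sw.pi_reduction)
            fixed = np.where(deme_freqs[d] >= 0.5, 2, 0).astype(calls.dtype)
            calls[:, mono] = fixed[mono]
        blocks.append(calls)
        sample_ids += [f"deme{d}_s{i}" for i in range(size)]
        pop_labels += [f"deme{d}"] * size
    calls = np.concatenate(blocks, axis=0).astype(np.int8)
    if params.missing_rate > 0:
        miss = rng.random(calls.shape) < params.missing_rate
        calls[miss] = MISSING
    return GenotypeMatrix(
        sample_ids=sample_ids,
        pop_labels=pop_labels,
        chrom=np.full(n_sites, params.chrom, dtype=object),
        pos=pos.astype(np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        calls=calls,
    )


def simulate_genotype_matrix(params: SimParams) -> GenotypeMatrix:
    """One-call convenience: frequencies + genotypes from a single seed."""
    rng = np.random.default_rng(params.seed)
    pos, _, freqs = simulate_frequencies(params, rng)
    return sample_genotypes(pos, freqs, params, rng)


def ground_truth_table(params: SimParams) -> "pd.DataFrame":  # noqa: F821
    """Sidecar table of per-site deme frequencies and sweep membership."""
    import pandas as pd

    rng = np.random.default_rng(params.seed)
    pos, p_anc, freqs = simulate_frequencies(params, rng)
    in_sweep = np.zeros(params.n_sites, dtype=bool)
    for sw in params.sweeps:
        in_sweep |= (pos - 1 >= sw.start) & (pos - 1 < sw.end)
    data = {"chrom": params.chrom, "pos": pos, "p_ancestral": p_anc}
    for d in range(params.n_demes):
        data[f"freq_deme{d}"] = freqs[d]
    data["in_sweep"] = in_sweep.astype(int)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# idealized k-mer spectrum
# ---------------------------------------------------------------------------

def simulate_kmer_spectrum(
    g_true: int,
    coverage: float,
    read_len: int,
    error_rate: float = 0.0,
    k: int = 17,
    seed: int = 0,
):
    """Idealized shotgun k-mer depth spectrum from a genome of known size.

    Reads of length ``read_len`` are assumed to tile a random genome of
    ``g_true`` bp uniformly; every genomic k-mer is treated as distinct (a good
    approximation for k=17 and genomes well below 4^17 bp), so its sequencing
    depth is Poisson with mean ``coverage * (L-k+1)/L * (1-e)^k``.  K-mer
    instances hit by a sequencing error are modelled as distinct singletons,
    the standard error-peak shape at depth 1.

    Returns a :class:`sweepkit.kmer.KmerSpectrum`; ``n_base`` is exact
    bookkeeping (whole reads), not an estimate.
    """
    from .kmer import KmerSpectrum

    if read_len <= k:
        raise ValueError("read length must exceed k")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0,1)")
    rng = np.random.default_rng(seed)
    n_reads = int(round(g_true * coverage / read_len))
    n_base = n_reads * read_len
    kmers_per_read = read_len - k + 1
    total_instances = n_reads * kmers_per_read
    p_clean = (1.0 - error_rate) ** k
    n_error = rng.binomial(total_instances, 1.0 - p_clean)
    lam = (total_instances - n_error) / g_true
    depths = rng.poisson(lam, size=int(g_true))
    depths = depths[depths > 0]
    vals, counts = np.unique(depths, return_counts=True)
    histogram = {int(v): int(c) for v, c in zip(vals, counts)}
    if n_error:
        histogram[1] = histogram.get(1, 0) + int(n_error)
    return KmerSpectrum(k=k, read_len=read_len, n_base=n_base, histogram=histogram)
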