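import numpy as np
import pytest

import sweepkit as sk


def make_record(
    chrom="chr1", pos=100, qual=31.0,
    qd=2.1, dp=6.0, fs=59.0, mq=41.0, sor=3.9,
    genotypes=(0, 1, 2),
    **overrides,
):
    """A VariantRecord passing every hard filter unless a field is overridden.

    Pass ``qd=None`` etc. to drop an INFO key entirely.
    """
    info = {"QD": qd, "DP": dp, "FS": fs, "MQ": mq, "SOR": sor}
    info = {k: v for k, v in info.items() if v is not None}
    return sk.VariantRecord(
        chrom=chrom, pos=pos, id=None, ref="A", alt="T",
        qual=qual, info=info, genotypes=list(genotypes), **overrides,
    )


@pytest.fixture
def two_deme_matrix():
    """A small two-deme Balding-Nichols genotype matrix with clear structure."""
    params = sk.SimParams(
        n_demes=2, deme_sizes=(10, 10), F=(0.2, 0.2),
        n_sites=500, chrom_length=10_000, seed=5,
    )
    return sk.simulate_genotype_matrix(params)


@pytest.fixture
def random_matrix_factory():
    """Small random genotype matrices for brute-force oracle comparisons."""

    def make(n_samples=6, n_sites=20, n_pops=2, seed=0, missing_rate=0.0):
        rng = np.random.default_rng(seed)
        calls = rng.integers(0, 3, size=(n_samples, n_sites)).astype(np.int8)
        if missing_rate:
            calls[rng.random(calls.shape) < missing_rate] = sk.MISSING
        labels = [f"pop{i % n_pops}" for i in range(n_samples)]
        return sk.GenotypeMatrix(
            sample_ids=[f"s{i}" for i in range(n_samples)],
            pop_labels=labels,
            chrom=np.full(n_sites, "chr1", dtype=object),
            pos=np.arange(1, n_sites + 1, dtype=np.int64) * 3,
            ref=np.full(n_sites, "A", dtype=object),
            alt=np.full(n_sites, "T", dtype=object),
            calls=calls,
        )

    return make
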