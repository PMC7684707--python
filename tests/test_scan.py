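"""Z(Fst) standardization, outlier calling and gene annotation."""

import numpy as np
import pandas as pd
import pytest

import sweepkit as sk
from sweepkit.scan import OutlierCall, _tail_cutoff


def windows_frame(fst, pi_a=None, pi_b=None, size=1000):
    n = len(fst)
    pi_a = np.full(n, 1e-3) if pi_a is None else np.asarray(pi_a, float)
    pi_b = np.full(n, 1e-3) if pi_b is None else np.asarray(pi_b, float)
    df = pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n) * size,
        "end": (np.arange(n) + 1) * size,
        "n_sites": 5,
        "pi_a": pi_a,
        "pi_b": pi_b,
        "fst": np.asarray(fst, float),
    })
    return sk.scan_windows(df, "popA", "popB")


class TestZTransform:
    def test_three_point_example(self):
        z, mu, sigma = sk.z_transform(np.array([1.0, 2.0, 3.0]))
        assert z == pytest.approx([-1.0, 0.0, 1.0])
        assert mu == 2.0 and sigma == 1.0  # sample sd, denominator N-1

    def test_normalization_identity(self):
        rng = np.random.default_rng(0)
        values = rng.gamma(2.0, 0.1, size=500)
        z, _, _ = sk.z_transform(values)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12

    def test_rank_order_preserved(self):
        rng = np.random.default_rng(1)
        values = rng.random(100)
        z, _, _ = sk.z_transform(values)
        assert (np.argsort(z) == np.argsort(values)).all()

    def test_constant_input_aborts(self):
        with pytest.raises(ValueError, match="sigma"):
            sk.z_transform(np.full(10, 0.3))


class TestLog2Ratio:
    def test_simple_ratios(self):
        out = sk.log2_pi_ratio(np.array([0.002, 0.001, 0.0005]),
                               np.array([0.001, 0.001, 0.002]))
        assert out == pytest.approx([1.0, 0.0, -2.0])

    def test_zero_diversity_excluded(self):
        out = sk.log2_pi_ratio(np.array([0.0, 0.001]), np.array([0.001, 0.0]))
        assert np.isnan(out).all()


class TestCallOutliers:
    def test_top_one_percent_of_thousand_is_ten(self):
        rng = np.random.default_rng(2)
        fst = rng.normal(0.1, 0.02, 1000)  # continuous: no ties
        df = windows_frame(fst)
        z = df["zfst"].to_numpy()
        cut = _tail_cutoff(z, 0.01, "high")
        assert (z >= cut).sum() == 10

    def test_intersection_requires_both_statistics(self):
        rng = np.random.default_rng(5)
        fst = rng.normal(0.1, 0.01, 200)
        pi_a = rng.lognormal(np.log(1e-3), 0.1, 200)
        pi_b = rng.lognormal(np.log(1e-3), 0.1, 200)
        fst[0] = 0.9  # extreme Fst, unremarkable ratio
        pi_b[1] = 1e-6  # extreme ratio, unremarkable Fst
        df = windows_frame(fst, pi_a, pi_b)
        calls, _ = sk.call_outliers(df, q=0.01, rule="intersection")
        assert all(c.start not in (0, 1000) for c in calls)
        union, _ = sk.call_outliers(df, q=0.01, rule="union")
        assert {c.start for c in union} >= {0, 1000}

    def test_outlier_set_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        fst = rng.beta(2, 20, 500)
        pi_a = rng.gamma(3, 1e-4, 500)
        pi_b = rng.gamma(3, 1e-4, 500)
        df = windows_frame(fst, pi_a, pi_b)
        base, _ = sk.call_outliers(df, q=0.02)
        # strictly increasing transforms of both statistics
        df2 = windows_frame(np.exp(3 * fst), pi_a**2 / (pi_a + pi_b),
                            pi_b**2 / (pi_a + pi_b))
        # ratio transform above is monotone in pi_a/pi_b: (a/b)^2 ordering kept
        trans, _ = sk.call_outliers(df2, q=0.02)
        assert {(c.start, c.end) for c in base} == {(c.start, c.end) for c in trans}

    def test_direction_names_low_diversity_population(self):
        rng = np.random.default_rng(4)
        fst = rng.normal(0.1, 0.01, 300)
        pi_a = np.full(300, 1e-3)
        pi_b = np.full(300, 1e-3)
        fst[5] = 0.8
        pi_b[5] = 1e-5  # sweep in popB: ratio high
        fst[7] = 0.8
        pi_a[7] = 1e-5  # sweep in popA: ratio low
        df = windows_frame(fst, pi_a, pi_b)
        calls, _ = sk.call_outliers(df, q=0.01)
        directions = {c.start: c.direction for c in calls}
        assert directions[5000] == "popB"
        assert directions[7000] == "popA"

    def test_q_bounds_rejected(self):
        df = windows_frame(np.random.default_rng(0).random(50))
        for bad in (0.0, 0.5, 1.0, -0.1):
            with pytest.raises(ValueError, match="q"):
                sk.call_outliers(df, q=bad)

    def test_ties_at_cutoff_all_included(self):
        fst = np.concatenate([np.full(96, 0.1), np.full(4, 0.5)])
        pi_b = np.concatenate([np.full(96, 1e-3), np.full(4, 1e-5)])
        df = windows_frame(fst, pi_b=pi_b)
        calls, _ = sk.call_outliers(df, q=0.01)
        # cutoff is the single most extreme value, but all 4 tied windows pass
        assert len(calls) == 4


class TestSweepRecovery:
    def test_injected_sweep_recovered_with_direction(self):
        """A strong sweep (F_sweep=0.6, pi_reduction=0.1) in 8 of 1000 windows
        is recovered at q=0.01 with sensitivity >= 0.8 and the right deme."""
        sweep = sk.SweepSpec(start=500_000, end=508_000, target_deme=1,
                             f_sweep=0.6, pi_reduction=0.1)
        params = sk.SimParams(
            n_demes=2, deme_sizes=(30, 30), F=(0.1, 0.1),
            n_sites=150_000, chrom_length=1_000_000, sweeps=(sweep,), seed=11,
        )
        matrix = sk.simulate_genotype_matrix(params)
        windows = sk.make_windows({"chr1": 1_000_000})
        df = sk.scan_windows(
            sk.window_stats(matrix, windows, "deme0", "deme1"), "deme0", "deme1")
        calls, _ = sk.call_outliers(df, q=0.01)
        called = {(c.start, c.end): c.direction for c in calls}
        sweep_windows = [(s, s + 1000) for s in range(500_000, 508_000, 1000)]
        hits = [w for w in sweep_windows if w in called]
        assert len(hits) / len(sweep_windows) >= 0.8
        assert all(called[w] == "deme1" for w in hits)
        false_positives = [w for w in called if w not in sweep_windows]
        assert len(false_positives) <= 1.5 * 0.01 * len(windows)

    def test_null_scan_positive_fraction_bounded(self):
        """Without a sweep the intersection rule calls at most ~q of windows."""
        fractions = []
        for seed in range(20):
            params = sk.SimParams(
                n_demes=2, deme_sizes=(15, 15), F=(0.05, 0.05),
                n_sites=2000, chrom_length=200_000, seed=seed,
            )
            matrix = sk.simulate_genotype_matrix(params)
            windows = sk.make_windows({"chr1": 200_000})
            df = sk.scan_windows(
                sk.window_stats(matrix, windows, "deme0", "deme1"),
                "deme0", "deme1")
            calls, _ = sk.call_outliers(df, q=0.01)
            fractions.append(len(calls) / len(windows))
        assert np.mean(fractions) <= 0.015


class TestAnnotateGenes:
    def call(self, chrom, start, end):
        return OutlierCall(chrom, start, end, zfst=3.0, log2_ratio=1.0,
                           direction="popB")

    def test_one_bp_overlap_counts(self):
        calls = [self.call("chr1", 1000, 2000)]
        genes = [sk.GeneInterval("chr1", 1999, 3000, "geneA")]
        by_gene = sk.annotate_genes(calls, genes)
        assert by_gene == {"geneA": calls}
        assert calls[0].genes == ["geneA"]

    def test_half_open_boundary_no_overlap(self):
        calls = [self.call("chr1", 1000, 2000)]
        genes = [sk.GeneInterval("chr1", 2000, 3000, "geneA")]
        assert sk.annotate_genes(calls, genes) == {}

    def test_chromosome_mismatch_warns(self, caplog):
        import logging

        calls = [self.call("chr1", 0, 100)]
        genes = [sk.GeneInterval("chr2", 0, 100, "g")]
        with caplog.at_level(logging.WARNING):
            assert sk.annotate_genes(calls, genes) == {}
        assert "no shared chromosome" in caplog.text

    def test_sweep_line_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(7)
        calls = []
        for _ in range(50):
            s = int(rng.integers(0, 10_000))
            calls.append(self.call("chr1", s, s + int(rng.integers(1, 500))))
        genes = []
        for i in range(50):
            s = int(rng.integers(0, 10_000))
            genes.append(sk.GeneInterval("chr1", s, s + int(rng.integers(1, 800)), f"g{i}"))
        by_gene = sk.annotate_genes(calls, genes)
        expected = {}
        for g in genes:
            hits = [c for c in calls if c.start < g.end and c.end > g.start]
            if hits:
                expected[g.gene_id] = {(c.start, c.end) for c in hits}
        assert {g: {(c.start, c.end) for c in cs} for g, cs in by_gene.items()} == expected


class TestCompareScans:
    def test_three_way_set_arithmetic(self):
        df = sk.compare_scans({
            "AB": {"a", "b", "c"}, "AC": {"b", "c", "d"}, "BC": {"c"}})
        assert set(df.index[df["n_shared"] == 3]) == {"c"}
        assert set(df.index[df["AB"] & df["AC"] & ~df["BC"]]) == {"b"}

    def test_disjoint_and_identical_sets(self):
        disjoint = sk.compare_scans({"x": {"a"}, "y": {"b"}})
        assert (disjoint["n_shared"] == 1).all()
        same = sk.compare_scans({"x": {"a", "b"}, "y": {"a", "b"}})
        assert (same["n_shared"] == 2).all()


def test_plot_scan_writes_figure(tmp_path):
    rng = np.random.default_rng(0)
    df = windows_frame(rng.normal(0.1, 0.02, 200))
    out = tmp_path / "scan.png"
    sk.scan.plot_scan(df, str(out))
    assert out.stat().st_size > 0
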