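"""Estimator checks against independent brute-force transcriptions.

The oracles below re-derive Weir & Cockerham's two-population variance
components, pairwise-difference pi, and Tajima's D normalisation directly
from the defining formulas, independently of the package implementation.
"""

import numpy as np
import pytest

from saltscan.io_filters import MISSING
from saltscan.popgen_stats import (
    compute_window_stats,
    fst_site,
    individual_heterozygosity,
    per_site_fst,
    tajima_constants,
    window_mean_fst,
    window_pi,
    window_tajima_d,
)

from conftest import make_table


# --- independent oracles ---------------------------------------------------

def wc84_fst_oracle(g1, g2):
    """Literal transcription of the 1984 two-population ANOVA estimator."""
    r = 2
    n = [len(g1), len(g2)]
    p = [sum(g1) / (2 * n[0]), sum(g2) / (2 * n[1])]
    h = [sum(1 for x in g1 if x == 1) / n[0], sum(1 for x in g2 if x == 1) / n[1]]
    nbar = sum(n) / r
    nc = (r * nbar - sum(x * x for x in n) / (r * nbar)) / (r - 1)
    pbar = sum(n[i] * p[i] for i in range(r)) / (r * nbar)
    s2 = sum(n[i] * (p[i] - pbar) ** 2 for i in range(r)) / ((r - 1) * nbar)
    hbar = sum(n[i] * h[i] for i in range(r)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


def tajima_d_oracle(haplotypes):
    """D from all-pairs difference counting plus the 1989 constants."""
    hap = np.asarray(haplotypes)
    n, S_all = hap.shape
    seg = [s for s in range(S_all) if 0 < hap[:, s].sum() < n]
    S = len(seg)
    diffs = [
        (hap[i, seg] != hap[j, seg]).sum()
        for i in range(n) for j in range(i + 1, n)
    ]
    k_hat = sum(diffs) / len(diffs)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return (k_hat - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


# --- FST -------------------------------------------------------------------

class TestFst:
    def test_fixed_difference_is_one(self):
        assert fst_site([0] * 5, [2] * 5) == pytest.approx(1.0)

    def test_monomorphic_both_demes_undefined(self):
        assert np.isnan(fst_site([0, 0, 0], [0, 0, 0]))

    def test_matches_wc84_oracle_on_example_table(self):
        g1, g2 = [0, 1, 1, 2, 2], [0, 0, 0, 1, 1]
        assert fst_site(g1, g2) == pytest.approx(wc84_fst_oracle(g1, g2), rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_oracle_on_random_polymorphic_sites(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            g1 = rng.integers(0, 3, size=6).tolist()
            g2 = rng.integers(0, 3, size=4).tolist()
            got = fst_site(g1, g2)
            if 0 < sum(g1) + sum(g2) < 2 * (len(g1) + len(g2)):
                assert got == pytest.approx(wc84_fst_oracle(g1, g2), rel=1e-10)

    def test_deme_with_no_calls_skipped(self):
        assert np.isnan(fst_site([MISSING, MISSING], [0, 1]))

    def test_at_most_one(self):
        rng = np.random.default_rng(3)
        g1 = rng.integers(0, 3, size=(200, 5))
        g2 = rng.integers(0, 3, size=(200, 5))
        vals = per_site_fst(g1, g2)
        assert np.nanmax(vals) <= 1.0 + 1e-12

    def test_panmictic_labels_give_near_zero_mean_fst(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(0.1, 0.9, size=20_000)
        g1 = rng.binomial(2, p[:, None], size=(20_000, 10)).astype(np.int8)
        g2 = rng.binomial(2, p[:, None], size=(20_000, 10)).astype(np.int8)
        assert abs(np.nanmean(per_site_fst(g1, g2))) < 0.01


class TestWindowMeanFst:
    def test_arithmetic_mean(self):
        assert window_mean_fst(np.array([0.1, 0.2, 0.3]))[0] == pytest.approx(0.2)

    def test_singleton(self):
        assert window_mean_fst(np.array([1.0]))[0] == pytest.approx(1.0)

    def test_mixed_defined_and_undefined(self):
        vals = np.array([0.1, np.nan, 0.5, np.nan])
        mean, n = window_mean_fst(vals)
        assert (mean, n) == (pytest.approx(0.3), 2)

    def test_below_min_snps_is_nan(self):
        mean, n = window_mean_fst(np.array([0.1, np.nan]), min_snps=2)
        assert np.isnan(mean) and n == 1


class TestPi:
    def test_empty_window_zero(self):
        assert window_pi(np.zeros((0, 4))) == 0.0

    def test_single_site_formula(self):
        # one SNP at 50/50, n_c = 4 chromosomes: (4/3 * 0.5) / 25000
        g = [[1, 1]]  # two diploids, dosage 1 each -> p = 0.5, 4 chroms
        assert window_pi(np.array(g), 25_000) == pytest.approx((4 / 3 * 0.5) / 25_000)

    def test_doubling_window_length_halves_pi(self):
        g = np.array([[1, 1], [0, 2]])
        assert window_pi(g, 50_000) == pytest.approx(window_pi(g, 25_000) / 2)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(5)
        g = rng.integers(0, 3, size=(30, 8)).astype(np.int8)
        assert window_pi(2 - g) == pytest.approx(window_pi(g))


class TestTajimaD:
    def test_no_segregating_sites_missing(self):
        assert np.isnan(window_tajima_d(np.zeros((0, 5))))
        assert np.isnan(window_tajima_d(np.zeros((4, 5), dtype=np.int8)))

    def test_all_singletons_negative(self):
        g = np.zeros((16, 5), dtype=np.int8)
        for s in range(16):
            g[s, s % 5] = 1
        assert window_tajima_d(g) < 0

    def test_constants_a1(self):
        assert tajima_constants(10)["a1"] == pytest.approx(sum(1 / i for i in range(1, 10)))

    def test_matches_all_pairs_oracle_on_haplotype_fixture(self):
        rng = np.random.default_rng(42)
        hap = (rng.random((10, 16)) < 0.3).astype(np.int8)
        # pair haplotypes into 5 diploids; no missing data so n is exact
        dos = hap[0::2] + hap[1::2]
        got = window_tajima_d(dos.T)
        want = tajima_d_oracle(hap)
        assert got == pytest.approx(want, rel=1e-10)

    def test_allele_flip_invariance(self):
        rng = np.random.default_rng(9)
        g = rng.integers(0, 3, size=(25, 6)).astype(np.int8)
        a, b = window_tajima_d(g), window_tajima_d(2 - g)
        assert a == pytest.approx(b)


class TestHeterozygosity:
    def test_all_homozygous_zero(self):
        vt = make_table([[0, 2], [2, 0]])
        assert individual_heterozygosity(vt).tolist() == [0.0, 0.0]

    def test_direct_count(self):
        vt = make_table([[0], [1], [1], [2]])
        assert individual_heterozygosity(vt).iloc[0] == pytest.approx(0.5)

    def test_invariant_under_site_reordering(self):
        vt = make_table([[0, 1], [1, 2], [2, 1], [1, 0]])
        perm = make_table([[1, 0], [2, 1], [0, 1], [1, 2]])
        assert individual_heterozygosity(vt).tolist() == individual_heterozygosity(perm).tolist()


class TestComputeWindowStats:
    def test_tiling_with_partial_terminal_window(self, four_sample_popmap):
        vt = make_table(
            [[0, 1, 1, 2]] * 3, pos=[10, 30_000, 55_000],
        )
        win = compute_window_stats(
            vt, four_sample_popmap, 25_000, min_snps=1,
            chrom_lengths={"chr1": 60_000},
        )
        assert len(win) == 3
        assert win["end"].tolist() == [25_000, 50_000, 60_000]
        assert win["partial"].tolist() == [False, False, True]
        assert not win["eligible"].iloc[2]

    def test_empty_table_gives_no_data_windows(self, four_sample_popmap):
        vt = make_table(np.zeros((0, 4), dtype=np.int8), pos=[])
        win = compute_window_stats(vt, four_sample_popmap)
        assert len(win) == 0 or win["n_snps"].sum() == 0

    def test_agrees_with_per_window_single_calls(self, four_sample_popmap):
        rng = np.random.default_rng(21)
        g = rng.integers(0, 3, size=(40, 4)).astype(np.int8)
        pos = np.sort(rng.choice(50_000, size=40, replace=False))
        vt = make_table(g, pos=pos)
        win = compute_window_stats(
            vt, four_sample_popmap, 25_000, min_snps=1,
            chrom_lengths={"chr1": 50_000},
        )
        for _, row in win.iterrows():
            in_w = (pos >= row["start"]) & (pos < row["end"])
            fst = per_site_fst(g[in_w][:, :2], g[in_w][:, 2:])
            assert row["mean_fst"] == pytest.approx(np.nanmean(fst), nan_ok=True)
            assert row["pi_upland"] == pytest.approx(
                window_pi(g[in_w][:, :2], row["end"] - row["start"])
            )
            assert row["tajima_d_saltmarsh"] == pytest.approx(
                window_tajima_d(g[in_w][:, 2:]), nan_ok=True
            )
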