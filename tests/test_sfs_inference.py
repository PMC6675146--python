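"""Joint-SFS construction, composite likelihood, projection and unit conversion."""

import numpy as np
import pytest
from scipy.special import gammaln

from saltscan.io_filters import PopulationMap
from saltscan.sfs_inference import (
    JointSFS,
    bootstrap_parameter_cis,
    build_joint_sfs,
    convert_units,
    expected_joint_sfs,
    fit_model,
    fold_matrix,
    load_sfs,
    poisson_composite_loglik,
    project_matrix,
    projection_weights,
    save_sfs,
)

from conftest import make_table


@pytest.fixture
def popmap6():
    return PopulationMap({
        "s0": "upland", "s1": "upland", "s2": "upland",
        "s3": "saltmarsh", "s4": "saltmarsh", "s5": "saltmarsh",
    })


class TestBuildJointSfs:
    def test_single_derived_allele_in_pop1(self, popmap6):
        vt = make_table([[1, 0, 0, 0, 0, 0]])
        sfs = build_joint_sfs(vt, popmap6, alt_is_derived=True)
        assert sfs.counts[1, 0] == 1
        assert sfs.n_sites_retained == 1
        assert not sfs.folded

    def test_hand_tally_ten_snps(self, popmap6):
        rng = np.random.default_rng(17)
        g = rng.integers(0, 3, size=(10, 6))
        vt = make_table(g)
        sfs = build_joint_sfs(vt, popmap6, alt_is_derived=True)
        want = np.zeros((7, 7))
        for row in g:
            i, j = row[:3].sum(), row[3:].sum()
            if (i, j) not in ((0, 0), (6, 6)):
                want[i, j] += 1
        np.testing.assert_array_equal(sfs.counts, want)

    def test_folding_is_flip_invariant(self, popmap6):
        rng = np.random.default_rng(8)
        g = rng.integers(0, 3, size=(40, 6)).astype(np.int8)
        a = build_joint_sfs(make_table(g), popmap6)
        b = build_joint_sfs(make_table(2 - g), popmap6)
        np.testing.assert_allclose(a.counts, b.counts)

    def test_outgroup_polarization_and_drops(self, popmap6):
        vt = make_table([[1, 0, 0, 0, 0, 0], [1, 0, 0, 0, 0, 0], [2, 2, 2, 2, 2, 1]])
        outgroup = {
            ("chr1", int(vt.pos[0])): "A",   # matches ref: alt is derived
            ("chr1", int(vt.pos[1])): "T",   # matches alt: ref is derived
            ("chr1", int(vt.pos[2])): "G",   # matches neither: dropped
        }
        with pytest.warns(UserWarning, match="dropped"):
            sfs = build_joint_sfs(vt, popmap6, outgroup_alleles=outgroup)
        assert sfs.counts[1, 0] == 1      # site 0 as-is
        assert sfs.counts[5, 6] == 1      # site 1 complemented
        assert sfs.n_dropped_outgroup == 1

    def test_missing_genotypes_rejected(self, popmap6):
        vt = make_table([[1, 0, 0, 0, 0, -1]])
        with pytest.raises(ValueError, match="complete cases"):
            build_joint_sfs(vt, popmap6)


class TestFoldAndProject:
    def test_fold_conserves_mass_and_halves_ties(self):
        m = np.arange(9, dtype=float).reshape(3, 3)  # n1 = n2 = 2
        f = fold_matrix(m)
        # mass conservation: below-fold + tie cells capture everything
        assert f.sum() == pytest.approx(m.sum())
        # tie-diagonal cells share each complementary pair equally
        assert f[0, 2] == pytest.approx(0.5 * (m[0, 2] + m[2, 0]))
        assert f[2, 0] == pytest.approx(0.5 * (m[2, 0] + m[0, 2]))
        # self-complementary centre cell keeps its own value
        assert f[1, 1] == pytest.approx(m[1, 1])
        # everything above the fold is zeroed
        assert f[2, 2] == 0 and f[2, 1] == 0 and f[1, 2] == 0

    def test_projection_weights_rows_sum_to_one(self):
        W = projection_weights(10, 4)
        np.testing.assert_allclose(W.sum(axis=0), 1.0)

    def test_projection_to_same_size_is_identity(self):
        m = np.random.default_rng(0).random((7, 5))
        np.testing.assert_allclose(project_matrix(m, 6, 4), m)

    def test_projection_preserves_total_mass(self):
        m = np.random.default_rng(1).random((9, 9))
        assert project_matrix(m, 4, 6).sum() == pytest.approx(m.sum())


class TestPoissonLoglik:
    def test_matches_term_by_term_oracle_on_3x3(self):
        obs = JointSFS(np.array([[0, 3, 1], [2, 5, 0], [1, 0, 0]], dtype=float),
                       folded=False)
        exp = np.array([[0.5, 1.0, 0.2], [1.5, 2.0, 0.3], [0.4, 0.1, 0.6]])
        theta = 2.0
        ll, _ = poisson_composite_loglik(obs, exp, theta=theta)
        want = 0.0
        mask = obs.mask
        for i in range(3):
            for j in range(3):
                if mask[i, j]:
                    continue
                lam = theta * exp[i, j]
                o = obs.counts[i, j]
                want += o * np.log(lam) - lam - gammaln(o + 1)
        assert ll == pytest.approx(want)

    def test_analytic_theta_is_poisson_mle(self):
        obs = JointSFS(np.array([[0, 4.0], [6.0, 0]]), folded=False)
        exp = np.array([[1.0, 2.0], [3.0, 1.0]])
        ll_hat, theta_hat = poisson_composite_loglik(obs, exp)
        assert theta_hat == pytest.approx(10 / 5)
        for t in (0.5 * theta_hat, 1.5 * theta_hat):
            ll_t, _ = poisson_composite_loglik(obs, exp, theta=t)
            assert ll_hat >= ll_t

    def test_all_zero_observed_closed_form(self):
        obs = JointSFS(np.zeros((3, 3)), folded=False)
        exp = np.ones((3, 3))
        theta = 1.7
        ll, _ = poisson_composite_loglik(obs, exp, theta=theta)
        assert ll == pytest.approx(-theta * 7)  # 9 cells minus 2 masked corners

    def test_zero_expected_cell_floored_with_warning(self):
        obs = JointSFS(np.array([[0, 1.0], [0, 0]]), folded=False)
        exp = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="floored"):
            ll, _ = poisson_composite_loglik(obs, exp, theta=1.0)
        assert np.isfinite(ll)


class TestExpectedSfs:
    def test_symmetric_model_symmetric_within_mc_error(self):
        params = {"nu1": 1.0, "nu2": 1.0, "T": 0.4, "M": 1.0}
        e = expected_joint_sfs("split_migration", params, 6, 6, 20_000, seed=3)
        rel = np.abs(e - e.T) / e.sum()
        assert np.max(rel) < 0.01

    def test_isolation_concentrates_mass_on_margins(self):
        params = {"nu1": 1.0, "nu2": 1.0, "T": 4.0}
        e = expected_joint_sfs("split_no_migration", params, 6, 6, 8_000, seed=4)
        margins = e[1:, 0].sum() + e[0, 1:].sum() + e[:, 6].sum() + e[6, :].sum()
        assert margins / e.sum() > 0.9

    def test_mc_error_scales_inverse_sqrt(self):
        params = {"nu1": 1.0, "nu2": 1.0, "T": 0.5, "M": 1.0}

        def spread(n_gen):
            cells = [
                expected_joint_sfs("split_migration", params, 4, 4, n_gen, seed=s)[1, 0]
                for s in range(12)
            ]
            return np.std(cells)

        s_small, s_big = spread(400), spread(1600)
        assert s_big < s_small / 1.4  # expect ~1/2, allow monte-carlo slack


class TestFitModel:
    def make_obs(self):
        params = {"nu1": 1.0, "nu2": 1.0, "T": 0.5, "M": 1.0}
        e = expected_joint_sfs("split_migration", params, 6, 6, 30_000, seed=7)
        rng = np.random.default_rng(7)
        return JointSFS(rng.poisson(4000 * e).astype(float), folded=False), params

    def test_deterministic_under_fixed_seed(self):
        obs, _ = self.make_obs()
        f1 = fit_model(obs, "split_migration", n_starts=1, seed=3,
                       n_genealogies=400, maxiter=20)
        f2 = fit_model(obs, "split_migration", n_starts=1, seed=3,
                       n_genealogies=400, maxiter=20)
        assert f1.params == f2.params
        assert f1.loglik == f2.loglik

    def test_start_at_truth_beats_perturbed_single_start(self):
        obs, truth = self.make_obs()
        at_truth = fit_model(obs, "split_migration", n_starts=1, seed=5,
                             start_params=truth, n_genealogies=600, maxiter=40)
        perturbed = fit_model(obs, "split_migration", n_starts=1, seed=11,
                              start_params={"nu1": 4.0, "nu2": 0.1, "T": 2.0, "M": 8.0},
                              n_genealogies=600, maxiter=5)
        assert at_truth.loglik >= perturbed.loglik

    def test_all_starts_logged(self):
        obs, _ = self.make_obs()
        fit = fit_model(obs, "split_no_migration", n_starts=3, seed=1,
                        n_genealogies=300, maxiter=15)
        assert len(fit.starts) == 3
        assert fit.loglik == max(s["loglik"] for s in fit.starts)


class TestBootstrap:
    def test_single_chromosome_is_an_error(self, popmap6):
        vt = make_table([[1, 0, 0, 0, 0, 0]] * 4)
        with pytest.raises(ValueError, match=">= 2 chromosomes"):
            bootstrap_parameter_cis(vt, popmap6, "split_no_migration", n_boot=2)

    def test_replicates_recorded(self, popmap6):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(60, 6)).astype(np.int8)
        chrom = np.array([f"r{i % 3}" for i in range(60)], dtype=object)
        pos = np.concatenate([np.arange(20) * 10 + 5] * 3).astype(np.int64)
        vt = make_table(g)
        vt.chrom = chrom
        vt.pos = pos
        cis, records = bootstrap_parameter_cis(
            vt, popmap6, "split_no_migration", n_boot=3, seed=1,
            alt_is_derived=True,
            fit_kwargs={"n_genealogies": 150, "maxiter": 8, "n_starts": 1},
        )
        assert len(records) == 3
        assert set(cis) == {"nu1", "nu2", "T", "theta"}
        for lo, hi in cis.values():
            assert lo <= hi


class TestConvertUnits:
    def test_inversion_identity(self):
        mu, L, N = 3.3e-9, 1e7, 50_000
        theta = 4 * N * mu * L
        out = convert_units(theta, mu, L, 1.0, {"nu1": 1.0})
        assert out["N_ref"] == pytest.approx(N)
        assert out["N_1"] == pytest.approx(N)

    def test_doubling_L_halves_Nref(self):
        a = convert_units(100.0, 3.3e-9, 1e6, 1.0, {})
        b = convert_units(100.0, 3.3e-9, 2e6, 1.0, {})
        assert b["N_ref"] == pytest.approx(a["N_ref"] / 2)

    def test_time_and_migration_scaling_round_trip(self):
        mu, L = 3.3e-9, 1e7
        scaled = {"T": 0.25, "M": 2.0, "nu2": 0.5}
        out = convert_units(1000.0, mu, L, 1.0, scaled)
        N_ref = out["N_ref"]
        assert out["T_generations"] == pytest.approx(0.25 * 2 * N_ref)
        assert out["m"] == pytest.approx(2.0 / (2 * N_ref))
        # algebraic inverse recovers the scaled values
        assert out["T_generations"] / (2 * N_ref) == pytest.approx(scaled["T"])
        assert out["m"] * 2 * N_ref == pytest.approx(scaled["M"])

    def test_bad_length_raises(self):
        with pytest.raises(ValueError, match="positive"):
            convert_units(1.0, 3.3e-9, 0, 1.0, {})


class TestSerialisation:
    def test_round_trip(self, tmp_path, popmap6):
        rng = np.random.default_rng(19)
        vt = make_table(rng.integers(0, 3, size=(30, 6)))
        sfs = build_joint_sfs(vt, popmap6)
        p = tmp_path / "sfs.txt"
        save_sfs(sfs, p)
        back = load_sfs(p)
        assert back.folded == sfs.folded
        np.testing.assert_allclose(back.counts, sfs.counts)
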