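"""Neural analyses on planted-tuning fixtures and constructed matrices."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import special_ortho_group
from sklearn.metrics import adjusted_rand_score

from econrnn import neuro
from econrnn.neuro import (
    PlantedGroup,
    classify_selectivity,
    delta_r2,
    fractional_task_variance,
    participation_ratio,
    pc_regression,
    principal_angles,
    procrustes_align,
    reaction_times,
    regress_all,
    regress_neuron,
    synthetic_rate_fixture,
    task_variance_clusters,
    temporal_stability_index,
    tsi_distribution,
)


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(7)
    groups = [
        PlantedGroup(30, "OVC", slope=0.5),
        PlantedGroup(20, "CV", slope=0.5),
        PlantedGroup(20, "CH", slope=1.0),
        PlantedGroup(30, "none"),
    ]
    tensor, labels = synthetic_rate_fixture(groups, n_trials=400, rng=rng,
                                            noise_sigma=0.3)
    regs = regress_all(tensor.window("offer"), tensor.trials[list(neuro.CANONICAL_VARIABLES)])
    return tensor, labels, regs


class TestRegression:
    def test_noiseless_line_is_fit_exactly(self, rng):
        x = rng.uniform(0, 1, 50)
        slope, r2, p = regress_neuron(2 * x + 1, x)
        assert slope == pytest.approx(2.0)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-20

    def test_shuffled_rates_produce_calibrated_false_positives(self, rng):
        hits = 0
        n_rep = 400
        x = rng.uniform(0, 1, 60)
        for _ in range(n_rep):
            y = rng.normal(0, 1, 60)
            _, _, p = regress_neuron(y, x)
            hits += p < 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.03)

    def test_vectorized_regression_matches_per_neuron_calls(self, rng):
        rates = rng.normal(1, 0.5, (40, 3, 4))
        x = rng.uniform(0, 2, 40)
        vars_ = pd.DataFrame({"OVC": x})
        regs = regress_all(rates, vars_)
        for t in range(3):
            for j in range(4):
                slope, r2, p = regress_neuron(rates[:, t, j], x)
                assert regs["OVC"]["slope"][t, j] == pytest.approx(slope)
                assert regs["OVC"]["r2"][t, j] == pytest.approx(r2)
                assert regs["OVC"]["p"][t, j] == pytest.approx(p, rel=1e-6)

    def test_degenerate_regressor_rejected(self, rng):
        with pytest.raises(ValueError):
            regress_neuron(rng.normal(0, 1, 10), np.ones(10))


class TestSelectivity:
    def test_planted_labels_recovered_during_offer_period(self, planted):
        tensor, labels, regs = planted
        prof = classify_selectivity(regs)
        mid = prof.labels.shape[0] // 2
        recovered = []
        for j, true in enumerate(labels):
            li = prof.labels[mid, j]
            recovered.append(prof.variables[li] if li >= 0 else "none")
        # planted CV/OV signals correlate, so require majority-correct recovery
        acc = np.mean([r == t for r, t in zip(recovered, labels) if t != "none"])
        assert acc > 0.8
        # with 8 candidate variables and no multiple-testing correction the
        # family-wise false-positive rate on untuned neurons is about
        # 1 - (1 - alpha_eff)^8; alpha_eff < 0.05 because the R2 floor also
        # binds, so anything approaching that bound (not the naive 5%) is
        # the calibrated expectation
        none_fp = np.mean([r != "none" for r, t in zip(recovered, labels)
                           if t == "none"])
        assert none_fp < 1 - 0.95 ** 8 + 0.1

    def test_noiseless_fixture_recovers_every_label(self, rng):
        groups = [PlantedGroup(10, "OVC", 0.5), PlantedGroup(10, "OVE", -0.5)]
        tensor, labels = synthetic_rate_fixture(groups, 200, rng, noise_sigma=0.0)
        regs = regress_all(tensor.window("offer"),
                           tensor.trials[["OVC", "OVE"]])
        prof = classify_selectivity(regs, variables=("OVC", "OVE"))
        got = [prof.variables[prof.labels[0, j]] for j in range(20)]
        assert got == labels

    def test_never_selective_neuron_gets_no_label(self, planted):
        tensor, labels, regs = planted
        prof = classify_selectivity(regs)
        # rule-period activity is untuned; use a pure-noise regression there
        assert (prof.labels >= -1).all()


class TestTSI:
    def test_constant_label_gives_unit_stability(self):
        assert temporal_stability_index(np.array([2, 2, 2, 2])) == 1.0

    def test_eight_of_ten_primary_bins(self):
        labels = np.array([0] * 8 + [1] * 2)
        assert temporal_stability_index(labels) == pytest.approx(0.8)

    def test_tie_breaks_to_lowest_variable_index(self):
        labels = np.array([0, 1, 0, 1, -1, -1])
        assert temporal_stability_index(labels) == pytest.approx(0.5)

    def test_never_selective_is_undefined(self):
        with pytest.raises(ValueError):
            temporal_stability_index(np.array([-1, -1]))

    def test_pure_coders_have_unit_tsi(self, rng):
        groups = [PlantedGroup(15, "CV", 0.8)]
        tensor, _ = synthetic_rate_fixture(groups, 300, rng, noise_sigma=0.05)
        regs = regress_all(tensor.window("offer"), tensor.trials[["OVC", "CV"]])
        prof = classify_selectivity(regs, variables=("OVC", "CV"))
        tsis = tsi_distribution(prof)
        assert np.median(tsis) > 0.9


class TestDeltaR2:
    def test_pure_coder_sits_at_plus_max(self, rng):
        groups = [PlantedGroup(10, "OVC", 1.0)]
        tensor, _ = synthetic_rate_fixture(groups, 300, rng, noise_sigma=0.01)
        regs = regress_all(tensor.window("offer"), tensor.trials[["OVC", "CH"]])
        d = delta_r2(regs, ("OVC", "CH"), mode="strict")
        assert d.size > 0 and (d > 0.4).all()

    def test_categorical_mixture_is_bimodal(self, rng):
        groups = [PlantedGroup(10, "OVC", 1.0), PlantedGroup(10, "CH", 2.0)]
        tensor, _ = synthetic_rate_fixture(groups, 400, rng, noise_sigma=0.05)
        regs = regress_all(tensor.window("offer"), tensor.trials[["OVC", "CH"]])
        d = delta_r2(regs, ("OVC", "CH"), mode="strict")
        assert (d > 0.4).any() and (d < -0.4).any()
        assert not ((-0.2 < d) & (d < 0.2)).any()

    def test_mixed_coders_concentrate_near_zero_lenient(self, rng):
        n_tr = 400
        rngl = np.random.default_rng(3)
        ovc = rngl.uniform(1, 10, n_tr)
        ove = rngl.uniform(1, 10, n_tr)
        trials = pd.DataFrame({"OVC": ovc, "OVE": ove})
        rates = (0.5 * ovc + 0.5 * ove)[:, None, None] + rngl.normal(0, 0.5, (n_tr, 2, 12))
        regs = regress_all(rates, trials)
        d = delta_r2(regs, ("OVC", "OVE"), mode="lenient")
        assert np.abs(np.median(d)) < 0.15


class TestParticipationRatio:
    def test_even_spread_counts_dimensions(self, rng):
        # two uncorrelated unit-variance directions -> PR = 2
        X = rng.normal(0, 1, (20_000, 2))
        assert participation_ratio(X) == pytest.approx(2.0, abs=0.05)

    def test_rank_one_activity_is_one_dimensional(self, rng):
        u = rng.normal(0, 1, 300)
        X = np.outer(u, [1.0, 2.0, -1.0])
        assert participation_ratio(X) == pytest.approx(1.0)

    def test_eigenvalue_arithmetic_2_1_1(self, rng):
        # eigenvalues (2,1,1): PR = 16/6
        X = rng.normal(0, 1, (60_000, 3)) * np.sqrt([2.0, 1.0, 1.0])
        assert participation_ratio(X) == pytest.approx(16 / 6, rel=0.03)

    def test_invariant_to_rotation(self, rng):
        X = rng.normal(0, 1, (500, 6)) * np.array([2.0, 1.5, 1, 0.5, 0.2, 0.1])
        Q = special_ortho_group.rvs(6, random_state=1)
        assert participation_ratio(X @ Q) == pytest.approx(participation_ratio(X))

    def test_unchanged_by_neuron_duplication(self, rng):
        X = rng.normal(0, 1, (400, 5))
        # doubling every neuron doubles each eigenvalue; the ratio is unchanged
        assert participation_ratio(np.hstack([X, X])) == pytest.approx(
            participation_ratio(X))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            participation_ratio(np.ones((10, 3)))

    def test_planted_two_dimensional_geometry(self, rng):
        groups = [PlantedGroup(20, "CV", 0.6), PlantedGroup(20, "CH", 3.0)]
        tensor, _ = synthetic_rate_fixture(groups, 500, rng, noise_sigma=0.05)
        act = neuro.offer_window_activity(tensor, epoch="offer")
        pr = participation_ratio(act)
        assert pr == pytest.approx(2.0, abs=0.5)


class TestPCRegression:
    def test_planted_pc1_is_chosen_value(self, rng):
        n = 600
        cv = rng.uniform(1, 10, n)
        ch = rng.choice([-1.0, 1.0], n)
        variables = pd.DataFrame({"CV": cv, "CH": ch})
        act = np.outer(cv, rng.uniform(0.5, 1, 30))
        act += np.outer(ch, np.concatenate([rng.uniform(0.2, 0.4, 15),
                                            -rng.uniform(0.2, 0.4, 15)]))
        act += rng.normal(0, 0.1, act.shape)
        table = pc_regression(act, variables)
        assert table.loc[1, "CV"] > 0.95
        assert table.loc[1, "CH"] < 0.3

    def test_variable_orthogonal_to_activity_scores_zero(self, rng):
        act = rng.normal(0, 1, (300, 10))
        variables = pd.DataFrame({"X": rng.normal(0, 1, 300)})
        table = pc_regression(act, variables)
        assert (table["X"] < 0.05).all()


class TestPrincipalAngles:
    def test_identical_subspaces_have_zero_angle(self, rng):
        X = rng.normal(0, 1, (400, 8)) * np.array([3, 2, 1, .1, .1, .1, .1, .1])
        M = principal_angles({"a": X, "b": X.copy()})
        assert M.loc["a", "b"] == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_planes_are_ninety_degrees(self, rng):
        n = 2000
        a = np.zeros((n, 4))
        b = np.zeros((n, 4))
        a[:, :2] = rng.normal(0, [2.0, 1.0], (n, 2))
        b[:, 2:] = rng.normal(0, [2.0, 1.0], (n, 2))
        M = principal_angles({"a": a, "b": b})
        assert M.loc["a", "b"] == pytest.approx(90.0, abs=1e-6)

    def test_random_planes_match_monte_carlo_oracle(self, rng):
        """The largest principal angle between random 2-planes in R^6 is
        compared against a direct Monte-Carlo distribution."""
        from scipy.linalg import subspace_angles as sa

        def sample_angle(r):
            A = r.normal(0, 1, (6, 2))
            B = r.normal(0, 1, (6, 2))
            return np.degrees(sa(A, B).max())

        oracle = np.array([sample_angle(rng) for _ in range(3000)])
        # activity whose covariance has an isotropic 2-plane structure
        draws = []
        for _ in range(60):
            A = rng.normal(0, 1, (6, 2))
            B = rng.normal(0, 1, (6, 2))
            Xa = rng.normal(0, 1, (800, 2)) @ A.T
            Xb = rng.normal(0, 1, (800, 2)) @ B.T
            M = principal_angles({"a": Xa, "b": Xb})
            draws.append(M.loc["a", "b"])
        lo, hi = np.percentile(oracle, [1, 99])
        assert lo < np.median(draws) < hi


class TestProcrustes:
    def test_identity_alignment_has_zero_residual(self, rng):
        X = rng.normal(0, 1, (5, 4))
        aligned, R, resid = procrustes_align(X, X)
        assert resid == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(aligned, X)

    def test_known_rotation_is_recovered(self, rng):
        X = rng.normal(0, 1, (6, 4))
        Q = special_ortho_group.rvs(4, random_state=2)
        aligned, R, resid = procrustes_align(X @ Q, X)
        assert resid == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, Q.T)

    def test_alignment_never_worse_than_unaligned(self, rng):
        X = rng.normal(0, 1, (5, 3))
        Y = X @ special_ortho_group.rvs(3, random_state=3) + rng.normal(0, 0.1, (5, 3))
        aligned, R, resid = procrustes_align(Y, X)
        assert resid <= ((Y - X) ** 2).sum() + 1e-12


class TestClustering:
    def test_planted_profiles_recovered(self, rng):
        profiles = np.vstack([
            np.tile([1, 1, 1, 1, 1.0], (40, 1)),
            np.tile([0.05, 0.05, 0.05, 1, 0.05], (30, 1)),
            np.tile([0.05, 0.05, 0.05, 0.05, 1.0], (30, 1)),
        ]) + rng.normal(0, 0.03, (100, 5))
        true = np.repeat([0, 1, 2], [40, 30, 30])
        labels, cents, k, sil = task_variance_clusters(profiles, seed=0)
        assert k == 3
        assert adjusted_rand_score(true, labels) > 0.9

    def test_profiles_normalized_to_unit_max(self, rng):
        tensors = {}
        for name in ["a", "b"]:
            groups = [PlantedGroup(10, "OVC", 1.0 if name == "a" else 0.2)]
            tensors[name], _ = synthetic_rate_fixture(groups, 100, rng,
                                                      noise_sigma=0.1)
        prof = neuro.task_variance_profiles(tensors)
        assert np.allclose(prof.max(axis=1), 1.0)

    def test_degenerate_identical_profiles_fall_back_to_two(self, rng):
        profiles = np.ones((30, 5)) + rng.normal(0, 1e-9, (30, 5))
        labels, cents, k, sil = task_variance_clusters(profiles, seed=0)
        assert k == 2


class TestFractionalTaskVariance:
    def test_balanced_variance_is_zero(self):
        assert fractional_task_variance(np.array([2.0]), np.array([2.0]))[0] == 0.0

    def test_exclusive_variance_is_plus_one(self):
        assert fractional_task_variance(np.array([1.0]), np.array([0.0]))[0] == 1.0

    def test_disjoint_populations_are_bimodal(self, rng):
        tv1 = np.concatenate([rng.uniform(0.5, 1, 50), np.zeros(50)])
        tv2 = np.concatenate([np.zeros(50), rng.uniform(0.5, 1, 50)])
        f = fractional_task_variance(tv1, tv2)
        assert ((f == 1) | (f == -1)).all()
        assert (f == 1).sum() == 50

    def test_zero_sum_neurons_excluded(self):
        f = fractional_task_variance(np.array([0.0, 1.0]), np.array([0.0, 0.0]))
        assert f.shape == (1,)


class TestReactionTimes:
    def _frame(self, rts, dv0, dv1):
        return pd.DataFrame({"completed": True, "rt_ms": rts,
                             "slot0_value": dv0, "slot1_value": dv1})

    def test_single_step_response_is_twenty_ms(self):
        f = self._frame([20.0], [5.0], [3.0])
        rts, slope, p = reaction_times(f)
        assert rts[0] == 20.0

    def test_difficulty_independent_rts_give_flat_slope(self, rng):
        n = 500
        f = self._frame(rng.choice([20.0, 40.0, 60.0], n),
                        rng.uniform(1, 10, n), rng.uniform(1, 10, n))
        _, slope, p = reaction_times(f)
        assert p > 0.01 or abs(slope) < 1.0

    def test_planted_difficulty_effect_detected(self, rng):
        n = 500
        v0 = rng.uniform(1, 10, n)
        v1 = rng.uniform(1, 10, n)
        rts = 200 - 10 * np.abs(v0 - v1) + rng.normal(0, 5, n)
        _, slope, p = reaction_times(self._frame(rts, v0, v1))
        assert slope == pytest.approx(-10, rel=0.15)
        assert p < 1e-6


class TestRateTensorIO:
    def test_hdf5_roundtrip(self, rng, tmp_path):
        groups = [PlantedGroup(5, "OVC", 1.0)]
        tensor, _ = synthetic_rate_fixture(groups, 40, rng, noise_sigma=0.1)
        path = tmp_path / "rates.h5"
        neuro.save_rate_tensor(path, tensor)
        back = neuro.load_rate_tensor(path)
        assert np.array_equal(back.rates, tensor.rates)
        assert back.epochs == tensor.epochs
        assert np.allclose(back.trials["OVC"], tensor.trials["OVC"])


class TestHistogramInvariance:
    def test_statistics_invariant_to_trial_order(self, rng):
        groups = [PlantedGroup(10, "OVC", 1.0), PlantedGroup(10, "CH", 1.0)]
        tensor, _ = synthetic_rate_fixture(groups, 200, rng, noise_sigma=0.2)
        regs = regress_all(tensor.window("offer"), tensor.trials[["OVC", "CH"]])
        d1 = delta_r2(regs, ("OVC", "CH"), mode="lenient")
        perm = np.random.default_rng(0).permutation(200)
        rates_p = tensor.rates[perm]
        regs_p = regress_all(rates_p[:, tensor.epochs["offer"][0]:tensor.epochs["offer"][1]],
                             tensor.trials.iloc[perm][["OVC", "CH"]].reset_index(drop=True))
        d2 = delta_r2(regs_p, ("OVC", "CH"), mode="lenient")
        assert np.allclose(np.sort(d1), np.sort(d2))
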