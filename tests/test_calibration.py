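"""Objective components, SCE optimizer, COFI and warming summaries."""

import numpy as np
import pytest
from scipy import stats

from cellumend.calibrate import (DEFAULT_BOUNDS, CofiResult, MendObjective,
                                 ObjectiveSpec, cofi_uncertainty,
                                 n_observations, objective_total,
                                 sce_optimize, warming_effect_table)
from cellumend.mend import MendParams, MendState, simulate
from cellumend.synthetic import (ForcingDesign, ObservationSet, gen_forcing,
                                 gen_observations)


@pytest.fixture(scope="module")
def noiseless_setup(default_params, default_init):
    fc = gen_forcing(ForcingDesign(n_days=365, seed=17))
    obs = gen_observations(default_params, default_init, fc,
                           noise_sd_map={"rh": 0, "mbc": 0, "gene": 0},
                           seed=3, substeps_per_day=1)
    return fc, obs


class TestObjective:
    def test_self_fit_is_zero(self, noiseless_setup, default_params,
                              default_init):
        fc, obs = noiseless_setup
        j, j1, j2, j3 = objective_total(default_params, obs, default_init,
                                        fc, ObjectiveSpec(w3=1.0),
                                        substeps_per_day=1)
        assert j == pytest.approx(0.0, abs=1e-9)
        assert j1 == pytest.approx(1.0, abs=1e-12)
        assert j2 == pytest.approx(1.0, abs=1e-12)
        assert j3 == pytest.approx(1.0, abs=1e-9)

    def test_zero_gene_weight_reduces_to_traditional(self, noiseless_setup,
                                                     default_params,
                                                     default_init):
        fc, obs = noiseless_setup
        spec_t = ObjectiveSpec(w3=0.0)
        j_t, j1, j2, j3 = objective_total(default_params, obs, default_init,
                                          fc, spec_t, substeps_per_day=1)
        assert j_t == pytest.approx(spec_t.w1 * (1 - j1)
                                    + spec_t.w2 * (1 - j2), abs=1e-15)
        assert np.isnan(j3)
        assert spec_t.mode == "tMEND"
        assert ObjectiveSpec(w3=0.5).mode == "gMEND"

    def test_shuffled_gene_series_destroys_j3(self, default_params,
                                              default_init):
        fc = gen_forcing(ForcingDesign(n_days=365, seed=17))
        obs = gen_observations(default_params, default_init, fc,
                               noise_sd_map={"rh": 0, "mbc": 0, "gene": 0},
                               seed=3, gene_every=30, substeps_per_day=1)
        rng = np.random.default_rng(5)
        j_self, *_ = objective_total(default_params, obs, default_init, fc,
                                     ObjectiveSpec(w3=1.0),
                                     substeps_per_day=1)
        j3s = []
        for _ in range(100):
            shuffled = ObservationSet(
                rh_days=obs.rh_days, rh=obs.rh, mbc_days=obs.mbc_days,
                mbc=obs.mbc, gene_days=obs.gene_days,
                gene=rng.permutation(obs.gene))
            j, _, _, j3 = objective_total(default_params, shuffled,
                                          default_init, fc,
                                          ObjectiveSpec(w3=1.0),
                                          substeps_per_day=1)
            j3s.append(j3)
            assert j > j_self
        assert abs(np.mean(j3s)) < 0.15

    def test_constant_observations_rejected(self, default_params,
                                            default_init):
        fc = gen_forcing(ForcingDesign(n_days=120, seed=2))
        obs = gen_observations(default_params, default_init, fc, seed=1)
        flat = ObservationSet(rh_days=obs.rh_days,
                              rh=np.full_like(obs.rh, 0.005),
                              mbc_days=obs.mbc_days, mbc=obs.mbc,
                              gene_days=obs.gene_days, gene=obs.gene)
        with pytest.raises(ValueError, match="constant observation"):
            objective_total(default_params, flat, default_init, fc,
                            ObjectiveSpec())

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            ObjectiveSpec(w1=0.0, w2=0.0, w3=0.0)
        with pytest.raises(ValueError):
            ObjectiveSpec(w1=-1.0)


class TestSce:
    def test_convex_quadratic_recovered(self):
        target = np.array([0.3, -1.2, 2.0, 0.7, -0.5])

        def f(x):
            return float(((np.asarray(x) - target) ** 2).sum())

        res = sce_optimize(f, [(-5, 5)] * 5, n_complexes=3, max_evals=3000,
                           seed=1)
        assert np.abs(res.best_x - target).max() < 1e-4

    def test_same_seed_identical_history(self):
        def f(x):
            return float((np.asarray(x) ** 2).sum())

        a = sce_optimize(f, [(-2, 2)] * 3, max_evals=300, seed=9)
        b = sce_optimize(f, [(-2, 2)] * 3, max_evals=300, seed=9)
        assert np.array_equal(a.history_x, b.history_x)
        assert np.array_equal(a.history_J, b.history_J)

    def test_all_evaluations_inside_bounds(self):
        bounds = [(-1, 2), (0.5, 3)]

        def f(x):
            return float((np.asarray(x) ** 2).sum())

        res = sce_optimize(f, bounds, max_evals=400, seed=4)
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        assert (res.history_x >= lo).all() and (res.history_x <= hi).all()

    def test_best_j_non_increasing_over_history_prefix(self):
        def f(x):
            return float((np.asarray(x) ** 2).sum())

        res = sce_optimize(f, [(-3, 3)] * 4, max_evals=500, seed=2)
        running = np.minimum.accumulate(res.history_J)
        assert (np.diff(running) <= 0).all()

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            sce_optimize(lambda x: 0.0, [(0, 0)], seed=0)
        with pytest.raises(ValueError):
            sce_optimize(lambda x: 0.0, [(0, 1)], n_complexes=1, seed=0)


class TestCofi:
    def test_f_quantile_hand_example(self):
        # p=2, n=12, alpha=0.05, J_min=1 -> 1 + 0.2 * F95(2,10)
        hist_x = np.array([[1.0, 1.0], [2.0, 2.0]])
        hist_j = np.array([1.0, 5.0])
        res = cofi_uncertainty(hist_x, hist_j, p=2, n=12, alpha=0.05)
        expected = 1.0 * (1 + 2 / 10 * stats.f.ppf(0.95, 2, 10))
        assert res.J_critical == pytest.approx(expected, abs=1e-12)
        assert res.J_critical == pytest.approx(1.8206, abs=1e-3)

    def test_alpha_to_one_shrinks_feasible_set_to_optimum(self):
        rng = np.random.default_rng(3)
        hist_x = rng.uniform(0, 1, size=(200, 3))
        hist_j = rng.uniform(1.0, 3.0, size=200)
        loose = cofi_uncertainty(hist_x, hist_j, p=3, n=50, alpha=0.05)
        tight = cofi_uncertainty(hist_x, hist_j, p=3, n=50, alpha=0.9999)
        assert tight.J_critical < loose.J_critical
        assert len(tight.feasible_J) <= len(loose.feasible_J)
        assert len(tight.feasible_J) >= 1  # optimum always feasible
        assert tight.J_critical >= tight.J_min

    def test_cv_nonnegative_and_optimum_always_feasible(self):
        rng = np.random.default_rng(8)
        hist_x = rng.uniform(1, 2, size=(50, 4))
        hist_j = rng.uniform(0.2, 1.0, size=50)
        res = cofi_uncertainty(hist_x, hist_j, p=4, n=30)
        assert (res.cv >= 0).all()
        assert res.feasible_J.min() == hist_j.min()

    def test_n_not_larger_than_p_rejected(self):
        with pytest.raises(ValueError, match="n > p"):
            cofi_uncertainty(np.ones((3, 2)), np.ones(3), p=2, n=2)

    def test_observation_count_per_mode(self, default_params, default_init):
        fc = gen_forcing(ForcingDesign(n_days=120, seed=6))
        obs = gen_observations(default_params, default_init, fc, seed=0)
        n_t = n_observations(obs, ObjectiveSpec(w3=0.0))
        n_g = n_observations(obs, ObjectiveSpec(w3=1.0))
        assert n_g == n_t + len(obs.gene)


class TestWarmingEffects:
    def test_identical_inputs_zero_change(self):
        s = {"Rh": [1.0, 1.1], "MB": [2.0, 2.1]}
        out = warming_effect_table(s, s)
        assert np.allclose(out["delta_pct"], 0.0)

    def test_temperature_monotonicity_of_rh(self, default_params,
                                            default_init):
        from cellumend.mend import ForcingSeries, derive_outputs
        n = 365
        lit = np.full(n, 0.005)
        cold = ForcingSeries(temperature=np.full(n, 16.3),
                             moisture=np.full(n, 0.35), litter_input=lit)
        warm = ForcingSeries(temperature=np.full(n, 18.1),
                             moisture=np.full(n, 0.35), litter_input=lit)
        oc = derive_outputs(simulate(default_params, default_init, cold))
        ow = derive_outputs(simulate(default_params, default_init, warm))
        out = warming_effect_table({k: [v] for k, v in oc.items()},
                                   {k: [v] for k, v in ow.items()})
        assert out.loc["Rh", "delta_pct"] > 0

    def test_delta_antisymmetry_identity(self):
        a = {"x": [2.0]}
        b = {"x": [3.0]}
        fwd = warming_effect_table(a, b).loc["x", "delta_pct"]
        rev = warming_effect_table(b, a).loc["x", "delta_pct"]
        assert rev == pytest.approx(-100 * fwd / (100 + fwd), abs=1e-12)


class TestMendObjectiveVector:
    def test_invalid_region_returns_large_penalty(self, noiseless_setup,
                                                  default_init):
        fc, obs = noiseless_setup
        objf = MendObjective(obs, default_init, fc, ObjectiveSpec(),
                             calibrated=("Vd", "Ec"))
        assert objf([0.5, 1.5]) == 1e6  # Ec outside (0,1)

    def test_bounds_match_calibrated_names(self, noiseless_setup,
                                           default_init):
        fc, obs = noiseless_setup
        objf = MendObjective(obs, default_init, fc, ObjectiveSpec(),
                             calibrated=("Vd", "Q10"))
        assert objf.bounds() == [DEFAULT_BOUNDS["Vd"], DEFAULT_BOUNDS["Q10"]]
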