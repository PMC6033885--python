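import numpy as np
import pytest
from scipy.special import logsumexp
from scipy.stats import spearmanr

import borerisk as br
from borerisk.enm import (FeatureSpec, binarize, compute_threshold, fit_gibbs,
                          fit_replicates_median, jackknife_importance,
                          predict_raw, presence_cell_indices, stack_richness)
from conftest import make_stack


class TestFit:
    def test_uniform_presences_give_near_zero_coefficients(self, small_landscape):
        stack, _ = small_landscape
        uniform = br.gen_true_suitability(stack, (0.0, 0.0))
        occs = br.sample_occurrences(uniform, 1000, seed=5)
        model = fit_gibbs(occs, stack, FeatureSpec(("linear",), beta=0.1))
        # coefficients stay within sampling noise of zero (SE ~ 0.16 at n=1000)
        assert np.all(np.abs(model.lam) <= 0.5)
        raw = predict_raw(model, stack).valid_values()
        n = stack.valid_mask.sum()
        # raw output approximately the uniform density 1/N
        assert np.all(np.abs(raw - 1.0 / n) <= 0.5 / n)

    def test_huge_penalty_zeroes_all_coefficients(self, small_landscape):
        stack, suit = small_landscape
        occs = br.sample_occurrences(suit, 200, seed=6)
        model = fit_gibbs(occs, stack, FeatureSpec(("linear", "quadratic"), beta=1e6))
        assert np.all(np.abs(model.lam) < 1e-4)

    def test_coefficient_recovery_without_penalty(self, small_landscape):
        """Mean fitted coefficients over seeds recover the generating ones."""
        stack, suit = small_landscape
        lams = []
        for s in range(6):
            occs = br.sample_occurrences(suit, 500, seed=40 + s)
            m = fit_gibbs(occs, stack, FeatureSpec(("linear",), beta=0.0))
            lams.append(m.lam)
        mean_lam = np.mean(lams, axis=0)
        assert np.all(np.abs(mean_lam - np.array([2.0, -1.0])) <= 0.2)

    def test_raw_output_sums_to_one_on_calibration(self, trained_model):
        _, _, _, model = trained_model
        stack = trained_model[0]
        raw = predict_raw(model, stack)
        assert raw.valid_values().sum() == pytest.approx(1.0, abs=1e-8)

    def test_fitted_lambda_is_a_local_optimum(self, trained_model):
        stack, _, occs, model = trained_model
        row, col, _ = presence_cell_indices(occs, stack)
        F_bg = model.features(stack)
        sub = br.EnvStack(list(stack.layer_names),
                          stack.values[:, row, col][:, :, None],
                          np.zeros((len(row), 1), bool), stack.georef)
        F_pres = model.features(sub)
        s = np.maximum(F_pres.std(axis=0, ddof=0), 1e-3)
        betas = model.feature_spec.betas(stack.layer_names) * s / np.sqrt(len(row))

        def objective(lam):
            pen = np.sum(betas * np.sqrt(lam ** 2 + 1e-8))
            return -(F_pres.mean(0) @ lam) + logsumexp(F_bg @ lam) + pen

        base = objective(model.lam)
        for j in range(len(model.lam)):
            for d in (+0.01, -0.01):
                lam = model.lam.copy()
                lam[j] += d
                assert objective(lam) >= base - 1e-7

    def test_stronger_penalty_shrinks_coefficient_norm(self, small_landscape):
        stack, suit = small_landscape
        occs = br.sample_occurrences(suit, 300, seed=8)
        norms = []
        for beta in (0.0, 0.5, 2.0, 10.0):
            m = fit_gibbs(occs, stack, FeatureSpec(("linear", "quadratic"), beta=beta))
            norms.append(np.abs(m.lam).sum())
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_presences_off_grid_warn_and_error(self, small_landscape):
        stack, suit = small_landscape
        occs = br.sample_occurrences(suit, 10, seed=9)
        df = occs.records.copy()
        df.loc[0, "lon"] = 50.0  # far outside the template
        with pytest.warns(UserWarning, match="dropped"):
            fit_gibbs(br.OccurrenceSet(df), stack)
        df2 = df.copy()
        df2["lon"] = 50.0
        with pytest.raises(ValueError):
            fit_gibbs(br.OccurrenceSet(df2), stack)


class TestTransfer:
    def test_calibration_prediction_normalized(self, trained_model):
        stack, _, _, model = trained_model
        assert predict_raw(model, stack).valid_values().sum() == pytest.approx(
            1.0, abs=1e-8)

    def test_zero_model_is_uniform(self, small_landscape):
        stack, _ = small_landscape
        model = br.GibbsModel(FeatureSpec(("linear",)), list(stack.layer_names),
                              np.zeros(2),
                              stack.table().min(0), stack.table().max(0),
                              float(np.log(stack.valid_mask.sum())),
                              int(stack.valid_mask.sum()))
        raw = predict_raw(model, stack).valid_values()
        np.testing.assert_allclose(raw, 1.0 / stack.valid_mask.sum(), rtol=1e-12)

    def test_transfer_clamps_out_of_range_values(self):
        # 3-cell training grid with layer in [0, 2]; hand-computed transfer
        train = make_stack({"a": np.array([[0.0, 1.0, 2.0]])})
        model = br.GibbsModel(FeatureSpec(("linear",), beta=0.0), ["a"],
                              np.array([1.0]), np.array([0.0]), np.array([2.0]),
                              float(logsumexp(np.array([0.0, 0.5, 1.0]))), 3)
        proj = make_stack({"a": np.array([[-5.0, 1.0, 99.0]])})
        raw = predict_raw(model, proj).values[0]
        z = np.exp(model.log_z)
        np.testing.assert_allclose(
            raw, [np.exp(0.0) / z, np.exp(0.5) / z, np.exp(1.0) / z], rtol=1e-12)
        assert np.isfinite(raw).all()

    def test_missing_layer_errors(self, trained_model):
        stack, _, _, model = trained_model
        other = make_stack({"zzz": np.zeros(stack.shape)},
                           cell=stack.georef.cell, x_min=stack.georef.x_min,
                           y_max=stack.georef.y_max)
        with pytest.raises(ValueError, match="missing"):
            predict_raw(model, other)


class TestReplicates:
    def test_single_replicate_median_is_the_raw_map(self, small_landscape):
        stack, suit = small_landscape
        occs = br.sample_occurrences(suit, 60, seed=13)
        median, fitted = fit_replicates_median(occs, stack, 1, 0.25, seed=2)
        assert len(fitted) == 1
        np.testing.assert_allclose(
            median.values[stack.valid_mask],
            predict_raw(fitted[0][0], stack).valid_values(), rtol=1e-12)

    def test_five_replicates_train_on_75_percent(self, small_landscape):
        stack, suit = small_landscape
        occs = br.sample_occurrences(suit, 40, seed=14)
        n = len(occs)
        median, fitted = fit_replicates_median(occs, stack, 5, 0.25, seed=2)
        assert len(fitted) == 5
        for _, test in fitted:
            assert len(test) == round(0.25 * n)
        assert median.valid_values().shape[0] == stack.valid_mask.sum()


class TestThresholds:
    def test_minimum_rule(self):
        assert compute_threshold([0.2, 0.5, 0.9], "min_training_presence") == 0.2

    def test_p10_matches_brute_force_over_candidates(self):
        rng = np.random.default_rng(4)
        vals = np.sort(rng.uniform(size=20))
        t = compute_threshold(vals, "p10_training_presence")
        # brute force: largest candidate with strictly-below fraction <= 10%
        best = max(v for v in vals if np.mean(vals < v) <= 0.10)
        assert t == best == vals[2]  # 3rd smallest omits 2/20 = 10%

    def test_all_equal_values(self):
        for rule in ("min_training_presence", "p10_training_presence"):
            assert compute_threshold([0.3, 0.3, 0.3], rule) == 0.3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold([], "min_training_presence")

    def test_binarize_contracts(self, trained_model):
        stack, _, occs, model = trained_model
        raw = predict_raw(model, stack)
        row, col, _ = presence_cell_indices(occs, stack)
        train_vals = raw.values[row, col]
        mtp = compute_threshold(train_vals, "min_training_presence")
        bm = binarize(raw, mtp)
        assert (bm.values[row, col] == 1).all()  # exactly zero training omission
        p10 = compute_threshold(train_vals, "p10_training_presence")
        bp = binarize(raw, p10)
        omitted = np.mean(bp.values[row, col] == 0)
        assert omitted <= 0.10
        # threshold above the global max blanks the map
        assert binarize(raw, float(np.nanmax(raw.values)) * 2).values.sum() == 0


class TestJackknifeAndRichness:
    def test_informative_layer_dominates_gain(self):
        spec = br.LandscapeSpec(shape=(30, 30), n_layers=3,
                                correlation_length=4.0, seed=21)
        stack = br.gen_env_stack(spec)
        suit = br.gen_true_suitability(stack, (4.0, 0.0, 0.0))
        occs = br.sample_occurrences(suit, 400, seed=22)
        gains = jackknife_importance(occs, stack, FeatureSpec(("linear",), beta=0.0))
        alone = {k: v[0] for k, v in gains.items()}
        without = {k: v[1] for k, v in gains.items()}
        assert max(alone, key=alone.get) == "env1"
        assert min(without, key=without.get) == "env1"
        # pure-noise layers carry almost no gain on their own
        assert alone["env2"] == pytest.approx(0.0, abs=0.05)
        assert alone["env3"] == pytest.approx(0.0, abs=0.05)

    def test_duplicated_layers_have_equal_gain(self, small_landscape):
        stack, suit = small_landscape
        dup = make_stack({"a": stack.values[0], "b": stack.values[0].copy()},
                         cell=stack.georef.cell, x_min=stack.georef.x_min,
                         y_max=stack.georef.y_max)
        occs = br.sample_occurrences(suit, 150, seed=23)
        gains = jackknife_importance(occs, dup, FeatureSpec(("linear",), beta=0.0))
        assert gains["a"][0] == pytest.approx(gains["b"][0], abs=1e-6)

    def test_richness_examples_and_brute_force(self, trained_model):
        stack, _, occs, model = trained_model
        raw = predict_raw(model, stack)
        bm = binarize(raw, float(np.nanmedian(raw.values)))
        same = stack_richness([bm, bm])
        assert set(np.unique(same)) <= {0, 2}
        inv = binarize(raw, float(np.nanmedian(raw.values)))
        inv.values = 1 - inv.values
        disjoint = stack_richness([bm, inv])
        assert disjoint.max() <= 2 and ((bm.values + inv.values) == disjoint).all()
        rng = np.random.default_rng(0)
        maps = []
        for _ in range(5):
            b = binarize(raw, float(rng.uniform(0, np.nanmax(raw.values))))
            maps.append(b)
        total = stack_richness(maps)
        np.testing.assert_array_equal(total, sum(m.values for m in maps))

    def test_misaligned_richness_rejected(self, trained_model):
        stack, _, _, model = trained_model
        raw = predict_raw(model, stack)
        bm = binarize(raw, 0.0)
        small = binarize(br.SuitabilityMap(np.zeros((2, 2)), "raw",
                                           stack.georef, np.zeros((2, 2), bool)), 1.0)
        with pytest.raises(ValueError, match="aligned"):
            stack_richness([bm, small])


def test_suitability_recovery_rank_correlation(small_landscape):
    """Default fit recovers the true surface's ranks on a fresh sample."""
    stack, suit = small_landscape
    occs = br.sample_occurrences(suit, 500, seed=30)
    model = fit_gibbs(occs, stack)
    est = predict_raw(model, stack).valid_values()
    rho = spearmanr(suit.valid_values(), est).statistic
    assert rho > 0.8
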