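import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lrtrial as lt
from lrtrial.causal_testing import (PoolWeights, closed_test,
                                    effects_table, fit_stratified_model,
                                    model_fit_stats, pooled_effect,
                                    stratum_effects)
from lrtrial.causal_testing import TestingError as CTError
from lrtrial.responder_stratification import StratumAssignment
from lrtrial.trial_data import FeatureSchema, TrialDataset


def build_dataset(y, treat, bhdd=None, stratum=None):
    n = len(y)
    df = pd.DataFrame({
        "subject_id": [f"s{i:04d}" for i in range(n)],
        "arm": np.where(np.asarray(treat) == 1, "ACTIVE", "PLACEBO"),
        "baseline_hdd": bhdd if bhdd is not None else np.full(n, 20),
        "outcome_hdd": 0,
        "delta_hdd": np.asarray(y, float),
    })
    df["outcome_hdd"] = np.clip(df["baseline_hdd"] - df["delta_hdd"],
                                0, 28).astype(int)
    df["delta_hdd"] = y
    ds = TrialDataset(df[["subject_id", "arm", "baseline_hdd",
                          "delta_hdd"]].assign(
        delta_hdd=np.asarray(y, float)), FeatureSchema(features=()))
    if stratum is None:
        stratum = np.ones(n, int)
    assign = StratumAssignment(pd.DataFrame({
        "subject_id": df["subject_id"], "score": 0.0,
        "stratum": np.asarray(stratum, int)}), int(np.max(stratum)))
    return ds, assign


def stratified_effects_dataset(effects, n_per_cell=40, noise_sd=0.0,
                               seed=0):
    """k strata, constant within-stratum treatment effect effects[s-1]."""
    rng = np.random.default_rng(seed)
    k = len(effects)
    y, treat, stratum, bhdd = [], [], [], []
    for s, c in enumerate(effects, start=1):
        for t in (0, 1):
            base = 5.0 + s  # stratum main effect
            eps = rng.normal(0, noise_sd, n_per_cell)
            y.extend(base + c * t + eps)
            treat.extend([t] * n_per_cell)
            stratum.extend([s] * n_per_cell)
            bhdd.extend(rng.integers(10, 28, n_per_cell))
    return build_dataset(np.array(y), np.array(treat), np.array(bhdd),
                         np.array(stratum))


class TestStratifiedFit:
    def test_constant_effect_recovered_exactly(self):
        ds, assign = stratified_effects_dataset([4.0, 4.0, 4.0])
        fit = fit_stratified_model(ds, assign)
        for e in stratum_effects(fit):
            assert e.estimate == pytest.approx(4.0, abs=1e-9)

    def test_stratum_specific_effects_recovered_exactly(self):
        effects = [-4.0, 0.0, 2.0, 4.5, 7.0]
        ds, assign = stratified_effects_dataset(effects)
        fit = fit_stratified_model(ds, assign)
        got = [e.estimate for e in stratum_effects(fit)]
        np.testing.assert_allclose(got, effects, atol=1e-9)

    def test_empty_cell_raises_named(self):
        ds, assign = stratified_effects_dataset([1.0, 2.0])
        df = ds.df.copy()
        drop = (assign.frame["stratum"] == 2).to_numpy() \
            & (df["arm"] == "PLACEBO").to_numpy()
        ds2 = TrialDataset(df[~drop].reset_index(drop=True), ds.schema)
        a2 = StratumAssignment(assign.frame[~drop].reset_index(drop=True), 2)
        with pytest.raises(CTError, match="stratum 2"):
            fit_stratified_model(ds2, a2)

    def test_missing_outcome_rejected(self):
        ds, assign = stratified_effects_dataset([1.0])
        df = ds.df.copy()
        df.loc[0, "delta_hdd"] = np.nan
        with pytest.raises(CTError, match="missing"):
            fit_stratified_model(TrialDataset(df, ds.schema), assign)

    def test_null_pvalues_uniform_under_permutation(self):
        # permuted labels under the global null: pooled p ~ Uniform(0,1)
        rng = np.random.default_rng(7)
        n = 80
        y = rng.normal(10, 4, n)
        bhdd = rng.integers(8, 28, n)
        stratum = np.repeat([1, 2], n // 2)
        ps = []
        for _ in range(400):
            treat = rng.permutation(np.repeat([0, 1], n // 2))
            ds, assign = build_dataset(y, treat, bhdd, stratum)
            fit = fit_stratified_model(ds, assign)
            ps.append(pooled_effect(fit).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPooled:
    def test_equal_effects_invariant_to_weights(self):
        ds, assign = stratified_effects_dataset([3.0, 3.0])
        fit = fit_stratified_model(ds, assign)
        for w in PoolWeights:
            assert pooled_effect(fit, w).estimate == pytest.approx(3.0,
                                                                   abs=1e-9)

    def test_cancellation_under_equal_weights(self):
        ds, assign = stratified_effects_dataset([-4.0, 0.0, 4.0])
        fit = fit_stratified_model(ds, assign)
        assert pooled_effect(fit, PoolWeights.EQUAL).estimate == \
            pytest.approx(0.0, abs=1e-9)

    def test_weightings_differ_by_analytic_gap(self):
        ds, assign = stratified_effects_dataset([0.0, 6.0])
        # unbalance stratum sizes by dropping half of stratum 1
        keep = np.ones(len(ds.df), bool)
        s1 = (assign.frame["stratum"] == 1).to_numpy()
        idx = np.flatnonzero(s1)[::2]
        keep[idx] = False
        ds2 = TrialDataset(ds.df[keep].reset_index(drop=True), ds.schema)
        a2 = StratumAssignment(assign.frame[keep].reset_index(drop=True), 2)
        fit = fit_stratified_model(ds2, a2)
        by_n = pooled_effect(fit, PoolWeights.BY_N).estimate
        eq = pooled_effect(fit, PoolWeights.EQUAL).estimate
        n1, n2 = 40, 80
        expect_gap = (n1 * 0 + n2 * 6) / (n1 + n2) - (0 + 6) / 2
        assert by_n - eq == pytest.approx(expect_gap, abs=1e-9)

    def test_k1_equals_covariate_adjusted_difference(self):
        # single stratum: pooled effect == OLS treatment coefficient of the
        # plain covariate-adjusted two-sample comparison (oracle: lstsq)
        rng = np.random.default_rng(3)
        n = 60
        y = rng.normal(8, 3, n)
        treat = rng.permutation(np.repeat([0, 1], n // 2))
        bhdd = rng.integers(5, 28, n)
        ds, assign = build_dataset(y, treat, bhdd)
        fit = fit_stratified_model(ds, assign)
        X = np.column_stack([np.ones(n), treat, bhdd - bhdd.mean()])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert pooled_effect(fit).estimate == pytest.approx(beta[1],
                                                            abs=1e-9)
        assert stratum_effects(fit)[0].estimate == pytest.approx(beta[1],
                                                                 abs=1e-9)

    def test_ci_covers_constant_effect(self):
        covered = 0
        reps = 60
        for r in range(reps):
            ds, assign = stratified_effects_dataset([4.0, 4.0],
                                                    n_per_cell=30,
                                                    noise_sd=3.0, seed=r)
            fit = fit_stratified_model(ds, assign)
            lo, hi = pooled_effect(fit).ci95
            covered += lo <= 4.0 <= hi
        assert covered >= 0.85 * reps


class TestClosedTest:
    def test_published_pattern_reject_then_retain(self):
        res = closed_test(0.031, 0.704, alpha=0.05)
        assert res.h1_lr == "reject"
        assert res.h2_full == "retain"

    def test_gatekeeping_blocks_second_test(self):
        res = closed_test(0.20, 0.001, alpha=0.05)
        assert res.h1_lr == "retain"
        assert res.h2_full == "not_tested"
        assert res.p_full is None

    def test_both_reject(self):
        res = closed_test(0.01, 0.02)
        assert (res.h1_lr, res.h2_full) == ("reject", "reject")

    def test_invalid_p(self):
        with pytest.raises(CTError):
            closed_test(1.5, 0.5)

    def test_fwer_under_global_null_uniform_ps(self):
        # direct probabilistic check of the gate with independent uniforms
        rng = np.random.default_rng(11)
        n = 4000
        p1 = rng.random(n)
        p2 = rng.random(n)
        false_any = sum(
            closed_test(a, b).h1_lr == "reject" for a, b in zip(p1, p2))
        rate = false_any / n
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)


class TestModelFitStats:
    def test_published_conversions(self):
        assert round(lt.r_to_pct_variance(0.53), 2) == 28.09
        assert round(lt.r_to_pct_variance(0.52), 2) == 27.04

    def test_saturated_noise_free_model(self):
        ds, assign = stratified_effects_dataset([2.0, 5.0])
        fit = fit_stratified_model(ds, assign)
        stats_ = model_fit_stats(fit)
        assert stats_.pct_variance == pytest.approx(100.0, abs=1e-6)

    def test_zero_variance_fitted_raises(self):
        rng = np.random.default_rng(0)
        ds, assign = build_dataset(np.full(20, 5.0), np.tile([0, 1], 10),
                                   bhdd=rng.integers(5, 28, 20))
        fit = fit_stratified_model(ds, assign)
        with pytest.raises(CTError):
            model_fit_stats(fit)


class TestEffectsTable:
    def test_shape_and_pooled_row(self):
        ds, assign = stratified_effects_dataset([1.0, 2.0, 3.0])
        fit = fit_stratified_model(ds, assign)
        tab = effects_table(fit)
        assert len(tab) == 4
        assert tab["stratum"].iloc[-1] == "pooled"
        assert (tab["ci_low"] <= tab["model_difference"]).all()
        assert (tab["model_difference"] <= tab["ci_high"]).all()
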