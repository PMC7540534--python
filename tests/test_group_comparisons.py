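import itertools

import numpy as np
import pandas as pd
import pytest

import lrtrial as lt
from lrtrial.group_comparisons import (CONTRAST_NAMES, baseline_compare,
                                       chi_square_test, comparison_frame,
                                       outcome_contrasts, wilcoxon_rank_sum)
from lrtrial.trial_data import (FeatureKind, FeatureSchema, FeatureSpec,
                                TrialDataset)


def exact_ranksum_p(x, y):
    """Independent oracle: enumerate every assignment of the pooled sample."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = pd.Series(pooled).rank().to_numpy()
    w_obs = ranks[:n].sum()
    mean_w = n * (n + m + 1) / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(n + m), n):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            count += 1
    return count / total


class TestWilcoxonOracle:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_agrees_with_enumeration_small(self, seed):
        rng = np.random.default_rng(seed)
        # tie-free small samples: exact method must match brute force
        vals = rng.permutation(16).astype(float)
        x, y = vals[:8], vals[8:]
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(exact_ranksum_p(x, y), abs=1e-9)

    def test_enumeration_count_8_8(self):
        # the full assignment space at 8/8 has C(16,8) = 12870 points
        assert len(list(itertools.combinations(range(16), 8))) == 12870

    def test_power_against_shifted_normal(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 200)
        y = rng.normal(1, 1, 200)
        _, p = wilcoxon_rank_sum(x, y)
        assert p < 0.001


class TestChiSquare:
    def test_closed_form_2x2(self):
        # sum (O-E)^2/E for (30,70 / 70,30) is exactly 32
        stat, p = chi_square_test([[30, 70], [70, 30]])
        assert stat == pytest.approx(32.0, abs=1e-9)
        assert p < 1e-7

    @pytest.mark.parametrize("table", [
        [[10, 20], [30, 40]], [[5, 5, 5], [10, 1, 4]], [[50, 50], [50, 50]],
    ])
    def test_matches_oe_formula(self, table):
        t = np.asarray(table, float)
        row = t.sum(1, keepdims=True)
        col = t.sum(0, keepdims=True)
        expect = row * col / t.sum()
        oracle = ((t - expect) ** 2 / expect).sum()
        stat, _ = chi_square_test(table)
        assert stat == pytest.approx(oracle, abs=1e-9)

    def test_identical_proportions_p_one(self):
        _, p = chi_square_test([[40, 60], [40, 60]])
        assert p == pytest.approx(1.0)


def label_frame(ids, labels):
    return pd.DataFrame({"subject_id": ids, "label": labels})


class TestBaselineCompare:
    def _dataset(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "arm": rng.choice(["ACTIVE", "PLACEBO"], n),
            "baseline_hdd": rng.integers(4, 29, n),
            "score_item": rng.integers(0, 5, n),
            "cat": rng.choice(["a", "b"], n),
        })
        schema = FeatureSchema(features=(
            FeatureSpec("score_item", FeatureKind.ORDINAL, lo=0, hi=4),
            FeatureSpec("cat", FeatureKind.CATEGORICAL, levels=("a", "b")),
        ))
        return TrialDataset(df, schema)

    def test_row_per_variable_and_tests_assigned(self):
        ds = self._dataset()
        rng = np.random.default_rng(1)
        labels = label_frame(ds.df["subject_id"],
                             rng.choice(["LR", "UR"], ds.n))
        rows = baseline_compare(ds, labels)
        by_var = {r.variable: r for r in rows}
        assert set(by_var) == {"baseline_hdd", "score_item", "cat"}
        assert by_var["baseline_hdd"].test == "wilcoxon"
        assert by_var["cat"].test == "chi-square"
        for r in rows:
            assert 0 <= r.p <= 1

    def test_identical_groups_chi_square_p_one(self):
        # duplicate every subject, one copy per label: proportions identical
        ds = self._dataset(n=60)
        df2 = ds.df.copy()
        df2["subject_id"] = df2["subject_id"] + "_dup"
        both = TrialDataset(pd.concat([ds.df, df2], ignore_index=True),
                            ds.schema)
        labels = label_frame(both.df["subject_id"],
                             ["LR"] * 60 + ["UR"] * 60)
        rows = baseline_compare(both, labels)
        cat_row = next(r for r in rows if r.variable == "cat")
        assert cat_row.p == pytest.approx(1.0)

    def test_single_level_flagged(self):
        ds = self._dataset(n=40)
        df = ds.df.copy()
        df["cat"] = "a"
        ds2 = TrialDataset(df, ds.schema)
        labels = label_frame(df["subject_id"], ["LR", "UR"] * 20)
        rows = baseline_compare(ds2, labels)
        cat_row = next(r for r in rows if r.variable == "cat")
        assert "untestable" in cat_row.flag

    def test_wilcoxon_detects_separation(self):
        rng = np.random.default_rng(9)
        n = 400
        lab = np.array(["LR"] * 200 + ["UR"] * 200)
        df = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(n)],
            "arm": ["ACTIVE", "PLACEBO"] * 200,
            "baseline_hdd": 20,
            "z": np.where(lab == "LR", rng.normal(1, 1, n),
                          rng.normal(0, 1, n)),
        })
        schema = FeatureSchema(features=(
            FeatureSpec("z", FeatureKind.CONTINUOUS),))
        rows = baseline_compare(TrialDataset(df, schema),
                                label_frame(df["subject_id"], lab))
        z_row = next(r for r in rows if r.variable == "z")
        assert z_row.p < 0.001


class TestOutcomeContrasts:
    def _dataset(self, cell_means, n_per_cell=50, sd=1.0, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        i = 0
        for (lab, arm), mu in cell_means.items():
            for _ in range(n_per_cell):
                recs.append({
                    "subject_id": f"s{i}", "arm": arm, "baseline_hdd": 20,
                    "sec_y": rng.normal(mu, sd), "_label": lab})
                i += 1
        df = pd.DataFrame(recs)
        labels = label_frame(df["subject_id"], df["_label"])
        schema = FeatureSchema(features=(), secondary=("sec_y",))
        return TrialDataset(df.drop(columns="_label"), schema), labels

    def test_four_contrasts_per_outcome(self):
        ds, labels = self._dataset({("UR", "ACTIVE"): 0, ("UR", "PLACEBO"): 0,
                                    ("LR", "ACTIVE"): 0,
                                    ("LR", "PLACEBO"): 0})
        rows = outcome_contrasts(ds, labels, outcomes=["sec_y"])
        assert len(rows) == 4
        assert {r.variable.split(":")[1] for r in rows} == set(CONTRAST_NAMES)

    def test_null_pvalues_uniform(self):
        ps = []
        for seed in range(150):
            ds, labels = self._dataset(
                {("UR", "ACTIVE"): 0, ("UR", "PLACEBO"): 0,
                 ("LR", "ACTIVE"): 0, ("LR", "PLACEBO"): 0},
                n_per_cell=12, seed=seed)
            rows = outcome_contrasts(ds, labels, outcomes=["sec_y"])
            ps.append(rows[0].p)
        from scipy import stats
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_shifted_cell_detected(self):
        ds, labels = self._dataset({("UR", "ACTIVE"): 0, ("UR", "PLACEBO"): 0,
                                    ("LR", "ACTIVE"): 2.0,
                                    ("LR", "PLACEBO"): 0}, sd=1.0)
        rows = {r.variable.split(":")[1]: r
                for r in outcome_contrasts(ds, labels, outcomes=["sec_y"])}
        assert rows["active_vs_placebo_in_LR"].p < 0.001
        assert rows["UR_vs_LR_in_active"].p < 0.001
        assert rows["active_vs_placebo_in_UR"].p > 0.01

    def test_empty_cell_flagged(self):
        ds, labels = self._dataset({("UR", "ACTIVE"): 0, ("UR", "PLACEBO"): 0,
                                    ("LR", "ACTIVE"): 0,
                                    ("LR", "PLACEBO"): 0}, n_per_cell=10)
        keep = ~((labels["label"] == "LR")
                 & (ds.df["arm"] == "PLACEBO"))
        ds2 = TrialDataset(ds.df[keep].reset_index(drop=True), ds.schema)
        labels2 = labels[keep].reset_index(drop=True)
        rows = outcome_contrasts(ds2, labels2, outcomes=["sec_y"])
        flagged = [r for r in rows if r.flag == "empty cell"]
        assert len(flagged) >= 2  # both contrasts touching the empty cell

    def test_comparison_frame_serialises(self):
        ds, labels = self._dataset({("UR", "ACTIVE"): 0, ("UR", "PLACEBO"): 0,
                                    ("LR", "ACTIVE"): 0,
                                    ("LR", "PLACEBO"): 0}, n_per_cell=5)
        frame = comparison_frame(outcome_contrasts(ds, labels,
                                                   outcomes=["sec_y"]))
        assert {"variable", "test", "statistic", "p"} <= set(frame.columns)
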