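import numpy as np
import pandas as pd
import pytest

import mitoscreen as ms
from mitoscreen.stats import benjamini_hochberg, class_contrast


def _table(groups: dict[str, list[float]]) -> pd.DataFrame:
    rows = [
        {"group": g, "value": v, "subject": i}
        for g, vals in groups.items()
        for i, v in enumerate(vals)
    ]
    return pd.DataFrame(rows)


# Hand-computed one-way ANOVA oracle for the 3x3 fixture below:
#   groups: a=(1,2,3) mean 2; b=(2,3,4) mean 3; c=(6,7,8) mean 7
#   grand mean = 4; SSB = 3[(2-4)^2+(3-4)^2+(7-4)^2] = 3*14 = 42; dfB = 2
#   SSW = (1+1) per group * 3 = 6; dfW = 6
#   F = (42/2)/(6/6) = 21, computed by hand from the sums of squares.
HAND_FIXTURE = {"a": [1.0, 2.0, 3.0], "b": [2.0, 3.0, 4.0], "c": [6.0, 7.0, 8.0]}
HAND_F = 21.0


class TestCompareGroups:
    def test_one_way_matches_hand_computation(self):
        res = ms.compare_groups(_table(HAND_FIXTURE), "value", "group", "one_way")
        assert res.statistic == pytest.approx(HAND_F, abs=1e-10)
        assert res.df == (2.0, 6.0)

    def test_f_equals_t_squared_two_groups(self):
        rng = np.random.default_rng(11)
        groups = {"x": list(rng.normal(0, 1, 8)), "y": list(rng.normal(0.5, 1, 8))}
        t_res = ms.compare_groups(_table(groups), "value", "group", "t_test")
        f_res = ms.compare_groups(_table(groups), "value", "group", "one_way")
        assert f_res.statistic == pytest.approx(t_res.statistic**2, abs=1e-9)
        assert f_res.p_value == pytest.approx(t_res.p_value, abs=1e-12)

    def test_identical_groups_convention(self):
        groups = {"x": [5.0, 5.0, 5.0], "y": [5.0, 5.0, 5.0]}
        for design in ("t_test", "one_way"):
            res = ms.compare_groups(_table(groups), "value", "group", design)
            assert res.statistic == 0.0
            assert res.p_value == 1.0

    def test_permutation_agreement(self):
        """Parametric two-sample p agrees with a 100,000-draw permutation p
        within 0.02 on a small fixture."""
        rng = np.random.default_rng(7)
        a = rng.normal(0.0, 1.0, 6)
        b = rng.normal(1.2, 1.0, 6)
        res = ms.compare_groups(
            _table({"a": list(a), "b": list(b)}), "value", "group", "t_test"
        )
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        n_draws = 100_000
        idx = np.argsort(rng.random((n_draws, pooled.size)), axis=1)
        perm = pooled[idx]
        diffs = np.abs(perm[:, :6].mean(axis=1) - perm[:, 6:].mean(axis=1))
        p_perm = (1 + np.sum(diffs >= obs - 1e-12)) / (n_draws + 1)
        assert abs(res.p_value - p_perm) < 0.02

    def test_rm_anova_matches_hand_blocked_f(self):
        """Subject-blocked RM-ANOVA F against explicit sums-of-squares loops."""
        rng = np.random.default_rng(5)
        n_subj, levels = 8, ("s1", "s2", "s3")
        data = {lv: rng.normal(i, 1.0, n_subj) for i, lv in enumerate(levels)}
        table = pd.DataFrame(
            [
                {"subject": s, "state": lv, "value": data[lv][s]}
                for lv in levels
                for s in range(n_subj)
            ]
        )
        res = ms.compare_groups(table, "value", "state", "rm_anova", subject="subject")
        # oracle: SS_treatment and SS_error computed by explicit loops
        grand = table["value"].mean()
        ss_treat = n_subj * sum(
            (data[lv].mean() - grand) ** 2 for lv in levels
        )
        ss_subj = len(levels) * sum(
            (table[table.subject == s]["value"].mean() - grand) ** 2
            for s in range(n_subj)
        )
        ss_tot = ((table["value"] - grand) ** 2).sum()
        ss_err = ss_tot - ss_treat - ss_subj
        df_t, df_e = len(levels) - 1, (len(levels) - 1) * (n_subj - 1)
        f_hand = (ss_treat / df_t) / (ss_err / df_e)
        assert res.statistic == pytest.approx(f_hand, rel=1e-9)
        assert res.df == (float(df_t), float(df_e))

    def test_errors(self):
        with pytest.raises(ValueError, match="2 groups"):
            ms.compare_groups(_table({"only": [1.0, 2.0]}), "value", "group")
        with pytest.raises(ValueError, match="n < 2"):
            ms.compare_groups(
                _table({"a": [1.0], "b": [1.0, 2.0]}), "value", "group"
            )
        with pytest.raises(ValueError, match="subject"):
            ms.compare_groups(
                _table({"a": [1.0, 2.0], "b": [3.0, 4.0]}),
                "value", "group", "rm_anova",
            )


def _metrics_frame(cond_values: dict[str, dict[str, list[float]]]) -> pd.DataFrame:
    """Long metrics table: condition -> compartment -> per-cell values."""
    rows = []
    for cond, comps in cond_values.items():
        for comp, vals in comps.items():
            for i, v in enumerate(vals):
                rows.append(
                    {
                        "roi_id": f"{cond}_{i}",
                        "condition": cond,
                        "cell_class": "microglia",
                        "compartment": comp,
                        "state": 0,
                        "metric": "total_pct_change",
                        "value": v,
                    }
                )
    return pd.DataFrame(rows)


class TestScreenReport:
    def test_null_screen_identical_cohorts(self):
        rng = np.random.default_rng(0)
        vals = list(rng.normal(100, 10, 10))
        metrics = _metrics_frame(
            {"ctrl": {"soma": vals}, "treat": {"soma": vals}}
        )
        rep = ms.screen_report(metrics, "ctrl", "treat")
        assert not rep.comparisons["significant"].any()

    def test_small_groups_skipped_with_warning(self):
        metrics = _metrics_frame(
            {"ctrl": {"soma": [1.0, 2.0, 3.0]}, "treat": {"soma": [4.0]}}
        )
        rep = ms.screen_report(metrics, "ctrl", "treat")
        assert rep.comparisons.empty or "soma" not in set(
            rep.comparisons["compartment"]
        )
        assert any("n < 2" in w for w in rep.warnings)

    def test_direction_and_significance(self):
        rng = np.random.default_rng(1)
        metrics = _metrics_frame(
            {
                "ctrl": {"soma": list(rng.normal(120, 5, 10))},
                "treat": {"soma": list(rng.normal(50, 5, 10))},
            }
        )
        rep = ms.screen_report(metrics, "ctrl", "treat")
        row = rep.comparisons.iloc[0]
        assert row["direction"] == "decrease"
        assert row["significant"]

    def test_class_contrast_present(self):
        rng = np.random.default_rng(2)
        rows = []
        for cls, comp, mu in (("microglia", "whole_cell", 250.0), ("neuron", "soma", 45.0)):
            for i, v in enumerate(rng.normal(mu, 20, 10)):
                rows.append(
                    {"roi_id": f"{cls}_{i}", "condition": "lps", "cell_class": cls,
                     "compartment": comp, "state": 0,
                     "metric": "total_pct_change", "value": v}
                )
        contrast = class_contrast(pd.DataFrame(rows), "lps")
        assert contrast is not None
        assert contrast.iloc[0]["direction"] == "increase"
        assert contrast.iloc[0]["p"] < 0.05

    def test_json_roundtrip(self, tmp_path):
        metrics = _metrics_frame(
            {"ctrl": {"soma": [1.0, 2.0, 3.0]}, "treat": {"soma": [1.5, 2.5, 3.5]}}
        )
        rep = ms.screen_report(metrics, "ctrl", "treat")
        path = tmp_path / "screen.json"
        rep.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["control"] == "ctrl"
        assert len(payload["comparisons"]) == len(rep.comparisons)


class TestBenjaminiHochberg:
    def test_monotone_and_bounded(self):
        p = np.array([0.001, 0.02, 0.04, 0.2, 0.9])
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        # order preserved
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)
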