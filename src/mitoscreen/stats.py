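"""Group-comparison statistics and the treatment screen report.

The statistical surface mirrors the experimental analysis: two-sample
t-tests, one-way ANOVA, and subject-blocked repeated-measures ANOVA, each
reported with the statistic, exact degrees of freedom, p-value and group
descriptives.  Differences are called significant at p <= alpha (default
0.05); p-values are reported raw by default, with optional Benjamini–Hochberg
adjustment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DESIGNS = ("t_test", "one_way", "rm_anova")


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    descriptives: pd.DataFrame  # one row per group: n, mean, sem

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _descriptives(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": k,
                "n": v.size,
                "mean": float(v.mean()),
                "sem": float(sps.sem(v)) if v.size > 1 else np.nan,
            }
            for k, v in groups.items()
        ]
    )


def compare_groups(
    table: pd.DataFrame,
    response: str,
    factor: str,
    design: str = "t_test",
    subject: str | None = None,
) -> TestResult:
    """Compare groups of ``response`` across levels of ``factor``.

    ``t_test`` is the pooled-variance two-sample t; ``one_way`` the standard
    between/within mean-square F; ``rm_anova`` the subject-blocked
    repeated-measures F (requires ``subject``).  Groups that are identical
    with zero within-group variance return statistic 0, p = 1 (documented
    convention: no evidence of any difference).
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    levels = list(pd.unique(table[factor]))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    groups = {
        str(lv): table.loc[table[factor] == lv, response].to_numpy(dtype=float)
        for lv in levels
    }
    for k, v in groups.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has n < 2")
    desc = _descriptives(groups)
    values = list(groups.values())

    all_equal = all(np.ptp(v) == 0 for v in values) and np.ptp(
        [v[0] for v in values]
    ) == 0

    if design == "t_test":
        if len(values) != 2:
            raise ValueError("t_test requires exactly 2 groups")
        n1, n2 = values[0].size, values[1].size
        if all_equal:
            return TestResult("t_test", 0.0, (float(n1 + n2 - 2),), 1.0, desc)
        t, p = sps.ttest_ind(values[0], values[1], equal_var=True)
        return TestResult("t_test", float(t), (float(n1 + n2 - 2),), float(p), desc)

    if design == "one_way":
        if all_equal:
            k, n = len(values), sum(v.size for v in values)
            return TestResult("one_way", 0.0, (float(k - 1), float(n - k)), 1.0, desc)
        f, p = sps.f_oneway(*values)
        k, n = len(values), sum(v.size for v in values)
        return TestResult("one_way", float(f), (float(k - 1), float(n - k)), float(p), desc)

    # rm_anova
    if subject is None:
        raise ValueError("rm_anova requires a subject column")
    import pingouin as pg

    if all_equal:
        k = len(values)
        n_subj = table[subject].nunique()
        return TestResult(
            "rm_anova", 0.0, (float(k - 1), float((k - 1) * (n_subj - 1))), 1.0, desc
        )
    aov = pg.rm_anova(data=table, dv=response, within=factor, subject=subject, detailed=False)
    row = aov.iloc[0]
    p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
    return TestResult(
        "rm_anova",
        float(row["F"]),
        (float(row["ddof1"]), float(row["ddof2"])),
        float(row[p_col]),
        desc,
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (step-up FDR)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(adj, 0.0, 1.0)
    return out


@dataclass
class ScreenReport:
    """Per-(compartment x state x metric) treatment comparisons."""

    control: str
    treatment: str
    alpha: float
    comparisons: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "control": self.control,
            "treatment": self.treatment,
            "alpha": self.alpha,
            "warnings": self.warnings,
            "comparisons": json.loads(
                self.comparisons.to_json(orient="records", double_precision=10)
            ),
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_markdown(self) -> str:
        lines = [
            f"# Treatment screen: {self.treatment} vs {self.control} (alpha={self.alpha})",
            "",
            self.comparisons.to_markdown(index=False, floatfmt=".4g"),
        ]
        if self.warnings:
            lines += ["", "Warnings:", *[f"- {w}" for w in self.warnings]]
        return "\n".join(lines)


def screen_report(
    metrics: pd.DataFrame,
    control: str,
    treatment: str,
    alpha: float = 0.05,
    adjust: bool = False,
) -> ScreenReport:
    """Screen a treatment against a control condition.

    ``metrics`` is a long table with columns roi_id / condition / cell_class /
    compartment / state / metric / value (state may be 0 for whole-window
    metrics such as total percent change).  Each (cell_class, compartment,
    state, metric) stratum present in both conditions with n >= 2 per group is
    compared with a two-sided pooled t-test; a microglia-vs-neuron whole-cell
    contrast within the treatment condition is appended when both classes are
    present.  Strata with n < 2 in either group are skipped with a warning.
    """
    required = {"roi_id", "condition", "cell_class", "compartment", "state", "metric", "value"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    present = set(metrics["condition"].unique())
    for cond in (control, treatment):
        if cond not in present:
            raise ValueError(f"condition {cond!r} not present in metrics")

    warnings_: list[str] = []
    rows = []
    df = metrics[metrics["condition"].isin([control, treatment])]
    for key, grp in df.groupby(["cell_class", "compartment", "state", "metric"], sort=True):
        cls, comp, state, metric = key
        sub = grp.pivot_table(index="roi_id", columns="condition", values="value", aggfunc="first")
        a = sub[control].dropna().to_numpy() if control in sub else np.array([])
        b = sub[treatment].dropna().to_numpy() if treatment in sub else np.array([])
        if a.size < 2 or b.size < 2:
            warnings_.append(
                f"skipped {cls}/{comp}/state {state}/{metric}: n < 2 in a group"
            )
            continue
        res = compare_groups(
            grp, response="value", factor="condition", design="t_test"
        )
        rows.append(
            {
                "cell_class": cls,
                "compartment": comp,
                "state": int(state),
                "metric": metric,
                "n_control": int(a.size),
                "n_treatment": int(b.size),
                "mean_control": float(a.mean()),
                "mean_treatment": float(b.mean()),
                "direction": "decrease" if b.mean() < a.mean() else "increase",
                "t": res.statistic,
                "df": res.df[0],
                "p": res.p_value,
            }
        )
    comp_df = pd.DataFrame(rows)
    if not comp_df.empty:
        if adjust:
            comp_df["p_adj"] = benjamini_hochberg(comp_df["p"].to_numpy())
            comp_df["significant"] = comp_df["p_adj"] <= alpha
        else:
            comp_df["significant"] = comp_df["p"] <= alpha

    # whole-cell microglia-vs-neuron contrast within the treatment condition
    contrast = class_contrast(metrics, treatment)
    if contrast is not None:
        comp_df = pd.concat([comp_df, contrast.assign(significant=contrast["p"] <= alpha)],
                            ignore_index=True)

    return ScreenReport(control, treatment, alpha, comp_df, warnings_)


def class_contrast(metrics: pd.DataFrame, condition: str) -> pd.DataFrame | None:
    """Microglia whole-cell vs neuron soma total-percent-change contrast."""
    df = metrics[(metrics["condition"] == condition) & (metrics["metric"] == "total_pct_change")]
    mg = df[(df["cell_class"] == "microglia") & (df["compartment"] == "whole_cell")]
    nu = df[(df["cell_class"] == "neuron") & (df["compartment"] == "soma")]
    if len(mg) < 2 or len(nu) < 2:
        return None
    tbl = pd.concat([mg, nu], ignore_index=True)
    res = compare_groups(tbl, response="value", factor="cell_class", design="t_test")
    return pd.DataFrame(
        [
            {
                "cell_class": "microglia_vs_neuron",
                "compartment": "whole_cell",
                "state": 0,
                "metric": "total_pct_change",
                "n_control": int(len(nu)),
                "n_treatment": int(len(mg)),
                "mean_control": float(nu["value"].mean()),
                "mean_treatment": float(mg["value"].mean()),
                "direction": "increase"
                if mg["value"].mean() > nu["value"].mean()
                else "decrease",
                "t": res.statistic,
                "df": res.df[0],
                "p": res.p_value,
            }
        ]
    )
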