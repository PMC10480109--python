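"""Feature-level statistical testing: normality gate, Friedman omnibus,
rank-based post hoc pairs, paired t with effect size, direction reports.

The omnibus path mirrors the analysis applied to condition-wise feature
values: Shapiro-Wilk decides the test family; the Friedman chi-square on
within-row ranks (average ranks for ties) compares the three conditions;
significant omnibus results are followed by all-pairs mean-rank z tests
with Bonferroni adjustment.  Paired comparisons report Cohen's d on the
differences and post-hoc power from the noncentral-t formulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.power import TTestPower

from .features import FeatureTable

ALPHA = 0.05


@dataclass
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    effect_size: float | None = None
    power: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class ConditionMatrix:
    """Rows = subjects (or units), columns = conditions, cells = means."""

    values: np.ndarray
    conditions: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("condition matrix must be 2-D")
        if self.values.shape[1] != len(self.conditions):
            raise ValueError("column count does not match conditions")
        if not np.isfinite(self.values).all():
            raise ValueError("condition matrix has missing cells")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


def normality_gate(samples, alpha: float = ALPHA):
    """Shapiro-Wilk normality check: ``(is_normal, p_value)``."""
    x = np.asarray(samples, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    stat, p = sstats.shapiro(x)
    return bool(p >= alpha), float(p)


def _row_ranks(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sstats.rankdata, 1, values)


def friedman_repeated(m: ConditionMatrix) -> TestResult:
    """Friedman chi-square on within-row ranks, tie-corrected.

    Uses the general form statistic = SS_treatment / MS_error of the
    ranks, which reduces to the classical formula without ties and stays
    defined (0, p = 1) when every row is constant.
    """
    if m.n < 3:
        raise ValueError("need at least 3 rows for the omnibus test")
    ranks = _row_ranks(m.values)
    n, k = m.n, m.k
    rbar = (k + 1) / 2.0
    ss_t = n * ((ranks.mean(axis=0) - rbar) ** 2).sum()
    ss_e = ((ranks - rbar) ** 2).sum() / (n * (k - 1))
    if ss_e <= 0:
        return TestResult("friedman", 0.0, 1.0, extra={"df": k - 1})
    stat = ss_t / ss_e
    p = float(sstats.chi2.sf(stat, k - 1))
    return TestResult("friedman", float(stat), p, extra={"df": k - 1})


def posthoc_pairwise(m: ConditionMatrix, alpha: float = ALPHA,
                     force: bool = False) -> pd.DataFrame:
    """All-pairs mean-rank comparisons after a significant omnibus test.

    z = |mean-rank difference| / sqrt(k (k+1) / (6 n)), two-sided normal
    p, Bonferroni-adjusted over the pairs.  Emitted only when the omnibus
    test rejects (unless ``force``); otherwise an empty table.
    """
    omni = friedman_repeated(m)
    cols = ["a", "b", "statistic", "p_value", "p_adjusted", "significant"]
    if omni.p_value >= alpha and not force:
        return pd.DataFrame(columns=cols)
    ranks = _row_ranks(m.values)
    mean_ranks = ranks.mean(axis=0)
    n, k = m.n, m.k
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    n_pairs = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            z = abs(mean_ranks[i] - mean_ranks[j]) / se
            p = 2 * float(sstats.norm.sf(z))
            p_adj = min(1.0, p * n_pairs)
            rows.append({"a": m.conditions[i], "b": m.conditions[j],
                         "statistic": z, "p_value": p, "p_adjusted": p_adj,
                         "significant": p_adj < alpha})
    return pd.DataFrame(rows, columns=cols)


def paired_t_effect(a, b, tail: str = "two") -> TestResult:
    """Paired t-test of a vs b with Cohen's d and post-hoc power.

    ``tail="one"`` tests the hypothesis mean(a - b) > 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    n = diff.size
    sd = diff.std(ddof=1)
    d = float(diff.mean() / sd) if sd > 0 else 0.0
    alternative = "greater" if tail == "one" else "two-sided"
    if sd == 0:
        t_stat, p = 0.0, 1.0 if tail == "two" else 0.5
        if np.allclose(diff, 0):
            p = 1.0
    else:
        t_stat, p = sstats.ttest_rel(a, b, alternative=alternative)
    power = float(TTestPower().power(
        effect_size=abs(d), nobs=n, alpha=ALPHA,
        alternative="larger" if tail == "one" else "two-sided",
    )) if n > 1 else float("nan")
    return TestResult(f"paired_t_{tail}", float(t_stat), float(p),
                      effect_size=d, power=power, extra={"n": n})


# ---------------------------------------------------------------------------
# Direction report
# ---------------------------------------------------------------------------

def condition_matrix_from_table(ft: FeatureTable, feature: str,
                                conditions, subject_col: str | None = None
                                ) -> ConditionMatrix:
    """Aggregate a feature to per-unit condition means.

    Units are subjects when a ``subject`` column is present, else the
    stimulus groups (event ids) are pooled per condition into one row.
    """
    df = ft.df
    unit = subject_col if subject_col and subject_col in df.columns else None
    if unit is None:
        # single-recording table: pair the i-th stimulus of each condition
        # (per-event window means, events ordered by id) into one unit row
        per_event = df.groupby(["label", "group"], sort=True)[feature].mean()
        cols = []
        for c in conditions:
            if c not in per_event.index.get_level_values(0):
                raise ValueError(f"condition {c!r} absent from table")
            cols.append(per_event[c].to_numpy())
        depth = min(len(v) for v in cols)
        if depth == 0:
            raise ValueError("no events for some condition")
        return ConditionMatrix(np.column_stack([v[:depth] for v in cols]),
                               list(conditions))
    piv = df.pivot_table(index=unit, columns="label", values=feature,
                         aggfunc="mean")
    missing = [c for c in conditions if c not in piv.columns]
    if missing:
        raise ValueError(f"conditions {missing} absent from table")
    piv = piv[list(conditions)].dropna()
    return ConditionMatrix(piv.to_numpy(), list(conditions))


def feature_direction_report(ft: FeatureTable, conditions=("P", "NP", "R"),
                             mode: str = "healthy",
                             subject_col: str = "subject") -> pd.DataFrame:
    """Per-feature condition means, difference signs and test results.

    Healthy mode runs the Friedman omnibus plus post hoc pairs on
    per-subject condition means; patient mode (two conditions) runs a
    paired t-test.  Returns a tidy frame, one row per feature.
    """
    conditions = [c for c in conditions if c in set(ft.df["label"])]
    rows = []
    for feat in ft.feature_names:
        if len(ft.df) == 0:
            break
        rec: dict = {"feature": feat}
        for c in conditions:
            rec[f"mean_{c}"] = float(
                ft.df.loc[ft.df["label"] == c, feat].mean())
        if "P" in conditions and "R" in conditions:
            rec["sign_P_minus_R"] = float(np.sign(rec["mean_P"] - rec["mean_R"]))
        if "P" in conditions and "NP" in conditions:
            rec["sign_P_minus_NP"] = float(np.sign(rec["mean_P"] - rec["mean_NP"]))
        try:
            m = condition_matrix_from_table(ft, feat, conditions, subject_col)
            if mode == "patient" or len(conditions) == 2:
                tr = paired_t_effect(m.values[:, 0], m.values[:, 1])
                rec.update(test="paired_t", statistic=tr.statistic,
                           p_value=tr.p_value, effect_size=tr.effect_size)
            elif m.n >= 3:
                omni = friedman_repeated(m)
                rec.update(test="friedman", statistic=omni.statistic,
                           p_value=omni.p_value)
                ph = posthoc_pairwise(m)
                for _, pr in ph.iterrows():
                    rec[f"p_{pr['a']}_vs_{pr['b']}"] = pr["p_adjusted"]
            else:
                rec.update(test="none", statistic=np.nan, p_value=np.nan)
        except ValueError:
            rec.update(test="none", statistic=np.nan, p_value=np.nan)
        rows.append(rec)
    return pd.DataFrame(rows)
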