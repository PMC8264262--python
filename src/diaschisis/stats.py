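"""Normality-gated group comparisons, correlation analysis and cohort
summary tables.

The reporting rules mirror common clinical-imaging practice: each variable is
first screened with the Shapiro-Wilk test (alpha 0.05); normally distributed
continuous variables are compared with an independent two-tailed Student's
t-test and summarized as mean +/- SD, everything else (non-normal, ordinal,
dichotomous) goes through the Mann-Whitney U test and is summarized as
median (IQR) or frequency (%). For dichotomous variables Fisher's exact test
is reported alongside as a secondary check (the 2x2 layout makes it the more
appropriate test, but Mann-Whitney remains the primary). Correlations use
Pearson when both variables pass the gate, Spearman otherwise. No
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "normality_gate",
    "compare_groups",
    "correlate",
    "build_cohort_tables",
]

ALPHA = 0.05


@dataclass(frozen=True)
class GroupComparison:
    variable_name: str
    test_used: str  # "t_test" | "mann_whitney"
    statistic: float
    p_value: float
    group_summaries: tuple[str, str]
    normality: tuple[str, str] | None = None
    fisher_p: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    r: float
    r_squared: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


def normality_gate(values) -> str:
    """Shapiro-Wilk screen at alpha 0.05: returns 'normal' or 'non_normal'."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 3:
        raise DegenerateInputError("normality test needs n >= 3")
    if np.ptp(v) == 0.0:
        raise DegenerateInputError("constant vector: normality undefined")
    _, p = sps.shapiro(v)
    return "normal" if p >= ALPHA else "non_normal"


def _summary(values: np.ndarray, kind: str, normal: bool) -> str:
    if kind == "dichotomous":
        k = int(np.sum(values != 0))
        pct = 100.0 * k / values.size
        return f"{k} ({pct:.0f}%)"
    if values.size == 1:
        return f"{values[0]:.2f}"
    if kind == "continuous" and normal:
        return f"{values.mean():.2f} ± {values.std(ddof=1):.2f}"
    q1, med, q3 = np.percentile(values, [25, 50, 75])  # type-7 linear interpolation
    return f"{med:.2f} ({q1:.2f}–{q3:.2f})"


def compare_groups(
    a_values,
    b_values,
    variable_kind: str = "continuous",
    variable_name: str = "",
    welch: bool = False,
) -> GroupComparison:
    """Two-group comparison routed by the normality gate.

    Continuous variables that are normal in *both* groups take the t-test
    path (equal-variance Student by default, Welch on request); everything
    else takes Mann-Whitney U (two-sided).
    """
    a = np.asarray(list(a_values), dtype=float)
    b = np.asarray(list(b_values), dtype=float)
    if a.size == 0 or b.size == 0:
        raise DegenerateInputError("empty group")
    if variable_kind not in ("continuous", "ordinal", "dichotomous"):
        raise ValueError(f"unknown variable kind {variable_kind!r}")

    normality = None
    use_t = False
    if variable_kind == "continuous" and a.size >= 3 and b.size >= 3:
        try:
            ga, gb = normality_gate(a), normality_gate(b)
            normality = (ga, gb)
            use_t = ga == "normal" and gb == "normal"
        except DegenerateInputError:
            normality = ("degenerate", "degenerate")

    fisher_p = None
    if use_t:
        stat, p = sps.ttest_ind(a, b, equal_var=not welch)
        test_used = "t_test"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        test_used = "mann_whitney"
        if variable_kind == "dichotomous":
            table = [
                [int((a != 0).sum()), int((a == 0).sum())],
                [int((b != 0).sum()), int((b == 0).sum())],
            ]
            fisher_p = float(sps.fisher_exact(table)[1])

    normal = use_t
    return GroupComparison(
        variable_name=variable_name,
        test_used=test_used,
        statistic=float(stat),
        p_value=float(min(1.0, p)),
        group_summaries=(_summary(a, variable_kind, normal), _summary(b, variable_kind, normal)),
        normality=normality,
        fisher_p=fisher_p,
    )


def correlate(x_values, y_values) -> CorrelationResult:
    """Pearson when both variables pass the normality gate, Spearman otherwise."""
    x = np.asarray(list(x_values), dtype=float)
    y = np.asarray(list(y_values), dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise DegenerateInputError("correlation needs n >= 3")
    try:
        both_normal = normality_gate(x) == "normal" and normality_gate(y) == "normal"
    except DegenerateInputError:
        both_normal = False
    if both_normal:
        r, p = sps.pearsonr(x, y)
        method = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        method = "spearman"
    r = float(r)
    return CorrelationResult(method=method, r=r, r_squared=r * r, p_value=float(p), n=int(x.size))


# ---------------------------------------------------------------------------
# Cohort summary tables
# ---------------------------------------------------------------------------

#: (row label, metrics column, variable kind) for the structural/hemodynamic
#: findings table; AI columns use the peduncle/thalamus/cerebellum stems.
FINDINGS_ROWS: tuple[tuple[str, str, str], ...] = (
    ("Volume ipsilateral cerebral peduncle (cm3)", "volume_cm3_peduncle_ipsi", "continuous"),
    ("Volume contralateral cerebral peduncle (cm3)", "volume_cm3_peduncle_contra", "continuous"),
    ("Cerebral peduncle volume AI (%)", "volume_ai_peduncle", "continuous"),
    ("Mean BOLD-CVR ipsilateral cerebral peduncle", "cvr_peduncle_ipsi", "continuous"),
    ("Mean BOLD-CVR contralateral cerebral peduncle", "cvr_peduncle_contra", "continuous"),
    ("Cerebral peduncular BOLD-CVR AI (%)", "cvr_ai_peduncle", "continuous"),
    ("Cerebral peduncular PET baseline AI (%)", "pet_baseline_ai_peduncle", "continuous"),
    ("Cerebral peduncular PET Diamox AI (%)", "pet_diamox_ai_peduncle", "continuous"),
    ("Ipsilateral thalamic diaschisis (%)", "itd_positive", "dichotomous"),
    ("Volume thalamus ipsilateral (cm3)", "volume_cm3_thalamus_ipsi", "continuous"),
    ("Volume thalamus contralateral (cm3)", "volume_cm3_thalamus_contra", "continuous"),
    ("Thalamic volume AI (%)", "volume_ai_thalamus", "continuous"),
    ("BOLD-CVR ipsilateral thalamus", "cvr_thalamus_ipsi", "continuous"),
    ("BOLD-CVR contralateral thalamus", "cvr_thalamus_contra", "continuous"),
    ("Thalamic BOLD-CVR AI (%)", "cvr_ai_thalamus", "continuous"),
    ("Thalamic PET baseline AI (%)", "pet_baseline_ai_thalamus", "continuous"),
    ("Thalamic PET Diamox AI (%)", "pet_diamox_ai_thalamus", "continuous"),
    ("Crossed cerebellar diaschisis (%)", "ccd_positive", "dichotomous"),
    ("Volume cerebellum ipsilateral (cm3)", "volume_cm3_cerebellum_ipsi", "continuous"),
    ("Volume cerebellum contralateral (cm3)", "volume_cm3_cerebellum_contra", "continuous"),
    ("Cerebellar volume AI (%)", "volume_ai_cerebellum", "continuous"),
    ("Cerebellar BOLD-CVR AI (%)", "cvr_ai_cerebellum", "continuous"),
    ("Cerebellar PET baseline AI (%)", "pet_baseline_ai_cerebellum", "continuous"),
    ("Cerebellar PET Diamox AI (%)", "pet_diamox_ai_cerebellum", "continuous"),
    ("Stroke volume (cm3)", "stroke_volume_cm3", "continuous"),
    ("Corticospinal tract involvement (%)", "cst_involved", "dichotomous"),
)

CLINICAL_ROWS: tuple[tuple[str, str, str], ...] = (
    ("Age", "age", "continuous"),
    ("Sex, n male (%)", "sex_male", "dichotomous"),
    ("Smoking n (%)", "smoking", "dichotomous"),
    ("Hypertension n (%)", "hypertension", "dichotomous"),
    ("Hypercholesterolemia n (%)", "hypercholesterolemia", "dichotomous"),
    ("Obesity n (%)", "obesity", "dichotomous"),
    ("Diabetes n (%)", "diabetes", "dichotomous"),
    ("Mean CO2 baseline (mmHg)", "co2_baseline_mmHg", "continuous"),
    ("Mean CO2 hypercapnia (mmHg)", "co2_hypercapnia_mmHg", "continuous"),
    ("Mean CO2 stepchange (mmHg)", "co2_step_mmHg", "continuous"),
    ("Mean time after stroke (weeks)", "time_after_stroke_weeks", "continuous"),
    ("Stroke volume (cm3)", "stroke_volume_cm3", "continuous"),
)

HEALTHY_ROWS: tuple[tuple[str, str, str], ...] = (
    ("Age", "age", "continuous"),
    ("Sex, n male (%)", "sex_male", "dichotomous"),
    ("Smoking n (%)", "smoking", "dichotomous"),
    ("Hypertension n (%)", "hypertension", "dichotomous"),
    ("Mean CVR whole brain", "cvr_whole_brain", "continuous"),
    ("Mean CVR left cerebral peduncle", "cvr_peduncle_L", "continuous"),
    ("Mean CVR right cerebral peduncle", "cvr_peduncle_R", "continuous"),
    ("Volume left cerebral peduncle (cm3)", "volume_cm3_peduncle_L", "continuous"),
    ("Volume right cerebral peduncle (cm3)", "volume_cm3_peduncle_R", "continuous"),
    ("Cerebral peduncle volume AI (%)", "volume_ai_peduncle", "continuous"),
    ("CVR Thalamic AI (%)", "cvr_ai_thalamus", "continuous"),
    ("Volume thalamus left (cm3)", "volume_cm3_thalamus_L", "continuous"),
    ("Volume thalamus right (cm3)", "volume_cm3_thalamus_R", "continuous"),
    ("CVR Cerebellar AI (%)", "cvr_ai_cerebellum", "continuous"),
)


def _describe(values: np.ndarray, kind: str) -> str:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return "n/a"
    if kind == "dichotomous":
        return _summary(values, "dichotomous", False)
    if values.size >= 3 and np.ptp(values) > 0:
        normal = normality_gate(values) == "normal"
    else:
        normal = True
    return _summary(values, "continuous", normal)


def _comparison_row(sub_a: pd.DataFrame, sub_b: pd.DataFrame, col: str, kind: str):
    """Per-variable WD+ vs WD- comparison; p flagged not-computable for
    single-subject groups or missing columns."""
    if col not in sub_a.columns or col not in sub_b.columns:
        return "n/a", "n/a", np.nan, "not_computable"
    a = sub_a[col].to_numpy(dtype=float)
    b = sub_b[col].to_numpy(dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        sa = _describe(a, kind) if a.size else "n/a"
        sb = _describe(b, kind) if b.size else "n/a"
        return sa, sb, np.nan, "not_computable"
    try:
        cmp_res = compare_groups(a, b, variable_kind=kind, variable_name=col)
    except DegenerateInputError:
        return _describe(a, kind), _describe(b, kind), np.nan, "not_computable"
    return cmp_res.group_summaries[0], cmp_res.group_summaries[1], cmp_res.p_value, cmp_res.test_used


def build_cohort_tables(metrics_df: pd.DataFrame, healthy_ref: dict | None = None):
    """Build the three cohort summary tables from a tidy metrics table.

    ``metrics_df`` must carry one row per subject with a ``group`` column
    (healthy / acute / chronic) and, for chronic subjects, ``wd_positive``,
    ``itd_positive`` and ``ccd_positive`` flags merged in. Subject order is
    irrelevant; every cell is an order-invariant statistic.

    Returns a dict with DataFrames ``healthy``, ``clinical``, ``findings``.
    """
    if metrics_df.empty:
        raise DegenerateInputError("empty metrics table")
    df = metrics_df.copy()

    healthy = df[df["group"] == "healthy"]
    chronic = df[df["group"] == "chronic"]
    if chronic.empty or healthy.empty:
        raise DegenerateInputError("need non-empty healthy and chronic cohorts")
    wd_pos = chronic[chronic["wd_positive"] == 1]
    wd_neg = chronic[chronic["wd_positive"] == 0]

    healthy_rows = []
    for label, col, kind in HEALTHY_ROWS:
        vals = healthy[col].to_numpy(dtype=float) if col in healthy.columns else np.array([])
        healthy_rows.append({"variable": label, f"total_n{len(healthy)}": _describe(vals, kind)})
    t_healthy = pd.DataFrame(healthy_rows)

    def group_table(rows):
        out = []
        for label, col, kind in rows:
            vals = chronic[col].to_numpy(dtype=float) if col in chronic.columns else np.array([])
            sa, sb, p, test = _comparison_row(wd_pos, wd_neg, col, kind)
            out.append(
                {
                    "variable": label,
                    f"total_n{len(chronic)}": _describe(vals, kind),
                    f"wd_positive_n{len(wd_pos)}": sa,
                    f"wd_negative_n{len(wd_neg)}": sb,
                    "p_value": p,
                    "test": test,
                }
            )
        return pd.DataFrame(out)

    return {
        "healthy": t_healthy,
        "clinical": group_table(CLINICAL_ROWS),
        "findings": group_table(FINDINGS_ROWS),
    }
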