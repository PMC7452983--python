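"""Error metrics and longitudinal statistics for cohort volume tables.

The cohort table is long-format: one averaged value per (subject,
timepoint, measure) with measures in {"OCC", "TV", "ratio"} and
timepoints in {"T0", "T1", "T2", "T3"}.  All tests are two-sided and all
standard deviations use the n-1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError

__all__ = [
    "MethodErrorResult",
    "GroupLabel",
    "method_error",
    "coefficient_of_variation",
    "holm_sidak_adjust",
    "holm_sidak_paired",
    "gg_epsilon",
    "rm_anova_gg",
    "rm_anova_gg_wide",
    "two_way_rm_interaction",
    "decrease_regression",
    "classify_ratio_change",
    "cohort_analysis",
]

TIMEPOINTS = ("T0", "T1", "T2", "T3")
DEFAULT_PAIRS = (("T0", "T1"), ("T0", "T2"), ("T0", "T3"),
                 ("T1", "T2"), ("T1", "T3"), ("T2", "T3"))


# ---------------------------------------------------------------------------
# error quantification


@dataclass
class MethodErrorResult:
    """Difference and percent difference of replicates against a reference."""

    mean_diff_cm3: float
    sd_diff_cm3: float
    mean_pct_diff: float
    sd_pct_diff: float
    n: int


def method_error(measured: list[float], reference_cm3: float) -> MethodErrorResult:
    """Absolute and percent differences of replicate measurements of an
    object of known volume (the phantom-accuracy protocol)."""
    if reference_cm3 <= 0:
        raise StatsError("reference volume must be positive")
    m = np.asarray(measured, dtype=float)
    if m.size < 1:
        raise StatsError("need at least one measurement")
    diff = np.abs(m - reference_cm3)
    pct = 100.0 * diff / reference_cm3
    sd = float(np.std(diff, ddof=1)) if m.size > 1 else 0.0
    sd_pct = float(np.std(pct, ddof=1)) if m.size > 1 else 0.0
    return MethodErrorResult(
        mean_diff_cm3=float(diff.mean()),
        sd_diff_cm3=sd,
        mean_pct_diff=float(pct.mean()),
        sd_pct_diff=sd_pct,
        n=int(m.size),
    )


def coefficient_of_variation(values: list[float]) -> float:
    """Sample SD as a percentage of the mean (intra-subject repeatability)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise StatsError("coefficient of variation needs at least 2 values")
    mean = float(v.mean())
    if mean == 0:
        raise StatsError("coefficient of variation undefined for zero mean")
    return 100.0 * float(np.std(v, ddof=1)) / abs(mean)


# ---------------------------------------------------------------------------
# multiple comparisons


def holm_sidak_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Step-down Sidak adjustment.

    Sort raw p ascending; adjusted_i = max_{j<=i} 1 - (1 - p_j)^(m - j + 1),
    capped at 1, mapped back to the input order.
    """
    p = np.asarray(p_raw, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty_like(adj_sorted)
    out[order] = adj_sorted
    return out


def _paired_t(a, b) -> tuple[float, float]:
    """Two-sided paired t with explicit zero-variance handling."""
    diff = np.asarray(a, float) - np.asarray(b, float)
    if np.allclose(diff, 0):
        return 0.0, 1.0
    if np.std(diff) == 0:  # constant nonzero shift: infinitely strong evidence
        return np.inf, 0.0
    t_stat, p = sps.ttest_rel(a, b)
    return float(t_stat), float(p)


def _wide(table: pd.DataFrame, measure: str) -> pd.DataFrame:
    t = table[table["measure"] == measure]
    if t.empty:
        raise StatsError(f"no rows for measure {measure!r}")
    if t.duplicated(["subject_id", "timepoint"]).any():
        raise StatsError(f"more than one value per (subject, timepoint) for {measure!r}")
    wide = t.pivot(index="subject_id", columns="timepoint", values="value")
    return wide


def holm_sidak_paired(
    table: pd.DataFrame,
    measure: str,
    comparisons: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired t-tests across timepoint pairs with step-down Sidak adjustment.

    Returns one row per comparison: t, raw two-sided p, adjusted p, and the
    rejection flag at ``alpha``.  Subjects missing either timepoint of a
    comparison make the design incomplete and are refused.
    """
    wide = _wide(table, measure)
    trows = []
    for a, b in comparisons:
        if a not in wide.columns or b not in wide.columns:
            raise StatsError(f"timepoint missing from table for comparison {a} vs {b}")
        pair = wide[[a, b]].dropna()
        if len(pair) < len(wide):
            raise StatsError(
                f"comparison {a} vs {b} has subjects with missing sessions; "
                "pairwise tests on gaps are refused"
            )
        if len(pair) < 2:
            raise StatsError("paired comparisons need at least 2 complete subjects")
        t_stat, p = _paired_t(pair[a], pair[b])
        trows.append({"timepoint_a": a, "timepoint_b": b,
                      "t": t_stat, "p_raw": p, "n": len(pair)})
    out = pd.DataFrame(trows)
    out["p_adj"] = holm_sidak_adjust(out["p_raw"].to_numpy())
    out["reject"] = out["p_adj"] < alpha
    return out


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon from a k x k covariance matrix."""
    S = np.asarray(cov, dtype=float)
    k = S.shape[0]
    if S.shape != (k, k) or k < 2:
        raise StatsError("epsilon needs a square covariance of at least 2 timepoints")
    # double centering
    row = S.mean(axis=0, keepdims=True)
    col = S.mean(axis=1, keepdims=True)
    C = S - row - col + S.mean()
    num = np.trace(C) ** 2
    den = (k - 1) * np.sum(C * C)
    if den <= 0:
        return 1.0
    return float(min(max(num / den, 1.0 / (k - 1)), 1.0))


@dataclass
class RmAnovaResult:
    F: float
    df_num: float
    df_den: float
    epsilon: float
    p: float
    n: int
    k: int


def rm_anova_gg(table: pd.DataFrame, measure: str) -> RmAnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    The within-subject F for the timepoint factor is referred to an F
    distribution with both degrees of freedom multiplied by the sample
    epsilon (computed from the covariance of the timepoint measures).
    """
    wide = _wide(table, measure)
    if wide.isna().any().any():
        raise StatsError("repeated-measures ANOVA needs a complete subjects x timepoints design")
    return rm_anova_gg_wide(wide.to_numpy(dtype=float))


def rm_anova_gg_wide(x: np.ndarray) -> RmAnovaResult:
    """GG-corrected one-way RM-ANOVA on an (n subjects x k timepoints) array."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise StatsError("need at least 2 subjects and 2 timepoints")
    grand = x.mean()
    time_means = x.mean(axis=0)
    subj_means = x.mean(axis=1)
    ss_time = n * float(((time_means - grand) ** 2).sum())
    resid = x - time_means[None, :] - subj_means[:, None] + grand
    ss_err = float((resid ** 2).sum())
    df_time, df_err = k - 1, (n - 1) * (k - 1)
    if ss_err <= 0:
        F = 0.0 if ss_time <= 0 else np.inf
    else:
        F = (ss_time / df_time) / (ss_err / df_err)
    eps = gg_epsilon(np.cov(x, rowvar=False))
    if F == 0.0:
        p = 1.0
    else:
        p = float(sps.f.sf(F, eps * df_time, eps * df_err))
    return RmAnovaResult(F=float(F), df_num=eps * df_time, df_den=eps * df_err,
                         epsilon=eps, p=p, n=n, k=k)


@dataclass
class TwoWayRmResult:
    interaction_F: float
    interaction_df: tuple[float, float]
    interaction_p: float
    measure_F: float
    measure_p: float
    time_F: float
    time_p: float
    posthoc: pd.DataFrame
    n: int


def two_way_rm_interaction(
    table: pd.DataFrame,
    measures: tuple[str, str] = ("OCC", "TV"),
    alpha: float = 0.05,
) -> TwoWayRmResult:
    """Two-factor within-subject ANOVA (measure x time) with interaction.

    The headline quantity is the measure-by-time interaction: parallel OCC
    and TV profiles give F near 0.  Post hoc, each measure's timepoint
    pairs are compared with paired t-tests under a single-step Sidak
    correction (1 - (1-p)^m over all cells tested).
    """
    wides = [_wide(table, m) for m in measures]
    common = wides[0].index.intersection(wides[1].index)
    wides = [w.loc[common, list(TIMEPOINTS)] for w in wides]
    if any(w.isna().any().any() for w in wides):
        raise StatsError("two-way RM ANOVA needs a complete 2 x k within-subject design")
    x = np.stack([w.to_numpy(dtype=float) for w in wides], axis=1)  # (n, 2, k)
    n, a, k = x.shape
    if n < 2:
        raise StatsError("two-way RM ANOVA needs at least 2 subjects")
    grand = x.mean()
    m_s = x.mean(axis=(1, 2))      # subject
    m_a = x.mean(axis=(0, 2))      # measure
    m_b = x.mean(axis=(0, 1))      # time
    m_ab = x.mean(axis=0)          # measure x time
    m_as = x.mean(axis=2)          # subject x measure
    m_bs = x.mean(axis=1)          # subject x time

    def ss(v):
        return float((v ** 2).sum())

    ss_a = n * k * ss(m_a - grand)
    ss_b = n * a * ss(m_b - grand)
    ss_ab = n * ss(m_ab - m_a[:, None] - m_b[None, :] + grand)
    ss_as = k * ss(m_as - m_s[:, None] - m_a[None, :] + grand)
    ss_bs = a * ss(m_bs - m_s[:, None] - m_b[None, :] + grand)
    resid = (
        x
        - m_ab[None, :, :]
        - m_as[:, :, None]
        - m_bs[:, None, :]
        + m_a[None, :, None]
        + m_b[None, None, :]
        + m_s[:, None, None]
        - grand
    )
    ss_abs = ss(resid)

    df_a, df_b = a - 1, k - 1
    df_ab = df_a * df_b
    df_as, df_bs, df_abs = (n - 1) * df_a, (n - 1) * df_b, (n - 1) * df_ab

    def f_of(ss_num, df_num, ss_den, df_den):
        if ss_den <= 0:
            return (0.0, 1.0) if ss_num <= 0 else (np.inf, 0.0)
        F = (ss_num / df_num) / (ss_den / df_den)
        return float(F), float(sps.f.sf(F, df_num, df_den))

    F_a, p_a = f_of(ss_a, df_a, ss_as, df_as)
    F_b, p_b = f_of(ss_b, df_b, ss_bs, df_bs)
    F_ab, p_ab = f_of(ss_ab, df_ab, ss_abs, df_abs)

    rows = []
    for mi, mname in enumerate(measures):
        for ta, tb in DEFAULT_PAIRS:
            ia, ib = TIMEPOINTS.index(ta), TIMEPOINTS.index(tb)
            t_stat, p = _paired_t(x[:, mi, ia], x[:, mi, ib])
            rows.append({"measure": mname, "timepoint_a": ta, "timepoint_b": tb,
                         "t": t_stat, "p_raw": p})
    posthoc = pd.DataFrame(rows)
    m_tests = len(posthoc)
    posthoc["p_sidak"] = 1.0 - (1.0 - posthoc["p_raw"]) ** m_tests
    posthoc["reject"] = posthoc["p_sidak"] < alpha

    return TwoWayRmResult(
        interaction_F=F_ab, interaction_df=(float(df_ab), float(df_abs)),
        interaction_p=p_ab, measure_F=F_a, measure_p=p_a,
        time_F=F_b, time_p=p_b, posthoc=posthoc, n=n,
    )


# ---------------------------------------------------------------------------
# decrease regression and group classification


@dataclass
class DecreaseRegression:
    slope: float
    intercept: float
    pearson_r: float
    p: float
    n: int
    deltas: pd.DataFrame


def decrease_regression(table: pd.DataFrame, t_from: str = "T0", t_to: str = "T1") -> DecreaseRegression:
    """OLS of the per-subject TV decrease on the OCC decrease (T0 - T1).

    Decreases are positive quantities; the Pearson correlation and its
    two-sided p-value come from t = r sqrt((n-2)/(1-r^2)).
    """
    occ = _wide(table, "OCC")
    tv = _wide(table, "TV")
    common = occ.index.intersection(tv.index)
    for w, name in ((occ, "OCC"), (tv, "TV")):
        if t_from not in w.columns or t_to not in w.columns:
            raise StatsError(f"{name} missing a timepoint for the decrease regression")
    d_occ = (occ.loc[common, t_from] - occ.loc[common, t_to]).dropna()
    d_tv = (tv.loc[common, t_from] - tv.loc[common, t_to]).dropna()
    common = d_occ.index.intersection(d_tv.index)
    d_occ, d_tv = d_occ.loc[common], d_tv.loc[common]
    n = len(common)
    if n < 3:
        raise StatsError("decrease regression needs at least 3 subjects")
    if np.std(d_occ) == 0:
        raise StatsError("zero variance in OCC decreases; regression undefined")
    res = sps.linregress(d_occ, d_tv)
    deltas = pd.DataFrame({"subject_id": common, "delta_occ_cm3": d_occ.to_numpy(),
                           "delta_tv_cm3": d_tv.to_numpy()})
    return DecreaseRegression(
        slope=float(res.slope), intercept=float(res.intercept),
        pearson_r=float(res.rvalue), p=float(res.pvalue), n=n, deltas=deltas,
    )


@dataclass(frozen=True)
class GroupLabel:
    """Stability class of a subject's TV/OCC change from T0 to T1."""

    label: str           # "I", "II" or "III"
    delta_ratio_pct: float


def classify_ratio_change(delta_ratio_pct: float) -> GroupLabel:
    """Group I: |change| within +/-2.0 percentage points (inclusive);
    group II: increase beyond +2.0; group III: decrease beyond -2.0."""
    d = float(delta_ratio_pct)
    if not np.isfinite(d):
        raise StatsError("ratio change must be finite")
    if -2.0 <= d <= 2.0:
        label = "I"
    elif d > 2.0:
        label = "II"
    else:
        label = "III"
    return GroupLabel(label=label, delta_ratio_pct=d)


# ---------------------------------------------------------------------------
# orchestration


def cohort_analysis(table: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Run the full longitudinal battery on a cohort table.

    Returns a dict with the Holm-Sidak timepoint comparisons for OCC and
    TV, the two-way measure x time interaction, the T0->T1 decrease
    regression, the GG-corrected RM-ANOVA of the TV/OCC ratio, and the
    per-subject stability groups with their counts.
    """
    required = {"subject_id", "timepoint", "measure", "value"}
    if not required.issubset(table.columns):
        raise StatsError(f"cohort table needs columns {sorted(required)}")
    out: dict = {"alpha": alpha}
    out["holm_sidak"] = {m: holm_sidak_paired(table, m, alpha=alpha) for m in ("OCC", "TV")}
    out["two_way"] = two_way_rm_interaction(table, alpha=alpha)
    out["regression"] = decrease_regression(table)
    out["ratio_rm_anova"] = rm_anova_gg(table, "ratio")

    ratio = _wide(table, "ratio")
    if "T0" not in ratio.columns or "T1" not in ratio.columns:
        raise StatsError("group classification needs ratio values at T0 and T1")
    delta = (ratio["T1"] - ratio["T0"]).dropna()
    groups = pd.DataFrame({
        "subject_id": delta.index,
        "delta_ratio_pct": delta.to_numpy(),
        "group": [classify_ratio_change(d).label for d in delta],
    })
    counts = groups["group"].value_counts().reindex(["I", "II", "III"], fill_value=0)
    out["groups"] = groups
    out["group_counts"] = {g: int(c) for g, c in counts.items()}
    return out


def analysis_report_json(analysis: dict) -> dict:
    """JSON-serializable summary of a cohort analysis."""
    hs = {
        m: df.to_dict(orient="records") for m, df in analysis["holm_sidak"].items()
    }
    tw = analysis["two_way"]
    reg = analysis["regression"]
    rm = analysis["ratio_rm_anova"]
    return {
        "alpha": analysis["alpha"],
        "holm_sidak": hs,
        "two_way": {
            "interaction_F": tw.interaction_F,
            "interaction_df": list(tw.interaction_df),
            "interaction_p": tw.interaction_p,
            "posthoc": tw.posthoc.to_dict(orient="records"),
        },
        "regression": {"slope": reg.slope, "intercept": reg.intercept,
                       "pearson_r": reg.pearson_r, "p": reg.p, "n": reg.n},
        "ratio_rm_anova": {"F": rm.F, "df": [rm.df_num, rm.df_den],
                           "epsilon": rm.epsilon, "p": rm.p},
        "groups": analysis["groups"].to_dict(orient="records"),
        "group_counts": analysis["group_counts"],
    }
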