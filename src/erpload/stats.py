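"""Repeated-measures statistics and behavioral/self-report scoring.

The workhorse is a balanced two-way within-subject ANOVA (workload x control
scheme) computed by direct sums-of-squares decomposition, reported with
uncorrected integer degrees of freedom plus a Greenhouse-Geisser-corrected
p-value as a supplementary column.  Post-hoc workload comparisons use a
Tukey-HSD-style familywise adjustment over the three pairs via the
studentized range distribution on the within-subject error term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy import stats as sps

from .errors import DataValidationError
from .io import CONDITION_ORDER, SCHEME_ORDER
from .simulate import REVERSE_SCORED_ITEMS


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    gg_epsilon: float
    p_gg: float
    partial_eta_sq: float


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_difference: float  # mean(x - y)
    n: int


@dataclass(frozen=True)
class PairwiseComparison:
    level_a: str
    level_b: str
    mean_difference: float  # mean(a) - mean(b)
    q: float
    df: int
    p_adjusted: float  # Tukey-HSD familywise over the 3 workload pairs
    p_unadjusted: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    defined: bool


def _ordered_levels(values, canonical: tuple[str, ...]) -> list[str]:
    present = list(dict.fromkeys(str(v) for v in values))
    ranked = [lvl for lvl in canonical if lvl in present]
    return ranked + [lvl for lvl in present if lvl not in ranked]


def _cell_matrix(table: pd.DataFrame, value_col: str) -> tuple[np.ndarray, list, list[str], list[str]]:
    """Pivot a long table to participants x condition x scheme, checking balance."""
    required = {"participant", "scheme", "condition", value_col}
    missing = required - set(table.columns)
    if missing:
        raise DataValidationError(f"amplitude table missing columns {sorted(missing)}")
    conditions = _ordered_levels(table["condition"], CONDITION_ORDER)
    schemes = _ordered_levels(table["scheme"], SCHEME_ORDER)
    participants = sorted(table["participant"].unique())
    pivot = table.pivot_table(
        index="participant", columns=["condition", "scheme"], values=value_col, aggfunc="count"
    )
    bad = []
    for p in participants:
        for cond in conditions:
            for sch in schemes:
                n = pivot.loc[p].get((cond, sch), np.nan) if p in pivot.index else np.nan
                if not n == 1:
                    bad.append(p)
                    break
            if bad and bad[-1] == p:
                break
    if bad:
        raise DataValidationError(
            f"incomplete/unbalanced cells; exclude participants {sorted(set(bad))}"
        )
    Y = np.empty((len(participants), len(conditions), len(schemes)))
    indexed = table.set_index(["participant", "condition", "scheme"])[value_col]
    for i, p in enumerate(participants):
        for j, cond in enumerate(conditions):
            for k, sch in enumerate(schemes):
                Y[i, j, k] = float(indexed.loc[(p, cond, sch)])
    return Y, participants, conditions, schemes


def _gg_epsilon(Z: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from subject x level scores (orthonormal contrasts)."""
    k = Z.shape[1]
    if k < 3:
        return 1.0
    C = linalg.helmert(k, full=False)
    V = np.cov(Z @ C.T, rowvar=False)
    V = np.atleast_2d(V)
    d = k - 1
    denom = d * np.sum(V * V)
    if denom == 0.0:
        return 1.0
    eps = np.trace(V) ** 2 / denom
    return float(np.clip(eps, 1.0 / d, 1.0))


def _interaction_epsilon(Y: np.ndarray) -> float:
    n, a, b = Y.shape
    d = (a - 1) * (b - 1)
    if d < 2:
        return 1.0
    Ca = linalg.helmert(a, full=False)
    Cb = linalg.helmert(b, full=False)
    Z = np.stack([(Ca @ Y[i] @ Cb.T).ravel() for i in range(n)])
    V = np.atleast_2d(np.cov(Z, rowvar=False))
    denom = d * np.sum(V * V)
    if denom == 0.0:
        return 1.0
    eps = np.trace(V) ** 2 / denom
    return float(np.clip(eps, 1.0 / d, 1.0))


def _f_p(F: float, df1: float, df2: float) -> float:
    return float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else float("nan")


def rm_anova(
    table: pd.DataFrame,
    value_col: str = "amplitude_uv",
    workload_factor: str = "workload",
    scheme_factor: str = "scheme",
) -> list[AnovaResult]:
    """Two-way fully within-subject ANOVA on a long (participant, scheme,
    condition, value) table.

    Returns results for the workload main effect, the scheme main effect, and
    their interaction, each with uncorrected df and a Greenhouse-Geisser
    supplementary p.
    """
    Y, participants, conditions, schemes = _cell_matrix(table, value_col)
    n, a, b = Y.shape
    if n < 2:
        raise DataValidationError("repeated-measures ANOVA needs >= 2 participants")
    g = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    m_ab = Y.mean(axis=0)

    results = []

    def effect(name: str, ss_eff: float, df_eff: int, ss_err: float, df_err: int, eps: float):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else float("inf"))
        denom = ss_eff + ss_err
        results.append(
            AnovaResult(
                effect=name,
                F=float(F),
                df_num=df_eff,
                df_den=df_err,
                p=_f_p(F, df_eff, df_err),
                gg_epsilon=eps,
                p_gg=_f_p(F, eps * df_eff, eps * df_err),
                partial_eta_sq=float(ss_eff / denom) if denom > 0 else 0.0,
            )
        )

    if a > 1:
        ss_a = n * b * np.sum((m_a - g) ** 2)
        resid_a = m_sa - m_s[:, None] - m_a[None, :] + g
        ss_as = b * np.sum(resid_a**2)
        effect(workload_factor, ss_a, a - 1, ss_as, (a - 1) * (n - 1), _gg_epsilon(m_sa))
    if b > 1:
        ss_b = n * a * np.sum((m_b - g) ** 2)
        resid_b = m_sb - m_s[:, None] - m_b[None, :] + g
        ss_bs = a * np.sum(resid_b**2)
        effect(scheme_factor, ss_b, b - 1, ss_bs, (b - 1) * (n - 1), _gg_epsilon(m_sb))
    if a > 1 and b > 1:
        ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)
        resid = (
            Y
            - m_sa[:, :, None]
            - m_sb[:, None, :]
            - m_ab[None, :, :]
            + m_s[:, None, None]
            + m_a[None, :, None]
            + m_b[None, None, :]
            - g
        )
        ss_abs = np.sum(resid**2)
        effect(
            f"{workload_factor} x {scheme_factor}",
            ss_ab,
            (a - 1) * (b - 1),
            ss_abs,
            (a - 1) * (b - 1) * (n - 1),
            _interaction_epsilon(Y),
        )
    return results


def posthoc_workload(
    table: pd.DataFrame, value_col: str = "amplitude_uv"
) -> list[PairwiseComparison]:
    """All pairwise workload comparisons, Tukey-HSD adjusted over the family.

    Scheme is collapsed by per-participant averaging; the error term is the
    condition x subject interaction of the one-way repeated-measures ANOVA.
    The unadjusted p uses the same statistic with a 2-level studentized range
    (equivalent to an uncorrected pooled-error t-test), so adjusted >=
    unadjusted always holds.
    """
    collapsed = (
        table.groupby(["participant", "condition"], sort=True)[value_col].mean().reset_index()
    )
    conditions = _ordered_levels(collapsed["condition"], CONDITION_ORDER)
    k = len(conditions)
    if k < 2:
        raise DataValidationError("post-hoc comparisons need >= 2 workload levels")
    wide = collapsed.pivot(index="participant", columns="condition", values=value_col)
    if wide.isna().any().any():
        raise DataValidationError("unbalanced workload cells in post-hoc table")
    Z = wide[conditions].to_numpy()
    n = Z.shape[0]
    means = Z.mean(axis=0)
    resid = Z - Z.mean(axis=1, keepdims=True) - means[None, :] + Z.mean()
    df_err = (k - 1) * (n - 1)
    ms_err = np.sum(resid**2) / df_err
    se = np.sqrt(ms_err / n)
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            if se == 0:
                q = 0.0 if diff == 0 else float("inf")
            else:
                q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df_err)) if np.isfinite(q) else 0.0
            p_un = float(sps.studentized_range.sf(q, 2, df_err)) if np.isfinite(q) else 0.0
            out.append(
                PairwiseComparison(
                    level_a=conditions[i],
                    level_b=conditions[j],
                    mean_difference=float(diff),
                    q=float(q),
                    df=df_err,
                    p_adjusted=min(p_adj, 1.0),
                    p_unadjusted=min(p_un, 1.0),
                )
            )
    return out


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Classical two-tailed paired-samples t-test on participant-matched vectors.

    All-zero differences return t = 0, p = 1 by convention; zero-variance
    nonzero differences return an infinite t with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataValidationError("paired_t needs two equal-length 1-D vectors")
    n = len(x)
    if n < 2:
        raise DataValidationError("paired_t needs at least 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return PairedTestResult(t=0.0, df=df, p=1.0, mean_difference=0.0, n=n)
        t = float(np.inf) if mean > 0 else float(-np.inf)
        return PairedTestResult(t=t, df=df, p=0.0, mean_difference=mean, n=n)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return PairedTestResult(t=float(t), df=df, p=p, mean_difference=mean, n=n)


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with a t-distributed two-tailed p on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataValidationError("pearson_corr needs two equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise DataValidationError("pearson_corr needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataValidationError("pearson_corr requires finite values")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        return CorrelationResult(r=float("nan"), p=float("nan"), n=n, defined=False)
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=n, defined=True)


def behavior_summary(trial_log: pd.DataFrame) -> pd.DataFrame:
    """Percent completed and success-only completion times per scheme x condition.

    View trials carry no success flag and are skipped.  Cells with zero
    successful trials get ``mean_time_defined = False`` and NaN times.
    """
    required = {"scheme", "condition", "success", "duration_s"}
    missing = required - set(trial_log.columns)
    if missing:
        raise DataValidationError(f"trial log missing columns {sorted(missing)}")
    rows = []
    scored = trial_log[trial_log["success"].notna()]
    for (scheme, condition), grp in scored.groupby(["scheme", "condition"], sort=True):
        success = grp["success"].astype(bool)
        n_trials = len(grp)
        n_success = int(success.sum())
        ok_times = grp.loc[success, "duration_s"]
        rows.append(
            {
                "scheme": scheme,
                "condition": condition,
                "n_trials": n_trials,
                "n_success": n_success,
                "percent_completed": 100.0 * n_success / n_trials,
                "mean_time_s": float(ok_times.mean()) if n_success else float("nan"),
                "sd_time_s": float(ok_times.std(ddof=1)) if n_success > 1 else float("nan"),
                "mean_time_defined": n_success > 0,
            }
        )
    return pd.DataFrame(rows)


def score_questionnaire(responses: Sequence[int]) -> int:
    """Total of 7 Likert items (1-5) with items 1, 3, 7 reverse scored (x -> 6-x)."""
    if len(responses) != 7:
        raise DataValidationError(f"expected exactly 7 responses, got {len(responses)}")
    total = 0
    for i, raw in enumerate(responses, start=1):
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            raise DataValidationError(f"item {i} is missing")
        value = int(raw)
        if value != raw or not 1 <= value <= 5:
            raise DataValidationError(f"item {i} response {raw!r} outside 1..5")
        total += (6 - value) if i in REVERSE_SCORED_ITEMS else value
    return total


def score_questionnaire_table(df: pd.DataFrame) -> pd.DataFrame:
    """Totals per participant x scheme from raw q1..q7 columns."""
    items = [f"q{i}" for i in range(1, 8)]
    missing = [c for c in ["participant", "scheme"] + items if c not in df.columns]
    if missing:
        raise DataValidationError(f"questionnaire table missing columns {missing}")
    rows = [
        {
            "participant": row["participant"],
            "scheme": row["scheme"],
            "total": score_questionnaire([row[c] for c in items]),
        }
        for _, row in df.iterrows()
    ]
    return pd.DataFrame(rows)
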