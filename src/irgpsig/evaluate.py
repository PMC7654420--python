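"""Risk stratification and evaluation of a gene-pair signature.

Covers the evaluation stages downstream of risk scoring: the time-dependent
ROC at a fixed horizon (cumulative-case / dynamic-control with inverse
probability of censoring weights), the Youden-optimal cutoff, high/low group
assignment, Kaplan–Meier plus log-rank comparison between groups,
univariate/multivariate Cox proportional-hazards fits against clinical
covariates, categorical cohort summaries, and per-feature rank-sum
comparisons (e.g. immune-cell fractions) between risk groups.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .model import RiskProfile
from .screen import KMCurve, km_estimate, logrank_test

__all__ = ["ROCCurve", "timedep_roc", "optimal_cutoff", "assign_groups",
           "compare_survival", "cox_fit", "encode_covariates",
           "summarize_cohort", "compare_feature_by_group"]


@dataclass
class ROCCurve:
    """Time-dependent ROC at a fixed horizon.

    ``thresholds`` are the distinct score values (ascending); a subject is
    called high-risk at threshold ``c`` when its score is strictly greater
    than ``c`` (matching the strict group-assignment rule).  ``sensitivity``
    and ``specificity`` are the (IPCW-weighted) true- and true-negative
    rates at each threshold; ``auc`` integrates the curve by trapezoid.
    """

    horizon: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff: float


def _censoring_survival(time: np.ndarray, event: np.ndarray) -> KMCurve:
    """KM estimate of the censoring distribution G (event roles flipped)."""
    return km_estimate(time, 1 - event)


def timedep_roc(profile: RiskProfile | np.ndarray, clinical: pd.DataFrame,
                horizon: float = 1.0, ipcw: bool = True) -> ROCCurve:
    """Cumulative-case / dynamic-control ROC at ``horizon``.

    Cases are subjects with an observed event at or before the horizon;
    controls are subjects still under observation past the horizon.
    Subjects censored before the horizon carry no direct label and enter
    only through the IPCW correction: cases are weighted by
    ``1/G(T⁻)`` and controls by ``1/G(horizon)``, with ``G`` the
    Kaplan–Meier estimate of the censoring survival function.  With no
    censoring all weights are 1 and the curve reduces to the empirical ROC.
    ``ipcw=False`` gives that unweighted variant regardless of censoring
    (censored-before-horizon subjects are simply dropped), for sensitivity
    analysis.
    """
    scores = profile.scores if isinstance(profile, RiskProfile) else \
        np.asarray(profile, dtype=float)
    if isinstance(profile, RiskProfile) and \
            list(clinical.index) != list(profile.sample_ids):
        raise ValueError("clinical table is not aligned with the risk profile")
    time = clinical["time"].to_numpy(dtype=float)
    event = clinical["event"].to_numpy(dtype=int)
    if scores.shape != time.shape:
        raise ValueError("scores and clinical table differ in length")
    if horizon <= 0:
        raise ValueError("horizon must be positive")

    is_case = (event == 1) & (time <= horizon)
    is_control = time > horizon
    if not is_case.any():
        raise ValueError(f"no events observed by the {horizon}-year horizon")
    if not is_control.any():
        raise ValueError(f"no subjects under observation past the {horizon}-year horizon")

    w = np.zeros_like(scores)
    if ipcw:
        g = _censoring_survival(time, event)
        g_tminus = np.array([g.survival_at(np.nextafter(t, -np.inf)) for t in time])
        g_h = g.survival_at(horizon)
        if g_h <= 0 or (g_tminus[is_case] <= 0).any():
            raise ValueError("censoring survival reaches 0 before the horizon; "
                             "IPCW weights are undefined")
        w[is_case] = 1.0 / g_tminus[is_case]
        w[is_control] = 1.0 / g_h
    else:
        w[is_case] = 1.0
        w[is_control] = 1.0

    thresholds = np.unique(scores)
    w_case = w * is_case
    w_ctrl = w * is_control
    total_case = w_case.sum()
    total_ctrl = w_ctrl.sum()
    # weighted counts of cases/controls with score > c, via suffix sums over
    # the sorted unique scores
    order = np.argsort(scores, kind="stable")
    s_sorted = scores[order]
    idx_gt = np.searchsorted(s_sorted, thresholds, side="right")
    case_cum = np.concatenate([[0.0], np.cumsum(w_case[order])])
    ctrl_cum = np.concatenate([[0.0], np.cumsum(w_ctrl[order])])
    sens = (total_case - case_cum[idx_gt]) / total_case
    spec = ctrl_cum[idx_gt] / total_ctrl

    fpr = np.concatenate([[1.0], 1.0 - spec, [0.0]])
    tpr = np.concatenate([[1.0], sens, [0.0]])
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))

    youden = sens + spec - 1.0
    best = int(np.argmax(youden))  # argmax takes the first (lowest) threshold on ties
    return ROCCurve(horizon, thresholds, sens, spec, auc,
                    float(thresholds[best]))


def optimal_cutoff(roc: ROCCurve) -> float:
    """Threshold maximizing Youden's index (sens + spec − 1), lowest on ties."""
    return roc.optimal_cutoff


def assign_groups(profile: RiskProfile, cutoff: float) -> RiskProfile:
    """Dichotomize: score strictly greater than the cutoff → high risk."""
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    group = np.where(profile.scores > cutoff, "high", "low")
    return RiskProfile(list(profile.sample_ids), profile.scores.copy(),
                       group, float(cutoff))


def compare_survival(profile: RiskProfile, clinical: pd.DataFrame
                     ) -> tuple[KMCurve, KMCurve, float]:
    """KM curves for the high and low groups plus the log-rank p-value."""
    if profile.group is None:
        raise ValueError("risk profile has no group labels; call assign_groups first")
    if list(clinical.index) != list(profile.sample_ids):
        raise ValueError("clinical table is not aligned with the risk profile")
    hi = profile.group == "high"
    if not hi.any() or hi.all():
        raise ValueError("both risk groups must be non-empty")
    time = clinical["time"].to_numpy(dtype=float)
    event = clinical["event"].to_numpy(dtype=int)
    km_hi = km_estimate(time[hi], event[hi])
    km_lo = km_estimate(time[~hi], event[~hi])
    _, p = logrank_test(time[~hi], event[~hi], time[hi], event[hi])
    return km_hi, km_lo, p


_GRADE_ORDINALS = {"Grade 1": 1, "Grade 2": 2, "Grade 3": 3, "Grade 4": 4,
                   "G1": 1, "G2": 2, "G3": 3, "G4": 4}
_STAGE_ORDINALS = {"Stage I": 1, "Stage II": 2, "Stage III": 3, "Stage IV": 4,
                   "I": 1, "II": 2, "III": 3, "IV": 4}


def encode_covariates(clinical: pd.DataFrame,
                      covariates: list[str]) -> pd.DataFrame:
    """Numeric encoding of clinical covariates for Cox regression.

    Age stays numeric (years); grade and stage become ordinal integers 1–4;
    gender becomes 0 (female) / 1 (male).  Unrecognized category labels
    raise rather than silently coerce.
    """
    out = {}
    for cov in covariates:
        if cov not in clinical.columns:
            raise KeyError(f"covariate {cov!r} not in clinical table")
        col = clinical[cov]
        if cov == "gender":
            mapping = {"Female": 0, "Male": 1, "female": 0, "male": 1, 0: 0, 1: 1}
            out[cov] = col.map(lambda v: _lookup(mapping, v, cov))
        elif cov == "grade":
            out[cov] = col.map(lambda v: _lookup(_GRADE_ORDINALS, v, cov))
        elif cov == "stage":
            out[cov] = col.map(lambda v: _lookup(_STAGE_ORDINALS, v, cov))
        else:
            out[cov] = pd.to_numeric(col)
    return pd.DataFrame(out, index=clinical.index).astype(float)


def _lookup(mapping, value, cov):
    if isinstance(value, (int, float, np.integer, np.floating)) and \
            not isinstance(value, bool) and cov in ("grade", "stage"):
        return float(value)
    if value not in mapping:
        raise ValueError(f"unrecognized {cov} category {value!r}")
    return mapping[value]


def cox_fit(covariates: pd.DataFrame, clinical: pd.DataFrame,
            mode: str = "univariate") -> pd.DataFrame:
    """Cox proportional-hazards fit(s) with Efron tie handling.

    ``mode="univariate"`` fits each covariate column alone;
    ``mode="multivariate"`` fits them jointly.  Returns one row per
    covariate with ``coef``, ``hazard_ratio``, Wald 95% CI bounds
    (``exp(coef ± 1.96·SE)``) and the Wald p-value.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    if list(covariates.index) != list(clinical.index):
        raise ValueError("covariates are not aligned with the clinical table")
    if clinical["event"].sum() == 0:
        raise ValueError("no events; a Cox model cannot be fit")
    blocks = [[c] for c in covariates.columns] if mode == "univariate" \
        else [list(covariates.columns)]
    rows = []
    for cols in blocks:
        df = covariates[cols].copy()
        df["time"] = clinical["time"].to_numpy(dtype=float)
        df["event"] = clinical["event"].to_numpy(dtype=int)
        fitter = CoxPHFitter()
        try:
            fitter.fit(df, duration_col="time", event_col="event")
        except Exception as exc:  # convergence / separation problems
            raise RuntimeError(
                f"Cox fit failed for covariates {cols}: {exc}") from exc
        for cov in cols:
            coef = float(fitter.params_[cov])
            se = float(fitter.standard_errors_[cov])
            rows.append({
                "covariate": cov,
                "coef": coef,
                "hazard_ratio": float(np.exp(coef)),
                "ci95_low": float(np.exp(coef - 1.96 * se)),
                "ci95_high": float(np.exp(coef + 1.96 * se)),
                "p_value": float(2 * stats.norm.sf(abs(coef / se))),
                "mode": mode,
            })
    return pd.DataFrame(rows).set_index("covariate")


def _pct_half_up(count: int, total: int) -> float:
    """Percentage rounded half-up to one decimal (table formatting rule)."""
    frac = decimal.Decimal(count) / decimal.Decimal(total) * 100
    return float(frac.quantize(decimal.Decimal("0.1"),
                               rounding=decimal.ROUND_HALF_UP))


def summarize_cohort(clinical: pd.DataFrame,
                     variables: list[str]) -> dict[str, pd.DataFrame]:
    """Per-variable category counts and percentages of non-missing samples.

    Category order follows first appearance; percentages are rounded
    half-up to one decimal, so each variable's column sums to 100 up to
    rounding.
    """
    out: dict[str, pd.DataFrame] = {}
    for var in variables:
        if var not in clinical.columns:
            raise KeyError(f"variable {var!r} not in clinical table")
        col = clinical[var].dropna()
        cats = list(dict.fromkeys(col))
        total = len(col)
        counts = [int((col == c).sum()) for c in cats]
        out[var] = pd.DataFrame({
            "count": counts,
            "percent": [_pct_half_up(n, total) for n in counts],
        }, index=pd.Index(cats, name=var))
    return out


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def compare_feature_by_group(features: pd.DataFrame,
                             profile: RiskProfile) -> pd.DataFrame:
    """Two-sided Mann–Whitney comparison of each feature between risk groups.

    ``features`` is samples × features (e.g. per-sample immune-cell
    fractions).  Direction is taken from the median difference; features
    constant across all samples get p = 1 and direction ``n.s.``.
    """
    if profile.group is None:
        raise ValueError("risk profile has no group labels; call assign_groups first")
    if list(features.index) != list(profile.sample_ids):
        raise ValueError("features are not aligned with the risk profile")
    hi = profile.group == "high"
    if not hi.any() or hi.all():
        raise ValueError("both risk groups must be non-empty")
    rows = []
    for col in features.columns:
        x_hi = features.loc[hi, col].to_numpy(dtype=float)
        x_lo = features.loc[~hi, col].to_numpy(dtype=float)
        if np.ptp(features[col].to_numpy(dtype=float)) == 0:
            stat, p = np.nan, 1.0
        else:
            stat, p = stats.mannwhitneyu(x_hi, x_lo, alternative="two-sided")
        if p >= 0.05:
            direction = "n.s."
        else:
            diff = np.median(x_hi) - np.median(x_lo)
            direction = "higher in high-risk" if diff > 0 else \
                "lower in high-risk" if diff < 0 else "n.s."
        rows.append({"feature": col, "statistic": stat, "p_value": p,
                     "direction": direction, "stars": _stars(p)})
    return pd.DataFrame(rows).set_index("feature")
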