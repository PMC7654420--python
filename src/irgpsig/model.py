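"""Lasso-penalized Cox fitting, stability selection, and risk scoring.

The signature is the modal (most frequent) non-zero coefficient set over
many repetitions of cross-validated lasso Cox regression with reshuffled
folds: each repetition fits an L1 path, picks a penalty by cross-validated
partial-likelihood deviance, and records which pairs are non-zero there;
the support that recurs most often is "the most stable model".  Final
coefficients are the penalized estimates at the (largest) penalty whose
full-data support equals that modal set.

The path and per-fold fits use glmnet-style coordinate descent
(``sksurv.linear_model.CoxnetSurvivalAnalysis``), with the Breslow
approximation for tied event times, matching the reference tooling for this
class of model.  Binary 0/1 pair indicators are deliberately **not**
standardized before penalization: standardizing would inflate coefficients
of unbalanced pairs and distort the sparsity pattern.

Risk scores are the signed sum of signature coefficients over the pair
indicators of a sample, computed directly from raw expression; no
normalization of the expression matrix is required (or performed).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis

from .pairs import IndicatorMatrix, Pair, compute_indicators

__all__ = ["LassoCoxConfig", "LassoCoxPath", "Signature", "RiskProfile",
           "breslow_loglik", "fit_lasso_cox", "stability_select", "risk_score"]


@dataclass(frozen=True)
class LassoCoxConfig:
    """Configuration of the penalized fit and its stability loop.

    ``repeats`` is the number of cross-validation repetitions with distinct
    fold assignments (the "iteration" count of the stability loop);
    ``lambda_rule`` picks the penalty per repetition: ``"min"`` for the
    deviance minimizer, ``"1se"`` for the sparsest model within one
    standard error of it.
    """

    n_lambda: int = 100
    cv_folds: int = 10
    repeats: int = 1000
    seed: int = 0
    lambda_rule: str = "min"
    # path floor: binary indicator features with many correlated candidates
    # make the dense small-penalty tail ill-conditioned and never optimal
    # under CV, so the path stops at 10% of the maximal penalty
    alpha_min_ratio: float = 0.1

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")
        if self.lambda_rule not in ("min", "1se"):
            raise ValueError("lambda_rule must be 'min' or '1se'")


@dataclass
class LassoCoxPath:
    """One cross-validated lasso-Cox fit along a decreasing penalty path."""

    alphas: np.ndarray          # decreasing penalty values
    coefs: np.ndarray           # (n_features, n_alphas) full-data coefficients
    cv_deviance: np.ndarray     # mean CV partial-likelihood deviance per alpha
    cv_se: np.ndarray           # standard error of the fold deviances
    best_index: int             # index of the chosen alpha
    feature_names: list[str]

    @property
    def best_alpha(self) -> float:
        return float(self.alphas[self.best_index])

    @property
    def best_coef(self) -> np.ndarray:
        return self.coefs[:, self.best_index]

    @property
    def support(self) -> frozenset[str]:
        return frozenset(n for n, c in zip(self.feature_names, self.best_coef)
                         if c != 0.0)


@dataclass
class Signature:
    """An ordered list of gene pairs with their Cox coefficients."""

    entries: list[tuple[str, str, float]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = [(a, b) for a, b, _ in self.entries]
        if len(set(pairs)) != len(pairs):
            raise ValueError("signature contains duplicate pairs")
        if any(c == 0.0 for _, _, c in self.entries):
            raise ValueError("signature coefficients must be non-zero")

    @property
    def pairs(self) -> list[Pair]:
        return [(a, b) for a, b, _ in self.entries]

    @property
    def coefficients(self) -> np.ndarray:
        return np.array([c for _, _, c in self.entries])

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for a, b, _ in self.entries:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["gene_a", "gene_b", "coefficient"])

    def write(self, path: str | Path) -> None:
        """Write the signature TSV plus a JSON provenance sidecar."""
        path = Path(path)
        # %.17g keeps the round-trip bit-exact for float64 coefficients
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True, default=str))

    @classmethod
    def read(cls, path: str | Path) -> "Signature":
        path = Path(path)
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
        sidecar = path.with_suffix(path.suffix + ".json")
        prov = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        entries = [(str(r.gene_a), str(r.gene_b), float(r.coefficient))
                   for r in df.itertuples()]
        return cls(entries, prov)


@dataclass
class RiskProfile:
    """Per-sample risk scores, optionally dichotomized at a cutoff."""

    sample_ids: list[str]
    scores: np.ndarray
    group: np.ndarray | None = None   # "high"/"low" labels
    cutoff: float | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if not np.isfinite(self.scores).all():
            raise ValueError("risk scores must be finite")
        if (self.group is None) != (self.cutoff is None):
            raise ValueError("group labels and cutoff must be set together")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids, "score": self.scores})
        if self.group is not None:
            df["group"] = self.group
        return df


def _breslow_loglik_multi(betas: np.ndarray, x: np.ndarray, time: np.ndarray,
                          event: np.ndarray) -> np.ndarray:
    """Breslow partial log-likelihood for each column of ``betas``."""
    eta = x @ betas                              # (n, L)
    order = np.argsort(-time, kind="stable")     # decreasing time
    eta_o = eta[order]
    t_o = time[order]
    d_o = event[order].astype(bool)
    m = eta_o.max(axis=0, keepdims=True)
    log_risk = m + np.log(np.cumsum(np.exp(eta_o - m), axis=0))
    # subjects tied on time must share the same (full) risk-set sum
    idx = np.searchsorted(-t_o, -t_o, side="right") - 1
    log_risk = log_risk[idx]
    return np.sum(eta_o[d_o] - log_risk[d_o], axis=0)


def breslow_loglik(beta: np.ndarray, x: np.ndarray, time: np.ndarray,
                   event: np.ndarray) -> float:
    """Cox partial log-likelihood with the Breslow tie approximation."""
    beta = np.asarray(beta, dtype=float)
    return float(_breslow_loglik_multi(beta[:, None], x, time, event)[0])


def _event_stratified_folds(event: np.ndarray, n_folds: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Fold labels balancing events across folds (round-robin after shuffle)."""
    fold = np.empty(event.size, dtype=int)
    for flag in (0, 1):
        idx = np.flatnonzero(event == flag)
        rng.shuffle(idx)
        fold[idx] = np.arange(idx.size) % n_folds
    return fold


def _prepare_xy(x: IndicatorMatrix | pd.DataFrame | np.ndarray,
                clinical: pd.DataFrame,
                feature_names: Sequence[str] | None = None):
    if isinstance(x, IndicatorMatrix):
        names = x.pair_ids
        mat = x.values.T.astype(float)          # samples × features
        if list(clinical.index) != list(x.sample_ids):
            raise ValueError("clinical table is not aligned with the features")
    elif isinstance(x, pd.DataFrame):
        names = [str(c) for c in x.columns]
        mat = x.to_numpy(dtype=float)
    else:
        mat = np.asarray(x, dtype=float)
        names = list(feature_names) if feature_names is not None else \
            [f"f{i}" for i in range(mat.shape[1])]
    time = clinical["time"].to_numpy(dtype=float)
    event = clinical["event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("no events in the cohort; a Cox model cannot be fit")
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 candidate features")
    keep = mat.std(axis=0) > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(f"dropping {len(dropped)} all-constant feature(s): "
                      f"{dropped[:5]}", stacklevel=3)
        mat = mat[:, keep]
        names = [n for n, k in zip(names, keep) if k]
    return mat, names, time, event


def _coxnet(alphas=None, n_alphas=100, alpha_min_ratio=0.01) -> CoxnetSurvivalAnalysis:
    return CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alphas=alphas,
        alpha_min_ratio=alpha_min_ratio, normalize=False, tol=1e-7)


def _surv_y(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    from sksurv.util import Surv
    return Surv.from_arrays(event=event.astype(bool), time=time)


def _cv_deviance(mat, time, event, alphas, fold: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated partial-likelihood deviance per penalty.

    Uses the Verweij–van Houwelingen construction: each held-out fold
    contributes ``-2 [ loglik(all; β_{-k}) − loglik(train_{-k}; β_{-k}) ]``,
    which is well defined even for tiny folds.
    """
    n_folds = fold.max() + 1
    contrib = np.zeros((n_folds, alphas.size))
    for k in range(n_folds):
        tr = fold != k
        est = _coxnet(alphas=alphas)
        with warnings.catch_warnings():
            # large-penalty path points legitimately have all-zero solutions
            warnings.simplefilter("ignore", UserWarning)
            est.fit(mat[tr], _surv_y(time[tr], event[tr]))
        fitted = np.asarray(est.alphas_)
        # coxnet may drop path points that fail to converge; map them back
        coef = np.asarray(est.coef_)
        if fitted.size != alphas.size or not np.allclose(fitted, alphas):
            nearest = np.array([int(np.argmin(np.abs(fitted - a))) for a in alphas])
            coef = coef[:, nearest]
        ll_all = _breslow_loglik_multi(coef, mat, time, event)
        ll_tr = _breslow_loglik_multi(coef, mat[tr], time[tr], event[tr])
        contrib[k] = -2.0 * (ll_all - ll_tr)
    total = contrib.sum(axis=0)  # total held-out deviance, glmnet-like scale
    se = contrib.std(axis=0, ddof=1) * np.sqrt(n_folds)
    return total, se


def fit_lasso_cox(x, clinical: pd.DataFrame,
                  cfg: LassoCoxConfig = LassoCoxConfig(),
                  rng: np.random.Generator | None = None) -> LassoCoxPath:
    """One cross-validated L1 Cox fit along a decreasing penalty path.

    ``x`` may be an :class:`~irgpsig.pairs.IndicatorMatrix` (features are
    pair ids), a samples × features DataFrame, or a plain array.  Returns
    the full-data path, the CV deviance curve, and the index of the penalty
    chosen under ``cfg.lambda_rule``.  Deterministic given ``cfg.seed``.
    """
    mat, names, time, event = _prepare_xy(x, clinical)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    full = _coxnet(n_alphas=cfg.n_lambda, alpha_min_ratio=cfg.alpha_min_ratio)
    full.fit(mat, _surv_y(time, event))
    alphas = np.asarray(full.alphas_)
    cv_mean, cv_se, best = _cv_choose(mat, time, event, alphas, cfg, rng)
    return LassoCoxPath(alphas, np.asarray(full.coef_), cv_mean, cv_se,
                        best, list(names))


def _cv_choose(mat, time, event, alphas, cfg: LassoCoxConfig,
               rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, int]:
    fold = _event_stratified_folds(event, cfg.cv_folds, rng)
    cv_mean, cv_se = _cv_deviance(mat, time, event, alphas, fold)
    best = int(np.argmin(cv_mean))
    if cfg.lambda_rule == "1se":
        bound = cv_mean[best] + cv_se[best]
        best = int(np.flatnonzero(cv_mean <= bound)[0])  # largest qualifying penalty
    return cv_mean, cv_se, best


def stability_select(x, clinical: pd.DataFrame,
                     cfg: LassoCoxConfig = LassoCoxConfig()) -> Signature:
    """Select the modal non-zero support over repeated cross-validation.

    Runs ``cfg.repeats`` cross-validated fits with reshuffled folds, records
    the non-zero coefficient set at each repetition's chosen penalty, and
    takes the most frequent set as the signature support (ties broken toward
    the smaller, then lexicographically earlier, set).  Coefficients come
    from the full-data path at the largest penalty whose support equals the
    modal set; if no path point matches exactly, a lasso path restricted to
    the modal pairs supplies them at the largest penalty keeping all of them
    active.
    """
    mat, names, time, event = _prepare_xy(x, clinical)
    rng = np.random.default_rng(cfg.seed)
    full = _coxnet(n_alphas=cfg.n_lambda, alpha_min_ratio=cfg.alpha_min_ratio)
    full.fit(mat, _surv_y(time, event))
    alphas = np.asarray(full.alphas_)
    coef = np.asarray(full.coef_)
    supports = [frozenset(n for n, c in zip(names, coef[:, j]) if c != 0.0)
                for j in range(alphas.size)]
    counts: dict[frozenset[str], int] = {}
    for _ in range(cfg.repeats):
        _, _, best = _cv_choose(mat, time, event, alphas, cfg, rng)
        counts[supports[best]] = counts.get(supports[best], 0) + 1

    def _rank(item):
        support, count = item
        return (-count, len(support), tuple(sorted(support)))

    modal, modal_count = min(counts.items(), key=_rank)
    if not modal:
        raise ValueError(
            "the modal cross-validated support is empty; the candidates carry "
            "no reproducible signal at this penalty rule — consider "
            "lambda_rule='min' or a larger alpha path")

    chosen: np.ndarray | None = None
    chosen_alpha: float | None = None
    for j, a in enumerate(alphas):  # decreasing: largest penalty first
        if supports[j] == modal:
            chosen = coef[:, j]
            chosen_alpha = float(a)
            break
    if chosen is None:
        idx = [i for i, n in enumerate(names) if n in modal]
        sub = _coxnet(n_alphas=cfg.n_lambda, alpha_min_ratio=cfg.alpha_min_ratio)
        sub.fit(mat[:, idx], _surv_y(time, event))
        sub_coef = np.asarray(sub.coef_)
        j_all = np.flatnonzero((sub_coef != 0.0).all(axis=0))
        j = int(j_all[0]) if j_all.size else sub_coef.shape[1] - 1
        chosen = np.zeros(len(names))
        chosen[idx] = sub_coef[:, j]
        chosen_alpha = float(np.asarray(sub.alphas_)[j])

    entries = [(*_split_pair(n), float(c))
               for n, c in zip(names, chosen) if c != 0.0]
    provenance = {
        "lambda": chosen_alpha,
        "seed": cfg.seed,
        "repeats": cfg.repeats,
        "cv_folds": cfg.cv_folds,
        "lambda_rule": cfg.lambda_rule,
        "modal_support_frequency": modal_count / cfg.repeats,
    }
    return Signature(entries, provenance)


def _split_pair(name: str) -> tuple[str, str]:
    if "|" in name:
        a, b = name.split("|", 1)
        return a, b
    return name, ""


def risk_score(sig: Signature, m: pd.DataFrame) -> RiskProfile:
    """Score each sample: Σ coefficient × indicator over the signature pairs.

    Indicators are computed on the fly from raw expression with the strict
    ``expr[a] > expr[b]`` rule; the score is invariant to any strictly
    increasing per-sample transform of ``m``, so no normalization is needed
    (or wanted) when scoring a cohort from a different platform.
    """
    missing = [g for g in sig.genes if g not in m.index]
    if missing:
        raise KeyError(f"signature gene {missing[0]!r} absent from expression matrix")
    im = compute_indicators(m, sig.pairs)
    scores = sig.coefficients @ im.values.astype(float)
    return RiskProfile([str(c) for c in m.columns], scores)
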