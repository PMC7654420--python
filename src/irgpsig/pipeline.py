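"""End-to-end orchestration: build a signature, validate it on a new cohort.

``run_build`` executes the full training workflow — pair enumeration,
indicator scoring, constancy filtering, log-rank screening, stability-
selected lasso Cox, risk scoring, 1-year ROC cutoff, group assignment and
group survival comparison — logging the pair counts at every checkpoint so
a run can be audited stage by stage.  ``run_validate`` applies a frozen
signature and cutoff to an independent cohort with no refitting and no
renormalization; thanks to the rank invariance of the pair indicators the
validation cohort may come from a different platform.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as irio
from .evaluate import (ROCCurve, assign_groups, compare_survival, cox_fit,
                       encode_covariates, timedep_roc)
from .model import (LassoCoxConfig, RiskProfile, Signature, risk_score,
                    stability_select)
from .pairs import FilterConfig, IndicatorMatrix, build_filtered_indicators, \
    enumerate_pairs
from .screen import KMCurve, ScreenConfig, ScreenResult, screen_pairs

logger = logging.getLogger("irgpsig")

__all__ = ["PipelineConfig", "BuildResult", "ValidationReport",
           "run_build", "run_validate"]


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of the per-stage configurations plus the evaluation horizon."""

    filter: FilterConfig = field(default_factory=FilterConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    lasso: LassoCoxConfig = field(default_factory=LassoCoxConfig)
    horizon: float = 1.0
    cox_covariates: tuple[str, ...] = ()
    seed: int = 0

    def manifest(self) -> dict:
        d = {
            "constancy_threshold": self.filter.constancy_threshold,
            "alpha": self.screen.alpha,
            "min_group_size": self.screen.min_group_size,
            "n_lambda": self.lasso.n_lambda,
            "cv_folds": self.lasso.cv_folds,
            "repeats": self.lasso.repeats,
            "lambda_rule": self.lasso.lambda_rule,
            "horizon": self.horizon,
            "cox_covariates": list(self.cox_covariates),
            "seed": self.seed,
        }
        d["config_hash"] = hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]
        return d


@dataclass
class BuildResult:
    """Everything the training run produced, plus stage-count checkpoints."""

    signature: Signature
    roc: ROCCurve
    cutoff: float
    profile: RiskProfile
    km_high: KMCurve
    km_low: KMCurve
    logrank_p: float
    screen_result: ScreenResult
    cox_tables: dict[str, pd.DataFrame]
    counts: dict[str, int]
    manifest: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.signature.write(out / "signature.tsv")
        self.profile.to_frame().to_csv(out / "risk_profile.tsv", sep="\t", index=False)
        self.screen_result.write_tsv(out / "screen.tsv")
        for name, tbl in self.cox_tables.items():
            tbl.to_csv(out / f"cox_{name}.tsv", sep="\t")
        for name, km in (("high", self.km_high), ("low", self.km_low)):
            pd.DataFrame({"time": km.times, "survival": km.survival,
                          "at_risk": km.at_risk}).to_csv(
                out / f"km_{name}.tsv", sep="\t", index=False)
        report = dict(self.manifest)
        report.update(self.counts)
        report.update({
            "auc": self.roc.auc, "cutoff": self.cutoff,
            "logrank_p": self.logrank_p,
            "n_high": int((self.profile.group == "high").sum()),
            "n_low": int((self.profile.group == "low").sum()),
        })
        (out / "report.json").write_text(json.dumps(report, indent=2))


@dataclass
class ValidationReport:
    """Frozen-signature evaluation of an independent cohort."""

    profile: RiskProfile
    km_high: KMCurve
    km_low: KMCurve
    logrank_p: float

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.profile.to_frame().to_csv(out / "validation_profile.tsv",
                                       sep="\t", index=False)
        (out / "validation_report.json").write_text(json.dumps({
            "logrank_p": self.logrank_p,
            "cutoff": self.profile.cutoff,
            "n_high": int((self.profile.group == "high").sum()),
            "n_low": int((self.profile.group == "low").sum()),
        }, indent=2))


def run_build(expression: pd.DataFrame, clinical: pd.DataFrame,
              gene_list: list[str] | None = None,
              cfg: PipelineConfig = PipelineConfig()) -> BuildResult:
    """Train a pair signature on one cohort and stratify it.

    ``expression`` and ``clinical`` follow the package conventions (genes ×
    samples; time in years).  When ``gene_list`` is given the matrix is
    first restricted to it.  Fully reproducible from (inputs, cfg): the only
    randomness is the fold reshuffling in the stability loop, driven by
    ``cfg.lasso.seed``.
    """
    if gene_list is not None:
        expression = irio.restrict_to_gene_list(expression, gene_list)
    expression, clinical = irio.align_cohort(expression, clinical)
    counts: dict[str, int] = {"n_samples": expression.shape[1],
                              "n_genes": expression.shape[0]}
    pairs = enumerate_pairs(list(expression.index))
    counts["n_pairs_enumerated"] = len(pairs)
    logger.info("enumerated %d pairs from %d genes", len(pairs), expression.shape[0])

    im = build_filtered_indicators(expression, pairs, cfg.filter)
    counts["n_pairs_after_filter"] = len(im.pairs)
    logger.info("constancy filter kept %d pairs", len(im.pairs))

    screened = screen_pairs(im, clinical, cfg.screen)
    sel = screened.selected
    counts["n_pairs_screened"] = int(sel.sum())
    logger.info("log-rank screen selected %d pairs at alpha=%g",
                counts["n_pairs_screened"], cfg.screen.alpha)
    if counts["n_pairs_screened"] < 2:
        raise RuntimeError(
            f"screening stage left {counts['n_pairs_screened']} pair(s); "
            "at least 2 are needed to fit a penalized model")
    im_sel = IndicatorMatrix([p for p, s in zip(im.pairs, sel) if s],
                             im.sample_ids, im.values[sel])

    signature = stability_select(im_sel, clinical, cfg.lasso)
    counts["n_pairs_signature"] = len(signature)
    logger.info("stability selection kept a %d-pair signature "
                "(modal support frequency %.2f)", len(signature),
                signature.provenance.get("modal_support_frequency", float("nan")))

    profile = risk_score(signature, expression)
    roc = timedep_roc(profile, clinical, cfg.horizon)
    cutoff = roc.optimal_cutoff
    profile = assign_groups(profile, cutoff)
    km_hi, km_lo, p = compare_survival(profile, clinical)
    logger.info("1-year AUC %.3f, cutoff %.3f, log-rank p %.3g",
                roc.auc, cutoff, p)

    cox_tables: dict[str, pd.DataFrame] = {}
    covs = pd.DataFrame({"risk_score": profile.scores}, index=clinical.index)
    if cfg.cox_covariates:
        covs = pd.concat(
            [covs, encode_covariates(clinical, list(cfg.cox_covariates))], axis=1)
    cox_tables["univariate"] = cox_fit(covs, clinical, "univariate")
    if covs.shape[1] > 1:
        cox_tables["multivariate"] = cox_fit(covs, clinical, "multivariate")

    return BuildResult(signature, roc, cutoff, profile, km_hi, km_lo, p,
                       screened, cox_tables, counts, cfg.manifest())


def run_validate(expression: pd.DataFrame, clinical: pd.DataFrame,
                 signature: Signature, cutoff: float) -> ValidationReport:
    """Score an independent cohort with a frozen signature and cutoff.

    No refitting and no renormalization happen here; indicators are
    recomputed from the validation expression alone, so a platform change
    that preserves within-sample orderings leaves the scores untouched.
    Raises when a risk group comes out empty rather than emitting a
    degenerate report.
    """
    expression, clinical = irio.align_cohort(expression, clinical)
    profile = assign_groups(risk_score(signature, expression), cutoff)
    n_high = int((profile.group == "high").sum())
    if n_high == 0 or n_high == len(profile.sample_ids):
        raise RuntimeError(
            f"cutoff {cutoff} puts {n_high} of {len(profile.sample_ids)} "
            "validation samples in the high-risk group; survival comparison "
            "is undefined")
    km_hi, km_lo, p = compare_survival(profile, clinical)
    logger.info("validation log-rank p %.3g (%d high / %d low)", p, n_high,
                len(profile.sample_ids) - n_high)
    return ValidationReport(profile, km_hi, km_lo, p)
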