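"""One-sample MR on individual-level data: genetic risk scores, instrument
strength, observational regression, and per-SNP Wald ratios combined by IVW.

The cohort design mirrors a biobank analysis of current daily smokers who
drink coffee: effect-allele dosages at a handful of SNPs, coffee consumption
(cups/day) as the exposure, cigarettes/day as the outcome, and covariates
(age, sex, principal components) for adjustment.  Per-SNP gene-exposure and
gene-outcome effects are estimated in-cohort with heteroscedasticity-robust
(HC3) standard errors; the genetic risk score instead uses externally
supplied weights, matching the two distinct uses of the instrument.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import ValidationError
from .mr import MRResult, WaldEstimate, ivw_fixed_effects, wald_ratio, weighted_median

logger = logging.getLogger(__name__)


@dataclass
class Cohort:
    """Individual-level genotype/exposure/outcome data.

    genotypes: (n_individuals, n_snps) effect-allele dosages in {0, 1, 2};
    snp_meta: per-SNP DataFrame with columns snp_id, effect_allele, weight
    (external exposure weight, cups/day per allele); true_params records the
    generating parameters for synthetic cohorts.
    """

    genotypes: np.ndarray
    exposure: np.ndarray
    outcome: np.ndarray
    snp_meta: pd.DataFrame
    covariates: pd.DataFrame | None = None
    true_params: dict | None = None
    imputed: bool = False   # permit fractional dosages from mean imputation

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.exposure = np.asarray(self.exposure, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=float)
        n, m = self.genotypes.shape
        if len(self.exposure) != n or len(self.outcome) != n:
            raise ValidationError("exposure/outcome length does not match genotype rows")
        if len(self.snp_meta) != m:
            raise ValidationError("snp_meta rows do not match genotype columns")
        if self.imputed:
            if np.isnan(self.genotypes).any() or (self.genotypes < 0).any() \
                    or (self.genotypes > 2).any():
                raise ValidationError("imputed dosages must be finite and within [0, 2]")
        elif not np.isin(self.genotypes, (0.0, 1.0, 2.0)).all():
            raise ValidationError("genotype dosages must be 0, 1 or 2")
        if not (np.isfinite(self.exposure).all() and np.isfinite(self.outcome).all()):
            raise ValidationError("exposure and outcome must be finite")
        if self.covariates is not None and len(self.covariates) != n:
            raise ValidationError("covariate rows do not match genotype rows")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def snp_ids(self) -> list[str]:
        return list(self.snp_meta["snp_id"])

    def subset(self, mask: np.ndarray) -> "Cohort":
        return Cohort(
            genotypes=self.genotypes[mask],
            exposure=self.exposure[mask],
            outcome=self.outcome[mask],
            snp_meta=self.snp_meta,
            covariates=None if self.covariates is None
            else self.covariates.loc[mask].reset_index(drop=True),
            true_params=self.true_params,
            imputed=self.imputed,
        )


def impute_mean_dosages(genotypes: np.ndarray) -> np.ndarray:
    """Replace missing (NaN) dosages with the per-SNP mean of observed values."""
    g = np.asarray(genotypes, dtype=float).copy()
    col_mean = np.nanmean(g, axis=0)
    idx = np.where(np.isnan(g))
    g[idx] = col_mean[idx[1]]
    return g


def filter_analysis_sample(cohort: Cohort, smoker_col: str = "smoker") -> Cohort:
    """Restrict to current daily smokers reporting at least some coffee.

    Keeps rows with exposure > 0 and, when the covariate column exists, a
    truthy smoker flag.
    """
    mask = cohort.exposure > 0
    if cohort.covariates is not None and smoker_col in cohort.covariates.columns:
        mask &= cohort.covariates[smoker_col].astype(bool).to_numpy()
    return cohort.subset(mask)


@dataclass(frozen=True)
class GRSResult:
    scores: np.ndarray
    weights: np.ndarray
    f_statistic: float
    r_squared: float


def compute_grs(cohort: Cohort, weights: Mapping[str, float] | None = None) -> np.ndarray:
    """Weighted genetic risk score: scoreᵢ = Σⱼ wⱼ·dosageᵢⱼ.

    ``weights`` maps snp_id → per-allele exposure weight; defaults to the
    external weights in ``cohort.snp_meta['weight']``.
    """
    if weights is None:
        if "weight" not in cohort.snp_meta.columns:
            raise ValidationError("cohort carries no external weights and none were given")
        w = cohort.snp_meta["weight"].to_numpy(dtype=float)
        if np.isnan(w).any():
            bad = cohort.snp_meta.loc[np.isnan(w), "snp_id"].iloc[0]
            raise ValidationError(f"missing weight for SNP {bad}")
    else:
        missing = [s for s in cohort.snp_ids if s not in weights]
        if missing:
            raise ValidationError(f"missing weight for SNP {missing[0]}")
        w = np.array([weights[s] for s in cohort.snp_ids], dtype=float)
    return cohort.genotypes @ w


def genetic_risk_score(
    cohort: Cohort,
    weights: Mapping[str, float] | None = None,
    covariates: pd.DataFrame | None = None,
) -> GRSResult:
    """Score individuals and summarize instrument strength in one record."""
    scores = compute_grs(cohort, weights)
    f_stat, r2 = instrument_strength(scores, cohort.exposure, covariates)
    if weights is None:
        w = cohort.snp_meta["weight"].to_numpy(dtype=float)
    else:
        w = np.array([weights[s] for s in cohort.snp_ids], dtype=float)
    return GRSResult(scores=scores, weights=w, f_statistic=f_stat, r_squared=r2)


def _design(covariates: pd.DataFrame | None, n: int, extra: dict) -> pd.DataFrame:
    X = pd.DataFrame(extra)
    if covariates is not None and len(covariates.columns):
        cov = covariates.reset_index(drop=True).astype(float)
        X = pd.concat([X, cov], axis=1)
    return sm.add_constant(X, has_constant="add")


def instrument_strength(
    scores: np.ndarray,
    exposure: np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> tuple[float, float]:
    """F-statistic and incremental R² of the score-exposure regression.

    F is the squared t-statistic of the score term in a (covariate-adjusted)
    linear regression of exposure on score; R² is the variance in exposure
    explained by the score over and above the covariates.  F > 10 is the
    conventional weak-instrument threshold.
    """
    scores = np.asarray(scores, dtype=float)
    exposure = np.asarray(exposure, dtype=float)
    if np.ptp(scores) == 0:
        raise ValidationError("score has zero variance; instrument strength undefined")
    X_full = _design(covariates, len(scores), {"score": scores})
    if len(scores) <= X_full.shape[1] + 1:
        raise ValidationError("too few individuals for the requested regression")
    fit = sm.OLS(exposure, X_full).fit()
    t = fit.tvalues["score"]
    f_stat = float(t * t) if np.isfinite(t) else float("inf")
    if covariates is not None and len(covariates.columns):
        base = sm.OLS(exposure, _design(covariates, len(scores), {})).fit()
        r2 = float(fit.rsquared - base.rsquared)
    else:
        r2 = float(fit.rsquared)
    return f_stat, r2


def observational_association(
    cohort: Cohort,
    adjustments: Sequence[str] | None = None,
    cov_type: str = "HC3",
) -> tuple[float, float]:
    """Observational slope of outcome on exposure with robust (HC3) SE."""
    cov = None
    if adjustments:
        if cohort.covariates is None:
            raise ValidationError("cohort has no covariates to adjust for")
        cov = cohort.covariates[list(adjustments)]
    X = _design(cov, cohort.n, {"exposure": cohort.exposure})
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValidationError("degenerate design matrix in observational regression")
    fit = sm.OLS(cohort.outcome, X).fit(cov_type=cov_type)
    return float(fit.params["exposure"]), float(fit.bse["exposure"])


@dataclass
class OneSampleConfig:
    """Settings for the one-sample MR pipeline."""

    covariates: tuple[str, ...] = ()
    delta_order: str = "first"
    method: str = "IVW-FE"          # or "weighted-median"
    n_boot: int = 1000
    seed: int = 20170712
    min_beta_x: float = 1e-8        # SNPs with weaker in-cohort exposure effects are dropped
    cov_type: str = "HC3"


def _per_snp_regressions(cohort: Cohort, config: OneSampleConfig) -> list[WaldEstimate]:
    cov = None
    if config.covariates:
        if cohort.covariates is None:
            raise ValidationError("cohort has no covariates to adjust for")
        cov = cohort.covariates[list(config.covariates)]
    wald: list[WaldEstimate] = []
    for j, snp in enumerate(cohort.snp_ids):
        dosage = cohort.genotypes[:, j]
        Xg = _design(cov, cohort.n, {"dosage": dosage})
        fx = sm.OLS(cohort.exposure, Xg).fit(cov_type=config.cov_type)
        fy = sm.OLS(cohort.outcome, Xg).fit(cov_type=config.cov_type)
        bx, sx = float(fx.params["dosage"]), float(fx.bse["dosage"])
        by, sy = float(fy.params["dosage"]), float(fy.bse["dosage"])
        if abs(bx) < config.min_beta_x:
            logger.warning("%s: in-cohort exposure effect %.3g below tolerance; excluded",
                           snp, bx)
            continue
        wald.append(wald_ratio(bx, sx, by, sy, order=config.delta_order, snp_id=snp))
    if not wald:
        raise ValidationError("no SNP with a usable exposure association")
    return wald


def one_sample_mr(cohort: Cohort, config: OneSampleConfig | None = None) -> MRResult:
    """One-sample MR: per-SNP in-cohort Wald ratios combined by IVW.

    Per SNP j, β_x(j) is the covariate-adjusted regression of exposure on
    dosage and β_y(j) the same for the outcome, both with robust SEs; ratios
    are combined by fixed-effects IVW (default) or the weighted-median
    sensitivity estimator.
    """
    config = config or OneSampleConfig()
    wald = _per_snp_regressions(cohort, config)
    if config.method == "IVW-FE":
        return ivw_fixed_effects(wald)
    if config.method == "weighted-median":
        return weighted_median(wald, n_boot=config.n_boot, seed=config.seed)
    raise ValidationError(f"unknown one-sample method {config.method!r}")
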