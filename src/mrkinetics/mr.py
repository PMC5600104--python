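"""Two-sample MR estimators: per-SNP Wald ratios, IVW meta-analysis, weighted median.

Given harmonized per-SNP effects (β_x, se_x) on the exposure and (β_y, se_y)
on the outcome, each SNP's causal estimate is the Wald ratio β_y/β_x with a
delta-method standard error.  Ratios are combined either by fixed-effects
inverse-variance weighting (efficient when every SNP is a valid instrument)
or by the weighted median (consistent when at least half the weight comes
from valid instruments, hence robust to pleiotropy in a minority of SNPs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .instruments import InstrumentSet

Z_95 = 1.96  # 95% intervals are estimate ± 1.96·SE throughout


@dataclass(frozen=True)
class WaldEstimate:
    """Per-SNP causal ratio estimate with inverse-variance weight."""

    snp_id: str
    ratio: float
    se: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.se) or self.se <= 0:
            raise ValidationError(f"{self.snp_id}: Wald SE must be positive and finite")
        if not np.isfinite(self.ratio):
            raise ValidationError(f"{self.snp_id}: Wald ratio must be finite")

    @property
    def weight(self) -> float:
        return self.se ** -2


@dataclass(frozen=True)
class MRResult:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    method: str
    n_snps: int
    per_snp: tuple[WaldEstimate, ...] = ()

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate, "se": self.se,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p, "method": self.method, "n_snps": self.n_snps,
            "per_snp": [
                {"snp_id": w.snp_id, "ratio": w.ratio, "se": w.se} for w in self.per_snp
            ],
        }


def wald_ratio(
    beta_x: float,
    se_x: float,
    beta_y: float,
    se_y: float,
    order: str = "first",
    snp_id: str = "",
) -> WaldEstimate:
    """Per-SNP causal effect β_y/β_x with delta-method SE.

    ``order="first"`` gives se = |se_y/β_x| (the default; ignores exposure
    uncertainty).  ``order="second"`` adds the exposure-uncertainty term:
    se = sqrt(se_y²/β_x² + β_y²·se_x²/β_x⁴).
    """
    if beta_x == 0:
        raise ZeroDivisionError(f"{snp_id or 'SNP'}: exposure beta is zero; Wald ratio undefined")
    if se_x < 0 or se_y <= 0:
        raise ValidationError(f"{snp_id or 'SNP'}: invalid standard errors (se_x={se_x}, se_y={se_y})")
    ratio = beta_y / beta_x
    if order == "first":
        se = abs(se_y / beta_x)
    elif order == "second":
        se = math.sqrt(se_y**2 / beta_x**2 + beta_y**2 * se_x**2 / beta_x**4)
    else:
        raise ValidationError(f"order must be 'first' or 'second', got {order!r}")
    return WaldEstimate(snp_id=snp_id, ratio=ratio, se=se)


def _result(estimate: float, se: float, method: str,
            per_snp: Sequence[WaldEstimate]) -> MRResult:
    z = estimate / se if se > 0 else math.inf
    p = 2 * stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0
    return MRResult(
        estimate=estimate, se=se,
        ci_low=estimate - Z_95 * se, ci_high=estimate + Z_95 * se,
        p=float(p), method=method, n_snps=len(per_snp), per_snp=tuple(per_snp),
    )


def ivw_fixed_effects(estimates: Sequence[WaldEstimate]) -> MRResult:
    """Fixed-effects inverse-variance-weighted combination of Wald ratios.

    estimate = Σ wⱼ·ratioⱼ / Σ wⱼ with wⱼ = seⱼ⁻²; se = (Σ wⱼ)^(−1/2).
    """
    if not estimates:
        raise ValidationError("ivw_fixed_effects requires at least one estimate")
    w = np.array([e.weight for e in estimates], dtype=float)
    r = np.array([e.ratio for e in estimates], dtype=float)
    if not np.all(np.isfinite(w)) or np.any(w <= 0):
        bad = estimates[int(np.argmin(np.isfinite(w) & (w > 0)))].snp_id
        raise ValidationError(f"non-finite or non-positive weight (SNP {bad})")
    est = float(np.sum(w * r) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return _result(est, se, "IVW-FE", estimates)


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median of ratio estimates by cumulative mid-weight interpolation.

    Sort ratios ascending; with normalized cumulative mid-weights
    pⱼ = (Σ_{i≤j} wᵢ − wⱼ/2)/Σ wᵢ, linearly interpolate (pⱼ, ratioⱼ) at p=0.5.
    """
    order = np.argsort(ratios)
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    p = (np.cumsum(w) - w / 2) / np.sum(w)
    if 0.5 <= p[0]:
        return float(r[0])
    if 0.5 >= p[-1]:
        return float(r[-1])
    return float(np.interp(0.5, p, r))


def weighted_median(
    estimates: Sequence[WaldEstimate],
    n_boot: int = 1000,
    seed: int | None = None,
) -> MRResult:
    """Pleiotropy-robust weighted-median causal estimate.

    The SE comes from a parametric bootstrap: each replicate redraws
    ratio*ⱼ ~ N(ratioⱼ, seⱼ) and recomputes the weighted median; the SE is the
    SD over replicates.  ``seed`` is mandatory for reproducibility.
    """
    if not estimates:
        raise ValidationError("weighted_median requires at least one estimate")
    if n_boot < 1:
        raise ValidationError(f"n_boot must be >= 1, got {n_boot}")
    if seed is None:
        raise ValidationError("weighted_median requires an explicit seed")
    if len(estimates) < 3:
        import warnings
        warnings.warn("weighted median with fewer than 3 SNPs is poorly identified",
                      stacklevel=2)
    r = np.array([e.ratio for e in estimates], dtype=float)
    s = np.array([e.se for e in estimates], dtype=float)
    w = s ** -2
    point = weighted_median_point(r, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=r, scale=s, size=(n_boot, len(r)))
    boot = np.array([weighted_median_point(d, w) for d in draws])
    se = float(np.std(boot, ddof=1)) if n_boot > 1 else float("nan")
    if not (se > 0):
        se = float("nan")
    if math.isnan(se):
        # degenerate (single estimate or zero spread): fall back to IVW-style SE
        se = float(np.sum(w) ** -0.5)
    return _result(point, se, "weighted-median", estimates)


@dataclass
class MRConfig:
    """Settings for a two-sample MR run."""

    models: tuple[str, ...] = ("8-SNP", "6-SNP", "2-SNP")
    methods: tuple[str, ...] = ("IVW-FE", "weighted-median")
    delta_order: str = "first"
    n_boot: int = 1000
    seed: int = 20170712


def run_two_sample_mr(instrument_set: InstrumentSet, config: MRConfig | None = None) -> list[MRResult]:
    """Run every requested model × method combination on a harmonized set.

    Results come back in (model, method) request order; each carries its
    per-SNP Wald estimates for forest-table output.  Deterministic given the
    config (the bootstrap seed is part of it).
    """
    from .instruments import select_model

    config = config or MRConfig()
    results: list[MRResult] = []
    for model in config.models:
        sub = select_model(instrument_set, model) if model != "custom" else instrument_set
        wald = [
            wald_ratio(e.beta_x, e.se_x, e.beta_y, e.se_y,
                       order=config.delta_order, snp_id=e.snp_id)
            for e in sub.entries
        ]
        for method in config.methods:
            if method == "IVW-FE":
                results.append(ivw_fixed_effects(wald))
            elif method == "weighted-median":
                results.append(weighted_median(wald, n_boot=config.n_boot, seed=config.seed))
            else:
                raise ValidationError(f"unknown MR method {method!r}")
    return results


def forest_table(result: MRResult) -> pd.DataFrame:
    """Forest-plot data: one row per SNP (ratio, 95% CI) plus the combined row."""
    rows = [
        {"snp_id": w.snp_id, "ratio": w.ratio,
         "ci_low": w.ratio - Z_95 * w.se, "ci_high": w.ratio + Z_95 * w.se}
        for w in result.per_snp
    ]
    rows.append({
        "snp_id": f"combined ({result.method})",
        "ratio": result.estimate, "ci_low": result.ci_low, "ci_high": result.ci_high,
    })
    return pd.DataFrame(rows, columns=["snp_id", "ratio", "ci_low", "ci_high"])
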