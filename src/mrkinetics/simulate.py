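"""Synthetic-data generators with known ground truth.

Three generators cover the pipeline's inputs: (1) confounded individual-level
MR cohorts from linear structural equations with a known causal effect;
(2) two-sample GWAS summary tables derived from two independent simulated
cohorts; (3) noisy enzyme-kinetics velocity tables under a stated inhibition
model.  All generators are bit-reproducible under explicit seeds.

Structural model for cohorts (per individual i, SNP j):

    dosage_ij ~ Binomial(2, maf_j)                (Hardy-Weinberg, no LD)
    U_i ~ N(0, 1)                                 (unobserved confounder)
    X_i = mu_x + Σ_j gamma_j·dosage_ij + c_x·U_i + N(0, sd_ex)
    Y_i = mu_y + beta_causal·X_i + c_y·U_i + N(0, sd_ey)

so the observational slope of Y on X is biased away from beta_causal by
c_x·c_y·Var(U)/Var(X), a closed form recorded in ``Cohort.true_params``.

Default marginals emulate a biobank smoking/coffee sample: exposure SD ≈ 2
cups/day around a mean of 3, outcome SD ≈ 8.5 cigarettes/day around 15, and
confounding tuned so the observational slope exceeds the causal effect by
0.45 cigarettes/day per cup/day.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .instruments import MODEL_SNPS, VariantAssociation
from .kinetics import KineticDataset, KineticParams, velocity
from .onesample import Cohort

#: default per-allele exposure effects (cups/day), 8-SNP instrument magnitudes
DEFAULT_GAMMA = (0.03, 0.03, 0.05, 0.06, 0.05, 0.03, 0.09, 0.03)
#: plausible European effect-allele frequencies for the eight loci
DEFAULT_MAFS = (0.40, 0.30, 0.60, 0.25, 0.30, 0.20, 0.30, 0.45)
DEFAULT_SNP_IDS = MODEL_SNPS["8-SNP"]
_DEFAULT_ALLELES = (("C", "T"), ("A", "G"), ("C", "T"), ("C", "T"),
                    ("A", "G"), ("C", "T"), ("T", "C"), ("G", "A"))


@dataclass
class CohortSpec:
    """Generating parameters for a synthetic MR cohort."""

    n: int = 8072
    mafs: tuple[float, ...] = DEFAULT_MAFS
    gamma: tuple[float, ...] = DEFAULT_GAMMA
    beta_causal: float = 0.0
    confounder_to_x: float = 0.6
    confounder_to_y: float = 3.0
    sd_ex: float = 1.907
    sd_ey: float = 7.95
    mean_exposure: float = 3.0
    mean_outcome: float = 15.0
    snp_ids: tuple[str, ...] = DEFAULT_SNP_IDS
    round_exposure: bool = False
    ld_rho: float = 0.0   # Gaussian-copula dosage correlation (0 = independent SNPs)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        if len(self.mafs) != len(self.gamma) or len(self.mafs) != len(self.snp_ids):
            raise ValidationError("mafs, gamma and snp_ids must have equal length")
        if not all(0 < m < 1 for m in self.mafs):
            raise ValidationError("all MAFs must lie in (0, 1)")
        if self.sd_ex < 0 or self.sd_ey < 0:
            raise ValidationError("residual SDs must be non-negative")

    @property
    def genetic_variance_x(self) -> float:
        """Variance in exposure contributed by the SNPs (HWE, no LD)."""
        return float(sum(g * g * 2 * m * (1 - m) for g, m in zip(self.gamma, self.mafs)))

    @property
    def var_x(self) -> float:
        return self.genetic_variance_x + self.confounder_to_x**2 + self.sd_ex**2

    @property
    def observational_bias(self) -> float:
        """Closed-form excess of the observational Y-on-X slope over beta_causal."""
        return self.confounder_to_x * self.confounder_to_y / self.var_x


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort from the structural model; ground truth in ``true_params``."""
    rng = np.random.default_rng(spec.seed)
    m = len(spec.mafs)
    if spec.ld_rho > 0:
        # Gaussian copula with exchangeable correlation, solely to exercise
        # LD pruning; the analysis model assumes independent instruments.
        from scipy import stats as _st
        shared = rng.standard_normal(spec.n)[:, None]
        z = (np.sqrt(spec.ld_rho) * shared
             + np.sqrt(1 - spec.ld_rho) * rng.standard_normal((spec.n, m)))
        dosage = _st.binom.ppf(_st.norm.cdf(z), 2, np.asarray(spec.mafs)).astype(float)
    else:
        dosage = rng.binomial(2, spec.mafs, size=(spec.n, m)).astype(float)
    u = rng.standard_normal(spec.n)
    x = (spec.mean_exposure + dosage @ np.asarray(spec.gamma)
         + spec.confounder_to_x * u + rng.normal(0, spec.sd_ex, spec.n))
    if spec.round_exposure:
        x = np.clip(np.round(x), 0, None)
    y = (spec.mean_outcome + spec.beta_causal * x
         + spec.confounder_to_y * u + rng.normal(0, spec.sd_ey, spec.n))
    covariates = pd.DataFrame({
        "age": rng.normal(50, 8, spec.n),
        "sex": rng.integers(0, 2, spec.n).astype(float),
        "smoker": np.ones(spec.n, dtype=bool),
    })
    snp_meta = pd.DataFrame({
        "snp_id": spec.snp_ids,
        "effect_allele": [a for a, _ in _DEFAULT_ALLELES[:m]] if m <= 8
        else ["A"] * m,
        "weight": spec.gamma,
    })
    return Cohort(
        genotypes=dosage, exposure=x, outcome=y,
        snp_meta=snp_meta, covariates=covariates,
        true_params={
            "beta_causal": spec.beta_causal,
            "observational_bias": spec.observational_bias,
            "var_x": spec.var_x,
            "spec": spec,
        },
    )


def empirical_ld_r2(genotypes: np.ndarray, snp_ids: Sequence[str]) -> dict[frozenset, float]:
    """Pairwise squared dosage correlations keyed by snp_id pairs (for ld_prune)."""
    corr = np.corrcoef(np.asarray(genotypes, dtype=float), rowvar=False)
    out: dict[frozenset, float] = {}
    for i in range(len(snp_ids)):
        for j in range(i + 1, len(snp_ids)):
            out[frozenset((snp_ids[i], snp_ids[j]))] = float(corr[i, j] ** 2)
    return out


def _simple_regressions(dosage: np.ndarray, phenotype: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP slope and classical SE of phenotype on dosage (vectorized)."""
    n, m = dosage.shape
    dc = dosage - dosage.mean(axis=0)
    yc = phenotype - phenotype.mean()
    sxx = (dc * dc).sum(axis=0)
    beta = (dc * yc[:, None]).sum(axis=0) / sxx
    resid_ss = (yc * yc).sum() - beta**2 * sxx
    sigma2 = resid_ss / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    return beta, se


def generate_two_sample_summary(
    spec: CohortSpec,
    seed_pair: tuple[int, int] | None = None,
    allele_swap: bool = False,
) -> tuple[list[VariantAssociation], list[VariantAssociation]]:
    """Summary tables from two independent cohorts (two-sample MR design).

    Exposure betas/SEs come from cohort 1, outcome betas/SEs from cohort 2,
    each by per-SNP simple regression.  With ``allele_swap`` the outcome table
    randomly relabels effect/other alleles (flipping beta signs) to exercise
    harmonization.
    """
    from dataclasses import replace

    if seed_pair is None:
        seed_pair = (spec.seed, spec.seed + 1)
    c1 = generate_cohort(replace(spec, seed=seed_pair[0]))
    c2 = generate_cohort(replace(spec, seed=seed_pair[1]))
    bx, sx = _simple_regressions(c1.genotypes, c1.exposure)
    by, sy = _simple_regressions(c2.genotypes, c2.outcome)
    rng = np.random.default_rng(seed_pair[1] + 10_007)
    m = len(spec.snp_ids)
    alleles = _DEFAULT_ALLELES[:m] if m <= 8 else [("A", "G")] * m

    exposure, outcome = [], []
    for j, snp in enumerate(spec.snp_ids):
        ea, oa = alleles[j]
        exposure.append(VariantAssociation(
            snp_id=snp, effect_allele=ea, other_allele=oa,
            beta=float(bx[j]), se=float(sx[j]), phenotype="exposure", n=spec.n))
        b, e1, e2 = float(by[j]), ea, oa
        if allele_swap and rng.random() < 0.5:
            b, e1, e2 = -b, oa, ea
        outcome.append(VariantAssociation(
            snp_id=snp, effect_allele=e1, other_allele=e2,
            beta=b, se=float(sy[j]), phenotype="outcome", n=spec.n))
    return exposure, outcome


def generate_kinetic_dataset(
    params: KineticParams,
    substrate_uM: Sequence[float],
    inhibitor_uM: Sequence[float],
    cv: float = 0.05,
    replicates: int = 2,
    preincubation_effect: float = 1.0,
    include_preincubated: bool = False,
    seed: int = 0,
    matrix_label: str = "microsomes",
) -> KineticDataset:
    """Simulated velocity table under the rate law with multiplicative noise.

    Velocities are velocity(S, I)·LogNormal(0, cv) per replicate (laboratory
    velocity errors are scale-proportional).  The pre-incubated arm (included
    when ``include_preincubated``) uses vmax·preincubation_effect in wells
    containing inhibitor — values below 1 emulate time-dependent
    (mechanism-based) inactivation, which requires the inhibitor to be present
    during the pre-incubation; inhibitor-free baseline wells are unaffected in
    either arm.
    """
    if not len(substrate_uM) or not len(inhibitor_uM):
        raise ValidationError("substrate and inhibitor grids must be non-empty")
    if cv < 0:
        raise ValidationError("cv must be non-negative")
    if not (0 < preincubation_effect <= 1):
        raise ValidationError("preincubation_effect must be in (0, 1]")
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    arms = [False] + ([True] if include_preincubated else [])
    rows = []
    for preinc in arms:
        for S in substrate_uM:
            for I in inhibitor_uM:
                v0 = velocity(float(S), float(I), params)
                if preinc and I > 0:
                    v0 *= preincubation_effect
                for r in range(replicates):
                    noise = rng.lognormal(mean=0.0, sigma=cv) if cv > 0 else 1.0
                    rows.append({
                        "substrate_uM": float(S), "inhibitor_uM": float(I),
                        "velocity": v0 * noise, "replicate": r,
                        "preincubated": preinc,
                    })
    return KineticDataset(pd.DataFrame(rows), matrix_label=matrix_label)
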