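"""CYP2A6 inhibition kinetics: velocity laws, Dixon / Cornish-Bowden analysis,
pre-incubation testing, and physiological fractional-inhibition prediction.

The general reversible-inhibition rate law used throughout is

    v = Vmax·S / ( Km·(1 + I/Ki_c) + S·(1 + I/Ki_u) )

where Ki_c is the competitive-component inhibition constant (binding to free
enzyme) and Ki_u the uncompetitive component (binding to the enzyme-substrate
complex).  The four classical inhibition types are patterns of these two
constants: competitive (Ki_u = ∞), uncompetitive (Ki_c = ∞), noncompetitive
(Ki_c = Ki_u), mixed (both finite, unequal).

Ki estimation follows graphical laboratory practice: Dixon plots (1/v against
[I] at fixed substrate levels) whose line intersection sits at I = −Ki_c, and
Cornish-Bowden plots ([S]/v against [I]) whose intersection sits at
I = −Ki_u.  Which line family is parallel and where the intersections sit
jointly identify the inhibition type.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DesignError, ValidationError

INHIBITION_MODELS = ("competitive", "uncompetitive", "noncompetitive", "mixed")

#: verdict marker for a line family with indistinguishable slopes
PARALLEL = "parallel"


@dataclass(frozen=True)
class KineticParams:
    """Michaelis-Menten parameters plus a two-constant inhibition pattern.

    ``vmax`` is in nmol/min per mg protein (microsomes) or nmol/min per pmol
    enzyme (supersomes); ``km``, ``ki_c`` and ``ki_u`` are in μM.  Infinite
    ``ki_c``/``ki_u`` means the corresponding binding mode is absent.
    """

    vmax: float
    km: float
    ki_c: float = math.inf
    ki_u: float = math.inf
    model: str = "competitive"

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0:
            raise ValidationError("vmax and km must be positive")
        if self.ki_c <= 0 or self.ki_u <= 0:
            raise ValidationError("ki_c and ki_u must be positive (or infinite)")
        if self.model not in INHIBITION_MODELS:
            raise ValidationError(f"unknown inhibition model {self.model!r}")
        ok = {
            "competitive": math.isfinite(self.ki_c) and math.isinf(self.ki_u),
            "uncompetitive": math.isinf(self.ki_c) and math.isfinite(self.ki_u),
            "noncompetitive": math.isfinite(self.ki_c) and self.ki_c == self.ki_u,
            "mixed": math.isfinite(self.ki_c) and math.isfinite(self.ki_u)
                     and self.ki_c != self.ki_u,
        }[self.model]
        if not ok:
            raise ValidationError(
                f"(ki_c={self.ki_c}, ki_u={self.ki_u}) inconsistent with model {self.model!r}"
            )

    @classmethod
    def competitive(cls, vmax: float, km: float, ki: float) -> "KineticParams":
        return cls(vmax=vmax, km=km, ki_c=ki, ki_u=math.inf, model="competitive")

    @classmethod
    def uncompetitive(cls, vmax: float, km: float, ki: float) -> "KineticParams":
        return cls(vmax=vmax, km=km, ki_c=math.inf, ki_u=ki, model="uncompetitive")

    @classmethod
    def noncompetitive(cls, vmax: float, km: float, ki: float) -> "KineticParams":
        return cls(vmax=vmax, km=km, ki_c=ki, ki_u=ki, model="noncompetitive")

    @classmethod
    def mixed(cls, vmax: float, km: float, ki_c: float, ki_u: float) -> "KineticParams":
        return cls(vmax=vmax, km=km, ki_c=ki_c, ki_u=ki_u, model="mixed")


REQUIRED_KINETIC_COLUMNS = ("substrate_uM", "inhibitor_uM", "velocity",
                            "replicate", "preincubated")


@dataclass
class KineticDataset:
    """Velocity observations on a substrate × inhibitor design.

    ``observations`` columns: substrate_uM, inhibitor_uM, velocity, replicate,
    preincubated (bool).  ``matrix_label`` tags the enzyme source
    ("microsomes" or "supersomes").
    """

    observations: pd.DataFrame
    matrix_label: str = "microsomes"

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_KINETIC_COLUMNS if c not in self.observations.columns]
        if missing:
            raise ValidationError(f"kinetic table missing column(s): {', '.join(missing)}")
        obs = self.observations
        if (obs["substrate_uM"] <= 0).any():
            raise ValidationError("substrate_uM must be positive")
        if (obs["inhibitor_uM"] < 0).any():
            raise ValidationError("inhibitor_uM must be non-negative")
        if (obs["velocity"] < 0).any():
            raise ValidationError("velocity must be non-negative")

    def arm(self, preincubated: bool) -> "KineticDataset":
        sub = self.observations[self.observations["preincubated"] == preincubated]
        return KineticDataset(sub.reset_index(drop=True), self.matrix_label)

    @classmethod
    def from_tsv(cls, source, matrix_label: str | None = None) -> "KineticDataset":
        df = pd.read_csv(source, sep="\t")
        label = matrix_label or (df["matrix"].iloc[0] if "matrix" in df.columns else "microsomes")
        if "preincubated" in df.columns:
            df["preincubated"] = df["preincubated"].astype(bool)
        return cls(df[list(REQUIRED_KINETIC_COLUMNS)].copy(), str(label))

    def to_tsv(self, path) -> None:
        out = self.observations.copy()
        out["matrix"] = self.matrix_label
        out.to_csv(path, sep="\t", index=False)


def velocity(substrate_uM, inhibitor_uM, params: KineticParams):
    """Reaction velocity under the general reversible-inhibition rate law.

    Vectorized over substrate and inhibitor concentrations.
    """
    S = np.asarray(substrate_uM, dtype=float)
    I = np.asarray(inhibitor_uM, dtype=float)
    if np.any(S <= 0):
        raise ValidationError("substrate_uM must be positive")
    if np.any(I < 0):
        raise ValidationError("inhibitor_uM must be non-negative")
    comp = 1.0 + (I / params.ki_c if math.isfinite(params.ki_c) else 0.0)
    unc = 1.0 + (I / params.ki_u if math.isfinite(params.ki_u) else 0.0)
    v = params.vmax * S / (params.km * comp + S * unc)
    return float(v) if np.isscalar(substrate_uM) and np.isscalar(inhibitor_uM) else v


@dataclass(frozen=True)
class Line:
    """Least-squares line y = slope·I + intercept for one substrate level."""

    substrate_uM: float
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    n_points: int
    residual_sd: float


@dataclass
class PlotFit:
    """One linearized-plot family (Dixon or Cornish-Bowden)."""

    kind: str                       # "dixon" | "cornish-bowden"
    lines: tuple[Line, ...]
    intersection: tuple[float, float] | str   # (I, y) or PARALLEL
    ki: float | None                # −(median intersection I); None when parallel


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """OLS slope/intercept with an HC3 sandwich slope SE.

    Laboratory velocity noise is scale-proportional, so the transformed
    responses (1/v, S/v) are heteroscedastic; the classical homoscedastic
    slope SE is biased low at wide inhibitor ranges, which would inflate the
    parallel-line test.  The HC3 leverage-corrected sandwich SE stays honest.
    """
    n = len(x)
    xb = x.mean()
    sxx = float(((x - xb) ** 2).sum())
    slope = float(((x - xb) * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * xb)
    resid = y - (slope * x + intercept)
    lev = 1.0 / n + (x - xb) ** 2 / sxx
    u = resid / (1.0 - lev)
    slope_se = float(np.sqrt((((x - xb) ** 2) * u**2).sum()) / sxx)
    intercept_se = float(np.sqrt(((1.0 / n - xb * (x - xb) / sxx) ** 2 * u**2).sum()))
    return slope, intercept, slope_se, intercept_se


def _fit_lines(dataset: KineticDataset, transform: str) -> tuple[Line, ...]:
    obs = dataset.observations
    if (obs["velocity"] <= 0).any():
        raise ValidationError("linearized fits require strictly positive velocities")
    levels = sorted(obs["substrate_uM"].unique())
    if len(levels) < 2:
        raise DesignError("need at least 2 distinct substrate levels")
    lines = []
    for S in levels:
        sub = obs[obs["substrate_uM"] == S]
        if sub["inhibitor_uM"].nunique() < 3:
            raise DesignError(
                f"substrate level {S} μM has fewer than 3 distinct inhibitor levels"
            )
        x = sub["inhibitor_uM"].to_numpy(dtype=float)
        y = 1.0 / sub["velocity"].to_numpy(dtype=float)
        if transform == "s_over_v":
            y = y * S
        slope, intercept, slope_se, intercept_se = _ols_line(x, y)
        dof = max(len(x) - 2, 1)
        resid = y - (slope * x + intercept)
        lines.append(Line(
            substrate_uM=float(S),
            slope=slope, intercept=intercept,
            slope_se=slope_se, intercept_se=intercept_se,
            n_points=len(x),
            residual_sd=float(np.sqrt(np.sum(resid**2) / dof)),
        ))
    return tuple(lines)


def _intersections(lines: Sequence[Line], rtol: float, alpha: float = 0.01) -> tuple:
    """Family-level parallelism test, then median pairwise intersection.

    The line family is declared parallel when either the relative slope spread
    is below ``rtol`` (the noise-free contract) or a weighted chi-square test
    cannot reject a common slope at level ``alpha`` given the per-line slope
    SEs.  Otherwise the median of pairwise intersection coordinates is
    returned; the median is robust to the occasional near-parallel pair.
    """
    m = np.array([ln.slope for ln in lines])
    se = np.array([ln.slope_se for ln in lines])
    scale = float(np.max(np.abs(m)))
    if scale == 0 or (np.max(m) - np.min(m)) < rtol * scale:
        return PARALLEL
    if np.all(se > 0):
        w = se**-2.0
        m_bar = float((w * m).sum() / w.sum())
        q = float((w * (m - m_bar) ** 2).sum())
        if q < stats.chi2.ppf(1 - alpha, len(m) - 1):
            return PARALLEL
    pts_i, pts_y = [], []
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            a, b = lines[i], lines[j]
            dm = a.slope - b.slope
            if abs(dm) < 1e-12 * scale:
                continue
            I = (b.intercept - a.intercept) / dm
            pts_i.append(I)
            pts_y.append(a.slope * I + a.intercept)
    return (float(np.median(pts_i)), float(np.median(pts_y)))


def fit_dixon(dataset: KineticDataset, parallel_rtol: float = 0.02) -> PlotFit:
    """Dixon-plot Ki estimation: lines of 1/v against [I] per substrate level.

    For inhibition with a competitive component the lines intersect at
    I = −Ki_c (and y = 1/Vmax for purely competitive data); Ki is taken as
    −(median of pairwise intersection abscissae), robust to unequal noise
    across substrate levels.  Parallel lines (slopes equal within tolerance)
    indicate no competitive component (uncompetitive inhibition) and yield no
    Dixon Ki.
    """
    lines = _fit_lines(dataset, "inverse_v")
    inter = _intersections(lines, parallel_rtol)
    ki = None if inter == PARALLEL else -inter[0]
    return PlotFit(kind="dixon", lines=lines, intersection=inter, ki=ki)


def fit_cornish_bowden(dataset: KineticDataset, parallel_rtol: float = 0.02) -> PlotFit:
    """Cornish-Bowden plot: lines of [S]/v against [I] per substrate level.

    Lines intersect at I = −Ki_u; parallel lines indicate no uncompetitive
    component (competitive inhibition).  The intersection ordinate equals
    Km(1 − Ki_u/Ki_c)/Vmax, so an intersection on the I-axis (y ≈ 0)
    indicates noncompetitive inhibition (Ki_c = Ki_u).
    """
    lines = _fit_lines(dataset, "s_over_v")
    inter = _intersections(lines, parallel_rtol)
    ki = None if inter == PARALLEL else -inter[0]
    return PlotFit(kind="cornish-bowden", lines=lines, intersection=inter, ki=ki)


@dataclass
class InhibitionFit:
    """Joint Dixon + Cornish-Bowden analysis with an inhibition-type verdict."""

    ki: float | None
    inferred_type: str
    dixon: PlotFit
    cornish_bowden: PlotFit
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def plot_doc(p: PlotFit) -> dict:
            return {
                "kind": p.kind,
                "ki": p.ki,
                "intersection": p.intersection if isinstance(p.intersection, str)
                else list(p.intersection),
                "lines": [
                    {"substrate_uM": ln.substrate_uM, "slope": ln.slope,
                     "intercept": ln.intercept, "slope_se": ln.slope_se}
                    for ln in p.lines
                ],
            }
        return {
            "ki": self.ki, "inferred_type": self.inferred_type,
            "dixon": plot_doc(self.dixon),
            "cornish_bowden": plot_doc(self.cornish_bowden),
            "diagnostics": self.diagnostics,
        }


def classify_inhibition(
    dataset: KineticDataset,
    parallel_rtol: float = 0.02,
    axis_rtol: float = 0.3,
) -> InhibitionFit:
    """Infer the inhibition type from the joint Dixon / Cornish-Bowden geometry.

    Decision rule: Dixon intersects & CB parallel → competitive (Ki from
    Dixon); Dixon parallel & CB intersects → uncompetitive (Ki from CB); both
    intersect with the CB ordinate within ``axis_rtol`` of the CB intercept
    scale of zero → noncompetitive; both intersect off-axis → mixed; both
    parallel → "undetermined" (no exception — diagnostics carry both fits).
    """
    dixon = fit_dixon(dataset, parallel_rtol)
    cb = fit_cornish_bowden(dataset, parallel_rtol)
    d_par = dixon.intersection == PARALLEL
    c_par = cb.intersection == PARALLEL
    diagnostics = {
        "dixon_residual_sd": [ln.residual_sd for ln in dixon.lines],
        "cb_residual_sd": [ln.residual_sd for ln in cb.lines],
    }
    if d_par and c_par:
        verdict, ki = "undetermined", None
    elif d_par:
        verdict, ki = "uncompetitive", cb.ki
    elif c_par:
        verdict, ki = "competitive", dixon.ki
    else:
        y_cb = cb.intersection[1]
        scale = np.mean([abs(ln.intercept) for ln in cb.lines])
        if abs(y_cb) < axis_rtol * scale:
            verdict, ki = "noncompetitive", dixon.ki
        else:
            verdict, ki = "mixed", dixon.ki
    return InhibitionFit(ki=ki, inferred_type=verdict, dixon=dixon,
                         cornish_bowden=cb, diagnostics=diagnostics)


def fit_velocity_law(dataset: KineticDataset, model: str) -> KineticParams:
    """Direct nonlinear least-squares fit of the velocity law (cross-check only).

    The Ki of record comes from the Dixon analysis; this fit is a convenient
    independent check on simulated or well-behaved data.
    """
    if model not in INHIBITION_MODELS:
        raise ValidationError(f"unknown inhibition model {model!r}")
    obs = dataset.observations
    S = obs["substrate_uM"].to_numpy(dtype=float)
    I = obs["inhibitor_uM"].to_numpy(dtype=float)
    v = obs["velocity"].to_numpy(dtype=float)
    v0 = v.max()
    km0 = np.median(S)
    ki0 = max(np.median(I[I > 0]), 1.0) if (I > 0).any() else 10.0

    def make(theta) -> KineticParams:
        if model == "competitive":
            return KineticParams.competitive(theta[0], theta[1], theta[2])
        if model == "uncompetitive":
            return KineticParams.uncompetitive(theta[0], theta[1], theta[2])
        if model == "noncompetitive":
            return KineticParams.noncompetitive(theta[0], theta[1], theta[2])
        return KineticParams.mixed(theta[0], theta[1], theta[2], theta[3])

    def resid(theta):
        try:
            p = make(theta)
        except ValidationError:
            return np.full_like(v, 1e6)
        return velocity(S, I, p) - v

    x0 = [v0, km0, ki0] + ([ki0] if model == "mixed" else [])
    sol = optimize.least_squares(resid, x0, bounds=(1e-9, np.inf))
    return make(sol.x)


@dataclass
class PreincubationResult:
    verdict: str                    # "mechanism-based-candidate" | "not-mechanism-based"
    p_value: float
    mean_difference: float          # pre-incubated minus control, percentage points
    activity_table: pd.DataFrame    # % activity remaining per condition


def percent_activity_remaining(dataset: KineticDataset) -> pd.DataFrame:
    """Percent of uninhibited activity remaining at each (substrate, inhibitor) cell.

    100·v(I)/v(0), with v averaged over replicates and v(0) the within-substrate
    uninhibited mean.
    """
    obs = dataset.observations
    mean_v = (obs.groupby(["substrate_uM", "inhibitor_uM"])["velocity"]
              .mean().reset_index())
    base = mean_v[mean_v["inhibitor_uM"] == 0].set_index("substrate_uM")["velocity"]
    if base.empty:
        raise DesignError("percent activity requires inhibitor_uM = 0 observations")
    mean_v["percent_activity"] = 100.0 * mean_v["velocity"] / mean_v["substrate_uM"].map(base)
    return mean_v[["substrate_uM", "inhibitor_uM", "percent_activity"]]


def preincubation_test(
    control: KineticDataset,
    preincubated: KineticDataset,
    alpha: float = 0.05,
) -> PreincubationResult:
    """Test for mechanism-based (irreversible) inhibition via pre-incubation.

    A mechanism-based inhibitor is metabolically activated during
    pre-incubation and inactivates the enzyme, so pre-incubated activity falls
    below the non-pre-incubated arm.  Percent activity remaining is compared
    cell-by-cell across the matched (substrate, inhibitor>0) grid with a
    one-sided paired t-test at level ``alpha`` (pre-incubated < control).
    """
    act_c = percent_activity_remaining(control)
    act_p = percent_activity_remaining(preincubated)
    merged = act_c.merge(act_p, on=["substrate_uM", "inhibitor_uM"],
                         suffixes=("_control", "_preincubated"), how="outer",
                         indicator=True)
    if (merged["_merge"] != "both").any():
        raise DesignError("pre-incubation arms must share the same substrate × inhibitor grid")
    merged = merged[merged["inhibitor_uM"] > 0].drop(columns="_merge")
    diff = (merged["percent_activity_preincubated"]
            - merged["percent_activity_control"]).to_numpy()
    mean_diff = float(np.mean(diff))
    if np.allclose(diff, diff[0]):
        # degenerate (e.g. noise-free): decide on sign alone
        p = 0.0 if mean_diff < 0 else 1.0
    else:
        p = float(stats.ttest_rel(merged["percent_activity_preincubated"],
                                  merged["percent_activity_control"],
                                  alternative="less").pvalue)
    verdict = ("mechanism-based-candidate"
               if (mean_diff < 0 and p < alpha) else "not-mechanism-based")
    table = merged.rename(columns={
        "percent_activity_control": "pct_activity_control",
        "percent_activity_preincubated": "pct_activity_preincubated",
    })
    return PreincubationResult(verdict=verdict, p_value=p,
                               mean_difference=mean_diff, activity_table=table)


def fractional_inhibition(
    inhibitor_uM: float,
    ki_uM: float,
    substrate_uM: float | None = None,
    km_uM: float | None = None,
) -> float:
    """Fraction by which a competitive inhibitor slows the reaction in vivo.

    In the low-substrate limit (the default; physiological nicotine is far
    below the CYP2A6 Km) the fraction is I/(I + Ki).  When a substrate
    concentration is supplied (Km required) the exact competitive-law fraction
    1 − v(S, I)/v(S, 0) is returned.
    """
    if ki_uM <= 0:
        raise ValidationError(f"ki must be positive, got {ki_uM}")
    if inhibitor_uM < 0:
        raise ValidationError("inhibitor concentration must be non-negative")
    if substrate_uM is None:
        return inhibitor_uM / (inhibitor_uM + ki_uM)
    if km_uM is None:
        raise ValidationError("km_uM is required when substrate_uM is given")
    params = KineticParams.competitive(vmax=1.0, km=km_uM, ki=ki_uM)
    return 1.0 - velocity(substrate_uM, inhibitor_uM, params) / velocity(substrate_uM, 0.0, params)


def mg_per_l_to_um(concentration_mg_per_l: float, molecular_weight_g_per_mol: float) -> float:
    """Convert a mass concentration to micromolar: μM = 1000·(mg/l)/MW."""
    if molecular_weight_g_per_mol <= 0:
        raise ValidationError("molecular weight must be positive")
    if concentration_mg_per_l < 0:
        raise ValidationError("concentration must be non-negative")
    return 1000.0 * concentration_mg_per_l / molecular_weight_g_per_mol


#: molecular weight of caffeic acid (g/mol), used in worked examples
CAFFEIC_ACID_MW = 180.16
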