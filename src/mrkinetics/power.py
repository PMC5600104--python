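"""Analytic statistical power for an MR design with continuous exposure and outcome.

The instrumental-variable estimate of a causal effect β (outcome units per
exposure unit) based on an instrument explaining a fraction R² of exposure
variance in a sample of n individuals has non-centrality parameter

    NCP = n · R² · (β·σx/σy)²

and two-sided power at level α of

    power = Φ(√NCP − z_{1−α/2}) + Φ(−√NCP − z_{1−α/2}).

The second (far-tail) term makes the size exact at β = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError


@dataclass(frozen=True)
class PowerSpec:
    """Design parameters for an MR power calculation.

    n: sample size; r_squared: exposure variance explained by the instrument;
    beta: causal effect to detect; sd_x / sd_y: exposure and outcome SDs;
    alpha: two-sided significance level.
    """

    n: int
    r_squared: float
    beta: float
    sd_x: float = 2.0
    sd_y: float = 8.5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")
        if not (0 < self.r_squared < 1):
            raise ValidationError(f"r_squared must be in (0, 1), got {self.r_squared}")
        if self.sd_x <= 0 or self.sd_y <= 0:
            raise ValidationError("sd_x and sd_y must be positive")
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha must be in (0, 1), got {self.alpha}")


def mr_power(spec: PowerSpec) -> float:
    """Two-sided power of the MR design, as a fraction in (0, 1)."""
    b = spec.beta * spec.sd_x / spec.sd_y
    ncp = spec.n * spec.r_squared * b * b
    z = stats.norm.ppf(1 - spec.alpha / 2)
    root = np.sqrt(ncp)
    return float(stats.norm.cdf(root - z) + stats.norm.cdf(-root - z))


def mr_power_curve(spec: PowerSpec, vary: str, grid) -> pd.DataFrame:
    """Evaluate :func:`mr_power` along a grid of one spec parameter."""
    if vary not in PowerSpec.__dataclass_fields__:
        raise ValidationError(f"unknown PowerSpec field {vary!r}")
    rows = []
    for value in grid:
        pt = replace(spec, **{vary: value})  # re-validates each point
        rows.append({vary: value, "power": mr_power(pt)})
    return pd.DataFrame(rows)
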