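"""Arrhenius analysis of temperature-dependent lipid diffusion.

Lateral diffusion in a bilayer is thermally activated; over a narrow
temperature window D(T) follows

    ln D = ln A - E_a / (R T)

with a temperature-independent pre-exponential factor A.  Regressing
ln D on 1/T yields the activation energy E_a = -slope * R.  Each D
comes with a confidence half-width from the per-trace FRAP fit, and the
regression weights points by the reciprocal of that uncertainty mapped
onto the ln scale by the delta method (sigma_lnD = sigma_D / D).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "R_GAS",
    "ArrheniusRecord",
    "ArrheniusSeries",
    "ActivationEnergyResult",
    "arrhenius_fit",
    "predict_D",
    "mobile_fraction_trend",
]

R_GAS = 8.314  # J mol^-1 K^-1


@dataclass
class ArrheniusRecord:
    """One (T, D) measurement with its uncertainty and metadata."""

    temperature_k: float
    d: float                      # um^2/s
    d_half_width: float = 0.0     # um^2/s, >= 0
    mobile_fraction: float | None = None
    sample_id: str = "s1"
    ramp: str = "heating"         # heating | cooling

    def __post_init__(self) -> None:
        if not 273.0 <= self.temperature_k <= 373.0:
            raise ValueError("temperature must lie in [273, 373] K")
        if self.d <= 0:
            raise ValueError("D must be positive")
        if self.d_half_width < 0:
            raise ValueError("D half-width must be non-negative")
        if self.ramp not in ("heating", "cooling"):
            raise ValueError("ramp must be 'heating' or 'cooling'")


@dataclass
class ArrheniusSeries:
    """An ordered collection of D(T) measurements."""

    records: list[ArrheniusRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def temperatures(self) -> np.ndarray:
        return np.array([r.temperature_k for r in self.records])

    def d_values(self) -> np.ndarray:
        return np.array([r.d for r in self.records])

    def d_half_widths(self) -> np.ndarray:
        return np.array([r.d_half_width for r in self.records])


@dataclass
class ActivationEnergyResult:
    e_a_kj_mol: float
    e_a_se_kj_mol: float
    ln_a: float
    ln_a_se: float
    weighting: str
    n_points: int
    r_squared: float
    residual_sd: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def arrhenius_fit(
    series: ArrheniusSeries,
    weighting: str = "reciprocal-sigma",
) -> ActivationEnergyResult:
    """Weighted linear regression of ln D on 1/T.

    Weighting modes (applied to the squared ln-scale residuals):

    - ``"reciprocal-sigma"`` (default): w_i = 1/sigma_i, the reciprocal of
      each point's ln-scale standard error sigma_i = hw_i / D_i.
    - ``"inverse-variance"``: w_i = 1/sigma_i**2 (textbook WLS).
    - ``"unweighted"``: ordinary least squares.

    If any half-width is zero the fit silently falls back to the
    unweighted mode (exact data makes the choice irrelevant).  E_a is
    reported in kJ/mol with its standard error from the WLS covariance.
    """
    if weighting not in ("reciprocal-sigma", "inverse-variance", "unweighted"):
        raise ValueError(f"unknown weighting mode {weighting!r}")
    temps = series.temperatures()
    d = series.d_values()
    hw = series.d_half_widths()
    if np.unique(temps).size < 3:
        raise ValueError("need >= 3 distinct temperatures")
    if np.any(d <= 0):
        raise ValueError("D must be positive everywhere")

    x = 1.0 / temps
    y = np.log(d)
    sigma_ln = hw / d
    if weighting == "unweighted" or np.any(sigma_ln == 0):
        w = np.ones_like(y)
        mode = "unweighted"
    elif weighting == "reciprocal-sigma":
        w = 1.0 / sigma_ln
        mode = weighting
    else:
        w = 1.0 / sigma_ln ** 2
        mode = weighting

    model = sm.WLS(y, sm.add_constant(x), weights=w)
    res = model.fit()
    intercept, slope = res.params
    se_int, se_slope = res.bse
    with np.errstate(divide="ignore", invalid="ignore"):
        r_squared = float(res.rsquared)  # degenerate for constant ln D

    return ActivationEnergyResult(
        e_a_kj_mol=float(-slope * R_GAS / 1000.0),
        e_a_se_kj_mol=float(se_slope * R_GAS / 1000.0),
        ln_a=float(intercept),
        ln_a_se=float(se_int),
        weighting=mode,
        n_points=int(y.size),
        r_squared=r_squared,
        residual_sd=float(np.sqrt(res.mse_resid)),
    )


def predict_D(temperature_k: float, result: ActivationEnergyResult) -> float:
    """Evaluate the fitted Arrhenius law, ``exp(ln A - E_a/(R T))``."""
    return float(np.exp(
        result.ln_a - result.e_a_kj_mol * 1000.0 / (R_GAS * temperature_k)
    ))


def mobile_fraction_trend(series: ArrheniusSeries) -> dict:
    """OLS slope of the mobile fraction against temperature (per K).

    Returns slope, its standard error, the p-value and a plain-language
    description of whether the trend is increasing, decreasing, or flat
    at the 5% level.
    """
    recs = [r for r in series.records if r.mobile_fraction is not None]
    if len(recs) < 3:
        raise ValueError("need >= 3 points with mobile fractions")
    t = np.array([r.temperature_k for r in recs])
    m = np.array([r.mobile_fraction for r in recs])
    lr = stats.linregress(t, m)
    if lr.pvalue < 0.05:
        description = "increasing" if lr.slope > 0 else "decreasing"
    else:
        description = "no significant trend"
    return {
        "slope_per_k": float(lr.slope),
        "slope_se": float(lr.stderr),
        "intercept": float(lr.intercept),
        "p_value": float(lr.pvalue),
        "n_points": int(t.size),
        "description": description,
    }
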