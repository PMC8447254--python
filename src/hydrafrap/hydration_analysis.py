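"""Aggregation of per-spot FRAP fits across relative-humidity conditions.

Membrane hydration is set by the relative humidity (RH) the bilayer is
equilibrated against.  Lipid diffusion responds in two regimes: above
~50% RH the diffusion coefficient falls steeply with dehydration, below
it D sits on a plateau nearly independent of RH.  This module averages
per-spot fits within RH bins, fits the two regimes with separate linear
regressions split at a fixed RH, locates the turnover as the
intersection of the two lines, quantifies the overall fold change and
dehydration/rehydration reversibility, and maps RH onto the number of
water molecules per lipid via a tabulated sorption isotherm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .frap_core import FitResult, fit_recovery, normalize_trace

__all__ = [
    "SpotMeasurement",
    "ExperimentSeries",
    "TwoRegimeFit",
    "HydrationIsotherm",
    "DEFAULT_ISOTHERM",
    "fit_series",
    "aggregate_by_rh",
    "two_regime_fit",
    "search_breakpoint",
    "fold_change",
    "reversibility_report",
    "waters_per_lipid",
    "map_series_to_hydration",
]


@dataclass
class SpotMeasurement:
    """One per-spot fit tagged with its experimental condition."""

    rh: float
    sample_id: str
    spot_id: str
    direction: str          # dehydration | rehydration
    phase: str              # Ld | Lo
    fit: FitResult

    def __post_init__(self) -> None:
        if not 0.0 <= self.rh <= 100.0:
            raise ValueError("rh must lie in [0, 100]")


@dataclass
class ExperimentSeries:
    """Ordered collection of spot measurements over an RH series."""

    records: list[SpotMeasurement] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"rh": r.rh, "sample_id": r.sample_id, "spot_id": r.spot_id,
             "direction": r.direction, "phase": r.phase,
             "d": r.fit.D, "mobile_fraction": r.fit.mobile_fraction,
             "tau_d": r.fit.tau_d, "converged": r.fit.converged}
            for r in self.records
        ])


def fit_series(dataset, w: float | None = None) -> ExperimentSeries:
    """Normalize and fit every trace of a generated (or loaded) dataset.

    ``dataset`` must expose ``records`` with ``trace``, ``rh``,
    ``sample_id``, ``spot_id``, ``direction`` and ``phase`` attributes,
    and a ``bleach_radius_um`` for the default spot radius.
    """
    if w is None:
        w = dataset.bleach_radius_um
    out = []
    for rec in dataset.records:
        trace = rec.trace
        fit = fit_recovery(normalize_trace(trace), w=w)
        out.append(SpotMeasurement(
            rh=rec.rh, sample_id=rec.sample_id, spot_id=rec.spot_id,
            direction=rec.direction, phase=rec.phase, fit=fit))
    return ExperimentSeries(records=out)


def _bin_center(rh: np.ndarray, bin_width: float) -> np.ndarray:
    return np.round(np.asarray(rh, dtype=float) / bin_width) * bin_width


def aggregate_by_rh(series: ExperimentSeries, bin_width: float = 5.0) -> pd.DataFrame:
    """Per-condition means of D and the mobile fraction.

    Records are grouped by hydration-change direction and RH bin
    (nearest multiple of ``bin_width``); within each group the mean and
    sample sd are unweighted, matching the averaging of repeated spots.
    Bins holding a single measurement are flagged (their sd is NaN).
    """
    if len(series) == 0:
        raise ValueError("cannot aggregate an empty series")
    df = series.to_frame()
    df["rh_bin"] = _bin_center(df["rh"].to_numpy(), bin_width)
    grouped = df.groupby(["direction", "rh_bin"], as_index=False).agg(
        rh_mean=("rh", "mean"),
        d_mean=("d", "mean"),
        d_sd=("d", lambda x: x.std(ddof=1)),
        mobile_mean=("mobile_fraction", "mean"),
        mobile_sd=("mobile_fraction", lambda x: x.std(ddof=1)),
        n=("d", "size"),
    )
    grouped["single_measurement"] = grouped["n"] == 1
    return grouped.sort_values(["direction", "rh_bin"]).reset_index(drop=True)


@dataclass
class TwoRegimeFit:
    split_rh: float
    high_slope: float        # um^2/s per %RH
    high_intercept: float
    high_stderr: float
    high_r2: float
    low_slope: float
    low_intercept: float
    low_stderr: float
    low_r2: float
    turnover_rh: float | None
    parallel: bool
    n_high: int
    n_low: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def two_regime_fit(aggregated: pd.DataFrame, split_rh: float = 55.0) -> TwoRegimeFit:
    """Separate OLS lines above and below ``split_rh`` and their crossing.

    Operates on the aggregated per-bin means (``rh_bin``/``d_mean``
    columns, or plain ``rh``/``d``).  The turnover RH is the abscissa
    where the two lines intersect; parallel lines leave it undefined
    and flagged.
    """
    rh_col = "rh_bin" if "rh_bin" in aggregated else "rh"
    d_col = "d_mean" if "d_mean" in aggregated else "d"
    rh = aggregated[rh_col].to_numpy(dtype=float)
    d = aggregated[d_col].to_numpy(dtype=float)

    high = rh > split_rh
    low = ~high
    if np.unique(rh[high]).size < 2 or np.unique(rh[low]).size < 2:
        raise ValueError(
            f"need >= 2 distinct RH values on each side of {split_rh}% RH")

    hi = stats.linregress(rh[high], d[high])
    lo = stats.linregress(rh[low], d[low])

    d_slope = hi.slope - lo.slope
    if d_slope == 0:
        turnover, parallel = None, True
    else:
        turnover = float((lo.intercept - hi.intercept) / d_slope)
        parallel = False

    return TwoRegimeFit(
        split_rh=float(split_rh),
        high_slope=float(hi.slope), high_intercept=float(hi.intercept),
        high_stderr=float(hi.stderr), high_r2=float(hi.rvalue ** 2),
        low_slope=float(lo.slope), low_intercept=float(lo.intercept),
        low_stderr=float(lo.stderr), low_r2=float(lo.rvalue ** 2),
        turnover_rh=turnover, parallel=parallel,
        n_high=int(high.sum()), n_low=int(low.sum()),
    )


def search_breakpoint(
    aggregated: pd.DataFrame,
    candidates: np.ndarray | None = None,
) -> tuple[float, TwoRegimeFit]:
    """Grid search for the split minimizing the total two-regime SSE.

    An optional refinement over the fixed 55% split: every candidate in
    35-75% RH (5% steps by default) that leaves two distinct RH values
    per side is scored by the summed squared residuals of both lines.
    """
    if candidates is None:
        candidates = np.arange(35.0, 75.0 + 1e-9, 5.0)
    rh_col = "rh_bin" if "rh_bin" in aggregated else "rh"
    d_col = "d_mean" if "d_mean" in aggregated else "d"
    rh = aggregated[rh_col].to_numpy(dtype=float)
    d = aggregated[d_col].to_numpy(dtype=float)

    best: tuple[float, TwoRegimeFit] | None = None
    best_sse = np.inf
    for split in candidates:
        high = rh > split
        if np.unique(rh[high]).size < 2 or np.unique(rh[~high]).size < 2:
            continue
        fit = two_regime_fit(aggregated, split_rh=float(split))
        pred = np.where(high, fit.high_intercept + fit.high_slope * rh,
                        fit.low_intercept + fit.low_slope * rh)
        sse = float(np.sum((d - pred) ** 2))
        if sse < best_sse:
            best_sse = sse
            best = (float(split), fit)
    if best is None:
        raise ValueError("no candidate split leaves 2 distinct RH values per side")
    return best


def _lookup_bin(aggregated: pd.DataFrame, rh: float, bin_width: float = 5.0) -> pd.Series:
    rh_col = "rh_bin" if "rh_bin" in aggregated else "rh"
    target = float(np.round(rh / bin_width) * bin_width)
    rows = aggregated[np.isclose(aggregated[rh_col], target)]
    if rows.empty:
        raise ValueError(f"no aggregated bin at {target}% RH (queried {rh}%)")
    return rows.iloc[0]


def fold_change(
    aggregated: pd.DataFrame,
    rh_high: float,
    rh_low: float,
    bin_width: float = 5.0,
) -> tuple[float, float]:
    """Ratio of mean D between two RH conditions, with propagated sd.

    Returns ``(ratio, sd)`` where the sd combines the two bins' sample
    sds in quadrature on the relative scale.
    """
    hi = _lookup_bin(aggregated, rh_high, bin_width)
    lo = _lookup_bin(aggregated, rh_low, bin_width)
    if lo["d_mean"] == 0:
        raise ValueError("denominator condition has zero mean D")
    ratio = float(hi["d_mean"] / lo["d_mean"])
    rel = 0.0
    for row in (hi, lo):
        if np.isfinite(row["d_sd"]) and row["d_mean"] != 0:
            rel += (row["d_sd"] / row["d_mean"]) ** 2
    return ratio, float(ratio * np.sqrt(rel))


def reversibility_report(
    series: ExperimentSeries,
    bin_width: float = 5.0,
    z_threshold: float = 3.0,
) -> tuple[pd.DataFrame, bool]:
    """Paired dehydration/rehydration differences per RH bin.

    For every RH bin present in both directions the difference of mean
    D is scored as a z value against the pooled standard error; the
    series is flagged reversible when every |z| stays below
    ``z_threshold``.
    """
    agg = aggregate_by_rh(series, bin_width=bin_width)
    deh = agg[agg["direction"] == "dehydration"].set_index("rh_bin")
    reh = agg[agg["direction"] == "rehydration"].set_index("rh_bin")
    common = deh.index.intersection(reh.index)
    if common.empty:
        raise ValueError("no RH bins matched between the two directions")
    rows = []
    for rh_bin in sorted(common):
        a, b = deh.loc[rh_bin], reh.loc[rh_bin]
        diff = float(a["d_mean"] - b["d_mean"])
        var = 0.0
        for row in (a, b):
            if np.isfinite(row["d_sd"]) and row["n"] > 0:
                var += row["d_sd"] ** 2 / row["n"]
        z = diff / np.sqrt(var) if var > 0 else (0.0 if diff == 0 else np.inf)
        rows.append({"rh_bin": float(rh_bin), "d_diff": diff,
                     "pooled_se": float(np.sqrt(var)), "z": float(z),
                     "n_dehydration": int(a["n"]), "n_rehydration": int(b["n"])})
    table = pd.DataFrame(rows)
    reversible = bool((table["z"].abs() < z_threshold).all())
    return table, reversible


@dataclass(frozen=True)
class HydrationIsotherm:
    """Tabulated RH -> water-molecules-per-lipid mapping.

    Anchors combine sorption measurements on stacked PC bilayers with
    the ~12-water first-shell count at full hydration; evaluation is
    linear between anchors and clamped to the end values outside them.
    """

    anchors: tuple[tuple[float, float], ...] = (
        (25.0, 2.4), (50.0, 3.6), (75.0, 6.3), (95.0, 10.9), (100.0, 12.0),
    )

    def __call__(self, rh):
        rh_arr = np.asarray(rh, dtype=float)
        if np.any((rh_arr < 0.0) | (rh_arr > 100.0)):
            raise ValueError("rh must lie in [0, 100]")
        xs = np.array([a[0] for a in self.anchors])
        ys = np.array([a[1] for a in self.anchors])
        out = np.interp(rh_arr, xs, ys)
        return float(out) if np.isscalar(rh) else out


DEFAULT_ISOTHERM = HydrationIsotherm()


def waters_per_lipid(rh) -> float | np.ndarray:
    """Water molecules per lipid at a given %RH (clamped to 2.4 below 25%)."""
    return DEFAULT_ISOTHERM(rh)


def map_series_to_hydration(
    aggregated: pd.DataFrame,
    isotherm: HydrationIsotherm = DEFAULT_ISOTHERM,
) -> pd.DataFrame:
    """Attach waters-per-lipid to each aggregated RH condition."""
    if aggregated.empty:
        raise ValueError("aggregated table is empty")
    rh_col = "rh_bin" if "rh_bin" in aggregated else "rh"
    out = aggregated.copy()
    out["waters_per_lipid"] = isotherm(out[rh_col].to_numpy(dtype=float))
    return out
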