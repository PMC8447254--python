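"""Per-trace FRAP analysis.

A circular spot of radius ``w`` is bleached instantaneously in a planar
membrane and fluorescence recovers as labelled lipids diffuse back in.
For free Brownian lateral diffusion into a hard-edged disk the
normalized recovery follows the Soumpasis solution

    f(t) = exp(-2 tau_D / t) * [I0(2 tau_D / t) + I1(2 tau_D / t)],

with ``tau_D = w**2 / (4 D)`` the characteristic diffusion time of the
spot and ``I0``, ``I1`` modified Bessel functions of the first kind.
Real traces do not start at zero and do not recover fully, so the model
fitted to data is the three-parameter form

    F(t) = b + a * f(t; tau_D),

where ``b`` is the residual fluorescence right after the bleach and
``a`` the recovery amplitude.  The mobile fraction is the amplitude
normalized to the total bleach depth, ``M = a / (1 - b)``, with the
pre-bleach level fixed at 1 by normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike
from scipy import optimize, special, stats

__all__ = [
    "FrapTrace",
    "FitResult",
    "soumpasis_f",
    "recovery_model",
    "normalize_trace",
    "fit_recovery",
    "mobile_fraction",
    "extract_trace_from_stack",
]

#: Lower bound on post-bleach frames for a fittable trace.
MIN_POST_FRAMES = 10


@dataclass
class FrapTrace:
    """One bleach-spot recovery time series.

    ``time`` is in seconds with t = 0 at the first post-bleach frame;
    pre-bleach frames carry negative times.  ``spot_intensity`` is the
    mean (or summed) signal inside the bleached circle and
    ``reference_intensity`` the signal of the rest of the field, used to
    divide out acquisition photobleaching.
    """

    time: np.ndarray
    spot_intensity: np.ndarray
    reference_intensity: np.ndarray
    prebleach_mask: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.spot_intensity = np.asarray(self.spot_intensity, dtype=float)
        self.reference_intensity = np.asarray(self.reference_intensity, dtype=float)
        self.prebleach_mask = np.asarray(self.prebleach_mask, dtype=bool)
        n = self.time.size
        if not (self.spot_intensity.size == self.reference_intensity.size
                == self.prebleach_mask.size == n):
            raise ValueError("all trace arrays must have the same length")
        if n > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.reference_intensity <= 0):
            raise ValueError("reference intensity must be positive everywhere")
        if self.n_prebleach < 1:
            raise ValueError("at least one pre-bleach frame is required")
        if self.n_postbleach < MIN_POST_FRAMES:
            raise ValueError(
                f"at least {MIN_POST_FRAMES} post-bleach frames are required"
            )

    @property
    def n_prebleach(self) -> int:
        return int(self.prebleach_mask.sum())

    @property
    def n_postbleach(self) -> int:
        return int((~self.prebleach_mask).sum())


@dataclass
class FitResult:
    """Fitted Soumpasis parameters and the quantities derived from them.

    ``ciw_*`` are confidence half-widths at ``confidence_level`` from the
    asymptotic (Jacobian-based) covariance with a Student-t quantile.
    ``D = w**2 / (4 tau_d)`` exactly; its half-width is propagated as
    ``|dD/dtau| * ciw_tau``.
    """

    a: float
    b: float
    tau_d: float
    covariance: np.ndarray
    confidence_level: float
    ciw_a: float
    ciw_b: float
    ciw_tau: float
    w: float
    D: float
    ciw_D: float
    mobile_fraction: float
    mobile_fraction_raw: float
    mobile_clipped: bool
    residual_sd: float
    converged: bool
    n_points: int

    def to_dict(self) -> dict:
        d = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.__dict__.items()
        }
        return d


def soumpasis_f(t: ArrayLike, tau_d: float) -> np.ndarray | float:
    """Normalized Soumpasis recovery ``f(t; tau_d)`` in [0, 1].

    Evaluated with exponentially scaled Bessel functions
    (``i0e``/``i1e``), stable for arguments 2*tau_d/t up to 1e4 and
    beyond; f(0) = 0 by continuous extension.
    """
    if tau_d <= 0:
        raise ValueError("tau_d must be positive")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    out = np.zeros_like(t_arr)
    pos = t_arr > 0
    x = 2.0 * tau_d / t_arr[pos]
    out[pos] = special.i0e(x) + special.i1e(x)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out)
    return out


def recovery_model(t: ArrayLike, a: float, b: float, tau_d: float) -> np.ndarray | float:
    """Three-parameter recovery curve ``F(t) = b + a * f(t; tau_d)``."""
    return b + a * soumpasis_f(t, tau_d)


def normalize_trace(raw: FrapTrace) -> FrapTrace:
    """Divide the spot signal by the whole-field reference and rescale.

    The per-frame ratio r(t) = spot/reference cancels acquisition
    photobleaching common to both channels; the ratio is then scaled so
    that its mean over pre-bleach frames equals 1.  Normalizing an
    already-normalized trace is an error, not a no-op.
    """
    if raw.normalized:
        raise ValueError("trace is already normalized")
    ratio = raw.spot_intensity / raw.reference_intensity
    pre_mean = float(ratio[raw.prebleach_mask].mean())
    if pre_mean <= 0:
        raise ValueError("pre-bleach ratio mean must be positive")
    return FrapTrace(
        time=raw.time.copy(),
        spot_intensity=ratio / pre_mean,
        reference_intensity=np.ones_like(ratio),
        prebleach_mask=raw.prebleach_mask.copy(),
        normalized=True,
    )


def _default_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # Half-recovery heuristic for tau_d; robust to moderate noise.
    b0 = float(y[0])
    a0 = float(y[-1]) - b0
    a0 = max(a0, 1e-3)
    b0 = min(max(b0, 0.0), 1.4)
    half = b0 + 0.5 * a0
    above = np.nonzero(y >= half)[0]
    above = above[above > 0]
    if above.size:
        tau0 = float(t[above[0]])
    else:
        tau0 = float(np.median(t[t > 0])) if np.any(t > 0) else 1.0
    tau0 = max(tau0, 1e-6)
    return a0, b0, tau0


def fit_recovery(
    trace: FrapTrace,
    w: float,
    init: tuple[float, float, float] | None = None,
    confidence_level: float = 0.95,
) -> FitResult:
    """Least-squares fit of ``b + a f(t)`` to the post-bleach frames.

    Parameters
    ----------
    trace
        A normalized trace (see :func:`normalize_trace`).
    w
        Bleach-spot radius in micrometres; sets the scale of
        ``D = w**2 / (4 tau_d)``.
    init
        Optional ``(a, b, tau_d)`` starting point; by default ``b`` starts
        at the first post-bleach value, ``a`` at the net recovery, and
        ``tau_d`` at the half-recovery time.
    confidence_level
        Level of the reported confidence half-widths.

    The fit is unweighted, with bounds a, b in [0, 1.5] and
    tau_d in (0, 100 * t_max].  Non-convergence is flagged on the
    result, never silent.
    """
    if not trace.normalized:
        raise ValueError("fit_recovery expects a normalized trace")
    if w <= 0:
        raise ValueError("spot radius w must be positive")
    post = ~trace.prebleach_mask
    t = trace.time[post]
    y = trace.spot_intensity[post]
    if t.size <= 3:
        raise ValueError("need more post-bleach points than parameters")

    x0 = np.asarray(init if init is not None else _default_init(t, y), dtype=float)
    t_max = float(t[-1])
    lower = np.array([0.0, 0.0, 1e-9])
    upper = np.array([1.5, 1.5, 100.0 * t_max])
    x0 = np.clip(x0, lower + 1e-9, upper - 1e-9)

    def residuals(p: np.ndarray) -> np.ndarray:
        return recovery_model(t, *p) - y

    sol = optimize.least_squares(
        residuals, x0, bounds=(lower, upper), method="trf",
        xtol=1e-13, ftol=1e-13, gtol=1e-13,
    )
    converged = bool(sol.status > 0)
    a_hat, b_hat, tau_hat = (float(v) for v in sol.x)

    dof = max(t.size - 3, 1)
    s2 = float(2.0 * sol.cost) / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(jtj)
        converged = False
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    tq = float(stats.t.ppf(0.5 * (1.0 + confidence_level), dof))
    ciw = tq * se

    D = w ** 2 / (4.0 * tau_hat)
    ciw_D = (w ** 2 / (4.0 * tau_hat ** 2)) * float(ciw[2])

    m_raw = a_hat / (1.0 - b_hat) if b_hat < 1.0 else np.inf
    clipped = m_raw > 1.0
    m = min(m_raw, 1.0)

    return FitResult(
        a=a_hat, b=b_hat, tau_d=tau_hat,
        covariance=cov, confidence_level=confidence_level,
        ciw_a=float(ciw[0]), ciw_b=float(ciw[1]), ciw_tau=float(ciw[2]),
        w=float(w), D=float(D), ciw_D=float(ciw_D),
        mobile_fraction=float(m), mobile_fraction_raw=float(m_raw),
        mobile_clipped=bool(clipped),
        residual_sd=float(np.sqrt(s2)), converged=converged,
        n_points=int(t.size),
    )


def mobile_fraction(fit: FitResult) -> float:
    """Mobile fraction ``M = a / (1 - b)``.

    The recovery amplitude is normalized to the total bleach depth
    (pre-bleach level minus post-bleach offset, i.e. 1 - b under the
    pipeline's normalization).  Values above 1 are clipped to 1 with a
    warning; b >= 1 means no bleach depth and is an error.
    """
    if fit.b >= 1.0:
        raise ValueError("b >= 1: no bleach depth, mobile fraction undefined")
    m = fit.a / (1.0 - fit.b)
    if m > 1.0:
        warnings.warn(
            f"mobile fraction {m:.3f} > 1; clipping to 1", stacklevel=2
        )
        return 1.0
    return float(m)


def extract_trace_from_stack(
    stack: np.ndarray,
    center: tuple[float, float],
    radius_px: float,
    *,
    bleach_frame: int,
    frame_interval: float,
) -> FrapTrace:
    """Build a :class:`FrapTrace` from an image time series.

    ``center`` is (row, col) in pixels; pixel centers sit at half-integer
    coordinates with 0-based indexing.  The spot signal is the mean over
    pixels whose center lies within ``radius_px`` of ``center``; the
    reference is the mean over all pixels strictly outside the circle
    (the whole field excluding the bleached spot).  ``bleach_frame`` is
    the index of the first post-bleach frame, which is assigned t = 0.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be a (frames, rows, cols) array")
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    n_frames, n_rows, n_cols = stack.shape
    r0, c0 = center
    if (r0 - radius_px < 0 or c0 - radius_px < 0
            or r0 + radius_px > n_rows or c0 + radius_px > n_cols):
        raise ValueError("bleach circle must lie fully inside the field")
    if not 1 <= bleach_frame <= n_frames - 1:
        raise ValueError("bleach_frame must leave >=1 pre- and post-bleach frame")

    rows = np.arange(n_rows) + 0.5
    cols = np.arange(n_cols) + 0.5
    dist2 = (rows[:, None] - r0) ** 2 + (cols[None, :] - c0) ** 2
    inside = dist2 <= radius_px ** 2
    if not inside.any():
        raise ValueError("no pixel centers fall inside the circle")

    flat = stack.reshape(n_frames, -1)
    spot = flat[:, inside.ravel()].mean(axis=1)
    ref = flat[:, ~inside.ravel()].mean(axis=1)

    time = (np.arange(n_frames) - bleach_frame) * float(frame_interval)
    pre = np.arange(n_frames) < bleach_frame
    return FrapTrace(time=time, spot_intensity=spot, reference_intensity=ref,
                     prebleach_mask=pre, normalized=False)
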