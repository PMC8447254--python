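"""Synthetic inputs for the whole pipeline, with full seed control.

Four generators mirror the four experiments the pipeline analyses:

* a Brownian-dynamics FRAP simulator — point particles diffusing in a
  periodic 2-D box with an instantaneous hard-edged disk bleach; it is
  the independent oracle for the Soumpasis model,
* analytic noisy recovery traces drawn directly from the model curve,
* relative-humidity series with a two-regime ground-truth D(RH) (steep
  above the breakpoint, plateau below) and per-spot lognormal jitter,
* Arrhenius temperature series, and
* phase-separated two-channel membrane images with circular L_o domains
  of controllable size spread and boundary roughness.

Generator defaults reproduce the study design the pipeline targets:
bleach-spot radius 5 um (10 um diameter), highest-hydration D of
1.69 um^2/s at 87% RH falling to a 0.27 um^2/s plateau below 50% RH,
five spots per humidity level on each of three samples, temperatures
spanning 25-45 C, and L_o domains of mean area 1.77 um^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .arrhenius import R_GAS, ArrheniusRecord, ArrheniusSeries
from .domain_morphology import DomainSet
from .frap_core import FrapTrace, soumpasis_f

__all__ = [
    "BrownianSimParams",
    "PiecewiseLinearProfile",
    "RhSeriesSpec",
    "RhTraceRecord",
    "RhSeriesDataset",
    "TemperatureSeriesSpec",
    "MembraneImageSpec",
    "MembraneImage",
    "simulate_frap_brownian",
    "generate_analytic_trace",
    "generate_rh_series",
    "generate_temperature_series",
    "generate_membrane_image",
]


# ---------------------------------------------------------------------------
# Brownian-dynamics FRAP oracle


@dataclass(frozen=True)
class BrownianSimParams:
    """Parameters of the particle-based FRAP simulation.

    The box is periodic and must be at least 10 bleach radii wide so the
    infinite-plane assumption of the recovery model approximately holds.
    ``dt`` (the integration step) may be left ``None``: it is then set
    to the largest value satisfying the step-length bound
    sqrt(2 D dt) <= w/10 that divides the frame interval evenly, which
    also makes traces invariant under the rescaling
    (D, frame_interval) -> (D/k, k*frame_interval).
    """

    n_particles: int = 20_000
    box_size: float = 60.0              # um
    bleach_radius: float = 5.0          # um
    diffusion_coefficient: float = 1.66  # um^2/s
    mobile_fraction: float = 1.0
    bleach_depth: float = 1.0
    dt: float | None = None             # s; None -> auto from step bound
    frame_interval: float | None = None  # s; None -> tau_d / 10
    prebleach_frames: int = 5
    postbleach_frames: int = 120
    acquisition_bleach_rate: float = 0.0  # 1/s
    noise_sd: float = 0.0               # on the normalized trace
    seed: int = 0

    @property
    def tau_d(self) -> float:
        if self.diffusion_coefficient <= 0:
            return math.inf
        return self.bleach_radius ** 2 / (4.0 * self.diffusion_coefficient)

    def resolved_frame_interval(self) -> float:
        if self.frame_interval is not None:
            return self.frame_interval
        if not math.isfinite(self.tau_d):
            return 1.0
        return self.tau_d / 10.0

    def resolved_substeps(self) -> int:
        """Integration substeps per frame satisfying the step bound."""
        dt_cap = self._dt_cap()
        interval = self.resolved_frame_interval()
        if self.dt is not None:
            sub = max(1, int(round(interval / self.dt)))
        else:
            sub = max(1, math.ceil(interval / dt_cap - 1e-12))
        return sub

    def _dt_cap(self) -> float:
        # from sqrt(2 D dt) <= w/10
        D = self.diffusion_coefficient
        if D <= 0:
            return math.inf
        return self.bleach_radius ** 2 / (200.0 * D)

    def validate(self) -> None:
        w = self.bleach_radius
        if w <= 0 or self.box_size <= 0:
            raise ValueError("bleach_radius and box_size must be positive")
        if self.box_size < 10.0 * w:
            raise ValueError("box_size must be >= 10 * bleach_radius")
        if self.n_particles < 1000:
            raise ValueError("need >= 1000 particles")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must lie in [0, 1]")
        if not 0.0 < self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must lie in (0, 1]")
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion coefficient must be non-negative")
        if self.acquisition_bleach_rate < 0:
            raise ValueError("acquisition_bleach_rate must be >= 0")
        if self.prebleach_frames < 1 or self.postbleach_frames < 10:
            raise ValueError("need >= 1 pre-bleach and >= 10 post-bleach frames")
        interval = self.resolved_frame_interval()
        if interval <= 0:
            raise ValueError("frame_interval must be positive")
        eff_dt = interval / self.resolved_substeps()
        step = math.sqrt(2.0 * self.diffusion_coefficient * eff_dt)
        if step > self.bleach_radius / 10.0 + 1e-12:
            raise ValueError(
                f"rms step {step:.3g} um exceeds w/10 = {w / 10:.3g} um; "
                "reduce dt"
            )


def simulate_frap_brownian(
    params: BrownianSimParams,
    *,
    return_stack: bool = False,
    image_px: int = 128,
) -> tuple[FrapTrace, dict]:
    """Run the particle simulation and return (trace, ground truth).

    Particles start uniform in the periodic box; a fixed subset of size
    (1 - M) * n never moves.  At t = 0 every particle inside the bleach
    circle is switched dark with probability ``bleach_depth``.  The spot
    signal is the bright count inside the circle and the reference the
    total bright count, both decayed by the acquisition-bleaching
    exponential; Gaussian noise of sd ``noise_sd`` is added to the
    normalized trace and folded back into the raw spot column so the
    emitted trace is a valid, unprocessed pipeline input.

    The ground-truth dict records D, M, tau_d and the raw bright-count
    time series; with ``return_stack=True`` it also carries a rendered
    (frames, image_px, image_px) particle-count stack.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    n = params.n_particles
    L = params.box_size
    w = params.bleach_radius
    center = L / 2.0
    interval = params.resolved_frame_interval()
    substeps = params.resolved_substeps()
    eff_dt = interval / substeps
    step_sd = math.sqrt(2.0 * params.diffusion_coefficient * eff_dt)

    n_immobile = int(round((1.0 - params.mobile_fraction) * n))
    mobile = np.ones(n, dtype=bool)
    mobile[:n_immobile] = False

    pos = rng.uniform(0.0, L, size=(n, 2))
    bright = np.ones(n, dtype=bool)

    n_pre = params.prebleach_frames
    n_post = params.postbleach_frames
    n_frames = n_pre + n_post
    times = (np.arange(n_frames) - n_pre) * interval

    spot_counts = np.empty(n_frames, dtype=float)
    ref_counts = np.empty(n_frames, dtype=float)
    stack = (np.empty((n_frames, image_px, image_px), dtype=float)
             if return_stack else None)
    edges = np.linspace(0.0, L, image_px + 1) if return_stack else None

    def in_circle() -> np.ndarray:
        d2 = (pos[:, 0] - center) ** 2 + (pos[:, 1] - center) ** 2
        return d2 <= w ** 2

    def record(i: int) -> None:
        inside = in_circle()
        spot_counts[i] = np.count_nonzero(bright & inside)
        ref_counts[i] = np.count_nonzero(bright)
        if return_stack:
            h, _, _ = np.histogram2d(pos[bright, 0], pos[bright, 1],
                                     bins=(edges, edges))
            stack[i] = h

    def advance() -> None:
        if step_sd > 0 and mobile.any():
            steps = rng.normal(0.0, step_sd, size=(int(mobile.sum()), 2))
            pos[mobile] = np.mod(pos[mobile] + steps, L)

    record(0)
    for i in range(1, n_frames):
        for _ in range(substeps):
            advance()
        if i == n_pre:  # instantaneous bleach at t = 0, before this frame
            inside = in_circle()
            dark = inside & (rng.random(n) < params.bleach_depth)
            bright[dark] = False
        record(i)

    decay = np.exp(-params.acquisition_bleach_rate * (times - times[0]))
    spot_raw = spot_counts * decay
    ref_raw = ref_counts * decay

    pre = times < 0
    ratio = spot_raw / ref_raw
    pre_mean = float(ratio[pre].mean())
    normalized = ratio / pre_mean
    if params.noise_sd > 0:
        normalized = normalized + rng.normal(0.0, params.noise_sd,
                                             size=n_frames)
    # fold noise back into the raw spot column: the trace stays a raw
    # (spot, reference) pair that normalize_trace maps onto `normalized`
    spot_out = normalized * pre_mean * ref_raw

    trace = FrapTrace(time=times, spot_intensity=spot_out,
                      reference_intensity=ref_raw, prebleach_mask=pre,
                      normalized=False)
    truth = {
        "D": params.diffusion_coefficient,
        "mobile_fraction": params.mobile_fraction,
        "tau_d": params.tau_d,
        "bleach_depth": params.bleach_depth,
        "spot_counts": spot_counts,
        "ref_counts": ref_counts,
        "prebleach_ratio_mean": pre_mean,
        "frame_interval": interval,
        "substeps": substeps,
        "params": params,
    }
    if return_stack:
        truth["stack"] = stack
        truth["image_px"] = image_px
    return trace, truth


# ---------------------------------------------------------------------------
# Analytic traces


def default_time_grid(tau_d: float, prebleach_frames: int = 5,
                      postbleach_frames: int = 120) -> np.ndarray:
    """Frame times at tau_d/10 spacing, t = 0 at the first post-bleach frame."""
    interval = tau_d / 10.0
    return (np.arange(prebleach_frames + postbleach_frames)
            - prebleach_frames) * interval


def generate_analytic_trace(
    tau_d: float,
    a: float,
    b: float,
    time_grid: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    prebleach_frames: int = 5,
    postbleach_frames: int = 120,
) -> FrapTrace:
    """Draw a trace directly from ``b + a f(t; tau_d)`` plus Gaussian noise.

    Pre-bleach frames (negative times) sit at 1.  The reference channel
    is identically 1, so the trace passes unchanged through the
    pipeline's normalization.  Deterministic for a fixed seed.
    """
    if tau_d <= 0:
        raise ValueError("tau_d must be positive")
    if time_grid is None:
        time_grid = default_time_grid(tau_d, prebleach_frames, postbleach_frames)
    time_grid = np.asarray(time_grid, dtype=float)
    pre = time_grid < 0
    values = np.ones_like(time_grid)
    post_t = time_grid[~pre]
    values[~pre] = b + a * soumpasis_f(post_t, tau_d)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=values.size)
    return FrapTrace(time=time_grid, spot_intensity=values,
                     reference_intensity=np.ones_like(values),
                     prebleach_mask=pre, normalized=False)


# ---------------------------------------------------------------------------
# RH series


@dataclass(frozen=True)
class PiecewiseLinearProfile:
    """Hockey-stick ground truth: flat plateau below the breakpoint,
    linear rise from (breakpoint, plateau) to (high_rh, high_value)
    above it (extrapolated linearly past high_rh)."""

    plateau: float
    breakpoint: float
    high_value: float
    high_rh: float

    def __call__(self, rh):
        rh_arr = np.asarray(rh, dtype=float)
        slope = (self.high_value - self.plateau) / (self.high_rh - self.breakpoint)
        out = np.where(rh_arr <= self.breakpoint, self.plateau,
                       self.plateau + slope * (rh_arr - self.breakpoint))
        return float(out) if np.isscalar(rh) else out


#: D(RH) ground truth: 0.27 um^2/s plateau below 50% RH, 1.69 at 87% RH.
DEFAULT_D_PROFILE = PiecewiseLinearProfile(0.27, 50.0, 1.69, 87.0)
#: M(RH) ground truth: ~45% mobile below 50% RH, 93% at 87% RH.
DEFAULT_MOBILE_PROFILE = PiecewiseLinearProfile(0.45, 50.0, 0.93, 87.0)


@dataclass(frozen=True)
class RhSeriesSpec:
    """Design of a synthetic humidity series.

    Five spots per level on each of three samples by default; per-spot
    jitter on D is lognormal with relative sd ``noise_sd_d`` (mean
    preserving, D stays positive).  ``direction='cycle'`` produces a
    dehydration leg followed by a rehydration leg with identical ground
    truth, emulating a reversible drying/rewetting cycle.
    """

    rh_levels: tuple[float, ...] = (87.0, 70.0, 60.0, 45.0, 30.0, 3.0)
    spots_per_level: int = 5
    samples: int = 3
    d_profile: PiecewiseLinearProfile = DEFAULT_D_PROFILE
    mobile_profile: PiecewiseLinearProfile = DEFAULT_MOBILE_PROFILE
    noise_sd_d: float = 0.15          # relative, lognormal on D
    mobile_jitter_sd: float = 0.02    # absolute, on M
    trace_noise_sd: float = 0.02      # on the normalized trace
    direction: str = "dehydration"    # dehydration | rehydration | cycle
    mode: str = "analytic"            # analytic | brownian
    bleach_depth: float = 0.8
    bleach_radius_um: float = 5.0
    brownian_n_particles: int = 4000
    seed: int = 0

    def validate(self) -> None:
        if len(self.rh_levels) == 0:
            raise ValueError("rh_levels must be non-empty")
        levels = np.asarray(self.rh_levels, dtype=float)
        if np.any((levels < 0) | (levels > 100)):
            raise ValueError("rh_levels must lie in [0, 100]")
        if self.spots_per_level < 1 or self.samples < 1:
            raise ValueError("spots_per_level and samples must be >= 1")
        if np.any(self.d_profile(levels) <= 0):
            raise ValueError("d_profile must be strictly positive")
        if self.direction not in ("dehydration", "rehydration", "cycle"):
            raise ValueError("direction must be dehydration|rehydration|cycle")
        if self.mode not in ("analytic", "brownian"):
            raise ValueError("mode must be analytic|brownian")
        if not 0.0 < self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must lie in (0, 1]")


@dataclass
class RhTraceRecord:
    rh: float
    sample_id: str
    spot_id: str
    direction: str
    phase: str
    trace: FrapTrace
    true_d: float
    true_mobile: float
    level_d: float
    level_mobile: float


@dataclass
class RhSeriesDataset:
    """Generated traces plus metadata and ground truth for one RH series."""

    records: list[RhTraceRecord]
    spec: RhSeriesSpec

    @property
    def bleach_radius_um(self) -> float:
        return self.spec.bleach_radius_um

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"rh_percent": r.rh, "sample_id": r.sample_id, "spot_id": r.spot_id,
             "direction": r.direction, "phase": r.phase,
             "true_d": r.true_d, "true_mobile": r.true_mobile}
            for r in self.records
        ])


def generate_rh_series(spec: RhSeriesSpec) -> RhSeriesDataset:
    """Generate one trace per (leg, RH level, sample, spot).

    Both cycle legs share the same D(RH) and M(RH) truth, so the
    dehydration and rehydration legs differ only through noise — the
    dataset-level ground truth is fully reversible by construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    w = spec.bleach_radius_um

    if spec.direction == "dehydration":
        legs = [("dehydration", sorted(spec.rh_levels, reverse=True))]
    elif spec.direction == "rehydration":
        legs = [("rehydration", sorted(spec.rh_levels))]
    else:
        legs = [("dehydration", sorted(spec.rh_levels, reverse=True)),
                ("rehydration", sorted(spec.rh_levels))]

    sigma = spec.noise_sd_d
    records: list[RhTraceRecord] = []
    for leg_name, levels in legs:
        for rh in levels:
            d_level = float(spec.d_profile(rh))
            m_level = float(np.clip(spec.mobile_profile(rh), 0.02, 0.99))
            for s in range(spec.samples):
                for k in range(spec.spots_per_level):
                    if sigma > 0:
                        ln_sigma = math.sqrt(math.log(1.0 + sigma ** 2))
                        d_spot = d_level * math.exp(
                            rng.normal(0.0, ln_sigma) - 0.5 * ln_sigma ** 2)
                    else:
                        d_spot = d_level
                    m_spot = float(np.clip(
                        m_level + rng.normal(0.0, spec.mobile_jitter_sd)
                        if spec.mobile_jitter_sd > 0 else m_level,
                        0.02, 0.99))
                    child_seed = int(rng.integers(0, 2 ** 31 - 1))
                    b = 1.0 - spec.bleach_depth
                    a = m_spot * spec.bleach_depth
                    if spec.mode == "analytic":
                        tau = w ** 2 / (4.0 * d_spot)
                        trace = generate_analytic_trace(
                            tau, a, b, noise_sd=spec.trace_noise_sd,
                            seed=child_seed)
                    else:
                        sim = BrownianSimParams(
                            n_particles=spec.brownian_n_particles,
                            box_size=max(10.0 * w, 60.0),
                            bleach_radius=w,
                            diffusion_coefficient=d_spot,
                            mobile_fraction=m_spot,
                            bleach_depth=spec.bleach_depth,
                            noise_sd=spec.trace_noise_sd,
                            seed=child_seed,
                        )
                        trace, _ = simulate_frap_brownian(sim)
                    records.append(RhTraceRecord(
                        rh=float(rh), sample_id=f"s{s + 1}",
                        spot_id=f"{leg_name[:3]}-rh{rh:g}-s{s + 1}-p{k + 1}",
                        direction=leg_name, phase="Ld", trace=trace,
                        true_d=float(d_spot), true_mobile=m_spot,
                        level_d=d_level, level_mobile=m_level,
                    ))
    return RhSeriesDataset(records=records, spec=spec)


# ---------------------------------------------------------------------------
# Temperature series


@dataclass(frozen=True)
class TemperatureSeriesSpec:
    """Arrhenius-distributed D(T) with lognormal measurement noise.

    ``d_ref`` anchors the curve at ``t_ref_c``; noise of sd
    ``ln_noise_sd`` is applied to ln D and the emitted per-point half
    widths are the matching delta-method D-scale errors, ready for the
    weighted regression.  Mobile fractions follow a linear trend in T.
    """

    temperatures_c: tuple[float, ...] = (25.0, 30.0, 35.0, 40.0, 45.0)
    e_a_kj_mol: float = 23.0
    d_ref: float = 1.66          # um^2/s at t_ref_c
    t_ref_c: float = 25.0
    ln_noise_sd: float = 0.0
    mobile_ref: float = 0.95
    mobile_slope_per_k: float = 0.0
    sample_id: str = "s1"
    ramp: str = "heating"
    seed: int = 0

    def validate(self) -> None:
        temps = np.asarray(self.temperatures_c, dtype=float)
        if temps.size == 0:
            raise ValueError("temperatures_c must be non-empty")
        if np.any((temps <= 0.0) | (temps >= 100.0)):
            raise ValueError("temperatures must lie strictly inside 0-100 C")
        if self.e_a_kj_mol < 0:
            raise ValueError("activation energy must be non-negative")
        if self.d_ref <= 0:
            raise ValueError("d_ref must be positive")


def generate_temperature_series(spec: TemperatureSeriesSpec) -> ArrheniusSeries:
    """Sample D(T) = exp(ln A - E_a/(R T)) with noise on ln D."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    t_ref_k = spec.t_ref_c + 273.15
    ea_j = spec.e_a_kj_mol * 1000.0
    ln_a = math.log(spec.d_ref) + ea_j / (R_GAS * t_ref_k)

    records = []
    for t_c in spec.temperatures_c:
        t_k = t_c + 273.15
        ln_d = ln_a - ea_j / (R_GAS * t_k)
        if spec.ln_noise_sd > 0:
            ln_d += rng.normal(0.0, spec.ln_noise_sd)
        d = math.exp(ln_d)
        half_width = d * spec.ln_noise_sd  # delta method back to D scale
        mob = float(np.clip(
            spec.mobile_ref + spec.mobile_slope_per_k * (t_k - t_ref_k),
            0.0, 1.0))
        records.append(ArrheniusRecord(
            temperature_k=t_k, d=d, d_half_width=half_width,
            mobile_fraction=mob, sample_id=spec.sample_id, ramp=spec.ramp))
    return ArrheniusSeries(records=records)


# ---------------------------------------------------------------------------
# Membrane images


@dataclass(frozen=True)
class MembraneImageSpec:
    """Two-channel phase-separated membrane image.

    Domains are near-circular blobs placed without overlap by rejection
    sampling; ``jaggedness`` in [0, 1] modulates the boundary radius with
    low-order angular harmonics of that relative amplitude.
    """

    image_size: int = 256
    pixel_size: float = 0.1          # um / px
    n_domains: int = 50
    mean_domain_area: float = 1.77   # um^2
    area_cv: float = 0.2
    jaggedness: float = 0.0
    lo_gain: float = 200.0
    ld_gain: float = 150.0
    background: float = 10.0
    noise_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 8 or self.pixel_size <= 0:
            raise ValueError("invalid image geometry")
        if self.n_domains < 0:
            raise ValueError("n_domains must be >= 0")
        if not 0.0 <= self.jaggedness <= 1.0:
            raise ValueError("jaggedness must lie in [0, 1]")
        if self.mean_domain_area <= 0 or self.area_cv < 0:
            raise ValueError("invalid domain-area parameters")
        field_area = (self.image_size * self.pixel_size) ** 2
        if self.n_domains * self.mean_domain_area >= 0.4 * field_area:
            raise ValueError("requested total domain area exceeds 40% of field")


@dataclass
class MembraneImage:
    """Channels 'lo' (ordered-phase marker) and 'ld' (disordered matrix)."""

    channels: dict[str, np.ndarray]
    pixel_size: float
    spec: MembraneImageSpec | None = None


def _boundary_profile(rng: np.random.Generator, jaggedness: float):
    """Random angular modulation g(theta), |g| <= 1, from harmonics 2-5."""
    if jaggedness == 0:
        return lambda theta: np.zeros_like(theta)
    modes = np.arange(2, 6)
    raw = rng.uniform(0.2, 1.0, size=modes.size)
    amps = raw / raw.sum()
    phases = rng.uniform(0.0, 2.0 * np.pi, size=modes.size)

    def g(theta: np.ndarray) -> np.ndarray:
        return sum(a * np.cos(m * theta + p)
                   for a, m, p in zip(amps, modes, phases))

    return g


def generate_membrane_image(
    spec: MembraneImageSpec,
) -> tuple[MembraneImage, DomainSet]:
    """Render the image and return it with the ground-truth DomainSet.

    Ground-truth areas are the true rasterized pixel counts converted to
    um^2, so segmentation accuracy can be judged against exactly what
    was drawn rather than against the pre-rasterization ideal.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    px = spec.pixel_size

    # sample areas (truncated normal around the mean) and convert to radii
    if spec.n_domains > 0:
        areas = spec.mean_domain_area * (
            1.0 + spec.area_cv * rng.standard_normal(spec.n_domains))
        areas = np.clip(areas, 0.2 * spec.mean_domain_area, None)
        radii_px = np.sqrt(areas / np.pi) / px
    else:
        radii_px = np.empty(0)

    # rejection placement: no overlap, no border contact
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    max_tries = 400 * max(spec.n_domains, 1)
    tries = 0
    for r in radii_px:
        r_eff = r * (1.0 + spec.jaggedness) + 2.0
        while True:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    "could not place all domains without overlap; "
                    "reduce n_domains or mean_domain_area")
            c = tuple(rng.uniform(r_eff, size - r_eff, size=2))
            ok = all(
                (c[0] - c0) ** 2 + (c[1] - c1) ** 2
                > (r_eff + r0 * (1.0 + spec.jaggedness) + 2.0) ** 2
                for (c0, c1), r0 in zip(centers, placed_r))
            if ok:
                centers.append(c)
                placed_r.append(float(r))
                break

    mask = np.zeros((size, size), dtype=bool)
    rows = []
    for label, ((cr, cc), r) in enumerate(zip(centers, placed_r), start=1):
        g = _boundary_profile(rng, spec.jaggedness)
        pad = int(np.ceil(r * (1.0 + spec.jaggedness))) + 2
        r0, r1 = max(int(cr) - pad, 0), min(int(cr) + pad + 1, size)
        c0, c1 = max(int(cc) - pad, 0), min(int(cc) + pad + 1, size)
        yy = np.arange(r0, r1)[:, None] + 0.5 - cr
        xx = np.arange(c0, c1)[None, :] + 0.5 - cc
        dist = np.hypot(yy, xx)
        theta = np.arctan2(yy, xx)
        r_theta = r * (1.0 + spec.jaggedness * g(theta))
        blob = dist <= r_theta
        mask[r0:r1, c0:c1] |= blob
        n_px = int(blob.sum())
        rows.append({
            "label": label,
            "area_um2": n_px * px ** 2,
            "centroid_row_um": cr * px,
            "centroid_col_um": cc * px,
            "circularity": np.nan,
            "touches_border": False,
        })

    lo = spec.background + spec.lo_gain * mask.astype(float)
    ld = spec.background + spec.ld_gain * (~mask).astype(float)
    if spec.noise_sd > 0:
        lo = lo + rng.normal(0.0, spec.noise_sd, size=lo.shape)
        ld = ld + rng.normal(0.0, spec.noise_sd, size=ld.shape)
    lo = np.clip(lo, 0.0, None)
    ld = np.clip(ld, 0.0, None)

    image = MembraneImage(channels={"lo": lo, "ld": ld}, pixel_size=px,
                          spec=spec)
    columns = ["label", "area_um2", "centroid_row_um", "centroid_col_um",
               "circularity", "touches_border"]
    table = pd.DataFrame(rows, columns=columns)
    truth = DomainSet(table=table, pixel_size=px, image_shape=(size, size),
                      source_channel="lo")
    return image, truth
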