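# Methods

## Recovery model and per-trace estimation

The bleached region is treated as a hard-edged disk of radius *w*
bleached instantaneously at *t* = 0 in an unbounded planar membrane with
free Brownian lateral diffusion. Under these assumptions the fractional
recovery of the spot signal is the Soumpasis curve
f(t) = e^(−2τ_D/t)[I₀(2τ_D/t) + I₁(2τ_D/t)] with τ_D = w²/(4D). It is
evaluated with exponentially scaled Bessel functions (`scipy.special
.i0e/i1e`), which keeps it finite and accurate for 2τ_D/t up to 10⁴ and
beyond; f(0) = 0 by continuous extension.

Measured traces are normalized per frame as spot/reference and rescaled
so the pre-bleach mean equals 1. The reference is the whole field
excluding the spot (or, in the simulator, the total bright count), so
any decay common to both channels — acquisition photobleaching —
cancels in the ratio. Normalizing twice is treated as an error because
the operation is not idempotent in the presence of noise.

The fitted model is F(t) = b + a·f(t; τ_D) on post-bleach frames only,
with the pre-bleach level fixed at 1 by the normalization rather than
fitted as a fourth parameter. Fitting is unweighted trust-region least
squares with bounds a, b ∈ [0, 1.5] and τ_D ∈ (0, 100·t_max], started
from b₀ = first post-bleach value, a₀ = net recovery, and τ_D⁰ = the
half-recovery time. Time zero is assigned to the first post-bleach
frame; bleach duration is treated as zero. Confidence half-widths come
from the asymptotic (Jacobian-based) covariance with a Student-t
quantile at a configurable level (default 95%). D = w²/(4τ_D) exactly,
with its half-width propagated as |∂D/∂τ_D|·ciw(τ_D). The mobile
fraction is M = a/(1 − b): amplitude over total bleach depth, the
standard FRAP definition; values marginally above 1 (noise) are clipped
to 1 and flagged. Non-convergence is flagged on the result, never
silent.

## Brownian-dynamics oracle

The simulator is deliberately a *different* model of the same physics:
n ≥ 10³ point particles uniform in a periodic square box of side
≥ 10·w, a fixed immobile subset of size (1 − M)·n, Gaussian
displacement steps of sd √(2DΔt) per axis, and an instantaneous bleach
that darkens particles inside the disk with probability equal to the
bleach depth. The spot signal is the bright count inside the disk and
the reference the total bright count; optional acquisition bleaching
multiplies both by e^(−rate·t), and Gaussian noise is applied on the
normalized scale and folded back into the raw spot column so the
emitted trace is a valid unprocessed pipeline input.

Numerical choices: the integration step is capped so the rms step is at
most w/10 (it otherwise rejects with a diagnostic); when derived
automatically the substep count depends only on the product
D·frame_interval, which makes traces bit-identical under the rescaling
(D, Δ) → (D/k, k·Δ) at a fixed seed. With a 60 µm box (12·w) the
periodic-image bias over a 120-frame acquisition at τ_D/10 spacing is
well below the binomial counting noise; smaller boxes shorten the
effective reservoir and bias recovery fast.

The default frame schedule — 5 pre-bleach frames, 120 post-bleach
frames at τ_D/10 spacing — is a declared package default; acquisition
timing is a free experimental choice, not something the model
constrains. Single-realization fits of simulated traces carry a
10–15% Monte-Carlo spread in D at n = 2×10⁴ because the particle-count
noise is strongly autocorrelated in time; quantitative recovery checks
therefore average several replicate simulated spots, exactly as the
experimental protocol averages at least five bleached spots per
condition.

## RH series: design and aggregation

The synthetic humidity series emulates the dehydration experiment's
design: by default six RH levels (87, 70, 60, 45, 30, 3%), five spots
per level on each of three samples, and a hockey-stick ground truth for
D(RH) — a plateau of 0.27 µm²/s below the 50% RH breakpoint rising
linearly to 1.69 µm²/s at 87% RH — with a matching mobile-fraction
profile (0.93 at high RH, ~0.45 on the plateau, bleach depth 0.8).
Per-spot scatter on D is lognormal with 15% relative sd (mean
preserving, strictly positive), a value chosen to match the
spot-to-spot spread reported for the high-hydration condition; trace
noise is 0.02 on the normalized scale. A `cycle` series generates a
dehydration and a rehydration leg from the *same* ground truth, so
reversibility holds by construction and the reversibility check tests
the pipeline, not the generator.

Aggregation groups fits by hydration-change direction and RH bin
(nearest 5%, reflecting the ±2% humidity control of the conditions) and
reports unweighted means and sample sds — repeated spots are treated as
exchangeable replicates. The two-regime analysis runs separate ordinary
least-squares lines on the per-bin means above and below a fixed 55% RH
split and reports the turnover as the intersection of the two lines;
parallel lines leave the turnover undefined and flagged. A grid-search
breakpoint (minimum total SSE over 35–75% splits) is available as an
extension but the fixed split is the reported procedure. Regressions
are unweighted; fully hydrated (bulk-water) measurements carry no
meaningful RH and are kept out of the two-regime fit. The fold change
between two conditions is the ratio of bin means with the relative sds
combined in quadrature; reversibility is scored per matched bin as a
z-value of the difference in means against the pooled standard error,
with |z| < 3 everywhere flagging the series reversible.

The RH → waters-per-lipid isotherm interpolates linearly between
anchor points (25, 2.4), (50, 3.6), (75, 6.3), (95, 10.9) — averages of
two sorption studies on stacked PC bilayers — plus a (100, 12) anchor
placing the full first hydration shell at saturation; evaluation is
clamped to the end anchors outside their range. The anchors are treated
as exact table values, not fitted.

## Arrhenius estimation

ln D is regressed on 1/T. Each D arrives with a confidence half-width
from its trace fit; the ln-scale standard error is obtained by the
delta method as σ_D/D, and the default weighting uses its reciprocal
(1/σ) as the WLS weight. The uncertainty convention behind
"reciprocal" weights is genuinely ambiguous (1/σ vs 1/σ², D scale vs ln
scale), so an inverse-variance mode and an unweighted mode are also
implemented; on exact data all modes coincide, and any zero half-width
triggers the unweighted fallback. E_a = −slope·R (R = 8.314 J mol⁻¹
K⁻¹) is reported in kJ/mol with its WLS standard error. Temperatures
enter in °C at the interfaces and are converted to Kelvin internally;
heating and cooling ramps are pooled by default. The mobile-fraction
trend is a plain OLS slope per Kelvin with descriptive significance at
the 5% level.

## Membrane images and segmentation

Synthetic images place near-circular L_o domains by rejection sampling
(no overlap, no border contact, total coverage capped below 40% of the
field), with boundary roughness from low-order angular harmonics scaled
by a `jaggedness` amplitude in [0, 1]. Ground-truth areas are the
rasterized pixel counts, so segmentation is judged against exactly what
was drawn. Segmentation itself is a global Otsu threshold on the L_o
channel, 8-connected labelling, removal of components under 4 px, and
exclusion of border-touching components from area statistics to avoid
truncation bias. These algorithmic choices are declared defaults of
this package — the original area measurements' procedure is not
specified anywhere — and the module exists to make the structural
numbers (mean domain area, coarsening percentage) exercisable on
synthetic data.

## What the synthetic data does and does not show

The generators reproduce the *statistical design* of the experiments —
sample sizes, noise scales, ground-truth parameter values — not the
physics they leave out: Gaussian/confocal bleach profiles, diffusion
during a finite bleach, anomalous diffusion, fluorophore photophysics
(including hydration-dependent quantum-yield changes), exchange between
L_o and L_d phases, and 3-D effects are all absent. Passing tests
therefore demonstrate that the estimation chain is correct and
well-calibrated under the stated model, not that the model captures
every feature of real recovery curves.

## Problem sizes and reproducibility

Every stochastic component takes an explicit integer seed and is
bit-reproducible. Default problem sizes are chosen so a full analysis
stays interactive: 2×10⁴ particles and 125 frames per oracle
simulation (~1 s), 90 traces per RH series (~0.4 s to fit), 500
replicates for estimator-calibration studies, 512² px images with 50
domains. The acceptance script averages 20 replicate simulated spots
for the fitted-D check, mirroring multi-spot experimental averaging.
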