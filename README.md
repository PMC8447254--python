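# hydrafrap

Quantitative analysis of **hydration-dependent lipid diffusion** in
supported lipid bilayers (SLBs) from FRAP (fluorescence recovery after
photobleaching) measurements — with a particle-based simulator that can
generate every input the pipeline consumes.

When an SLB is equilibrated against a controlled relative humidity (RH)
instead of bulk water, the number of water molecules hydrating each lipid
head group drops, and with it the lateral mobility of the lipids. This
package implements the full analysis chain used to quantify that effect:

1. **Per-trace fitting** (`frap_core`). A circular spot of radius *w* is
   bleached and the normalized recovery is fitted with the modified
   Soumpasis model

   *F*(*t*) = *b* + *a* · *f*(*t*),  *f*(*t*) = e^(−2τ_D/t) [I₀(2τ_D/t) + I₁(2τ_D/t)],

   giving the diffusion coefficient *D* = *w*²/(4τ_D) and the mobile
   fraction *M* = *a*/(1 − *b*) (recovery amplitude over total bleach
   depth). Traces are normalized spot/reference with the pre-bleach
   level scaled to 1, which divides out acquisition photobleaching.
2. **RH-series aggregation** (`hydration_analysis`). Per-spot fits are
   averaged within RH bins per hydration-change direction; two separate
   linear regressions (above and below a 55% RH split) locate the
   turnover where steep hydration dependence gives way to a plateau;
   fold changes and dehydration/rehydration reversibility are
   quantified; RH is mapped to water molecules per lipid through a
   tabulated sorption isotherm (12 waters ≈ full first shell).
3. **Arrhenius analysis** (`arrhenius`). ln *D* = ln *A* − *E*_a/(*RT*)
   is fitted by weighted linear regression (weights from the reciprocal
   per-point uncertainties) to estimate the diffusion activation energy,
   plus the mobile-fraction-vs-temperature trend.
4. **Domain morphology** (`domain_morphology`). Otsu segmentation and
   area statistics of liquid-ordered (L_o) domains in two-channel
   membrane images, including coarsening (percent area growth).
5. **Synthetic data** (`synthetic_data`). A Brownian-dynamics FRAP
   simulator (periodic box, instantaneous disk bleach, mobile/immobile
   populations) that serves as an independent oracle for the Soumpasis
   model, plus generators for analytic traces, RH series with a
   two-regime ground truth, Arrhenius series, and membrane images —
   all bit-reproducible under a seed.

## Worked example

```python
import hydrafrap as hf
from hydrafrap.hydration_analysis import fit_series

# one noisy trace from the analytic model, fitted back
trace = hf.generate_analytic_trace(3.77, a=0.65, b=0.3, noise_sd=0.02, seed=7)
fit = hf.fit_recovery(hf.normalize_trace(trace), w=5.0)
print(f"D = {fit.D:.3f} +- {fit.ciw_D:.3f} um^2/s, "
      f"mobile fraction = {fit.mobile_fraction:.3f}")

# a full synthetic dehydration series, aggregated and regressed
dataset = hf.generate_rh_series(hf.RhSeriesSpec(seed=0))
agg = hf.aggregate_by_rh(fit_series(dataset))
print(agg[["rh_bin", "d_mean", "d_sd", "n"]].round(3))
print("turnover:", round(hf.two_regime_fit(agg).turnover_rh, 1), "% RH")
print("fold change:", round(hf.fold_change(agg, 87.0, 3.0)[0], 2))
```

prints

```
D = 1.563 +- 0.181 um^2/s, mobile fraction = 0.939
 rh_bin  d_mean  d_sd   n
    5.0   0.267 0.045  15
   30.0   0.274 0.034  15
   45.0   0.270 0.055  15
   60.0   0.610 0.093  15
   70.0   1.056 0.161  15
   85.0   1.705 0.130  15
turnover: 52.2 % RH
fold change: 6.4
```

The fitted *D* of 1.56 ± 0.18 µm²/s recovers the 1.66 µm²/s implied by
the generating τ_D = 3.77 s within its confidence half-width. The
aggregated series reproduces the generator's design: high mobility
(~1.7 µm²/s) at 87% RH, a ~0.27 µm²/s plateau below 50% RH, a >6-fold
drop overall, and a two-regime turnover near 50% RH.

A thin CLI wraps the same functions:

```bash
hydrafrap simulate series --seed 0 --out series/
hydrafrap series --meta series/meta.csv --split-rh 55
hydrafrap fit --trace series/deh-rh87-s1-p1.csv --spot-diameter-um 10
hydrafrap simulate image --seed 5 --out membrane.tif
hydrafrap segment --image membrane.tif --pixel-size-um 0.1
```

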