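# Methods

`perfopt` implements the computational chain of a dual-mode diffuse optical
perfusion monitor for free-flap surveillance: diffuse correlation
spectroscopy (DCS) for a blood-flow surrogate and diffuse reflectance
spectroscopy (DRS) for hemoglobin oximetry, together with simulators that
stand in for the instrument and the animal experiments so every stage can
be exercised offline.

## DCS: from photon arrivals to τ½

Detected single photons arrive as time tags with a tick resolution of
80 ns. Binning onto a regular grid (half-open bins, trailing partial bin
discarded; the default analysis bin is 13 ticks ≈ 1.04 µs so the lag grid
is an exact multiple of the tagger clock) gives the intensity vector `I_j`
from which the normalized intensity autocorrelation

    g2(τ) = ⟨I(t) I(t+τ)⟩ / ⟨I⟩²

is estimated. Three estimators share one normalization convention (a
constant trace gives exactly 1; lag 0, the shot-noise self-term, is always
excluded):

* **FFT, circular** — the inverse transform of the power spectrum, the
  literal periodic estimator.
* **FFT, linear** (default) — zero-padded to ≥ 2N with each lag k
  normalized by its N−k overlapping terms; wrap-around artifacts corrupt
  the long lags of short records, which is why linear is the analysis path.
* **Multitau** — m = 16 linear lags at base resolution, then m/2 new lags
  per bin-doubling level with symmetric (per-lag monitor) normalization;
  the quasi-logarithmic grid of real-time correlators.

A brute-force double-loop estimator with the linear normalization serves
as the oracle in the test suite; FFT(linear) matches it to < 1e-10.
Curves are smoothed by a logarithmic filter: lags are pooled into bins of
1/15 decade (bins centered on the log comb anchored at the first lag, so a
curve already on the target grid passes through unchanged); each output
point is the geometric mean of member lags and arithmetic mean of member
g2 values.

**τ½** is the lag at which g2 has decayed halfway between its top and
bottom plateaus — a model-free flow surrogate chosen instead of a
correlation-diffusion-equation blood-flow-index fit, which would require
optical coefficients that change during occlusion. Because measured curves
rarely show textbook plateaus, the estimator enumerates candidate plateau
windows (all contiguous runs of length 3–5 within the first 10 and last 10
lags of the smoothed curve), keeps (top, bottom) pairs whose contrast
clears a guard (3× the standard deviation of the bottom region by
default), computes one sub-estimate per pair as the first downward
crossing of the midpoint level (interpolated linearly in g2 vs log τ), and
reports the plain mean over the sub-estimate distribution with its
standard deviation as spread. Pairs whose crossing fails are dropped and
counted, never imputed. The estimator is exactly scale-equivariant in the
lag axis.

Known bias: when the smoothed curve's first decade of lags is not well
above the decay (bins coarser than ~τc/250), the top "plateau" samples the
decay itself and τ½ is biased upward by tens of percent. Analysis bins are
therefore chosen ≲ τc/250 for quantitative work; trend monitoring (the
classifier) is insensitive to the common-mode part of this bias.

## DRS: Monte Carlo LUT forward model and inversion

Raw spectra are corrected with dark and 50%-reflectance-standard
measurements, R = 0.5·(raw − dark)/(ref − dark), then smoothed with a
centered moving average (default 5 points, edges shrink). The forward
model is

    R_model(λ) = scale · f_LUT(μa(λ), μs′(λ))
    μs′(λ) = A (λ/λ₀)^−B,            λ₀ = 600 nm
    μa(λ) = ln10 · [HbT] · (StO₂ ε_HbO₂ + (1−StO₂) ε_Hb)

with base-10 molar extinctions. The shipped extinction table
(`data/hb_extinction_synthetic.tsv`) is a synthetic, literature-shaped
compilation reproducing the visible band structure of hemoglobin (double
HbO₂ peak at 542/577 nm, Hb peak at 555 nm, isosbestic crossings near
500/547/571/583 nm, Hb ≫ HbO₂ above 600 nm); all recovery studies are
self-consistent (spectra generated and inverted with the same table), so
conclusions about the inversion machinery do not depend on tabulation
accuracy — absolute [HbT]/StO₂ from real spectra would.

f_LUT is built by photon-packet Monte Carlo in a semi-infinite homogeneous
medium (MCML conventions): exponential steps with μt = μa + μs, implicit
weighted absorption, Henyey–Greenstein scattering with g = 0.9, Fresnel
reflection at the tissue/fiber-face boundary (tissue n = 1.4, silica
n = 1.457), Russian roulette below weight 1e-4 with survival 0.1. Launch
is uniform over the source fiber footprint into the NA = 0.22 acceptance
cone; a packet scores if it exits within the detector footprint
(separation 1.1 mm) inside the NA cone. Because the problem is
azimuthally symmetric, the detector-hit test is replaced by the
azimuth-averaged arc-overlap weight of the exit radius with the detector
disc — unbiased, with ~40× lower variance than the binary test. The
full study grid is 21 μs′ values (0–40 cm⁻¹ step 2; the table is indexed
by μs′ and simulated with μs = μs′/(1−g)) × 12 μa values
(0.01, 0.5, 1, 3, …, 19 cm⁻¹) = 252 cells; recovery studies use a reduced
6×5 grid (μa 0.04–6, μs′ 4–36 cm⁻¹) at 1e5 photons per cell, which covers
the physiologic range of the hemoglobin model over 500–650 nm at desk
scale. μs′ = 0 cells are defined as zero reflectance so the degenerate
column interpolates cleanly. Cell sub-seeds are spawned from one parent
seed; the build is deterministic per seed and platform.

Two independent oracles check the transport: a steady-state
diffusion-approximation closed form (extrapolated-boundary dipole,
Groenhuis internal-reflection parameter) agrees with a matched-boundary
pencil-beam MC tally within 20% in the diffusive regime, and the
Henyey–Greenstein sampler reproduces ⟨cos θ⟩ = g to 1e-3 at 1e6 samples.
The Mie series (Bohren–Huffman, logarithmic-derivative downward
recurrence) supplies the polystyrene-phantom optical properties for the
scalar calibration ratio; it is cross-checked against coefficients
assembled directly from scipy's spherical Bessel functions.

The inversion minimizes the mean absolute percent error between model and
measurement over 500–650 nm (the instrument's reliable range tops out at
650 nm) under box bounds ([HbT] 1–100 µM, StO₂ 0–1, A 2–30 cm⁻¹ at λ₀,
B 0.1–3), using bounded Powell searches from 5 latin-hypercube starts
(fixed seed). During optimization LUT queries are clamped to the hull;
the ftol is 1e-6 with at most 500 iterations per start. The objective is
non-smooth (absolute values), which Powell handles without gradients —
the same role the reference constrained optimizer played in the original
workflow.

## Synthetic data

* **Photon streams.** A unit-variance complex Ornstein–Uhlenbeck field
  E(t) with correlation time τc gives chaotic-light intensity |E|²;
  mixing with a static background sets the Siegert intercept:
  I ∝ (1−√β) + √β|E|² yields exactly g2(τ) = 1 + β e^(−2τ/τc).
  Arrivals are inhomogeneous Poisson on a τc/50 grid, quantized to ticks.
  Defaults 50 kHz and β = 1 (single-mode fiber detection).
* **Flow series.** τc = k/speed — the inverse relation the flow phantom
  demonstrates — so log τ½ regresses on log speed with slope −1; a
  no-flow record has τc much larger than any flowing record.
* **Occlusion protocol.** Clamp gap 3.2 mm held for 2 min, −0.4 mm per
  minute to full occlusion (0.4 mm) at minute 8, held 2 min (4 min in the
  first-animal variant), reopened symmetrically, ~20 min total.
* **Failure trajectories.** Baseline [HbT] = 19 µM, StO₂ = 0.68 (the
  normal post-anastomosis range). Arterial ligation: 1-min time constant,
  flow → 0.05 (residual-motion floor), [HbT] → 10 µM, StO₂ → 0.16.
  Venous congestion: 8-min time constant, flow → 0.10, [HbT] → 50 µM,
  StO₂ → 0.03. Small multiplicative jitter (1.5%) models physiologic
  variability. The generator is constructed so that the sign of the
  [HbT] change alone separates the two failure modes — the premise the
  classifier operationalizes. Magnitudes echo the directional physiology
  ("immediate" arterial vs "gradual" venous), not any animal's measured
  values.
* **Rendering.** Per time point the baseline τc is divided by the flow
  factor (floored) and the spectrum is the LUT forward model at the
  trajectory's ([HbT], StO₂) with multiplicative Gaussian noise (1%);
  everything is deterministic per seed.

What the generator does *not* emulate: probe-coupling variability,
motion artifacts, detector afterpulsing and dead time, inter-animal
physiologic spread, wavelength-dependent system response, and chromophores
beyond hemoglobin. Passing recovery and classification tests therefore
demonstrates correctness of the analysis chain under the stated model, not
field performance on tissue.

## Responses and classification

The response of each parameter is P = 100(ȳ−x̄)/x̄ between the baseline
mean x̄ and response-window mean ȳ, with uncertainty
σ_P = 100·√[(σ_y/x̄)² + (ȳσ_x/x̄²)²] using the standard deviations (not
standard errors) of the contributing scans. Baselines: first-and-last-2-min
edges for short occlusion runs, first three scans for failure simulations.
Scans whose τ½ estimation fails are recorded as missing and excluded from
the means.

Classification thresholds (defaults, configurable): flow +50%, StO₂ −20%,
[HbT] ±20% — well inside the separation the generator produces while
rejecting normal fluctuation. Rule: slowed flow AND desaturation ⇒
compromise; [HbT] up ⇒ venous, down ⇒ arterial, otherwise indeterminate;
no signature ⇒ none.

## Study sizes and numerical choices

Recovery studies run at desk scale: 10-s, 50-kHz streams (20 seeds) for
end-to-end τ½ recovery; 5 pump speeds with duration scaled to ≥ 2000 τc
for the flow power law; the reduced 6×5 LUT at 1e5 photons/cell for
inversion (the 252-cell study grid and 1e7 photons are available through
the same API); 30 monitoring runs (10 per scenario, 16 min at 2-min
cadence, 2.5-s records at 20 kHz) for classification. Analysis bins are
τc/250–τc/500 with lags kept below 1/20 of the record.

Tie-breaks and degenerate inputs: empty photon streams bin to all-zero
traces (valid); all-zero traces have no defined g2 (error); flat curves
raise a flat-curve error that series analysis converts to a missing scan;
out-of-hull LUT queries raise a range error naming the offending axis
except inside the bounded fitter, where they clamp.

## Known limitations

* τ½ is a relative surrogate; no blood-flow index or correlation
  diffusion equation fit is attempted (deliberately out of scope).
* The LUT is geometry-specific (geometry hash stored and checked) and the
  transport model is homogeneous and semi-infinite — no layers, no
  time-resolved or polarized transport.
* The shipped extinction table is synthetic (see above); swap in a
  literature tabulation for absolute oximetry.
* Monte Carlo cells at very low μa are the slowest (deep wandering
  packets) and carry ~10–15% relative noise at 1e5 photons/cell; the
  inversion inherits this as forward-model noise, which the inverse-crime
  studies bypass by construction.
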