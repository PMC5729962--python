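# perfopt

Analysis chain for a compact dual-mode diffuse optical monitor of tissue
perfusion, aimed at post-surgical surveillance of microvascular free
flaps, where early detection of arterial or venous compromise decides
whether a flap can be salvaged. Two complementary modalities are
implemented end to end:

* **Diffuse correlation spectroscopy (DCS).** Multiply scattered coherent
  light forms a speckle pattern whose intensity decorrelates as red blood
  cells move. From photon arrival time tags the package estimates the
  intensity autocorrelation g2(τ) = ⟨I(t)I(t+τ)⟩/⟨I⟩² (FFT, multitau and
  brute-force estimators) and reduces each curve to **τ½**, the lag at
  which g2 has decayed halfway between its top and bottom plateaus — a
  model-free blood-flow surrogate: faster flow ⇒ smaller τ½. Robustness
  to noisy plateaus comes from averaging over many candidate plateau-pair
  sub-estimates.
* **Diffuse reflectance spectroscopy (DRS).** Calibrated reflectance
  spectra are inverted against a Monte-Carlo lookup table
  R_model(λ) = scale·f_LUT(μa(λ), μs′(λ)), with μs′(λ) = A(λ/λ₀)^−B and
  μa(λ) = ln10·[HbT]·(StO₂ ε_HbO₂ + (1−StO₂) ε_Hb), yielding total
  hemoglobin **[HbT]** (µM) and oxygen saturation **StO₂**. The LUT is
  built by photon-packet transport (Henyey–Greenstein, g = 0.9, fiber
  NA 0.22, 1.1-mm source–detector separation) and calibrated against a
  Mie-characterized polystyrene microsphere phantom.

A synthetic-data module generates photon streams with a prescribed
g2(τ) = 1 + β e^(−2τ/τc) (complex Ornstein–Uhlenbeck intensity process),
flow-phantom series with τc ∝ 1/speed, the stepped arterial-occlusion
clamp protocol, and venous/arterial failure trajectories, so the whole
pipeline runs offline. The pipeline module converts measurement series
into baseline-referenced percent responses with propagated uncertainty
and classifies compromise type: flow slows and StO₂ falls in both failure
modes, while **[HbT] rises under venous congestion and falls under
arterial failure** — the sign that separates them.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
import numpy as np
import perfopt as pf

# a 10-s, 50-kHz photon stream whose intensity decorrelates with tauc = 1 ms
stream = pf.simulate_photon_stream(pf.StreamSpec(
    mean_rate_hz=50_000, duration_s=10.0, tauc_s=1e-3, beta=1.0, seed=1))
curve = pf.g2_from_stream(stream, bin_seconds=2e-6, max_lag_s=5e-2)
est = pf.estimate_tau_half(curve)
print(f"photons: {stream.n_photons}")
print(f"tau_half = {est.tau_half*1e3:.4f} ms "
      f"(analytic {1e-3*np.log(2)/2*1e3:.4f} ms), "
      f"spread {est.spread*1e3:.4f} ms over {est.n_pairs} plateau pairs")
```

prints

```
photons: 505263
tau_half = 0.3638 ms (analytic 0.3466 ms), spread 0.0044 ms over 441 plateau pairs
```

The stream realizes ~505k arrivals (50 kHz × 10 s). For the Siegert-form
decay g2 = 1 + e^(−2τ/τc) the half-decay lag is τc·ln2/2 ≈ 0.347 ms; the
full pipeline (binning → FFT autocorrelation → logarithmic smoothing →
plateau-pair averaging over 441 (top, bottom) window pairs) recovers it
within ~5%, with the sub-estimate spread reported alongside.

A command-line interface wraps the same library:

```sh
perfopt build-lut --grid 6x5 --photons 100000 --seed 1 --out lut.h5
perfopt simulate --scenario venous_failure --lut lut.h5 --seed 2 --out run/
perfopt run-occlusion run/ --lut lut.h5 --out report/
```

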