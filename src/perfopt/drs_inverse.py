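"""Diffuse reflectance preprocessing and LUT-based spectral inversion.

Measured reflectance spectra are calibrated against dark and 50%-standard
reference measurements, smoothed with a moving average, and fitted against
the Monte Carlo lookup-table forward model to estimate tissue hemodynamics:

* total hemoglobin concentration [HbT] (uM) and oxygen saturation StO2
  enter through the absorption model
      mu_a(lambda) = ln(10) [HbT] (StO2 eps_HbO2 + (1-StO2) eps_Hb),
  with base-10 molar extinction coefficients;
* reduced scattering follows the tissue power law
      mu_s'(lambda) = A (lambda/lambda_0)^(-B);
* the model spectrum is R(lambda) = scale * f_LUT(mu_a, mu_s'), with a
  single scalar scale calibrated on a Mie-characterized microsphere
  phantom.

The fit minimizes the mean absolute percent error between model and
measurement under box constraints (bounded Powell search, multi-start).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import minimize
from scipy.stats import qmc

from .exceptions import CalibrationError
from .mc_forward import ReflectanceLUT, lut_lookup

LN10 = np.log(10.0)

_STAGES = ("raw", "dark_corrected", "reference_corrected", "smoothed", "calibrated")

DEFAULT_FIT_RANGE_NM = (500.0, 650.0)
DEFAULT_LAMBDA0_NM = 600.0
#: parameter boxes: [HbT] uM, StO2, scattering amplitude A (1/cm at lambda0),
#: scattering power B
DEFAULT_BOUNDS = {
    "hbt_uM": (1.0, 100.0),
    "sto2": (0.0, 1.0),
    "A": (2.0, 30.0),
    "B": (0.1, 3.0),
}


@dataclass(frozen=True)
class ReflectanceSpectrum:
    """A spectrum at one processing stage."""

    wavelengths_nm: np.ndarray
    values: np.ndarray
    stage: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)
        if wl.shape != vals.shape:
            raise ValueError("wavelengths and values must match in length")
        if wl.size > 1 and np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.stage in ("reference_corrected", "smoothed", "calibrated") and (
            vals.size and vals.min() < 0
        ):
            raise ValueError("calibrated reflectance must be >= 0")

    def restrict(self, lo_nm: float, hi_nm: float) -> "ReflectanceSpectrum":
        sel = (self.wavelengths_nm >= lo_nm) & (self.wavelengths_nm <= hi_nm)
        return ReflectanceSpectrum(
            self.wavelengths_nm[sel], self.values[sel], self.stage, dict(self.meta)
        )


@dataclass(frozen=True)
class TissueModelParams:
    """([HbT], StO2, A, B) driving the absorption and scattering models."""

    hbt_uM: float
    sto2: float
    A: float
    B: float
    lambda0_nm: float = DEFAULT_LAMBDA0_NM

    def __post_init__(self):
        if self.hbt_uM < 0:
            raise ValueError("hbt_uM must be >= 0")
        if not 0 <= self.sto2 <= 1:
            raise ValueError("sto2 must be in [0, 1]")
        if self.A < 0:
            raise ValueError("A must be >= 0")
        if self.lambda0_nm <= 0:
            raise ValueError("lambda0_nm must be positive")


@dataclass(frozen=True)
class ExtinctionTable:
    """Base-10 molar extinction of HbO2 and Hb on a common wavelength grid."""

    wavelengths_nm: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray
    source: str = ""

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        e1 = np.asarray(self.eps_hbo2, dtype=float)
        e2 = np.asarray(self.eps_hb, dtype=float)
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "eps_hbo2", e1)
        object.__setattr__(self, "eps_hb", e2)
        if not (wl.shape == e1.shape == e2.shape):
            raise ValueError("table columns must match in length")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if e1.min() <= 0 or e2.min() <= 0:
            raise ValueError("extinction values must be positive")

    def interp(self, wavelengths_nm) -> tuple[np.ndarray, np.ndarray]:
        wl = np.asarray(wavelengths_nm, dtype=float)
        if wl.min() < self.wavelengths_nm[0] or wl.max() > self.wavelengths_nm[-1]:
            raise ValueError(
                f"wavelengths outside table range "
                f"[{self.wavelengths_nm[0]}, {self.wavelengths_nm[-1]}] nm"
            )
        return (
            np.interp(wl, self.wavelengths_nm, self.eps_hbo2),
            np.interp(wl, self.wavelengths_nm, self.eps_hb),
        )


def load_extinction_table() -> ExtinctionTable:
    """The packaged (synthetic, literature-shaped) Hb/HbO2 extinction table."""
    text = resources.files("perfopt.data").joinpath(
        "hb_extinction_synthetic.tsv"
    ).read_text()
    rows = [
        line.split() for line in text.splitlines()
        if line and not line.startswith("#") and not line.startswith("wavelength")
    ]
    data = np.asarray(rows, dtype=float)
    return ExtinctionTable(
        wavelengths_nm=data[:, 0],
        eps_hbo2=data[:, 1],
        eps_hb=data[:, 2],
        source="synthetic compilation shipped with perfopt",
    )


@dataclass(frozen=True)
class FitResult:
    params: TissueModelParams
    objective: float  # mean absolute percent error
    n_iterations: int
    converged: bool
    residual_spectrum: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.objective < 0:
            raise ValueError("objective must be >= 0")


# ---------------------------------------------------------------------------
# preprocessing


def correct_spectrum(
    raw: ReflectanceSpectrum,
    dark: ReflectanceSpectrum,
    reference: ReflectanceSpectrum,
    reference_reflectance: float = 0.5,
) -> ReflectanceSpectrum:
    """System-response correction: R = r_ref * (raw-dark)/(reference-dark)."""
    wl = raw.wavelengths_nm
    if not (
        np.array_equal(wl, dark.wavelengths_nm)
        and np.array_equal(wl, reference.wavelengths_nm)
    ):
        raise ValueError("raw, dark and reference must share one wavelength grid")
    denom = reference.values - dark.values
    if np.any(denom <= 0):
        raise CalibrationError(
            "reference minus dark is non-positive inside the fit range"
        )
    vals = reference_reflectance * (raw.values - dark.values) / denom
    return ReflectanceSpectrum(wl, np.clip(vals, 0.0, None), "reference_corrected")


def smooth_spectrum(spec: ReflectanceSpectrum, window_points: int = 5) -> ReflectanceSpectrum:
    """Centered moving average; edge windows shrink symmetrically."""
    if window_points < 1 or window_points % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window_points > spec.values.size:
        raise ValueError("window longer than the spectrum")
    half = window_points // 2
    vals = spec.values
    out = np.empty_like(vals)
    for i in range(vals.size):
        k = min(half, i, vals.size - 1 - i)
        out[i] = vals[i - k : i + k + 1].mean()
    return ReflectanceSpectrum(spec.wavelengths_nm, out, "smoothed", dict(spec.meta))


# ---------------------------------------------------------------------------
# forward model


def model_mua(params: TissueModelParams, eps: ExtinctionTable, wavelengths_nm) -> np.ndarray:
    """Absorption spectrum (1/cm) from hemoglobin alone."""
    e_hbo2, e_hb = eps.interp(wavelengths_nm)
    hbt_M = params.hbt_uM * 1e-6
    return LN10 * hbt_M * (params.sto2 * e_hbo2 + (1.0 - params.sto2) * e_hb)


def model_musp(params: TissueModelParams, wavelengths_nm) -> np.ndarray:
    """Reduced scattering power law A (lambda/lambda0)^-B (1/cm)."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    return params.A * (wl / params.lambda0_nm) ** (-params.B)


def model_spectrum(
    params: TissueModelParams,
    lut: ReflectanceLUT,
    eps: ExtinctionTable,
    wavelengths_nm,
    scale: float = 1.0,
    clip: bool = False,
) -> ReflectanceSpectrum:
    """Model reflectance: scale * f_LUT(mu_a(lambda), mu_s'(lambda))."""
    wl = np.asarray(wavelengths_nm, dtype=float)
    mua = model_mua(params, eps, wl)
    musp = model_musp(params, wl)
    refl = scale * lut_lookup(lut, mua, musp, clip=clip)
    return ReflectanceSpectrum(wl, refl, "calibrated")


def calibrate_scale(
    measured_phantom: ReflectanceSpectrum,
    phantom_props_by_mie,
    lut: ReflectanceLUT,
) -> float:
    """Least-squares scalar ratio between a measured phantom spectrum and the
    LUT forward model evaluated at its Mie-known optical properties.

    ``phantom_props_by_mie`` maps each wavelength to OpticalProperties; a
    single OpticalProperties is broadcast over the spectrum.
    """
    wl = measured_phantom.wavelengths_nm
    try:
        props_list = [phantom_props_by_mie(w) for w in wl]
    except TypeError:
        props_list = [phantom_props_by_mie] * wl.size
    model = np.array(
        [lut_lookup(lut, p.mua, p.musp) for p in props_list]
    )
    denom = float(np.sum(model**2))
    if denom <= 0:
        raise CalibrationError("degenerate model spectrum: zero everywhere")
    return float(np.sum(measured_phantom.values * model) / denom)


# ---------------------------------------------------------------------------
# inversion


def _objective_factory(measured, lut, eps, scale, lambda0_nm):
    wl = measured.wavelengths_nm
    meas = measured.values
    if np.any(meas <= 0):
        raise ValueError("measured reflectance must be positive in the fit range")
    e_hbo2, e_hb = eps.interp(wl)
    ratio = (wl / lambda0_nm)

    def objective(x):
        hbt, sto2, A, B = x
        mua = LN10 * hbt * 1e-6 * (sto2 * e_hbo2 + (1.0 - sto2) * e_hb)
        musp = A * ratio ** (-B)
        model = scale * lut_lookup(lut, mua, musp, clip=True)
        return float(np.mean(np.abs(model - meas) / meas)) * 100.0

    return objective


def fit_spectrum(
    measured: ReflectanceSpectrum,
    lut: ReflectanceLUT,
    eps: ExtinctionTable,
    scale: float = 1.0,
    bounds: dict | None = None,
    init: TissueModelParams | None = None,
    tol: float = 1e-6,
    n_starts: int = 5,
    seed: int = 0,
    fit_range_nm: tuple[float, float] = DEFAULT_FIT_RANGE_NM,
    lambda0_nm: float = DEFAULT_LAMBDA0_NM,
) -> FitResult:
    """Constrained inversion of a corrected spectrum.

    Minimizes the mean absolute percent error between the LUT model and the
    measurement over ([HbT], StO2, A, B) within box bounds, using bounded
    Powell searches from ``n_starts`` latin-hypercube initial points (plus
    ``init`` when given); the best run is returned.
    """
    if measured.stage not in ("reference_corrected", "smoothed", "calibrated"):
        raise ValueError("measured spectrum must be corrected before fitting")
    spec = measured.restrict(*fit_range_nm)
    if spec.values.size < 8:
        raise ValueError("too few points inside the fit range")
    box = {**DEFAULT_BOUNDS, **(bounds or {})}
    keys = ("hbt_uM", "sto2", "A", "B")
    lo = np.array([box[k][0] for k in keys])
    hi = np.array([box[k][1] for k in keys])
    objective = _objective_factory(spec, lut, eps, scale, lambda0_nm)

    sampler = qmc.LatinHypercube(d=4, seed=seed)
    starts = [lo + (hi - lo) * row for row in sampler.random(n_starts)]
    if init is not None:
        starts.insert(0, np.clip(
            np.array([init.hbt_uM, init.sto2, init.A, init.B]), lo, hi
        ))

    best = None
    n_iter_total = 0
    for x0 in starts:
        res = minimize(
            objective,
            x0,
            method="Powell",
            bounds=list(zip(lo, hi)),
            options={"ftol": tol, "xtol": 1e-8, "maxiter": 500},
        )
        n_iter_total += int(res.nit)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("all optimizer starts failed; see optimizer diagnostics")

    hbt, sto2, A, B = [float(v) for v in best.x]
    params = TissueModelParams(hbt_uM=hbt, sto2=min(max(sto2, 0.0), 1.0), A=A, B=B,
                               lambda0_nm=lambda0_nm)
    model = model_spectrum(params, lut, eps, spec.wavelengths_nm, scale, clip=True)
    return FitResult(
        params=params,
        objective=float(best.fun),
        n_iterations=n_iter_total,
        converged=bool(best.success),
        residual_spectrum=model.values - spec.values,
        meta={"n_starts": len(starts), "message": str(best.message)},
    )


# ---------------------------------------------------------------------------
# TSV I/O


def write_spectrum(spec: ReflectanceSpectrum, path) -> None:
    with open(Path(path), "w") as fh:
        fh.write(f"#stage={spec.stage}\n")
        fh.write("wavelength_nm\tvalue\n")
        for wl, val in zip(spec.wavelengths_nm, spec.values):
            fh.write(f"{float(wl)!r}\t{float(val)!r}\n")


def read_spectrum(path) -> ReflectanceSpectrum:
    stage = "raw"
    rows = []
    with open(Path(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#stage="):
                stage = line.split("=", 1)[1]
            elif not line.startswith("#") and not line.startswith("wavelength"):
                wl, val = line.split("\t")
                rows.append((float(wl), float(val)))
    arr = np.asarray(rows)
    return ReflectanceSpectrum(arr[:, 0], arr[:, 1], stage)
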