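"""Synthetic stand-ins for the instrument and the animal experiments.

Nothing in this package requires hardware: this module generates every
input the analysis pipeline consumes.

* Photon time-tag streams with a prescribed intensity autocorrelation
  g2(tau) = 1 + beta exp(-2 tau / tauc): a complex Ornstein-Uhlenbeck field
  E(t) (correlation time tauc) gives a chaotic-light intensity |E|^2; mixing
  with a static background sets the Siegert intercept beta, and photon
  arrivals are drawn as an inhomogeneous Poisson process. The analytic g2
  makes every downstream estimator testable against a closed form.
* Flow-phantom series: decorrelation time inversely proportional to pump
  speed (tauc = k / speed), the relation the flow-phantom experiment
  demonstrates, plus a quasi-static no-flow record.
* The stepped arterial occlusion protocol of the animal studies (clamp gap
  3.2 -> 0.4 -> 3.2 mm in 0.4-mm steps per minute).
* Hemodynamic trajectories with venous-vs-arterial failure signatures:
  arterial ligation drains the flap (flow, [HbT], StO2 all drop fast);
  venous blockage pools blood ([HbT] rises while StO2 falls, slower time
  constant). Magnitudes are generator defaults anchored to the normal range
  [HbT] ~ 19 uM, StO2 ~ 0.68.
* ``render_experiment`` composes the above into per-time-point (photon
  stream, reflectance spectrum) pairs via the LUT forward model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .drs_inverse import (
    ExtinctionTable,
    ReflectanceSpectrum,
    TissueModelParams,
    model_spectrum,
)
from .mc_forward import ReflectanceLUT
from .photon_stream import DEFAULT_TICK_SECONDS, PhotonTimetagStream

BASELINE_HBT_UM = 19.0
BASELINE_STO2 = 0.68
DEFAULT_SCATTER_A = 20.0
DEFAULT_SCATTER_B = 1.2
FLOW_FLOOR = 0.05  # residual microvascular motion: tauc is never infinite


@dataclass(frozen=True)
class StreamSpec:
    """Target statistics of a simulated photon stream."""

    mean_rate_hz: float = 50_000.0
    duration_s: float = 10.0
    tauc_s: float = 1e-3
    beta: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.mean_rate_hz <= 0 or self.duration_s <= 0 or self.tauc_s <= 0:
            raise ValueError("rate, duration and tauc must be positive")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must be in (0, 1]")


def simulate_photon_stream(
    spec: StreamSpec, tick_seconds: float = DEFAULT_TICK_SECONDS
) -> PhotonTimetagStream:
    """Photon arrivals whose intensity process has the prescribed g2.

    The intensity is I(t) = rate * [c + s |E(t)|^2] with E a unit-variance
    complex OU process, s = sqrt(beta), c = 1 - sqrt(beta): the intensity
    autocorrelation is then exactly 1 + beta exp(-2 tau / tauc). Arrivals
    are an inhomogeneous Poisson process given I(t), discretized on a grid
    of tauc/50 and quantized to tagger ticks. Deterministic given the seed.
    """
    if tick_seconds > spec.tauc_s / 10:
        warnings.warn(
            "tick resolution coarser than tauc/10: decay unresolvable",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    dt = spec.tauc_s / 50.0
    n_cells = int(np.ceil(spec.duration_s / dt))
    rho = np.exp(-dt / spec.tauc_s)
    sig = np.sqrt(1.0 - rho * rho)
    noise = (
        rng.standard_normal(n_cells) + 1j * rng.standard_normal(n_cells)
    ) * np.sqrt(0.5)
    e0 = (rng.standard_normal() + 1j * rng.standard_normal()) * np.sqrt(0.5)
    field_ = lfilter([sig], [1.0, -rho], noise, zi=np.array([rho * e0]))[0]
    s = np.sqrt(spec.beta)
    intensity_rel = (1.0 - s) + s * np.abs(field_) ** 2
    lam = spec.mean_rate_hz * dt * intensity_rel
    counts = rng.poisson(lam)
    total = int(counts.sum())
    cell_starts = np.repeat(np.arange(n_cells) * dt, counts)
    times = cell_starts + rng.random(total) * dt
    times.sort()
    duration_ticks = int(round(spec.duration_s / tick_seconds))
    ticks = np.floor(times / tick_seconds).astype(np.int64)
    ticks = ticks[ticks < duration_ticks]
    return PhotonTimetagStream(
        ticks=ticks,
        duration_ticks=duration_ticks,
        tick_seconds=tick_seconds,
        channel=f"sim-tauc{spec.tauc_s:g}",
    )


def simulate_flow_series(
    dial_speeds,
    k: float,
    base_spec: StreamSpec,
    include_noflow: bool = True,
    noflow_tauc_factor: float = 50.0,
) -> list[tuple[float, PhotonTimetagStream]]:
    """One stream per pump speed with tauc = k / speed.

    Returns (speed, stream) pairs; speed 0.0 labels the no-flow record,
    whose decorrelation time is ``noflow_tauc_factor`` times the slowest
    flowing tauc (quasi-static scatterers, not a frozen speckle).
    """
    speeds = [float(v) for v in dial_speeds]
    if any(v <= 0 for v in speeds):
        raise ValueError("dial speeds must be positive")
    out = []
    if include_noflow:
        tauc_noflow = noflow_tauc_factor * k / min(speeds)
        spec0 = StreamSpec(
            mean_rate_hz=base_spec.mean_rate_hz,
            duration_s=base_spec.duration_s,
            tauc_s=tauc_noflow,
            beta=base_spec.beta,
            seed=base_spec.seed,
        )
        out.append((0.0, simulate_photon_stream(spec0)))
    for i, speed in enumerate(speeds):
        spec = StreamSpec(
            mean_rate_hz=base_spec.mean_rate_hz,
            duration_s=base_spec.duration_s,
            tauc_s=k / speed,
            beta=base_spec.beta,
            seed=base_spec.seed + 1 + i,
        )
        out.append((speed, simulate_photon_stream(spec)))
    return out


# ---------------------------------------------------------------------------
# occlusion protocol


@dataclass(frozen=True)
class OcclusionProtocol:
    """Per-minute Hoffman-clamp gap series (mm)."""

    time_min: np.ndarray
    gap_mm: np.ndarray
    start_gap_mm: float = 3.2
    step_mm: float = 0.4
    full_occlusion_gap_mm: float = 0.4
    variant: str = ""

    def __post_init__(self):
        t = np.asarray(self.time_min, dtype=int)
        g = np.asarray(self.gap_mm, dtype=float)
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "gap_mm", g)
        if t.shape != g.shape:
            raise ValueError("time and gap series must match")
        if g.min() < self.full_occlusion_gap_mm - 1e-9 or g.max() > self.start_gap_mm + 1e-9:
            raise ValueError("gap must stay within [full occlusion, wide open]")

    @property
    def duration_min(self) -> int:
        return int(self.time_min[-1] + 1)

    def gap_at(self, minute: float) -> float:
        idx = min(int(minute), self.time_min.size - 1)
        return float(self.gap_mm[idx])

    def first_full_occlusion_minute(self) -> int:
        hits = np.nonzero(self.gap_mm <= self.full_occlusion_gap_mm + 1e-9)[0]
        if hits.size == 0:
            raise ValueError("protocol never reaches full occlusion")
        return int(self.time_min[hits[0]])


def make_occlusion_protocol(variant: str = "pigs234_hold2") -> OcclusionProtocol:
    """Stepped clamp series: hold wide open 2 min, close 0.4 mm/min to full
    occlusion at minute 8, hold (4 min for the pig1 variant, else 2 min),
    reopen symmetrically, then hold wide open to ~20 min total."""
    if variant not in ("pig1_hold4", "pigs234_hold2"):
        raise ValueError(f"unknown variant {variant!r}")
    hold = 4 if variant == "pig1_hold4" else 2
    gaps = [3.2, 3.2]  # minutes 0 and 1: baseline hold
    gaps += [3.2 - 0.4 * k for k in range(1, 8)]  # minutes 2..8: close
    gaps += [0.4] * (hold - 1)  # remaining full-occlusion minutes
    gaps += [0.4 + 0.4 * k for k in range(1, 8)]  # reopen to 3.2
    while len(gaps) < 20:
        gaps.append(3.2)
    gap_mm = np.round(np.asarray(gaps), 6)  # exact 0.4-mm levels
    return OcclusionProtocol(
        time_min=np.arange(gap_mm.size),
        gap_mm=gap_mm,
        variant=variant,
    )


# ---------------------------------------------------------------------------
# hemodynamic trajectories


@dataclass(frozen=True)
class HemodynamicTrajectory:
    """Ground-truth time courses of flow, [HbT] and StO2 for one scenario."""

    time_s: np.ndarray
    flow_factor: np.ndarray
    hbt_uM: np.ndarray
    sto2: np.ndarray
    scenario: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("time_s", "flow_factor", "hbt_uM", "sto2"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (
            self.time_s.shape == self.flow_factor.shape == self.hbt_uM.shape == self.sto2.shape
        ):
            raise ValueError("trajectory series must share one length")
        if self.flow_factor.min() < 0 or self.flow_factor.max() > 1:
            raise ValueError("flow_factor must be in [0, 1]")
        if self.sto2.min() < 0 or self.sto2.max() > 1:
            raise ValueError("sto2 must be in [0, 1]")
        if self.hbt_uM.min() < 0:
            raise ValueError("hbt must be >= 0")


SCENARIOS = ("normal", "arterial_failure", "venous_failure")

# plateaus and time constants for the failure scenarios: arterial ligation is
# near-immediate (1-min time constant, flap drains and desaturates); venous
# blockage pools blood over ~8 min
_SCENARIO_DYNAMICS = {
    "arterial_failure": {
        "tau_min": 1.0,
        "flow_end": FLOW_FLOOR,
        "hbt_end": 10.0,
        "sto2_end": 0.16,
    },
    "venous_failure": {
        "tau_min": 8.0,
        "flow_end": 0.10,
        "hbt_end": 50.0,
        "sto2_end": 0.03,
    },
}


def simulate_failure_trajectory(
    scenario: str,
    duration_min: float = 16.0,
    seed: int = 0,
    cadence_s: float = 7.0,
    event_min: float = 3.0,
    noise_sd: float = 0.015,
) -> HemodynamicTrajectory:
    """Ground-truth hemodynamics for one monitoring run.

    Baseline values hold until ``event_min`` (normal runs have no event);
    afterwards each parameter relaxes exponentially toward its scenario
    plateau. Small multiplicative Gaussian fluctuations model physiologic
    variability.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min * 60.0 + 1e-9, cadence_s)
    flow = np.ones_like(t)
    hbt = np.full_like(t, BASELINE_HBT_UM)
    sto2 = np.full_like(t, BASELINE_STO2)
    if scenario != "normal":
        dyn = _SCENARIO_DYNAMICS[scenario]
        elapsed = np.clip(t / 60.0 - event_min, 0.0, None)
        relax = 1.0 - np.exp(-elapsed / dyn["tau_min"])
        flow = 1.0 + (dyn["flow_end"] - 1.0) * relax
        hbt = BASELINE_HBT_UM + (dyn["hbt_end"] - BASELINE_HBT_UM) * relax
        sto2 = BASELINE_STO2 + (dyn["sto2_end"] - BASELINE_STO2) * relax
    jitter = lambda x: x * (1.0 + noise_sd * rng.standard_normal(t.size))  # noqa: E731
    return HemodynamicTrajectory(
        time_s=t,
        flow_factor=np.clip(jitter(flow), 0.0, 1.0),
        hbt_uM=np.clip(jitter(hbt), 0.0, None),
        sto2=np.clip(jitter(sto2), 0.0, 1.0),
        scenario=scenario,
        meta={"seed": seed, "event_min": event_min, "noise_sd": noise_sd},
    )


def trajectory_from_protocol(
    protocol: OcclusionProtocol,
    cadence_s: float = 7.0,
    seed: int = 0,
    noise_sd: float = 0.01,
) -> HemodynamicTrajectory:
    """Hemodynamics driven by the clamp gap.

    The measured occlusion response is near-binary: flow collapses only at
    nearly full occlusion. Modelled with a sharp logistic in the gap around
    0.6 mm; [HbT] and StO2 track the flow deficit with a 1-min lag.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, protocol.duration_min * 60.0, cadence_s)
    gaps = np.array([protocol.gap_at(m) for m in t / 60.0])
    flow = 1.0 / (1.0 + np.exp(-(gaps - 0.6) / 0.08))
    # first-order lag of the slow chromophore pools behind the flow state
    alpha = 1.0 - np.exp(-cadence_s / 60.0)
    lagged = np.empty_like(flow)
    acc = 1.0
    for i, f in enumerate(flow):
        acc += alpha * (f - acc)
        lagged[i] = acc
    hbt = BASELINE_HBT_UM * (0.55 + 0.45 * lagged)
    sto2 = BASELINE_STO2 * (0.25 + 0.75 * lagged)
    jitter = lambda x: x * (1.0 + noise_sd * rng.standard_normal(t.size))  # noqa: E731
    return HemodynamicTrajectory(
        time_s=t,
        flow_factor=np.clip(flow, 0.0, 1.0),
        hbt_uM=np.clip(jitter(hbt), 0.0, None),
        sto2=np.clip(jitter(sto2), 0.0, 1.0),
        scenario="occlusion_protocol",
        meta={"variant": protocol.variant, "seed": seed},
    )


# ---------------------------------------------------------------------------
# end-to-end rendering


@dataclass(frozen=True)
class ExperimentRecord:
    """One acquisition cycle: a DCS stream and a DRS spectrum."""

    time_s: float
    stream: PhotonTimetagStream
    spectrum: ReflectanceSpectrum


def render_experiment(
    trajectory: HemodynamicTrajectory,
    lut: ReflectanceLUT,
    eps: ExtinctionTable,
    stream_spec: StreamSpec | None = None,
    noise: float = 0.01,
    seed: int = 0,
    wavelengths_nm=None,
    scatter_A: float = DEFAULT_SCATTER_A,
    scatter_B: float = DEFAULT_SCATTER_B,
    scale: float = 1.0,
) -> list[ExperimentRecord]:
    """Render a trajectory into raw measurements.

    Per time point: the DCS decorrelation time is the baseline tauc divided
    by the flow factor (floored at the residual-motion level), and the DRS
    spectrum is the LUT forward model at the trajectory's ([HbT], StO2) with
    multiplicative Gaussian noise. Deterministic given the seed.
    """
    if stream_spec is None:
        stream_spec = StreamSpec(mean_rate_hz=20_000.0, duration_s=3.0)
    if wavelengths_nm is None:
        wavelengths_nm = np.arange(500.0, 650.0 + 1e-9, 2.0)
    rng = np.random.default_rng(seed)
    records = []
    for i, t in enumerate(trajectory.time_s):
        flow = max(float(trajectory.flow_factor[i]), FLOW_FLOOR)
        spec_i = StreamSpec(
            mean_rate_hz=stream_spec.mean_rate_hz,
            duration_s=stream_spec.duration_s,
            tauc_s=stream_spec.tauc_s / flow,
            beta=stream_spec.beta,
            seed=int(
                np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31 - 1)
            ),
        )
        stream = simulate_photon_stream(spec_i)
        params = TissueModelParams(
            hbt_uM=float(trajectory.hbt_uM[i]),
            sto2=float(trajectory.sto2[i]),
            A=scatter_A,
            B=scatter_B,
        )
        model = model_spectrum(params, lut, eps, wavelengths_nm, scale=scale)
        vals = model.values
        if noise > 0:
            vals = vals * (1.0 + noise * rng.standard_normal(vals.size))
        spectrum = ReflectanceSpectrum(
            np.asarray(wavelengths_nm, dtype=float),
            np.clip(vals, 0.0, None),
            "reference_corrected",
        )
        records.append(ExperimentRecord(time_s=float(t), stream=stream, spectrum=spectrum))
    return records
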