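"""End-to-end analysis: streams -> tau_1/2 series, spectra -> [HbT]/StO2
series, baseline-referenced percent responses with propagated uncertainty,
and venous-vs-arterial classification.

The response of each perfusion parameter is the percent difference between
its baseline mean and its response-window mean, with uncertainty from the
standard propagation-of-error formula treating the two means as independent
with the sample standard deviations of the contributing scans. The
compromise classifier operationalizes the directional signature that
separates failure modes: flow slows (tau_1/2 up) and StO2 falls in both,
while [HbT] rises under venous congestion (blood pools) and falls under
arterial failure (the flap drains).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic
from .correlator import g2_from_stream
from .drs_inverse import ExtinctionTable, fit_spectrum, read_spectrum, smooth_spectrum
from .exceptions import FlatCurveError, NoCrossingError, PerfoptError
from .mc_forward import ReflectanceLUT
from .photon_stream import read_timetags
from .tau_half import PlateauConfig, estimate_tau_half


@dataclass(frozen=True)
class ResponseMeasure:
    """Percent change from baseline with propagated uncertainty."""

    percent_change: float
    uncertainty: float
    baseline_mean: float
    baseline_sd: float
    response_mean: float
    response_sd: float
    n_baseline: int
    n_response: int

    def __post_init__(self):
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")


@dataclass(frozen=True)
class CompromiseCall:
    """Classifier output with the per-parameter evidence behind it."""

    label: str  # none | arterial | venous | indeterminate
    evidence: dict = field(default_factory=dict)


def percent_change(baseline, response) -> ResponseMeasure:
    """P = 100 (ybar - xbar)/xbar with propagation-of-error uncertainty.

    sigma_P = 100 sqrt[(sigma_y/xbar)^2 + (ybar sigma_x / xbar^2)^2],
    treating the baseline and response means as independent, each carrying
    the standard deviation of its contributing scans.
    """
    x = np.asarray(baseline, dtype=float)
    y = np.asarray(response, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("baseline and response must be non-empty")
    xbar, ybar = x.mean(), y.mean()
    if xbar == 0:
        raise ZeroDivisionError("zero baseline mean: percent change undefined")
    sx, sy = x.std(ddof=0), y.std(ddof=0)
    p = 100.0 * (ybar - xbar) / xbar
    sigma = 100.0 * np.sqrt((sy / xbar) ** 2 + (ybar * sx / xbar**2) ** 2)
    return ResponseMeasure(
        percent_change=float(p),
        uncertainty=float(sigma),
        baseline_mean=float(xbar),
        baseline_sd=float(sx),
        response_mean=float(ybar),
        response_sd=float(sy),
        n_baseline=int(x.size),
        n_response=int(y.size),
    )


def select_baseline(times_s, mode: str = "edges_2min") -> np.ndarray:
    """Boolean mask of baseline scans.

    ``edges_2min``: scans in the first and last 2 minutes (short occlusion
    protocols, clamp wide open at both ends). ``first_three``: the first
    three scans (failure-simulation protocols).
    """
    t = np.asarray(times_s, dtype=float)
    if mode == "edges_2min":
        if t[-1] - t[0] < 240.0:
            raise ValueError(
                "series shorter than 4 min: edge baseline windows overlap"
            )
        return (t < t[0] + 120.0) | (t > t[-1] - 120.0)
    if mode == "first_three":
        if t.size < 3:
            raise ValueError("need at least 3 scans for first_three baseline")
        mask = np.zeros(t.size, dtype=bool)
        mask[:3] = True
        return mask
    raise ValueError(f"unknown baseline mode {mode!r}")


def select_response(times_s, mode: str = "last_three", window_s=None) -> np.ndarray:
    """Boolean mask of response scans: ``last_three`` scans, or an explicit
    (t0, t1) window in seconds (e.g. the full-occlusion plateau)."""
    t = np.asarray(times_s, dtype=float)
    if mode == "window":
        if window_s is None:
            raise ValueError("window mode needs window_s=(t0, t1)")
        t0, t1 = window_s
        return (t >= t0) & (t <= t1)
    if mode == "last_three":
        if t.size < 3:
            raise ValueError("need at least 3 scans for last_three response")
        mask = np.zeros(t.size, dtype=bool)
        mask[-3:] = True
        return mask
    raise ValueError(f"unknown response mode {mode!r}")


DEFAULT_THRESHOLDS = {"flow": 50.0, "sto2": 20.0, "hbt": 20.0}


def classify_compromise(
    responses: dict[str, ResponseMeasure],
    thresholds: dict[str, float] | None = None,
) -> CompromiseCall:
    """Sign-logic classifier on (tau_half, sto2, hbt) percent responses.

    A compromise requires slowed flow (tau_half response above the flow
    threshold) and desaturation (sto2 response below minus its threshold);
    the [HbT] direction then separates venous (up) from arterial (down).
    A flow/oxygen signature without a clear [HbT] direction is
    indeterminate; no signature at all is 'none' (or indeterminate if some
    parameter moved beyond threshold without the compromise pattern).
    """
    thr = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    missing = {"tau_half", "sto2", "hbt"} - responses.keys()
    if missing:
        raise ValueError(f"missing responses for: {sorted(missing)}")
    flow_p = responses["tau_half"].percent_change
    sto2_p = responses["sto2"].percent_change
    hbt_p = responses["hbt"].percent_change
    evidence = {"tau_half": flow_p, "sto2": sto2_p, "hbt": hbt_p}
    if flow_p > thr["flow"] and sto2_p < -thr["sto2"]:
        if hbt_p > thr["hbt"]:
            return CompromiseCall("venous", evidence)
        if hbt_p < -thr["hbt"]:
            return CompromiseCall("arterial", evidence)
        return CompromiseCall("indeterminate", evidence)
    if (
        abs(flow_p) <= thr["flow"]
        and abs(sto2_p) <= thr["sto2"]
        and abs(hbt_p) <= thr["hbt"]
    ):
        return CompromiseCall("none", evidence)
    return CompromiseCall("indeterminate", evidence)


# ---------------------------------------------------------------------------
# series analysis


def analyze_experiment(
    records,
    lut: ReflectanceLUT,
    eps: ExtinctionTable,
    scale: float = 1.0,
    dcs_bin_seconds: float | None = None,
    dcs_max_lag_s: float | None = None,
    plateau_cfg: PlateauConfig | None = None,
    smooth_window: int = 5,
    fit_seed: int = 0,
) -> pd.DataFrame:
    """Per-scan tau_1/2 and DRS fit for a rendered or loaded experiment.

    Scans whose tau_1/2 estimation fails (flat curve, no crossing) are
    recorded as NaN and counted, never aborting the series.
    """
    rows = []
    for rec in records:
        row = {"time_s": rec.time_s, "tau_half_s": np.nan, "tau_half_spread_s": np.nan,
               "n_pairs": 0, "dcs_failed": False}
        try:
            curve = g2_from_stream(
                rec.stream, bin_seconds=dcs_bin_seconds, max_lag_s=dcs_max_lag_s
            )
            est = estimate_tau_half(curve, plateau_cfg)
            row.update(
                tau_half_s=est.tau_half,
                tau_half_spread_s=est.spread,
                n_pairs=est.n_pairs,
            )
        except (FlatCurveError, NoCrossingError, ValueError):
            row["dcs_failed"] = True
        row.update(hbt_uM=np.nan, sto2=np.nan, A=np.nan, B=np.nan,
                   fit_objective=np.nan, drs_failed=False)
        try:
            spec = rec.spectrum
            if smooth_window > 1:
                spec = smooth_spectrum(spec, smooth_window)
            fit = fit_spectrum(spec, lut, eps, scale=scale, seed=fit_seed)
            row.update(
                hbt_uM=fit.params.hbt_uM,
                sto2=fit.params.sto2,
                A=fit.params.A,
                B=fit.params.B,
                fit_objective=fit.objective,
            )
        except (PerfoptError, ValueError, RuntimeError):
            row["drs_failed"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def compute_responses(
    series: pd.DataFrame,
    baseline_mode: str = "first_three",
    response_mode: str = "last_three",
    response_window_s=None,
) -> dict[str, ResponseMeasure]:
    """Baseline-vs-response percent changes for tau_1/2, StO2 and [HbT]."""
    t = series["time_s"].to_numpy()
    base = select_baseline(t, baseline_mode)
    resp = select_response(t, response_mode, response_window_s)
    out = {}
    for key, col in (("tau_half", "tau_half_s"), ("sto2", "sto2"), ("hbt", "hbt_uM")):
        vals = series[col].to_numpy()
        out[key] = percent_change(vals[base], vals[resp])
    return out


def run_occlusion_analysis(data_dir, out_dir=None, config: dict | None = None) -> dict:
    """Analyze a simulated (or same-layout) experiment directory.

    Expects ``timetags/t####.csv``, ``spectra/t####.tsv`` and ``times.tsv``
    as written by the ``perfopt simulate`` command; writes ``series.tsv``
    and ``responses.json`` when ``out_dir`` is given and returns the report
    as a dict.
    """
    cfg = config or {}
    data_dir = Path(data_dir)
    times = np.loadtxt(data_dir / "times.tsv", ndmin=1)
    tag_files = sorted((data_dir / "timetags").glob("t*"))
    spec_files = sorted((data_dir / "spectra").glob("t*"))
    if not (len(times) == len(tag_files) == len(spec_files)):
        raise ValueError("times, timetags and spectra are inconsistent")
    records = [
        synthetic.ExperimentRecord(
            time_s=float(t),
            stream=read_timetags(f),
            spectrum=read_spectrum(s),
        )
        for t, f, s in zip(times, tag_files, spec_files)
    ]
    from .mc_forward import load_lut
    from .drs_inverse import load_extinction_table

    lut = load_lut(cfg["lut_path"]) if "lut_path" in cfg else cfg["lut"]
    eps = cfg.get("eps") or load_extinction_table()
    series = analyze_experiment(
        records,
        lut,
        eps,
        scale=cfg.get("scale", 1.0),
        dcs_bin_seconds=cfg.get("dcs_bin_seconds"),
        dcs_max_lag_s=cfg.get("dcs_max_lag_s"),
        fit_seed=cfg.get("seed", 0),
    )
    responses = compute_responses(
        series,
        baseline_mode=cfg.get("baseline_mode", "first_three"),
        response_mode=cfg.get("response_mode", "last_three"),
        response_window_s=cfg.get("response_window_s"),
    )
    call = classify_compromise(responses, cfg.get("thresholds"))
    report = {
        "responses": {k: asdict(v) for k, v in responses.items()},
        "classification": {"label": call.label, "evidence": call.evidence},
        "n_scans": int(len(series)),
        "n_dcs_failed": int(series["dcs_failed"].sum()),
        "n_drs_failed": int(series["drs_failed"].sum()),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        series.to_csv(out_dir / "series.tsv", sep="\t", index=False)
        with open(out_dir / "responses.json", "w") as fh:
            json.dump(report, fh, indent=2)
    return report
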