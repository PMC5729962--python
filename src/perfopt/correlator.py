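"""Intensity autocorrelation estimators for DCS.

Three interchangeable estimators of the normalized intensity autocorrelation
g2(tau) = <I(t) I(t+tau)> / <I>^2 from a binned photon trace:

``g2_fft``
    FFT-based estimator. ``mode="circular"`` is the literal periodic form
    (inverse transform of the power spectrum); ``mode="linear"`` zero-pads
    to at least twice the record and normalizes each lag k by the N-k
    overlapping terms, avoiding wrap-around artifacts on short records.
    Linear mode is the default analysis path.
``g2_multitau``
    The classic quasi-logarithmic correlator: m linear lags at base
    resolution then m/2 new lags per bin-doubling level, with symmetric
    (per-lag monitor) normalization.
``g2_direct``
    A literal double-loop estimator with the linear-mode normalization,
    kept as the brute-force oracle the fast paths are validated against.

All estimators exclude lag zero (the shot-noise self-term) and normalize so
that a constant trace gives g2 = 1 exactly at every lag. Curves can be
smoothed with ``log_downsample``, which averages lags within logarithmically
spaced bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft

from .photon_stream import IntensityTrace


@dataclass(frozen=True)
class AutocorrelationCurve:
    """A g2 curve on a strictly increasing positive lag grid (seconds)."""

    lags: np.ndarray
    g2: np.ndarray
    method: str
    n_photons: int = 0
    duration_seconds: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        lags = np.asarray(self.lags, dtype=float)
        g2 = np.asarray(self.g2, dtype=float)
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "g2", g2)
        if lags.shape != g2.shape:
            raise ValueError("lags and g2 must have the same length")
        if lags.size:
            if lags[0] <= 0:
                raise ValueError("lag 0 (and negative lags) are excluded")
            if np.any(np.diff(lags) <= 0):
                raise ValueError("lags must be strictly increasing")
            if not np.all(np.isfinite(g2)):
                raise ValueError("g2 values must be finite")

    def __len__(self) -> int:
        return int(self.lags.size)


def _check_trace(trace: IntensityTrace) -> tuple[np.ndarray, float]:
    counts = np.asarray(trace.counts, dtype=float)
    if counts.size < 2:
        raise ValueError("trace must have at least 2 bins")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("all-zero trace: g2 normalization undefined")
    return counts, mean


def g2_fft(trace: IntensityTrace, mode: str = "linear") -> AutocorrelationCurve:
    """Estimate g2 via FFT of the intensity trace.

    Circular mode: g2(k) = (1/N) sum_j I_j I_{(j+k) mod N} / <I>^2, the
    inverse transform of the power spectrum. Linear mode: zero-pad to at
    least 2N so products never wrap, then normalize lag k by the N-k
    overlapping terms and <I>^2.
    """
    counts, mean = _check_trace(trace)
    n = counts.size
    if mode == "circular":
        spec = rfft(counts, n)
        raw = irfft(spec * np.conj(spec), n)
        g2 = raw[1:] / (n * mean**2)
    elif mode == "linear":
        nfft = next_fast_len(2 * n)
        spec = rfft(counts, nfft)
        raw = irfft(spec * np.conj(spec), nfft)[:n]
        overlap = n - np.arange(1, n)
        g2 = raw[1:] / (overlap * mean**2)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    lags = np.arange(1, n) * trace.bin_seconds
    return AutocorrelationCurve(
        lags=lags,
        g2=g2,
        method="fft",
        n_photons=int(trace.counts.sum()),
        duration_seconds=trace.duration_seconds,
        meta={"mode": mode, "bin_seconds": trace.bin_seconds},
    )


def g2_direct(trace: IntensityTrace, lag_bins) -> AutocorrelationCurve:
    """Brute-force estimator, lag by lag; the oracle for ``g2_fft(linear)``."""
    counts, mean = _check_trace(trace)
    n = counts.size
    lag_bins = np.asarray(lag_bins, dtype=int)
    if lag_bins.size and (lag_bins.min() < 1 or lag_bins.max() >= n):
        raise ValueError("lag offsets must satisfy 1 <= k < n_bins")
    g2 = np.empty(lag_bins.size)
    for i, k in enumerate(lag_bins):
        g2[i] = np.dot(counts[:-k], counts[k:]) / ((n - k) * mean**2)
    return AutocorrelationCurve(
        lags=lag_bins * trace.bin_seconds,
        g2=g2,
        method="direct",
        n_photons=int(trace.counts.sum()),
        duration_seconds=trace.duration_seconds,
        meta={"bin_seconds": trace.bin_seconds},
    )


def g2_multitau(trace: IntensityTrace, m: int = 16, levels: int | None = None) -> AutocorrelationCurve:
    """Multitau estimator: m base lags then m/2 new lags per doubling level.

    Symmetric normalization: each lag k is normalized by the means of the
    left and right monitor segments, which makes the estimate exactly
    invariant under count scaling and unbiased for slow drifts.
    """
    if m < 8 or m % 2:
        raise ValueError("m must be even and >= 8")
    counts, _ = _check_trace(trace)
    if levels is None:
        # deepest level still keeping >= 2m samples after doubling
        levels = max(1, int(np.floor(np.log2(counts.size / (2 * m)))) + 1)
    if levels < 1:
        raise ValueError("levels must be >= 1")

    def _sym(x: np.ndarray, k: int) -> float:
        a, b = x[:-k], x[k:]
        return float((a * b).mean() / (a.mean() * b.mean()))

    lags, g2 = [], []
    x = counts
    width = trace.bin_seconds
    level = 0
    while level < levels:
        ks = range(1, m + 1) if level == 0 else range(m // 2 + 1, m + 1)
        if x.size <= m + 1 or x[: len(x)].mean() == 0:
            warnings.warn(
                f"trace too short for {levels} multitau levels; truncated at {level}",
                stacklevel=2,
            )
            break
        for k in ks:
            lags.append(k * width)
            g2.append(_sym(x, k))
        nhalf = (x.size // 2) * 2
        x = x[:nhalf].reshape(-1, 2).sum(axis=1).astype(float)
        width *= 2
        level += 1
    return AutocorrelationCurve(
        lags=np.asarray(lags),
        g2=np.asarray(g2),
        method="multitau",
        n_photons=int(trace.counts.sum()),
        duration_seconds=trace.duration_seconds,
        meta={"m": m, "levels": level, "bin_seconds": trace.bin_seconds},
    )


def log_downsample(curve: AutocorrelationCurve, points_per_decade: int = 15) -> AutocorrelationCurve:
    """Smooth a curve onto a quasi-logarithmic grid.

    Lags are partitioned into logarithmically spaced bins; each output point
    is the geometric mean of the member lags and the arithmetic mean of the
    member g2 values. Empty bins are dropped. A curve whose lags already
    fall one per bin passes through unchanged.
    """
    if points_per_decade < 1:
        raise ValueError("points_per_decade must be >= 1")
    if len(curve) <= 1:
        return curve
    logt = np.log10(curve.lags)
    lo, hi = logt[0], logt[-1]
    step = 1.0 / points_per_decade
    # bins centered on the logarithmic comb anchored at the first lag, so a
    # curve already on the target grid passes through unchanged
    n_bins = int(np.floor((hi - lo) / step + 0.5)) + 1
    edges = lo + (np.arange(n_bins + 1) - 0.5) * step
    idx = np.clip(np.searchsorted(edges, logt, side="right") - 1, 0, n_bins - 1)
    out_lags, out_g2 = [], []
    for b in np.unique(idx):
        sel = idx == b
        out_lags.append(10 ** logt[sel].mean())  # geometric mean
        out_g2.append(curve.g2[sel].mean())
    return AutocorrelationCurve(
        lags=np.asarray(out_lags),
        g2=np.asarray(out_g2),
        method=curve.method,
        n_photons=curve.n_photons,
        duration_seconds=curve.duration_seconds,
        meta={**curve.meta, "points_per_decade": points_per_decade},
    )


def truncate_lags(curve: AutocorrelationCurve, max_lag_s: float) -> AutocorrelationCurve:
    sel = curve.lags <= max_lag_s
    return AutocorrelationCurve(
        lags=curve.lags[sel],
        g2=curve.g2[sel],
        method=curve.method,
        n_photons=curve.n_photons,
        duration_seconds=curve.duration_seconds,
        meta=dict(curve.meta),
    )


def g2_from_stream(
    stream,
    bin_seconds: float | None = None,
    max_lag_s: float | None = None,
    points_per_decade: int = 15,
    mode: str = "linear",
) -> AutocorrelationCurve:
    """Stream -> binned trace -> FFT g2 -> lag cut -> logarithmic smoothing.

    The standard analysis path: defaults bin at 13 ticks (~1.04 us) and keep
    lags up to 1/20 of the record, where single-record statistics are still
    usable.
    """
    from .photon_stream import DEFAULT_BIN_TICKS, bin_timetags

    if bin_seconds is None:
        bin_seconds = DEFAULT_BIN_TICKS * stream.tick_seconds
    trace = bin_timetags(stream, bin_seconds)
    curve = g2_fft(trace, mode=mode)
    if max_lag_s is None:
        max_lag_s = stream.duration_seconds / 20
    curve = truncate_lags(curve, max_lag_s)
    return log_downsample(curve, points_per_decade)


# ---------------------------------------------------------------------------
# TSV serialization


def write_curve(curve: AutocorrelationCurve, path) -> None:
    with open(Path(path), "w") as fh:
        fh.write(f"#method={curve.method}\n")
        fh.write(f"#n_photons={curve.n_photons}\n")
        fh.write(f"#duration_seconds={curve.duration_seconds!r}\n")
        fh.write("lag_s\tg2\n")
        for lag, val in zip(curve.lags, curve.g2):
            fh.write(f"{float(lag)!r}\t{float(val)!r}\n")


def read_curve(path) -> AutocorrelationCurve:
    meta: dict[str, str] = {}
    rows = []
    with open(Path(path)) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key] = value
            elif not line.startswith("lag_s"):
                lag, val = line.split("\t")
                rows.append((float(lag), float(val)))
    arr = np.asarray(rows)
    return AutocorrelationCurve(
        lags=arr[:, 0],
        g2=arr[:, 1],
        method=meta.get("method", "unknown"),
        n_photons=int(meta.get("n_photons", 0)),
        duration_seconds=float(meta.get("duration_seconds", 0.0)),
    )
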