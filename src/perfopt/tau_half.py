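"""Robust half-decay statistic tau_1/2 for DCS autocorrelation curves.

tau_1/2 is the lag at which a g2 curve has decayed halfway between its top
and bottom plateaus. It is a model-free blood-flow surrogate: faster moving
scatterers (red blood cells) decorrelate the speckle field sooner, so
tau_1/2 shrinks as flow speeds up — without requiring the optical
coefficients that a diffusion-equation blood-flow-index fit would need.

Measured curves rarely show textbook plateaus, so a single (max, min) pair
is fragile. Instead, many candidate top and bottom plateau windows are
enumerated; each retained (top, bottom) pair yields one sub-estimate
(tau_1/2^sub, the first downward crossing of the midpoint level), and the
reported tau_1/2 is the plain mean over the distribution of sub-estimates,
with their standard deviation as a spread measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlator import AutocorrelationCurve
from .exceptions import FlatCurveError, NoCrossingError


@dataclass(frozen=True)
class PlateauConfig:
    """Enumeration scheme for candidate plateau windows.

    Top windows are all contiguous runs of the configured lengths within the
    first ``top_region_points`` lags; bottom windows likewise within the
    last ``bottom_region_points`` lags. A (top, bottom) pair is retained only
    if its contrast (top mean − bottom mean) clears ``min_contrast``; when
    ``min_contrast`` is None it defaults to 3x the standard deviation of the
    bottom region, a guard against calling noise a decay.
    """

    top_window_lengths: tuple[int, ...] = (3, 4, 5)
    bottom_window_lengths: tuple[int, ...] = (3, 4, 5)
    top_region_points: int = 10
    bottom_region_points: int = 10
    min_contrast: float | None = None

    def __post_init__(self):
        lengths = (*self.top_window_lengths, *self.bottom_window_lengths)
        if any(w < 2 for w in lengths):
            raise ValueError("window lengths must be >= 2")
        if self.top_region_points < max(self.top_window_lengths):
            raise ValueError("top region smaller than largest top window")
        if self.bottom_region_points < max(self.bottom_window_lengths):
            raise ValueError("bottom region smaller than largest bottom window")
        if self.min_contrast is not None and self.min_contrast <= 0:
            raise ValueError("min_contrast must be positive")


@dataclass(frozen=True)
class TauHalfEstimate:
    """tau_1/2 with the distribution of plateau-pair sub-estimates."""

    tau_half: float
    sub_values: np.ndarray
    spread: float
    n_pairs: int
    n_failed_pairs: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        sub = np.asarray(self.sub_values, dtype=float)
        object.__setattr__(self, "sub_values", sub)
        if self.n_pairs < 1:
            raise ValueError("at least one plateau pair required")
        if self.spread < 0:
            raise ValueError("spread must be >= 0")


def _window_means(values: np.ndarray, lengths: tuple[int, ...]) -> list[float]:
    means = []
    for w in lengths:
        for start in range(0, values.size - w + 1):
            means.append(float(values[start : start + w].mean()))
    return means


def enumerate_plateau_pairs(
    curve: AutocorrelationCurve, cfg: PlateauConfig | None = None
) -> list[tuple[float, float]]:
    """All (top_mean, bottom_mean) pairs passing the contrast guard."""
    cfg = cfg or PlateauConfig()
    n = len(curve)
    if n < cfg.top_region_points + cfg.bottom_region_points:
        raise ValueError(
            f"curve has {n} points; need >= "
            f"{cfg.top_region_points + cfg.bottom_region_points}"
        )
    top_region = curve.g2[: cfg.top_region_points]
    bottom_region = curve.g2[-cfg.bottom_region_points :]
    min_contrast = cfg.min_contrast
    if min_contrast is None:
        min_contrast = max(3.0 * float(bottom_region.std()), 1e-9)
    tops = _window_means(top_region, cfg.top_window_lengths)
    bottoms = _window_means(bottom_region, cfg.bottom_window_lengths)
    pairs = [(t, b) for t in tops for b in bottoms if t - b >= min_contrast]
    if not pairs:
        raise FlatCurveError(
            f"no plateau pair clears the contrast guard ({min_contrast:.3g}); "
            "curve shows no measurable decay"
        )
    return pairs


def tau_half_sub(curve: AutocorrelationCurve, top_mean: float, bottom_mean: float) -> float:
    """Lag of the first downward crossing of (top+bottom)/2.

    Interpolated linearly in g2 versus log(lag) between the bracketing
    samples — the natural metric for correlation decays viewed on a log lag
    axis. Noisy curves can re-cross; the first crossing is used.
    """
    if top_mean <= bottom_mean:
        raise ValueError("top_mean must exceed bottom_mean")
    target = 0.5 * (top_mean + bottom_mean)
    g2 = curve.g2
    above = g2 >= target
    for i in range(1, g2.size):
        if above[i - 1] and not above[i]:
            lt0, lt1 = np.log(curve.lags[i - 1]), np.log(curve.lags[i])
            frac = (g2[i - 1] - target) / (g2[i - 1] - g2[i])
            return float(np.exp(lt0 + frac * (lt1 - lt0)))
    raise NoCrossingError(
        f"curve never crosses the half-decay level {target:.4g} from above"
    )


def estimate_tau_half(
    curve: AutocorrelationCurve, cfg: PlateauConfig | None = None
) -> TauHalfEstimate:
    """tau_1/2 as the mean over all plateau-pair sub-estimates.

    Pairs whose crossing search fails are dropped (and counted), never
    imputed, so sentinel values cannot bias the distribution.
    """
    pairs = enumerate_plateau_pairs(curve, cfg)
    subs = []
    n_failed = 0
    for top, bottom in pairs:
        try:
            subs.append(tau_half_sub(curve, top, bottom))
        except NoCrossingError:
            n_failed += 1
    if not subs:
        raise NoCrossingError(
            f"all {len(pairs)} plateau pairs failed the half-decay crossing"
        )
    sub_values = np.asarray(subs)
    return TauHalfEstimate(
        tau_half=float(sub_values.mean()),
        sub_values=sub_values,
        spread=float(sub_values.std()),
        n_pairs=len(subs),
        n_failed_pairs=n_failed,
    )
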