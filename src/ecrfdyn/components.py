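"""Extraction of surround modulation components from z-scored LOR maps.

Three component mechanisms are read out of a map:

* tuned facilitation -- the positive peak of the collinear band average
  (orientations within 20 deg of 0 and 180 relative to the CRF preference);
* untuned suppression -- the negative peak of the orthogonal band average
  (within 20 deg of 90 and 270);
* tuned suppression -- the negative peak of the collinear-minus-orthogonal
  difference time course, which cancels the orientation-unselective part so a
  purely untuned mechanism does not masquerade as a tuned one.

Magnitude is the peak z over the time course; onset/offset are the threshold
(|z| = 2) crossings bracketing the peak, found by linear interpolation
between lag samples; duration is offset minus onset.  Orientation tuning
curves, full-width-at-half-height bandwidth and axial circular variance are
computed from a per-neuron time window around the component peak.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .revcorr import LORMap

__all__ = [
    "BandSpec",
    "ComponentSummary",
    "TuningCurve",
    "collinear_band",
    "orthogonal_band",
    "band_rows",
    "band_average",
    "extract_component",
    "summarize_components",
    "default_tuning_window",
    "tuning_curve",
    "circular_variance",
    "population_compare",
]

Z_THRESHOLD = 2.0


@dataclasses.dataclass(frozen=True)
class BandSpec:
    """A set of orientation-band centers with a common half-width (deg)."""

    name: str
    centers: Tuple[float, ...]
    half_width: float


def collinear_band(half_width: float = 20.0) -> BandSpec:
    return BandSpec("collinear", (0.0, 180.0), half_width)


def orthogonal_band(half_width: float = 20.0) -> BandSpec:
    return BandSpec("orthogonal", (90.0, 270.0), half_width)


def _circ_dist(a: np.ndarray, b: float) -> np.ndarray:
    d = np.abs((a - b) % 360.0)
    return np.minimum(d, 360.0 - d)


def band_rows(band: BandSpec, orientations: np.ndarray) -> np.ndarray:
    """Indices of map rows belonging to the band (inclusive half-width)."""
    orientations = np.asarray(orientations, dtype=float)
    inside = np.zeros(len(orientations), dtype=bool)
    for c in band.centers:
        inside |= _circ_dist(orientations, c) <= band.half_width + 1e-9
    return np.nonzero(inside)[0]


def band_average(lmap: LORMap, band: BandSpec, use: str = "z") -> np.ndarray:
    """Mean over the band's orientation rows at each lag.

    On the default 20-deg grid the collinear band is exactly the rows
    {340, 0, 20, 160, 180, 200}; the orthogonal band centers (90, 270) fall
    between grid orientations, so it is the four rows {80, 100, 260, 280}.
    """
    rows = band_rows(band, lmap.orientations)
    if len(rows) == 0:
        raise ValueError(f"band {band.name!r} matches no orientation in the map grid")
    mat = lmap.zmap if use == "z" else lmap.values
    return mat[rows, :].mean(axis=0)


@dataclasses.dataclass(frozen=True)
class ComponentSummary:
    """Magnitude and timing of one surround mechanism."""

    component: str
    peak_z: float
    peak_time_ms: float
    onset_ms: float       # NaN when not significant
    offset_ms: float
    duration_ms: float
    significant: bool


def _cross_level(lags: np.ndarray, s: np.ndarray, i_peak: int, level: float,
                 direction: int) -> float:
    """Linear-interpolated lag where s crosses ``level`` walking from the peak.

    ``direction`` -1 walks toward earlier lags (onset), +1 toward later
    (offset).  Clamps to the grid edge when the curve never drops below the
    level inside the grid.
    """
    j = i_peak
    while 0 <= j + direction < len(s):
        k = j + direction
        if s[k] < level:
            # crossing between lags[j] (>= level) and lags[k] (< level)
            frac = (s[j] - level) / (s[j] - s[k])
            return float(lags[j] + frac * (lags[k] - lags[j]))
        j = k
    return float(lags[0] if direction < 0 else lags[-1])


def extract_component(
    lags: np.ndarray,
    timecourse: np.ndarray,
    sign: str,
    z_threshold: float = Z_THRESHOLD,
    component: str = "",
) -> ComponentSummary:
    """Peak, onset, offset and duration of a band-averaged z time course.

    ``sign`` "+" extracts the positive extremum (facilitation), "-" the
    negative one (suppression).  Ties break to the earliest lag.  When the
    peak does not exceed the threshold the component is flagged
    insignificant and onset/offset/duration are NaN.
    """
    lags = np.asarray(lags, dtype=float)
    tc = np.asarray(timecourse, dtype=float)
    if sign not in ("+", "-"):
        raise ValueError("sign must be '+' or '-'")
    s = tc if sign == "+" else -tc
    i = int(np.argmax(s))
    peak_z = float(tc[i])
    significant = bool(s[i] > z_threshold)
    if not significant:
        onset = offset = duration = float("nan")
    else:
        onset = _cross_level(lags, s, i, z_threshold, -1)
        offset = _cross_level(lags, s, i, z_threshold, +1)
        duration = offset - onset
    return ComponentSummary(
        component=component or ("facilitation" if sign == "+" else "suppression"),
        peak_z=peak_z,
        peak_time_ms=float(lags[i]),
        onset_ms=onset,
        offset_ms=offset,
        duration_ms=duration,
        significant=significant,
    )


def summarize_components(
    lmap: LORMap,
    z_threshold: float = Z_THRESHOLD,
    collinear: Optional[BandSpec] = None,
    orthogonal: Optional[BandSpec] = None,
) -> dict:
    """The three component summaries of a z-scored map.

    Returns a dict keyed by "facilitation", "untuned_suppression" and
    "tuned_suppression".  Note the tuned-suppression time course is the
    collinear-minus-orthogonal difference (see module docstring); its z units
    are those of the map, so the shared threshold is conservative for the
    difference's slightly larger noise.
    """
    coll = band_average(lmap, collinear or collinear_band())
    orth = band_average(lmap, orthogonal or orthogonal_band())
    return {
        "facilitation": extract_component(
            lmap.lags, coll, "+", z_threshold, "facilitation"
        ),
        "untuned_suppression": extract_component(
            lmap.lags, orth, "-", z_threshold, "untuned_suppression"
        ),
        "tuned_suppression": extract_component(
            lmap.lags, coll - orth, "-", z_threshold, "tuned_suppression"
        ),
    }


def default_tuning_window(summary: ComponentSummary) -> Tuple[float, float]:
    """Per-neuron adaptive window: peak time +- half the component duration."""
    if not summary.significant:
        raise ValueError("cannot derive a tuning window from an insignificant component")
    half = summary.duration_ms / 2.0
    return (summary.peak_time_ms - half, summary.peak_time_ms + half)


@dataclasses.dataclass(frozen=True)
class TuningCurve:
    """Mean z per orientation in a lag window, with bandwidth metrics.

    ``bandwidth_fwhh_deg`` is NaN when the curve never falls to half height
    on one flank (reported missing, never clamped); ``at_resolution`` flags
    bandwidths at or below the orientation grid step.
    """

    orientations: np.ndarray
    response: np.ndarray
    window: Tuple[float, float]
    peak_orientation_deg: float
    bandwidth_fwhh_deg: float
    at_resolution: bool


def tuning_curve(lmap: LORMap, window: Tuple[float, float], use: str = "z") -> TuningCurve:
    """Per-orientation mean of the (z-scored) map over a lag window.

    The peak orientation is the extremum of largest magnitude (so suppression
    maps peak at their most negative orientation); bandwidth is the full
    width at half height of the sign-rectified curve about that extremum,
    linearly interpolated between grid orientations with circular wrap.
    """
    lo, hi = window
    cols = (lmap.lags >= lo - 1e-9) & (lmap.lags <= hi + 1e-9)
    if not np.any(cols):
        raise ValueError("tuning window contains no lag samples")
    mat = lmap.zmap if use == "z" else lmap.values
    resp = mat[:, cols].mean(axis=1)

    i_peak = int(np.argmax(np.abs(resp)))
    peak_ori = float(lmap.orientations[i_peak])

    bandwidth = float("nan")
    at_res = False
    if not np.allclose(resp, resp[0]):
        sgn = 1.0 if resp[i_peak] >= 0 else -1.0
        y = sgn * resp
        half = y[i_peak] / 2.0
        step = float(lmap.orientations[1] - lmap.orientations[0])
        n = len(y)

        def flank(direction: int) -> float:
            width = 0.0
            j = i_peak
            for _ in range(n):
                k = (j + direction) % n
                if y[k] < half:
                    frac = (y[j] - half) / (y[j] - y[k])
                    return width + frac * step
                width += step
                j = k
            return float("nan")  # never drops below half on this flank

        left, right = flank(-1), flank(+1)
        bandwidth = left + right
        if math.isfinite(bandwidth):
            at_res = bandwidth <= step + 1e-9
    return TuningCurve(
        orientations=lmap.orientations.copy(),
        response=resp,
        window=(float(lo), float(hi)),
        peak_orientation_deg=peak_ori,
        bandwidth_fwhh_deg=bandwidth,
        at_resolution=at_res,
    )


def circular_variance(curve, orientations=None) -> float:
    """Axial circular variance: 1 - |sum r * exp(2i theta)| / sum r.

    0 means perfectly selective (all response in one orientation), 1 means
    flat.  Angles are doubled so the two drift directions of one axial
    grating count as the same orientation.  Responses are offset by the curve
    minimum only when negative, guaranteeing non-negative weights while
    leaving already-non-negative curves (e.g. a flat positive one) untouched.
    """
    if isinstance(curve, TuningCurve):
        r = np.asarray(curve.response, dtype=float)
        theta = np.asarray(curve.orientations, dtype=float)
    else:
        r = np.asarray(curve, dtype=float)
        theta = np.asarray(orientations, dtype=float)
    r = r - min(0.0, float(r.min()))
    total = r.sum()
    if total <= 0:
        raise ValueError("circular variance undefined for an all-zero curve")
    z = np.sum(r * np.exp(2j * np.radians(theta)))
    return float(1.0 - np.abs(z) / total)


def population_compare(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "wilcoxon",
) -> Tuple[float, float]:
    """Standard paired/population statistics used for group comparisons.

    ``method="wilcoxon"``: paired Wilcoxon signed-rank test (zero differences
    handled by zero-splitting so identical samples give p = 1).
    ``method="pearson"``: Pearson correlation.  Returns (statistic, p-value).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired comparison needs equal-length samples")
    if len(a) < 3:
        raise ValueError("need at least 3 pairs")
    if method == "wilcoxon":
        res = stats.wilcoxon(a, b, zero_method="zsplit")
        return float(res.statistic), float(res.pvalue)
    if method == "pearson":
        res = stats.pearsonr(a, b)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown method {method!r}")
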