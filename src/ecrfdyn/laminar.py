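"""Template cross-correlation of orientation x time maps across groups.

Mirrors the laminar analysis of real recordings: average the z-scored maps
of a group of neurons into a template (optionally normalizing each member to
unit peak |z| so every neuron weighs equally), then cross-correlate each
neuron's map with the group templates over time lags of -100..+100 ms.  The
zero-lag correlation difference between two templates classifies which
group's dynamics dominate a neuron.

Lag sign convention (stated explicitly because it is easy to invert): the
reported lag L is the shift applied to the *template*, with r(L) the Pearson
correlation between map(t) and template(t - L) over their overlapping lag
columns, all orientation rows flattened.  A neuron whose dynamics lead the
template therefore peaks at negative L ("the template must be shifted
earlier to align").  Correlations use the overlap region only -- no zero
padding, which would bias r toward 0 asymmetrically.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .revcorr import LORMap

__all__ = [
    "MapTemplate",
    "CrossCorrResult",
    "average_map",
    "xcorr_template",
    "correlation_difference",
]


@dataclasses.dataclass(eq=False)
class MapTemplate:
    """Group-average orientation x lag map."""

    orientations: np.ndarray
    lags: np.ndarray
    values: np.ndarray
    group: str = ""
    n_members: int = 1
    normalized: bool = False


def _grids_match(o1, l1, o2, l2) -> bool:
    return (
        len(o1) == len(o2)
        and len(l1) == len(l2)
        and np.allclose(o1, o2)
        and np.allclose(l1, l2)
    )


def average_map(
    maps: Sequence[LORMap],
    normalize: bool = False,
    use: str = "z",
    group: str = "",
) -> MapTemplate:
    """Elementwise mean of member maps, optionally per-map peak-normalized.

    With ``normalize=True`` each member is scaled to unit peak |z| before
    averaging so strongly modulated neurons do not dominate the template.
    """
    if len(maps) == 0:
        raise ValueError("need at least one map")
    ref = maps[0]
    stack = []
    for m in maps:
        if not _grids_match(ref.orientations, ref.lags, m.orientations, m.lags):
            raise ValueError("maps are not on identical orientation/lag grids")
        mat = (m.zmap if use == "z" else m.values).astype(float)
        if normalize:
            peak = np.max(np.abs(mat))
            if peak > 0:
                mat = mat / peak
        stack.append(mat)
    return MapTemplate(
        orientations=ref.orientations.copy(),
        lags=ref.lags.copy(),
        values=np.mean(stack, axis=0),
        group=group,
        n_members=len(maps),
        normalized=normalize,
    )


@dataclasses.dataclass(frozen=True)
class CrossCorrResult:
    """Correlation r(L) over template shifts L, with the zero-lag value."""

    lags: np.ndarray
    r: np.ndarray
    r_zero: float
    peak_lag: float


def _pearson_flat(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel()
    b = b.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return float("nan")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def xcorr_template(
    lmap: LORMap,
    template: MapTemplate,
    max_lag_ms: float = 100.0,
    use: str = "z",
) -> CrossCorrResult:
    """Cross-correlate a map with a template over template shifts.

    See the module docstring for the lag sign convention.  Raises when the
    overlap at the extreme shift would be shorter than 3 lag columns.
    """
    if not _grids_match(lmap.orientations, lmap.lags, template.orientations, template.lags):
        raise ValueError("map and template are not on identical grids")
    step = lmap.lag_step
    n_shift = int(round(max_lag_ms / step))
    ncol = len(lmap.lags)
    if ncol - n_shift < 3:
        raise ValueError("overlap shorter than 3 lag columns at the extreme shift")
    A = (lmap.zmap if use == "z" else lmap.values).astype(float)
    B = template.values.astype(float)

    lag_values = np.arange(-n_shift, n_shift + 1, dtype=float) * step
    r = np.empty(len(lag_values))
    for i, k in enumerate(range(-n_shift, n_shift + 1)):
        # r(L) = corr(map[:, j], template[:, j - k]) over valid j
        j_lo, j_hi = max(0, k), ncol + min(0, k)
        r[i] = _pearson_flat(A[:, j_lo:j_hi], B[:, j_lo - k : j_hi - k])
    i_zero = n_shift
    i_peak = int(np.nanargmax(r))
    return CrossCorrResult(
        lags=lag_values,
        r=r,
        r_zero=float(r[i_zero]),
        peak_lag=float(lag_values[i_peak]),
    )


def correlation_difference(
    lmap: LORMap,
    template_a: MapTemplate,
    template_b: MapTemplate,
    use: str = "z",
) -> float:
    """Zero-lag correlation difference r0(map, a) - r0(map, b); positive favors a."""
    ra = xcorr_template(lmap, template_a, use=use).r_zero
    rb = xcorr_template(lmap, template_b, use=use).r_zero
    return ra - rb
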