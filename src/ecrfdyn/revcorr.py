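"""Reverse correlation: log-odds-ratio orientation x lag modulation maps.

For each spike at time t and each lag tau, the surround stimulus occupying
t - tau is tallied.  The modulation statistic is the log-odds ratio

    R_theta(tau) = log[ p(theta | tau, spike) / p(blank | tau, spike) ]

(natural log), estimated from Laplace-smoothed counts.  Positive values mean
the orientation preceded spikes more often than a blank did (facilitation),
negative values mean suppression.  Maps are z-scored against the noise in the
pre-causal 0-20 ms lag window (cortical latencies exceed ~30 ms, so anything
earlier is noise), and |z| > 2 is the downstream significance rule.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Tuple

import numpy as np

from .spikesim import SpikeTrain
from .stimgen import StimulusSequence

__all__ = [
    "LagGrid",
    "CountTable",
    "LORMap",
    "BootstrapBounds",
    "make_lag_grid",
    "count_stimuli_before_spikes",
    "lor_map",
    "lor_maps_by_phase",
    "zscore_map",
    "bootstrap_maps",
]

DEFAULT_BASELINE_WINDOW = (0.0, 20.0)


@dataclasses.dataclass(frozen=True)
class LagGrid:
    """Uniformly spaced lags (ms before each spike), spanning [0, max]."""

    lags: np.ndarray
    step: float


def make_lag_grid(max_lag_ms: float = 200.0, step_ms: float = 5.0) -> LagGrid:
    if step_ms <= 0 or max_lag_ms < step_ms:
        raise ValueError("need 0 < step_ms <= max_lag_ms")
    n = max_lag_ms / step_ms
    if abs(n - round(n)) > 1e-9:
        raise ValueError("step_ms must divide max_lag_ms")
    lags = np.arange(int(round(n)) + 1, dtype=float) * step_ms
    if lags[-1] < DEFAULT_BASELINE_WINDOW[1]:
        raise ValueError("lag grid must cover the 0-20 ms baseline window")
    return LagGrid(lags=lags, step=float(step_ms))


@dataclasses.dataclass(eq=False)
class CountTable:
    """Spike-preceding stimulus counts per class and lag.

    ``counts`` has one row per stimulus class plus a final blank row; column
    sums equal the number of spikes usable at each lag (spikes whose t - tau
    precedes trial start are excluded at that lag only).
    """

    counts: np.ndarray          # (n_classes, n_lags) including blank row
    orientations: np.ndarray    # grid orientations (one per non-blank class group)
    lags: np.ndarray
    phases: Optional[tuple]     # None => marginal over phase
    n_trials: int

    @property
    def blank_row(self) -> int:
        return self.counts.shape[0] - 1

    @property
    def n_spikes_used(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def probabilities(self) -> np.ndarray:
        """p(class | tau): per-lag class frequencies (columns sum to 1)."""
        tot = self.n_spikes_used.astype(float)
        return self.counts / np.where(tot > 0, tot, 1.0)


def _frame_class_codes(
    sequence: StimulusSequence, phase_mode: str
) -> Tuple[np.ndarray, int]:
    """Per-frame class code; blank is the last code."""
    grid = sequence.grid
    n_ori = len(grid)
    ori_idx = np.zeros(sequence.n_frames, dtype=np.int64)
    nb = ~sequence.is_blank
    ori_idx[nb] = np.round(sequence.orientation_deg[nb] / grid.step_deg).astype(np.int64) % n_ori
    if phase_mode == "marginal":
        codes = np.where(sequence.is_blank, n_ori, ori_idx)
        return codes, n_ori + 1
    if phase_mode == "conditioned":
        n_ph = len(sequence.phases)
        phase_idx = np.zeros(sequence.n_frames, dtype=np.int64)
        ph = np.asarray(sequence.phases, dtype=float)
        phase_idx[nb] = np.argmin(
            np.abs(sequence.phase_deg[nb, None] - ph[None, :]), axis=1
        )
        codes = np.where(sequence.is_blank, n_ori * n_ph, ori_idx * n_ph + phase_idx)
        return codes, n_ori * n_ph + 1
    raise ValueError(f"unknown phase_mode {phase_mode!r}")


def _count_per_trial(
    spikes: SpikeTrain,
    sequence: StimulusSequence,
    grid: LagGrid,
    phase_mode: str,
) -> np.ndarray:
    """Counts resolved per trial: (n_trials, n_classes, n_lags)."""
    codes, n_classes = _frame_class_codes(sequence, phase_mode)
    n_lags = len(grid.lags)
    out = np.zeros((sequence.n_trials, n_classes, n_lags), dtype=np.int64)
    for j, tau in enumerate(grid.lags):
        t_pre = spikes.time_ms - tau
        valid = t_pre >= 0.0
        idx = sequence.frame_index_at(spikes.trial[valid], t_pre[valid])
        cls = codes[idx]
        flat = spikes.trial[valid] * n_classes + cls
        binc = np.bincount(flat, minlength=sequence.n_trials * n_classes)
        out[:, :, j] = binc.reshape(sequence.n_trials, n_classes)
    return out


def count_stimuli_before_spikes(
    spikes: SpikeTrain,
    sequence: StimulusSequence,
    grid: Optional[LagGrid] = None,
    phase_mode: str = "marginal",
) -> CountTable:
    """Tally the stimulus class occupying t - tau for every spike and lag.

    ``phase_mode="marginal"`` pools the two spatial phases of each
    orientation (the default analysis); ``"conditioned"`` keeps them separate
    for phase-resolved maps.
    """
    if grid is None:
        grid = make_lag_grid()
    if spikes.n_spikes == 0:
        raise ValueError("empty spike train; simulate longer or check the recording")
    if spikes.n_trials != sequence.n_trials or spikes.trial_ms != sequence.trial_ms:
        raise ValueError("spike train and stimulus sequence disagree on trial structure")
    per_trial = _count_per_trial(spikes, sequence, grid, phase_mode)
    return CountTable(
        counts=per_trial.sum(axis=0),
        orientations=sequence.grid.values.copy(),
        lags=grid.lags.copy(),
        phases=None if phase_mode == "marginal" else tuple(sequence.phases),
        n_trials=sequence.n_trials,
    )


@dataclasses.dataclass(eq=False)
class LORMap:
    """Orientation x lag matrix of log-odds ratios, optionally z-scored."""

    orientations: np.ndarray
    lags: np.ndarray
    values: np.ndarray            # (n_orientations, n_lags), natural-log LOR
    pseudo_count: float
    baseline_sd: Optional[float] = None
    phase: Optional[float] = None

    @property
    def zmap(self) -> np.ndarray:
        if self.baseline_sd is None:
            raise ValueError("map is not z-scored; call zscore_map first")
        return self.values / self.baseline_sd

    @property
    def lag_step(self) -> float:
        return float(self.lags[1] - self.lags[0])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LORMap):
            return NotImplemented
        same_sd = (
            (self.baseline_sd is None and other.baseline_sd is None)
            or (
                self.baseline_sd is not None
                and other.baseline_sd is not None
                and self.baseline_sd == other.baseline_sd
            )
        )
        return (
            same_sd
            and self.pseudo_count == other.pseudo_count
            and np.array_equal(self.orientations, other.orientations)
            and np.array_equal(self.lags, other.lags)
            and np.array_equal(self.values, other.values)
        )


def _lor_from_counts(ori_counts: np.ndarray, blank_counts: np.ndarray, pc: float) -> np.ndarray:
    return np.log((ori_counts + pc) / (blank_counts + pc))


def lor_map(table: CountTable, pseudo_count: float = 1.0) -> LORMap:
    """Log-odds-ratio map from a phase-marginal count table.

    Laplace smoothing with ``pseudo_count`` keeps every entry finite; at
    realistic spike counts (hundreds per class and lag) it is negligible.
    """
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be > 0")
    if table.phases is not None:
        raise ValueError("table is phase-conditioned; use lor_maps_by_phase")
    ori = table.counts[:-1, :].astype(float)
    blank = table.counts[-1, :].astype(float)
    return LORMap(
        orientations=table.orientations.copy(),
        lags=table.lags.copy(),
        values=_lor_from_counts(ori, blank[None, :], pseudo_count),
        pseudo_count=float(pseudo_count),
    )


def lor_maps_by_phase(table: CountTable, pseudo_count: float = 1.0) -> dict:
    """One LOR map per spatial phase from a phase-conditioned count table."""
    if pseudo_count <= 0:
        raise ValueError("pseudo_count must be > 0")
    if table.phases is None:
        raise ValueError("table is phase-marginal; use lor_map")
    n_ph = len(table.phases)
    n_ori = len(table.orientations)
    blank = table.counts[-1, :].astype(float)
    body = table.counts[:-1, :].reshape(n_ori, n_ph, -1).astype(float)
    return {
        phase: LORMap(
            orientations=table.orientations.copy(),
            lags=table.lags.copy(),
            values=_lor_from_counts(body[:, p, :], blank[None, :], pseudo_count),
            pseudo_count=float(pseudo_count),
            phase=float(phase),
        )
        for p, phase in enumerate(table.phases)
    }


def zscore_map(
    lmap: LORMap, baseline_window: Tuple[float, float] = DEFAULT_BASELINE_WINDOW
) -> LORMap:
    """Fill the z-map using the pre-causal baseline noise estimate.

    ``baseline_sd`` is the sample standard deviation of all LOR entries at
    lags inside the (inclusive) baseline window; the z-map is values / sd.
    """
    lo, hi = baseline_window
    cols = (lmap.lags >= lo) & (lmap.lags <= hi)
    if not np.any(cols):
        raise ValueError("baseline window contains no lag samples")
    sd = float(np.std(lmap.values[:, cols], ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate baseline: zero variance in the 0-20 ms window")
    return LORMap(
        orientations=lmap.orientations.copy(),
        lags=lmap.lags.copy(),
        values=lmap.values.copy(),
        pseudo_count=lmap.pseudo_count,
        baseline_sd=sd,
        phase=lmap.phase,
    )


@dataclasses.dataclass(frozen=True)
class BootstrapBounds:
    """Per-bin percentile confidence bounds on the LOR map."""

    orientations: np.ndarray
    lags: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_boot: int


def _bounds_from_per_trial(
    per_trial: np.ndarray,
    indices: np.ndarray,
    pseudo_count: float,
    level: float,
) -> Tuple[np.ndarray, np.ndarray]:
    counts = per_trial[indices].sum(axis=1)        # (n_boot, n_classes, n_lags)
    ori = counts[:, :-1, :].astype(float)
    blank = counts[:, -1:, :].astype(float)
    lor = _lor_from_counts(ori, blank, pseudo_count)
    alpha = (100.0 - level) / 2.0
    lower = np.percentile(lor, alpha, axis=0)
    upper = np.percentile(lor, 100.0 - alpha, axis=0)
    return lower, upper


def bootstrap_maps(
    spikes: SpikeTrain,
    sequence: StimulusSequence,
    grid: Optional[LagGrid] = None,
    n_boot: int = 200,
    seed: Optional[int] = None,
    pseudo_count: float = 1.0,
    level: float = 95.0,
    phase_mode: str = "marginal",
) -> BootstrapBounds:
    """Trial-resampling bootstrap confidence bounds on the LOR map.

    Trials are resampled with replacement ``n_boot`` times; per-bin percentile
    intervals of the recomputed maps are returned.  Reproducible from
    ``seed``.
    """
    if grid is None:
        grid = make_lag_grid()
    if sequence.n_trials < 2:
        raise ValueError("bootstrap needs at least 2 trials")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    per_trial = _count_per_trial(spikes, sequence, grid, phase_mode)
    if phase_mode != "marginal":
        raise NotImplementedError("bootstrap bounds are computed on phase-marginal maps")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, sequence.n_trials, size=(n_boot, sequence.n_trials))
    lower, upper = _bounds_from_per_trial(per_trial, idx, pseudo_count, level)
    return BootstrapBounds(
        orientations=sequence.grid.values.copy(),
        lags=grid.lags.copy(),
        lower=lower,
        upper=upper,
        level=float(level),
        n_boot=int(n_boot),
    )
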