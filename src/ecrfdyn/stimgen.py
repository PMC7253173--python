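"""Dynamic surround (eCRF) stimulus protocol.

The experimental protocol this module emulates: a grating drifting over the
classical receptive field (CRF) provides constant drive, while an annular
surround plays a rapid sequence of high-contrast gratings -- one per 20-ms
slot (two frames of a 100-Hz monitor), each drawn uniformly from 18 drift
directions spaced 20 degrees apart crossed with 2 spatial phases.  Occasional
mean-grey blanks act as the no-stimulus reference class for the log-odds
analysis.  Trials are 10 s long and independent; no cross-trial continuity is
ever assumed.

All times are milliseconds on a trial-relative clock.  Frame intervals are
half-open ``[onset, onset + duration)``.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "OrientationGrid",
    "StimulusFrame",
    "StimulusSequence",
    "make_orientation_grid",
    "generate_sequence",
    "stimulus_at",
    "DEFAULT_P_BLANK",
]

#: Default blank probability: the blank behaves as a 19th stimulus class on the
#: default 18-orientation grid, giving balanced class priors so the log-odds
#: ratio of any orientation against blank is zero under the null.
DEFAULT_P_BLANK = 1.0 / 19.0


@dataclasses.dataclass(frozen=True)
class OrientationGrid:
    """Equally spaced drift directions covering [0, 360).

    Drift direction is included, so 0 and 180 are distinct entries even though
    the underlying gratings are axial.
    """

    step_deg: float
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)

    def index_of(self, orientation_deg: float) -> int:
        """Map an orientation to its grid index (mod 360)."""
        idx = int(round((orientation_deg % 360.0) / self.step_deg))
        if not np.isclose(idx * self.step_deg % 360.0, orientation_deg % 360.0):
            raise ValueError(f"orientation {orientation_deg} not on grid (step {self.step_deg})")
        return idx % len(self.values)


def make_orientation_grid(step_deg: float) -> OrientationGrid:
    """Build the orientation grid for a given angular step.

    ``step_deg`` must divide 360; the default protocol uses 20 degrees,
    giving 18 directions {0, 20, ..., 340}.
    """
    if step_deg <= 0:
        raise ValueError("step_deg must be positive")
    n = 360.0 / step_deg
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"step_deg={step_deg} does not divide 360")
    n = int(round(n))
    values = np.arange(n, dtype=float) * float(step_deg)
    return OrientationGrid(step_deg=float(step_deg), values=values)


@dataclasses.dataclass(frozen=True)
class StimulusFrame:
    """One surround stimulus slot.  Blank frames carry no orientation/phase."""

    trial: int
    onset_ms: float
    duration_ms: float
    orientation_deg: Optional[float]
    phase_deg: Optional[float]

    @property
    def is_blank(self) -> bool:
        return self.orientation_deg is None

    @property
    def center_ms(self) -> float:
        return self.onset_ms + self.duration_ms / 2.0


@dataclasses.dataclass(eq=False)
class StimulusSequence:
    """A full multi-trial surround sequence, stored columnar.

    Frames tile each trial without gaps or overlap at a constant ``frame_ms``.
    Blank frames have NaN orientation and phase with ``is_blank`` set.
    """

    trial: np.ndarray          # int, frame -> trial id
    onset_ms: np.ndarray       # float
    duration_ms: np.ndarray    # float
    orientation_deg: np.ndarray  # float, NaN on blanks
    phase_deg: np.ndarray        # float, NaN on blanks
    is_blank: np.ndarray         # bool
    trial_ms: float
    n_trials: int
    frame_ms: float
    grid: OrientationGrid
    p_blank: float
    phases: tuple
    seed: Optional[int]

    # -- basic structure ----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self.onset_ms)

    @property
    def frames_per_trial(self) -> int:
        return int(round(self.trial_ms / self.frame_ms))

    def frames(self) -> Iterator[StimulusFrame]:
        """Iterate frames as objects (row view of the columnar store)."""
        for i in range(self.n_frames):
            blank = bool(self.is_blank[i])
            yield StimulusFrame(
                trial=int(self.trial[i]),
                onset_ms=float(self.onset_ms[i]),
                duration_ms=float(self.duration_ms[i]),
                orientation_deg=None if blank else float(self.orientation_deg[i]),
                phase_deg=None if blank else float(self.phase_deg[i]),
            )

    # -- lookup -------------------------------------------------------------
    def frame_index_at(self, trials: np.ndarray, times_ms: np.ndarray) -> np.ndarray:
        """Vectorised frame lookup; -1 where the time is outside the trial.

        Relies on the uniform tiling invariant (constant ``frame_ms``).
        """
        trials = np.asarray(trials)
        times_ms = np.asarray(times_ms, dtype=float)
        if np.any(trials < 0) or np.any(trials >= self.n_trials):
            raise KeyError("trial id outside sequence")
        slot = np.floor(times_ms / self.frame_ms).astype(np.int64)
        idx = trials.astype(np.int64) * self.frames_per_trial + slot
        valid = (times_ms >= 0.0) & (times_ms < self.trial_ms)
        return np.where(valid, idx, -1)

    def stimulus_at(self, trial: int, t_ms: float) -> Optional[StimulusFrame]:
        """The unique frame whose half-open interval contains ``t_ms``.

        A time exactly on a frame boundary belongs to the later frame.
        Returns None for times outside [0, trial_ms).
        """
        if not (0 <= trial < self.n_trials):
            raise KeyError(f"unknown trial id {trial}")
        if t_ms < 0 or t_ms >= self.trial_ms:
            return None
        idx = int(self.frame_index_at(np.array([trial]), np.array([t_ms]))[0])
        blank = bool(self.is_blank[idx])
        return StimulusFrame(
            trial=int(self.trial[idx]),
            onset_ms=float(self.onset_ms[idx]),
            duration_ms=float(self.duration_ms[idx]),
            orientation_deg=None if blank else float(self.orientation_deg[idx]),
            phase_deg=None if blank else float(self.phase_deg[idx]),
        )

    # -- equality (used by round-trip I/O tests) ----------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StimulusSequence):
            return NotImplemented
        return (
            self.trial_ms == other.trial_ms
            and self.n_trials == other.n_trials
            and self.frame_ms == other.frame_ms
            and self.p_blank == other.p_blank
            and tuple(self.phases) == tuple(other.phases)
            and self.seed == other.seed
            and self.grid.step_deg == other.grid.step_deg
            and np.array_equal(self.trial, other.trial)
            and np.array_equal(self.onset_ms, other.onset_ms)
            and np.array_equal(self.duration_ms, other.duration_ms)
            and np.array_equal(self.orientation_deg, other.orientation_deg, equal_nan=True)
            and np.array_equal(self.phase_deg, other.phase_deg, equal_nan=True)
            and np.array_equal(self.is_blank, other.is_blank)
        )


def generate_sequence(
    grid: Optional[OrientationGrid] = None,
    *,
    frame_ms: float = 20.0,
    trial_ms: float = 10_000.0,
    n_trials: int = 40,
    p_blank: float = DEFAULT_P_BLANK,
    phases: tuple = (0.0, 180.0),
    seed: Optional[int] = None,
) -> StimulusSequence:
    """Draw a full surround stimulus sequence.

    Each frame slot independently is a blank with probability ``p_blank``,
    otherwise a uniform draw over (orientation, phase) pairs.  Identical
    ``seed`` and configuration give an identical sequence.

    Defaults are the recording protocol: 20-ms frames, 10-s trials, 40 trials,
    18 orientations x 2 phases, blanks as a balanced 19th class.
    """
    if grid is None:
        grid = make_orientation_grid(20.0)
    if frame_ms <= 0 or trial_ms <= 0:
        raise ValueError("frame_ms and trial_ms must be positive")
    slots = trial_ms / frame_ms
    if abs(slots - round(slots)) > 1e-9:
        raise ValueError(f"frame_ms={frame_ms} does not divide trial_ms={trial_ms}")
    if not (0.0 <= p_blank < 1.0):
        raise ValueError("p_blank must lie in [0, 1)")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    slots = int(round(slots))
    n = n_trials * slots

    rng = np.random.default_rng(seed)
    blank = rng.random(n) < p_blank
    ori_idx = rng.integers(0, len(grid), size=n)
    phase_idx = rng.integers(0, len(phases), size=n)

    orientation = grid.values[ori_idx].astype(float)
    phase = np.asarray(phases, dtype=float)[phase_idx]
    orientation[blank] = np.nan
    phase[blank] = np.nan

    trial = np.repeat(np.arange(n_trials, dtype=np.int64), slots)
    onset = np.tile(np.arange(slots, dtype=float) * frame_ms, n_trials)
    duration = np.full(n, float(frame_ms))

    return StimulusSequence(
        trial=trial,
        onset_ms=onset,
        duration_ms=duration,
        orientation_deg=orientation,
        phase_deg=phase,
        is_blank=blank,
        trial_ms=float(trial_ms),
        n_trials=int(n_trials),
        frame_ms=float(frame_ms),
        grid=grid,
        p_blank=float(p_blank),
        phases=tuple(float(p) for p in phases),
        seed=seed,
    )


def stimulus_at(sequence: StimulusSequence, trial: int, t_ms: float) -> Optional[StimulusFrame]:
    """Module-level alias for :meth:`StimulusSequence.stimulus_at`."""
    return sequence.stimulus_at(trial, t_ms)
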