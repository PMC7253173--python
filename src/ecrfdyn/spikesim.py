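"""Generative gain-kernel model of CRF/eCRF interaction.

The CRF drive is a homogeneous Poisson process (default 60 spikes/s, the rate
evoked by a ~50%-response-contrast grating).  Each surround (eCRF) mechanism
is a multiplicative gain kernel: a Gaussian temporal profile (peak gain =
amplitude, latency = mu, width = sd) optionally scaled by an axial Von Mises
orientation profile.  Facilitative kernels multiply the drive as (1 + D),
suppressive kernels divide it as 1/(1 + D), where D is the kernel's summed
drive from all surround frames.

Discretised convolution convention: each 20-ms surround frame contributes one
kernel evaluation referenced to the frame's temporal *center*, so the printed
amplitudes are exact single-frame peak gain contributions and the occupancy-
based reverse correlation downstream recovers the kernel latency mu without a
half-frame bias.  Contributions from successive frames sum linearly within a
kernel's drive before the (1 + D) nonlinearity.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional

import numpy as np

from .stimgen import StimulusSequence

__all__ = [
    "FACILITATION",
    "UNTUNED_SUPPRESSION",
    "TUNED_SUPPRESSION",
    "TemporalKernel",
    "OrientationProfile",
    "KernelSpec",
    "NeuronModel",
    "SpikeTrain",
    "temporal_kernel_value",
    "orientation_scaling",
    "gain_timecourse",
    "simulate_spikes",
    "uniform_profile",
    "von_mises_profile",
]

FACILITATION = "facilitation"
UNTUNED_SUPPRESSION = "untuned_suppression"
TUNED_SUPPRESSION = "tuned_suppression"
_COMPONENTS = (FACILITATION, UNTUNED_SUPPRESSION, TUNED_SUPPRESSION)
_SUPPRESSIVE = (UNTUNED_SUPPRESSION, TUNED_SUPPRESSION)

#: Gaussian support half-width in units of sd; beyond this the kernel is
#: treated as exactly zero (tail < 2e-8 of the amplitude).
_SUPPORT_SD = 6.0


@dataclasses.dataclass(frozen=True)
class TemporalKernel:
    """Gaussian temporal gain profile: amplitude * exp(-(t-mu)^2 / (2 sd^2))."""

    amplitude: float  # dimensionless peak gain contribution
    mu_ms: float      # latency of peak response
    sd_ms: float      # temporal width

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.sd_ms <= 0:
            raise ValueError("sd_ms must be > 0")

    def value(self, t_ms):
        t = np.asarray(t_ms, dtype=float)
        return self.amplitude * np.exp(-((t - self.mu_ms) ** 2) / (2.0 * self.sd_ms**2))


def temporal_kernel_value(kernel: TemporalKernel, t_ms):
    """Kernel gain contribution at time ``t_ms`` after the driving event."""
    return kernel.value(t_ms)


@dataclasses.dataclass(frozen=True)
class OrientationProfile:
    """Orientation scaling in [0, 1]; axial (period 180 deg) when tuned.

    ``von_mises`` profiles are parameterised by the half-width at half height
    (HWHH) of the axial Von Mises exp(kappa*(cos(2*dtheta) - 1)), with kappa
    solved so the profile is exactly 0.5 at dtheta = hwhh_deg.
    """

    kind: str = "uniform"  # "uniform" | "von_mises"
    peak_deg: float = 0.0
    hwhh_deg: float = 30.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "von_mises"):
            raise ValueError(f"unknown orientation profile kind {self.kind!r}")
        if self.kind == "von_mises" and not (0.0 < self.hwhh_deg < 90.0):
            raise ValueError("hwhh_deg must lie strictly between 0 and 90 degrees")

    @property
    def kappa(self) -> float:
        if self.kind != "von_mises":
            raise ValueError("kappa defined only for von_mises profiles")
        return math.log(2.0) / (1.0 - math.cos(2.0 * math.radians(self.hwhh_deg)))


def uniform_profile() -> OrientationProfile:
    return OrientationProfile(kind="uniform")


def von_mises_profile(peak_deg: float = 0.0, hwhh_deg: float = 30.0) -> OrientationProfile:
    return OrientationProfile(kind="von_mises", peak_deg=peak_deg, hwhh_deg=hwhh_deg)


def orientation_scaling(profile: OrientationProfile, theta_deg):
    """Amplitude scaling for a surround orientation relative to CRF preference.

    Uniform profiles return 1 everywhere.  Von Mises profiles peak at 1,
    fall to 0.5 at the HWHH, and are axial: theta and theta + 180 scale
    identically (collinear means both drift directions).
    """
    theta = np.asarray(theta_deg, dtype=float)
    if profile.kind == "uniform":
        return np.ones_like(theta)
    d = np.radians(theta - profile.peak_deg)
    return np.exp(profile.kappa * (np.cos(2.0 * d) - 1.0))


@dataclasses.dataclass(frozen=True)
class KernelSpec:
    """One eCRF mechanism: temporal kernel + orientation profile + class."""

    component: str
    temporal: TemporalKernel
    orientation: OrientationProfile

    def __post_init__(self) -> None:
        if self.component not in _COMPONENTS:
            raise ValueError(f"unknown component {self.component!r}")
        if self.component == UNTUNED_SUPPRESSION and self.orientation.kind != "uniform":
            raise ValueError("untuned suppression must carry a uniform orientation profile")

    @property
    def is_suppressive(self) -> bool:
        return self.component in _SUPPRESSIVE


@dataclasses.dataclass(frozen=True)
class NeuronModel:
    """Baseline CRF drive plus a set of surround gain kernels.

    Total gain G(t) = prod over facilitative kernels (1 + D_k(t))
                    / prod over suppressive kernels (1 + D_k(t)),
    which is strictly positive for all admissible kernels (D_k >= 0).
    """

    baseline_rate_hz: float
    kernels: tuple = ()
    name: str = ""

    def __post_init__(self) -> None:
        if self.baseline_rate_hz < 0:
            raise ValueError("baseline_rate_hz must be >= 0")


@dataclasses.dataclass(eq=False)
class SpikeTrain:
    """Spike times (ms) with trial ids, sorted within trial."""

    trial: np.ndarray
    time_ms: np.ndarray
    n_trials: int
    trial_ms: float
    seed: Optional[int] = None
    description: str = ""

    @property
    def n_spikes(self) -> int:
        return len(self.time_ms)

    @property
    def total_time_s(self) -> float:
        return self.n_trials * self.trial_ms / 1000.0

    @property
    def mean_rate_hz(self) -> float:
        return self.n_spikes / self.total_time_s

    def subset_trials(self, trial_ids) -> "SpikeTrain":
        """Spikes of the given trials, re-labelled 0..len(trial_ids)-1.

        Repeated ids are allowed (used by trial-resampling bootstraps).
        """
        parts_t, parts_s = [], []
        for new_id, t in enumerate(trial_ids):
            m = self.trial == t
            parts_t.append(np.full(m.sum(), new_id, dtype=np.int64))
            parts_s.append(self.time_ms[m])
        return SpikeTrain(
            trial=np.concatenate(parts_t) if parts_t else np.empty(0, np.int64),
            time_ms=np.concatenate(parts_s) if parts_s else np.empty(0, float),
            n_trials=len(list(trial_ids)),
            trial_ms=self.trial_ms,
            seed=self.seed,
            description=self.description,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return (
            self.n_trials == other.n_trials
            and self.trial_ms == other.trial_ms
            and np.array_equal(self.trial, other.trial)
            and np.array_equal(self.time_ms, other.time_ms)
        )


# ---------------------------------------------------------------------------
# Gain and spiking
# ---------------------------------------------------------------------------

def _kernel_drive(
    spec: KernelSpec,
    event_center_ms: np.ndarray,
    event_weight: np.ndarray,
    trial: np.ndarray,
    n_trials: int,
    n_bins: int,
    dt: float,
) -> np.ndarray:
    """Summed drive D(t) of one kernel over per-trial time bins.

    ``event_weight`` carries the orientation scaling (and any partial-frame
    weighting); each event adds amplitude * weight * Gaussian(t - center - 0
    ; mu, sd) evaluated at bin centers, restricted to +-6 sd support.
    """
    k = spec.temporal
    drive = np.zeros(n_trials * n_bins)
    if len(event_center_ms) == 0:
        return drive.reshape(n_trials, n_bins)

    lo = k.mu_ms - _SUPPORT_SD * k.sd_ms
    width = int(math.ceil(2.0 * _SUPPORT_SD * k.sd_ms / dt)) + 2
    # first bin whose center could fall inside the support window
    start = np.floor((event_center_ms + lo) / dt).astype(np.int64)
    offsets = np.arange(width, dtype=np.int64)
    bins = start[:, None] + offsets[None, :]                      # (n_ev, width)
    t_bins = (bins + 0.5) * dt                                    # bin centers
    vals = event_weight[:, None] * k.value(t_bins - event_center_ms[:, None])
    inside = (bins >= 0) & (bins < n_bins)
    flat = trial[:, None] * n_bins + np.clip(bins, 0, n_bins - 1)
    np.add.at(drive, flat[inside], vals[inside])
    return drive.reshape(n_trials, n_bins)


def gain_timecourse(
    model: NeuronModel,
    sequence: StimulusSequence,
    dt: float = 1.0,
):
    """Multiplicative gain G(t) sampled on a per-trial dt grid (bin centers).

    Returns ``(t, gain)`` where ``t`` has shape (n_bins,) and ``gain``
    (n_trials, n_bins).  G(t) > 0 always; with no kernels (or an all-blank
    sequence) G is identically 1.
    """
    if dt > 5.0 or dt <= 0.0:
        raise ValueError("dt must lie in (0, 5] ms")
    nb = sequence.trial_ms / dt
    if abs(nb - round(nb)) > 1e-9:
        raise ValueError("dt must divide the trial length")
    nb = int(round(nb))
    t = (np.arange(nb) + 0.5) * dt

    keep = ~sequence.is_blank
    centers = sequence.onset_ms[keep] + sequence.duration_ms[keep] / 2.0
    trials = sequence.trial[keep]
    theta = sequence.orientation_deg[keep]

    gain = np.ones((sequence.n_trials, nb))
    for spec in model.kernels:
        # amplitude lives inside TemporalKernel.value; weights carry only the
        # orientation scaling of each frame
        w = orientation_scaling(spec.orientation, theta)
        d = _kernel_drive(spec, centers, w, trials, sequence.n_trials, nb, dt)
        if spec.is_suppressive:
            gain /= 1.0 + d
        else:
            gain *= 1.0 + d
    return t, gain


def simulate_spikes(
    model: NeuronModel,
    sequence: StimulusSequence,
    dt: float = 1.0,
    seed: Optional[int] = None,
) -> SpikeTrain:
    """Inhomogeneous Poisson spikes with rate baseline * G(t).

    Per-bin Poisson counts at the bin-center rate (exact for the piecewise-
    constant rate), spike times uniform within their bin, sorted per trial.
    Raises when rate * dt reaches 1 spike per bin, i.e. when ``dt`` is too
    coarse to resolve the modulated rate.
    """
    rng = np.random.default_rng(seed)
    if model.baseline_rate_hz == 0.0:
        return SpikeTrain(
            trial=np.empty(0, np.int64), time_ms=np.empty(0, float),
            n_trials=sequence.n_trials, trial_ms=sequence.trial_ms,
            seed=seed, description=model.name,
        )

    if model.kernels:
        _, gain = gain_timecourse(model, sequence, dt)
    else:
        nb = int(round(sequence.trial_ms / dt))
        gain = np.ones((sequence.n_trials, nb))
    lam = model.baseline_rate_hz * gain * (dt / 1000.0)
    if np.any(lam >= 1.0):
        raise ValueError(
            "expected count per bin reaches 1 (rate*dt too large); use a smaller dt"
        )

    counts = rng.poisson(lam)
    tr_idx, bin_idx = np.nonzero(counts)
    reps = counts[tr_idx, bin_idx]
    trial = np.repeat(tr_idx, reps).astype(np.int64)
    bins = np.repeat(bin_idx, reps)
    times = (bins + rng.random(bins.size)) * dt
    order = np.lexsort((times, trial))
    return SpikeTrain(
        trial=trial[order], time_ms=times[order],
        n_trials=sequence.n_trials, trial_ms=sequence.trial_ms,
        seed=seed, description=model.name,
    )
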