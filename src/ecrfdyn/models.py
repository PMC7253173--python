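"""Reference neuron models with the canonical kernel parameters.

These are the ground-truth generative models used throughout the analyses:
three single-mechanism neurons (tuned facilitation, untuned suppression,
tuned suppression), the strong suppression kernel paired with facilitation in
the first duration model, the two duration-experiment mixtures, a
three-mechanism neuron mimicking the average population, and two synthetic
"laminar" groups with distinct surround timing for the template
cross-correlation analysis.

Kernel parameters (gain amplitude, latency mu in ms, width sd in ms):

====================  =========  =====  ====
mechanism             amplitude  mu     sd
====================  =========  =====  ====
facilitation          1.2        50     5
strong suppression    1.7        80     10
untuned suppression   1.1        60     7
tuned suppression     1.1        80     10
====================  =========  =====  ====

Tuned mechanisms carry an axial Von Mises orientation profile with peak at
0 deg (collinear) and half-width at half height of 30 deg.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .spikesim import (
    FACILITATION,
    TUNED_SUPPRESSION,
    UNTUNED_SUPPRESSION,
    KernelSpec,
    NeuronModel,
    TemporalKernel,
    uniform_profile,
    von_mises_profile,
)

__all__ = [
    "BASELINE_RATE_HZ",
    "facilitation_kernel",
    "strong_suppression_kernel",
    "untuned_suppression_kernel",
    "tuned_suppression_kernel",
    "collinear_profile",
    "baseline_neuron",
    "facilitation_neuron",
    "untuned_suppression_neuron",
    "tuned_suppression_neuron",
    "strong_suppression_neuron",
    "duration_model_one",
    "duration_model_two",
    "three_mechanism_neuron",
    "laminar_group_models",
]

#: CRF drive at ~50% response contrast.
BASELINE_RATE_HZ = 60.0


def facilitation_kernel() -> TemporalKernel:
    return TemporalKernel(amplitude=1.2, mu_ms=50.0, sd_ms=5.0)


def strong_suppression_kernel() -> TemporalKernel:
    """The suppression kernel paired with facilitation in duration model one."""
    return TemporalKernel(amplitude=1.7, mu_ms=80.0, sd_ms=10.0)


def untuned_suppression_kernel() -> TemporalKernel:
    return TemporalKernel(amplitude=1.1, mu_ms=60.0, sd_ms=7.0)


def tuned_suppression_kernel() -> TemporalKernel:
    return TemporalKernel(amplitude=1.1, mu_ms=80.0, sd_ms=10.0)


def collinear_profile():
    """Axial Von Mises profile peaking at collinear (0 deg), HWHH 30 deg."""
    return von_mises_profile(peak_deg=0.0, hwhh_deg=30.0)


def baseline_neuron(rate_hz: float = BASELINE_RATE_HZ) -> NeuronModel:
    """CRF drive only; no surround mechanisms."""
    return NeuronModel(baseline_rate_hz=rate_hz, kernels=(), name="baseline")


def facilitation_neuron(rate_hz: float = BASELINE_RATE_HZ) -> NeuronModel:
    return NeuronModel(
        baseline_rate_hz=rate_hz,
        kernels=(KernelSpec(FACILITATION, facilitation_kernel(), collinear_profile()),),
        name="facilitation-only",
    )


def untuned_suppression_neuron(rate_hz: float = BASELINE_RATE_HZ) -> NeuronModel:
    return NeuronModel(
        baseline_rate_hz=rate_hz,
        kernels=(KernelSpec(UNTUNED_SUPPRESSION, untuned_suppression_kernel(), uniform_profile()),),
        name="untuned-suppression-only",
    )


def tuned_suppression_neuron(rate_hz: float = BASELINE_RATE_HZ) -> NeuronModel:
    return NeuronModel(
        baseline_rate_hz=rate_hz,
        kernels=(KernelSpec(TUNED_SUPPRESSION, tuned_suppression_kernel(), collinear_profile()),),
        name="tuned-suppression-only",
    )


def strong_suppression_neuron(rate_hz: float = BASELINE_RATE_HZ) -> NeuronModel:
    """Single-kernel neuron carrying the strong (model-one) suppression."""
    return NeuronModel(
        baseline_rate_hz=rate_hz,
        kernels=(KernelSpec(UNTUNED_SUPPRESSION, strong_suppression_kernel(), uniform_profile()),),
        name="strong-suppression-only",
    )


def duration_model_one(rate_hz: float = BASELINE_RATE_HZ) -> NeuronModel:
    """Short-latency moderate facilitation + long-latency strong suppression.

    Total gain (1 + K_f) / (1 + K_s); used for the net-modulation-vs-duration
    experiment at collinear orientation.
    """
    return NeuronModel(
        baseline_rate_hz=rate_hz,
        kernels=(
            KernelSpec(FACILITATION, facilitation_kernel(), uniform_profile()),
            KernelSpec(UNTUNED_SUPPRESSION, strong_suppression_kernel(), uniform_profile()),
        ),
        name="facilitation+suppression",
    )


def duration_model_two(rate_hz: float = BASELINE_RATE_HZ) -> NeuronModel:
    """Short-latency untuned + long-latency tuned suppression.

    Both mechanisms are divisive: G = 1 / ((1 + K_us)(1 + alpha * K_ts)),
    with alpha the axial Von Mises orientation scaling of the tuned kernel.
    Used for the suppression-tuning-vs-duration experiment.
    """
    return NeuronModel(
        baseline_rate_hz=rate_hz,
        kernels=(
            KernelSpec(UNTUNED_SUPPRESSION, untuned_suppression_kernel(), uniform_profile()),
            KernelSpec(TUNED_SUPPRESSION, tuned_suppression_kernel(), collinear_profile()),
        ),
        name="untuned+tuned-suppression",
    )


def three_mechanism_neuron(rate_hz: float = BASELINE_RATE_HZ) -> NeuronModel:
    """All three mechanisms with population-average-like timing.

    Facilitation (mu 50, sd 5), untuned suppression (mu 60, sd 7) and tuned
    suppression (mu 80, sd 10), the ordering of widths that produces the
    qualitative duration ordering facilitation < untuned < tuned.
    """
    return NeuronModel(
        baseline_rate_hz=rate_hz,
        kernels=(
            KernelSpec(FACILITATION, facilitation_kernel(), collinear_profile()),
            KernelSpec(UNTUNED_SUPPRESSION, untuned_suppression_kernel(), uniform_profile()),
            KernelSpec(TUNED_SUPPRESSION, tuned_suppression_kernel(), collinear_profile()),
        ),
        name="three-mechanism",
    )


def laminar_group_models(
    seed: int = 0,
    n_members: int = 6,
    rate_hz: float = BASELINE_RATE_HZ,
) -> Tuple[List[NeuronModel], List[NeuronModel]]:
    """Two synthetic groups with distinct surround timing.

    Group A ("magno-like"): early untuned suppression plus tuned suppression,
    mirroring fast, transient input-layer dynamics.  Group B ("parvo-like"):
    late tuned suppression only.  Member kernels are jittered in latency
    (+-5 ms) and amplitude (+-10%) so each group has within-group variability.
    """
    rng = np.random.default_rng(seed)

    def jitter(mu, amp):
        return (mu + rng.uniform(-5.0, 5.0), amp * rng.uniform(0.9, 1.1))

    group_a, group_b = [], []
    for i in range(n_members):
        mu_us, a_us = jitter(55.0, 1.1)
        mu_ts, a_ts = jitter(75.0, 1.0)
        group_a.append(
            NeuronModel(
                baseline_rate_hz=rate_hz,
                kernels=(
                    KernelSpec(
                        UNTUNED_SUPPRESSION,
                        TemporalKernel(a_us, mu_us, 7.0),
                        uniform_profile(),
                    ),
                    KernelSpec(
                        TUNED_SUPPRESSION,
                        TemporalKernel(a_ts, mu_ts, 10.0),
                        collinear_profile(),
                    ),
                ),
                name=f"groupA-{i}",
            )
        )
    for i in range(n_members):
        mu_ts, a_ts = jitter(95.0, 1.1)
        group_b.append(
            NeuronModel(
                baseline_rate_hz=rate_hz,
                kernels=(
                    KernelSpec(
                        TUNED_SUPPRESSION,
                        TemporalKernel(a_ts, mu_ts, 12.0),
                        collinear_profile(),
                    ),
                ),
                name=f"groupB-{i}",
            )
        )
    return group_a, group_b
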