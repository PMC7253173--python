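"""Shared fixtures: the recording protocol and seeded single-kernel runs."""

import pytest
from hypothesis import settings

from ecrfdyn import models, revcorr, spikesim, stimgen

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

#: number of seeded repetitions for the multi-seed recovery properties
N_SEEDS = 20

#: ground truth for the single-kernel reference neurons:
#: (model factory, kernel latency mu, sign of the effect, tuned?)
SINGLE_KERNEL_NEURONS = {
    "facilitation": (models.facilitation_neuron, 50.0, +1, True),
    "strong_suppression": (models.strong_suppression_neuron, 80.0, -1, False),
    "untuned_suppression": (models.untuned_suppression_neuron, 60.0, -1, False),
    "tuned_suppression": (models.tuned_suppression_neuron, 80.0, -1, True),
}


@pytest.fixture(scope="session")
def protocol_sequence():
    """The full recording protocol: 40 trials x 10 s, 18 orientations x 20 ms."""
    return stimgen.generate_sequence(seed=2024)


def _zmap_for(model, sequence, seed):
    spikes = spikesim.simulate_spikes(model, sequence, seed=seed)
    table = revcorr.count_stimuli_before_spikes(spikes, sequence)
    return revcorr.zscore_map(revcorr.lor_map(table))


@pytest.fixture(scope="session")
def single_kernel_runs(protocol_sequence):
    """z-scored LOR maps for each reference neuron over N_SEEDS spike seeds."""
    runs = {}
    for name, (factory, _, _, _) in SINGLE_KERNEL_NEURONS.items():
        model = factory()
        runs[name] = [
            _zmap_for(model, protocol_sequence, seed=1000 + s) for s in range(N_SEEDS)
        ]
    return runs


@pytest.fixture(scope="session")
def null_run(protocol_sequence):
    """A kernel-free (baseline-only) recording at the full protocol."""
    spikes = spikesim.simulate_spikes(models.baseline_neuron(), protocol_sequence, seed=77)
    table = revcorr.count_stimuli_before_spikes(spikes, protocol_sequence)
    return spikes, table, revcorr.zscore_map(revcorr.lor_map(table))
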