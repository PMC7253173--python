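"""Canned small datasets used by tests and worked examples.

All fixtures are generated programmatically and deterministically from a
seed; writing them twice with the same seed produces byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import numpy as np

from . import io, models
from .spikesim import SpikeTrain, simulate_spikes
from .stimgen import StimulusSequence, generate_sequence, make_orientation_grid

__all__ = ["micro_experiment", "make_fixtures"]


def micro_experiment(seed: int = 0) -> Tuple[StimulusSequence, SpikeTrain]:
    """A 3-trial, 10-frame-per-trial micro recording with ~20 spikes.

    Small enough that spike-preceding stimulus counts can be checked against
    exhaustive hand enumeration.
    """
    seq = generate_sequence(
        make_orientation_grid(20.0),
        frame_ms=20.0,
        trial_ms=200.0,
        n_trials=3,
        p_blank=0.2,  # raised so the tiny sequence actually contains blanks
        seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    counts = (7, 6, 7)
    trial = np.repeat(np.arange(3, dtype=np.int64), counts)
    times = np.concatenate([np.sort(rng.uniform(0.0, 200.0, c)) for c in counts])
    spikes = SpikeTrain(
        trial=trial, time_ms=times, n_trials=3, trial_ms=200.0,
        seed=seed + 1, description="micro-fixture",
    )
    return seq, spikes


def make_fixtures(seed: int, outdir) -> dict:
    """Write the canned fixture set; returns a dict of written paths.

    (a) the micro experiment (hand-checkable counts);
    (b) the three single-mechanism reference neurons, as model YAML plus a
        short 5-trial simulated recording each;
    (c) the two duration-experiment models (model YAML);
    (d) two synthetic laminar groups (member model YAML files).
    """
    outdir = Path(outdir)
    written = {}

    seq, spikes = micro_experiment(seed)
    io.write_stimulus(seq, outdir / "micro" / "stimulus.csv")
    io.write_spikes(spikes, outdir / "micro" / "spikes.csv")
    written["micro"] = [outdir / "micro" / "stimulus.csv", outdir / "micro" / "spikes.csv"]

    ref = {
        "facilitation": models.facilitation_neuron(),
        "untuned_suppression": models.untuned_suppression_neuron(),
        "tuned_suppression": models.tuned_suppression_neuron(),
    }
    short_seq = generate_sequence(n_trials=5, seed=seed + 10)
    io.write_stimulus(short_seq, outdir / "neurons" / "stimulus.csv")
    written["neurons"] = [outdir / "neurons" / "stimulus.csv"]
    for i, (name, model) in enumerate(sorted(ref.items())):
        mpath = outdir / "neurons" / f"{name}.yaml"
        spath = outdir / "neurons" / f"{name}_spikes.csv"
        io.write_model(model, mpath)
        io.write_spikes(simulate_spikes(model, short_seq, seed=seed + 20 + i), spath)
        written["neurons"] += [mpath, spath]

    written["duration_models"] = []
    for name, model in (
        ("duration_model_one", models.duration_model_one()),
        ("duration_model_two", models.duration_model_two()),
    ):
        mpath = outdir / "duration" / f"{name}.yaml"
        io.write_model(model, mpath)
        written["duration_models"].append(mpath)

    group_a, group_b = models.laminar_group_models(seed=seed + 40)
    written["laminar"] = []
    for label, group in (("groupA", group_a), ("groupB", group_b)):
        for i, model in enumerate(group):
            mpath = outdir / "laminar" / f"{label}_{i}.yaml"
            io.write_model(model, mpath)
            written["laminar"].append(mpath)

    io.write_manifest(
        outdir / "manifest.json",
        seed=seed,
        files={k: [str(p) for p in v] for k, v in written.items()},
    )
    return written
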