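# ecrfdyn

Reverse-correlation analysis and generative modeling of extra-classical
receptive field (eCRF) dynamics in primary visual cortex.

Neurons in V1 respond to stimuli inside their classical receptive field
(CRF), but stimuli in the surrounding region — the eCRF — modulate that
response without driving spikes themselves. This modulation is a mixture of
mechanisms with different signs, orientation preferences and latencies:
orientation-tuned facilitation, orientation-untuned suppression, and
orientation-tuned suppression. `ecrfdyn` is for sensory neurophysiologists
and modelers who want to separate those mechanisms in the *temporal* domain:
it implements the dynamic-surround reverse-correlation paradigm end to end,
together with a generative gain-kernel model whose ground truth validates
every stage by parameter recovery.

## The statistic and the model

A grating drifting over the CRF provides steady drive (~60 spikes/s) while
the surround plays a rapid sequence: every 20 ms a new orientation θ is
drawn uniformly from 18 drift directions × 2 spatial phases, with occasional
mean-grey blanks. For each lag τ ∈ [0, 200] ms the analysis asks which
stimulus preceded spikes, and summarises modulation as the log-odds ratio

    R_θ(τ) = ln [ p(θ | τ, spike) / p(blank | τ, spike) ],

positive when orientation θ at lag τ facilitates spiking, negative when it
suppresses. Maps are z-scored by the SD of the pre-causal 0–20 ms lags and
thresholded at |z| > 2; band averages (collinear = within 20° of 0°/180°,
orthogonal = within 20° of 90°/270°) yield per-mechanism magnitude, peak
time, onset, offset and duration, plus orientation tuning metrics (peak,
full-width-at-half-height bandwidth, axial circular variance).

The generative model drives an inhomogeneous Poisson process with
multiplicative gain kernels: each surround frame contributes a Gaussian
temporal kernel `A·exp(−(t−μ)²/2σ²)` (scaled by an axial Von Mises
orientation profile when tuned), combined as

    G(t) = Π_fac (1 + D_k(t)) / Π_sup (1 + D_k(t)).

Canonical kernels: facilitation A=1.2, μ=50 ms, σ=5 ms; strong suppression
A=1.7, μ=80, σ=10; untuned suppression A=1.1, μ=60, σ=7; tuned suppression
A=1.1, μ=80, σ=10 (Von Mises peak 0°, HWHH 30°). See `docs/methods.md` for
conventions and numerical choices.

## Worked example

```python
import numpy as np
from ecrfdyn import components, models, revcorr, spikesim, stimgen

seq    = stimgen.generate_sequence(seed=2024)          # 40 trials x 10 s
spikes = spikesim.simulate_spikes(models.facilitation_neuron(), seq, seed=1000)
table  = revcorr.count_stimuli_before_spikes(spikes, seq)
zmap   = revcorr.zscore_map(revcorr.lor_map(table))
tc     = components.band_average(zmap, components.collinear_band())
s      = components.summarize_components(zmap)["facilitation"]
print(f"{spikes.n_spikes} spikes at {spikes.mean_rate_hz:.1f} Hz; "
      f"collinear peak z={tc.max():.1f} at {zmap.lags[np.argmax(tc)]:.0f} ms; "
      f"component {s.onset_ms:.1f}-{s.offset_ms:.1f} ms")
```

prints

```
30676 spikes at 76.7 Hz; collinear peak z=15.6 at 50 ms; component 31.0-66.1 ms
```

The simulated neuron's only surround mechanism is the facilitation kernel
with latency μ = 50 ms; reverse correlation recovers that latency exactly
(peak of the collinear band average at lag 50 ms), with the component
significant from ~31 to ~66 ms.

The numbered scripts under `analysis/` run the full study on synthetic data:
`01` simulates reference neurons, `02` builds their orientation × time maps
(recovered latencies 50/80/60/80 ms), `03` extracts component and tuning
metrics, `04` classifies two synthetic "laminar" groups by template
cross-correlation (100% correct, early group peaking ~30 ms before the late
template), and `05` maps net modulation against stimulus duration (no net
effect below 40 ms, net facilitation at 60–80 ms, net suppression beyond
200 ms deepening to −0.41 at 1920 ms). Each writes tidy tables under
`results/`.

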