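#!/usr/bin/env python
"""Extract component magnitude, timing and orientation-tuning metrics.

From each z-scored map written by 02_reverse_correlation_maps.py, extracts
the three component readouts (tuned facilitation, untuned suppression,
tuned suppression), their peak z, peak time, onset/offset/duration at the
|z| = 2 criterion, and -- for significant tuned components -- the orientation
tuning curve in the per-neuron window (peak +- half duration), its peak
orientation, full-width-at-half-height bandwidth and circular variance.
Writes one tidy table per kind under results/components/.
"""

import sys
from pathlib import Path

import pandas as pd

from ecrfdyn import components as comp
from ecrfdyn import io

MAPS = Path(__file__).resolve().parent.parent / "results" / "maps"
OUT = Path(__file__).resolve().parent.parent / "results" / "components"


def main() -> int:
    paths = sorted(MAPS.glob("*_map.csv"))
    if not paths:
        print("run analysis/02_reverse_correlation_maps.py first", file=sys.stderr)
        return 1

    comp_rows, tuning_rows = [], []
    for path in paths:
        neuron = path.stem.replace("_map", "")
        m = io.read_map(path)
        for cname, s in comp.summarize_components(m).items():
            comp_rows.append({
                "neuron": neuron, "component": cname, "peak_z": s.peak_z,
                "peak_time_ms": s.peak_time_ms, "onset_ms": s.onset_ms,
                "offset_ms": s.offset_ms, "duration_ms": s.duration_ms,
                "significant": s.significant,
            })
            if s.significant and cname != "untuned_suppression":
                tc = comp.tuning_curve(m, comp.default_tuning_window(s))
                tuning_rows.append({
                    "neuron": neuron, "component": cname,
                    "peak_orientation_deg": tc.peak_orientation_deg,
                    "bandwidth_fwhh_deg": tc.bandwidth_fwhh_deg,
                    "circular_variance": comp.circular_variance(tc),
                })

    OUT.mkdir(parents=True, exist_ok=True)
    cdf = pd.DataFrame(comp_rows)
    tdf = pd.DataFrame(tuning_rows)
    cdf.to_csv(OUT / "component_summaries.csv", index=False)
    tdf.to_csv(OUT / "tuning_metrics.csv", index=False)

    print("component summaries (significant only):")
    sig = cdf[cdf.significant]
    print(sig.to_string(index=False, float_format=lambda x: f"{x:6.1f}"))
    print("\ntuning metrics:")
    print(tdf.to_string(index=False, float_format=lambda x: f"{x:6.2f}")
          if len(tdf) else "  (none)")
    print(f"\nwrote {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
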