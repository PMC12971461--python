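#!/usr/bin/env python
"""Generate the study's synthetic cEEG recording with scheduled ictal events.

Emulates a 4-channel, 250 Hz epidural recording: 1/f baseline at 20 uV RMS,
then alternating focal 3 Hz spike-wave bursts (confined to one channel) and
generalized common-source bursts (coherence 0.9, source Hurst 0.3), all at
5x baseline RMS.  Writes the EDF to scratch/ (binary) and the ground-truth
event table to results/.
"""

from pathlib import Path

import ictalkit as ik
from ictalkit.synthetic import archetype_spec

ROOT = Path(__file__).resolve().parents[1]
SEED = 21


def main() -> None:
    spec = archetype_spec(seed=SEED, n_events=6)
    rec, truth = ik.assemble_recording(spec)
    (ROOT / "scratch").mkdir(exist_ok=True)
    (ROOT / "results").mkdir(exist_ok=True)
    ik.write_edf(rec, ROOT / "scratch" / "recording.edf")
    truth.to_csv(ROOT / "results" / "ground_truth_events.csv", index=False)
    print(f"recording: {rec.n_channels} channels, {rec.duration:.0f} s at "
          f"{rec.sampling_rate:.0f} Hz")
    print(f"injected {len(truth)} events "
          f"({(truth.kind == 'focal').sum()} focal, "
          f"{(truth.kind == 'generalized').sum()} generalized)")
    print(f"wrote scratch/recording.edf and results/ground_truth_events.csv")


if __name__ == "__main__":
    main()
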