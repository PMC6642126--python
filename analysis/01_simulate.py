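#!/usr/bin/env python
"""Simulate the averaged-ABR dataset for the paired noise-burst design.

Generates one averaged recording per subject x condition for the 4x4
stimulus grid (NB1 5/10/30/100 ms x gap 2/3/5/10 ms, NB2 50 ms) with the
default generator (8 subjects, 600-sweep averaging noise, suppression /
enhancement modulation switching at gap/NB1 = 0.5) and stores them in the
HDF5 recording container.
"""

from pathlib import Path

from abrgap import GeneratorConfig, default_grid, generate_dataset, write_recordings

SEED = 1
OUT = Path("scratch/recordings.h5")


def main() -> None:
    grid = default_grid()
    recordings = generate_dataset(grid, n_subjects=8, config=GeneratorConfig(), seed=SEED)
    OUT.parent.mkdir(exist_ok=True)
    write_recordings(recordings, OUT)
    n_sup = sum(1 for r in recordings if r.condition.gap_ms / r.condition.nb1_ms <= 0.5)
    print(f"wrote {len(recordings)} recordings to {OUT}")
    print(f"  {n_sup} in suppressed conditions, {len(recordings) - n_sup} in "
          "balanced/enhanced conditions")


if __name__ == "__main__":
    main()
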