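#!/usr/bin/env python
"""Simulate the synthetic 18-subject infant cohort.

Generates parameter maps (vfm, nu_ic, nu_iso) on the default 32^3 grid at
the 18 study ages (102-2713 days, 13 M / 5 F) under the calibrated
region-specific growth laws, and writes the NIfTI volumes, label atlas,
subject table and ground-truth growth-law record under scratch/cohort/.
"""

from pathlib import Path

from gratio_dev import cohort

SEED = 0
OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"


def main() -> None:
    spec = cohort.default_cohort_spec(rng_seed=SEED)
    c = cohort.generate_cohort(spec)
    written = cohort.write_cohort(c, OUT)
    print(f"Simulated {len(c.subjects)} subjects on a {spec.grid_shape} grid "
          f"({len(c.regions)} atlas regions).")
    print(f"Voxel draws clamped into [0, 1]: {c.clamp_fraction:.3%} "
          "(well under the 1% budget at default noise).")
    print(f"Wrote {len(written)} files to {OUT}")
    print(c.subject_table().to_string(index=False))


if __name__ == "__main__":
    main()
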