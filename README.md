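# gratio-dev

Myelin g-ratio index mapping and developmental trajectory analysis for
infant quantitative MRI.

## The problem

The g-ratio — the ratio of the inner axon diameter to the outer
myelinated-fiber diameter — governs the conduction velocity and efficiency
of white-matter pathways; theory puts the CNS optimum near 0.77–0.8.
It cannot be measured directly in vivo, but an aggregate voxel-wise
*index* of it can be computed by combining two quantitative MRI modalities:
a myelin water volume fraction map VF_M (multicomponent relaxometry,
e.g. mcDESPOT) and the NODDI diffusion-model volume fractions ν_IC
(intracellular/neurite) and ν_ISO (isotropic/free water):

    VF_A = (1 − VF_M)(1 − ν_ISO) ν_IC        axon volume fraction
    VF_F = VF_M + VF_A                        total fiber volume fraction
    g    = √(1 − VF_M / VF_F)                 g-ratio index

In early childhood g falls from near 1 (axons present, little myelin) toward
the theoretical optimum as myelination proceeds. This package implements the
full analysis around that index for a cross-sectional infant cohort
(18 subjects, 102–2713 days):

1. **Synthetic cohort generation** — seeded 3-D parameter maps with
   region-specific growth laws (sigmoidal VF_M, logarithmic ν_IC, small
   constant ν_ISO, Gaussian voxel noise) over a block-shaped label atlas,
   so every downstream stage is testable without scan data.
2. **Voxel-wise g-ratio maps** with degenerate-voxel handling and a
   clamp/strict policy for slightly out-of-range inputs.
3. **Regional statistics** — per-subject mean/SD per atlas region, with
   voxel-count-weighted hemisphere merging.
4. **Trajectory modeling** — OLS fits of g(age) = α·ln(age) + β per region
   and hemisphere, an extra-sum-of-squares F-test (dual- vs single-curve,
   df = (2, n−4)) for hemispheric asymmetry, and extrapolation to
   10,000 days for the late-childhood asymptote.
5. **Association statistics** — age-controlled Pearson partial correlations
   of g with VF_M, VF_F, ν_IC, ν_ISO, converted to T statistics (df = n−3).

The package also ships the published per-region trajectory coefficients and
asymptote values as a versioned fixture and can re-derive one table from
the other (`gratio-dev verify-tables`).

## Worked example

Run the numbered analysis scripts in order (volumes go under `scratch/`,
tables under `results/`):

```bash
python analysis/01_simulate_cohort.py
python analysis/02_compute_gratio_maps.py
python analysis/03_regional_trajectories.py
python analysis/04_associations.py
python analysis/05_verify_published_tables.py
```

`02_compute_gratio_maps.py` prints the per-subject median white-matter
g-ratio index, which falls with age exactly as the biology dictates:

```
sub-01 (age   102 d): median white-matter g = 0.947
sub-02 (age   116 d): median white-matter g = 0.946
...
sub-17 (age  2713 d): median white-matter g = 0.838
```

`03_regional_trajectories.py` fits the logarithmic trajectories and
extrapolates to 10,000 days; the synthetic cohort's asymptotes cluster
around 0.79 (e.g. left frontal white matter 0.79, from the fitted curve
−0.039·ln(age) + 1.147), near the theoretical optimum.
`05_verify_published_tables.py` recomputes the reference asymptote table
from the reference fits:

```
      region hemisphere  computed_asymptote  published_asymptote  match
  Frontal WM       left                0.77                 0.77   True
  Frontal WM      right                0.78                 0.78   True
...
19/20 cells reproduced exactly; the single mismatch (right cerebellar:
computed 0.91 vs reported 0.84) is a known inconsistency inside the
source tables themselves.
Cross-region average of the 20 reported values: 0.78
```

The same stages are available as a CLI
(`gratio-dev simulate|compute-gratio|aggregate|fit-trajectories|associations|run-all|verify-tables`);
`run-all` executes the whole pipeline into one directory with a manifest of
output hashes, and is hash-identical across runs with the same seed.

## Layout

- `src/gratio_dev/` — the library: `cohort` (simulator + atlas), `gratio`
  (index math), `roi` (regional stats), `trajectories` (fits, F-test,
  asymptotes), `associations` (partial correlations), `pipeline`
  (orchestration + verification), `reference` (shipped tables), `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and end-to-end suites.
- `docs/methods.md` — model, assumptions, parameter choices, limitations.
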