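# gastrulaquant

Quantitative image analysis of mechanically stimulated gastrulation in
blastula-stage embryos (and curvature inversion in choanoflagellate sheets),
built as a tested, reusable pipeline and exercised end-to-end on a synthetic
embryo-image generator with exhaustively known ground truth.

It is written for people quantifying epithelial-sheet morphogenesis from
multi-channel confocal stacks: embryo-scale morphometrics, cell-scale
segmentation of junctional (actin) networks, fluorescence ratio and gradient
measurements, the parameterization of orbital-shaker flow stimulation, and
the exact cohort statistics that compare stimulated and control embryos.

## What it computes

**Morphometry.** From a 2-D section of the stack, the embryo outline is
segmented (Otsu threshold, largest component, holes filled) and measured:

- elliptic deformation `L/W` — major over minor axis of the moment-equivalent
  ellipse; percent deformation is `100·(L/W − 1)`;
- invagination depth `d/D` — the convex-hull deficiency of the outline (the
  deepest dent below the hull chord) over the equivalent-area diameter `D`;
- gastrulation call — `d/D > 0.18`, strict inequality.

**Cell catalog.** The cell-scale algorithm: project the stack to 2-D (sum of
5 planes around the per-pixel z maximum of the junctional channel), Otsu
filter, reduce the junctional signal to a one-pixel ridge skeleton, dilate it
to the junction width (5 px), watershed-partition the tissue, and emit one
record per cell: apical area, apical perimeter, and per-channel junctional
and cytosolic mean intensities normalised to the background mean.

**Intensity quantification.** Per-cell nuclear/cytoplasmic signal ratios
(each nucleus vs an equal-area cytoplasmic region of the same cell, ~10
random cells per embryo), tissue-scale total intensity per pixel normalised
to background, the oral–aboral gradient (brightest 10 %-of-extent slab along
the embryo axis over the rest, in percent), and per-cell counts of
internalised fluorescent beads.

**Stimulation.** Orbital-shaker flow: peak tangential speed
`2π·(rpm/60)·radius` and the mean |v| of a sinusoidally reversing flow
(`2/π` of peak), plus seeded stochastic stimulation schedules drawn within
instrument limits and a validator for hand-written schedules.

**Statistics.** Fisher's exact test on positive/negative embryo counts
(two-sided by probability ordering, exact integer arithmetic), the
Mann–Whitney U test on per-embryo measures (exact permutation p for small
samples, tie-corrected normal approximation otherwise), the five-vs-five
subsampling rule for bimodal samples, and the responder-pool fraction
`(p_stim − p_ctrl)/(1 − p_ctrl)`.

## Worked example

```python
from gastrulaquant import flow_speed, ShakerSettings, responder_pool_fraction
from gastrulaquant.synthetic import EmbryoSpec, generate_embryo_stack
from gastrulaquant.morphometry import (
    segment_embryo, measure_invagination, midplane_section, elliptic_ratio)

stack, truth = generate_embryo_stack(EmbryoSpec(invagination_depth_frac=0.25, seed=1))
shape = segment_embryo(midplane_section(stack), stack.pixel_size_um)
inv = measure_invagination(shape)
print(f"L/W = {elliptic_ratio(shape):.3f},  d/D = {inv.d_over_D:.3f},  "
      f"gastrulating = {inv.gastrulating}")

peak, mean_abs = flow_speed(ShakerSettings(rpm=85, radius_cm=2.0, reversal_period_s=2.5))
print(f"85 rpm, 2 cm orbit: peak = {peak:.1f} cm/s, mean |v| = {mean_abs:.1f} cm/s")
print(f"responder pool: {100 * responder_pool_fraction(0.78, 0.33):.1f} %")
```

prints

```
L/W = 1.209,  d/D = 0.247,  gastrulating = True
85 rpm, 2 cm orbit: peak = 17.8 cm/s, mean |v| = 11.3 cm/s
responder pool: 67.2 %
```

The synthetic embryo was built with an imposed dent of `d/D = 0.25`; the
measurement recovers 0.247 and classifies the embryo as gastrulating (the
0.18 threshold is exceeded).  An invagination rate of 78 % under stimulation
against 33 % in static controls means 67 % of the embryos that would have
stayed non-invaginated were switched by the flow.  (The measured `L/W` of a
dented embryo reflects the dent; elliptic deformation is meant for
non-invaginated outlines.)

## Command line

`gastrulaquant` exposes the stages as verbs:
`simulate`, `morpho`, `cells`, `nc-ratio`, `tissue`, `gradient`, `beads`,
`schedule`, `test`, `run`.  For example:

```sh
gastrulaquant simulate --spec spec.yaml --out sim/ --seed 3
gastrulaquant morpho --stack sim/stack.tif --out morpho.csv
gastrulaquant schedule --total-min 120 --seed 1 --out schedule.csv
gastrulaquant test --counts 26 7 10 20
```

## Analysis scripts

`analysis/01…06` are thin narrative drivers over the library: simulate a
two-condition cohort, measure it, demonstrate cell-catalog and intensity
recovery, parameterize the stimulation, and run the cohort statistics.
Tables land in `results/`; bulky image stacks go to `scratch/`.

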