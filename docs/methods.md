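# Methods

This note documents the measurement models, the synthetic-data model, the
numerical choices, and the limits of what the tests demonstrate.

## Embryo morphometry

A blastula is treated as a closed epithelial monolayer imaged as a confocal
z-stack.  Measurements run on a 2-D view of the junctional (cortical actin)
channel.

**Section, not projection, for depth.**  The invagination is a crater: in a
full axial projection the surrounding shell occludes it, and the silhouette
of a dented ball under-reports the depth by a geometry-dependent amount that
saturates at `R·(1 − cos w)` for a mouth half-angle `w`, independent of the
true depth.  Depth is therefore measured on a mid-plane section (default:
the single central z plane, `MorphometryConfig.section_planes = 1`), with
the dent axis assumed to lie in the imaging plane.  Averaging several planes
is supported but dilutes steep dent walls, which shift radially by a full
shell thickness between adjacent planes on deep invaginations.

**Outline.**  The section is thresholded, the largest connected component
kept, holes filled, and the mask smoothed (Gaussian, sigma 1 px, then
re-thresholded at 0.5) to suppress pixel-scale concavities before hull
computation.  Two candidate background cuts are evaluated — the 2-class Otsu
threshold and the lowest cut of a 3-class multi-Otsu — because on thin
sections the background can so dominate the histogram that the 2-class split
lands between the shell baseline and the junctional peak.  The kept
candidate is the one whose filled largest component does not run along the
field border (the specimen is imaged away from the edge), preferring the
larger mask.  On genuinely two-level images only the plain Otsu branch
applies.

**Quantities.**
- `L`, `W`: major/minor axis of the moment-equivalent ellipse (µm).
  Percent deformation `= 100·(L/W − 1)`, so ratios of 1.05 / 1.30 read as
  5 % / 30 %.  Intended for non-invaginated outlines; a dent biases the
  moments.
- `D`: diameter of the circle with the mask's area.  Chosen over a caliper
  diameter because it is stable on dented shapes and equals `2r` on disks.
- `d`: the maximum distance from the convex-hull boundary to the outline —
  the depth of the deepest dent below its mouth chord.  Parameter-free,
  orientation-independent, and equivalent to manually calipering from a line
  drawn across the dent mouth.
- Gastrulation call: `d/D > 0.18`, strictly.  A sweep of imposed depths
  0–0.40 in 0.05 steps classifies with zero mislabels; the step sits between
  0.15 and 0.20.

Only the single deepest dent is measured; multi-site or tubular
invaginations are out of scope.

## Cell catalog

The cell-scale chain mirrors the junctional-image workflow: (1) project each
channel by summing a 5-plane window centred on the per-pixel z maximum of
the junctional channel (the same window for all channels, so every channel
is read on the same apical surface); (2) Otsu the projection and take the
filled largest component as the tissue mask; (3) skeletonize the junctional
ridges; (4) dilate the skeleton by 5 px (the junction width) and use the
skeleton-free components as watershed seeds on the junctional intensity
landscape; (5) record per cell: apical area (pixel count × pixel area),
apical perimeter (Crofton estimate), centroid, border flag, and per-channel
junctional (cell ∩ dilated skeleton) and cytosolic (cell minus the dilated
skeleton plus a one-pixel guard ring) means, each divided by the mean
intensity outside the mask.

The skeletonizer is a deliberately simple ridge follower: Gaussian smoothing
(sigma 1 px), a threshold on the in-mask response (Otsu by default, a
quantile if configured), morphological thinning, and iterative endpoint
pruning (8 px) to remove spurs while preserving loops.  It plays the role of
a discrete Morse-complex ridge extractor — junction centerlines — and no
equivalence with any such tool is claimed; its pruning length has no
externally anchored default.

The one-pixel cytosolic guard ring exists because a rasterised centerline
sits within half a pixel of the true junction: without the guard, the
brightest junction-edge pixels leak into the cytosolic mean and bias
junctional/cytosolic contrasts low by tens of percent.

Border cells are flagged and excluded from summary statistics by default
(truncated apices bias area and perimeter).  Watershed and thinning are
deterministic, so identical inputs give identical catalogs.

## Intensity quantification

- **N/C ratio.**  For each sampled cell, the nuclear mean over the mean of
  an equal-area cytoplasmic region of the same cell — the pixels nearest the
  nucleus, inside the cell, outside the junction band (an annulus grown by
  distance ordering until it matches the nucleus pixel count).  Ten cells
  are sampled (seeded, without replacement) from the domain of interest; a
  caller-supplied domain mask restricts sampling, e.g. to lateral
  invagination domains when the dent centre loses signal.  Because sampling
  is without replacement from a finite sheet, the variance of the embryo
  mean scales as `(1 − n/N)/n` rather than `1/n`.
- **Tissue intensity.**  The z-summed stack's mean over the embryo mask
  divided by its mean over the background; meant for half-embryo stacks
  (plane spacing 2 µm), checked only with a warning.
- **Gradient.**  The axis is either supplied (embryo centroid towards the
  dent apex) or taken as the intensity-centroid offset direction, which is
  how non-gastrulated embryos are oriented.  The "blastopore plane" is a
  slab of 10 % of the embryo extent along the axis — a slab rather than a
  single plane for noise robustness — positioned where its mean intensity is
  maximal; the result is `100·(slab/rest − 1)` percent.
- **Beads.**  Strict local maxima of the bead channel above
  `background mean + 5·SD`, assigned to their containing cell label.
  Sub-resolution beads are single PSF-scale blobs, so one maximum each; the
  detector has no anchored reference, and `k = 5` is a conventional
  spot-detection setting.

All four outputs are dimensionless and invariant under global rescaling of
signal and background together.

## Stimulation

Peak tangential speed `2π·(rpm/60)·radius_cm` (cm/s).  The reversing flow
has no stated velocity model, so the mean |v| is exposed under two models:
sinusoidal (`2/π` of peak, default) and square (equal to peak).  For the
85 rpm / 2 cm embryo setting these give 17.8 and 11.3 cm/s; both are
reported and neither is asserted against any external figure.  Stochastic
schedules draw `(rpm, duration, period)` segments uniformly within
caller-supplied instrument limits (defaults 68–99 rpm, 2–9 s, 5–29 min),
truncating the last segment so the total duration is exact; `validate_schedule`
reports out-of-envelope segments, and the bundled six-segment reference
sequence indeed contains two rpm values (58, 55) below the default floor.

## Statistics

- **Fisher's exact test**: two-sided by probability ordering, computed on
  exact integer hypergeometric numerators (the common denominator cancels),
  so the tail ordering involves no floating-point tolerance; practical for
  totals up to ~10⁴.  One-sided variants are available.
- **Mann–Whitney U**: midranks; exact permutation p (all `C(n1+n2, n1)`
  label assignments, ties handled exactly through the midranks) when both
  samples have ≤ 8 observations, otherwise the normal approximation with tie
  correction and continuity correction.
- **Bimodal subsample rule**: the caller asserts bimodality (it is not
  auto-detected); the five largest values of the upper mode are compared
  with the five values closest to the lower-mode mean, ties among equally
  close values broken reproducibly by seed.
- **Responder-pool fraction**: `(p_stim − p_ctrl)/(1 − p_ctrl)`, clipped
  below at zero; undefined at `p_ctrl = 1`.

No multiple-testing correction is applied anywhere.

## Synthetic data model

The generator produces the study conditions the measurements assume, with
exhaustively known truth.

**Embryos.**  A ~100 µm ellipsoidal shell (semi-axes `(a, b, b)`,
`a/b = L/W`, volume preserved), shell thickness 8 µm measured as true
Euclidean depth from the surface (anisotropic EDT — a radial band breaks up
on steep dent walls).  The cell lattice is the spherical Voronoi
tessellation of a Fibonacci point set (default 200 cells; tests use 120,
giving ~13 µm cells), rendered as a 2 µm junctional band at 120 counts over
a 40-count cortical baseline, background 10.  Nuclei are 2.5 µm blobs
mid-shell under each cell centre.  Default sampling: 1 µm pixels, 2 µm
z-step.

**Invagination.**  A solid-of-revolution dent about the oral axis: radius
scaled by `1 − A·g(θ/w)` with a steep-walled bump `g(t) = exp(−(t/0.5)⁴)`.
The mouth half-angle narrows with depth, `w = min(π/3, arccos(2·(d/D) +
0.12))`, because the measured depth is the drop below the hull chord: with a
wide mouth the chord itself sits deeper than the apex and no amplitude can
realise a large imposed `d/D`.  The amplitude `A` is solved by bisection so
that the convex-hull deficiency of the analytic mid-plane curve equals the
imposed `d/D` times the equivalent diameter of the dented section (the `D`
the measurement will see), iterated to a fixed point.  The imposed `d/D` is
thus the measurable quantity by construction, not a free-hand parameter.

**Gradient.**  A cosine ramp from the oral pole whose amplitude is
calibrated on the rendered shell voxels so that the 10 %-of-extent oral slab
over the rest equals exactly `1 + gradient_ratio` before noise.

**Flat sheets.**  Single-plane Voronoi (jittered grid for square counts,
Lloyd-relaxed random seeds otherwise) or regular hexagonal lattices;
per-pixel truth labels come from exact nearest-seed assignment, and truth
areas/perimeters from the exact polygons, so they tile the sheet to machine
precision.  An optional constriction zone raises seed density so the mean
apical area inside is a set fraction of outside.  Nuclear translocation
moves a fraction τ of each cell's cytosolic signal mass into its nucleus
(mass conserving), giving a per-cell true N/C ratio `(1 + κτ)/(1 − τ)` with
κ the cytosol/nucleus area ratio; `translocation_for_nc_ratio` inverts the
mean for a target ratio.  Beads are Poisson per cell, placed ≥ 3 px apart
and ≥ 2 px from junctions and nuclei so that noiseless detection is exact.

**Noise** is Poisson photon noise on the scaled intensity followed by
additive Gaussian read noise, applied last, all driven by one seeded
generator: identical spec + seed reproduces stacks bit for bit.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no optical PSF or axial blur, no photobleaching or
depth-dependent attenuation, no cell-shape irregularity beyond the Voronoi
lattice, no fluid–structure mechanics, no three-axis acquisition schemes,
and sheet fixtures are strictly planar.  Recovery results certify the
measurement code against its stated geometry, not segmentation performance
on degraded microscopy.

## Problem sizes and runtimes

The test battery uses 120-cell, 100 µm embryos at 1 µm/px (about 2 s to
render each), sheets of 9–64 cells for segmentation recovery, 10⁴ null
simulations for the Mann–Whitney level check, and 100–200 random cases for
the Otsu/Fisher oracles; the whole suite runs in about a minute on one CPU.
These sizes were chosen as the smallest at which the geometric tolerances
(±0.03 on ratios, 10 % on areas) are meaningfully exercised.

## Known limitations

- Depth measurement assumes the dent axis lies in the imaging plane of the
  chosen section; out-of-plane invaginations are under-measured.
- The elliptic ratio of an invaginated outline is biased by the dent; use it
  on non-invaginated (flow-deformed) outlines.
- The skeleton stand-in has no persistence control; very low-contrast
  junctions fragment and merge cells.
- `apex_area_in_zone` counts centroids, so cells straddling the zone edge
  contribute stochastically; zones should sit well inside the domain.
- The exact Mann–Whitney branch enumerates up to `C(16, 8)` assignments;
  larger samples switch to the approximation regardless of ties.
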