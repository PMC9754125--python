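"""Fluorescence quantification: N/C ratios, tissue levels, gradients, beads.

Four measurements mirror the imaging readouts of the study:

* per-cell nuclear/cytoplasmic signal ratio, each nucleus normalised to an
  equal-area cytoplasmic annulus of the same cell, sampled over ~10 random
  cells of a domain of interest;
* tissue-scale total intensity per pixel of the summed half-embryo stack,
  normalised to the external background;
* the oral-aboral intensity gradient: the mean of the brightest
  10 %-of-extent slab along the embryo axis over the mean of the rest;
* per-cell counts of internalised fluorescent beads (sub-resolution spots
  detected as strict local maxima above background + k sigma).

All outputs are dimensionless, so they are invariant under a global
rescaling of signal and background together.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .io import ImageStack

log = logging.getLogger("gastrulaquant")

__all__ = [
    "NuclearRatioResult",
    "GradientResult",
    "TissueIntensityResult",
    "nuclear_cytoplasmic_ratio",
    "tissue_intensity",
    "gradient_ratio",
    "count_beads_per_cell",
]


@dataclass(frozen=True)
class NuclearRatioResult:
    per_cell_ratios: np.ndarray
    n_cells_sampled: int
    embryo_mean: float
    sampled_labels: np.ndarray

    def __post_init__(self) -> None:
        if self.n_cells_sampled < 1:
            raise ValueError("need at least one sampled cell")


@dataclass(frozen=True)
class TissueIntensityResult:
    total_intensity_per_pixel: float
    n_planes: int
    z_step_um: float


@dataclass(frozen=True)
class GradientResult:
    blastopore_plane_mean: float
    rest_mean: float
    gradient_ratio_percent: float
    orientation_axis: tuple[float, float, float]


def nuclear_cytoplasmic_ratio(
    signal: np.ndarray,
    nuclei_mask: np.ndarray,
    labels: np.ndarray,
    domain: np.ndarray | None = None,
    junction_mask: np.ndarray | None = None,
    n_sample: int = 10,
    seed: int | None = 0,
) -> NuclearRatioResult:
    """Nuclear over cytoplasmic mean signal, per cell, over a random sample.

    For each sampled cell the nuclear mean is divided by the mean over an
    equal-area cytoplasmic region of the same cell: the pixels nearest the
    nucleus, inside the cell, outside the junction band.  ``domain`` (boolean
    mask) restricts eligibility, e.g. to the lateral invagination domains
    when the dent centre has lost signal.  Sampling is seeded; if fewer than
    ``n_sample`` cells qualify, all are used with a warning.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(labels)
    junction_mask = np.zeros_like(nuclei_mask) if junction_mask is None else junction_mask

    eligible = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        cell = labels == lab
        nuc = cell & nuclei_mask
        cyt = cell & ~nuclei_mask & ~junction_mask
        if not nuc.any() or not cyt.any():
            continue
        if domain is not None and not (cell & domain).sum() > 0.5 * cell.sum():
            continue
        eligible.append(lab)
    if not eligible:
        raise ValueError("no eligible cells with nonempty nuclei in the domain")
    if len(eligible) < n_sample:
        warnings.warn(
            f"only {len(eligible)} eligible cells for n_sample={n_sample}; using all"
        )
        chosen = np.asarray(eligible)
    else:
        chosen = rng.choice(np.asarray(eligible), size=n_sample, replace=False)

    ratios = np.empty(len(chosen))
    for i, lab in enumerate(chosen):
        cell = labels == lab
        nuc = cell & nuclei_mask
        allowed = cell & ~nuclei_mask & ~junction_mask
        dist = ndi.distance_transform_edt(~nuc)
        ys, xs = np.nonzero(allowed)
        order = np.argsort(dist[ys, xs], kind="stable")
        k = min(int(nuc.sum()), len(order))
        ann = (ys[order[:k]], xs[order[:k]])
        ratios[i] = signal[nuc].mean() / signal[ann].mean()
    return NuclearRatioResult(
        per_cell_ratios=ratios,
        n_cells_sampled=len(chosen),
        embryo_mean=float(ratios.mean()),
        sampled_labels=np.asarray(chosen),
    )


def tissue_intensity(stack: ImageStack, mask: np.ndarray, channel: str = "signal",
                     expected_diameter_um: float | None = None) -> TissueIntensityResult:
    """Total intensity per embryo pixel of the z-summed stack, normalised to
    the per-pixel background of the same summed image."""
    img = stack.channel(channel)
    if expected_diameter_um is not None:
        covered = stack.n_planes * stack.z_step_um
        if abs(covered - expected_diameter_um / 2) > 0.5 * expected_diameter_um / 2:
            log.warning(
                "stack covers %.0f um; expected about half the diameter (%.0f um)",
                covered, expected_diameter_um / 2,
            )
    summed = img.sum(axis=0)
    bg = ~mask
    if not bg.any():
        raise ValueError("empty background: normalisation undefined")
    value = summed[mask].mean() / summed[bg].mean()
    return TissueIntensityResult(
        total_intensity_per_pixel=float(value),
        n_planes=stack.n_planes,
        z_step_um=stack.z_step_um,
    )


def _voxel_coords(stack: ImageStack, mask: np.ndarray) -> np.ndarray:
    zi, yi, xi = np.nonzero(mask)
    return np.column_stack([
        xi * stack.pixel_size_um,
        yi * stack.pixel_size_um,
        zi * stack.z_step_um,
    ])


def gradient_ratio(
    stack: ImageStack,
    mask: np.ndarray,
    axis: np.ndarray | None = None,
    slab_frac: float = 0.10,
    channel: str = "signal",
) -> GradientResult:
    """Blastopore-slab over rest-of-embryo mean intensity, as a percent.

    ``mask`` is the 3-D embryo foreground.  The orientation axis is either
    supplied (e.g. embryo centroid towards the dent apex for gastrulating
    embryos) or taken as the direction of the intensity-centroid offset --
    the maximum-gradient direction used to orient non-gastrulated embryos.
    The blastopore plane is implemented as the ``slab_frac`` (10 %) of the
    embryo extent along the axis with the maximal mean intensity, a slab
    rather than a single plane for noise robustness.
    """
    if not mask.any():
        raise ValueError("empty mask")
    vals = stack.channel(channel)[mask]
    pos = _voxel_coords(stack, mask)
    if axis is None:
        geo = pos.mean(axis=0)
        wsum = vals.sum()
        intens = (pos * vals[:, None]).sum(axis=0) / wsum
        offset = intens - geo
        nrm = np.linalg.norm(offset)
        if nrm < 1e-12:
            axis = np.array([1.0, 0.0, 0.0])
        else:
            axis = offset / nrm
    else:
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)

    s = pos @ axis
    lo, hi = s.min(), s.max()
    h = slab_frac * (hi - lo)
    if h <= 0:
        raise ValueError("degenerate mask extent")
    starts = np.linspace(lo, hi - h, 41)
    best_mean, best_slab = -np.inf, None
    for s0 in starts:
        sel = (s >= s0) & (s <= s0 + h)
        if sel.sum() < 10:
            continue
        m = vals[sel].mean()
        if m > best_mean:
            best_mean, best_slab = m, sel
    if best_slab is None:
        raise ValueError("no slab with enough voxels")
    rest = ~best_slab
    if not rest.any():
        raise ValueError("slab swallowed the embryo: no rest region")
    rest_mean = vals[rest].mean()
    return GradientResult(
        blastopore_plane_mean=float(best_mean),
        rest_mean=float(rest_mean),
        gradient_ratio_percent=float(100.0 * (best_mean / rest_mean - 1.0)),
        orientation_axis=tuple(axis),
    )


def count_beads_per_cell(
    bead_channel: np.ndarray,
    labels: np.ndarray,
    k_sigma: float = 5.0,
    min_distance: int = 2,
) -> dict[int, int]:
    """Count bead spots per cell: strict local maxima above
    background mean + k * background SD, assigned to their containing label.

    Background is the zero-label region.  Sub-resolution beads appear as
    PSF-scale blobs, so one maximum per bead.
    """
    img = np.asarray(bead_channel, dtype=float)
    labels = np.asarray(labels)
    bg = img[labels == 0]
    if bg.size == 0:
        raise ValueError("no background region (label 0) for the detector")
    thr = bg.mean() + k_sigma * bg.std()
    size = 2 * min_distance + 1
    is_max = img == ndi.maximum_filter(img, size=size, mode="nearest")
    peaks = is_max & (img > thr)
    counts = {int(lab): 0 for lab in np.unique(labels) if lab != 0}
    for lab in labels[peaks]:
        if lab != 0:
            counts[int(lab)] += 1
    return counts
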