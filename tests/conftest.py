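"""Shared fixtures: synthetic embryos and sheets reused across test modules.

Everything is generated noiseless unless a test needs noise; session scope
keeps the (few-second) 3-D renders to one per configuration.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from gastrulaquant.synthetic import EmbryoSpec, generate_embryo_stack, generate_flat_sheet

EMBRYO_N_CELLS = 120  # ~13 um cells on a 100 um blastula


@pytest.fixture(scope="session")
def embryo_by_ratio():
    """Noiseless embryos with imposed elliptic ratios 1.00 / 1.05 / 1.30."""
    out = {}
    for lw in (1.00, 1.05, 1.30):
        spec = EmbryoSpec(elliptic_ratio=lw, n_cells=EMBRYO_N_CELLS, seed=11)
        out[lw] = generate_embryo_stack(spec)
    return out


@pytest.fixture(scope="session")
def embryo_depth_sweep():
    """Noiseless embryos over the d/D sweep 0 .. 0.40 in 0.05 steps."""
    out = {}
    for frac in np.round(np.arange(0.0, 0.401, 0.05), 2):
        spec = EmbryoSpec(invagination_depth_frac=float(frac), n_cells=EMBRYO_N_CELLS, seed=7)
        out[float(frac)] = generate_embryo_stack(spec)
    return out


@pytest.fixture(scope="session")
def sheet25():
    """25-cell noiseless flat sheet at 0.5 um/px (cells ~30 px across)."""
    spec = EmbryoSpec(n_cells=25, diameter_um=150, pixel_size_um=1.0, seed=3)
    return generate_flat_sheet(spec)


@pytest.fixture(scope="session")
def sheet_sizes():
    """Noiseless sheets of 9 / 25 / 64 cells for segmentation recovery."""
    out = {}
    for n in (9, 25, 64):
        spec = EmbryoSpec(n_cells=n, diameter_um=150, pixel_size_um=1.0, seed=3)
        out[n] = generate_flat_sheet(spec)
    return out


@pytest.fixture(scope="session")
def bead_sheet():
    """100 cells, Poisson bead rate 2.0, noiseless."""
    spec = EmbryoSpec(n_cells=100, diameter_um=200, pixel_size_um=0.5, bead_rate=2.0, seed=6)
    return generate_flat_sheet(spec)


def segment_sheet(stack, config=None):
    """Run the junction-skeleton/watershed chain on a sheet stack."""
    from gastrulaquant.catalog import (
        SkeletonConfig, foreground_mask, project_stack, segment_cells,
        skeletonize_junctions,
    )

    config = config or SkeletonConfig()
    proj = project_stack(stack)
    junction = proj["junction"]
    mask = foreground_mask(junction)
    skel = skeletonize_junctions(junction, mask, config)
    labels = segment_cells(skel, mask, junction, config)
    return proj, mask, skel, labels


def match_labels(labels: np.ndarray, truth_labels: np.ndarray, cell_ids) -> dict[int, int]:
    """Greedy truth-cell -> segmented-label matching by overlap."""
    nlab = int(labels.max())
    out = {}
    for cid in cell_ids:
        tm = truth_labels == cid
        overlap = np.bincount(labels[tm].ravel(), minlength=nlab + 1)
        out[int(cid)] = int(np.argmax(overlap[1:]) + 1) if overlap[1:].any() else 0
    return out
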