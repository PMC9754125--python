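"""Intensity quantification: N/C ratios, tissue levels, gradients, beads."""

from __future__ import annotations

from dataclasses import replace
from math import sqrt

import numpy as np
import pytest

from gastrulaquant.catalog import otsu_threshold
from gastrulaquant.io import ImageStack
from gastrulaquant.quant import (
    count_beads_per_cell,
    gradient_ratio,
    nuclear_cytoplasmic_ratio,
    tissue_intensity,
)
from gastrulaquant.synthetic import (
    EmbryoSpec,
    generate_embryo_stack,
    generate_flat_sheet,
    translocation_for_nc_ratio,
)


def _sheet_parts(stack, truth):
    signal = stack.channel("signal")[0]
    nuclei = stack.channel("nuclei")[0] > 60
    band = stack.channel("junction")[0] > 60
    return signal, nuclei, band


# ---------------------------------------------------------------------------
# nuclear / cytoplasmic ratio
# ---------------------------------------------------------------------------

def test_nc_ratio_uniform_signal_is_one():
    spec = EmbryoSpec(n_cells=25, diameter_um=150, pixel_size_um=1.0, seed=5)
    stack, truth = generate_flat_sheet(spec)
    signal, nuclei, band = _sheet_parts(stack, truth)
    res = nuclear_cytoplasmic_ratio(
        np.full_like(signal, 42.0), nuclei, truth.labels,
        junction_mask=band, n_sample=10, seed=0,
    )
    assert np.allclose(res.per_cell_ratios, 1.0)
    assert res.embryo_mean == pytest.approx(1.0)


def test_nc_ratio_recovers_generator_truth():
    spec = EmbryoSpec(n_cells=49, diameter_um=150, pixel_size_um=0.5,
                      nuclear_translocation=0.2, seed=5)
    stack, truth = generate_flat_sheet(spec)
    signal, nuclei, band = _sheet_parts(stack, truth)
    res = nuclear_cytoplasmic_ratio(signal, nuclei, truth.labels,
                                    junction_mask=band, n_sample=10, seed=1)
    assert res.embryo_mean == pytest.approx(np.nanmean(truth.nc_ratio_true), rel=0.10)


def test_nc_ratio_monotone_in_translocation():
    means = []
    for tau in (0.0, 0.25, 0.5):
        spec = EmbryoSpec(n_cells=49, diameter_um=150, pixel_size_um=0.5,
                          nuclear_translocation=tau, seed=5)
        stack, truth = generate_flat_sheet(spec)
        signal, nuclei, band = _sheet_parts(stack, truth)
        res = nuclear_cytoplasmic_ratio(signal, nuclei, truth.labels,
                                        junction_mask=band, n_sample=10, seed=1)
        means.append(res.embryo_mean)
    assert means[0] < means[1] < means[2]


def test_nc_ratio_sampling_variance_shrinks_with_n():
    """Across seeds, the variance of the embryo mean scales roughly like
    (1 - n/N) / n (without-replacement sampling from a finite sheet)."""
    spec = EmbryoSpec(n_cells=100, diameter_um=220, pixel_size_um=0.75,
                      nuclear_translocation=0.3, seed=8)
    stack, truth = generate_flat_sheet(spec)
    signal, nuclei, band = _sheet_parts(stack, truth)

    def spread(n_sample: int) -> float:
        means = [
            nuclear_cytoplasmic_ratio(signal, nuclei, truth.labels,
                                      junction_mask=band,
                                      n_sample=n_sample, seed=s).embryo_mean
            for s in range(120)
        ]
        return float(np.var(means))

    v5, v20 = spread(5), spread(20)
    assert v5 > v20
    assert 2.0 < v5 / v20 < 9.0  # ~4.75 expected for N=100


def test_nc_ratio_warns_when_sample_short():
    spec = EmbryoSpec(n_cells=9, diameter_um=90, pixel_size_um=1.0, seed=2)
    stack, truth = generate_flat_sheet(spec)
    signal, nuclei, band = _sheet_parts(stack, truth)
    with pytest.warns(UserWarning, match="eligible"):
        res = nuclear_cytoplasmic_ratio(signal, nuclei, truth.labels,
                                        junction_mask=band, n_sample=20, seed=0)
    assert res.n_cells_sampled <= 9


# ---------------------------------------------------------------------------
# tissue intensity
# ---------------------------------------------------------------------------

def test_tissue_intensity_trivial_levels():
    mask = np.zeros((20, 20), dtype=bool)
    mask[5:15, 5:15] = True
    flat = ImageStack(np.full((1, 4, 20, 20), 7.0), ("signal",))
    assert tissue_intensity(flat, mask).total_intensity_per_pixel == pytest.approx(1.0)
    data = np.full((1, 4, 20, 20), 5.0)
    data[:, :, mask] = 15.0
    stack = ImageStack(data, ("signal",))
    assert tissue_intensity(stack, mask).total_intensity_per_pixel == pytest.approx(3.0)


def test_tissue_intensity_linear_in_amplitude():
    spec = EmbryoSpec(n_cells=40, diameter_um=60, pixel_size_um=1.5, seed=3)
    stack, _ = generate_embryo_stack(spec)
    sig = stack.channel("signal")
    # doubling the foreground excess over background doubles the excess ratio
    base = tissue_intensity(stack, sig.max(axis=0) > 15).total_intensity_per_pixel
    data2 = stack.data.copy()
    ch = stack.channels.index("signal")
    fg = data2[ch] > 15
    data2[ch][fg] = 10.0 + 2 * (data2[ch][fg] - 10.0)
    doubled = ImageStack(data2, stack.channels, stack.pixel_size_um, stack.z_step_um)
    b2 = tissue_intensity(doubled, sig.max(axis=0) > 15).total_intensity_per_pixel
    assert (b2 - 1.0) == pytest.approx(2 * (base - 1.0), rel=0.05)


def test_tissue_intensity_empty_background_raises():
    stack = ImageStack(np.random.default_rng(0).random((1, 3, 8, 8)), ("signal",))
    with pytest.raises(ValueError, match="background"):
        tissue_intensity(stack, np.ones((8, 8), dtype=bool))


# ---------------------------------------------------------------------------
# gradient
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def gradient_embryos():
    out = {}
    for g in (0.0, 0.1, 0.2, 0.4):
        spec = EmbryoSpec(gradient_ratio=g, n_cells=60, seed=4, noise=(4.0, 0.0))
        out[g] = generate_embryo_stack(spec)
    return out


def test_gradient_uniform_signal_is_zero():
    spec = EmbryoSpec(gradient_ratio=0.0, n_cells=40, diameter_um=60,
                      pixel_size_um=1.5, seed=1)
    stack, _ = generate_embryo_stack(spec)
    sig = stack.channel("signal")
    mask3d = sig > otsu_threshold(sig)
    res = gradient_ratio(stack, mask3d)
    assert abs(res.gradient_ratio_percent) < 1.0


def test_gradient_recovery_monotone_with_noise(gradient_embryos):
    """Imposed gradients 0 / 10 / 20 / 40 % recovered monotonically, each
    within 20 % relative (10 % Gaussian noise on the signal level)."""
    measured = {}
    for g, (stack, truth) in gradient_embryos.items():
        sig = stack.channel("signal")
        mask3d = sig > otsu_threshold(sig)
        res = gradient_ratio(stack, mask3d)
        measured[g] = res.gradient_ratio_percent
    assert measured[0.0] < 3.0
    for g in (0.1, 0.2, 0.4):
        assert measured[g] == pytest.approx(100 * g, rel=0.20)
    vals = [measured[g] for g in sorted(measured)]
    assert vals == sorted(vals)


def test_gradient_rotation_invariant(gradient_embryos):
    stack, _ = gradient_embryos[0.2]
    sig = stack.channel("signal")
    mask3d = sig > otsu_threshold(sig)
    base = gradient_ratio(stack, mask3d).gradient_ratio_percent
    # rotate 90 degrees in-plane (x -> y)
    rot = ImageStack(np.rot90(stack.data, axes=(2, 3)).copy(), stack.channels,
                     stack.pixel_size_um, stack.z_step_um)
    rsig = rot.channel("signal")
    rres = gradient_ratio(rot, rsig > otsu_threshold(rsig))
    assert rres.gradient_ratio_percent == pytest.approx(base, abs=2.0)


def test_gradient_empty_mask_raises():
    stack = ImageStack(np.zeros((1, 3, 8, 8)), ("signal",))
    with pytest.raises(ValueError, match="empty mask"):
        gradient_ratio(stack, np.zeros((3, 8, 8), dtype=bool))


# ---------------------------------------------------------------------------
# beads
# ---------------------------------------------------------------------------

def test_no_beads_all_zero(sheet25):
    stack, truth = sheet25
    counts = count_beads_per_cell(stack.channel("beads")[0], truth.labels)
    assert sum(counts.values()) == 0


def test_bead_counts_exact_per_cell(bead_sheet):
    """Noiseless fixture: detected counts equal the generator truth exactly,
    per cell and in total."""
    stack, truth = bead_sheet
    counts = count_beads_per_cell(stack.channel("beads")[0], truth.labels)
    assert sum(counts.values()) == truth.bead_counts.sum()
    for i, cid in enumerate(truth.cell_ids):
        assert counts[int(cid)] == truth.bead_counts[i]


def test_bead_rate_doubling_doubles_means():
    totals = {}
    for lam in (1.0, 2.0):
        spec = EmbryoSpec(n_cells=100, diameter_um=200, pixel_size_um=0.5,
                          bead_rate=lam, seed=17)
        _, truth = generate_flat_sheet(spec)
        totals[lam] = truth.bead_counts.sum()
    # ratio within 3 sigma of 2 under Poisson
    lam_tot = 100.0
    sigma = sqrt(totals[1.0] + 4 * totals[1.0]) / lam_tot  # rough delta method
    assert totals[2.0] / totals[1.0] == pytest.approx(2.0, abs=3 * max(sigma, 0.2))


# ---------------------------------------------------------------------------
# rescaling invariance
# ---------------------------------------------------------------------------

def test_quantities_invariant_under_global_rescale(bead_sheet):
    stack, truth = bead_sheet
    k = 3.7
    scaled = ImageStack(stack.data * k, stack.channels,
                        stack.pixel_size_um, stack.z_step_um)
    c1 = count_beads_per_cell(stack.channel("beads")[0], truth.labels)
    c2 = count_beads_per_cell(scaled.channel("beads")[0], truth.labels)
    assert c1 == c2
    signal, nuclei, band = _sheet_parts(stack, truth)
    r1 = nuclear_cytoplasmic_ratio(signal, nuclei, truth.labels,
                                   junction_mask=band, seed=0)
    r2 = nuclear_cytoplasmic_ratio(signal * k, nuclei, truth.labels,
                                   junction_mask=band, seed=0)
    assert np.allclose(r1.per_cell_ratios, r2.per_cell_ratios, rtol=1e-6)


def test_translocation_helper_hits_target():
    spec = EmbryoSpec(n_cells=49, diameter_um=150, pixel_size_um=0.5, seed=5)
    tau = translocation_for_nc_ratio(spec, 1.5)
    _, truth = generate_flat_sheet(replace(spec, nuclear_translocation=tau))
    assert np.nanmean(truth.nc_ratio_true) == pytest.approx(1.5, abs=1e-6)
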