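"""Synthetic blastula-like embryos and flat epithelial sheets with known truth.

The generator emulates the image data the analysis pipeline consumes: a
~100 um spherical shell of polygonal cells (a blastula imaged as a confocal
stack) and planar epithelial sheets for cell-scale unit tests.  Every
generated stack comes with a :class:`GroundTruth` holding the imposed
morphometric quantities (L/W, d/D, oral-aboral gradient), the exact cell
lattice (polygons, areas, perimeters), the noiseless per-region channel
intensities and the per-cell bead counts, so recovery by the measurement code
can be scored against construction rather than against another measurement.

Geometry
--------
The embryo surface is an ellipsoid of semi-axes (a, b, b) with a/b equal to
the imposed elliptic ratio L/W (volume preserved relative to the sphere of
the requested diameter).  The invagination is a solid-of-revolution dent
about ``invagination_axis``: the surface radius is scaled by
``1 - A * g(theta / w)`` inside an angular mouth of half-width ``w``, with a
steep-walled bump profile ``g``.  The amplitude ``A`` is solved numerically
so that the convex-hull deficiency of the mid-plane section -- the quantity
the morphometry stage measures as the depth ``d`` -- equals the imposed
``d/D`` times the equivalent diameter of the dented section.  The mouth
narrows for deep dents (w = min(pi/3, arccos(2 d/D + 0.12))) because a wide
mouth places the hull chord deeper than the dent apex, which would make the
imposed depth geometrically unreachable.

The cell lattice on the embryo is the spherical Voronoi tessellation of a
Fibonacci point set, rendered as a bright junctional band over a dimmer
cortical (shell) baseline.  The oral-aboral signal gradient is a cosine ramp
whose amplitude is calibrated on the rendered shell voxels so that the
mean intensity of the 10 %-of-extent oral slab over the rest of the embryo
equals ``1 + gradient_ratio`` exactly before noise.

Noise, applied last and seed-controlled, is Poisson photon noise on the
scaled intensity followed by additive Gaussian read noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import acos, ceil, pi, sqrt

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import SphericalVoronoi, cKDTree
import shapely
from shapely.geometry import MultiPoint, Point, Polygon, box
from shapely.ops import voronoi_diagram

from .io import ImageStack

__all__ = [
    "EmbryoSpec",
    "GroundTruth",
    "generate_embryo_stack",
    "generate_flat_sheet",
    "translocation_for_nc_ratio",
]

# noiseless channel levels (arbitrary camera units)
BACKGROUND = 10.0
SHELL_BASE = 40.0      # cortical actin baseline in the junction channel
JUNCTION_PEAK = 120.0  # junctional band in the junction channel
NUCLEUS_PEAK = 120.0
NUCLEI_SHELL = 20.0
SIGNAL_BASE = 40.0
SHEET_CYTO = 30.0
SHEET_JUNCTION = 90.0
SHEET_NUCLEI_BG = 20.0
SHEET_NUCLEUS = 100.0
BEAD_AMP = 150.0

CHANNELS = ("junction", "nuclei", "signal", "beads")


@dataclass(frozen=True)
class EmbryoSpec:
    """Parameters of a synthetic embryo (or flat sheet) acquisition."""

    diameter_um: float = 100.0
    elliptic_ratio: float = 1.0
    invagination_depth_frac: float = 0.0
    invagination_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    n_cells: int = 200
    gradient_ratio: float = 0.0
    nuclear_translocation: float = 0.0
    bead_rate: float = 0.0
    pixel_size_um: float = 1.0
    z_step_um: float = 2.0
    noise: tuple[float, float] = (0.0, 0.0)  # (gaussian_sd, poisson_scale)
    seed: int = 0
    # morphology details
    shell_thickness_um: float = 8.0
    junction_width_um: float = 2.0
    nucleus_radius_um: float = 2.5
    # flat-sheet extras
    lattice: str = "voronoi"  # "voronoi" | "hex"
    hex_side_um: float = 10.0
    sheet_margin_um: float = 12.0
    nucleus_radius_frac: float = 0.25
    constriction_factor: float | None = None   # area scale inside the zone
    constriction_center_frac: tuple[float, float] = (0.5, 0.5)
    constriction_radius_frac: float = 0.25

    def __post_init__(self) -> None:
        checks = {
            "diameter_um": self.diameter_um > 0,
            "elliptic_ratio": self.elliptic_ratio >= 1.0,
            "invagination_depth_frac": 0.0 <= self.invagination_depth_frac < 1.0,
            "n_cells": self.n_cells >= 1,
            "gradient_ratio": self.gradient_ratio >= 0.0,
            "nuclear_translocation": 0.0 <= self.nuclear_translocation <= 1.0,
            "bead_rate": self.bead_rate >= 0.0,
            "pixel_size_um": self.pixel_size_um > 0,
            "z_step_um": self.z_step_um > 0,
            "noise": len(self.noise) == 2 and min(self.noise) >= 0.0,
            "lattice": self.lattice in ("voronoi", "hex"),
        }
        for name, ok in checks.items():
            if not ok:
                raise ValueError(f"EmbryoSpec.{name} out of range: {getattr(self, name)!r}")
        ax = np.asarray(self.invagination_axis, dtype=float)
        if ax.shape != (3,) or not np.isfinite(ax).all() or np.linalg.norm(ax) == 0:
            raise ValueError("EmbryoSpec.invagination_axis must be a nonzero 3-vector")


@dataclass
class GroundTruth:
    """Everything the generator knows about a stack, for recovery scoring."""

    kind: str                                  # "embryo" | "sheet"
    L_over_W: float
    d_over_D: float
    gradient_ratio: float
    background: dict[str, float]
    cell_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    areas_um2: np.ndarray = field(default_factory=lambda: np.zeros(0))
    perimeters_um: np.ndarray = field(default_factory=lambda: np.zeros(0))
    polygons: list[np.ndarray] = field(default_factory=list)
    total_area_um2: float = 0.0
    channel_means: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    bead_counts: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    nc_ratio_true: np.ndarray = field(default_factory=lambda: np.zeros(0))
    labels: np.ndarray | None = None           # sheet: exact per-pixel cell labels
    seeds_px: np.ndarray | None = None         # sheet: seed/centroid coordinates
    diameter_equiv_um: float = 0.0
    depth_um: float = 0.0
    oral_axis: tuple[float, float, float] | None = None
    constriction_mask: np.ndarray | None = None

    def validate(self) -> None:
        ids, counts = np.unique(self.cell_ids, return_counts=True)
        if ids.size != self.cell_ids.size:
            raise AssertionError("duplicate cell labels in ground truth")
        if self.total_area_um2 > 0:
            rel = abs(self.areas_um2.sum() - self.total_area_um2) / self.total_area_um2
            if rel > 0.01:
                raise AssertionError(f"truth areas sum off by {rel:.3%}")

    def to_json(self, path) -> None:
        payload = {
            "kind": self.kind,
            "L_over_W": self.L_over_W,
            "d_over_D": self.d_over_D,
            "gradient_ratio": self.gradient_ratio,
            "background": self.background,
            "cell_ids": self.cell_ids.tolist(),
            "areas_um2": self.areas_um2.tolist(),
            "perimeters_um": self.perimeters_um.tolist(),
            "total_area_um2": self.total_area_um2,
            "bead_counts": self.bead_counts.tolist(),
            "diameter_equiv_um": self.diameter_equiv_um,
            "depth_um": self.depth_um,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# dent geometry
# ---------------------------------------------------------------------------

def _bump(t: np.ndarray | float) -> np.ndarray | float:
    """Steep-walled dent profile on [-1, 1]; ~0 outside the mouth."""
    t = np.asarray(t, dtype=float)
    out = np.exp(-((np.abs(t) / 0.5) ** 4))
    return np.where(np.abs(t) <= 1.0, out, 0.0)


def _ellipse_radius(phi: np.ndarray, a: float, b: float) -> np.ndarray:
    return 1.0 / np.sqrt((np.cos(phi) / a) ** 2 + (np.sin(phi) / b) ** 2)


def _midplane_curve(a: float, b: float, A: float, w: float, n: int = 2400):
    """Mid-plane boundary of the dented ellipsoid, dent along +x."""
    phi = np.linspace(-pi, pi, n, endpoint=False)
    r = _ellipse_radius(phi, a, b)
    if A > 0:
        m = 1.0 - A * _bump(phi / w)
        r = r * m
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def _hull_deficiency(points: np.ndarray) -> float:
    """Max distance from the convex hull boundary to the curve (the dent depth)."""
    poly = Polygon(points)
    hull = poly.convex_hull
    pts = shapely.points(points)
    return float(shapely.distance(pts, hull.exterior).max())


def _solve_dent(a: float, b: float, frac: float) -> tuple[float, float, float, float]:
    """Solve mouth half-angle w and amplitude A so that the mid-plane hull
    deficiency equals ``frac`` times the equivalent diameter of the dented
    section.  Returns (A, w, d_um, D_um)."""
    if frac <= 0:
        D = 2.0 * sqrt(a * b)
        return 0.0, 0.0, 0.0, D
    D = 2.0 * sqrt(a * b)  # starting point: undented equivalent diameter
    A = w = 0.0
    d = frac * D
    for _ in range(4):
        d = frac * D
        w = min(pi / 3.0, acos(min(0.97, d / min(a, b) + 0.12)))
        a_hi = 1.0 - 0.02  # keep the apex off the centre

        def err(amp: float) -> float:
            return _hull_deficiency(_midplane_curve(a, b, amp, w)) - d

        if err(a_hi) < 0:
            raise ValueError(
                f"invagination_depth_frac={frac} is too deep for this geometry"
            )
        A = brentq(err, 0.0, a_hi, xtol=1e-5)
        area = Polygon(_midplane_curve(a, b, A, w)).area
        D = 2.0 * sqrt(area / pi)
    return A, w, d, D


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    th = pi * (3.0 - sqrt(5.0)) * i
    return np.column_stack([r * np.cos(th), r * np.sin(th), z])


def _rotation_to(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix sending +x to ``axis`` (unit)."""
    x = np.array([1.0, 0.0, 0.0])
    v = np.cross(x, axis)
    c = float(np.dot(x, axis))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([-1.0, -1.0, 1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _apply_noise(data: np.ndarray, noise: tuple[float, float], rng: np.random.Generator) -> np.ndarray:
    gaussian_sd, poisson_scale = noise
    out = data
    if poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * poisson_scale).astype(np.float64) / poisson_scale
    if gaussian_sd > 0:
        out = out + rng.normal(0.0, gaussian_sd, size=out.shape)
    return out


# ---------------------------------------------------------------------------
# embryo stacks
# ---------------------------------------------------------------------------

def generate_embryo_stack(spec: EmbryoSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a 4-channel 3-D embryo stack and its ground truth.

    Channels: junction (cortical actin + junctional bands), nuclei, signal
    (oral-aboral graded channel), beads.
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.diameter_um / 2.0
    s = spec.elliptic_ratio
    b = R / s ** (1.0 / 3.0)
    a = s * b
    axis = np.asarray(spec.invagination_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    A, w, d_um, D_um = _solve_dent(a, b, spec.invagination_depth_frac)

    px, pz = spec.pixel_size_um, spec.z_step_um
    half_xy = 1.12 * a
    half_z = 1.12 * a
    nx = int(ceil(2 * half_xy / px)) | 1
    nz = int(ceil(2 * half_z / pz)) | 1
    xs = (np.arange(nx) - nx // 2) * px
    zs = (np.arange(nz) - nz // 2) * pz
    Z, Y, X = np.meshgrid(zs, xs, xs, indexing="ij")
    P = np.stack([X, Y, Z], axis=-1)          # physical coords, (z,y,x,3)
    r = np.sqrt(X * X + Y * Y + Z * Z)
    with np.errstate(invalid="ignore", divide="ignore"):
        U = P / r[..., None]
    U[r == 0] = (1.0, 0.0, 0.0)

    # surface radius along each voxel direction
    Re = 1.0 / np.sqrt(
        (U[..., 0] / a) ** 2 + (U[..., 1] / b) ** 2 + (U[..., 2] / b) ** 2
    )
    if A > 0:
        cos_t = np.clip(U @ axis, -1.0, 1.0)
        theta = np.arccos(cos_t)
        rho = Re * (1.0 - A * _bump(theta / w))
    else:
        rho = Re
    t_sh = spec.shell_thickness_um
    from scipy.ndimage import distance_transform_edt

    interior = r <= rho
    depth_in = distance_transform_edt(interior, sampling=(pz, px, px))
    shell = interior & (depth_in <= t_sh)  # true thickness along the normal
    sh_idx = np.nonzero(shell)
    sh_pos = P[sh_idx]
    sh_dir = U[sh_idx]

    # cell lattice: spherical Voronoi of a Fibonacci point set (radial map)
    seeds = _fibonacci_sphere(spec.n_cells)
    cos_sim = sh_dir @ seeds.T
    order2 = np.argpartition(-cos_sim, kth=1, axis=1)[:, :2]
    top = np.take_along_axis(cos_sim, order2, axis=1)
    swap = top[:, 0] < top[:, 1]
    order2[swap] = order2[swap][:, ::-1]
    top[swap] = top[swap][:, ::-1]
    cell_of_voxel = order2[:, 0]
    d1 = np.arccos(np.clip(top[:, 0], -1, 1))
    d2 = np.arccos(np.clip(top[:, 1], -1, 1))
    junction_band = (d2 - d1) * R < spec.junction_width_um

    # channel: junction
    junction = np.full(shell.shape, BACKGROUND)
    junction[sh_idx] = np.where(junction_band, JUNCTION_PEAK, SHELL_BASE)

    # channel: nuclei (one blob per cell, mid-shell under the seed direction)
    rho_seed = 1.0 / np.sqrt(
        (seeds[:, 0] / a) ** 2 + (seeds[:, 1] / b) ** 2 + (seeds[:, 2] / b) ** 2
    )
    if A > 0:
        th_seed = np.arccos(np.clip(seeds @ axis, -1, 1))
        rho_seed = rho_seed * (1.0 - A * np.asarray(_bump(th_seed / w)))
    nuc_centers = seeds * (rho_seed - t_sh / 2.0)[:, None]
    tree = cKDTree(nuc_centers)
    dist_n, _ = tree.query(sh_pos, k=1)
    in_nucleus = dist_n < spec.nucleus_radius_um
    nuclei = np.full(shell.shape, BACKGROUND)
    nuclei[sh_idx] = np.where(in_nucleus, NUCLEUS_PEAK, NUCLEI_SHELL)

    # channel: signal with calibrated oral-aboral gradient
    gamma = spec.gradient_ratio
    sproj = sh_pos @ axis
    f = 0.5 * (1.0 + np.clip(sh_dir @ axis, -1, 1))  # cosine ramp, 1 at oral pole
    if gamma > 0:
        lo, hi = sproj.min(), sproj.max()
        slab = sproj >= hi - 0.1 * (hi - lo)
        f_s, f_r = f[slab].mean(), f[~slab].mean()
        denom = f_s - f_r * (1.0 + gamma)
        if denom <= 0:
            raise ValueError(f"gradient_ratio={gamma} not reachable with cosine ramp")
        alpha = gamma / denom
    else:
        alpha = 0.0
    sig_vals = SIGNAL_BASE * (1.0 + alpha * f)
    # nuclear translocation in the oral cap (cells within pi/3 of the axis)
    tau = spec.nuclear_translocation
    if tau > 0:
        oral_vox = np.arccos(np.clip(sh_dir @ axis, -1, 1)) < pi / 3.0
        cyto_vox = oral_vox & ~in_nucleus & ~junction_band
        nuc_vox = oral_vox & in_nucleus
        n_c, n_n = max(cyto_vox.sum(), 1), max(nuc_vox.sum(), 1)
        sig_vals = sig_vals.copy()
        moved = tau * sig_vals[cyto_vox].sum()
        sig_vals[cyto_vox] *= 1.0 - tau
        sig_vals[nuc_vox] += moved / n_n
    signal = np.full(shell.shape, BACKGROUND)
    signal[sh_idx] = sig_vals

    # channel: beads (Poisson per cell, on the shell)
    bead_counts = np.zeros(spec.n_cells, dtype=int)
    beads = np.full(shell.shape, BACKGROUND)
    if spec.bead_rate > 0:
        bead_counts = rng.poisson(spec.bead_rate, size=spec.n_cells)
        shell_zyx = np.column_stack(sh_idx)
        placed: list[np.ndarray] = []
        for cid, cnt in enumerate(bead_counts):
            cand = np.nonzero((cell_of_voxel == cid) & ~junction_band)[0]
            if cand.size == 0 or cnt == 0:
                bead_counts[cid] = 0
                continue
            chosen: list[int] = []
            perm = rng.permutation(cand)
            for j in perm:
                if len(chosen) == cnt:
                    break
                p = shell_zyx[j]
                if all(np.abs(p - shell_zyx[c]).max() > 2 for c in chosen):
                    chosen.append(j)
            bead_counts[cid] = len(chosen)
            placed.extend(shell_zyx[c] for c in chosen)
        for p in placed:
            beads[tuple(p)] += BEAD_AMP

    data = np.stack([junction, nuclei, signal, beads]).astype(np.float64)
    data = _apply_noise(data, spec.noise, rng).astype(np.float32)
    stack = ImageStack(
        data=data,
        channels=CHANNELS,
        pixel_size_um=px,
        z_step_um=pz,
    )

    # --- ground truth ------------------------------------------------------
    import trimesh

    mesh = trimesh.creation.icosphere(subdivisions=4)
    verts = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1, keepdims=True)
    re_v = 1.0 / np.sqrt(
        (verts[:, 0] / a) ** 2 + (verts[:, 1] / b) ** 2 + (verts[:, 2] / b) ** 2
    )
    if A > 0:
        th_v = np.arccos(np.clip(verts @ axis, -1, 1))
        re_v = re_v * (1.0 - A * np.asarray(_bump(th_v / w)))
    surf = trimesh.Trimesh(vertices=verts * re_v[:, None], faces=mesh.faces, process=False)
    centers = surf.triangles_center
    cdir = centers / np.linalg.norm(centers, axis=1, keepdims=True)
    face_cell = np.argmax(cdir @ seeds.T, axis=1)
    areas = np.bincount(face_cell, weights=surf.area_faces, minlength=spec.n_cells)
    total_area = float(surf.area_faces.sum())

    sv = SphericalVoronoi(seeds)
    sv.sort_vertices_of_regions()
    polygons: list[np.ndarray] = []
    perims = np.zeros(spec.n_cells)
    for i, region in enumerate(sv.regions):
        v = sv.vertices[region]
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        rv = 1.0 / np.sqrt((v[:, 0] / a) ** 2 + (v[:, 1] / b) ** 2 + (v[:, 2] / b) ** 2)
        if A > 0:
            tv = np.arccos(np.clip(v @ axis, -1, 1))
            rv = rv * (1.0 - A * np.asarray(_bump(tv / w)))
        pv = v * rv[:, None]
        polygons.append(pv)
        perims[i] = float(np.linalg.norm(np.roll(pv, -1, axis=0) - pv, axis=1).sum())

    def _cell_mean(values: np.ndarray, sel: np.ndarray) -> np.ndarray:
        cnt = np.bincount(cell_of_voxel[sel], minlength=spec.n_cells).astype(float)
        tot = np.bincount(cell_of_voxel[sel], weights=values[sel], minlength=spec.n_cells)
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)

    chan_means = {
        "junction": {
            "junctional": np.full(spec.n_cells, JUNCTION_PEAK),
            "cytosolic": np.full(spec.n_cells, SHELL_BASE),
        },
        "signal": {
            "junctional": _cell_mean(sig_vals, junction_band),
            "cytosolic": _cell_mean(sig_vals, ~junction_band),
        },
    }

    truth = GroundTruth(
        kind="embryo",
        L_over_W=s,
        d_over_D=spec.invagination_depth_frac,
        gradient_ratio=gamma,
        background={c: BACKGROUND for c in CHANNELS},
        cell_ids=np.arange(spec.n_cells),
        areas_um2=areas,
        perimeters_um=perims,
        polygons=polygons,
        total_area_um2=total_area,
        channel_means=chan_means,
        bead_counts=bead_counts,
        diameter_equiv_um=D_um,
        depth_um=d_um,
        oral_axis=tuple(axis),
    )
    truth.validate()
    return stack, truth


# ---------------------------------------------------------------------------
# flat sheets
# ---------------------------------------------------------------------------

def _sheet_seeds(spec: EmbryoSpec, side_px: float, rng: np.random.Generator) -> np.ndarray:
    n = spec.n_cells
    if spec.constriction_factor is not None:
        # density contrast instead of a CVT: mean apical area inside the zone
        # is ``constriction_factor`` times the outside mean
        f = spec.constriction_factor
        cx, cy = (np.asarray(spec.constriction_center_frac) * side_px)
        rad = spec.constriction_radius_frac * side_px
        A_zone = pi * rad**2
        A_rest = side_px**2 - A_zone
        n_in = int(round(n * (A_zone / f) / (A_zone / f + A_rest)))
        n_in = min(max(n_in, 1), n - 1)
        pts_in = []
        while len(pts_in) < n_in:
            p = rng.uniform(0, side_px, size=2)
            if (p[0] - cx) ** 2 + (p[1] - cy) ** 2 < rad**2:
                pts_in.append(p)
        pts_out = []
        while len(pts_out) < n - n_in:
            p = rng.uniform(0, side_px, size=2)
            if (p[0] - cx) ** 2 + (p[1] - cy) ** 2 >= rad**2:
                pts_out.append(p)
        return np.array(pts_in + pts_out)
    g = int(round(sqrt(n)))
    if g * g == n:
        # jittered grid: well-shaped cells, exact count
        step = side_px / g
        gx, gy = np.meshgrid(np.arange(g), np.arange(g))
        pts = np.column_stack([gx.ravel(), gy.ravel()]) * step + step / 2.0
        pts = pts + rng.uniform(-0.15 * step, 0.15 * step, size=pts.shape)
        return pts
    # general n: random seeds relaxed by a few Lloyd iterations
    pts = rng.uniform(0, side_px, size=(n, 2))
    rect = box(0, 0, side_px, side_px)
    for _ in range(8):
        cells = _voronoi_cells(pts, rect)
        pts = np.array([np.asarray(c.centroid.coords[0]) for c in cells])
    return pts


def _voronoi_cells(pts: np.ndarray, rect: Polygon) -> list[Polygon]:
    vd = voronoi_diagram(MultiPoint(pts.tolist()), envelope=rect)
    cells: list[Polygon | None] = [None] * len(pts)
    polys = list(vd.geoms)
    tree = shapely.STRtree(polys)
    for i, p in enumerate(pts):
        j = tree.query(Point(p), predicate="within")
        if len(j) == 0:
            j = [int(np.argmin([Point(p).distance(q) for q in polys]))]
        cells[i] = polys[int(j[0])].intersection(rect)
    return cells  # type: ignore[return-value]


def _hex_centers(side_px: float, s: float) -> np.ndarray:
    """Flat-top hexagon centres covering the sheet square."""
    dx, dy = 1.5 * s, sqrt(3.0) * s
    centers = []
    ncol = int(ceil(side_px / dx)) + 2
    nrow = int(ceil(side_px / dy)) + 2
    for col in range(-1, ncol):
        for row in range(-1, nrow):
            x = col * dx
            y = row * dy + (0.5 * dy if col % 2 else 0.0)
            centers.append((x, y))
    return np.array(centers)


def generate_flat_sheet(spec: EmbryoSpec) -> tuple[ImageStack, GroundTruth]:
    """Render a single-plane epithelial sheet with the embryo channel
    semantics and exact per-pixel cell labels in the truth."""
    if spec.n_cells < 4 and spec.lattice == "voronoi":
        raise ValueError(f"EmbryoSpec.n_cells out of range for sheets: {spec.n_cells}")
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_um
    side_px = spec.diameter_um / px
    margin = int(round(spec.sheet_margin_um / px))
    rect = box(0.0, 0.0, side_px, side_px)

    if spec.lattice == "hex":
        seeds = _hex_centers(side_px, spec.hex_side_um / px)
    else:
        seeds = _sheet_seeds(spec, side_px, rng)
    cells = _voronoi_cells(seeds, rect) if spec.lattice != "hex" else None
    if spec.lattice == "hex":
        # hexagonal Voronoi of the centre lattice == regular hexagons
        cells = _voronoi_cells(seeds, rect)
        keep = [i for i, c in enumerate(cells) if not c.is_empty and c.area > 1e-9]
        seeds = seeds[keep]
        cells = [cells[i] for i in keep]

    n = len(seeds)
    npx = int(round(side_px))
    H = npx + 2 * margin
    yy, xx = np.mgrid[0:npx, 0:npx]
    pix = np.column_stack([xx.ravel() + 0.5, yy.ravel() + 0.5])
    lab_flat = cKDTree(seeds).query(pix, k=1)[1]
    labels_sheet = (lab_flat + 1).reshape(npx, npx)
    labels = np.zeros((H, H), dtype=np.int32)
    labels[margin : margin + npx, margin : margin + npx] = labels_sheet
    sheet_mask = labels > 0

    from scipy.ndimage import distance_transform_edt
    from skimage.segmentation import find_boundaries

    wj = max(1, int(round(spec.junction_width_um / px)))
    edges = find_boundaries(labels, mode="thick") & sheet_mask
    # the outer rim of the sheet is junctional cortex too
    edges |= sheet_mask & (distance_transform_edt(sheet_mask) <= 1.0)
    band = (distance_transform_edt(~edges) < wj / 2.0 + 0.01) & sheet_mask

    # nuclei: one disk per cell, kept clear of the junction band
    from skimage.draw import disk as draw_disk

    nuc_mask = np.zeros_like(sheet_mask)
    dist_band = distance_transform_edt(~band & sheet_mask)
    centers_px = np.zeros((n, 2))
    for i in range(n):
        cy, cx = np.nonzero(labels == i + 1)
        if cy.size == 0:
            continue
        interior = np.argmax(dist_band[cy, cx])
        c = (cy[interior], cx[interior])
        centers_px[i] = c
        area_px = cy.size
        r_n = spec.nucleus_radius_frac * sqrt(area_px / pi)
        r_n = max(1.0, min(r_n, dist_band[c] - 1.0))
        rr, cc = draw_disk(c, r_n, shape=sheet_mask.shape)
        keep = labels[rr, cc] == i + 1
        nuc_mask[rr[keep], cc[keep]] = True
    nuc_mask &= ~band

    junction = np.full(labels.shape, BACKGROUND)
    junction[sheet_mask] = SHEET_CYTO
    junction[band] = SHEET_JUNCTION

    nuclei = np.full(labels.shape, BACKGROUND)
    nuclei[sheet_mask] = SHEET_NUCLEI_BG
    nuclei[nuc_mask] = SHEET_NUCLEUS

    # signal channel with per-cell nuclear translocation (mass conserving)
    tau = spec.nuclear_translocation
    signal = np.full(labels.shape, BACKGROUND)
    signal[sheet_mask] = SHEET_CYTO
    signal[band] = SHEET_JUNCTION
    nc_true = np.full(n, np.nan)
    for i in range(n):
        cell = labels == i + 1
        nucleus = cell & nuc_mask
        cyto = cell & ~band & ~nuc_mask
        a_n, a_c = nucleus.sum(), cyto.sum()
        if a_n == 0 or a_c == 0:
            continue
        c_val = SHEET_CYTO * (1.0 - tau)
        n_val = SHEET_CYTO + tau * SHEET_CYTO * (a_c / a_n)
        signal[cyto] = c_val
        signal[nucleus] = n_val
        nc_true[i] = n_val / c_val

    # beads: Poisson per cell, >=2 px from band/nucleus, >=3 px apart
    beads = np.full(labels.shape, BACKGROUND)
    bead_counts = np.zeros(n, dtype=int)
    if spec.bead_rate > 0:
        safe = distance_transform_edt(~band & ~nuc_mask & sheet_mask) >= 2.0
        bead_counts = rng.poisson(spec.bead_rate, size=n)
        kernel = np.array([[0, 60, 0], [60, BEAD_AMP, 60], [0, 60, 0]])
        for i in range(n):
            cand = np.column_stack(np.nonzero((labels == i + 1) & safe))
            if cand.size == 0:
                bead_counts[i] = 0
                continue
            chosen: list[np.ndarray] = []
            if bead_counts[i] > 0:
                for j in rng.permutation(len(cand)):
                    if len(chosen) == bead_counts[i]:
                        break
                    p = cand[j]
                    if all(np.abs(p - q).max() > 2 for q in chosen):
                        chosen.append(p)
            bead_counts[i] = len(chosen)
            for p in chosen:
                beads[p[0] - 1 : p[0] + 2, p[1] - 1 : p[1] + 2] += kernel

    # truth geometry from the exact Voronoi polygons (um units)
    areas = np.array([c.area for c in cells]) * px * px
    perims = np.array([c.length for c in cells]) * px
    polygons = [np.asarray(c.exterior.coords) * px for c in cells]

    def _region_mean(img: np.ndarray, region: np.ndarray) -> np.ndarray:
        out = np.full(n, np.nan)
        for i in range(n):
            m = region & (labels == i + 1)
            if m.any():
                out[i] = img[m].mean()
        return out

    chan_means = {
        "junction": {
            "junctional": _region_mean(junction, band),
            "cytosolic": _region_mean(junction, sheet_mask & ~band & ~nuc_mask),
        },
        "signal": {
            "junctional": _region_mean(signal, band),
            "cytosolic": _region_mean(signal, sheet_mask & ~band & ~nuc_mask),
            "nuclear": _region_mean(signal, nuc_mask),
        },
    }

    data = np.stack([junction, nuclei, signal, beads])[:, None, :, :].astype(np.float64)
    data = _apply_noise(data, spec.noise, rng).astype(np.float32)
    stack = ImageStack(data=data, channels=CHANNELS, pixel_size_um=px, z_step_um=spec.z_step_um)

    czone = None
    if spec.constriction_factor is not None:
        cx, cy = np.asarray(spec.constriction_center_frac) * side_px
        rad = spec.constriction_radius_frac * side_px
        yy2, xx2 = np.mgrid[0:H, 0:H]
        czone = ((xx2 - margin - cx) ** 2 + (yy2 - margin - cy) ** 2) < rad**2

    truth = GroundTruth(
        kind="sheet",
        L_over_W=1.0,
        d_over_D=0.0,
        gradient_ratio=0.0,
        background={c: BACKGROUND for c in CHANNELS},
        cell_ids=np.arange(1, n + 1),
        areas_um2=areas,
        perimeters_um=perims,
        polygons=polygons,
        total_area_um2=float(rect.area) * px * px,
        channel_means=chan_means,
        bead_counts=bead_counts,
        nc_ratio_true=nc_true,
        labels=labels,
        seeds_px=seeds + margin,
        constriction_mask=czone,
    )
    truth.validate()
    return stack, truth


def translocation_for_nc_ratio(spec: EmbryoSpec, target: float) -> float:
    """Translocation fraction tau giving a mean true N/C ratio of ``target``.

    Each cell's true ratio is (1 + kappa * tau) / (1 - tau) with kappa its
    cytosol-to-nucleus area ratio, fixed by the lattice geometry; kappa is
    read off one (cheap) sheet render and the mean ratio inverted for tau.
    """
    if target < 1.0:
        raise ValueError("target N/C ratio must be >= 1")
    from dataclasses import replace

    probe_tau = 0.5
    _, truth = generate_flat_sheet(replace(spec, nuclear_translocation=probe_tau))
    ratios = truth.nc_ratio_true
    kappa = (ratios * (1.0 - probe_tau) - 1.0) / probe_tau

    def err(tau: float) -> float:
        return float(np.nanmean((1.0 + kappa * tau) / (1.0 - tau))) - target

    if target == 1.0:
        return 0.0
    return float(brentq(err, 0.0, 0.95, xtol=1e-10))
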