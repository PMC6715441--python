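"""Synthetic quad-microraft-array scene generator with exact ground truth.

Renders bright-field z-stacks of a regular array of 2x2 microraft clusters
("quads") the way a motorized microscope sees them: microrafts and PDMS
barriers with distinct mean intensities and fine static texture, a smooth
illumination gradient, sensor noise, sub-pixel stage misregistration between
the pre-seeding ("background") and cell-bearing ("signal") scans, and cell
colonies whose punctate/halo appearance varies between focal planes while the
array background does not.  That focus dependence is the physical contrast
mechanism the standard-deviation projection exploits, so the generator
reproduces it explicitly:

* background structures are rendered identically at every focal offset;
* pixels inside the drawn cell mask are modulated by a random field that is
  re-drawn per focal plane, plus a perimeter halo whose amplitude changes
  from plane to plane.

Every scene returns its ground truth exactly as drawn (cell mask, colony
labels, per-raft coverage fractions, quad centroids), so downstream
segmentation, indexing, cytometry and release planning are all testable
without external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .preprocess import ImagePlane, ZStack

__all__ = [
    "ArrayGeometry",
    "ColonySpec",
    "SceneSpec",
    "GroundTruth",
    "SUB_RAFTS",
    "render_array_background",
    "render_signal_stack",
    "render_el_release_frame",
    "distorted_lattice",
    "random_scene",
    "growth_series_specs",
]

SUB_RAFTS = ("NW", "NE", "SW", "SE")

# Sign of the (x, y) offset of each sub-raft center from the quad center.
_SUB_SIGNS = {"NW": (-1, -1), "NE": (1, -1), "SW": (-1, 1), "SE": (1, 1)}

# Bright-field-like radiometry (arbitrary units, background mean ~1).
_I_RAFT = 1.0
_I_GAP = 0.78
_I_BARRIER = 0.70
_I_RAFT_EDGE = 1.18
_EDGE_WIDTH_UM = 4.0
_TEXTURE_AMP = 0.05
_CELL_AMP = 0.25  # focal-plane-dependent modulation of intensity inside cells
_HALO_AMP = 0.25
_DEFOCUS_DECORR_UM = 10.0  # decorrelation scale of cell appearance vs focus

# Release-frame radiometry (electroluminescent transmission view).
_EL_RAFT = 1.0
_EL_EMPTY = 0.30
_EL_SURROUND = 0.45


@dataclass(frozen=True)
class ArrayGeometry:
    """Physical layout of a quad microraft array.

    Defaults describe an array of 41 x 41 quads of four 200 um microrafts,
    30 um PDMS gaps inside each quad and 100 um barriers between quads,
    imaged at 1.625 um/px (6.5 um sensor pixel behind a 4x objective).
    """

    raft_side: float = 200.0
    intra_quad_gap: float = 30.0
    barrier_width: float = 100.0
    quad_rows: int = 41
    quad_cols: int = 41
    pixel_size: float = 1.625
    raft_wall_height: float = 50.0  # informational only

    def __post_init__(self) -> None:
        for name in ("raft_side", "intra_quad_gap", "barrier_width", "pixel_size"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.quad_rows < 1 or self.quad_cols < 1:
            raise ValueError("grid must have at least one quad")
        if self.pixel_size > self.intra_quad_gap / 4:
            raise ValueError("pixel_size too coarse to resolve intra-quad gaps")

    @property
    def quad_pitch(self) -> float:
        """Center-to-center quad spacing (530 um under defaults)."""
        return 2 * self.raft_side + self.intra_quad_gap + self.barrier_width

    @property
    def quad_side(self) -> float:
        """Outer side of the 2x2 raft cluster (430 um under defaults)."""
        return 2 * self.raft_side + self.intra_quad_gap

    @property
    def extent(self) -> tuple[float, float]:
        """(width, height) of the rendered field in um."""
        return (self.quad_cols * self.quad_pitch, self.quad_rows * self.quad_pitch)

    def image_shape(self) -> tuple[int, int]:
        w, h = self.extent
        return (int(round(h / self.pixel_size)), int(round(w / self.pixel_size)))

    def quad_center(self, row: int, col: int) -> tuple[float, float]:
        """Ideal (x, y) um position of quad (row, col) on the undistorted array."""
        p = self.quad_pitch
        return (col * p + p / 2, row * p + p / 2)

    def raft_center(self, row: int, col: int, sub: str) -> tuple[float, float]:
        qx, qy = self.quad_center(row, col)
        sx, sy = _SUB_SIGNS[sub]
        off = (self.raft_side + self.intra_quad_gap) / 2
        return (qx + sx * off, qy + sy * off)


@dataclass(frozen=True)
class ColonySpec:
    """One drawn colony: where it sits and how far it has spread.

    ``raft_coverage`` gives the fraction of each sub-raft (NW, NE, SW, SE)
    covered by cells; ``pdms_fraction`` the covered fraction of the intra-quad
    PDMS cross.  ``growth_center`` offsets the radial growth origin from the
    quad center (um) so coverage can be asymmetric, as for a colony seeded
    off-center.
    """

    quad: tuple[int, int]
    raft_coverage: tuple[float, float, float, float]
    pdms_fraction: float = 0.0
    growth_center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.raft_coverage) != 4:
            raise ValueError("raft_coverage needs 4 fractions (NW, NE, SW, SE)")
        for f in (*self.raft_coverage, self.pdms_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("coverage fractions must lie in [0, 1]")

    @property
    def raft_class(self) -> int:
        return int(sum(f >= 0.5 for f in self.raft_coverage))


@dataclass(frozen=True)
class SceneSpec:
    """Complete description of one synthetic scene.

    The same spec plus seed always renders bit-identical stacks and truth.
    """

    geometry: ArrayGeometry
    colonies: tuple[ColonySpec, ...] = ()
    distortion_amplitude: float = 0.0  # um
    distortion_wavelength: float = 4000.0  # um
    rotation: float = 0.0  # degrees, array vs. image frame
    background_signal_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    illumination_gradient: float = 0.0
    noise_sd: float = 0.0
    focal_offsets: tuple[float, ...] = (-57.0, 0.0, 57.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.focal_offsets)) < 2:
            raise ValueError("need at least 2 distinct focal offsets")
        if self.distortion_wavelength <= 0:
            raise ValueError("distortion wavelength must be positive")
        g = self.geometry
        for c in self.colonies:
            r, q = c.quad
            if not (0 <= r < g.quad_rows and 0 <= q < g.quad_cols):
                raise ValueError(f"colony quad {c.quad} outside the grid")


@dataclass
class GroundTruth:
    """Exact per-scene truth as drawn (synthetic stand-in for fluorescence
    ground truth)."""

    cell_mask: np.ndarray  # bool, signal-frame pixels
    colony_labels: np.ndarray  # int32, 0 = background
    quad_centroids: pd.DataFrame  # row, col, x_um, y_um (signal frame)
    per_raft_coverage: pd.DataFrame  # quad_row, quad_col, sub_raft, coverage
    colonies: pd.DataFrame  # label, quad_row, quad_col, area_um2, raft_class

    def coverage_of(self, row: int, col: int) -> dict[str, float]:
        t = self.per_raft_coverage
        sel = t[(t.quad_row == row) & (t.quad_col == col)]
        return dict(zip(sel.sub_raft, sel.coverage))


# ---------------------------------------------------------------------------
# Coordinate machinery
# ---------------------------------------------------------------------------

def _seeded(spec_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, stream]))


def _displacement(spec: SceneSpec, x: np.ndarray, y: np.ndarray):
    """Smooth sinusoidal displacement field (um) evaluated at (x, y) um."""
    a = spec.distortion_amplitude
    if a == 0.0:
        return np.zeros_like(x), np.zeros_like(y)
    k = 2 * np.pi / spec.distortion_wavelength
    rng = _seeded(spec.seed, 11)
    p1, p2, p3, p4 = rng.uniform(0, 2 * np.pi, 4)
    dx = a * np.sin(k * y + p1) * np.cos(k * x + p2)
    dy = a * np.sin(k * x + p3) * np.cos(k * y + p4)
    return dx, dy


def _image_grid_um(spec: SceneSpec):
    h, w = spec.geometry.image_shape()
    ps = spec.geometry.pixel_size
    y, x = np.mgrid[0:h, 0:w].astype(np.float32)
    return (x + 0.5) * ps, (y + 0.5) * ps


def _rotate_pts(x, y, cx, cy, theta_deg):
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    xr = c * (x - cx) - s * (y - cy) + cx
    yr = s * (x - cx) + c * (y - cy) + cy
    return xr, yr


def _array_coords(spec: SceneSpec, extra_offset=None):
    """Array-frame coordinates (um) of every image pixel.

    ``extra_offset`` is the (dx, dy, dtheta) stage misregistration applied to
    the signal scan relative to the background scan.
    """
    x, y = _image_grid_um(spec)
    w, h = spec.geometry.extent
    cx, cy = w / 2, h / 2
    if extra_offset is not None:
        dx, dy, dth = extra_offset
        x, y = _rotate_pts(x, y, cx, cy, -dth)
        x = x - dx
        y = y - dy
    if spec.rotation != 0.0:
        x, y = _rotate_pts(x, y, cx, cy, -spec.rotation)
    ddx, ddy = _displacement(spec, x, y)
    return (x - ddx).astype(np.float32), (y - ddy).astype(np.float32)


def quad_centroid_image(
    spec: SceneSpec, row: int, col: int, signal_frame: bool = True
) -> tuple[float, float]:
    """Image-frame (x, y) um position at which quad (row, col) is drawn.

    Inverts the rendering coordinate map (lattice position -> rotation ->
    distortion -> optional stage offset) by a short fixed-point iteration;
    the distortion field is smooth and small compared to the pitch, so three
    iterations converge far below pixel resolution.
    """
    g = spec.geometry
    w, h = g.extent
    cx, cy = w / 2, h / 2
    px, py = g.quad_center(row, col)
    x, y = px, py
    off = spec.background_signal_offset if signal_frame else None
    for _ in range(4):
        xa = np.asarray([x], dtype=np.float64)
        ya = np.asarray([y], dtype=np.float64)
        ddx, ddy = _displacement(spec, xa, ya)
        u, v = px + ddx[0], py + ddy[0]
        u, v = _rotate_pts(u, v, cx, cy, spec.rotation)
        if off is not None:
            u, v = u + off[0], v + off[1]
            u, v = _rotate_pts(u, v, cx, cy, off[2])
        x, y = float(u), float(v)
    return x, y


# ---------------------------------------------------------------------------
# Background rendering
# ---------------------------------------------------------------------------

def _base_intensity(g: ArrayGeometry, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Focus-invariant array intensity at array coordinates (u, v) um."""
    p = g.quad_pitch
    lu = np.abs(np.mod(u, p) - p / 2)
    lv = np.abs(np.mod(v, p) - p / 2)
    half_quad = g.quad_side / 2
    half_gap = g.intra_quad_gap / 2

    out = np.full(u.shape, _I_BARRIER, dtype=np.float32)
    inside_quad = (lu <= half_quad) & (lv <= half_quad)
    gap = inside_quad & ((lu <= half_gap) | (lv <= half_gap))
    raft = inside_quad & ~gap
    out[gap] = _I_GAP
    out[raft] = _I_RAFT
    # Bright ring at raft walls (bowl-shaped rafts scatter at their edges).
    d_u = np.minimum(lu - half_gap, half_quad - lu)
    d_v = np.minimum(lv - half_gap, half_quad - lv)
    edge = raft & (np.minimum(d_u, d_v) <= _EDGE_WIDTH_UM)
    out[edge] = _I_RAFT_EDGE
    # Beyond the array footprint there is only flat PDMS.
    w, h = g.extent
    outside = (u < 0) | (u > w) | (v < 0) | (v > h)
    out[outside] = _I_BARRIER
    return out


def _texture_field(spec: SceneSpec):
    """Static fine texture tied to the array surface (shared by both scans)."""
    g = spec.geometry
    h, w = g.image_shape()
    margin = 64
    rng = _seeded(spec.seed, 21)
    tex = rng.standard_normal((h + 2 * margin, w + 2 * margin)).astype(np.float32)
    tex = ndi.gaussian_filter(tex, 1.0)
    tex /= float(tex.std())
    return tex, margin


def _sample_texture(spec: SceneSpec, u, v):
    tex, margin = _texture_field(spec)
    ps = spec.geometry.pixel_size
    rows = v / ps - 0.5 + margin
    cols = u / ps - 0.5 + margin
    return ndi.map_coordinates(tex, [rows, cols], order=1, mode="constant")


def _illumination(spec: SceneSpec, shape) -> np.ndarray:
    if spec.illumination_gradient == 0.0:
        return np.ones(shape, dtype=np.float32)
    h, w = shape
    rng = _seeded(spec.seed, 31)
    ax, ay = rng.uniform(-1, 1, 2)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    field = ax * (xx / w - 0.5) + ay * (yy / h - 0.5)
    return (1.0 + spec.illumination_gradient * field).astype(np.float32)


def _background_component(spec: SceneSpec, signal_frame: bool) -> np.ndarray:
    off = spec.background_signal_offset if signal_frame else None
    u, v = _array_coords(spec, extra_offset=off)
    img = _base_intensity(spec.geometry, u, v)
    img *= 1.0 + _TEXTURE_AMP * _sample_texture(spec, u, v).astype(np.float32)
    return img


def render_array_background(spec: SceneSpec) -> ZStack:
    """Render the pre-seeding bright-field stack.

    The array background is focus-invariant: the same structural image is
    emitted at every focal offset, with only the illumination gradient and
    fresh per-plane sensor noise on top.
    """
    base = _background_component(spec, signal_frame=False)
    illum = _illumination(spec, base.shape)
    planes = []
    for i, f in enumerate(spec.focal_offsets):
        img = base * illum
        if spec.noise_sd > 0:
            rng = _seeded(spec.seed, 100 + i)
            img = img + spec.noise_sd * rng.standard_normal(img.shape).astype(
                np.float32
            )
        planes.append(
            ImagePlane(
                pixels=img,
                pixel_size=spec.geometry.pixel_size,
                focal_offset=float(f),
                acquisition_tag="background",
            )
        )
    return ZStack(planes=planes)


# ---------------------------------------------------------------------------
# Signal rendering (cells + ground truth)
# ---------------------------------------------------------------------------

def _colony_masks(spec: SceneSpec, u, v):
    """Draw each colony as a radially grown region realizing the requested
    per-raft coverage fractions exactly (to one pixel)."""
    g = spec.geometry
    ps = g.pixel_size
    cell = np.zeros(u.shape, dtype=bool)
    labels = np.zeros(u.shape, dtype=np.int32)
    cov_rows = []
    colony_rows = []
    half_gap = g.intra_quad_gap / 2
    half_quad = g.quad_side / 2
    win = int(np.ceil((half_quad + 3 * ps) / ps)) + 2

    for lab, c in enumerate(spec.colonies, start=1):
        r, q = c.quad
        qx, qy = g.quad_center(r, q)
        # Crop a window around where the quad lands in the signal frame.
        ix, iy = quad_centroid_image(spec, r, q, signal_frame=True)
        ci = int(round(iy / ps - 0.5))
        cj = int(round(ix / ps - 0.5))
        i0, i1 = max(ci - win, 0), min(ci + win + 1, u.shape[0])
        j0, j1 = max(cj - win, 0), min(cj + win + 1, u.shape[1])
        lu = u[i0:i1, j0:j1] - qx
        lv = v[i0:i1, j0:j1] - qy
        gx, gy = c.growth_center
        dist2 = (lu - gx) ** 2 + (lv - gy) ** 2
        region = np.zeros(lu.shape, dtype=bool)

        def grow(candidate: np.ndarray, fraction: float) -> None:
            n_total = int(candidate.sum())
            n = int(round(fraction * n_total))
            if n <= 0 or n_total == 0:
                return
            d = np.where(candidate, dist2, np.inf).ravel()
            idx = np.argpartition(d, min(n, d.size - 1))[:n]
            flat = region.ravel()
            flat[idx] = True

        for k, sub in enumerate(SUB_RAFTS):
            sx, sy = _SUB_SIGNS[sub]
            in_raft = (
                (sx * lu >= half_gap)
                & (sx * lu <= half_quad)
                & (sy * lv >= half_gap)
                & (sy * lv <= half_quad)
            )
            grow(in_raft, c.raft_coverage[k])
        in_gap = ((np.abs(lu) <= half_gap) | (np.abs(lv) <= half_gap)) & (
            np.abs(lu) <= half_quad
        ) & (np.abs(lv) <= half_quad)
        grow(in_gap, c.pdms_fraction)

        cell[i0:i1, j0:j1] |= region
        labels[i0:i1, j0:j1][region] = lab
        for k, sub in enumerate(SUB_RAFTS):
            cov_rows.append((r, q, sub, float(c.raft_coverage[k])))
        colony_rows.append(
            (lab, r, q, float(region.sum()) * ps * ps, c.raft_class)
        )

    cov = pd.DataFrame(
        cov_rows, columns=["quad_row", "quad_col", "sub_raft", "coverage"]
    )
    colonies = pd.DataFrame(
        colony_rows,
        columns=["label", "quad_row", "quad_col", "area_um2", "raft_class"],
    )
    return cell, labels, cov, colonies


def _quad_centroid_table(spec: SceneSpec, signal_frame: bool) -> pd.DataFrame:
    g = spec.geometry
    rows = []
    for r in range(g.quad_rows):
        for c in range(g.quad_cols):
            x, y = quad_centroid_image(spec, r, c, signal_frame=signal_frame)
            rows.append((r, c, x, y))
    return pd.DataFrame(rows, columns=["row", "col", "x_um", "y_um"])


def render_signal_stack(
    spec: SceneSpec, truth_out: bool = True
) -> tuple[ZStack, GroundTruth | None]:
    """Render the cell-bearing stack and (optionally) its exact ground truth.

    The background component is the pre-seeding render transformed by the
    stage misregistration; cells appear only inside the drawn mask, as a
    punctate modulation and perimeter halo that change with focal offset.
    """
    g = spec.geometry
    u, v = _array_coords(spec, extra_offset=spec.background_signal_offset)
    base = _base_intensity(g, u, v)
    base *= 1.0 + _TEXTURE_AMP * _sample_texture(spec, u, v).astype(np.float32)

    cell, labels, cov, colonies = _colony_masks(spec, u, v)
    halo = cell & ~ndi.binary_erosion(cell, iterations=2)
    illum = _illumination(spec, base.shape)

    # Cell appearance decorrelates with defocus distance but saturates within
    # roughly one objective depth of focus: the per-plane punctate field is a
    # phase rotation between two fixed random fields, with the phase running
    # from 0 (in focus) to +-90 deg (far defocus) over ~10 um.
    fields = []
    if cell.any():
        sig_px = max(1.0, 1.5 / g.pixel_size)
        for stream in (201, 202):
            f2 = _seeded(spec.seed, stream).standard_normal(base.shape).astype(
                np.float32
            )
            f2 = ndi.gaussian_filter(f2, sig_px)
            f2 /= float(f2.std())
            fields.append(f2)
        rng_h = _seeded(spec.seed, 203)
        halo_a, halo_b = rng_h.uniform(0.4, 1.6, 2)

    planes = []
    for i, f in enumerate(spec.focal_offsets):
        img = base.copy()
        if cell.any():
            phase = (np.pi / 2) * np.tanh(f / _DEFOCUS_DECORR_UM)
            speck = fields[0] * np.cos(phase) + fields[1] * np.sin(phase)
            img[cell] *= 1.0 + _CELL_AMP * speck[cell]
            img[halo] += _HALO_AMP * float(
                halo_a * np.cos(phase) + halo_b * np.sin(phase)
            )
            np.clip(img, 0.02, None, out=img)
        img *= illum
        if spec.noise_sd > 0:
            rng_n = _seeded(spec.seed, 300 + i)
            img = img + spec.noise_sd * rng_n.standard_normal(img.shape).astype(
                np.float32
            )
        planes.append(
            ImagePlane(
                pixels=img,
                pixel_size=g.pixel_size,
                focal_offset=float(f),
                acquisition_tag="signal",
            )
        )
    stack = ZStack(planes=planes)
    if not truth_out:
        return stack, None
    truth = GroundTruth(
        cell_mask=cell,
        colony_labels=labels,
        quad_centroids=_quad_centroid_table(spec, signal_frame=True),
        per_raft_coverage=cov,
        colonies=colonies,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Single-well release frames
# ---------------------------------------------------------------------------

def render_el_release_frame(
    geometry: ArrayGeometry,
    well: tuple[int, int, str],
    remaining_fraction: float,
    displacement: tuple[float, float] = (0.0, 0.0),
    margin_um: float = 60.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ImagePlane:
    """Render one microwell as seen through transmitted EL illumination.

    A connected region of raft material covering ``remaining_fraction`` of
    the well area, offset by ``displacement`` um, renders at raft intensity;
    the cleared part of the well renders at empty-well intensity.
    """
    r, c, sub = well
    if not (0 <= r < geometry.quad_rows and 0 <= c < geometry.quad_cols):
        raise ValueError(f"well address {well} outside the grid")
    if sub not in SUB_RAFTS:
        raise ValueError(f"unknown sub-raft {sub!r}")
    if not 0.0 <= remaining_fraction <= 1.0:
        raise ValueError("remaining_fraction must lie in [0, 1]")

    ps = geometry.pixel_size
    half = geometry.raft_side / 2
    size_um = geometry.raft_side + 2 * margin_um
    n = int(round(size_um / ps))
    yy, xx = np.mgrid[0:n, 0:n].astype(np.float32)
    x = (xx + 0.5) * ps - size_um / 2
    y = (yy + 0.5) * ps - size_um / 2

    img = np.full((n, n), _EL_SURROUND, dtype=np.float32)
    well_fp = (np.abs(x) <= half) & (np.abs(y) <= half)
    img[well_fp] = _EL_EMPTY

    dx, dy = displacement
    material_fp = (np.abs(x - dx) <= half) & (np.abs(y - dy) <= half)
    n_well = int(well_fp.sum())
    n_take = min(int(round(remaining_fraction * n_well)), int(material_fp.sum()))
    if n_take > 0:
        d2 = np.where(material_fp, (x - dx) ** 2 + (y - dy) ** 2, np.inf).ravel()
        idx = np.argpartition(d2, min(n_take, d2.size - 1))[:n_take]
        flat = img.ravel()
        flat[idx] = _EL_RAFT
    if noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
        img = img + noise_sd * rng.standard_normal(img.shape).astype(np.float32)
    return ImagePlane(pixels=img, pixel_size=ps, acquisition_tag="signal")


def well_footprint(geometry: ArrayGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the (centered) microwell footprint in a release frame."""
    ps = geometry.pixel_size
    half = geometry.raft_side / 2
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    x = (xx + 0.5) * ps - w * ps / 2
    y = (yy + 0.5) * ps - h * ps / 2
    return (np.abs(x) <= half) & (np.abs(y) <= half)


# ---------------------------------------------------------------------------
# Point-level fixtures and scene factories
# ---------------------------------------------------------------------------

def distorted_lattice(
    geometry: ArrayGeometry,
    amplitude: float = 20.0,
    wavelength: float = 4000.0,
    jitter_sd: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """True quad centroids of a smoothly distorted, jittered lattice (um).

    Point-level fixture for grid indexing/interpolation: each ideal lattice
    center is displaced by a low-frequency sinusoidal field plus independent
    Gaussian jitter.  Columns: row, col, x_um, y_um.
    """
    spec = SceneSpec(
        geometry=geometry,
        distortion_amplitude=amplitude,
        distortion_wavelength=wavelength,
        seed=seed,
    )
    rng = _seeded(seed, 51)
    rows = []
    for r in range(geometry.quad_rows):
        for c in range(geometry.quad_cols):
            px, py = geometry.quad_center(r, c)
            ddx, ddy = _displacement(
                spec, np.asarray([px], float), np.asarray([py], float)
            )
            x = px + float(ddx[0]) + jitter_sd * rng.standard_normal()
            y = py + float(ddy[0]) + jitter_sd * rng.standard_normal()
            rows.append((r, c, x, y))
    return pd.DataFrame(rows, columns=["row", "col", "x_um", "y_um"])


def _random_colony(
    rng: np.random.Generator, quad: tuple[int, int], target_class: int
) -> ColonySpec:
    """Draw a colony whose per-raft coverages realize ``target_class``.

    Colonies either spread well onto a raft or barely touch it, so covered
    rafts draw from [0.55, 1.0] and uncovered ones from {0} u [0.05, 0.45].
    """
    covered = list(rng.choice(4, size=target_class, replace=False))
    cov = []
    for k in range(4):
        if k in covered:
            cov.append(float(rng.uniform(0.55, 1.0)))
        elif rng.random() < 0.5:
            cov.append(0.0)
        else:
            cov.append(float(rng.uniform(0.05, 0.45)))
    pdms = float(rng.uniform(0.05, 0.4)) if target_class >= 2 else float(
        rng.uniform(0.0, 0.1)
    )
    center = tuple(rng.uniform(-90.0, 90.0, 2))
    return ColonySpec(
        quad=quad,
        raft_coverage=tuple(cov),
        pdms_fraction=pdms,
        growth_center=(float(center[0]), float(center[1])),
    )


def reduced_geometry(quad_rows: int = 8, quad_cols: int = 8, **kw) -> ArrayGeometry:
    """Reduced-size geometry (8x8 quads by default) for desk-scale scenes."""
    return ArrayGeometry(quad_rows=quad_rows, quad_cols=quad_cols, **kw)


def random_scene(
    seed: int,
    geometry: ArrayGeometry | None = None,
    n_colonies: int = 15,
    noise_sd: float = 0.02,
    illumination_gradient: float = 0.1,
    focal_offsets: tuple[float, ...] = (-57.0, 0.0, 57.0),
    distortion_amplitude: float = 5.0,
) -> SceneSpec:
    """Default study-condition scene: an 8x8 quad field with ~15 colonies,
    mild distortion, a smooth illumination gradient, sensor noise, and a
    random sub-pixel stage offset between background and signal scans."""
    g = geometry or reduced_geometry()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 61]))
    n_sites = g.quad_rows * g.quad_cols
    n_colonies = min(n_colonies, n_sites)
    flat = rng.choice(n_sites, size=n_colonies, replace=False)
    colonies = []
    for f in flat:
        quad = (int(f // g.quad_cols), int(f % g.quad_cols))
        target_class = int(rng.integers(1, 5))
        colonies.append(_random_colony(rng, quad, target_class))
    offset = (
        float(rng.uniform(-5, 5)),
        float(rng.uniform(-5, 5)),
        float(rng.uniform(-0.15, 0.15)),
    )
    return SceneSpec(
        geometry=g,
        colonies=tuple(colonies),
        distortion_amplitude=distortion_amplitude,
        distortion_wavelength=4000.0,
        rotation=float(rng.uniform(-0.2, 0.2)),
        background_signal_offset=offset,
        illumination_gradient=illumination_gradient,
        noise_sd=noise_sd,
        focal_offsets=focal_offsets,
        seed=seed,
    )


def growth_series_specs(
    seed: int,
    geometry: ArrayGeometry | None = None,
    n_colonies: int = 20,
    n_timepoints: int = 7,
) -> list[SceneSpec]:
    """A multi-day growth series: the same colony sites expand from a small
    patch on one raft toward full quad coverage over ``n_timepoints`` days."""
    g = geometry or reduced_geometry()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 71]))
    n_sites = g.quad_rows * g.quad_cols
    n_colonies = min(n_colonies, n_sites)
    flat = rng.choice(n_sites, size=n_colonies, replace=False)
    sites = [(int(f // g.quad_cols), int(f % g.quad_cols)) for f in flat]
    centers = rng.uniform(-90.0, 90.0, (n_colonies, 2))
    rates = rng.uniform(0.8, 1.2, n_colonies)
    home = rng.integers(0, 4, n_colonies)

    specs = []
    for t in range(n_timepoints):
        frac = (t + 1) / n_timepoints
        colonies = []
        for i, quad in enumerate(sites):
            level = min(1.0, float(rates[i]) * frac)
            cov = [0.0, 0.0, 0.0, 0.0]
            cov[home[i]] = min(1.0, 0.3 + 1.4 * level)
            for k in range(4):
                if k != home[i]:
                    cov[k] = max(0.0, min(1.0, 1.8 * (level - 0.45)))
            pdms = max(0.0, min(0.8, 1.5 * (level - 0.4)))
            colonies.append(
                ColonySpec(
                    quad=quad,
                    raft_coverage=tuple(cov),
                    pdms_fraction=pdms,
                    growth_center=(float(centers[i, 0]), float(centers[i, 1])),
                )
            )
        specs.append(
            SceneSpec(
                geometry=g,
                colonies=tuple(colonies),
                distortion_amplitude=5.0,
                rotation=0.05,
                background_signal_offset=(2.0, -3.0, 0.05),
                illumination_gradient=0.1,
                noise_sd=0.02,
                seed=seed + 1000 * t,
            )
        )
    return specs


# ---------------------------------------------------------------------------
# On-disk formats
# ---------------------------------------------------------------------------

def save_stack(stack: ZStack, path: str | Path, scene_seed: int | None = None) -> None:
    """Write a stack as a multi-page TIFF plus a JSON metadata sidecar."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, stack.data().astype(np.float32))
    meta = {
        "pixel_size_um": stack.pixel_size,
        "focal_offsets_um": stack.focal_offsets,
        "acquisition_tag": stack.planes[0].acquisition_tag,
        "seed": scene_seed,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_stack(path: str | Path) -> ZStack:
    import tifffile

    path = Path(path)
    data = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    planes = [
        ImagePlane(
            pixels=data[i],
            pixel_size=float(meta["pixel_size_um"]),
            focal_offset=float(meta["focal_offsets_um"][i]),
            acquisition_tag=str(meta["acquisition_tag"]),
        )
        for i in range(data.shape[0])
    ]
    return ZStack(planes=planes)


def save_ground_truth(truth: GroundTruth, outdir: str | Path) -> None:
    """Write the mask as 8-bit PNG, labels as 16-bit PNG, tables as CSV."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(outdir / "cell_mask.png", (truth.cell_mask * 255).astype(np.uint8))
    iio.imwrite(
        outdir / "colony_labels.png", truth.colony_labels.astype(np.uint16)
    )
    truth.quad_centroids.to_csv(outdir / "quad_centroids.csv", index=False)
    truth.per_raft_coverage.to_csv(outdir / "per_raft_coverage.csv", index=False)
    truth.colonies.to_csv(outdir / "colonies.csv", index=False)
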