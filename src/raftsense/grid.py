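"""Microraft/quad detection, grid indexing, interpolation and tracking.

Quads (2x2 microraft clusters) are segmented from corrected bright-field
planes by Otsu thresholding and morphological cleanup, consolidated into one
centroid per colony site, and assigned (row, col) indices relative to the
overall array lattice starting from the top-left site.  Sites missed by
detection (occlusion, dense cell cover, deliberate deletion) are recovered by
piecewise-linear interpolation along rows and columns in 8 mm (about 15-quad)
segments, which tolerates smooth array distortion.  Indexed grids from
successive timepoints are matched index-by-index so each colony site keeps
one identity over a whole culture series.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import cKDTree
from skimage import morphology, segmentation
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import disk

from .preprocess import ImagePlane
from .synth import SUB_RAFTS, _SUB_SIGNS, ArrayGeometry

__all__ = [
    "QuadDetection",
    "IndexedGrid",
    "detect_quads",
    "consolidate_centroids",
    "index_grid",
    "interpolate_missing",
    "track_timepoints",
]


@dataclass
class QuadDetection:
    """One detected (or interpolated) colony-site centroid."""

    centroid: tuple[float, float]  # (x, y) um
    side_length: float  # um, mean of bounding extents
    source: str = "detected"  # detected | interpolated
    quality: dict = field(default_factory=dict)
    index: tuple[int, int] | None = None  # (row, col) once assigned


@dataclass
class IndexedGrid:
    """Row/column-addressed map of quad centroids plus the fitted lattice.

    ``lattice_fit`` holds the affine lattice model: ``origin`` (um), and the
    column/row step vectors ``vec_col``/``vec_row`` (um per index step).
    """

    entries: dict[tuple[int, int], QuadDetection]
    geometry: ArrayGeometry
    lattice_fit: dict = field(default_factory=dict)

    def centroid(self, row: int, col: int) -> tuple[float, float]:
        return self.entries[(row, col)].centroid

    def predict(self, row: float, col: float) -> np.ndarray:
        f = self.lattice_fit
        return np.asarray(f["origin"]) + col * np.asarray(f["vec_col"]) + row * np.asarray(
            f["vec_row"]
        )

    def raft_center(self, row: int, col: int, sub: str) -> tuple[float, float]:
        """Center of one sub-raft, using the fitted lattice orientation."""
        cx, cy = self.entries[(row, col)].centroid
        f = self.lattice_fit
        ec = np.asarray(f["vec_col"], dtype=float)
        er = np.asarray(f["vec_row"], dtype=float)
        ec = ec / np.linalg.norm(ec)
        er = er / np.linalg.norm(er)
        off = (self.geometry.raft_side + self.geometry.intra_quad_gap) / 2
        sx, sy = _SUB_SIGNS[sub]
        p = np.asarray([cx, cy]) + sx * off * ec + sy * off * er
        return (float(p[0]), float(p[1]))

    def detected(self) -> list[QuadDetection]:
        return [d for d in self.entries.values() if d.source == "detected"]

    def to_frame(self, timepoint: int = 0) -> pd.DataFrame:
        rows = [
            (
                timepoint,
                r,
                c,
                d.centroid[0],
                d.centroid[1],
                d.side_length,
                d.source,
            )
            for (r, c), d in sorted(self.entries.items())
        ]
        return pd.DataFrame(
            rows,
            columns=["timepoint", "row", "col", "x_um", "y_um", "side_um", "source"],
        )


def detect_quads(
    plane: ImagePlane, geometry: ArrayGeometry, closing_radius_um: float = 20.0
) -> list[QuadDetection]:
    """Segment quads from a corrected bright-field plane.

    Otsu thresholding separates the bright microraft surfaces from the PDMS
    background; interior holes (cell-darkened patches) are filled, objects at
    the image border removed, the four sub-rafts of a quad merged by
    morphological closing (the closing disk bridges the 30 um intra-quad gap
    but not the 100 um barrier), and size exclusion keeps only plausible
    whole quads.
    """
    valid = plane.valid_mask()
    vals = plane.pixels[valid]
    if vals.size == 0 or float(vals.min()) == float(vals.max()):
        if vals.size and float(vals.std()) == 0.0:
            return []
        raise ValueError("degenerate histogram: cannot threshold")
    thr = float(threshold_otsu(vals))
    binary = (plane.pixels > thr) & valid
    if not binary.any():
        return []
    binary = ndi.binary_fill_holes(binary)
    binary = segmentation.clear_border(binary)
    # Drop speckle islands before closing so they cannot be merged into a
    # quad and bias its centroid.
    speck_px = max(1, int(round((10.0 / plane.pixel_size) ** 2)))
    binary = morphology.remove_small_objects(binary, max_size=speck_px)
    r = max(1, int(round(closing_radius_um / plane.pixel_size)))
    binary = morphology.closing(binary, footprint=disk(r, decomposition="sequence"))
    binary = ndi.binary_fill_holes(binary)

    labels, _ = ndi.label(binary)
    ps = plane.pixel_size
    nominal_area = geometry.quad_side**2
    out = []
    for p in regionprops(labels):
        area_um2 = p.area * ps * ps
        if not (0.5 * nominal_area <= area_um2 <= 1.5 * nominal_area):
            continue
        cy, cx = p.centroid
        h = (p.bbox[2] - p.bbox[0]) * ps
        w = (p.bbox[3] - p.bbox[1]) * ps
        out.append(
            QuadDetection(
                centroid=((cx + 0.5) * ps, (cy + 0.5) * ps),
                side_length=float((h + w) / 2),
                quality={"area_um2": float(area_um2), "solidity": float(p.solidity)},
            )
        )
    return out


def consolidate_centroids(
    detections: list[QuadDetection], min_separation: float = 430.0
) -> list[QuadDetection]:
    """Merge duplicate centroids closer than ``min_separation`` um.

    Merging is transitive (single linkage) and repeated until no two output
    centroids are closer than the separation; a merged centroid is the mean
    of its members.
    """
    dets = list(detections)
    while len(dets) > 1:
        pts = np.asarray([d.centroid for d in dets])
        pairs = cKDTree(pts).query_pairs(min_separation, output_type="ndarray")
        if len(pairs) == 0:
            break
        parent = np.arange(len(dets))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in pairs:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
        groups: dict[int, list[int]] = {}
        for i in range(len(dets)):
            groups.setdefault(find(i), []).append(i)
        merged = []
        for members in groups.values():
            if len(members) == 1:
                merged.append(dets[members[0]])
                continue
            cx = float(np.mean([dets[i].centroid[0] for i in members]))
            cy = float(np.mean([dets[i].centroid[1] for i in members]))
            side = float(np.mean([dets[i].side_length for i in members]))
            merged.append(
                QuadDetection(
                    centroid=(cx, cy),
                    side_length=side,
                    quality={"merged_from": len(members)},
                )
            )
        dets = merged
    return dets


def _robust_mean(x: np.ndarray) -> float:
    """Mean after one round of outlier rejection at 3 MAD."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return float(med)
    keep = np.abs(x - med) <= 3 * 1.4826 * mad
    return float(x[keep].mean())


def _estimate_lattice(pts: np.ndarray, pitch_nominal: float) -> tuple[float, float]:
    """Estimate in-plane rotation (deg) and pitch (um) from nearest-neighbor
    displacement vectors."""
    tree = cKDTree(pts)
    k = min(5, len(pts))
    dist, idx = tree.query(pts, k=k)
    vecs = []
    for i in range(len(pts)):
        for j in range(1, k):
            d = dist[i, j]
            # Accept only distance-1 lattice neighbors: the gate must exclude
            # diagonal neighbors at sqrt(2) x pitch even under distortion.
            if 0.75 * pitch_nominal <= d <= 1.25 * pitch_nominal:
                vecs.append(pts[idx[i, j]] - pts[i])
    if not vecs:
        raise ValueError("too few detections to fit a lattice")
    vecs = np.asarray(vecs)
    norms = np.linalg.norm(vecs, axis=1)
    ang = np.degrees(np.arctan2(vecs[:, 1], vecs[:, 0]))
    # Map angles into [-45, 45) modulo the 90 deg lattice symmetry.
    ang = (ang + 45.0) % 90.0 - 45.0
    theta = _robust_mean(ang)
    pitch = _robust_mean(norms)
    return theta, pitch


def index_grid(
    detections: list[QuadDetection], geometry: ArrayGeometry
) -> IndexedGrid:
    """Assign (row, col) lattice indices to consolidated centroids.

    A robust global lattice (rotation + pitch, then a full affine refinement)
    is fitted to the centroids; each detection takes the index of its nearest
    lattice site, with collisions resolved in favor of the nearer detection.
    Indices are shifted so the top-left detection receives (0, 0).
    """
    if len(detections) < 4:
        raise ValueError("need at least 4 detections to index a grid")
    pts = np.asarray([d.centroid for d in detections], dtype=float)
    theta, pitch = _estimate_lattice(pts, geometry.quad_pitch)

    t = np.deg2rad(theta)
    rot = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
    q = (pts - pts.mean(axis=0)) @ rot.T / pitch
    # Common fractional offset of the lattice, from the circular mean of the
    # fractional parts.
    frac = q - np.floor(q)
    phase = np.angle(np.exp(2j * np.pi * frac).mean(axis=0)) / (2 * np.pi)
    idx_f = q - phase
    cols = np.round(idx_f[:, 0]).astype(int)
    rows = np.round(idx_f[:, 1]).astype(int)
    if np.ptp(rows) < 1 or np.ptp(cols) < 1:
        raise ValueError("detections do not span at least 2 rows and 2 columns")

    # Affine refinement: x = origin + col * vec_col + row * vec_row.
    A = np.column_stack([np.ones(len(pts)), cols, rows])
    coef, *_ = np.linalg.lstsq(A, pts, rcond=None)
    resid = np.linalg.norm(pts - A @ coef, axis=1)
    med = np.median(resid)
    mad = np.median(np.abs(resid - med))
    keep = resid <= med + 3 * 1.4826 * mad if mad > 0 else np.ones(len(pts), bool)
    if keep.sum() >= 4:
        coef, *_ = np.linalg.lstsq(A[keep], pts[keep], rcond=None)
    origin, vec_col, vec_row = coef[0], coef[1], coef[2]

    # Re-assign indices from the refined lattice.
    B = np.column_stack([vec_col, vec_row])
    rel = np.linalg.solve(B.T @ B, B.T @ (pts - origin).T).T
    cols = np.round(rel[:, 0]).astype(int)
    rows = np.round(rel[:, 1]).astype(int)

    rows -= rows.min()
    cols -= cols.min()
    origin_shifted = origin  # re-fit origin for shifted indices below
    A = np.column_stack([np.ones(len(pts)), cols, rows])
    coef, *_ = np.linalg.lstsq(A, pts, rcond=None)
    origin_shifted, vec_col, vec_row = coef[0], coef[1], coef[2]

    fit = {
        "origin": tuple(origin_shifted),
        "vec_col": tuple(vec_col),
        "vec_row": tuple(vec_row),
        "pitch": float(pitch),
        "theta_deg": float(theta),
    }
    entries: dict[tuple[int, int], QuadDetection] = {}
    lattice_pt = lambda r, c: origin_shifted + c * vec_col + r * vec_row
    for i, det in enumerate(detections):
        key = (int(rows[i]), int(cols[i]))
        cand = replace(det, index=key)
        if key in entries:
            # Collision: keep the detection nearest the fitted lattice site.
            p0 = np.asarray(entries[key].centroid)
            p1 = np.asarray(det.centroid)
            lp = lattice_pt(*key)
            if np.linalg.norm(p1 - lp) < np.linalg.norm(p0 - lp):
                entries[key] = cand
        else:
            entries[key] = cand
    return IndexedGrid(entries=entries, geometry=geometry, lattice_fit=fit)


def _segment_fit(
    anchors: list[tuple[int, np.ndarray]], target: int, seg_len: int, n_total: int
) -> np.ndarray | None:
    """Linear fit of centroid vs index over the 15-quad segment containing
    ``target``, widening to neighboring segments when anchors are scarce."""
    block = target // seg_len
    for widen in range(0, n_total // seg_len + 2):
        lo = (block - widen) * seg_len
        hi = (block + widen + 1) * seg_len
        sel = [(i, p) for i, p in anchors if lo <= i < hi]
        if len(sel) >= 2:
            idx = np.asarray([i for i, _ in sel], dtype=float)
            pts = np.asarray([p for _, p in sel])
            coef = np.polynomial.polynomial.polyfit(idx, pts, 1)
            return coef[0] + coef[1] * target
    return None


def interpolate_missing(grid: IndexedGrid, segment_length_mm: float = 8.0) -> IndexedGrid:
    """Fill every lattice position by piecewise-linear interpolation.

    Missing centroids are estimated independently along their row and their
    column in segments of about ``segment_length_mm`` (15 quads at the
    default 530 um pitch) and the two estimates averaged; the short segments
    follow smooth array distortion that a single global line would not.
    """
    g = grid.geometry
    seg_len = max(2, int(round(segment_length_mm * 1000.0 / g.quad_pitch)))
    detected = {k: d for k, d in grid.entries.items() if d.source == "detected"}
    by_row: dict[int, list] = {}
    by_col: dict[int, list] = {}
    for (r, c), d in detected.items():
        by_row.setdefault(r, []).append((c, np.asarray(d.centroid)))
        by_col.setdefault(c, []).append((r, np.asarray(d.centroid)))

    entries = dict(grid.entries)
    side = float(np.median([d.side_length for d in detected.values()])) if detected else g.quad_side
    for r in range(g.quad_rows):
        for c in range(g.quad_cols):
            if (r, c) in entries:
                continue
            est = []
            if r in by_row:
                p = _segment_fit(by_row[r], c, seg_len, g.quad_cols)
                if p is not None:
                    est.append(p)
            if c in by_col:
                p = _segment_fit(by_col[c], r, seg_len, g.quad_rows)
                if p is not None:
                    est.append(p)
            if not est:
                if grid.lattice_fit:
                    est.append(grid.predict(r, c))
                else:
                    continue  # unresolvable: no anchors and no lattice model
            p = np.mean(est, axis=0)
            entries[(r, c)] = QuadDetection(
                centroid=(float(p[0]), float(p[1])),
                side_length=side,
                source="interpolated",
                index=(r, c),
            )
    return IndexedGrid(entries=entries, geometry=g, lattice_fit=dict(grid.lattice_fit))


def track_timepoints(grids: list[IndexedGrid]) -> pd.DataFrame:
    """Match colony sites across timepoints by lattice index.

    Each grid is indexed independently; a per-timepoint integer index offset
    (and the implied rigid shift) is resolved against the first timepoint by
    minimizing the median centroid displacement of shared detected sites.
    Returns a table (timepoint, row, col, x_um, y_um, side_um, source).
    """
    if not grids:
        raise ValueError("need at least one grid")
    base = grids[0]
    pitch = base.geometry.quad_pitch
    frames = [base.to_frame(timepoint=0)]
    base_det = {k: np.asarray(d.centroid) for k, d in base.entries.items() if d.source == "detected"}
    for t, g in enumerate(grids[1:], start=1):
        det = {k: np.asarray(d.centroid) for k, d in g.entries.items() if d.source == "detected"}
        best = None
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                shared = [
                    np.linalg.norm(det[k] - base_det[(k[0] + dr, k[1] + dc)])
                    for k in det
                    if (k[0] + dr, k[1] + dc) in base_det
                ]
                if len(shared) < 3:
                    continue
                m = float(np.median(shared))
                if best is None or m < best[0]:
                    best = (m, dr, dc)
        if best is None or best[0] > 0.5 * pitch:
            raise ValueError(f"registration failure between timepoints 0 and {t}")
        _, dr, dc = best
        entries = {
            (k[0] + dr, k[1] + dc): replace(d, index=(k[0] + dr, k[1] + dc))
            for k, d in g.entries.items()
        }
        shifted = IndexedGrid(entries=entries, geometry=g.geometry, lattice_fit=dict(g.lattice_fit))
        frames.append(shifted.to_frame(timepoint=t))
    out = pd.concat(frames, ignore_index=True)
    return out
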