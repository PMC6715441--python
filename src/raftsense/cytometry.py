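"""Colony-coverage cytometry, segmentation metrics and growth fits.

Combines colony masks with the indexed raft grid to describe each colony by
the surface it actually occupies: per-sub-raft coverage fractions, PDMS
overgrowth, and the 1-4-raft class (a raft counts as covered at >= 50%
surface coverage).  Also provides pixelwise segmentation evaluation
(sensitivity/specificity/MCC), SNR gain of processed over raw images,
colony-area error summaries, biomarker area ratios and log-linear
doubling-time fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import regionprops

from .bsdp import ColonyMask
from .grid import IndexedGrid
from .preprocess import ImagePlane
from .synth import SUB_RAFTS, _SUB_SIGNS

__all__ = [
    "ColonyRecord",
    "SegMetrics",
    "colony_records",
    "classify_growth",
    "evaluate_mask",
    "snr_gain",
    "median_area_error",
    "biomarker_positive_fraction",
    "doubling_time",
    "DoublingTime",
]


@dataclass
class ColonyRecord:
    """One detected colony and the microfeatures underneath it."""

    colony_id: int
    quad: tuple[int, int] | None  # (row, col); None when off-grid
    area: float  # um^2
    equivalent_radius: float  # um
    raft_coverage: dict[str, float]  # NW/NE/SW/SE -> fraction in [0, 1]
    pdms_coverage: float  # fraction of the quad's PDMS footprint covered
    raft_pdms_outgrowth: dict[str, float] = field(default_factory=dict)
    timepoint: int = 0

    @property
    def raft_class(self) -> int:
        """Number of sub-rafts covered at >= 50% surface area."""
        return int(sum(v >= 0.5 for v in self.raft_coverage.values()))


@dataclass(frozen=True)
class SegMetrics:
    """Pixelwise confusion counts and derived rates for one evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def accuracy(self) -> float:
        n = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / n if n else float("nan")

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def mcc(self) -> float:
        tp, fp, tn, fn = (float(x) for x in (self.tp, self.fp, self.tn, self.fn))
        denom = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        if denom == 0:
            return float("nan")
        return (tp * tn - fp * fn) / denom


def colony_records(
    mask: ColonyMask,
    grid: IndexedGrid,
    pdms_ring: str = "half_barrier",
    timepoint: int = 0,
) -> list[ColonyRecord]:
    """Describe each labeled colony by the microfeatures it covers.

    A colony is assigned to the quad containing its centroid; coverage is
    the covered pixel fraction of each sub-raft footprint.  The PDMS
    footprint is the intra-quad gap cross plus (by default) the half-barrier
    ring around the quad; set ``pdms_ring="gap_only"`` to restrict it to the
    cross.  Per-raft PDMS outgrowth partitions the PDMS footprint by nearest
    sub-raft, which release planning uses to pick the most cleanly
    releasable raft.
    """
    g = grid.geometry
    ps = mask.pixel_size
    fit = grid.lattice_fit
    half_quad = g.quad_side / 2
    half_gap = g.intra_quad_gap / 2
    ring = g.barrier_width / 2 if pdms_ring == "half_barrier" else 0.0
    win = int(np.ceil((half_quad + ring + 2 * ps) / ps)) + 1

    # Invert the lattice to find the quad index under a point.
    B = np.column_stack([fit["vec_col"], fit["vec_row"]])
    Binv = np.linalg.inv(B.T @ B) @ B.T
    origin = np.asarray(fit["origin"], dtype=float)

    out: list[ColonyRecord] = []
    binary = mask.binary
    for p in regionprops(mask.labels):
        cy, cx = p.centroid
        pt = np.asarray([(cx + 0.5) * ps, (cy + 0.5) * ps])
        rel = Binv @ (pt - origin)
        key = (int(round(rel[1])), int(round(rel[0])))
        area = float(p.area) * ps * ps
        radius = float(np.sqrt(area / np.pi))
        if key not in grid.entries:
            out.append(
                ColonyRecord(
                    colony_id=int(p.label),
                    quad=None,
                    area=area,
                    equivalent_radius=radius,
                    raft_coverage={s: 0.0 for s in SUB_RAFTS},
                    pdms_coverage=0.0,
                    timepoint=timepoint,
                )
            )
            continue
        center = grid.entries[key].centroid
        ci = int(round(center[1] / ps - 0.5))
        cj = int(round(center[0] / ps - 0.5))
        i0, i1 = max(ci - win, 0), min(ci + win + 1, binary.shape[0])
        j0, j1 = max(cj - win, 0), min(cj + win + 1, binary.shape[1])
        sub_mask = mask.labels[i0:i1, j0:j1] == p.label
        yy, xx = np.mgrid[i0:i1, j0:j1].astype(np.float32)
        x = (xx + 0.5) * ps - center[0]
        y = (yy + 0.5) * ps - center[1]
        ec = np.asarray(fit["vec_col"], dtype=float)
        er = np.asarray(fit["vec_row"], dtype=float)
        ec = ec / np.linalg.norm(ec)
        er = er / np.linalg.norm(er)
        lu = x * ec[0] + y * ec[1]
        lv = x * er[0] + y * er[1]

        coverage: dict[str, float] = {}
        outgrowth: dict[str, float] = {}
        in_gap = (
            ((np.abs(lu) <= half_gap) | (np.abs(lv) <= half_gap))
            & (np.abs(lu) <= half_quad)
            & (np.abs(lv) <= half_quad)
        )
        in_ring = (
            (np.maximum(np.abs(lu), np.abs(lv)) > half_quad)
            & (np.abs(lu) <= half_quad + ring)
            & (np.abs(lv) <= half_quad + ring)
        ) if ring > 0 else np.zeros_like(in_gap)
        pdms_fp = in_gap | in_ring
        for sub in SUB_RAFTS:
            sx, sy = _SUB_SIGNS[sub]
            in_raft = (
                (sx * lu >= half_gap)
                & (sx * lu <= half_quad)
                & (sy * lv >= half_gap)
                & (sy * lv <= half_quad)
            )
            n = int(in_raft.sum())
            coverage[sub] = float((sub_mask & in_raft).sum() / n) if n else 0.0
            near = pdms_fp & (sx * lu >= 0) & (sy * lv >= 0)
            m = int(near.sum())
            outgrowth[sub] = float((sub_mask & near).sum() / m) if m else 0.0
        n_pdms = int(pdms_fp.sum())
        pdms_cov = float((sub_mask & pdms_fp).sum() / n_pdms) if n_pdms else 0.0
        out.append(
            ColonyRecord(
                colony_id=int(p.label),
                quad=key,
                area=area,
                equivalent_radius=radius,
                raft_coverage=coverage,
                pdms_coverage=pdms_cov,
                raft_pdms_outgrowth=outgrowth,
                timepoint=timepoint,
            )
        )
    return out


_RECORD_COLUMNS = [
    "colony_id",
    "timepoint",
    "quad_row",
    "quad_col",
    "area_um2",
    "equivalent_radius_um",
    "cov_nw",
    "cov_ne",
    "cov_sw",
    "cov_se",
    "pdms_cov",
    "out_nw",
    "out_ne",
    "out_sw",
    "out_se",
    "raft_class",
]


def records_frame(records: Sequence[ColonyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "colony_id": r.colony_id,
                "timepoint": r.timepoint,
                "quad_row": r.quad[0] if r.quad else -1,
                "quad_col": r.quad[1] if r.quad else -1,
                "area_um2": r.area,
                "equivalent_radius_um": r.equivalent_radius,
                "cov_nw": r.raft_coverage.get("NW", 0.0),
                "cov_ne": r.raft_coverage.get("NE", 0.0),
                "cov_sw": r.raft_coverage.get("SW", 0.0),
                "cov_se": r.raft_coverage.get("SE", 0.0),
                "pdms_cov": r.pdms_coverage,
                "out_nw": r.raft_pdms_outgrowth.get("NW", 0.0),
                "out_ne": r.raft_pdms_outgrowth.get("NE", 0.0),
                "out_sw": r.raft_pdms_outgrowth.get("SW", 0.0),
                "out_se": r.raft_pdms_outgrowth.get("SE", 0.0),
                "raft_class": r.raft_class,
            }
        )
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def classify_growth(records_by_time: dict[int, Sequence[ColonyRecord]]) -> pd.DataFrame:
    """Per-timepoint histogram of 1-4-raft colony classes.

    Returns a table (timepoint, class_0..class_4, n_colonies, raft_area_um2,
    pdms-covered mean fraction) summarizing how colonies spread across their
    quads over time.
    """
    rows = []
    for t in sorted(records_by_time):
        recs = list(records_by_time[t])
        counts = {f"class_{k}": 0 for k in range(5)}
        for r in recs:
            counts[f"class_{r.raft_class}"] += 1
        rows.append(
            {
                "timepoint": t,
                **counts,
                "n_colonies": len(recs),
                "total_area_um2": float(sum(r.area for r in recs)),
                "mean_pdms_cov": float(np.mean([r.pdms_coverage for r in recs]))
                if recs
                else 0.0,
            }
        )
    return pd.DataFrame(rows)


def evaluate_mask(
    predicted: ColonyMask | np.ndarray,
    truth: np.ndarray,
    valid: np.ndarray | None = None,
) -> SegMetrics:
    """Pixelwise confusion of a predicted mask against a ground-truth mask."""
    pred = predicted.binary if isinstance(predicted, ColonyMask) else np.asarray(predicted, bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch between predicted and truth masks")
    if valid is None:
        valid = np.ones_like(truth)
    p = pred[valid]
    t = truth[valid]
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return SegMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def snr_gain(
    raw: ImagePlane | np.ndarray,
    processed: ImagePlane | np.ndarray,
    truth: np.ndarray,
) -> float:
    """Ratio of processed to raw signal-to-noise, SNR = (mean_in - mean_out) / std_out."""
    raw_px = raw.pixels if isinstance(raw, ImagePlane) else np.asarray(raw, float)
    pro_px = (
        processed.pixels if isinstance(processed, ImagePlane) else np.asarray(processed, float)
    )
    truth = np.asarray(truth, bool)
    if not truth.any() or truth.all():
        raise ValueError("mask must contain both classes")

    def _snr(img: np.ndarray) -> float:
        inside = float(img[truth].mean())
        outside = img[~truth]
        sd = float(outside.std())
        if sd == 0:
            raise ValueError("zero outside-std: SNR undefined")
        return (inside - float(outside.mean())) / sd

    return _snr(pro_px) / _snr(raw_px)


def median_area_error(
    pairs: Sequence[tuple[float, float]], min_radius: float = 25.0
) -> float:
    """Median relative area error over matched (predicted, truth) colony
    areas (um^2), restricted to truth equivalent radius >= ``min_radius``."""
    errs = []
    for a_pred, a_true in pairs:
        if a_true <= 0:
            continue
        if np.sqrt(a_true / np.pi) < min_radius:
            continue
        errs.append(abs(a_pred - a_true) / a_true)
    if not errs:
        raise ValueError("no qualifying colony pairs")
    return float(np.median(errs))


def biomarker_positive_fraction(
    marker: ImagePlane | np.ndarray,
    nuclei: ImagePlane | np.ndarray,
    marker_thresh: float | None = None,
    nuclei_thresh: float | None = None,
) -> float:
    """Biomarker-positive area divided by total nuclear (Hoechst) area.

    Thresholds default to Otsu per channel.
    """
    m = marker.pixels if isinstance(marker, ImagePlane) else np.asarray(marker, float)
    n = nuclei.pixels if isinstance(nuclei, ImagePlane) else np.asarray(nuclei, float)
    if m.shape != n.shape:
        raise ValueError("marker and nuclei shapes differ")
    if marker_thresh is None:
        marker_thresh = float(threshold_otsu(m))
    if nuclei_thresh is None:
        nuclei_thresh = float(threshold_otsu(n))
    n_area = int(np.count_nonzero(n > nuclei_thresh))
    if n_area == 0:
        raise ValueError("zero nuclei area")
    m_area = int(np.count_nonzero(m > marker_thresh))
    return m_area / n_area


@dataclass(frozen=True)
class DoublingTime:
    """Result of a log-linear growth fit."""

    hours: float | None
    ci: tuple[float | None, float | None]
    slope: float  # doublings per hour
    ok: bool


def doubling_time(
    times_h: Sequence[float],
    areas: Sequence[float],
    window_h: float = 72.0,
    alpha: float = 0.05,
) -> DoublingTime:
    """Doubling time from a linear fit of log2(area) against time.

    Only observations within ``window_h`` hours of the first positive area
    enter the fit; the confidence interval follows from the slope CI at the
    given significance level.  A non-positive slope yields an explicitly
    flagged undefined doubling time rather than a silent infinity.
    """
    t = np.asarray(times_h, dtype=float)
    a = np.asarray(areas, dtype=float)
    if np.any(a <= 0):
        raise ValueError("areas must be positive for log-linear fitting")
    t0 = t.min()
    sel = (t - t0) <= window_h
    t, a = t[sel], a[sel]
    if len(t) < 3:
        raise ValueError("need at least 3 observations within the window")
    y = np.log2(a)
    res = stats.linregress(t, y)
    slope = float(res.slope)
    if slope <= 0:
        return DoublingTime(hours=None, ci=(None, None), slope=slope, ok=False)
    dof = len(t) - 2
    tcrit = stats.t.ppf(1 - alpha / 2, dof) if dof > 0 else float("nan")
    lo = slope - tcrit * res.stderr
    hi = slope + tcrit * res.stderr
    ci_hi = (1.0 / lo) if lo > 0 else None  # slow-growth bound
    ci_lo = 1.0 / hi
    return DoublingTime(hours=1.0 / slope, ci=(ci_lo, ci_hi), slope=slope, ok=True)
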