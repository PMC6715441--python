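"""Smart biopsy planning and the image-guided microraft release loop.

Given per-colony coverage records, the planner selects one release target
per eligible quad (a quad is eligible when at least two of its microrafts
carry more than 50% cell coverage, so that a biopsy leaves a viable mother
fragment behind) and, among the covered rafts, picks the one with the least
cellular outgrowth onto the adjacent PDMS, the raft most likely to release
cleanly.  Targets are ordered by a greedy Nearest-Neighbor tour to minimize
stage travel.

The release controller then iterates image -> actuate -> measure for each
target: the dislodgement extent is the cleared fraction of the microwell
estimated by intensity thresholding against the pre-release frame, and the
loop re-aims each retry at the area-weighted centroid of the remaining raft
material.  It concludes on success (extent > 80%), or halts when the
residual centroid has drifted more than 70 um from its initial location,
when more than 1/3 of the raft lies outside its microwell, or after eight
attempts.  A stochastic simulated ejector stands in for the microneedle
hardware so the whole loop is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from skimage.filters import threshold_otsu

from .cytometry import ColonyRecord
from .grid import IndexedGrid
from .preprocess import ImagePlane
from .synth import SUB_RAFTS, ArrayGeometry, render_el_release_frame, well_footprint

__all__ = [
    "ReleaseTarget",
    "ReleasePlan",
    "AttemptOutcome",
    "ReleaseThresholds",
    "select_targets",
    "order_targets",
    "dislodgement_extent",
    "release_loop",
    "simulate_ejection",
    "SimulatedEjector",
]


@dataclass(frozen=True)
class ReleaseTarget:
    """One microraft chosen for biopsy release."""

    quad: tuple[int, int]
    sub_raft: str
    expected_centroid: tuple[float, float]  # (x, y) um
    rationale: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ReleasePlan:
    """Greedy nearest-neighbor ordering of release targets."""

    targets: tuple[ReleaseTarget, ...]
    route_length: float  # um
    start: tuple[float, float]


@dataclass(frozen=True)
class ReleaseThresholds:
    """Halting rules of the release feedback loop."""

    success_extent: float = 0.8
    max_attempts: int = 8
    max_displacement: float = 70.0  # um from the initial residual centroid
    max_outside_fraction: float = 1.0 / 3.0


@dataclass(frozen=True)
class AttemptOutcome:
    """One iteration of the release feedback loop."""

    attempt_index: int
    extent: float
    residual_centroid: tuple[float, float] | None  # (x, y) um, frame coords
    centroid_displacement: float  # um from the initial centroid
    outside_fraction: float
    status: str  # success | retry | halted_displacement | halted_outside | halted_attempts


def select_targets(records: Sequence[ColonyRecord]) -> list[ReleaseTarget]:
    """Pick one release target per eligible quad.

    Eligibility requires >= 2 sub-rafts with coverage strictly above 0.5;
    among those covered rafts the one with minimal adjacent-PDMS outgrowth
    is targeted (ties broken by NW/NE/SW/SE order).
    """
    out = []
    for rec in sorted(
        (r for r in records if r.quad is not None), key=lambda r: r.quad
    ):
        covered = [s for s in SUB_RAFTS if rec.raft_coverage.get(s, 0.0) > 0.5]
        if len(covered) < 2:
            continue
        pick = min(
            covered,
            key=lambda s: (rec.raft_pdms_outgrowth.get(s, 0.0), SUB_RAFTS.index(s)),
        )
        out.append(
            ReleaseTarget(
                quad=rec.quad,
                sub_raft=pick,
                # Physical position is resolved against a fitted grid by
                # targets_with_positions(); selection itself is geometry-free.
                expected_centroid=(0.0, 0.0),
                rationale={
                    "coverage": dict(rec.raft_coverage),
                    "pdms_outgrowth": dict(rec.raft_pdms_outgrowth),
                    "colony_id": rec.colony_id,
                },
            )
        )
    return out


def targets_with_positions(
    targets: Sequence[ReleaseTarget], grid: IndexedGrid
) -> list[ReleaseTarget]:
    """Fill expected centroids from the fitted grid's raft centers."""
    out = []
    for t in targets:
        pos = grid.raft_center(t.quad[0], t.quad[1], t.sub_raft)
        out.append(
            ReleaseTarget(
                quad=t.quad,
                sub_raft=t.sub_raft,
                expected_centroid=pos,
                rationale=dict(t.rationale),
            )
        )
    return out


def order_targets(
    targets: Sequence[ReleaseTarget], start: tuple[float, float] = (0.0, 0.0)
) -> ReleasePlan:
    """Greedy Nearest-Neighbor tour over the targets from ``start``.

    From the current stage position the Euclidean-nearest unvisited target is
    always taken next; ties break by (row, col, sub-raft) order so replays
    are deterministic.
    """
    remaining = list(targets)
    pos = np.asarray(start, dtype=float)
    ordered: list[ReleaseTarget] = []
    total = 0.0
    while remaining:
        def key(t: ReleaseTarget):
            d = float(np.linalg.norm(np.asarray(t.expected_centroid) - pos))
            return (d, t.quad[0], t.quad[1], SUB_RAFTS.index(t.sub_raft))

        nxt = min(remaining, key=key)
        remaining.remove(nxt)
        total += float(np.linalg.norm(np.asarray(nxt.expected_centroid) - pos))
        pos = np.asarray(nxt.expected_centroid, dtype=float)
        ordered.append(nxt)
    return ReleasePlan(targets=tuple(ordered), route_length=total, start=tuple(start))


def dislodgement_extent(
    pre_frame: ImagePlane,
    post_frame: ImagePlane,
    well: np.ndarray,
    nominal_raft_area_px: int | None = None,
) -> tuple[float, tuple[float, float] | None, float]:
    """Measure how much of the microwell an ejection attempt cleared.

    Pixels are classified as remaining raft material by Otsu thresholding of
    the pooled in-well intensities of the pre- and post-release frames (the
    pre frame anchors the intact-raft intensity, so a fully cleared well is
    still classified correctly).  Returns ``(extent, residual_centroid,
    outside_fraction)`` where extent is the cleared-well area over the well
    area, the residual centroid is the intensity-area-weighted centroid of
    remaining material (``None`` when everything cleared), and
    outside_fraction is material found outside the well over the nominal
    raft area.
    """
    if pre_frame.shape != post_frame.shape or pre_frame.shape != well.shape:
        raise ValueError("frames and well footprint must share one shape")
    post = post_frame.pixels.astype(np.float64)
    pre = pre_frame.pixels.astype(np.float64)
    if post.size == 0 or not np.all(np.isfinite(post)):
        raise ValueError("degenerate post frame")
    pool = np.concatenate([pre[well], post[well]])
    # Otsu splits the pooled in-well histogram (the pre frame anchors the
    # intact-raft mode); the operating threshold is the midpoint of the two
    # class means, which is stable wherever in the inter-mode gap the Otsu
    # split lands.  A unimodal pool (post indistinguishable from the intact
    # pre frame) means nothing was dislodged.
    bimodal = False
    if float(pool.min()) < float(pool.max()):
        t0 = float(threshold_otsu(pool))
        lo = pool[pool <= t0]
        hi = pool[pool > t0]
        if lo.size and hi.size:
            sep = float(hi.mean() - lo.mean())
            spread = max(float(lo.std()), float(hi.std()), 1e-12)
            if sep > 4.0 * spread:
                bimodal = True
                thr = float((lo.mean() + hi.mean()) / 2)
    if bimodal:
        material = post > thr
    else:
        material = well.copy()
    ps = pre_frame.pixel_size
    n_well = int(well.sum())
    extent = float((well & ~material).sum() / n_well)
    if nominal_raft_area_px is None:
        nominal_raft_area_px = n_well
    outside = float((material & ~well).sum() / nominal_raft_area_px)
    if not material.any():
        return extent, None, outside
    ys, xs = np.nonzero(material)
    weights = post[ys, xs]
    cx = float(((xs + 0.5) * ps * weights).sum() / weights.sum())
    cy = float(((ys + 0.5) * ps * weights).sum() / weights.sum())
    return extent, (cx, cy), outside


class Ejector(Protocol):
    """Minimal actuator interface the release loop drives."""

    def image(self) -> ImagePlane: ...

    def aim(self, x: float, y: float) -> None: ...

    def actuate(self) -> ImagePlane: ...


def release_loop(
    target: ReleaseTarget,
    ejector: Ejector,
    thresholds: ReleaseThresholds | None = None,
    geometry: ArrayGeometry | None = None,
) -> list[AttemptOutcome]:
    """Run the closed-loop release of one target.

    Each attempt aims (initially at the well center as seen in the
    pre-release frame, then at the residual-material centroid), actuates,
    and measures the dislodgement extent against the first pre-release
    frame.  Success requires extent > 80%; otherwise the loop retries until
    a halting rule fires.  The displacement rule is cumulative: it compares
    the current residual centroid with the centroid measured before the
    first attempt.
    """
    th = thresholds or ReleaseThresholds()
    g = geometry or ArrayGeometry()
    pre = ejector.image()
    well = well_footprint(g, pre.shape)
    nominal = int(well.sum())
    _, initial_centroid, _ = dislodgement_extent(pre, pre, well, nominal)
    if initial_centroid is None:  # nothing in the well to start with
        initial_centroid = (
            pre.shape[1] * pre.pixel_size / 2,
            pre.shape[0] * pre.pixel_size / 2,
        )
    aim_point = initial_centroid
    outcomes: list[AttemptOutcome] = []
    for attempt in range(1, th.max_attempts + 1):
        try:
            ejector.aim(*aim_point)
            post = ejector.actuate()
        except Exception as e:
            raise RuntimeError(
                f"actuator failure at attempt {attempt} of target {target.quad}/{target.sub_raft}: {e}"
            ) from e
        extent, residual, outside = dislodgement_extent(pre, post, well, nominal)
        if residual is not None:
            disp = float(np.linalg.norm(np.subtract(residual, initial_centroid)))
        else:
            disp = 0.0
        if extent > th.success_extent:
            status = "success"
        elif disp > th.max_displacement:
            status = "halted_displacement"
        elif outside > th.max_outside_fraction:
            status = "halted_outside"
        elif attempt >= th.max_attempts:
            status = "halted_attempts"
        else:
            status = "retry"
        outcomes.append(
            AttemptOutcome(
                attempt_index=attempt,
                extent=extent,
                residual_centroid=residual,
                centroid_displacement=disp,
                outside_fraction=outside,
                status=status,
            )
        )
        if status != "retry":
            break
        if residual is not None:
            aim_point = residual
    return outcomes


def _default_clear_probability(offset_um: float) -> float:
    """Chance that one microneedle strike fully dislodges the raft, as a
    function of how far the aim is from the raft-material centroid."""
    return 0.95 * float(np.exp(-((offset_um / 80.0) ** 2) / 2))


class SimulatedEjector:
    """Stochastic stand-in for the microneedle release hardware.

    Tracks the remaining raft fraction and its drift inside one microwell
    and renders every frame through the synthetic single-well renderer, so
    the loop exercises the same image-measurement path it would on hardware.
    ``aim_error_sd`` models the stage/needle position error (um) and
    ``clear_probability_model`` maps aim offset (um) to the per-attempt
    probability of a full dislodgement; a miss partially clears the well and
    nudges the residual material.
    """

    def __init__(
        self,
        geometry: ArrayGeometry,
        well: tuple[int, int, str],
        aim_error_sd: float = 3.0,
        clear_probability_model: Callable[[float], float] | None = None,
        partial_clear_range: tuple[float, float] = (0.05, 0.35),
        drift_sd: float = 8.0,
        seed: int = 0,
    ) -> None:
        self.geometry = geometry
        self.well = well
        self.aim_error_sd = float(aim_error_sd)
        self.clear_probability = clear_probability_model or _default_clear_probability
        if not 0 <= partial_clear_range[0] <= partial_clear_range[1] <= 1:
            raise ValueError("invalid partial_clear_range")
        self.partial_clear_range = partial_clear_range
        self.drift_sd = float(drift_sd)
        self.rng = np.random.default_rng(np.random.SeedSequence([seed, 81]))
        self.remaining = 1.0
        self.displacement = np.zeros(2)
        self._aim: np.ndarray | None = None
        self.attempts = 0

    def _frame(self) -> ImagePlane:
        return render_el_release_frame(
            self.geometry,
            self.well,
            remaining_fraction=self.remaining,
            displacement=(float(self.displacement[0]), float(self.displacement[1])),
            noise_sd=0.01,
            seed=int(self.rng.integers(0, 2**31 - 1)),
        )

    def image(self) -> ImagePlane:
        return self._frame()

    def aim(self, x: float, y: float) -> None:
        self._aim = np.asarray([x, y], dtype=float)

    def actuate(self) -> ImagePlane:
        if self._aim is None:
            raise RuntimeError("actuate() called before aim()")
        self.attempts += 1
        if self.remaining > 0:
            frame = self._frame()
            half = (
                frame.shape[1] * frame.pixel_size / 2,
                frame.shape[0] * frame.pixel_size / 2,
            )
            material_center = np.asarray(half) + self.displacement
            err = self.rng.normal(0.0, self.aim_error_sd, 2)
            offset = float(np.linalg.norm(self._aim + err - material_center))
            p = float(np.clip(self.clear_probability(offset), 0.0, 1.0))
            if self.rng.random() < p:
                self.remaining = 0.0
            else:
                lo, hi = self.partial_clear_range
                self.remaining = max(0.0, self.remaining - float(self.rng.uniform(lo, hi)))
                self.displacement = self.displacement + self.rng.normal(
                    0.0, self.drift_sd, 2
                )
        return self._frame()


def simulate_ejection(
    geometry: ArrayGeometry,
    well: tuple[int, int, str],
    aim_error_model: float = 3.0,
    clear_probability_model: Callable[[float], float] | None = None,
    seed: int = 0,
    **kw,
) -> SimulatedEjector:
    """Construct a seeded simulated actuator for one microwell."""
    return SimulatedEjector(
        geometry,
        well,
        aim_error_sd=aim_error_model,
        clear_probability_model=clear_probability_model,
        seed=seed,
        **kw,
    )
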