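"""Coverage records, classification, evaluation metrics and growth fits."""

import numpy as np
import pytest

from raftsense import (
    ColonyMask,
    ColonyRecord,
    SUB_RAFTS,
    biomarker_positive_fraction,
    classify_growth,
    colony_records,
    doubling_time,
    evaluate_mask,
    median_area_error,
    snr_gain,
    reduced_geometry,
)
from raftsense.grid import IndexedGrid, QuadDetection


def _axis_grid(g):
    """Axis-aligned IndexedGrid whose entries sit at the ideal lattice."""
    entries = {}
    for r in range(g.quad_rows):
        for c in range(g.quad_cols):
            entries[(r, c)] = QuadDetection(
                centroid=g.quad_center(r, c), side_length=g.quad_side, index=(r, c)
            )
    fit = {
        "origin": g.quad_center(0, 0),
        "vec_col": (g.quad_pitch, 0.0),
        "vec_row": (0.0, g.quad_pitch),
        "pitch": g.quad_pitch,
        "theta_deg": 0.0,
    }
    return IndexedGrid(entries=entries, geometry=g, lattice_fit=fit)


def _raft_box_mask(g, row, col, sub, shape):
    cx, cy = g.raft_center(row, col, sub)
    ps = g.pixel_size
    half = g.raft_side / 2
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    x = (xx + 0.5) * ps
    y = (yy + 0.5) * ps
    return (np.abs(x - cx) <= half) & (np.abs(y - cy) <= half)


class TestColonyRecords:
    def test_exact_raft_footprint_gives_unit_coverage(self):
        g = reduced_geometry(2, 2)
        grid = _axis_grid(g)
        shape = g.image_shape()
        box = _raft_box_mask(g, 0, 0, "NE", shape)
        mask = ColonyMask(labels=box.astype(np.int32), pixel_size=g.pixel_size)
        recs = colony_records(mask, grid)
        assert len(recs) == 1
        r = recs[0]
        assert r.quad == (0, 0)
        assert r.raft_coverage["NE"] == pytest.approx(1.0, abs=0.02)
        for s in ("NW", "SW", "SE"):
            assert r.raft_coverage[s] == pytest.approx(0.0, abs=0.02)
        assert r.raft_class == 1

    def test_full_quad_coverage_gives_class_four(self):
        g = reduced_geometry(2, 2)
        grid = _axis_grid(g)
        shape = g.image_shape()
        ps = g.pixel_size
        cx, cy = g.quad_center(1, 1)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
        quad_box = (np.abs((xx + 0.5) * ps - cx) <= g.quad_side / 2) & (
            np.abs((yy + 0.5) * ps - cy) <= g.quad_side / 2
        )
        mask = ColonyMask(labels=quad_box.astype(np.int32), pixel_size=ps)
        r = colony_records(mask, grid)[0]
        assert r.quad == (1, 1)
        for s in SUB_RAFTS:
            assert r.raft_coverage[s] == pytest.approx(1.0, abs=0.02)
        assert r.raft_class == 4
        # the gap cross is covered but the half-barrier ring is not, and the
        # cross is about a fifth of the full PDMS footprint
        cross = 2 * g.quad_side * g.intra_quad_gap - g.intra_quad_gap**2
        ring = (g.quad_side + g.barrier_width) ** 2 - g.quad_side**2
        assert r.pdms_coverage == pytest.approx(cross / (cross + ring), abs=0.03)

    def test_recovered_coverages_on_rendered_scene(self, pipeline_small):
        """End-to-end: coverages recovered within +-0.1 of the drawn truth."""
        from raftsense.grid import (
            consolidate_centroids,
            detect_quads,
            index_grid,
            interpolate_missing,
        )
        from raftsense.preprocess import correct_stack

        spec = pipeline_small["spec"]
        sigc = correct_stack(pipeline_small["signal"])
        dets = detect_quads(sigc.middle_plane(), spec.geometry)
        dets = consolidate_centroids(dets, min_separation=0.8 * spec.geometry.quad_pitch)
        grid = interpolate_missing(index_grid(dets, spec.geometry))
        recs = colony_records(pipeline_small["mask"], grid)
        per_quad = {}
        for r in recs:
            if r.quad is None:
                continue
            agg = per_quad.setdefault(r.quad, dict.fromkeys(SUB_RAFTS, 0.0))
            for s in SUB_RAFTS:
                agg[s] += r.raft_coverage[s]
        checked = 0
        for c in spec.colonies:
            agg = per_quad.get(c.quad)
            assert agg is not None, f"colony at {c.quad} not recovered"
            for s, true_cov in zip(SUB_RAFTS, c.raft_coverage):
                assert agg[s] == pytest.approx(true_cov, abs=0.1)
                checked += 1
        assert checked == 4 * len(spec.colonies)


class TestClassifyGrowth:
    def _rec(self, quad, cov, t=0, cid=1):
        return ColonyRecord(
            colony_id=cid,
            quad=quad,
            area=10000.0,
            equivalent_radius=56.0,
            raft_coverage=dict(zip(SUB_RAFTS, cov)),
            pdms_coverage=0.0,
            timepoint=t,
        )

    def test_single_raft_colonies_all_class_one(self):
        recs = [self._rec((0, i), (0.9, 0.1, 0.0, 0.0), cid=i) for i in range(5)]
        table = classify_growth({0: recs})
        assert table.loc[0, "class_1"] == 5
        assert table.loc[0, ["class_2", "class_3", "class_4"]].sum() == 0

    def test_class_counts_sum_to_total(self):
        rng = np.random.default_rng(0)
        recs = [
            self._rec((0, i), tuple(rng.uniform(0, 1, 4)), cid=i) for i in range(20)
        ]
        table = classify_growth({0: recs})
        assert (
            table.loc[0, [f"class_{k}" for k in range(5)]].sum()
            == table.loc[0, "n_colonies"]
        )

    def test_empty_timepoint_is_zero_histogram(self):
        table = classify_growth({0: [], 1: [self._rec((0, 0), (1, 1, 0, 0))]})
        assert table.loc[0, "n_colonies"] == 0
        assert table.loc[1, "class_2"] == 1


class TestEvaluateMask:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(1)
        truth = rng.random((50, 50)) > 0.7
        m = evaluate_mask(truth, truth)
        assert m.sensitivity == 1.0 and m.specificity == 1.0
        assert m.accuracy == 1.0 and m.precision == 1.0 and m.mcc == 1.0

    def test_complement_gives_minus_one(self):
        rng = np.random.default_rng(2)
        truth = rng.random((50, 50)) > 0.5
        m = evaluate_mask(~truth, truth)
        assert m.mcc == pytest.approx(-1.0)

    def test_mcc_formula_spot_check(self):
        from raftsense.cytometry import SegMetrics

        m = SegMetrics(tp=88, fn=12, tn=98, fp=2)
        expected = (88 * 98 - 2 * 12) / np.sqrt(90 * 100 * 100 * 110)
        assert m.mcc == pytest.approx(expected, abs=1e-12)
        assert m.mcc == pytest.approx(0.864, abs=5e-4)
        assert m.sensitivity == pytest.approx(0.88)
        assert m.specificity == pytest.approx(0.98)

    def test_swapping_pred_truth_preserves_mcc(self):
        rng = np.random.default_rng(3)
        a = rng.random((40, 40)) > 0.6
        b = rng.random((40, 40)) > 0.4
        assert evaluate_mask(a, b).mcc == pytest.approx(evaluate_mask(b, a).mcc)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_mask(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestSnrGain:
    def test_identity_gain_is_one(self):
        rng = np.random.default_rng(4)
        img = rng.normal(1.0, 0.1, (60, 60))
        mask = np.zeros((60, 60), bool)
        mask[20:40, 20:40] = True
        img[mask] += 1.0
        assert snr_gain(img, img, mask) == pytest.approx(1.0)

    def test_halved_noise_doubles_gain(self):
        rng = np.random.default_rng(5)
        noise = rng.normal(0.0, 0.2, (80, 80))
        mask = np.zeros((80, 80), bool)
        mask[30:50, 30:50] = True
        raw = 1.0 + noise + mask * 1.0
        processed = 1.0 + noise / 2 + mask * 1.0
        assert snr_gain(raw, processed, mask) == pytest.approx(2.0, rel=0.05)

    def test_single_class_mask_rejected(self):
        img = np.ones((10, 10))
        with pytest.raises(ValueError):
            snr_gain(img, img, np.ones((10, 10), bool))


class TestAreaError:
    def test_identical_areas_zero_error(self):
        pairs = [(4000.0, 4000.0), (9000.0, 9000.0)]
        assert median_area_error(pairs) == 0.0

    def test_uniform_ten_percent_bias(self):
        pairs = [(1.1 * a, a) for a in (3000.0, 5000.0, 8000.0)]
        assert median_area_error(pairs) == pytest.approx(0.10, abs=1e-9)

    def test_small_colonies_excluded(self):
        small = np.pi * 20**2  # radius 20 um < 25 um cutoff
        with pytest.raises(ValueError):
            median_area_error([(small, small)])


class TestBiomarker:
    def test_marker_equal_to_nuclei_gives_one(self):
        rng = np.random.default_rng(6)
        img = (rng.random((50, 50)) > 0.6).astype(float)
        assert biomarker_positive_fraction(img, img, 0.5, 0.5) == 1.0

    def test_half_marker_area(self):
        nuclei = np.zeros((40, 40))
        nuclei[:20, :] = 1.0
        marker = np.zeros((40, 40))
        marker[:10, :] = 1.0
        assert biomarker_positive_fraction(marker, nuclei, 0.5, 0.5) == 0.5

    def test_zero_nuclei_rejected(self):
        with pytest.raises(ValueError):
            biomarker_positive_fraction(
                np.ones((10, 10)), np.zeros((10, 10)), 0.5, 0.5
            )


class TestDoublingTime:
    def test_exact_doubling_every_17_hours(self):
        t = np.arange(0, 72, 8.0)
        areas = 1000.0 * 2 ** (t / 17.0)
        fit = doubling_time(t, areas)
        assert fit.ok
        assert fit.hours == pytest.approx(17.0, abs=1e-9)

    def test_constant_areas_flagged_undefined(self):
        t = np.arange(0, 72, 12.0)
        fit = doubling_time(t, np.full(len(t), 500.0))
        assert not fit.ok
        assert fit.hours is None

    def test_nonpositive_area_rejected(self):
        with pytest.raises(ValueError):
            doubling_time([0, 12, 24], [100.0, 0.0, 200.0])

    def test_ci_covers_generating_value(self):
        """Simulation recovery: the 95% CI covers the generating doubling
        time in at least 90% of 100 noisy series."""
        rng = np.random.default_rng(7)
        t = np.arange(0, 72, 6.0)
        true_dt = 17.0
        covered = 0
        for _ in range(100):
            areas = 1000.0 * 2 ** (t / true_dt) * np.exp(rng.normal(0, 0.08, len(t)))
            fit = doubling_time(t, areas)
            if fit.ok and fit.ci[0] is not None and fit.ci[1] is not None:
                if fit.ci[0] <= true_dt <= fit.ci[1]:
                    covered += 1
        assert covered >= 90
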