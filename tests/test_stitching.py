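"""Window planning, XIM extraction and mobilogram stitching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from simstitch.errors import ConsistencyError, DomainError, PlanningError
from simstitch.stitching import (Mobilogram, Segment, Window, extract_xim,
                                 interior_boundaries, plan_windows, stitch)


def brute_force_starts(range_start, range_end, width, overlap):
    """Enumeration oracle for window starts on the 1e-6 lattice."""
    micro = 1_000_000
    s = round(range_start * micro)
    e = round(range_end * micro)
    w = round(width * micro)
    o = round(overlap * micro)
    starts = [s]
    while starts[-1] + w < e:
        starts.append(starts[-1] + (w - o))
    return [x / micro for x in starts]


class TestPlanWindows:
    def test_reference_four_window_plan(self, paper_plan):
        bounds = [(w.start_inv_k0, w.end_inv_k0) for w in paper_plan.windows]
        assert bounds == [(0.70, 0.85), (0.80, 0.95), (0.90, 1.05), (1.00, 1.15)]
        assert interior_boundaries(paper_plan) == [0.85, 0.95, 1.05]

    def test_single_window_identity(self):
        plan = plan_windows(0.70, 0.85, 0.15, 0.0)
        assert len(plan.windows) == 1
        assert interior_boundaries(plan) == []

    def test_final_window_extends_past_requested_end(self):
        plan = plan_windows(0.70, 1.10, 0.15, 0.05)
        starts = [w.start_inv_k0 for w in plan.windows]
        assert starts == [0.70, 0.80, 0.90, 1.00]
        assert plan.windows[-1].end_inv_k0 == 1.15

    def test_three_window_interior_boundaries(self):
        plan = plan_windows(0.70, 1.05, 0.15, 0.05)
        assert interior_boundaries(plan) == [0.85, 0.95]

    def test_overlap_not_below_width_guard(self):
        with pytest.raises(PlanningError):
            plan_windows(0.7, 1.15, 0.15, 0.15)
        with pytest.raises(PlanningError):
            plan_windows(0.7, 1.15, 0.15, 0.2)

    def test_empty_range_rejected(self):
        with pytest.raises(PlanningError):
            plan_windows(1.0, 1.0, 0.15, 0.05)

    def test_boundary_equality_is_exact(self):
        # scaled-integer arithmetic: 0.70 + 3*(0.10) must equal 1.00 exactly
        plan = plan_windows(0.70, 1.15, 0.15, 0.05)
        assert plan.windows[3].start_inv_k0 == 1.00
        assert plan.windows[1].end_inv_k0 == 0.95

    def test_against_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            start = round(rng.uniform(0.2, 1.2), 3)
            width = round(rng.uniform(0.05, 0.3), 3)
            overlap = round(rng.uniform(0.0, width * 0.9), 3)
            if overlap >= width:
                continue
            end = round(start + rng.uniform(0.01, 1.0), 3)
            plan = plan_windows(start, end, width, overlap)
            assert [w.start_inv_k0 for w in plan.windows] == \
                brute_force_starts(start, end, width, overlap)


def _segment(window, x, intensity, mz=100.0, seg_id="s"):
    x = np.asarray(x, dtype=float)
    return Segment(window, x, np.full(len(x), mz), np.asarray(intensity, float),
                   segment_id=seg_id)


class TestExtractXim:
    def test_records_inside_tolerance_kept(self, paper_plan):
        w = paper_plan.windows[0]
        seg = Segment(w, np.array([0.72, 0.73, 0.74]),
                      np.array([292.048, 292.043, 292.053]),
                      np.array([10.0, 20.0, 30.0]), segment_id="a")
        out = extract_xim([seg], 292.048, tol=0.01)
        assert out[0].total_intensity == 60.0

    def test_record_outside_tolerance_dropped(self, paper_plan):
        w = paper_plan.windows[0]
        seg = Segment(w, np.array([0.72]), np.array([292.070]), np.array([10.0]))
        out = extract_xim([seg], 292.048, tol=0.01)
        assert len(out[0].inv_k0) == 0

    def test_colocated_records_are_summed(self, paper_plan):
        w = paper_plan.windows[0]
        seg = Segment(w, np.array([0.72, 0.72]), np.array([292.048, 292.050]),
                      np.array([10.0, 5.0]))
        out = extract_xim([seg], 292.048, tol=0.01)
        assert list(out[0].intensity) == [15.0]

    def test_channels_separated_when_spacing_exceeds_twice_tol(self, paper_plan):
        # two co-eluting channels 0.03 Da apart with tol 0.01: zero crosstalk
        w = paper_plan.windows[0]
        x = np.linspace(0.71, 0.84, 50)
        seg = Segment(w, np.concatenate([x, x]),
                      np.concatenate([np.full(50, 292.048), np.full(50, 292.078)]),
                      np.concatenate([np.full(50, 7.0), np.full(50, 13.0)]))
        lo = extract_xim([seg], 292.048, tol=0.01)
        hi = extract_xim([seg], 292.078, tol=0.01)
        assert lo[0].total_intensity == pytest.approx(50 * 7.0)
        assert hi[0].total_intensity == pytest.approx(50 * 13.0)

    def test_nonpositive_tolerance_rejected(self, paper_plan):
        with pytest.raises(DomainError):
            extract_xim([], 292.0, tol=0.0)


class TestStitch:
    def test_single_segment_identity(self, paper_plan):
        plan = plan_windows(0.70, 0.85, 0.15, 0.0)
        x = np.round(np.arange(0.70, 0.8501, 0.001), 9)
        y = np.sin(np.arange(len(x))) ** 2
        seg = _segment(plan.windows[0], x, y)
        for mode in ("per_segment", "combined"):
            rule = "first" if mode == "per_segment" else "sum"
            mob = stitch([seg], plan, mode=mode, overlap_rule=rule)
            assert np.array_equal(mob.axis, x)
            assert np.allclose(mob.intensity, y, rtol=0, atol=0)

    def test_restitching_single_segment_result_is_noop(self, paper_plan):
        plan = plan_windows(0.70, 0.85, 0.15, 0.0)
        x = np.round(np.arange(0.70, 0.8501, 0.001), 9)
        seg = _segment(plan.windows[0], x, np.cos(np.arange(len(x))) ** 2)
        mob1 = stitch([seg], plan)
        mob2 = stitch([mob1.to_segment(plan.windows[0])], plan)
        assert np.array_equal(mob1.axis, mob2.axis)
        assert np.array_equal(mob1.intensity, mob2.intensity)

    def test_flat_overlap_doubles_under_combined_sum(self):
        plan = plan_windows(0.70, 0.90, 0.15, 0.05)   # 0.70-0.85, 0.80-0.95
        step = 0.001
        segs = []
        for i, w in enumerate(plan.windows):
            x = np.round(np.arange(w.start_inv_k0, w.end_inv_k0 + step / 2, step), 9)
            segs.append(_segment(w, x, np.ones(len(x)), seg_id=f"s{i}"))
        mob = stitch(segs, plan, mode="combined", overlap_rule="sum")
        overlap = (mob.axis >= 0.80) & (mob.axis <= 0.85)
        assert np.all(mob.intensity[overlap] == 2.0)
        assert np.all(mob.intensity[~overlap] == 1.0)

    def test_per_segment_first_takes_earlier_window_in_overlap(self):
        plan = plan_windows(0.70, 0.90, 0.15, 0.05)
        step = 0.001
        segs = []
        for i, w in enumerate(plan.windows):
            x = np.round(np.arange(w.start_inv_k0, w.end_inv_k0 + step / 2, step), 9)
            segs.append(_segment(w, x, np.full(len(x), float(i + 1)), seg_id=f"s{i}"))
        mob = stitch(segs, plan, mode="per_segment", overlap_rule="first")
        overlap = (mob.axis >= 0.80) & (mob.axis <= 0.85)
        assert np.all(mob.intensity[overlap] == 1.0)
        # and conservation: nothing counted twice
        dupes = (mob.axis >= 0.80) & (mob.axis <= 0.85)
        expected_total = sum(s.total_intensity for s in segs) - 2.0 * dupes.sum()
        assert mob.total_intensity == pytest.approx(expected_total, rel=1e-12)

    def test_segment_not_in_plan_rejected(self, paper_plan):
        rogue = _segment(Window(0.60, 0.75), [0.65], [1.0])
        with pytest.raises(ConsistencyError):
            stitch([rogue], paper_plan)

    def test_incompatible_grids_are_regridded(self):
        plan = plan_windows(0.70, 0.90, 0.15, 0.05)
        x1 = np.round(np.arange(0.70, 0.8501, 0.001), 9)
        x2 = np.round(np.arange(0.8005, 0.9501, 0.001), 9)  # offset grid
        segs = [_segment(plan.windows[0], x1, np.ones(len(x1)), seg_id="a"),
                _segment(plan.windows[1], x2, np.ones(len(x2)), seg_id="b")]
        mob = stitch(segs, plan, mode="combined", overlap_rule="mean")
        assert np.all(np.diff(mob.axis) > 0)
        interior = (mob.axis > 0.705) & (mob.axis < 0.945)
        assert np.allclose(mob.intensity[interior], 1.0)

    def test_artifact_mask_zeroes_boundary_band_and_flags(self):
        plan = plan_windows(0.70, 0.90, 0.15, 0.05)
        step = 0.001
        segs = []
        for i, w in enumerate(plan.windows):
            x = np.round(np.arange(w.start_inv_k0, w.end_inv_k0 + step / 2, step), 9)
            segs.append(_segment(w, x, np.ones(len(x)), seg_id=f"s{i}"))
        mob = stitch(segs, plan, artifact_mask=0.004)
        band = np.abs(mob.axis - 0.85) <= 0.004 + 1e-9
        assert np.all(mob.intensity[band] == 0.0)
        assert np.all(mob.masked[band])
        assert np.all(mob.intensity[~band] == 1.0)

    @given(mask=st.sampled_from([0.0, 0.002, 0.005, 0.01, 0.05]))
    @settings(max_examples=5, deadline=None, derandomize=True)
    def test_mask_monotonicity(self, mask):
        plan = plan_windows(0.70, 0.90, 0.15, 0.05)
        step = 0.001
        rng = np.random.default_rng(5)
        segs = []
        for i, w in enumerate(plan.windows):
            x = np.round(np.arange(w.start_inv_k0, w.end_inv_k0 + step / 2, step), 9)
            segs.append(_segment(w, x, rng.uniform(0, 10, len(x)), seg_id=f"s{i}"))
        base = stitch(segs, plan, artifact_mask=0.0).total_intensity
        masked = stitch(segs, plan, artifact_mask=mask).total_intensity
        assert masked <= base + 1e-12

    def test_empty_input_gives_empty_mobilogram(self, paper_plan):
        mob = stitch([], paper_plan)
        assert len(mob) == 0


def test_segment_record_outside_window_fails_validation():
    seg = _segment(Window(0.70, 0.85), [0.9], [1.0], seg_id="bad")
    with pytest.raises(ConsistencyError, match="bad"):
        seg.validate()


def test_mobilogram_requires_strictly_increasing_axis():
    with pytest.raises(ConsistencyError):
        Mobilogram(np.array([0.1, 0.1, 0.2]), np.zeros(3))
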