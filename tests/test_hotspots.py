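"""Run-of-three rule, CoG reductions, distances and the overlap metric."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stimmap.errors import EmptyInputError, FrameMismatchError, UndefinedOverlapError
from stimmap.hotspots import (
    INTERRUPTED,
    NORMAL,
    TRIAL_COLUMNS,
    CoGPoint,
    HotspotSet,
    OverlapRule,
    center_of_gravity,
    cog_distance,
    detect_hotspots,
    field_overlap,
)
from stimmap.phantom import SurfacePatch
from stimmap.volume_conductor import FieldSolution
from tests.oracles import brute_force_positive


def trials_frame(sequences, modality="DES"):
    rows = []
    for sid, seq in enumerate(sequences, start=1):
        for t, outcome in enumerate(seq, start=1):
            rows.append((sid, float(sid), 0.0, 0.0, t, outcome, modality))
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


class TestRunOfThreeRule:
    @pytest.mark.parametrize(
        "seq, positive",
        [
            ([INTERRUPTED] * 3, True),
            ([INTERRUPTED, NORMAL, INTERRUPTED, INTERRUPTED], False),
            ([NORMAL, INTERRUPTED, INTERRUPTED, INTERRUPTED, NORMAL], True),
        ],
    )
    def test_stated_examples(self, seq, positive):
        hs = detect_hotspots(trials_frame([seq]))
        assert (len(hs) == 1) is positive

    @pytest.mark.parametrize("length", range(1, 9))
    def test_exhaustive_agreement_with_brute_force(self, length):
        seqs = [
            [INTERRUPTED if b else NORMAL for b in bits]
            for bits in itertools.product((0, 1), repeat=length)
        ]
        hs = detect_hotspots(trials_frame(seqs))
        positive_ids = set(hs.site_ids.tolist())
        for sid, bits in enumerate(itertools.product((0, 1), repeat=length), start=1):
            assert (sid in positive_ids) == brute_force_positive([bool(b) for b in bits])

    def test_fewer_than_three_trials_cannot_be_positive(self):
        hs = detect_hotspots(trials_frame([[INTERRUPTED, INTERRUPTED]]))
        assert len(hs) == 0

    def test_nonconsecutive_trial_indices_rejected(self):
        df = trials_frame([[INTERRUPTED] * 3])
        df.loc[1, "trial"] = 7
        with pytest.raises(ValueError):
            detect_hotspots(df)


class TestCenterOfGravity:
    def test_midpoint_of_equal_weights(self):
        hs = HotspotSet("nTMS", [1, 2], [[0, 0, 0], [2, 0, 0]])
        assert np.allclose(center_of_gravity(hs).coords, [1, 0, 0])

    def test_weighted_mean(self):
        hs = HotspotSet("nTMS", [1, 2], [[0, 0, 0], [2, 0, 0]], weights=[1.0, 3.0])
        assert np.allclose(center_of_gravity(hs, weighting="weights").coords, [1.5, 0, 0])

    def test_single_site_is_its_own_cog(self):
        hs = HotspotSet("DES", [1], [[4.0, -2.0, 7.0]])
        assert np.allclose(center_of_gravity(hs).coords, [4, -2, 7])

    def test_empty_set_rejected(self):
        hs = HotspotSet("DES", [], np.zeros((0, 3)))
        with pytest.raises(EmptyInputError):
            center_of_gravity(hs)

    @given(
        st.lists(
            st.tuples(*[st.floats(-50, 50) for _ in range(3)]), min_size=1, max_size=8
        ),
        st.tuples(*[st.floats(-20, 20) for _ in range(3)]),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_translation_equivariance_and_permutation_invariance(self, coords, shift):
        coords = np.asarray(coords)
        hs = HotspotSet("nTMS", np.arange(len(coords)), coords)
        cog = center_of_gravity(hs).coords
        shifted = center_of_gravity(
            HotspotSet("nTMS", np.arange(len(coords)), coords + np.asarray(shift))
        ).coords
        assert np.allclose(shifted, cog + np.asarray(shift), atol=1e-9)
        perm = np.random.default_rng(0).permutation(len(coords))
        permuted = center_of_gravity(HotspotSet("nTMS", np.arange(len(coords)), coords[perm]))
        assert np.allclose(permuted.coords, cog, atol=1e-9)

    def test_magnitude_weighted_cog_equals_brute_force_sum(self):
        rng = np.random.default_rng(42)
        n = 200
        centers = rng.uniform(-30, 30, (n, 3))
        inner = rng.integers(0, 4, (n, 3))
        patch = SurfacePatch(4, centers, np.full(n, 4.0), inner, np.zeros((n, 3)))
        field = np.zeros((4, 4, 4, 3))
        field[..., 0] = rng.uniform(0.1, 5.0, (4, 4, 4))
        sol = FieldSolution(field, np.eye(4), "nTMS", 0.0)
        cog = center_of_gravity(sol, weighting="magnitude", patch=patch).coords
        w = np.linalg.norm(field[inner[:, 0], inner[:, 1], inner[:, 2]], axis=1)
        expected = (w[:, None] * centers).sum(0) / w.sum()
        assert np.allclose(cog, expected)


class TestCogDistance:
    def test_three_four_five(self):
        a = CoGPoint([0, 0, 0], "nTMS")
        b = CoGPoint([3, 4, 0], "DES")
        assert cog_distance(a, b) == pytest.approx(5.0)

    def test_identical_points(self):
        p = CoGPoint([1.5, -2, 9], "nTMS")
        assert cog_distance(p, CoGPoint([1.5, -2, 9], "DES")) == 0.0

    def test_frame_mismatch_rejected(self):
        a = CoGPoint([0, 0, 0], "nTMS", frame="subject-1")
        b = CoGPoint([1, 0, 0], "DES", frame="subject-2")
        with pytest.raises(FrameMismatchError):
            cog_distance(a, b)

    @given(st.lists(st.tuples(*[st.floats(-100, 100) for _ in range(3)]), min_size=3, max_size=3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_metric_properties(self, pts):
        a, b, c = (CoGPoint(p, "nTMS") for p in pts)
        assert cog_distance(a, b) == pytest.approx(cog_distance(b, a))
        assert cog_distance(a, b) <= cog_distance(a, c) + cog_distance(c, b) + 1e-9


def flat_patch_fields(vn, vd, area=1.0):
    """A 1-D strip of faces with prescribed |E| values for both modalities."""
    n = len(vn)
    centers = np.stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)], axis=1)
    inner = np.stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)], axis=1)
    patch = SurfacePatch(4, centers, np.full(n, area), inner, np.zeros((n, 3)))
    def sol(vals, modality):
        field = np.zeros((n, 1, 1, 3))
        field[:, 0, 0, 0] = vals
        return FieldSolution(field, np.eye(4), modality, 0.0)
    return sol(np.asarray(vn, float), "nTMS"), sol(np.asarray(vd, float), "DES"), patch


class TestFieldOverlap:
    def test_identical_fields_give_full_overlap(self):
        vals = np.linspace(1, 10, 20)
        en, ed, patch = flat_patch_fields(vals, vals)
        rule = OverlapRule(des_mode="fraction", roi_radius=100.0)
        assert field_overlap(en, ed, patch, roi_center=[0, 0, 0], rule=rule).percent == 100.0

    def test_disjoint_areas_give_zero(self):
        vn = np.r_[np.full(10, 10.0), np.full(10, 0.1)]
        vd = np.r_[np.full(10, 0.1), np.full(10, 10.0)]
        en, ed, patch = flat_patch_fields(vn, vd)
        rule = OverlapRule(des_mode="fraction", roi_radius=100.0)
        assert field_overlap(en, ed, patch, roi_center=[0, 0, 0], rule=rule).percent == 0.0

    def test_invariant_under_common_rescaling(self):
        rng = np.random.default_rng(1)
        vn, vd = rng.uniform(0, 5, 30), rng.uniform(0, 5, 30)
        en, ed, patch = flat_patch_fields(vn, vd)
        en2, ed2, _ = flat_patch_fields(17.3 * vn, 0.02 * vd)
        rule = OverlapRule(des_mode="fraction", roi_radius=100.0)
        r1 = field_overlap(en, ed, patch, roi_center=[0, 0, 0], rule=rule)
        r2 = field_overlap(en2, ed2, patch, roi_center=[0, 0, 0], rule=rule)
        assert r1.percent == pytest.approx(r2.percent)
        assert 0.0 <= r1.percent <= 100.0

    def test_undefined_when_no_supra_threshold_ntms_area(self):
        en, ed, patch = flat_patch_fields(np.ones(10), np.ones(10))
        rule = OverlapRule(ntms_absolute=99.0, des_mode="fraction", roi_radius=100.0)
        with pytest.raises(UndefinedOverlapError):
            field_overlap(en, ed, patch, roi_center=[0, 0, 0], rule=rule)

    def test_roi_rule_measures_coverage_of_the_ntms_area(self):
        # nTMS half-max spot spans faces 0..9; ROI of radius 5.5 captures 6 of 10
        vn = np.r_[np.full(10, 10.0), np.full(10, 1.0)]
        vd = np.ones(20)
        en, ed, patch = flat_patch_fields(vn, vd)
        res = field_overlap(en, ed, patch, roi_center=[0, 0, 0], rule=OverlapRule(roi_radius=5.5))
        assert res.percent == pytest.approx(60.0)
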