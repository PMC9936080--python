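"""FA computation and deterministic streamline tracking on constructed bundles."""

import numpy as np
import pytest

from stimmap.synthetic import BundleSpec, gen_tensor_bundle
from stimmap.tracking import (
    TensorVolume,
    TrackingParams,
    compute_fa,
    fa_from_eigenvalues,
    streamline_length,
    track_streamlines,
    tract_stats,
)
from tests.oracles import fa_closed_form


@pytest.fixture(scope="module")
def straight60():
    vol, centerline = gen_tensor_bundle(BundleSpec(kind="straight", length=60.0))
    return vol, centerline


@pytest.fixture(scope="module")
def arc40():
    vol, centerline = gen_tensor_bundle(BundleSpec(kind="arc", arc_radius=40.0))
    return vol, centerline


class TestFractionalAnisotropy:
    @pytest.mark.parametrize(
        "evals, expected",
        [((1.0, 1.0, 1.0), 0.0), ((1.0, 0.0, 0.0), 1.0), ((0.0, 0.0, 0.0), 0.0)],
    )
    def test_limit_cases(self, evals, expected):
        assert compute_fa(np.diag(evals)) == pytest.approx(expected)

    def test_matches_closed_form_on_stated_triple(self):
        evals = (1.7e-3, 0.3e-3, 0.2e-3)
        expected = fa_closed_form(*evals)
        assert expected == pytest.approx(0.836, abs=5e-4)
        assert compute_fa(np.diag(evals)) == pytest.approx(expected, rel=1e-12)

    def test_rotation_and_scale_invariance(self):
        rng = np.random.default_rng(5)
        d = np.diag([1.7e-3, 0.3e-3, 0.2e-3])
        base = compute_fa(d)
        for _ in range(5):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            t = q @ d @ q.T
            assert compute_fa(t) == pytest.approx(base, rel=1e-9)
            assert compute_fa(42.0 * t) == pytest.approx(base, rel=1e-9)

    def test_negative_eigenvalues_clamped(self):
        assert 0.0 <= float(fa_from_eigenvalues([1.0, -0.1, 0.05])) <= 1.0


class TestStraightBundle:
    def test_length_recovered_within_one_step(self, straight60):
        vol, centerline = straight60
        mid = centerline[len(centerline) // 2]
        lines = track_streamlines(vol, mid, TrackingParams())
        st = tract_stats(lines, vol)
        assert st.count > 0
        assert abs(st.mean_length - 60.0) <= 1.0

    def test_short_bundle_removed_by_min_length_filter(self):
        vol, _ = gen_tensor_bundle(BundleSpec(kind="straight", length=15.0))
        lines = track_streamlines(vol, [7.5, 0.0, 0.0], TrackingParams())
        assert lines == []

    def test_low_fa_background_confines_tracking(self, straight60):
        # background FA 0.05 < 0.1 stop: no streamline point leaves the corridor
        vol, _ = straight60
        lines = track_streamlines(vol, [30.0, 0.0, 0.0], TrackingParams())
        pts = np.vstack(lines)
        assert np.all(pts[:, 0] >= -2.0) and np.all(pts[:, 0] <= 62.0)
        assert np.abs(pts[:, 1:]).max() <= BundleSpec().corridor_radius + 2.0

    def test_tracking_is_deterministic(self, straight60):
        vol, centerline = straight60
        mid = centerline[len(centerline) // 2]
        a = track_streamlines(vol, mid, TrackingParams())
        b = track_streamlines(vol, mid, TrackingParams())
        assert len(a) == len(b)
        for la, lb in zip(a, b):
            assert np.array_equal(la, lb)

    def test_all_streamlines_satisfy_min_length(self, straight60):
        vol, centerline = straight60
        params = TrackingParams(min_length=30.0)
        lines = track_streamlines(vol, centerline[len(centerline) // 2], params)
        assert all(streamline_length(l) >= 30.0 for l in lines)

    def test_empty_seed_region_yields_no_streamlines(self, straight60):
        vol, _ = straight60
        # seed far in the isotropic background
        lines = track_streamlines(vol, [-8.0, 10.0, 10.0], TrackingParams(seed_radius=2.0))
        assert lines == []


class TestArcBundle:
    def test_arc_length_recovered_within_five_percent(self, arc40):
        vol, centerline = arc40
        mid = centerline[len(centerline) // 2]
        st = tract_stats(track_streamlines(vol, mid, TrackingParams()), vol)
        assert st.mean_length == pytest.approx(np.pi * 40.0 / 2, rel=0.05)

    def test_off_center_seed_changes_length_below_ten_percent(self, arc40):
        vol, centerline = arc40
        mid = centerline[len(centerline) // 2]
        st0 = tract_stats(track_streamlines(vol, mid, TrackingParams()), vol)
        off = mid + np.array([1.4, 1.4, 0.0])
        st1 = tract_stats(track_streamlines(vol, off, TrackingParams()), vol)
        assert abs(st1.mean_length - st0.mean_length) / st0.mean_length < 0.10


class TestTractStats:
    def test_two_point_line_in_uniform_fa_field(self):
        iso = 0.7e-3
        lam_ax, lam_rad = 1.4e-3, 0.466e-3  # FA 0.5 cigar along x
        from stimmap.synthetic import eigenvalues_for_fa

        lam_ax, lam_rad = eigenvalues_for_fa(0.5, iso)
        data = np.zeros((25, 5, 5, 6))
        data[..., 0] = lam_ax
        data[..., 3] = lam_rad
        data[..., 5] = lam_rad
        vol = TensorVolume(data, np.diag([2.0, 2.0, 2.0, 1.0]))
        line = np.array([[2.0, 4.0, 4.0], [42.0, 4.0, 4.0]])
        st = tract_stats([line], vol)
        assert st.count == 1
        assert st.mean_length == pytest.approx(40.0)
        assert st.mean_fa == pytest.approx(0.5, abs=1e-6)

    def test_duplication_leaves_means_unchanged(self, straight60):
        vol, centerline = straight60
        lines = track_streamlines(vol, centerline[len(centerline) // 2], TrackingParams())
        st = tract_stats(lines, vol)
        st2 = tract_stats(lines + lines, vol)
        assert st2.count == 2 * st.count
        assert st2.mean_length == pytest.approx(st.mean_length)
        assert st2.mean_fa == pytest.approx(st.mean_fa)

    def test_empty_set_flagged(self, straight60):
        vol, _ = straight60
        st = tract_stats([], vol)
        assert st.count == 0 and not st.defined


class TestParams:
    @pytest.mark.parametrize(
        "kw", [{"fa_stop": 0.0}, {"fa_stop": 1.0}, {"min_length": 0}, {"step": 0}, {"max_angle": 95}]
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            TrackingParams(**kw)
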