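"""Marker layout, trajectory I/O, gap repair and layout validation."""

import numpy as np
import pytest

import chestwall as cw
from chestwall.marker_model import PAIR_ROLES


def small_traj(n_frames=5, fs=60.0, n_markers=None, layout=None, seed=0):
    layout = layout or cw.default_layout()
    ids = layout.marker_ids if n_markers is None else layout.marker_ids[:n_markers]
    rng = np.random.default_rng(seed)
    pos = rng.normal(size=(n_frames, len(ids), 3))
    return cw.TrajectorySet(pos, fs, ids)


class TestLayout:
    def test_default_layout_is_valid_36_marker_grid(self, layout):
        assert layout.n_markers == 36
        assert layout.n_rows == 6 and layout.n_cols == 6
        rows = [layout.row_index(r) for r in
                ("clavicular_row", "xiphisternal_row", "lower_costal_row", "pubic_row")]
        assert rows == sorted(rows)

    def test_duplicate_grid_cell_rejected(self, layout):
        grid = dict(layout.grid)
        grid["r0c1"] = grid["r0c0"]
        with pytest.raises(ValueError, match="unique"):
            cw.MarkerLayout(layout.marker_ids, grid, layout.landmarks)

    def test_missing_role_rejected(self, layout):
        lm = {k: v for k, v in layout.landmarks.items() if k != "costal10_left"}
        with pytest.raises(ValueError, match="costal10_left"):
            cw.MarkerLayout(layout.marker_ids, layout.grid, lm)

    def test_identical_left_right_pair_rejected(self, layout):
        lm = dict(layout.landmarks)
        lm["axillary_sternal_left"] = lm["axillary_sternal_right"]
        with pytest.raises(ValueError, match="distinct"):
            cw.MarkerLayout(layout.marker_ids, layout.grid, lm)

    def test_yaml_round_trip(self, layout, tmp_path):
        path = tmp_path / "layout.yaml"
        cw.layout_to_yaml(layout, path)
        back = cw.layout_from_yaml(path)
        assert back.marker_ids == layout.marker_ids
        assert dict(back.grid) == dict(layout.grid)
        assert dict(back.landmarks) == dict(layout.landmarks)


class TestAxisConvention:
    def test_default_is_right_handed_identity(self):
        ax = cw.AxisConvention()
        assert ax.right_handed
        np.testing.assert_allclose(ax.matrix(), np.eye(3))

    def test_non_orthogonal_axes_rejected(self):
        with pytest.raises(ValueError):
            cw.AxisConvention(lateral=(1.0, 0.1, 0.0))


class TestIO:
    def test_round_trip_preserves_positions_and_rate(self, tmp_path, layout):
        t = small_traj(n_frames=2)
        path = tmp_path / "t.csv"
        cw.save_trajectories(t, path)
        back = cw.load_trajectories(path, layout=layout)
        assert back.sample_rate == 60.0
        assert back.n_frames == 2
        np.testing.assert_allclose(back.positions, t.positions, atol=1e-6)
        # second round trip is idempotent
        path2 = tmp_path / "t2.csv"
        cw.save_trajectories(back, path2)
        again = cw.load_trajectories(path2)
        np.testing.assert_array_equal(again.positions, back.positions)

    def test_round_trip_preserves_gaps(self, tmp_path):
        t = small_traj(n_frames=4)
        t.positions[2, 5] = np.nan
        t = cw.TrajectorySet(t.positions, t.sample_rate, t.marker_ids)
        path = tmp_path / "g.csv"
        cw.save_trajectories(t, path)
        back = cw.load_trajectories(path)
        assert not back.gap_mask[2, 5]
        assert back.gap_mask.sum() == t.gap_mask.sum()

    def test_missing_marker_raises_layout_mismatch(self, tmp_path, layout):
        t = small_traj(n_markers=35)
        path = tmp_path / "m.csv"
        cw.save_trajectories(t, path)
        with pytest.raises(cw.LayoutMismatchError, match="r5c5"):
            cw.load_trajectories(path, layout=layout)

    def test_c3d_not_supported(self, tmp_path):
        with pytest.raises(cw.UnsupportedFormatError):
            cw.load_trajectories(tmp_path / "x.c3d", format="c3d")

    def test_unreadable_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("not,a,header\n1,2\n")
        with pytest.raises(cw.FormatError):
            cw.load_trajectories(bad)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(cw.FormatError):
            cw.load_trajectories(tmp_path / "absent.csv")


class TestFillGaps:
    def test_single_frame_gap_filled_with_linear_midpoint(self):
        t = small_traj(n_frames=5)
        ramp = np.linspace(0.0, 1.0, 5)
        t.positions[:, 0, :] = ramp[:, None]
        t.positions[2, 0] = np.nan
        t = cw.TrajectorySet(t.positions, 60.0, t.marker_ids)
        out = cw.fill_gaps(t, max_gap_s=0.1)
        np.testing.assert_allclose(out.positions[2, 0], 0.5)
        assert out.gap_mask[2, 0]

    def test_long_gap_stays_flagged(self):
        t = small_traj(n_frames=20)
        t.positions[5:15, 0] = np.nan
        t = cw.TrajectorySet(t.positions, 60.0, t.marker_ids)
        out = cw.fill_gaps(t, max_gap_s=0.05)  # 3 frames max
        assert not out.gap_mask[5:15, 0].any()

    def test_edge_gaps_stay_flagged(self):
        t = small_traj(n_frames=10)
        t.positions[0, 0] = np.nan
        t.positions[-1, 1] = np.nan
        t = cw.TrajectorySet(t.positions, 60.0, t.marker_ids)
        out = cw.fill_gaps(t, max_gap_s=1.0)
        assert not out.gap_mask[0, 0] and not out.gap_mask[-1, 1]

    def test_no_gaps_identity_and_valid_samples_untouched(self):
        t = small_traj(n_frames=30, seed=3)
        t.positions[10:12, 4] = np.nan
        t = cw.TrajectorySet(t.positions, 60.0, t.marker_ids)
        out = cw.fill_gaps(t, max_gap_s=1.0)
        np.testing.assert_array_equal(
            out.positions[t.gap_mask], t.positions[t.gap_mask]
        )
        clean = small_traj(n_frames=30, seed=4)
        out2 = cw.fill_gaps(clean, max_gap_s=1.0)
        np.testing.assert_array_equal(out2.positions, clean.positions)
        np.testing.assert_array_equal(out2.gap_mask, clean.gap_mask)


class TestValidateLayout:
    def test_synthetic_subject_has_no_issues(self, quiet_subject, layout):
        traj, _ = quiet_subject
        assert cw.validate_layout(traj, layout).ok

    def test_swapped_axillary_pair_detected(self, quiet_subject, layout):
        traj, _ = quiet_subject
        lm = dict(layout.landmarks)
        lm["axillary_sternal_left"], lm["axillary_sternal_right"] = (
            lm["axillary_sternal_right"],
            lm["axillary_sternal_left"],
        )
        swapped = cw.MarkerLayout(layout.marker_ids, layout.grid, lm)
        report = cw.validate_layout(traj, swapped)
        assert any("swap" in issue for issue in report.issues)

    def test_missing_marker_reported(self, layout):
        t = small_traj(n_markers=35)
        report = cw.validate_layout(t, layout)
        assert any("missing" in issue for issue in report.issues)
        assert not report.ok

    @pytest.mark.parametrize("role", PAIR_ROLES)
    def test_every_pair_role_checked(self, layout, role):
        assert isinstance(layout.landmarks[role], str)
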