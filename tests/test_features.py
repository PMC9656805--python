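import warnings

import numpy as np
import pytest

from graspadl.features import (
    ADJACENT_PAIRS,
    FeatureBlock,
    FeatureError,
    HandLengthM,
    afa,
    assemble,
    atd,
    build_feature_matrix,
    dft_features,
    dpuv,
    fha,
    fte,
    geometric_features,
    hand_length,
    ja,
    nptd,
    standardize,
    windowed_td_features,
)
from graspadl.hand_model import FINGERS, identity_basis_row, structure_frame
from graspadl.trial import TrialRecording, CoordinateFrame
from conftest import make_hcs_trial, random_frame_row, random_trial, scale_positions

M1 = HandLengthM(M=1.0)


def _set_joint(row, finger_joint, xyz):
    from graspadl.hand_model import _SLOTS

    s = _SLOTS[finger_joint]
    row[s : s + 3] = xyz


def _random_frame(rng):
    return structure_frame(random_frame_row(rng))


# ---------------------------------------------------------------------------
# hand length


class TestHandLength:
    def _chain_trial(self, n_frames=30):
        row = identity_basis_row()
        _set_joint(row, "middle.mcp", (1, 0, 0))
        _set_joint(row, "middle.pip", (2, 0, 0))
        _set_joint(row, "middle.dip", (3, 0, 0))
        _set_joint(row, "middle.tip", (4, 0, 0))
        frames = np.tile(row, (n_frames, 1))
        return TrialRecording(frames=frames, task_label="cup", subject_id="S0",
                              coordinate_frame=CoordinateFrame.HCS)

    def test_unit_segments_sum_to_four(self):
        M = hand_length(self._chain_trial())
        assert M.M == pytest.approx(4.0, abs=1e-12)
        assert M.n_frames_averaged == 30

    def test_homogeneity_under_scaling(self):
        t = self._chain_trial()
        M1_ = hand_length(t)
        M3 = hand_length(scale_positions(t, 3.0))
        assert M3.M == pytest.approx(3.0 * M1_.M, rel=1e-12)

    def test_against_loop_oracle(self, rng):
        t = random_trial(rng, n_frames=35)
        M = hand_length(t, n_frames=30)
        totals = []
        for i in range(30):
            fr = structure_frame(t.frames[i])
            mcp, pip_, dip, tip = fr.role_joints("middle")
            d = (
                np.linalg.norm(mcp - fr.palm_center)
                + np.linalg.norm(pip_ - mcp)
                + np.linalg.norm(dip - pip_)
                + np.linalg.norm(tip - dip)
            )
            totals.append(d)
        assert M.M == pytest.approx(np.mean(totals), rel=1e-12)

    def test_too_few_frames_names_shortfall(self, rng):
        with pytest.raises(ValueError, match="need at least 30"):
            hand_length(random_trial(rng, n_frames=10))

    def test_nonpositive_M_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            HandLengthM(M=0.0)


# ---------------------------------------------------------------------------
# per-frame geometric features


class TestAfa:
    def test_orthogonal_adjacent_tips(self):
        row = identity_basis_row()
        _set_joint(row, "thumb.tip", (1, 0, 0))
        _set_joint(row, "index.tip", (0, 0, 1))
        _set_joint(row, "middle.tip", (1, 0, 0))
        _set_joint(row, "ring.tip", (0, 0, 1))
        _set_joint(row, "pinky.tip", (0, 0, -1))
        vals = afa(structure_frame(row))
        assert vals[0] == pytest.approx(0.5)  # thumb-index orthogonal
        assert vals[1] == pytest.approx(0.5)
        assert vals[3] == pytest.approx(1.0)  # ring vs pinky antiparallel

    def test_parallel_tips_zero(self):
        row = identity_basis_row()
        for f in FINGERS:
            _set_joint(row, f + ".tip", (2, 0, 0))
        assert np.allclose(afa(structure_frame(row)), 0.0)

    def test_against_arccos_oracle(self, rng):
        for _ in range(30):
            fr = _random_frame(rng)
            vals = afa(fr)
            for k, (fa, fb) in enumerate(ADJACENT_PAIRS):
                u = fr.fingertip(fa) - fr.palm_center
                v = fr.fingertip(fb) - fr.palm_center
                c = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                assert vals[k] == pytest.approx(np.arccos(np.clip(c, -1, 1)) / np.pi, abs=1e-12)

    def test_zero_length_tip_vector_names_finger(self):
        row = identity_basis_row()  # all tips at palm center
        with pytest.raises(FeatureError, match="thumb"):
            afa(structure_frame(row))


class TestAtd:
    def test_coincident_tips_zero(self):
        row = identity_basis_row()
        for f in FINGERS:
            _set_joint(row, f + ".tip", (3, 1, 2))
        assert np.allclose(atd(structure_frame(row), M1), 0.0)

    def test_ten_mm_apart_with_m_twenty(self):
        row = identity_basis_row()
        _set_joint(row, "thumb.tip", (0, 0, 0))
        _set_joint(row, "index.tip", (10, 0, 0))
        vals = atd(structure_frame(row), HandLengthM(M=20.0))
        assert vals[0] == pytest.approx(0.5)

    def test_against_distance_oracle(self, rng):
        fr = _random_frame(rng)
        M = HandLengthM(M=7.5)
        vals = atd(fr, M)
        for k, (fa, fb) in enumerate(ADJACENT_PAIRS):
            assert vals[k] == pytest.approx(
                np.linalg.norm(fr.fingertip(fa) - fr.fingertip(fb)) / 7.5, abs=1e-12
            )


class TestDpuv:
    def test_unit_z(self):
        row = identity_basis_row()
        for f in FINGERS:  # keep every finger non-degenerate
            _set_joint(row, f + ".tip", (1, 1, 1))
        _set_joint(row, "thumb.dip", (0, 0, 0))
        _set_joint(row, "thumb.tip", (0, 0, 2))
        vals = dpuv(structure_frame(row))
        assert np.allclose(vals[:3], (0, 0, 1))

    def test_per_finger_norm_one(self, rng):
        for _ in range(20):
            vals = dpuv(_random_frame(rng))
            norms = np.linalg.norm(vals.reshape(5, 3), axis=1)
            assert np.allclose(norms, 1.0, atol=1e-12)

    def test_against_vector_oracle(self, rng):
        fr = _random_frame(rng)
        vals = dpuv(fr).reshape(5, 3)
        for k, f in enumerate(FINGERS):
            _, _, dip, tip = fr.role_joints(f)
            v = tip - dip
            assert np.allclose(vals[k], v / np.linalg.norm(v), atol=1e-12)

    def test_coincident_tip_dip_rejected(self):
        row = identity_basis_row()
        with pytest.raises(FeatureError, match="coincides"):
            dpuv(structure_frame(row))


class TestNptd:
    def test_tip_at_palm_center_zero(self):
        row = identity_basis_row()
        vals = nptd(structure_frame(row), M1)
        assert np.allclose(vals, 0.0)

    def test_tip_at_distance_m_gives_one(self):
        row = identity_basis_row()
        _set_joint(row, "index.tip", (0, 5, 0))
        vals = nptd(structure_frame(row), HandLengthM(M=5.0))
        assert vals[1] == pytest.approx(1.0)

    def test_against_distance_oracle(self, rng):
        fr = _random_frame(rng)
        M = HandLengthM(M=3.25)
        vals = nptd(fr, M)
        for k, f in enumerate(FINGERS):
            assert vals[k] == pytest.approx(
                np.linalg.norm(fr.fingertip(f) - fr.palm_center) / 3.25, abs=1e-12
            )


class TestJa:
    def _straight_finger_row(self):
        row = identity_basis_row()
        for f in FINGERS:
            joints = ("cmc", "mcp", "dip", "tip") if f == "thumb" else ("cmc", "mcp", "pip", "dip", "tip")
            for i, j in enumerate(joints, start=1):
                _set_joint(row, f"{f}.{j}", (i, 0, 0))
        return row

    def test_collinear_bones_all_zero(self):
        vals = ja(structure_frame(self._straight_finger_row()))
        assert np.allclose(vals, 0.0, atol=1e-9)

    def test_right_angle_at_dip(self):
        row = self._straight_finger_row()
        _set_joint(row, "index.tip", (4, 0, 1))  # bend 90 deg after DIP at (4,0,0)
        vals = ja(structure_frame(row))
        assert vals[3 * 1 + 2] == pytest.approx(0.5)  # index DIP angle

    def test_against_arccos_oracle(self, rng):
        for _ in range(20):
            fr = _random_frame(rng)
            vals = ja(fr).reshape(5, 3)
            for k, f in enumerate(FINGERS):
                mcp, pip_, dip, tip = fr.role_joints(f)
                bones = (mcp - fr.palm_center, pip_ - mcp, dip - pip_, tip - dip)
                for j in range(3):
                    u, v = bones[j], bones[j + 1]
                    c = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                    assert vals[k, j] == pytest.approx(
                        np.arccos(np.clip(c, -1, 1)) / np.pi, abs=1e-12
                    )

    def test_zero_length_bone_names_joint(self):
        row = self._straight_finger_row()
        _set_joint(row, "ring.dip", (3, 0, 0))
        _set_joint(row, "ring.tip", (3, 0, 0))  # tip == dip
        with pytest.raises(FeatureError, match="ring"):
            ja(structure_frame(row))


class TestFha:
    def test_projection_along_plus_h_zero(self):
        row = identity_basis_row()
        for f in FINGERS:
            _set_joint(row, f + ".tip", (2, 1, 0))  # projection (2,0,0) ~ +h
        vals = fha(structure_frame(row))
        assert np.allclose(vals, 0.0, atol=1e-12)

    def test_projection_along_minus_h_one(self):
        row = identity_basis_row()
        for f in FINGERS:
            _set_joint(row, f + ".tip", (-3, 0.5, 0))
        vals = fha(structure_frame(row))
        assert np.allclose(vals, 1.0, atol=1e-12)

    def test_against_projection_oracle(self, rng):
        fr = _random_frame(rng)
        vals = fha(fr)
        for k, f in enumerate(FINGERS):
            p = fr.fingertip(f)
            proj = p - ((p - fr.palm_center) @ fr.n_vec) * fr.n_vec
            u = proj - fr.palm_center
            c = u @ fr.h / np.linalg.norm(u)
            assert vals[k] == pytest.approx(np.arccos(np.clip(c, -1, 1)) / np.pi, abs=1e-12)


class TestFte:
    def test_tip_on_palm_plane_zero(self):
        row = identity_basis_row()
        for f in FINGERS:
            _set_joint(row, f + ".tip", (4, 0, 2))  # n_vec is e2; y=0 -> on plane
        vals = fte(structure_frame(row), M1)
        assert np.allclose(vals, 0.0)

    def test_sign_convention_at_distance_m(self):
        row = identity_basis_row()
        _set_joint(row, "index.tip", (0, 5, 0))  # C + M*n
        _set_joint(row, "middle.tip", (0, -5, 0))  # C - M*n
        vals = fte(structure_frame(row), HandLengthM(M=5.0))
        assert vals[1] == pytest.approx(1.0)
        assert vals[2] == pytest.approx(-1.0)

    def test_against_signed_distance_oracle(self, rng):
        fr = _random_frame(rng)
        M = HandLengthM(M=11.0)
        vals = fte(fr, M)
        for k, f in enumerate(FINGERS):
            d = (fr.fingertip(f) - fr.palm_center) @ fr.n_vec
            assert vals[k] == pytest.approx(d / 11.0, abs=1e-12)

    def test_sign_flips_with_negated_normal(self, rng):
        fr = _random_frame(rng)
        vals = fte(fr, M1)
        fr.n_vec = -fr.n_vec
        fr.b = -fr.b  # keep right-handedness irrelevant for this feature
        assert np.allclose(fte(fr, M1), -vals, atol=1e-12)


# ---------------------------------------------------------------------------
# windowed features


class TestWindowedTimeDomain:
    def test_constant_channel_closed_forms(self):
        t = make_hcs_trial(np.full((15, 72), 3.0))
        out = windowed_td_features(t, M1, window=15)
        assert np.allclose(out["MAV"].values, 3.0)
        assert np.allclose(out["RMS"].values, 3.0)
        assert np.allclose(out["VAR"].values, 0.0)
        assert np.allclose(out["WL"].values, 0.0)

    def test_alternating_signs(self):
        x = np.tile(np.array([1.0 if i % 2 == 0 else -1.0 for i in range(15)]), (72, 1)).T
        out = windowed_td_features(make_hcs_trial(x), M1, window=15)
        assert np.allclose(out["MAV"].values, 1.0)
        assert np.allclose(out["RMS"].values, 1.0)
        assert np.allclose(out["WL"].values, 28.0)  # 14 steps of size 2
        assert np.allclose(out["VAR"].values, 16.0 / 15.0)  # frozen from ddof-1 formula

    def test_against_loop_oracles(self, rng):
        channels = rng.standard_normal((45, 72)) * 5
        t = make_hcs_trial(channels)
        M = HandLengthM(M=2.0)
        out = windowed_td_features(t, M, window=15)
        x = channels / 2.0
        for w in range(3):
            seg = x[15 * w : 15 * (w + 1)]
            for c in (0, 40, 71):
                s = seg[:, c]
                assert out["MAV"].values[w, c] == pytest.approx(np.mean(np.abs(s)), rel=1e-12)
                assert out["RMS"].values[w, c] == pytest.approx(np.sqrt(np.mean(s**2)), rel=1e-12)
                assert out["VAR"].values[w, c] == pytest.approx(
                    np.sum((s - s.mean()) ** 2) / 14, rel=1e-9
                )
                assert out["WL"].values[w, c] == pytest.approx(
                    sum(abs(s[i + 1] - s[i]) for i in range(14)), rel=1e-12
                )

    def test_row_count_and_partial_window_dropped(self, rng):
        t = make_hcs_trial(rng.standard_normal((47, 72)))
        out = windowed_td_features(t, M1, window=15)
        assert all(b.values.shape[0] == 3 for b in out.values())

    def test_requires_full_window(self, rng):
        t = make_hcs_trial(rng.standard_normal((10, 72)))
        with pytest.raises(ValueError, match="at least 15"):
            windowed_td_features(t, M1, window=15)

    def test_gcs_trial_rejected(self, rng):
        with pytest.raises(ValueError, match="HCS"):
            windowed_td_features(random_trial(rng, 20), M1)


def _naive_dft(x):
    N = len(x)
    out = np.empty(N, dtype=complex)
    for k in range(N):
        out[k] = sum(x[n] * np.exp(-2j * np.pi * n * k / N) for n in range(N))
    return out


class TestDft:
    def test_constant_channel_dc_only(self):
        t = make_hcs_trial(np.full((15, 72), 2.5))
        block = dft_features(t, window=15, kept_bins=8)
        vals = block.values.reshape(1, 72, 8)
        assert np.allclose(vals[0, :, 0], 15 * 2.5)
        assert np.allclose(vals[0, :, 1:], 0.0, atol=1e-9)

    def test_pure_tone_concentrates_in_bin_three(self):
        n = np.arange(15)
        channels = np.tile(np.cos(2 * np.pi * 3 * n / 15), (72, 1)).T
        block = dft_features(make_hcs_trial(channels), window=15, kept_bins=8)
        vals = block.values.reshape(1, 72, 8)
        assert np.allclose(vals[0, :, 3], 7.5, atol=1e-9)
        others = np.delete(vals[0, 0], 3)
        assert np.all(np.abs(others) < 1e-9)

    def test_against_naive_double_sum(self, rng):
        channels = rng.standard_normal((15, 72))
        block = dft_features(make_hcs_trial(channels), window=15, kept_bins=8)
        vals = block.values.reshape(1, 72, 8)
        for c in (0, 17, 71):
            expected = np.abs(_naive_dft(channels[:, c]))[:8]
            assert np.allclose(vals[0, c], expected, atol=1e-9)

    def test_kept_bins_bounds(self, rng):
        t = make_hcs_trial(rng.standard_normal((15, 72)))
        with pytest.raises(ValueError, match="kept_bins"):
            dft_features(t, window=15, kept_bins=16)


# ---------------------------------------------------------------------------
# assembly / standardization


class TestAssemble:
    def test_single_block_identity(self, rng):
        vals = rng.standard_normal((6, 4))
        b = FeatureBlock("AFA", vals, ("a", "b", "c", "d"), "per_frame", trial_id="t0")
        fm = assemble([b], labels=2, groups="t0")
        assert np.array_equal(fm.values, vals)
        assert np.all(fm.labels == 2)
        assert np.all(fm.groups == "t0")

    def test_mixed_rates_window_averaged(self, rng):
        per_frame = rng.standard_normal((30, 3))
        per_window = rng.standard_normal((2, 5))
        bf = FeatureBlock("JA", per_frame, ("a", "b", "c"), "per_frame", trial_id="t0")
        bw = FeatureBlock("MAV", per_window, tuple("vwxyz"), "per_window", trial_id="t0")
        fm = assemble([bf, bw], labels=0, groups="t0", window=15)
        assert fm.values.shape == (2, 8)
        expected0 = per_frame[:15].mean(axis=0)  # window-mean oracle
        expected1 = per_frame[15:30].mean(axis=0)
        assert np.allclose(fm.values[0, :3], expected0)
        assert np.allclose(fm.values[1, :3], expected1)
        assert np.array_equal(fm.values[:, 3:], per_window)

    def test_blocks_from_different_trials_rejected(self, rng):
        b1 = FeatureBlock("AFA", rng.standard_normal((3, 1)), ("a",), "per_frame", "t0")
        b2 = FeatureBlock("ATD", rng.standard_normal((3, 1)), ("b",), "per_frame", "t1")
        with pytest.raises(ValueError, match="different trials"):
            assemble([b1, b2], labels=0, groups="t0")

    def test_irreconcilable_rows_named(self, rng):
        b1 = FeatureBlock("MAV", rng.standard_normal((2, 1)), ("a",), "per_window", "t0")
        b2 = FeatureBlock("RMS", rng.standard_normal((3, 1)), ("b",), "per_window", "t0")
        with pytest.raises(ValueError, match="MAV.*RMS|irreconcilable"):
            assemble([b1, b2], labels=0, groups="t0")


class TestStandardize:
    def _fm(self, values):
        values = np.asarray(values, dtype=float)
        n = values.shape[0]
        from graspadl.features import FeatureMatrix

        return FeatureMatrix(
            values=values,
            labels=np.zeros(n, dtype=int),
            groups=np.array(["t"] * n),
            column_names=tuple(f"c{i}" for i in range(values.shape[1])),
        )

    def test_two_point_column(self):
        out = standardize(self._fm([[1.0], [3.0]]))
        expected = 1.0 / np.sqrt(2.0)  # sample sd of [1,3] is sqrt(2)
        assert np.allclose(out.values[:, 0], [-expected, expected])

    def test_already_standardized_unchanged(self, rng):
        x = rng.standard_normal((50, 3))
        x = (x - x.mean(0)) / x.std(0, ddof=1)
        out = standardize(self._fm(x))
        assert np.allclose(out.values, x, atol=1e-9)

    def test_fit_rows_applied_everywhere(self, rng):
        x = rng.standard_normal((10, 2))
        fit = np.arange(5)
        out = standardize(self._fm(x), fit_rows=fit)
        mean, sd = out.standardization
        assert np.allclose(mean, x[:5].mean(0))
        assert np.allclose(sd, x[:5].std(0, ddof=1))
        assert np.allclose(out.values, (x - mean) / sd)
        assert abs(out.values[fit].mean()) < 1e-8
        assert np.allclose(out.values[fit].std(0, ddof=1), 1.0, atol=1e-6)

    def test_constant_column_zeroed_with_warning(self, rng):
        x = rng.standard_normal((8, 2))
        x[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            out = standardize(self._fm(x))
        assert np.all(out.values[:, 1] == 0.0)


# ---------------------------------------------------------------------------
# cross-cutting invariants


class TestScaleInvariance:
    def test_scale_invariant_features(self, rng):
        trial = random_trial(rng, n_frames=30)
        from graspadl.preprocess import to_hcs

        base = to_hcs(trial)
        scaled = to_hcs(scale_positions(trial, 2.0))
        M_base = hand_length(base, 30)
        M_scaled = hand_length(scaled, 30)
        assert M_scaled.M == pytest.approx(2.0 * M_base.M, rel=1e-12)
        for name in ("AFA", "ATD", "DPUV", "NPTD", "JA", "FHA", "FTE"):
            a = geometric_features(base, M_base, (name,))[name].values
            b = geometric_features(scaled, M_scaled, (name,))[name].values
            assert np.allclose(a, b, rtol=1e-9, atol=1e-9), name
        for name in ("MAV", "RMS", "WL"):
            a = windowed_td_features(base, M_base)[name].values
            b = windowed_td_features(scaled, M_scaled)[name].values
            assert np.allclose(a, b, rtol=1e-9, atol=1e-9), name
        a = windowed_td_features(base, M_base)["VAR"].values
        b = windowed_td_features(scaled, M_scaled)["VAR"].values
        assert np.allclose(a, b, rtol=1e-9, atol=1e-12)

    def test_range_invariants(self, rng):
        trial = random_trial(rng, n_frames=5)
        from graspadl.preprocess import to_hcs

        hcs = to_hcs(trial)
        M = HandLengthM(M=50.0)
        g = geometric_features(hcs, M)
        for name in ("AFA", "JA", "FHA"):
            assert np.all(g[name].values >= 0) and np.all(g[name].values <= 1)
        assert np.all(g["ATD"].values >= 0)
        assert np.all(g["NPTD"].values >= 0)


class TestBuildFeatureMatrix:
    def test_stacks_trials_with_labels_and_groups(self, rng):
        trials = [
            random_trial(rng, 16, task_label="cup", subject_id="S0", trial_index=0),
            random_trial(rng, 16, task_label="pen", subject_id="S0", trial_index=0),
        ]
        from graspadl.preprocess import to_hcs

        pre = [to_hcs(t) for t in trials]
        hl = {"S0": HandLengthM(M=100.0)}
        fm = build_feature_matrix(pre, hl, ("JA", "NPTD"))
        assert fm.values.shape == (32, 20)
        assert set(fm.labels) == {0, 5}  # cup=0, pen=5
        assert set(fm.groups) == {pre[0].trial_id, pre[1].trial_id}

    def test_unknown_feature_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown"):
            build_feature_matrix([], {}, ("BOGUS",))
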