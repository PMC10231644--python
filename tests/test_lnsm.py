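import numpy as np
import pytest

from lsmpipe import lnsm
from lsmpipe.io_model import AnalysisConfig, LesionMask, StatMap
from lsmpipe.lnsm import (
    NormativeRun,
    framewise_displacement,
    lesion_network_map,
    lnsm_glm_inference,
    preprocess_run,
    roi_eigenvariate,
    seed_connectivity_map,
)

AFF2 = np.diag([2.0, 2.0, 2.0, 1.0])
SHAPE = (10, 10, 10)


def _tissue(value=1.0):
    return StatMap(np.full(SHAPE, value, dtype=np.float32), np.ones(SHAPE), "percent", AFF2)


def _run(data, motion=None, tr=0.72):
    t = data.shape[3]
    return NormativeRun(
        subject_id="con-001", run_id="RL", data=data, tr_s=tr,
        motion=motion if motion is not None else np.zeros((t, 6)),
        gm_prob=_tissue(1.0), wm_prob=_tissue(0.0), csf_prob=_tissue(0.0),
    )


class TestFramewiseDisplacement:
    def test_zero_motion(self):
        assert framewise_displacement(np.zeros((30, 6))).max() == 0.0

    def test_translation_step(self):
        motion = np.zeros((10, 6))
        motion[5:, 0] = 1.0
        fd = framewise_displacement(motion)
        assert fd[5] == 1.0
        assert (fd > 0).sum() == 1

    def test_rotation_scaled_by_50mm(self):
        motion = np.zeros((10, 6))
        motion[5:, 3] = 0.01  # radians
        fd = framewise_displacement(motion)
        assert fd[5] == pytest.approx(0.5)


class TestPreprocessRun:
    def test_inband_sinusoid_retained(self):
        rng = np.random.default_rng(0)
        t = 300
        tr = 0.72
        data = rng.normal(0, 0.3, size=SHAPE + (t,))
        freq = 0.04
        times = np.arange(t) * tr
        data[5, 5, 5] = np.sin(2 * np.pi * freq * times)
        run = _run(data, tr=tr)
        cfg = AnalysisConfig()
        out = preprocess_run(run, cfg, skip=("smooth",))
        k = int(round(freq * t * tr))
        amp_in = np.abs(np.fft.rfft(data[5, 5, 5]))[k]
        amp_out = np.abs(np.fft.rfft(out.data[5, 5, 5]))[k]
        assert amp_out >= 0.9 * amp_in

    def test_out_of_band_sinusoid_attenuated(self):
        rng = np.random.default_rng(1)
        t = 300
        tr = 0.72
        data = rng.normal(0, 0.3, size=SHAPE + (t,))
        freq = 0.2
        times = np.arange(t) * tr
        data[5, 5, 5] = np.sin(2 * np.pi * freq * times)
        run = _run(data, tr=tr)
        out = preprocess_run(run, AnalysisConfig(), skip=("smooth",))
        k = int(round(freq * t * tr))
        amp_in = np.abs(np.fft.rfft(data[5, 5, 5]))[k]
        amp_out = np.abs(np.fft.rfft(out.data[5, 5, 5]))[k]
        assert amp_out <= 0.1 * amp_in

    def test_zero_motion_keeps_all_frames(self):
        rng = np.random.default_rng(2)
        run = _run(rng.normal(size=SHAPE + (40,)))
        out = preprocess_run(run, AnalysisConfig())
        assert out.kept_frames.size == 40

    def test_censoring_drops_high_fd_frames(self):
        rng = np.random.default_rng(3)
        motion = np.zeros((40, 6))
        motion[10:, 0] = 1.0
        run = _run(rng.normal(size=SHAPE + (40,)), motion=motion)
        out = preprocess_run(run, AnalysisConfig())
        assert out.kept_frames.size == 39
        assert 10 not in out.kept_frames

    def test_all_censored_rejected(self):
        # frame 0 always has FD=0, so force the branch with an impossible threshold
        rng = np.random.default_rng(4)
        run = _run(rng.normal(size=SHAPE + (40,)))
        cfg = AnalysisConfig()
        cfg.fd_threshold_mm = -1.0
        with pytest.raises(ValueError, match="unusable"):
            preprocess_run(run, cfg)

    def test_nuisance_residuals_orthogonal(self):
        rng = np.random.default_rng(5)
        motion = np.cumsum(rng.normal(0, 0.01, (50, 6)), axis=0)
        run = _run(rng.normal(size=SHAPE + (50,)), motion=motion)
        out = preprocess_run(run, AnalysisConfig(), skip=("smooth", "bandpass", "censor"))
        flat = out.data.reshape(-1, 50)
        for reg in motion.T:
            assert np.max(np.abs(flat @ (reg - reg.mean()))) < 1e-6

    def test_steps_bypassable_and_logged(self):
        rng = np.random.default_rng(6)
        run = _run(rng.normal(size=SHAPE + (30,)))
        out = preprocess_run(run, AnalysisConfig(), skip=("smooth", "nuisance"))
        assert out.steps == ("bandpass", "censor")


class TestRoiEigenvariate:
    def test_single_voxel_identity(self):
        rng = np.random.default_rng(7)
        data = rng.normal(size=(4, 4, 4, 50))
        roi = np.zeros((4, 4, 4), dtype=bool)
        roi[1, 1, 1] = True
        ev = roi_eigenvariate(data, roi)
        assert abs(np.corrcoef(ev, data[1, 1, 1])[0, 1]) == pytest.approx(1.0, abs=1e-10)
        assert np.corrcoef(ev, data[1, 1, 1])[0, 1] > 0  # sign convention

    def test_identical_voxels_common_series(self):
        rng = np.random.default_rng(8)
        ts = rng.normal(size=60)
        data = np.zeros((3, 3, 3, 60))
        roi = np.zeros((3, 3, 3), dtype=bool)
        for v in [(0, 0, 0), (1, 1, 1), (2, 2, 2)]:
            data[v] = ts
            roi[v] = True
        ev = roi_eigenvariate(data, roi)
        assert np.corrcoef(ev, ts)[0, 1] == pytest.approx(1.0, abs=1e-10)
        assert ev.std() == pytest.approx(1.0)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(9)
        data = rng.normal(size=(3, 1, 1, 40))
        roi = np.ones((3, 1, 1), dtype=bool)
        ev = roi_eigenvariate(data, roi)
        M = data.reshape(3, 40).T
        Mc = M - M.mean(axis=0)
        # independent oracle: eigendecomposition of the time-time Gram matrix
        w, V = np.linalg.eigh(Mc @ Mc.T)
        u = V[:, np.argmax(w)]
        u *= np.sign(np.dot(u, M.mean(axis=1) - M.mean()))
        u /= u.std()
        assert np.allclose(np.abs(ev), np.abs(u), atol=1e-8)
        assert np.allclose(ev, u, atol=1e-8)

    def test_empty_roi(self):
        with pytest.raises(ValueError, match="empty ROI"):
            roi_eigenvariate(np.zeros((2, 2, 2, 30)), np.zeros((2, 2, 2), dtype=bool))


class TestSeedConnectivityMap:
    def test_identical_series_clipped(self):
        rng = np.random.default_rng(10)
        data = rng.normal(size=(3, 3, 3, 50))
        seed = data[1, 1, 1].copy()
        out = seed_connectivity_map(data, seed, AFF2)
        assert out.grid[1, 1, 1] == pytest.approx(np.arctanh(1 - 1e-7), rel=1e-5)

    def test_zero_correlation_maps_to_zero(self):
        data = np.zeros((2, 2, 2, 40))
        t = np.arange(40.0)
        data[0, 0, 0] = np.sin(2 * np.pi * t / 40)
        data[1, 1, 1] = np.cos(2 * np.pi * t / 40)  # orthogonal
        out = seed_connectivity_map(data, data[0, 0, 0].copy(), AFF2)
        assert abs(out.grid[1, 1, 1]) < 1e-6

    def test_half_correlation_closed_form(self):
        rng = np.random.default_rng(11)
        s = rng.normal(size=100)
        s = (s - s.mean()) / s.std()
        o = rng.normal(size=100)
        o -= o.mean() + s * (s @ o) / (s @ s) * 0  # just center
        o = o - s * (s @ (o - o.mean())) / (s @ s)
        o = (o - o.mean()) / o.std()
        v = 0.5 * s + np.sqrt(0.75) * o  # exact r = 0.5 with seed s
        data = np.zeros((2, 1, 1, 100))
        data[0, 0, 0] = v
        data[1, 0, 0] = rng.normal(size=100)
        out = seed_connectivity_map(data, s, AFF2)
        assert out.grid[0, 0, 0] == pytest.approx(0.5493, abs=1e-3)

    def test_constant_seed_rejected(self):
        with pytest.raises(ValueError, match="constant seed"):
            seed_connectivity_map(np.zeros((2, 2, 2, 30)), np.ones(30), AFF2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            seed_connectivity_map(np.zeros((2, 2, 2, 30)), np.ones(29), AFF2)


class TestLesionNetworkMap:
    def _lesion(self, truth):
        grid = np.zeros(truth.grid_shape, dtype=np.uint8)
        c = np.asarray(truth.grid_shape) // 2
        grid[c[0] - 1 : c[0] + 1, c[1] - 1 : c[1] + 1, c[2] - 1 : c[2] + 1] = 1
        return LesionMask("sub-x", grid, truth.affine)

    def test_single_run_identity(self, truth, cleaned_runs, config):
        lesion = self._lesion(truth)
        nm1 = lesion_network_map(lesion, cleaned_runs[:1], config)
        assert nm1.n_maps_averaged == 1
        nm2 = lesion_network_map(lesion, cleaned_runs[:1] * 2, config)
        assert np.allclose(nm1.zmap.grid, nm2.zmap.grid, atol=1e-6)

    def test_duplicated_subject_invariance(self, truth, cleaned_runs, config):
        lesion = self._lesion(truth)
        base = lesion_network_map(lesion, cleaned_runs, config)
        dup = lesion_network_map(lesion, cleaned_runs + cleaned_runs, config)
        assert np.allclose(base.zmap.grid, dup.zmap.grid, atol=1e-6)

    def test_community_structure_recovered(self, truth, cleaned_runs, config):
        mods = truth.network_modules
        vox = np.argwhere(mods == 2)
        center = vox.mean(axis=0).astype(int)
        grid = np.zeros(truth.grid_shape, dtype=np.uint8)
        grid[tuple(center)] = 1
        lesion = LesionMask("sub-c", grid, truth.affine)
        if mods[tuple(center)] != 2:  # ensure seed voxel is in community 2
            grid[tuple(center)] = 0
            grid[tuple(vox[0])] = 1
            lesion = LesionMask("sub-c", grid, truth.affine)
        comm = mods[lesion.grid.astype(bool)][0]
        nm = lesion_network_map(lesion, cleaned_runs, config)
        z_in = nm.zmap.grid[mods == comm].mean()
        z_out = nm.zmap.grid[(mods > 0) & (mods != comm)].mean()
        assert z_in > z_out + 0.2


class TestGlmInference:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(12)
        n, shape = 12, (4, 4, 4)
        maps = []
        for i in range(n):
            g = rng.normal(size=shape)
            maps.append(
                lnsm.LesionNetworkMap(
                    f"p{i}", StatMap(g, np.ones(shape), "z", AFF2), 1
                )
            )
        y = rng.normal(size=n)
        cfg = AnalysisConfig(rng_seed=0)
        tmap, _ = lnsm_glm_inference(maps, y, cfg, n_permutations=10)
        Z = np.stack([m.zmap.grid for m in maps]).reshape(n, -1)
        for j in rng.choice(Z.shape[1], 10, replace=False):
            X = np.column_stack([np.ones(n), Z[:, j]])
            XtX_inv = np.linalg.inv(X.T @ X)
            beta = XtX_inv @ X.T @ y
            resid = y - X @ beta
            sigma2 = resid @ resid / (n - 2)
            t_oracle = beta[1] / np.sqrt(sigma2 * XtX_inv[1, 1])
            assert tmap.grid.reshape(-1)[j] == pytest.approx(t_oracle, abs=1e-8)

    def test_mask_restriction(self):
        rng = np.random.default_rng(13)
        n, shape = 15, (6, 6, 6)
        maps = [
            lnsm.LesionNetworkMap(f"p{i}", StatMap(rng.normal(size=shape), np.ones(shape), "z", AFF2), 1)
            for i in range(n)
        ]
        y = rng.normal(size=n)
        region = np.zeros(shape, dtype=bool)
        region[:3] = True
        cfg = AnalysisConfig(rng_seed=0, lnsm_voxel_p=0.2)
        tmap, clusters = lnsm_glm_inference(maps, y, cfg, region_mask=region, n_permutations=20)
        assert np.all(tmap.mask[~region] == 0)
        for c in clusters:
            v = c["voxels"]
            assert region[v[:, 0], v[:, 1], v[:, 2]].all()

    def test_needs_ten_patients(self):
        maps = [
            lnsm.LesionNetworkMap("p", StatMap(np.zeros((3, 3, 3)), np.ones((3, 3, 3)), "z", AFF2), 1)
        ] * 5
        with pytest.raises(ValueError, match=">= 10"):
            lnsm_glm_inference(maps, np.arange(5.0), AnalysisConfig())
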