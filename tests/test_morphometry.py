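import math

import numpy as np
import pytest
from scipy import ndimage

from cervidct import (
    BinaryVolume,
    ParameterError,
    bv_tv,
    local_thickness,
    make_plate_phantom,
    make_rod_phantom,
    make_sphere_phantom,
    make_trabecular_phantom,
    profile,
    smi,
    surface_mesh_area_volume,
    tb_n,
    tb_pf,
    tb_sp,
    tb_th,
)

VOX = 20.0  # µm
MM = VOX / 1000.0


def oracle_local_thickness(phase: np.ndarray) -> np.ndarray:
    """Exhaustive sphere-fitting oracle, in voxels.

    For every phase voxel c the inscribed-sphere radius r(c) is the minimum
    distance to any off-phase voxel centre (brute-force pairwise search);
    every voxel x with ||x − c|| < r(c) is covered by that sphere and gets
    thickness max over covering spheres of 2·r(c) − 1.
    """
    fg = np.argwhere(phase).astype(np.int64)
    bg = np.argwhere(~phase).astype(np.int64)
    assert fg.size and bg.size
    r2 = np.empty(len(fg))
    for start in range(0, len(fg), 256):
        chunk = fg[start:start + 256]
        d2 = ((chunk[:, None, :] - bg[None, :, :]) ** 2).sum(-1)
        r2[start:start + 256] = d2.min(axis=1)
    tau = np.zeros(phase.shape)
    order = np.argsort(r2)[::-1]
    flat_tau = np.zeros(len(fg))
    for j in order:
        dist2 = ((fg - fg[j]) ** 2).sum(1)
        covered = (dist2 < r2[j]) & (flat_tau == 0)
        flat_tau[covered] = 2.0 * math.sqrt(r2[j]) - 1.0
    tau[tuple(fg.T)] = flat_tau
    return tau


class TestBvTv:
    def test_all_foreground_is_100(self):
        b = BinaryVolume(np.ones((5, 5, 5), bool), VOX)
        assert bv_tv(b) == 100.0

    def test_plate_and_trabecular_fills(self):
        assert bv_tv(make_plate_phantom(0.2, 0.2, (80, 10, 10), VOX)) == \
            pytest.approx(50.0, abs=1.0)
        assert bv_tv(make_trabecular_phantom(0.06, 0.65, (40, 40, 40), VOX, 1)) == \
            pytest.approx(65.0, abs=1.0)

    def test_empty_mask_rejected(self):
        b = BinaryVolume(np.ones((4, 4, 4), bool), VOX,
                         mask=np.zeros((4, 4, 4), bool))
        with pytest.raises(ParameterError):
            bv_tv(b)

    def test_mask_restricts_counting(self):
        data = np.zeros((4, 4, 4), bool)
        data[:2] = True
        mask = np.zeros((4, 4, 4), bool)
        mask[:2] = True  # mask covers exactly the foreground
        assert bv_tv(BinaryVolume(data, VOX, mask=mask)) == 100.0


class TestLocalThickness:
    def test_plate_thickness_within_one_voxel(self):
        p = make_plate_phantom(0.3, 0.3, (90, 30, 30), VOX)  # 15-voxel slabs
        tm = local_thickness(p)
        assert tm.mean_mm() == pytest.approx(0.3, abs=MM + 1e-12)

    def test_rod_core_thickness_within_one_voxel(self):
        rod = make_rod_phantom(0.2, (40, 51, 51), VOX)  # R = 10 vox, centred
        tm = local_thickness(rod)
        core = tm.values_mm[20, 25, 25]
        assert core == pytest.approx(0.4, abs=MM + 1e-12)

    def test_empty_phase_rejected(self):
        b = BinaryVolume(np.ones((4, 4, 4), bool), VOX)
        with pytest.raises(ParameterError):
            local_thickness(b, "background")

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_exhaustive_oracle_voxel_for_voxel(self, seed):
        rng = np.random.default_rng(seed)
        field = ndimage.gaussian_filter(rng.standard_normal((20, 20, 20)), 2.0)
        phase = field > np.quantile(field, 0.5)
        b = BinaryVolume(phase, VOX)
        impl = local_thickness(b).values_mm / MM
        assert np.allclose(impl, oracle_local_thickness(phase), atol=1e-9)


class TestThicknessSeparation:
    @pytest.mark.parametrize("t,s,n_axis", [(0.19, 0.18, 74), (0.23, 0.24, 94)])
    def test_corpus_mean_plates_recovered_within_one_voxel(self, t, s, n_axis):
        p = make_plate_phantom(t, s, (n_axis, 40, 40), VOX)
        assert tb_th(p) == pytest.approx(t, abs=MM + 1e-12)
        assert tb_sp(p) == pytest.approx(s, abs=MM + 1e-12)

    def test_phase_duality_swaps_th_and_sp(self):
        p = make_trabecular_phantom(0.06, 0.5, (36, 36, 36), VOX, seed=4)
        comp = BinaryVolume(~p.data, VOX)
        assert tb_sp(p) == pytest.approx(tb_th(comp), rel=1e-12)
        assert tb_th(p) == pytest.approx(tb_sp(comp), rel=1e-12)


class TestTbN:
    def test_symmetric_plate_closed_form_odd_parity_exact(self):
        # 9-voxel slabs/gaps: thickness is recovered exactly, so
        # tb_n = 1/(t+s) holds tightly
        p = make_plate_phantom(0.18, 0.18, (72, 30, 30), VOX)
        assert tb_n(p) == pytest.approx(1 / 0.36, rel=0.02)

    def test_symmetric_plate_closed_form_even_parity(self):
        # 10-voxel slabs read one voxel thin (no voxel centre sits on the
        # mid-plane), so tb_n = f/th may exceed 1/(t+s) by up to th/(th-1vox)
        p = make_plate_phantom(0.2, 0.2, (80, 30, 30), VOX)
        assert tb_n(p) == pytest.approx(2.5, rel=0.12)

    def test_reindeer_like_plate_closed_form(self):
        p = make_plate_phantom(0.19, 0.18, (74, 30, 30), VOX)
        assert tb_n(p) == pytest.approx(1 / 0.37, rel=0.07)

    def test_plate_model_identity_within_5_percent(self):
        for t, s, n_axis in ((0.19, 0.18, 74), (0.23, 0.24, 94), (0.2, 0.2, 80)):
            p = make_plate_phantom(t, s, (n_axis, 30, 30), VOX)
            assert tb_n(p) * (tb_th(p) + tb_sp(p)) == pytest.approx(1.0, abs=0.05)

    def test_scale_equivariance_by_relabelling_voxel_size(self):
        data = make_trabecular_phantom(0.06, 0.5, (36, 36, 36), VOX, seed=8).data
        a = BinaryVolume(data, VOX)
        b = BinaryVolume(data, 2 * VOX)
        assert tb_th(b) == pytest.approx(2 * tb_th(a), rel=1e-12)
        assert tb_n(b) == pytest.approx(tb_n(a) / 2, rel=1e-12)
        assert tb_pf(b) == pytest.approx(tb_pf(a) / 2, rel=1e-9)
        assert bv_tv(b) == bv_tv(a)
        assert smi(b) == pytest.approx(smi(a), rel=1e-9)


class TestSurfaceMesh:
    def test_sphere_area_and_volume_near_analytic(self):
        r = 15 * MM
        s, v = surface_mesh_area_volume(make_sphere_phantom(r, (41, 41, 41), VOX))
        assert s == pytest.approx(4 * math.pi * r**2, rel=0.03)
        assert v == pytest.approx((4 / 3) * math.pi * r**3, rel=0.02)

    def test_single_voxel_volume_exact(self):
        data = np.zeros((7, 7, 7), bool)
        data[3, 3, 3] = True
        _, v = surface_mesh_area_volume(BinaryVolume(data, VOX))
        assert v == MM**3

    def test_padding_invariance(self):
        small = make_sphere_phantom(0.2, (27, 27, 27), VOX)
        embedded = np.zeros((41, 41, 41), bool)
        embedded[7:34, 7:34, 7:34] = small.data
        s1, v1 = surface_mesh_area_volume(small)
        s2, v2 = surface_mesh_area_volume(BinaryVolume(embedded, VOX))
        assert v1 == v2
        assert s1 == pytest.approx(s2, rel=1e-9)


class TestSMI:
    def test_sphere_scores_four(self):
        assert smi(make_sphere_phantom(0.4, (48, 48, 48), VOX)) == \
            pytest.approx(4.0, abs=0.3)

    def test_rod_scores_three(self):
        assert smi(make_rod_phantom(0.3, (100, 44, 44), VOX)) == \
            pytest.approx(3.0, abs=0.3)

    def test_plate_scores_zero(self):
        assert smi(make_plate_phantom(0.3, 0.3, (64, 80, 80), VOX)) == \
            pytest.approx(0.0, abs=0.3)

    def test_concave_cavity_scores_negative(self):
        block = np.ones((40, 40, 40), bool)
        x, y, z = np.meshgrid(*[np.arange(40) - 19.5] * 3, indexing="ij")
        block[x**2 + y**2 + z**2 <= 12**2] = False
        assert smi(BinaryVolume(block, VOX)) < 0

    def test_mask_filling_foreground_rejected(self):
        with pytest.raises(ParameterError):
            smi(BinaryVolume(np.ones((5, 5, 5), bool), VOX))


class TestTbPf:
    def test_isolated_sphere_positive_near_2_over_r(self):
        r = 15 * MM
        val = tb_pf(make_sphere_phantom(r, (44, 44, 44), VOX))
        assert val > 0
        assert val == pytest.approx(2 / r, rel=0.15)

    def test_connected_trabecular_mesh_negative(self):
        t = make_trabecular_phantom(0.06, 0.65, (64, 64, 64), VOX, seed=1)
        assert tb_pf(t) < 0

    def test_sign_flips_for_complement_of_sparse_convex_foreground(self):
        sphere = make_sphere_phantom(0.24, (64, 64, 64), VOX)
        pos = tb_pf(sphere)
        neg = tb_pf(BinaryVolume(~sphere.data, VOX))
        assert pos > 0 > neg


class TestProfile:
    def test_reindeer_like_plate_profile_closed_forms(self):
        p = make_plate_phantom(0.19, 0.18, (74, 40, 40), VOX)
        prof = profile(p)
        assert prof.tb_th == pytest.approx(0.19, abs=MM + 1e-12)
        assert prof.tb_sp == pytest.approx(0.18, abs=MM + 1e-12)
        assert prof.tb_n == pytest.approx(2.7, abs=0.2)
        assert prof.warnings  # slabs touch the frame laterally: open surface

    def test_deterministic(self):
        p = make_trabecular_phantom(0.06, 0.5, (30, 30, 30), VOX, seed=2)
        assert profile(p).as_dict() == profile(p).as_dict()

    def test_complement_swaps_thickness_and_separation(self):
        p = make_trabecular_phantom(0.06, 0.5, (30, 30, 30), VOX, seed=3)
        a = profile(p)
        b = profile(BinaryVolume(~p.data, VOX))
        assert a.tb_th == pytest.approx(b.tb_sp, rel=1e-12)
        assert a.tb_sp == pytest.approx(b.tb_th, rel=1e-12)

    def test_single_phase_rejected(self):
        with pytest.raises(ParameterError):
            profile(BinaryVolume(np.ones((5, 5, 5), bool), VOX))
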