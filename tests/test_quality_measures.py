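import numpy as np
import pytest

from siqr import (
    ScalarVolume,
    TissueSegmentation,
    add_noise,
    apply_bias,
    bias_correct,
    cjv,
    compute_measures,
    degrade_resolution,
    ecr_raw,
    estimate_bias_field,
    euler_characteristic,
    fec_raw,
    icr_raw,
    laplace_smooth,
    local_std,
    make_phantom,
    ncr_raw,
    normalize_intensity,
    optimize_masks,
    res_rms,
    smooth,
    threshold_resegment,
    tissue_stats,
)
from siqr.quality_measures import MeasureError, ParameterError, TopologyError
from siqr.tissue_regions import QcRegions

from conftest import small_spec


def _prepared(vol, seg):
    vn = normalize_intensity(vol, seg)
    st = tissue_stats(vn, seg)
    rg = optimize_masks(vn, seg, st)
    return vn, st, rg


class TestLocalStd:
    def test_constant_volume_zero(self):
        vol = ScalarVolume(data=np.full((12, 12, 12), 3.7), voxel_size=(1, 1, 1))
        assert np.allclose(local_std(vol).data, 0.0, atol=1e-6)

    def test_even_k_rejected(self):
        vol = ScalarVolume(data=np.zeros((8, 8, 8)), voxel_size=(1, 1, 1))
        with pytest.raises(ParameterError):
            local_std(vol, k=4)

    def test_checkerboard_matches_brute_force(self):
        idx = np.indices((11, 11, 11)).sum(axis=0)
        data = np.where(idx % 2 == 0, 1.0, -1.0)
        vol = ScalarVolume(data=data, voxel_size=(1, 1, 1))
        out = local_std(vol, k=5).data
        block = data[3:8, 3:8, 3:8]  # brute force on one interior 5^3 block
        assert out[5, 5, 5] == pytest.approx(float(np.std(block)), abs=1e-12)
        assert out[5, 5, 5] == pytest.approx(1.0, abs=1e-3)

    def test_gaussian_noise_recovers_sd(self, rng):
        s = 0.07
        data = rng.normal(0.0, s, size=(64, 64, 64))
        vol = ScalarVolume(data=data, voxel_size=(1, 1, 1))
        mean_sd = float(local_std(vol, k=5).data.mean())
        assert mean_sd == pytest.approx(s, rel=0.03)


class TestBiasField:
    def test_bias_free_phantom_flat_field(self, phantom64):
        vol, seg = phantom64
        vn, st, rg = _prepared(vol, seg)
        field, failed = estimate_bias_field(vn, rg)
        assert not failed
        brain = (seg.csf + seg.gm + seg.wm) > 0.5
        assert field.data[brain].min() > 0.99
        assert field.data[brain].max() < 1.01

    def test_linear_ramp_recovered(self, phantom64):
        vol, seg = phantom64
        nx = vol.shape[0]
        ramp = 0.8 + 0.4 * (np.arange(nx) / (nx - 1))
        biased = vol.with_data(vol.data * ramp[:, None, None])
        vn, st, rg = _prepared(biased, seg)
        field, _ = estimate_bias_field(vn, rg)
        truth = np.broadcast_to(ramp[:, None, None], vol.shape)
        r = np.corrcoef(field.data[rg.wme], truth[rg.wme])[0, 1]
        assert r > 0.95

    def test_correction_halves_wm_sd_at_40pct(self, phantom64):
        vol, seg = phantom64
        biased = apply_bias(vol, 40.0, "A")
        vn, st, rg = _prepared(biased, seg)
        field, _ = estimate_bias_field(vn, rg)
        cbc = bias_correct(vn, field, seg.wm > 0.9)
        sd_before = vn.data[rg.wme].std()
        sd_after = cbc.data[rg.wme].std()
        assert sd_after <= 0.5 * sd_before

    def test_identity_field_is_identity(self, phantom64):
        vol, seg = phantom64
        vn = normalize_intensity(vol, seg)
        field = vn.with_data(np.ones_like(vn.data))
        cbc = bias_correct(vn, field, seg.wm > 0.9)
        assert np.allclose(cbc.data, vn.data)

    def test_algebraic_inverse(self, phantom64):
        vol, seg = phantom64
        vn = normalize_intensity(vol, seg)
        g = 1.0 + 0.2 * np.sin(np.linspace(0, np.pi, vol.shape[0]))[:, None, None]
        g = np.broadcast_to(g, vol.shape).copy()
        prod = vn.with_data(vn.data * g)
        cbc = bias_correct(prod, vn.with_data(g), seg.wm > 0.9)
        # recovered up to the WM-median rescaling
        ratio = cbc.data[seg.wm > 0.9] / np.where(
            vn.data[seg.wm > 0.9] == 0, 1, vn.data[seg.wm > 0.9]
        )
        assert np.allclose(ratio, ratio.mean(), atol=1e-6)

    def test_full_pipeline_reduces_cjv_at_100pct(self, phantom64):
        vol, seg = phantom64
        noisy = add_noise(apply_bias(vol, 100.0, "A"), 1.0, seed=0)
        vn, st, rg = _prepared(noisy, seg)
        field, _ = estimate_bias_field(vn, rg)
        cbc = bias_correct(vn, field, seg.wm > 0.9)
        assert cjv(tissue_stats(cbc, seg)) < cjv(tissue_stats(vn, seg))


class TestLaplaceSmooth:
    def test_constant_is_fixed_point(self):
        vol = ScalarVolume(data=np.full((16, 16, 16), 2.5), voxel_size=(1, 1, 1))
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[4:12, 4:12, 4:12] = True
        out = laplace_smooth(vol, mask)
        assert np.allclose(out.data, 2.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_discrete_maximum_principle(self, seed):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(20, 20, 20))
        vol = ScalarVolume(data=data, voxel_size=(1, 1, 1))
        mask = np.zeros((20, 20, 20), dtype=bool)
        a, b = sorted(rng.integers(3, 9, size=2) + np.array([0, 6]))
        mask[a:b, a:b, a:b] = True
        out = laplace_smooth(vol, mask)
        lo, hi = data[mask].min(), data[mask].max()
        assert out.data[mask].min() >= lo - 1e-9
        assert out.data[mask].max() <= hi + 1e-9

    def test_interior_noise_strongly_suppressed(self, rng):
        data = rng.normal(0.0, 1.0, size=(26, 26, 26))
        vol = ScalarVolume(data=data, voxel_size=(1, 1, 1))
        mask = np.zeros((26, 26, 26), dtype=bool)
        mask[3:23, 3:23, 3:23] = True  # 20^3 cube
        out = laplace_smooth(vol, mask)
        from scipy import ndimage

        interior = ndimage.binary_erosion(mask, iterations=2)
        assert out.data[interior].std() < 0.25 * data[interior].std()

    def test_outside_mask_untouched(self, rng):
        data = rng.normal(size=(16, 16, 16))
        vol = ScalarVolume(data=data, voxel_size=(1, 1, 1))
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[5:11, 5:11, 5:11] = True
        out = laplace_smooth(vol, mask)
        assert np.array_equal(out.data[~mask], data[~mask])

    def test_no_interior_warns_and_returns_input(self, rng):
        data = rng.normal(size=(10, 10, 10))
        vol = ScalarVolume(data=data, voxel_size=(1, 1, 1))
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask[4] = True  # flat sheet: no 6-connected interior
        with pytest.warns(UserWarning, match="no interior"):
            out = laplace_smooth(vol, mask)
        assert np.array_equal(out.data, data)


class TestNcr:
    def test_noiseless_phantom_near_zero(self, phantom64):
        vol, seg = phantom64
        m = compute_measures(vol, seg)
        assert m.ncr_raw < 0.002

    def test_closed_form_sigma_over_contrast(self, phantom64):
        vol, seg = phantom64
        noisy = add_noise(vol, 3.0, seed=5)
        m = compute_measures(noisy, seg)
        assert m.ncr_raw == pytest.approx(0.03 / m.c_min, rel=0.10)

    def test_strictly_increasing_in_noise(self, phantom64):
        vol, seg = phantom64
        values = []
        for pct in (1.0, 3.0, 5.0, 7.0, 9.0):
            noisy = add_noise(vol, pct, seed=2)
            values.append(compute_measures(noisy, seg).ncr_raw)
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_invariant_to_global_scaling(self, phantom64):
        vol, seg = phantom64
        noisy = add_noise(vol, 3.0, seed=9)
        a = compute_measures(noisy, seg).ncr_raw
        b = compute_measures(noisy.with_data(noisy.data * 42.0), seg).ncr_raw
        assert a == pytest.approx(b, rel=1e-9)

    def test_stable_under_planted_bias(self, phantom96):
        vol, seg = phantom96
        noisy = add_noise(vol, 3.0, seed=9)
        a = compute_measures(noisy, seg).ncr_raw
        b = compute_measures(
            add_noise(apply_bias(vol, 100.0, "A"), 3.0, seed=9), seg
        ).ncr_raw
        assert b == pytest.approx(a, rel=0.10)


class TestIcr:
    def test_clean_phantom_near_zero(self, phantom64):
        vol, seg = phantom64
        assert compute_measures(vol, seg).icr_raw < 0.005

    def test_monotone_in_bias_amplitude(self, phantom64):
        vol, seg = phantom64
        values = []
        for pct in (20.0, 40.0, 60.0, 80.0, 100.0):
            biased = apply_bias(vol, pct, "A")
            values.append(compute_measures(biased, seg).icr_raw)
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_noise_changes_icr_under_20pct(self, phantom64):
        vol, seg = phantom64
        biased = apply_bias(vol, 60.0, "A")
        base = compute_measures(biased, seg).icr_raw
        noisy = compute_measures(add_noise(biased, 5.0, seed=4), seg).icr_raw
        assert abs(noisy - base) / base < 0.20

    def test_small_wm_mask_rejected(self, phantom64):
        vol, seg = phantom64
        vn = normalize_intensity(vol, seg)
        tiny = QcRegions(
            csfe=np.zeros(vol.shape, dtype=bool),
            wme=np.zeros(vol.shape, dtype=bool),
            boundary_band=np.zeros(vol.shape, dtype=bool),
        )
        tiny.wme[30:32, 30:32, 30:32] = True  # 8 voxels < 27
        with pytest.raises(MeasureError):
            icr_raw(vn, tiny, 0.4)


class TestRes:
    @pytest.mark.parametrize(
        "vs, expected",
        [((1.0, 1.0, 1.0), 1.0), ((0.5, 0.5, 2.5), 1.5), ((2.0, 2.0, 2.0), 2.0)],
    )
    def test_rms_arithmetic(self, vs, expected):
        rms, _ = res_rms(vs)
        assert rms == pytest.approx(expected)

    def test_resm_diagnostic_is_plain_mean(self):
        _, resm = res_rms((0.5, 0.5, 2.5))
        assert resm == pytest.approx(3.5 / 3.0)

    def test_anisotropy_penalized_at_equal_volume(self):
        aniso, _ = res_rms((0.5, 0.5, 2.5))
        iso_edge = (0.5 * 0.5 * 2.5) ** (1 / 3)
        iso, _ = res_rms((iso_edge,) * 3)
        assert aniso > iso

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            res_rms((1.0, 0.0, 1.0))


def _slab_fixture():
    """GM/WM step along x with a single partial-volume plane at x=15."""
    shape = (32, 32, 32)
    wm = np.zeros(shape)
    wm[16:] = 1.0
    wm[15] = 0.5
    gm = np.zeros(shape)
    gm[4:15] = 1.0
    gm[15] = 0.5
    csf = np.zeros(shape)
    csf[2:4] = 1.0
    seg = TissueSegmentation(csf=csf, gm=gm, wm=wm, voxel_size=(1, 1, 1))
    vol = ScalarVolume(
        data=0.2 * csf + 0.6 * gm + 1.0 * wm, voxel_size=(1, 1, 1)
    )
    band = (wm >= 0.25) & (wm <= 0.75)
    regions = QcRegions(
        csfe=np.zeros(shape, dtype=bool),
        wme=np.zeros(shape, dtype=bool),
        boundary_band=band,
    )
    return vol, seg, regions


class TestEcr:
    def test_slab_step_matches_brute_force(self):
        vol, seg, regions = _slab_fixture()
        got = ecr_raw(vol, regions, c_min=0.4, seg=seg)
        # independent finite-difference oracle over the band plane
        slopes = []
        d = vol.data
        for i, j, k in zip(*np.where(regions.boundary_band)):
            slopes.append(abs(d[i + 1, j, k] - d[i - 1, j, k]) / 2.0)
        expected = float(np.mean(slopes)) / 0.4
        assert got == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(((1.0 - 0.6) / 2.0) / 0.4)

    def test_strictly_decreasing_with_smoothing(self, phantom64):
        vol, seg = phantom64
        values = []
        for fwhm in (0.0, 1.0, 2.0, 3.0):
            m = compute_measures(smooth(vol, fwhm), seg)
            values.append(m.ecr_raw)
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_reinterpolation_lowers_ecr_not_res(self, phantom64):
        vol, seg = phantom64
        native = compute_measures(vol, seg)
        blurred = degrade_resolution(vol, 2.0, reinterpolate=True)
        degraded = compute_measures(blurred, seg)
        assert degraded.res_rms == native.res_rms  # header-blind RMS
        assert degraded.ecr_raw < native.ecr_raw  # true detail loss seen

    def test_small_band_rejected(self):
        vol, seg, regions = _slab_fixture()
        regions.boundary_band[:] = False
        regions.boundary_band[15, :3, :3] = True  # 9 voxels < 50
        with pytest.raises(MeasureError):
            ecr_raw(vol, regions, c_min=0.4, seg=seg)


def _ball(radius, center, shape):
    idx = np.indices(shape)
    d2 = sum((g - c) ** 2 for g, c in zip(idx, center))
    return d2 <= radius**2


class TestEulerCharacteristic:
    def test_solid_ball_is_two(self):
        assert euler_characteristic(_ball(6, (10, 10, 10), (21, 21, 21))) == 2

    @pytest.mark.parametrize("k", [2, 3])
    def test_additive_over_components(self, k):
        shape = (16, 16 * k, 16)
        grid = np.zeros(shape, dtype=bool)
        for i in range(k):
            grid |= _ball(4, (8, 8 + 16 * i, 8), shape)
        assert euler_characteristic(grid) == 2 * k

    def test_solid_torus_is_zero(self):
        # handmade voxel torus: (sqrt(x^2+y^2) - R)^2 + z^2 <= r^2
        n = 30
        idx = np.indices((n, n, n)) - (n - 1) / 2.0
        rho = np.sqrt(idx[0] ** 2 + idx[1] ** 2)
        torus = (rho - 8.0) ** 2 + idx[2] ** 2 <= 3.0**2
        assert euler_characteristic(torus) == 0

    def test_closed_form_genus_and_components(self):
        # chi = 2 - 2g + 2(c - 1): one torus plus two balls -> 0 + 4
        n = 30
        idx = np.indices((n, n, 60)) - np.array([(n - 1) / 2, (n - 1) / 2, 0])[
            :, None, None, None
        ]
        rho = np.sqrt(idx[0] ** 2 + idx[1] ** 2)
        grid = (rho - 8.0) ** 2 + (idx[2] - 14) ** 2 <= 9.0
        grid |= _ball(4, (8, 8, 40), grid.shape)
        grid |= _ball(4, (20, 20, 52), grid.shape)
        assert euler_characteristic(grid) == 2 - 2 * 1 + 2 * (3 - 1)

    def test_empty_foreground_rejected(self):
        with pytest.raises(TopologyError):
            euler_characteristic(np.zeros((8, 8, 8), dtype=bool))


class TestFec:
    def test_clean_phantom_no_defects(self, phantom96):
        _, seg = phantom96
        fec, chi_lo, chi_hi, fallback = fec_raw(seg)
        assert (chi_lo, chi_hi) == (2, 2)
        assert fec == 0.0
        assert not fallback

    def test_planted_blobs_add_two_defects_each(self, phantom96):
        _, seg = phantom96
        k = 5
        wm = seg.wm.copy()
        for i in range(k):  # isolated 4-mm cubes in the background corner
            x = 4 + 12 * i
            wm[x : x + 4, 4:8, 4:8] = 1.0
        pert = TissueSegmentation(
            csf=np.where(wm > seg.wm, 0.0, seg.csf),
            gm=np.where(wm > seg.wm, 0.0, seg.gm),
            wm=wm,
            voxel_size=seg.voxel_size,
        )
        base = fec_raw(seg)[0]
        fec, chi_lo, chi_hi, _ = fec_raw(pert)
        assert chi_lo == 2 * (k + 1)
        assert chi_hi == 2 * (k + 1)
        assert fec - base == pytest.approx(2 * k)

    def test_nondecreasing_with_noise_via_resegmentation(self):
        # a GM shell thicker than the 2-mm max-filter reach, so noise
        # speckles can form isolated WM components instead of merging
        # with the main surface
        vol, seg = make_phantom(
            small_spec(wm_radii=(12.0, 14.0, 11.0), gm_thickness=8.0)
        )
        brain = (seg.csf + seg.gm + seg.wm) > 0.5
        values = []
        for pct in (1.0, 5.0, 9.0):
            noisy = add_noise(vol, pct, seed=3)
            reseg = threshold_resegment(noisy, mask=brain)
            values.append(fec_raw(reseg)[0])
        assert all(a <= b for a, b in zip(values, values[1:]))
        assert values[-1] > values[0]


class TestComputeMeasures:
    def test_default_phantom_satisfies_invariants(self, phantom64):
        vol, seg = phantom64
        m = compute_measures(add_noise(vol, 3.0, seed=1), seg)
        assert m.ncr_raw >= 0 and m.icr_raw >= 0 and m.fec_raw >= 0
        assert m.ecr_raw >= 0 and m.res_rms > 0
        assert isinstance(m.chi_025, int) and isinstance(m.chi_075, int)
        assert m.fec_raw == pytest.approx(
            (abs(2 - m.chi_025) + abs(2 - m.chi_075)) / 2.0
        )

    def test_bitwise_deterministic(self, phantom64):
        vol, seg = phantom64
        noisy = add_noise(vol, 5.0, seed=11)
        a = compute_measures(noisy, seg)
        b = compute_measures(noisy, seg)
        for f in ("ncr_raw", "icr_raw", "res_rms", "ecr_raw", "fec_raw", "c_min"):
            assert getattr(a, f) == getattr(b, f)

    def test_good_scan_dominates_bad_scan(self, phantom64):
        vol, seg = phantom64
        brain = (seg.csf + seg.gm + seg.wm) > 0.5

        good_img = add_noise(apply_bias(vol, 20.0, "A"), 1.0, seed=6)
        good_seg = threshold_resegment(good_img, mask=brain)
        good = compute_measures(good_img, good_seg)

        bad_img = add_noise(apply_bias(vol, 100.0, "B"), 9.0, seed=6)
        bad_img = degrade_resolution(bad_img, 2.0, reinterpolate=False)
        bad_seg = threshold_resegment(bad_img)
        bad = compute_measures(bad_img, bad_seg)

        assert good.ncr_raw < bad.ncr_raw
        assert good.icr_raw < bad.icr_raw
        assert good.res_rms < bad.res_rms
        assert good.ecr_raw > bad.ecr_raw  # sharper is larger
        assert good.fec_raw <= bad.fec_raw

    def test_small_grid_rejected(self):
        shape = (6, 6, 6)
        ones = np.ones(shape)
        seg = TissueSegmentation(
            csf=ones * 0, gm=ones * 0, wm=ones, voxel_size=(1, 1, 1)
        )
        vol = ScalarVolume(data=ones, voxel_size=(1, 1, 1))
        with pytest.raises(MeasureError):
            compute_measures(vol, seg)
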