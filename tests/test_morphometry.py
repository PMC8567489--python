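"""CT synthesis and cortical morphometry."""

import numpy as np
import pytest

from cortbs.ctsim import CTParams, synthesize_microct
from cortbs.morphometry import (
    analyze_volume,
    cortical_thickness,
    local_porosity_map,
    moment_stats,
    pore_diameter_dist,
    pore_segmentation_bh,
    segment_cortex,
)
from cortbs.pores import PorePopulation, baseline_only, pathological, sample_pore_population

ANNULUS_ARC = 2 * np.pi * 4.5  # mid-circumference for r_out 6, thickness 3


def annulus_params(**kw):
    base = dict(noise_sd=0.0, psf_sigma_um=0.0, n_slices=8)
    base.update(kw)
    return CTParams(**base)


@pytest.fixture(scope="module")
def empty_annulus():
    pop = PorePopulation(slab_extent=(ANNULUS_ARC, 5.0, 3.0),
                         centers=np.empty((0, 2)), diameters_um=np.empty(0))
    return synthesize_microct(pop, annulus_params(), seed=0)


@pytest.fixture(scope="module")
def porous_volume():
    params = pathological(tail_weight=0.12, areal_density=15.0)
    pop = sample_pore_population(params, (ANNULUS_ARC * 0.98, 5.0, 3.0), seed=2)
    return pop, synthesize_microct(pop, annulus_params(), seed=2)


class TestSynthesis:
    def test_zero_pores_cortex_at_matrix_vbmd(self, empty_annulus):
        """Interior cortex voxels equal the matrix vBMD exactly (no pores,
        no noise, no blur); only annulus-boundary voxels carry partial
        volume."""
        from scipy import ndimage

        vol = empty_annulus
        interior = ndimage.binary_erosion(vol.truth["cortex_mask"], iterations=2)
        vals = vol.data[0][interior]
        assert vals.size > 1000
        assert np.all(np.abs(vals - 1100.0) < 1e-9)

    def test_raster_porosity_matches_analytic(self, porous_volume):
        _, vol = porous_volume
        assert vol.truth["raster_porosity_pct"] == pytest.approx(
            vol.truth["analytic_porosity_pct"], abs=1.0
        )

    def test_resolution_classification(self):
        p = annulus_params()
        assert 30.0 < p.voxel_um  # Haversian canals are sub-voxel
        assert 200.0 / p.voxel_um > 3.0  # giant pores span >3 voxels

    def test_sub_voxel_phantom_rejected(self):
        pop = PorePopulation(slab_extent=(1.0, 1.0, 0.01),
                             centers=np.empty((0, 2)), diameters_um=np.empty(0))
        with pytest.raises(ValueError, match="voxel"):
            synthesize_microct(pop, annulus_params(cortical_thickness_mm=0.03), seed=0)

    def test_seed_determinism(self, porous_volume):
        pop, vol = porous_volume
        vol2 = synthesize_microct(pop, annulus_params(), seed=2)
        assert np.array_equal(vol.data, vol2.data)


class TestSegmentation:
    def test_noiseless_masks_match_generating_annulus(self, empty_annulus):
        masks = segment_cortex(empty_annulus)
        truth = empty_annulus.truth["cortex_mask"]
        got = masks.filled_cortex[0]
        inter = np.logical_and(got, truth).sum()
        dice = 2 * inter / (got.sum() + truth.sum())
        assert dice > 0.99

    def test_noisy_blurred_dice(self):
        params = pathological(tail_weight=0.12, areal_density=15.0)
        pop = sample_pore_population(params, (ANNULUS_ARC * 0.98, 5.0, 3.0), seed=4)
        vol = synthesize_microct(pop, annulus_params(psf_sigma_um=45.0, noise_sd=25.0),
                                 seed=4)
        masks = segment_cortex(vol)
        truth = vol.truth["cortex_mask"]
        got = masks.filled_cortex[0]
        dice = 2 * np.logical_and(got, truth).sum() / (got.sum() + truth.sum())
        assert dice >= 0.95

    def test_roi_subset_of_cortex(self, empty_annulus):
        masks = segment_cortex(empty_annulus, roi_sector_deg=(200, 250))
        assert not np.any(masks.roi & ~masks.filled_cortex)
        assert masks.roi.sum() < masks.filled_cortex.sum()

    def test_empty_volume_rejected(self, empty_annulus):
        from cortbs.ctsim import MicroCTVolume

        blank = MicroCTVolume(data=np.zeros_like(empty_annulus.data),
                              voxel_um=empty_annulus.voxel_um,
                              calibration=empty_annulus.calibration)
        with pytest.raises(ValueError, match="bone"):
            segment_cortex(blank)


class TestThickness:
    def test_annulus_thickness_analytic(self, empty_annulus):
        masks = segment_cortex(empty_annulus)
        th = cortical_thickness(masks, empty_annulus.voxel_um)
        assert th == pytest.approx(3.0, abs=empty_annulus.voxel_um * 1e-3 * 2)

    def test_agrees_with_brute_force_nearest_boundary(self, empty_annulus):
        """Medial-axis doubling vs brute-force nearest-boundary distance."""
        from scipy import ndimage
        from skimage import morphology as sm

        masks = segment_cortex(empty_annulus)
        sl = masks.filled_cortex[0]
        skel, dist = sm.medial_axis(sl, return_distance=True)
        ys, xs = np.nonzero(skel)
        boundary = sl & ~ndimage.binary_erosion(sl)
        by, bx = np.nonzero(~sl)
        # brute force: for a sample of skeleton points, distance to nearest
        # non-mask pixel
        rng = np.random.default_rng(0)
        pick = rng.choice(ys.size, size=min(50, ys.size), replace=False)
        for i in pick:
            d_brute = np.min(np.hypot(by - ys[i], bx - xs[i]))
            assert 2 * dist[ys[i], xs[i]] == pytest.approx(2 * d_brute, rel=0.05, abs=2.1)

    def test_empty_mask_rejected(self, empty_annulus):
        masks = segment_cortex(empty_annulus)
        masks.filled_cortex[:] = False
        with pytest.raises(ValueError, match="empty"):
            cortical_thickness(masks, empty_annulus.voxel_um)


class TestPoreSegmentation:
    def test_no_pores_zero_porosity(self, empty_annulus):
        masks = segment_cortex(empty_annulus)
        _, po, dn = pore_segmentation_bh(empty_annulus, masks)
        assert po < 0.05 and dn < 0.05

    def test_resolvable_pores_porosity_within_1pct_absolute(self):
        """Clearly-resolvable pores: threshold porosity ~ rasterized truth."""
        params = baseline_only(median_um=250.0, log_sd=0.15, areal_density=0.6,
                               hard_core_um=120.0)
        pop = sample_pore_population(params, (ANNULUS_ARC * 0.95, 5.0, 3.0), seed=6)
        vol = synthesize_microct(pop, annulus_params(), seed=6)
        masks = segment_cortex(vol)
        _, po, _ = pore_segmentation_bh(vol, masks)
        assert po == pytest.approx(vol.truth["raster_porosity_pct"], abs=1.0)

    def test_monotone_in_added_pores(self):
        """Adding pores never decreases the threshold porosity."""
        base = baseline_only(median_um=250.0, log_sd=0.15, areal_density=0.3,
                             hard_core_um=120.0)
        pops = []
        pop1 = sample_pore_population(base, (ANNULUS_ARC * 0.95, 5.0, 3.0), seed=7)
        extra = sample_pore_population(base, (ANNULUS_ARC * 0.95, 5.0, 3.0), seed=8)
        pop2 = PorePopulation(
            slab_extent=pop1.slab_extent,
            centers=np.vstack([pop1.centers, extra.centers]),
            diameters_um=np.concatenate([pop1.diameters_um, extra.diameters_um]),
        )
        po = []
        for p in (pop1, pop2):
            vol = synthesize_microct(p, annulus_params(), seed=9)
            masks = segment_cortex(vol)
            po.append(pore_segmentation_bh(vol, masks)[1])
        assert po[1] >= po[0]


class TestDiameterDistribution:
    def test_single_sphere_diameter(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        zz, yy, xx = np.mgrid[0:20, 0:20, 0:20]
        r_vox = 100.0 / 60.7  # 200 um sphere at 60.7 um voxels
        mask[(zz - 10.0) ** 2 + (yy - 10.0) ** 2 + (xx - 10.0) ** 2 <= r_vox**2] = True
        d = pore_diameter_dist(mask, 60.7)
        assert d.size == 1
        assert d[0] == pytest.approx(200.0, abs=61.0)

    def test_resolvable_diameters_match_truth_ks(self, porous_volume):
        """KS distance truth-vs-CT for pores above the resolution limit."""
        from scipy import stats as st

        pop, vol = porous_volume
        masks = segment_cortex(vol)
        pm, _, _ = pore_segmentation_bh(vol, masks)
        est = pore_diameter_dist(pm, vol.voxel_um, vol=vol, masks=masks)
        truth = vol.truth["diameters_um"]
        lim = 2 * vol.voxel_um  # ~121 um
        est_r, truth_r = est[est >= lim], truth[truth >= lim]
        assert est_r.size > 10
        ks = st.ks_2samp(est_r, truth_r).statistic
        assert ks <= 0.1

    def test_unresolved_pores_absent(self, porous_volume):
        """~30 um pores exist in truth but not in the CT distribution."""
        pop, vol = porous_volume
        masks = segment_cortex(vol)
        pm, _, _ = pore_segmentation_bh(vol, masks)
        est = pore_diameter_dist(pm, vol.voxel_um)
        assert (vol.truth["diameters_um"] < 60).sum() > 0
        assert est.size < vol.truth["diameters_um"].size
        assert est.min() >= vol.voxel_um  # nothing below one voxel

    def test_empty_mask_gives_empty_distribution(self):
        assert pore_diameter_dist(np.zeros((4, 4, 4), bool), 60.7).size == 0


class TestLocalPorosity:
    def test_pure_matrix_window_zero(self, empty_annulus):
        masks = segment_cortex(empty_annulus)
        vals = local_porosity_map(empty_annulus, masks)
        assert np.median(vals) == pytest.approx(0.0, abs=0.5)

    def test_unresolved_pores_mae_below_calibration_bound(self):
        """30 um pores at ~5% porosity: map MAE <= 3.4% (calibration claim)."""
        params = baseline_only(median_um=30.0, log_sd=0.2, areal_density=60.0,
                               hard_core_um=5.0)
        pop = sample_pore_population(params, (ANNULUS_ARC * 0.98, 5.0, 3.0), seed=3)
        vol = synthesize_microct(pop, annulus_params(psf_sigma_um=45.0), seed=3)
        masks = segment_cortex(vol)
        vals = local_porosity_map(vol, masks)
        true_po = vol.truth["raster_porosity_pct"]
        assert np.mean(np.abs(vals - true_po)) <= 3.4

    def test_map_mean_tracks_total_porosity(self, porous_volume):
        pop, vol = porous_volume
        masks = segment_cortex(vol)
        vals = local_porosity_map(vol, masks)
        assert vals.mean() == pytest.approx(vol.truth["raster_porosity_pct"], abs=2.0)

    def test_window_larger_than_cortex_rejected(self, empty_annulus):
        masks = segment_cortex(empty_annulus)
        with pytest.raises(ValueError, match="window"):
            local_porosity_map(empty_annulus, masks, window_mm=50.0)


class TestMomentStats:
    def test_gaussian_sample_moments(self):
        rng = np.random.default_rng(0)
        x = rng.normal(10.0, 2.0, 200_000)
        st = moment_stats(x)
        assert st["skewness"] == pytest.approx(0.0, abs=0.03)
        assert st["kurtosis"] == pytest.approx(3.0, abs=0.05)  # non-excess
        assert st["VAR"] == pytest.approx(st["SD"] ** 2, rel=1e-12)

    def test_exact_match_brute_force_20_numbers(self):
        rng = np.random.default_rng(1)
        x = rng.random(20) * 7 + 3
        st = moment_stats(x)
        n = x.size
        mu = x.sum() / n
        sd = np.sqrt(((x - mu) ** 2).sum() / (n - 1))
        m2 = ((x - mu) ** 2).sum() / n
        m3 = ((x - mu) ** 3).sum() / n
        m4 = ((x - mu) ** 4).sum() / n
        assert st["mean"] == pytest.approx(mu, rel=1e-12)
        assert st["SD"] == pytest.approx(sd, rel=1e-12)
        assert st["skewness"] == pytest.approx(m3 / m2**1.5, rel=1e-12)
        assert st["kurtosis"] == pytest.approx(m4 / m2**2, rel=1e-12)
        assert st["Q10"] == pytest.approx(np.quantile(x, 0.1), rel=1e-12)
        assert st["kurtosis"] >= 1 + st["skewness"] ** 2  # Pearson inequality

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.random(50)
        a = moment_stats(x)
        b = moment_stats(x[rng.permutation(50)])
        for k in a:
            assert b[k] == pytest.approx(a[k], rel=1e-9)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="8"):
            moment_stats(np.arange(5))


class TestAnalyzeVolume:
    def test_full_pipeline_result_fields(self, porous_volume):
        _, vol = porous_volume
        res = analyze_volume(vol)
        d = res.as_dict()
        assert 0 <= d["Ct.Po_BH_full"] <= 100
        assert d["Ct.Th_full"] > 0
        assert "Ct.Po.D_kurtosis_full" in d
        assert d["Ct.Po.D_VAR_full"] == pytest.approx(d["Ct.Po.D_SD_full"] ** 2, rel=1e-9)

    def test_roi_scope(self, porous_volume):
        _, vol = porous_volume
        res = analyze_volume(vol, scope="roi")
        assert res.scope == "roi"
        # pores merging into the endosteal boundary thin the ring locally,
        # so the porous-cortex thickness sits slightly below the 3 mm shell
        assert 2.2 < res.ct_th_mm <= 3.1
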