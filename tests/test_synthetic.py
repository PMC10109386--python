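import dataclasses

import numpy as np
import pytest
from scipy.stats import spearmanr

from ndaikit import (
    CameraModel,
    ForwardModel,
    SceneSpec,
    compute_index,
    index_summary,
    make_evaluation_set,
    mask_iou,
    render_multispectral,
    render_rgb,
    segment_stack,
    SegmentationParams,
)


def object_mean(source, truth, obj, name="NDAI"):
    imap = compute_index(source, name, truth.object_mask(obj))
    return index_summary(imap).mean


class TestForwardModel:
    def test_green_strictly_decreasing_in_anthocyanin(self):
        m = ForwardModel()
        r = [m.reflectances(c, 1.0)["green"] for c in (100, 500, 1000, 1600)]
        assert np.all(np.diff(r) < 0)

    def test_red_decreasing_in_chl_independent_of_anthocyanin(self):
        m = ForwardModel()
        assert m.reflectances(100, 1.0)["red"] == m.reflectances(1600, 1.0)["red"]
        assert m.reflectances(100, 1.5)["red"] < m.reflectances(100, 0.5)["red"]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ForwardModel(base_green=0.0)
        with pytest.raises(ValueError):
            ForwardModel(noise_sd=-0.1)


class TestRenderMultispectral:
    def test_deterministic_under_fixed_seed(self, two_disc_spec):
        s1, t1 = render_multispectral(two_disc_spec)
        s2, t2 = render_multispectral(two_disc_spec)
        for role in ("green", "red", "nir"):
            np.testing.assert_array_equal(
                s1[role].intensities, s2[role].intensities
            )
        np.testing.assert_array_equal(t1.labels, t2.labels)

    def test_higher_anthocyanin_disc_has_higher_ndai(self, two_disc_spec, noiseless_model):
        stack, truth = render_multispectral(two_disc_spec, noiseless_model)
        assert object_mean(stack, truth, 1) < object_mean(stack, truth, 2)

    def test_null_model_makes_ndai_insensitive_to_anthocyanin(self, two_disc_spec):
        model = ForwardModel(anth_green=0.0, noise_sd=0.0)
        stack, truth = render_multispectral(two_disc_spec, model)
        a = object_mean(stack, truth, 1)
        b = object_mean(stack, truth, 2)
        assert a == pytest.approx(b, abs=1 / 255)  # ±quantization

    def test_oversized_disc_rejected(self):
        spec = SceneSpec(n_objects=4, width=40, height=40, disc_radius_px=15)
        with pytest.raises(ValueError, match="border"):
            render_multispectral(spec)

    def test_quantization_round_trip_within_half_step(self, two_disc_spec, noiseless_model):
        stack, truth = render_multispectral(two_disc_spec, noiseless_model)
        for role in ("green", "red", "nir"):
            recovered = stack[role].intensities / 255.0
            assert np.max(np.abs(recovered - truth.noiseless_reflectance[role])) <= 1 / 510

    def test_monotone_object_means_in_anthocyanin(self, noiseless_model):
        """All indices rise with c at fixed chlorophyll in noiseless scenes."""
        cs = [200.0, 600.0, 1000.0, 1400.0]
        spec = SceneSpec(
            n_objects=4, width=128, height=128,
            anthocyanin=cs, chlorophyll=[1.0] * 4, seed=1,
        )
        stack, truth = render_multispectral(spec, noiseless_model)
        for name in ("NDAI", "ARI", "mARI", "RGI", "mACI"):
            means = [object_mean(stack, truth, k + 1, name) for k in range(4)]
            assert np.all(np.diff(means) > 0), name

    def test_chl_perturbs_maci_more_than_ndai(self, noiseless_model):
        """NIR-based mACI lacks the chlorophyll correction the red band gives NDAI."""
        chls = np.linspace(0.8, 1.2, 9)
        nd, mc = [], []
        for i, chl in enumerate(chls):
            spec = SceneSpec(n_objects=1, anthocyanin=[800.0], chlorophyll=[chl], seed=i)
            stack, truth = render_multispectral(spec, noiseless_model)
            nd.append(object_mean(stack, truth, 1, "NDAI"))
            mc.append(object_mean(stack, truth, 1, "mACI"))

        def span(name):  # index swing across the full c range at fixed chl
            out = []
            for c in (108.0, 1673.0):
                spec = SceneSpec(n_objects=1, anthocyanin=[c], chlorophyll=[1.0], seed=0)
                stack, truth = render_multispectral(spec, noiseless_model)
                out.append(object_mean(stack, truth, 1, name))
            return abs(out[1] - out[0])

        assert np.std(nd) / span("NDAI") < np.std(mc) / span("mACI")

    def test_rosette_layout_renders_canopy(self):
        spec = SceneSpec(layout="rosette", n_objects=6, width=120, height=120, seed=2)
        stack, truth = render_multispectral(spec)
        assert truth.mask.n_true > 1000
        assert set(np.unique(truth.labels)) <= set(range(7))


class TestSegmentationRecovery:
    @pytest.mark.parametrize("noise_sd,min_iou", [(0.0, 0.95), (0.02, 0.90)])
    def test_recovered_mask_iou(self, noise_sd, min_iou):
        model = ForwardModel(noise_sd=noise_sd)
        params = SegmentationParams(method="otsu")
        for seed in range(5):
            spec = SceneSpec(n_objects=3, width=96, height=96, seed=seed)
            stack, truth = render_multispectral(spec, model)
            mask = segment_stack(stack, params)
            assert mask_iou(mask, truth.mask) >= min_iou


class TestRenderRGB:
    def test_gray_world_flat_scene_flat_illuminant(self):
        model = ForwardModel(
            base_green=0.4, base_red=0.4, base_nir=0.4, base_blue=0.4,
            anth_green=0.0, chl_green=0.0, chl_red=0.0, chl_blue=0.0,
            noise_sd=0.0, background_reflectance=0.4,
        )
        camera = CameraModel(illuminant=None)
        rgb, _ = render_rgb(SceneSpec(n_objects=1, seed=0), model, camera)
        px = rgb.pixels.astype(int)
        assert np.abs(px[:, :, 0] - px[:, :, 1]).max() <= 1
        assert np.abs(px[:, :, 1] - px[:, :, 2]).max() <= 1

    def test_cross_system_object_means_track(self, noiseless_model):
        ms, rv = [], []
        for seed in range(12):
            spec = SceneSpec(n_objects=1, seed=200 + seed)
            stack, truth = render_multispectral(spec, noiseless_model)
            rgb, _ = render_rgb(spec, noiseless_model)
            ms.append(object_mean(stack, truth, 1))
            rv.append(object_mean(rgb, truth, 1))
        assert spearmanr(ms, rv).statistic >= 0.9

    def test_narrow_sensitivities_converge_to_band_ndai(self, noiseless_model):
        spec = SceneSpec(n_objects=1, seed=5)
        stack, truth = render_multispectral(spec, noiseless_model)
        narrow = CameraModel(
            green_peak_nm=516, green_fwhm_nm=2,
            red_peak_nm=664, red_fwhm_nm=2,
            illuminant=None,
        )
        rgb, _ = render_rgb(spec, noiseless_model, narrow)
        a = object_mean(stack, truth, 1)
        b = object_mean(rgb, truth, 1)
        assert b == pytest.approx(a, abs=0.02)

    def test_empty_wavelength_grid_rejected(self):
        with pytest.raises(ValueError, match="empty|cover"):
            CameraModel(grid_nm=np.array([]))

    def test_camera_responses_nonnegative_unit_peak(self):
        cam = CameraModel()
        for resp in cam.effective_responses().values():
            assert resp.min() >= 0
            assert resp.max() == pytest.approx(1.0)


class TestEvaluationSet:
    def test_deterministic_csv(self, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        make_evaluation_set(n_samples=6, seed=3, csv_path=p1)
        make_evaluation_set(n_samples=6, seed=3, csv_path=p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_rank_correlation_with_true_concentration(self):
        t = make_evaluation_set(n_samples=25, model=ForwardModel(noise_sd=0.0), seed=4)
        rho = spearmanr(t["NDAI"], t["concentration_ug_g"]).statistic
        assert rho >= 0.99

    def test_ndai_outranks_noise_dummy_by_aic(self):
        from ndaikit import compare_indices

        t = make_evaluation_set(
            n_samples=25, model=ForwardModel(noise_sd=0.02), seed=5,
            include_noise_dummy=True,
        )
        report = compare_indices(t.drop(columns=["sample_id"]))
        ranks = {row["Index"]: i for i, row in report.iterrows()}
        assert ranks["NDAI"] < ranks["noise_dummy"]

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            make_evaluation_set(n_samples=4)
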