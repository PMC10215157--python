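"""Synthetic-histology generator: profiles, sampling, rendering, datasets."""

import dataclasses

import numpy as np
import pytest

import vacuoquant as vq
from vacuoquant.synth import (
    MIN_PLANT_AREA,
    _sample_areas,
    lognormal_area_params,
    rasterize_vacuole,
)


class TestGroupProfiles:
    def test_packaged_calibration_defaults(self):
        assert vq.generate_group_profile("CONTROL").area_mean == pytest.approx(88.4908)
        assert vq.generate_group_profile("TMG").vd_presence_prob == pytest.approx(0.90)
        assert vq.generate_group_profile("CMG").vd_presence_prob == pytest.approx(0.75)
        assert vq.generate_group_profile("CEG").vd_presence_prob == pytest.approx(0.66)
        assert vq.generate_group_profile("CONTROL").vd_presence_prob == pytest.approx(0.50)

    def test_axis_ratio_reflects_group_eccentricity(self):
        # mean eccentricity ~0.78 in every group -> minor/major ~0.62
        for g in vq.GROUPS:
            p = vq.generate_group_profile(g)
            ecc = np.sqrt(1 - p.axis_ratio_mean**2)
            assert 0.77 < ecc < 0.80

    def test_unknown_group_names_valid_groups(self):
        with pytest.raises(ValueError, match="CONTROL, TMG, CMG, CEG"):
            vq.generate_group_profile("XYZ")

    def test_overrides_and_invariant_validation(self):
        p = vq.generate_group_profile("TMG", {"area_mean": 10.0})
        assert p.area_mean == 10.0
        with pytest.raises(ValueError):
            vq.generate_group_profile("TMG", {"area_mean": -1.0})
        with pytest.raises(ValueError):
            vq.generate_group_profile("TMG", {"vd_presence_prob": 1.5})
        with pytest.raises(ValueError):
            vq.generate_group_profile("TMG", {"axis_ratio_mean": 0.0})


class TestVacuoleSampler:
    def test_zero_lesions_gives_empty_list(self):
        p = vq.generate_group_profile("CONTROL")
        assert vq.sample_vacuoles(p, 0, 1) == []

    def test_deterministic_given_seed(self):
        p = vq.generate_group_profile("CMG")
        a = vq.sample_vacuoles(p, 10, 7, canvas=(400, 400))
        b = vq.sample_vacuoles(p, 10, 7, canvas=(400, 400))
        assert a == b

    def test_zero_dispersion_plants_constant_areas(self):
        p = vq.generate_group_profile("TMG", {"area_sd": 0.0, "lesion_count_range": (1, 1)})
        specs = vq.sample_vacuoles(p, 1000, 3, canvas=(2000, 2000))
        areas = np.array([s.planted_area for s in specs])
        assert np.allclose(areas, p.area_mean, rtol=1e-9)

    def test_sampler_moments_match_profile_targets(self):
        # long-run mean/SD of planted areas converge to the profile's
        for g in ("CONTROL", "CEG"):
            p = vq.generate_group_profile(g)
            rng = np.random.default_rng(0)
            x = _sample_areas(p, 200_000, rng)
            assert x.min() >= MIN_PLANT_AREA
            assert x.mean() == pytest.approx(p.area_mean, rel=0.03)
            assert x.std() == pytest.approx(p.area_sd, rel=0.05)

    def test_truncated_moment_matching_is_exact(self):
        from vacuoquant.synth import _truncated_lognormal_moments

        mu, sigma = lognormal_area_params(88.4908, 231.7392)
        m, s = _truncated_lognormal_moments(mu, sigma, MIN_PLANT_AREA)
        assert m == pytest.approx(88.4908, rel=1e-6)
        assert s == pytest.approx(231.7392, rel=1e-6)

    def test_specs_fit_canvas_and_do_not_overlap(self):
        p = vq.generate_group_profile("TMG")
        specs = vq.sample_vacuoles(p, 25, 11, canvas=(500, 500))
        union = np.zeros((500, 500), dtype=bool)
        total = 0
        for s in specs:
            m = rasterize_vacuole(s, (500, 500))
            total += m.sum()
            union |= m
        assert union.sum() == total  # pairwise disjoint

    def test_canvas_too_small_raises(self):
        p = vq.generate_group_profile("TMG", {"area_mean": 5000.0, "area_sd": 0.0})
        with pytest.raises(ValueError):
            vq.sample_vacuoles(p, 40, 1, canvas=(120, 120))


class TestRenderImage:
    def test_lesion_pixels_near_white_before_noise(self):
        spec = vq.VacuoleSpec(center=(60, 60), major_axis=30, minor_axis=20, orientation=0.4)
        rec = vq.render_image([spec], canvas=(128, 128), rng_seed=2, noise_sd=0.0)
        truth_px = rasterize_vacuole(spec, (128, 128))
        assert rec.image[truth_px].min() >= 240

    def test_overlapping_specs_rejected(self):
        a = vq.VacuoleSpec(center=(50, 50), major_axis=30, minor_axis=30, orientation=0)
        b = vq.VacuoleSpec(center=(55, 55), major_axis=30, minor_axis=30, orientation=0)
        with pytest.raises(ValueError, match="overlap"):
            vq.render_image([a, b], canvas=(128, 128))

    def test_vein_fully_covered_by_exclusion_mask(self):
        rec = vq.render_image([], canvas=(300, 300), with_vein=True, rng_seed=9)
        assert rec.exclusion_mask is not None
        white = np.all(rec.image >= 200, axis=-1)
        # the only large white blob is the vein; it must lie inside the mask
        from skimage.measure import label

        lab = label(white, connectivity=2)
        sizes = np.bincount(lab.ravel())
        big = sizes[1:].argmax() + 1
        assert rec.exclusion_mask[lab == big].all()

    def test_roughness_perturbs_boundary_but_keeps_area(self):
        smooth = vq.VacuoleSpec(center=(64, 64), major_axis=40, minor_axis=30, orientation=0.2)
        rough = dataclasses.replace(smooth, roughness=0.15, roughness_seed=5)
        m_smooth = rasterize_vacuole(smooth, (128, 128))
        m_rough = rasterize_vacuole(rough, (128, 128))
        assert (m_smooth ^ m_rough).any()
        assert m_rough.sum() == pytest.approx(m_smooth.sum(), rel=0.25)


class TestMakeDataset:
    def test_small_config_counts_and_manifest(self, tmp_path):
        cfg = {"counts": {"CONTROL": 2, "TMG": 2}, "canvas": [256, 256],
               "profiles": {g: {"lesion_count_range": [3, 6]} for g in ("CONTROL", "TMG")}}
        records, manifest, truth = vq.make_dataset(cfg, 5, tmp_path)
        assert len(records) == 4
        assert len(manifest) == 4
        assert list(manifest.columns) == ["path", "mask_path", "group", "vd_present", "seed"]
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "truth.csv").exists()
        # truth rows only for VD-present images
        assert set(truth.image_id) == {
            r.image_id for r in records if r.vd_present
        }

    def test_rerun_same_seed_is_byte_identical(self, tmp_path):
        cfg = {"counts": {"CONTROL": 2, "CMG": 1}, "canvas": [256, 256],
               "profiles": {g: {"lesion_count_range": [3, 6]} for g in ("CONTROL", "CMG")}}
        a, b = tmp_path / "a", tmp_path / "b"
        vq.make_dataset(cfg, 99, a)
        vq.make_dataset(cfg, 99, b)
        files = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
        assert files
        for f in files:
            assert (a / f).read_bytes() == (b / f).read_bytes(), f

    def test_adding_a_group_preserves_existing_images(self):
        cfg1 = {"counts": {"CONTROL": 2}, "canvas": [256, 256],
                "profiles": {"CONTROL": {"lesion_count_range": [3, 6]}}}
        cfg2 = {"counts": {"CONTROL": 2, "CEG": 1}, "canvas": [256, 256],
                "profiles": {"CONTROL": {"lesion_count_range": [3, 6]},
                             "CEG": {"lesion_count_range": [3, 6]}}}
        r1, _, _ = vq.make_dataset(cfg1, 17)
        r2, _, _ = vq.make_dataset(cfg2, 17)
        for a, b in zip(r1, [r for r in r2 if r.group == "CONTROL"]):
            assert np.array_equal(a.image, b.image)

    def test_mask_coverage_invariant(self, default_dataset):
        records, _, _ = default_dataset
        for rec in records:
            assert rec.exclusion_mask is not None
            # vein pixels (large bright area under the mask) never leak into truth
            for spec in rec.truth:
                m = rasterize_vacuole(spec, rec.image.shape[:2])
                assert not (m & rec.exclusion_mask).any()


class TestCalibrationRecovery:
    def test_pipeline_recovers_profile_area_means(self, region_rich_dataset):
        """Pooled measured areas match the planted population and the
        group profile targets (10%) through the full pipeline."""
        regions, manifest, planted_mean = region_rich_dataset
        merged = regions.merge(manifest[["image_id", "group"]], on="image_id")
        for g in vq.GROUPS:
            areas = merged.loc[merged.group == g, "area"].to_numpy()
            assert len(areas) >= 500
            measured = areas.mean()
            # no pipeline bias: measured vs planted rasterized truth
            assert measured == pytest.approx(planted_mean[g], rel=0.02)
            # calibration: measured vs profile target
            target = vq.generate_group_profile(g).area_mean
            assert measured == pytest.approx(target, rel=0.10)
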