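import numpy as np
import pytest
from scipy import ndimage

from ccvoid.dataio import read_manifest
from ccvoid.errors import InvalidSpecError
from ccvoid.masking import rasterize_faz
from ccvoid.synthetic import (CCSpec, StudySpec, SVPSpec, generate_bscan,
                              generate_cc_angiogram, generate_diurnal_study,
                              generate_svp_angiogram, sample_thickness_truths,
                              simulate_graders)


class TestCCGenerator:
    def test_zero_fraction_no_voids(self):
        _, truth = generate_cc_angiogram(CCSpec(void_fraction=0.0))
        assert truth.true_count == 0
        assert truth.true_density_pct == 0.0

    def test_density_lands_on_target(self):
        """Blob placement stops within one blob of the requested fraction."""
        _, truth = generate_cc_angiogram(CCSpec(void_fraction=0.16, seed=7))
        assert abs(truth.true_density_pct - 16.0) <= 1.0

    def test_seeded_determinism(self):
        spec = CCSpec(void_fraction=0.16, seed=11)
        a, ta = generate_cc_angiogram(spec)
        b, tb = generate_cc_angiogram(spec)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        np.testing.assert_array_equal(ta.void_mask.pixels, tb.void_mask.pixels)

    def test_truth_self_consistency(self):
        """density * area = count * mean size, exactly, in pixel units."""
        spec = CCSpec(grid_size=128, void_fraction=0.2, seed=3)
        _, truth = generate_cc_angiogram(spec)
        n = spec.grid_size
        area_um2 = n * n * spec.lateral_scale_um ** 2
        lhs = truth.true_density_pct * area_um2 / 100.0
        rhs = truth.true_count * truth.true_mean_size_um2
        assert lhs == pytest.approx(rhs, rel=1e-12)
        # and the mask itself agrees
        _, count = ndimage.label(truth.void_mask.pixels, np.ones((3, 3)))
        assert count == truth.true_count

    def test_invalid_specs_rejected(self):
        with pytest.raises(InvalidSpecError):
            CCSpec(void_fraction=1.0)
        with pytest.raises(InvalidSpecError):
            CCSpec(void_level=200.0, background_level=160.0)
        with pytest.raises(InvalidSpecError):
            CCSpec(grid_size=16)

    def test_void_pixels_darker_than_background(self):
        img, truth = generate_cc_angiogram(CCSpec(grid_size=96, seed=2))
        voids = truth.void_mask.pixels
        assert img.pixels[voids].mean() < img.pixels[~voids].mean()


class TestSVPGenerator:
    def test_zero_vessels_empty_truth(self):
        _, truth = generate_svp_angiogram(SVPSpec(n_vessels=0))
        assert truth.large_vessel_mask.area_px() == 0

    def test_vessel_fraction_near_request(self):
        _, truth = generate_svp_angiogram(SVPSpec(seed=1))
        realized = truth.large_vessel_mask.pixels.mean()
        assert realized == pytest.approx(0.10, abs=0.02)

    def test_zero_faz_radius_empty_polygon(self):
        _, truth = generate_svp_angiogram(SVPSpec(faz_radius_um=0.0))
        assert truth.faz_polygon == []

    def test_faz_region_is_dark(self):
        img, truth = generate_svp_angiogram(SVPSpec(seed=4))
        faz = rasterize_faz(truth.faz_polygon, img.shape).pixels
        assert img.pixels[faz].mean() < img.pixels[~faz].mean()

    def test_oversized_footprint_rejected(self):
        with pytest.raises(InvalidSpecError):
            SVPSpec(vessel_fraction=0.9)

    def test_seeded_determinism(self):
        a, _ = generate_svp_angiogram(SVPSpec(seed=8))
        b, _ = generate_svp_angiogram(SVPSpec(seed=8))
        np.testing.assert_array_equal(a.pixels, b.pixels)


class TestStudyGenerator:
    def test_delta_arithmetic_with_zero_noise(self):
        """With zero measurement noise the per-timepoint truth means differ
        by exactly the injected diurnal deltas."""
        deltas = (0.0, -2.0, -4.1, -2.0, -3.9)
        spec = StudySpec(n_subjects=6, n_visits=1,
                         thickness_diurnal_deltas=deltas,
                         thickness_noise_sd=0.0, thickness_baseline_sd=20.0,
                         seed=5)
        df = sample_thickness_truths(spec, np.random.default_rng(5))
        means = df.groupby("timepoint", sort=False)["choroidal_um"].mean()
        baseline = means.iloc[0]
        for j, d in enumerate(deltas):
            assert means.iloc[j] - baseline == pytest.approx(d, abs=1e-9)

    def test_all_zero_deltas_and_noise_constant_series(self):
        spec = StudySpec(n_subjects=3, n_visits=1,
                         thickness_diurnal_deltas=(0.0,) * 5,
                         thickness_noise_sd=0.0, seed=1)
        df = sample_thickness_truths(spec, np.random.default_rng(1))
        per_subject = df.groupby("subject_id")["choroidal_um"].nunique()
        assert (per_subject == 1).all()

    def test_distributional_contract(self):
        """Across 200 replicate draws the empirical mean at each timepoint
        stays within 3 standard errors of baseline_mean + delta."""
        deltas = (0.0, -2.0, -4.1, -2.0, -3.9)
        spec = StudySpec(n_subjects=14, n_visits=1,
                         thickness_baseline_mean=297.7,
                         thickness_baseline_sd=20.0,
                         thickness_diurnal_deltas=deltas,
                         thickness_noise_sd=1.5, seed=0)
        rng = np.random.default_rng(123)
        sums = np.zeros(5)
        n_per_tp = 200 * spec.n_subjects
        for _ in range(200):
            df = sample_thickness_truths(spec, rng)
            sums += df.groupby("timepoint", sort=False)["choroidal_um"].mean().to_numpy()
        means = sums / 200
        se = np.sqrt(spec.thickness_baseline_sd ** 2
                     + spec.thickness_noise_sd ** 2) / np.sqrt(n_per_tp)
        for j, d in enumerate(deltas):
            assert abs(means[j] - (297.7 + d)) <= 3 * se

    def test_manifest_record_counts(self, tmp_path):
        """14 subjects x 2 visits x 5 timepoints = 140 records per slab."""
        spec = StudySpec(n_subjects=14, n_visits=2,
                         cc_spec=CCSpec(grid_size=64),
                         thickness_baseline_sd=20.0, seed=9)
        manifest = read_manifest(generate_diurnal_study(spec, tmp_path / "s"))
        per_slab = manifest.records.groupby("slab").size()
        assert set(per_slab.index) == {"CC", "SVP", "DVP", "BSCAN"}
        assert (per_slab == 140).all()

    def test_mismatched_delta_length_rejected(self):
        with pytest.raises(InvalidSpecError):
            StudySpec(thickness_diurnal_deltas=(0.0, 1.0))

    def test_study_files_deterministic(self, tmp_path):
        spec = StudySpec(n_subjects=2, n_visits=1, cc_spec=CCSpec(grid_size=64),
                         thickness_baseline_sd=20.0, seed=21)
        p1 = generate_diurnal_study(spec, tmp_path / "a")
        p2 = generate_diurnal_study(spec, tmp_path / "b")
        for f1 in sorted(p1.parent.iterdir()):
            f2 = p2.parent / f1.name
            assert f1.read_bytes() == f2.read_bytes(), f1.name


class TestBScanGeneratorContract:
    def test_foveal_column_is_thinnest(self):
        bscan, _ = generate_bscan(
            __import__("ccvoid.synthetic", fromlist=["BScanSpec"]).BScanSpec(seed=0))
        gaps = bscan.boundaries["rpe_row"] - bscan.boundaries["ilm_row"]
        assert gaps.idxmin() == len(gaps) // 2


def test_simulate_graders_reliability(rng):
    """Grader noise small relative to between-subject spread gives the
    near-perfect agreement reported for thickness grading."""
    from ccvoid.stats import icc
    truths = rng.normal(297.7, 92.1, size=28)
    ratings = simulate_graders(truths, n_graders=2, noise_sd=9.0, seed=1)
    assert icc(ratings, "icc2_1").icc > 0.95
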