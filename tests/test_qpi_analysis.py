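"""Segmentation, dry density, expression, LD statistics and Mann-Whitney."""

import math
from itertools import combinations

import numpy as np
import pytest

from airyqpi.image_formation import ImageStack3D
from airyqpi.qpi_analysis import (
    AnalysisConfig,
    DryDensityParams,
    PhaseImage,
    analyze_cells,
    classify_localization,
    dry_density,
    expression_level,
    ld_surface_coverage,
    mann_whitney,
    records_to_dataframe,
    segment_by_phase,
)
from airyqpi.synthetic_phantoms import (
    SceneParams,
    generate_cell_scene,
    scene_to_fluor,
    scene_to_phase,
    scene_truth_masks,
)


class TestDryDensity:
    def test_zero_phase_zero_density(self):
        assert dry_density(0.0) == 0.0

    def test_hand_computed_value_six_significant_figures(self):
        # rho = lambda <Phi> / (2 pi dn/dc): 5e-7 m / (2 pi 1.85e-4 m^3/kg)
        # = 4.30148...e-4 kg/m^2 = 0.430148... pg/um^2
        expected_kg_m2 = 5.0e-7 / (2.0 * math.pi * 1.85e-4)
        got = dry_density(1.0, DryDensityParams(0.5, 1.85e-4))
        assert got == pytest.approx(expected_kg_m2 * 1e3, rel=1e-7)

    def test_linearity_exact(self):
        assert dry_density(2.6) == 2.0 * dry_density(1.3)


class TestSegmentation:
    def test_blank_image_empty(self):
        assert segment_by_phase(PhaseImage(np.zeros((64, 64)), 0.1), 0.5) == []

    def test_five_cells_recovered_with_high_dice(self):
        params = SceneParams(field_size_um=(30.0, 30.0), cytosol_phase_per_um=0.55,
                             ld_count_range=(0, 0))
        scene = generate_cell_scene(5, params, seed=11)
        phase = scene_to_phase(scene, 0.1)
        regions = segment_by_phase(phase, 0.5, min_area=3.0)
        assert len(regions) == 5
        truths = scene_truth_masks(scene, 0.1)
        for truth in truths:
            overlaps = [(m & truth).sum() for m in regions]
            m = regions[int(np.argmax(overlaps))]
            dice = 2.0 * (m & truth).sum() / (m.sum() + truth.sum())
            assert dice >= 0.95

    def test_ld_mask_nested_in_cell_mask(self):
        params = SceneParams(field_size_um=(20.0, 20.0), ld_count_range=(1, 1))
        scene = generate_cell_scene(1, params, seed=2)
        phase = scene_to_phase(scene, 0.1)
        cells = segment_by_phase(phase, 0.4, 3.0)
        lds = segment_by_phase(phase, 1.8, 0.05)
        assert cells and lds
        assert np.all(cells[0][lds[0]])  # strict containment

    def test_min_area_filters_specks(self):
        img = np.zeros((100, 100))
        img[50, 50] = 5.0  # single-pixel speck: 0.01 um^2 at 0.1 um pitch
        img[10:40, 10:40] = 2.0
        regions = segment_by_phase(PhaseImage(img, 0.1), 0.5, min_area=1.0)
        assert len(regions) == 1


class TestExpression:
    def test_uniform_stack_zero(self):
        stack = ImageStack3D(np.full((4, 16, 16), 9.0), (0.1, 0.1, 0.2))
        mask = np.zeros((16, 16), bool)
        mask[2:6, 2:6] = True
        bg = ~mask
        assert expression_level(stack, mask, bg) == 0.0

    def test_constructed_difference(self):
        vox = np.full((4, 16, 16), 100.0)
        mask = np.zeros((16, 16), bool)
        mask[2:6, 2:6] = True
        vox[:, mask] = 150.0
        stack = ImageStack3D(vox, (0.1, 0.1, 0.2))
        assert expression_level(stack, mask, ~mask) == pytest.approx(50.0)

    def test_offset_invariance(self):
        rng = np.random.default_rng(0)
        vox = rng.uniform(50, 150, size=(4, 16, 16))
        mask = np.zeros((16, 16), bool)
        mask[3:9, 3:9] = True
        a = expression_level(ImageStack3D(vox, (0.1, 0.1, 0.2)), mask, ~mask)
        b = expression_level(ImageStack3D(vox + 37.0, (0.1, 0.1, 0.2)), mask, ~mask)
        assert b == pytest.approx(a, abs=1e-9)

    def test_empty_region_rejected(self):
        stack = ImageStack3D(np.ones((2, 8, 8)), (0.1, 0.1, 0.2))
        with pytest.raises(ValueError, match="empty"):
            expression_level(stack, np.zeros((8, 8), bool), np.ones((8, 8), bool))


def shell_stack(r=0.5, shell_frac=0.9, pitch=(0.1, 0.1, 0.1), n=48, background=0.0):
    """Flux split between an LD shell and a uniform cloud."""
    c = n // 2 * pitch[0]
    z, y, x = np.meshgrid(*(np.arange(n) * p for p in pitch[::-1]), indexing="ij")
    dist = np.sqrt((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)
    shell = np.abs(dist - r) <= 0.1
    cloud = dist <= 2.0
    vox = np.zeros((n, n, n))
    vox[shell] = shell_frac * 1000.0 / shell.sum()
    vox[cloud] += (1 - shell_frac) * 1000.0 / cloud.sum()
    return ImageStack3D(vox + background, pitch), (c, c, c)


class TestLocalization:
    def test_shell_dominated_flux_is_localized(self):
        stack, center = shell_stack(shell_frac=0.9)
        assert classify_localization(stack, center, 1.0) == "localized"

    def test_uniform_cytosolic_flux_is_diffusive(self):
        # uniform flux in a 5.3 um cell versus a 1 um LD shell: the geometric
        # shell fraction is far below 0.5
        pitch = (0.1, 0.1, 0.2)
        n = (40, 64, 64)
        c = (3.2, 3.2, 4.0)
        z, y, x = np.meshgrid(np.arange(n[0]) * pitch[2], np.arange(n[1]) * pitch[1],
                              np.arange(n[2]) * pitch[0], indexing="ij")
        cell = ((x - c[0]) / 2.65) ** 2 + ((y - c[1]) / 1.85) ** 2 + (
            (z - c[2]) / 1.85) ** 2 <= 1.0
        vox = np.where(cell, 100.0, 0.0)
        stack = ImageStack3D(vox, pitch)
        assert classify_localization(stack, c, 1.0) == "diffusive"

    def test_no_ld_is_diffusive_by_contract(self):
        stack, _ = shell_stack()
        assert classify_localization(stack, None, 1.0) == "diffusive"


class TestCoverage:
    def test_no_supra_threshold_voxels(self):
        stack = ImageStack3D(np.full((32, 32, 32), 1.0), (0.1, 0.1, 0.1))
        c = (1.6, 1.6, 1.6)
        assert ld_surface_coverage(stack, c, 1.0, intensity_threshold=5.0) == 0.0

    def test_complete_shell_full_coverage(self):
        stack, center = shell_stack(shell_frac=1.0)
        cov = ld_surface_coverage(stack, center, 1.0, intensity_threshold=1e-6)
        assert cov == pytest.approx(100.0)

    def test_hemisphere_matches_brute_force(self):
        # hemispherical cap: brute-force patch enumeration is the oracle
        pitch = (0.1, 0.1, 0.1)
        n = 48
        c = n // 2 * 0.1
        z, y, x = np.meshgrid(*(np.arange(n) * p for p in pitch), indexing="ij")
        dist = np.sqrt((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2)
        r = 0.8
        shell = np.abs(dist - r) <= 0.08
        cap = shell & (z > c)
        vox = np.where(cap, 100.0, 0.0)
        stack = ImageStack3D(vox, pitch)
        got = ld_surface_coverage(stack, (c, c, c), 2 * r, intensity_threshold=1.0)

        diag = math.sqrt(3) * 0.1
        surface = np.abs(dist - r) <= diag / 2.0
        supra = np.argwhere(vox > 1.0) * 0.1
        patches = np.argwhere(surface) * 0.1
        covered = 0
        for p in patches:
            if np.min(np.linalg.norm(supra - p, axis=1)) <= diag * (1 + 1e-9):
                covered += 1
        expected = 100.0 * covered / len(patches)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(50.0, abs=10.0)

    def test_sphere_outside_volume_rejected(self):
        stack = ImageStack3D(np.ones((16, 16, 16)), (0.1, 0.1, 0.1))
        with pytest.raises(ValueError, match="outside"):
            ld_surface_coverage(stack, (0.1, 0.8, 0.8), 1.0)

    def test_radial_mode_extremes(self):
        stack, center = shell_stack(shell_frac=1.0)
        # a complete shell reads full coverage up to patch-discretisation
        # scatter in the projected per-patch flux
        assert ld_surface_coverage(stack, center, 1.0, mode="radial",
                                   background=0.0) == pytest.approx(100.0, abs=3.0)
        empty = ImageStack3D(np.zeros((32, 32, 32)), (0.1, 0.1, 0.1))
        assert ld_surface_coverage(empty, (1.6, 1.6, 1.6), 1.0, mode="radial") == 0.0


class TestMannWhitney:
    def test_separated_samples_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_samples_midranks(self):
        res = mann_whitney([5, 5, 5, 5], [5, 5, 5, 5])
        assert res.u_statistic == pytest.approx(16 / 2)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=6), rng.normal(1.0, 1.0, size=7)
        r1, r2 = mann_whitney(a, b), mann_whitney(b, a)
        assert r1.u_statistic + r2.u_statistic == pytest.approx(42.0)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_exact_matches_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(9)
        a, b = rng.normal(size=7), rng.normal(0.8, 1.0, size=6)
        ours = mann_whitney(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.u_statistic == pytest.approx(ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approximation_matches_scipy(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(size=30), rng.normal(0.5, 1.0, size=30)
        ours = mann_whitney(a, b)
        assert ours.method == "normal-approximation"
        from scipy.stats import mannwhitneyu

        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_power_at_one_sd_effect(self):
        # normal shift of 1 SD, n = 30 per group: >= 80% rejection at 0.05
        rng = np.random.default_rng(42)
        rejected = 0
        for _ in range(200):
            a = rng.normal(0.0, 1.0, 30)
            b = rng.normal(1.0, 1.0, 30)
            if mann_whitney(a, b).p_value < 0.05:
                rejected += 1
        assert rejected / 200 >= 0.80

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestAnalyzeCells:
    def test_empty_phase_image(self, cell_psf):
        phase = PhaseImage(np.zeros((120, 120)), 0.12)
        fluor = ImageStack3D(np.full((20, 120, 120), 10.0), (0.12, 0.12, 0.24))
        assert analyze_cells(phase, fluor) == []

    def test_registration_mismatch_rejected(self, cell_psf):
        phase = PhaseImage(np.zeros((100, 100)), 0.12)
        fluor = ImageStack3D(np.full((20, 120, 120), 10.0), (0.12, 0.12, 0.24))
        with pytest.raises(ValueError):
            analyze_cells(phase, fluor)

    def test_ten_cell_phantom_recovery(self, cell_psf):
        params = SceneParams(field_size_um=(42.0, 42.0), z_extent_um=8.0)
        scene = generate_cell_scene(10, params, seed=5)
        pitch = cell_psf.pitch
        phase = scene_to_phase(scene, pitch.x, noise_sd=0.05, noise_seed=105)
        noiseless = scene_to_phase(scene, pitch.x)
        fluor = scene_to_fluor(scene, cell_psf, pitch=pitch, noise_seed=205)
        records = analyze_cells(phase, fluor)
        assert len(records) == 10

        # dry density against the noiseless map over each record's own ROI
        masks = segment_by_phase(phase, AnalysisConfig().cell_threshold_rad, 3.0)
        for rec, mask in zip(records, masks):
            truth_density = dry_density(float(noiseless.phase[mask].mean()))
            assert rec.dry_density_pg_um2 == pytest.approx(truth_density, rel=0.05)

        # per-cell dry mass against the analytic ellipsoid + droplet integral
        lam_factor = dry_density(1.0)  # pg/um^2 per radian
        analytic = {
            i: lam_factor * (scene.params.cytosol_phase_per_um
                             * cell.phase_area_integral()
                             + cell.ld_phase_area_integral())
            for i, cell in enumerate(scene.cells)
        }
        truths = scene_truth_masks(scene, pitch.x)
        for rec, mask in zip(records, masks):
            overlaps = [(mask & t).sum() for t in truths]
            i = int(np.argmax(overlaps))
            measured_mass = rec.dry_density_pg_um2 * rec.area_um2
            assert measured_mass == pytest.approx(analytic[i], rel=0.05)

        df = records_to_dataframe(records)
        assert set(df["localization"]) <= {"localized", "diffusive"}
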