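"""Phantom construction, the dual-wavelength forward model, and the
round-trip recovery properties that anchor the whole pipeline."""

import numpy as np
import pytest

from paquant import (
    ConfigurationError,
    Ellipsoid,
    ForwardModelConfig,
    GeometryError,
    PhantomSpec,
    VesselSegment,
    build_phantom,
    compute_so2,
    forward_project,
    generate_cohort,
    normalize_by_energy,
)

from .conftest import simple_tumour_spec


class TestBuildPhantom:
    def test_tumour_only_truth_field(self):
        """No vessels, empty background: truth SO2 exists exactly on tumour voxels."""
        spec = simple_tumour_spec(background_thb=0.0, tumour_so2=0.7)
        ph = build_phantom(spec)
        truth = ph.truth_so2
        assert ph.tumour_mask.count > 0
        np.testing.assert_allclose(truth[ph.tumour_mask.data], 0.7)
        assert np.isnan(truth[~ph.tumour_mask.data]).all()

    def test_vessel_capsule_matches_exhaustive_distance_oracle(self):
        """Painted vessel voxels are exactly those within the capsule radius."""
        # axis placed off-lattice so no voxel centre sits exactly at the radius
        seg = VesselSegment(p0=(1.0, 4.05, 3.95), p1=(6.5, 4.05, 3.95), radius=0.5, so2=0.9, thb=2e-3)
        spec = simple_tumour_spec(background_thb=0.0, vessel_segments=(seg,))
        ph = build_phantom(spec)
        vessel = ph.c_hb == seg.thb * seg.so2  # painted last, distinct value

        dz, dy, dx = spec.voxel_size
        p0, p1 = np.array(seg.p0), np.array(seg.p1)
        d = p1 - p0
        count = 0
        oracle = np.zeros(spec.grid_shape, dtype=bool)
        for i in range(spec.grid_shape[0]):
            for j in range(spec.grid_shape[1]):
                for k in range(spec.grid_shape[2]):
                    p = np.array([i * dz, j * dy, k * dx])
                    t = np.clip(np.dot(p - p0, d) / np.dot(d, d), 0, 1)
                    if np.linalg.norm(p - (p0 + t * d)) <= seg.radius:
                        oracle[i, j, k] = True
                        count += 1
        np.testing.assert_array_equal(vessel, oracle)
        # analytic capsule volume: pi r^2 L + 4/3 pi r^3, within 20% at r = 2 voxels
        L = np.linalg.norm(d)
        analytic = (np.pi * seg.radius**2 * L + 4 / 3 * np.pi * seg.radius**3) / (dz * dy * dx)
        assert abs(count - analytic) / analytic < 0.20

    def test_later_vessel_wins_on_overlap(self):
        a = VesselSegment(p0=(2, 4, 4), p1=(6, 4, 4), radius=0.5, so2=0.2, thb=1e-3)
        b = VesselSegment(p0=(4, 2, 4), p1=(4, 6, 4), radius=0.5, so2=0.9, thb=1e-3)
        spec = simple_tumour_spec(background_thb=0.0, vessel_segments=(a, b))
        ph = build_phantom(spec)
        # the crossing point belongs to both capsules; the later one wins
        i, j, k = (int(round(4 / s)) for s in spec.voxel_size)
        assert ph.truth_so2[i, j, k] == pytest.approx(0.9)

    def test_determinism(self):
        spec = simple_tumour_spec(seed=42)
        a, b = build_phantom(spec), build_phantom(spec)
        np.testing.assert_array_equal(a.c_hb, b.c_hb)
        np.testing.assert_array_equal(a.c_dehb, b.c_dehb)
        np.testing.assert_array_equal(a.tumour_mask.data, b.tumour_mask.data)

    def test_tumour_outside_grid_rejected(self):
        with pytest.raises(GeometryError, match="outside the grid"):
            simple_tumour_spec(
                tumour_ellipsoid=Ellipsoid(
                    center=[7.5, 4, 4], semi_axes=[3, 1, 1], orientation=np.eye(3)
                )
            )

    def test_contours_trace_the_tumour_cross_sections(self):
        ph = build_phantom(simple_tumour_spec())
        assert len(ph.contour_stack) > 0
        for sl in ph.contour_stack.slices:
            for poly in sl.polygons:
                assert len(poly) >= 16
                pts = np.column_stack([np.full(len(poly), sl.position), poly[:, 1], poly[:, 0]])
                # vertices lie on the generating ellipsoid surface
                np.testing.assert_allclose(
                    ph.spec.tumour_ellipsoid.mahalanobis(pts), 1.0, atol=1e-9
                )


class TestForwardProject:
    def test_unit_factor_signal_is_the_absorption_sum(self, ext, noise_free_case):
        phantom, volume = noise_free_case
        for wl in (750.0, 830.0):
            eo, ed = ext.coefficients(wl)
            np.testing.assert_allclose(
                volume.stacks[wl], phantom.c_hb * eo + phantom.c_dehb * ed, rtol=1e-12
            )

    def test_equal_attenuation_makes_wavelength_ratio_depth_independent(self, ext):
        """With equal mu at both wavelengths, fluence cancels in the ratio."""
        spec = simple_tumour_spec(background_thb=50e-6)
        ph = build_phantom(spec)
        cfg = ForwardModelConfig(
            effective_attenuation={750.0: 0.25, 830.0: 0.25},
            surface_fluence={750.0: 2.0, 830.0: 3.0},
        )
        vol = forward_project(ph, ext, cfg)
        ratio = vol.stacks[750.0] / vol.stacks[830.0]
        # rows outside the tumour share the background composition: the ratio
        # there must not vary with depth despite the exponential decay
        bg = ~ph.tumour_mask.data
        per_row = [ratio[:, j, :][bg[:, j, :]] for j in range(spec.grid_shape[1])]
        means = np.array([r.mean() for r in per_row if r.size])
        np.testing.assert_allclose(means, means[0], rtol=1e-12)

    def test_linearity_in_concentration(self, ext):
        spec1 = simple_tumour_spec(background_thb=20e-6, tumour_thb=100e-6)
        spec2 = simple_tumour_spec(background_thb=40e-6, tumour_thb=200e-6)
        v1 = forward_project(build_phantom(spec1), ext, ForwardModelConfig())
        v2 = forward_project(build_phantom(spec2), ext, ForwardModelConfig())
        for wl in (750.0, 830.0):
            np.testing.assert_allclose(v2.stacks[wl], 2 * v1.stacks[wl], rtol=1e-12)

    def test_missing_wavelength_in_extinction_is_configuration_error(self, ext, noise_free_case):
        phantom, _ = noise_free_case
        cfg = ForwardModelConfig(
            surface_fluence={750.0: 1.0, 805.0: 1.0},
            effective_attenuation={750.0: 0.0, 805.0: 0.0},
        )
        with pytest.raises(ConfigurationError):
            forward_project(phantom, ext, cfg)

    def test_frame_energies_recorded(self, ext):
        ph = build_phantom(simple_tumour_spec())
        vol = forward_project(ph, ext, ForwardModelConfig(energy_jitter_sd=0.05, seed=9))
        for wl in (750.0, 830.0):
            e = vol.frame_energies[wl]
            assert e.shape == (ph.spec.grid_shape[0],)
            assert e.std() > 0


class TestRoundTrip:
    def test_noise_free_recovery_to_1e9(self, ext, noise_free_case):
        phantom, volume = noise_free_case
        so2 = compute_so2(normalize_by_energy(volume), ext, floor_quantile=0.0)
        truth = phantom.truth_so2
        ok = np.isfinite(truth)
        assert np.nanmax(np.abs(so2.so2[ok] - truth[ok])) <= 1e-9

    def test_energy_jitter_recovery_after_normalization(self, ext):
        phantom = build_phantom(simple_tumour_spec())
        jittered = forward_project(
            phantom, ext, ForwardModelConfig(energy_jitter_sd=0.10, seed=77)
        )
        so2 = compute_so2(normalize_by_energy(jittered), ext, floor_quantile=0.0)
        truth = phantom.truth_so2
        ok = np.isfinite(truth)
        assert np.nanmax(np.abs(so2.so2[ok] - truth[ok])) <= 1e-9

    def test_rms_error_grows_with_noise(self, ext):
        """Voxelwise RMS SO2 error is non-decreasing in the noise level."""
        errors = []
        for noise_sd in (0.01, 0.05, 0.15):
            spec = simple_tumour_spec(noise_sd=noise_sd, seed=123)
            ph = build_phantom(spec)
            vol = forward_project(ph, ext, ForwardModelConfig())
            so2 = compute_so2(normalize_by_energy(vol), ext, floor_quantile=0.0)
            truth = ph.truth_so2
            ok = np.isfinite(truth) & np.isfinite(so2.so2)
            errors.append(float(np.sqrt(np.mean((so2.so2[ok] - truth[ok]) ** 2))))
        assert errors[0] <= errors[1] <= errors[2]


class TestGenerateCohort:
    KW = dict(
        grid_shape=(24, 32, 36),
        voxel_size=(0.6, 0.5, 0.5),
        size_range_mm=(5.0, 8.0),
        seed=3,
    )

    def test_counts_and_labels(self, ext):
        cases, truth = generate_cohort(8, 16, extinction=ext, **self.KW)
        assert len(cases) == 24
        assert sum(c.group == "benign" for c in cases) == 8
        assert sum(c.group == "malignant" for c in cases) == 16
        assert list(truth["group"]) == [c.group for c in cases]

    def test_zero_sd_collapses_group_distribution(self, ext):
        _, truth = generate_cohort(
            2, 5, extinction=ext,
            group_so2={"benign": (0.78, 0.0), "malignant": (0.71, 0.0)},
            **self.KW,
        )
        mal = truth.loc[truth["group"] == "malignant", "truth_tumour_so2"]
        assert mal.nunique() == 1
        assert mal.iloc[0] == pytest.approx(0.71)

    def test_same_seed_same_truth(self, ext):
        _, t1 = generate_cohort(3, 3, extinction=ext, **self.KW)
        _, t2 = generate_cohort(3, 3, extinction=ext, **self.KW)
        assert t1.equals(t2)

    def test_invalid_group_mean_rejected(self, ext):
        with pytest.raises(ConfigurationError, match="group mean"):
            generate_cohort(
                2, 2, extinction=ext, group_so2={"benign": (1.5, 0.1)}, **self.KW
            )
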