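"""Radial profiles, subvoxel edges, layer widths, gaps, openings."""

import math

import numpy as np
import pytest

from capsidkit import (
    LayerWindow,
    detect_openings,
    edge_position,
    layer_width,
    layer_windows,
    membrane_gap,
    phantom_spec,
    make_phantom,
    radial_profile,
    radius_shift,
    render_section,
    vertex_diameter,
)
from capsidkit.morphometry import MorphometryError, NoEdgeError, RadialProfile

from .conftest import NOISE


def synthetic_profile(fn, r_max=150.0, bin_nm=0.5):
    radii = np.arange(bin_nm / 2, r_max, bin_nm)
    return RadialProfile(
        radii=radii,
        density=fn(radii),
        counts=np.ones_like(radii, dtype=np.int64),
        mode="spherical-3D",
        voxel_size=bin_nm * 10,
    )


def smooth_step_down(r0, sigma=0.5):
    from scipy.special import erf

    return lambda r: 0.5 * (1.0 - erf((r - r0) / (math.sqrt(2) * sigma)))


class TestRadialProfile:
    def test_uniform_ball_plateau(self):
        vol = make_phantom(phantom_spec("Full"), voxel_size=20, seed=1)
        prof = radial_profile(vol)
        inner = prof.density[(prof.radii > 10) & (prof.radii < 60)]
        assert inner.std() < 0.02
        assert inner.mean() == pytest.approx(0.8, abs=0.02)

    def test_thin_shell_peak_position(self):
        vol = make_phantom(phantom_spec("Empty", n_openings=0), voxel_size=10,
                           seed=1)
        prof = radial_profile(vol)
        w = layer_windows()["membrane"]
        sl = prof.window_slice(w)
        peak_r = prof.radii[sl][np.argmax(prof.density[sl])]
        mid = (105.5 + 99.8) / 2  # preset membrane center
        assert peak_r == pytest.approx(mid, abs=1.5)

    def test_density_conservation(self):
        vol = make_phantom(phantom_spec("Full"), voxel_size=20, seed=1)
        prof = radial_profile(vol)
        total_profile = (prof.density * prof.counts).sum() * vol.voxel_nm**3
        assert total_profile == pytest.approx(vol.integral(), rel=1e-6)

    def test_rotation_invariance(self):
        """Spherical profile is unchanged by volume rotation (<0.5% RMS)."""
        from scipy.ndimage import rotate

        vol = make_phantom(phantom_spec("Full"), voxel_size=20, seed=1)
        rotated = rotate(vol.data, 30.0, axes=(1, 2), reshape=False, order=3)
        from capsidkit.phantoms import DensityVolume

        p0 = radial_profile(vol)
        p1 = radial_profile(DensityVolume(rotated, vol.voxel_size))
        sel = p0.radii < 120
        rms = np.sqrt(np.mean((p0.density[sel] - p1.density[sel]) ** 2))
        assert rms < 0.005 * p0.density[sel].max()

    def test_recenter_by_center_of_mass(self):
        vol = make_phantom(phantom_spec("Full"), voxel_size=20, seed=1)
        shifted = np.roll(vol.data, 3, axis=0)
        from capsidkit.phantoms import DensityVolume

        p = radial_profile(DensityVolume(shifted, vol.voxel_size),
                           recenter_tolerance_nm=2.0)
        p0 = radial_profile(vol)
        n = min(len(p.density), len(p0.density))
        sel = p0.radii[:n] < 110
        assert np.abs(p.density[:n][sel] - p0.density[:n][sel]).max() < 0.05


class TestEdgeEstimators:
    def test_step_edge_position(self):
        prof = synthetic_profile(smooth_step_down(130.0))
        w = LayerWindow("edge", 120, 140)
        assert edge_position(prof, w) == pytest.approx(130.0, abs=0.1)

    def test_translation_equivariance(self):
        a = synthetic_profile(smooth_step_down(130.0))
        b = synthetic_profile(smooth_step_down(130.8))
        w = LayerWindow("edge", 120, 140)
        shift = edge_position(b, w) - edge_position(a, w)
        assert shift == pytest.approx(0.8, abs=0.1)

    def test_radius_shift_antisymmetric(self, fine_profiles):
        w = layer_windows()["spike-edge"]
        ab = radius_shift(fine_profiles["Empty"], fine_profiles["Full"], w)
        ba = radius_shift(fine_profiles["Full"], fine_profiles["Empty"], w)
        assert ab == -ba

    def test_identical_profiles_zero_shift(self, fine_profiles):
        w = layer_windows()["membrane"]
        assert radius_shift(fine_profiles["Full"], fine_profiles["Full"], w) == 0.0

    def test_flat_window_raises(self):
        prof = synthetic_profile(lambda r: np.ones_like(r))
        with pytest.raises(NoEdgeError):
            edge_position(prof, LayerWindow("flat", 50, 100))

    def test_gaussian_fwhm_closed_form(self):
        sigma = 3.0
        prof = synthetic_profile(
            lambda r: np.exp(-0.5 * ((r - 100.0) / sigma) ** 2)
        )
        w = LayerWindow("g", 85, 115)
        assert layer_width(prof, w) == pytest.approx(2.3548 * sigma, rel=0.02)

    def test_rectangular_shell_width(self):
        vol = make_phantom(phantom_spec("Full"), voxel_size=10, seed=1)
        prof = radial_profile(vol)
        w = layer_windows()["membrane"]
        assert layer_width(prof, w) == pytest.approx(5.7, abs=0.3)


class TestMembraneGap:
    @pytest.mark.parametrize("gap", [2.0, 4.0, 6.0])
    def test_parameter_recovery(self, gap):
        spec = phantom_spec("Full", membrane_gap=gap)
        prof = radial_profile(make_phantom(spec, voxel_size=10, seed=1))
        assert membrane_gap(prof) == pytest.approx(gap, abs=0.3)

    def test_zero_gap(self):
        spec = phantom_spec("Full", membrane_gap=0.0)
        prof = radial_profile(make_phantom(spec, voxel_size=10, seed=1))
        assert membrane_gap(prof) == pytest.approx(0.0, abs=1.0)

    def test_no_nucleoid_raises(self):
        prof = radial_profile(
            make_phantom(phantom_spec("Empty"), voxel_size=10, seed=1)
        )
        with pytest.raises(MorphometryError):
            membrane_gap(prof)


class TestVertexDiameter:
    def test_sphere_equals_two_radii(self):
        vol = make_phantom(phantom_spec("Full"), voxel_size=10, seed=1)
        d = vertex_diameter(vol, axis=(0.0, 0.0, 1.0))
        assert d == pytest.approx(2 * phantom_spec("Full").capsid_outer_radius,
                                  abs=1.0)

    def test_scale_equivariance(self):
        base = phantom_spec("Full")
        scaled = phantom_spec(
            "Full",
            capsid_outer_radius=base.capsid_outer_radius * 1.1,
            capsid_thickness=base.capsid_thickness * 1.1,
            membrane_outer_radius=base.membrane_outer_radius * 1.1,
            membrane_thickness=base.membrane_thickness * 1.1,
            membrane_gap=base.membrane_gap * 1.1,
            spike_length=base.spike_length * 1.1,
        )
        d0 = vertex_diameter(make_phantom(base, voxel_size=10, seed=1),
                             axis=(0, 0, 1.0))
        d1 = vertex_diameter(make_phantom(scaled, voxel_size=10, seed=1),
                             axis=(0, 0, 1.0))
        assert d1 / d0 == pytest.approx(1.1, rel=0.01)

    def test_orientation_search_matches_known_axis(self):
        vol = make_phantom(phantom_spec("Full"), voxel_size=10, seed=1,
                           faceted=True)
        d_known = vertex_diameter(vol)
        vol.meta["vertex_axis"] = None
        d_found = vertex_diameter(vol)
        assert d_found == pytest.approx(d_known, abs=0.5)


class TestOpenings:
    def test_closed_membrane_no_openings(self):
        vol = make_phantom(phantom_spec("Full"), voxel_size=10, seed=2)
        assert detect_openings(vol) == []

    def test_two_openings_roundtrip(self):
        vol = make_phantom(phantom_spec("Empty"), voxel_size=10, seed=2)
        arcs = detect_openings(vol)
        assert len(arcs) == 2
        for _start, extent in arcs:
            assert extent == pytest.approx(30.0, abs=5.0)

    def test_single_opening_p_empty_geometry(self):
        vol = make_phantom(phantom_spec("Empty", n_openings=1), voxel_size=10,
                           seed=4)
        arcs = detect_openings(vol)
        assert len(arcs) == 1

    def test_noisy_detection_rate(self):
        """Opening count recovered in >=90% of noisy renderings."""
        vol = make_phantom(phantom_spec("Empty"), voxel_size=10, seed=2)
        hits = 0
        n_trials = 30
        for s in range(n_trials):
            sec = render_section(vol, thickness_nm=10.0, noise=NOISE, seed=s)
            try:
                hits += len(detect_openings(sec)) == 2
            except MorphometryError:
                pass
        assert hits >= 0.9 * n_trials

    def test_no_ring_raises(self):
        import numpy as np

        from capsidkit.phantoms import SectionImage

        blank = SectionImage(np.zeros((128, 128), np.float32), 20.0, 10.0)
        with pytest.raises(MorphometryError):
            detect_openings(blank)
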