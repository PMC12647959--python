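"""Acoustic holography: array layout, delay laws, field synthesis and the
derived intensity/power/radiation-force descriptors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from holotus import acoustics as ac

from conftest import attenuated_plane_wave


class TestArrayLayout:
    def test_elements_lie_on_the_sphere_within_tolerance(self, full_array):
        r = np.linalg.norm(full_array.element_positions, axis=1)
        assert np.abs(r - 0.04).max() < 1e-9

    def test_cap_coverage_and_count_match_the_request(self, full_array):
        assert full_array.n_elements == 512
        polar = np.degrees(np.arccos(
            -full_array.element_positions[:, 2] / 0.04))
        assert polar.max() == pytest.approx(75.0, abs=0.5)
        assert polar.max() <= 75.0 + 1e-9

    def test_single_element_sits_at_the_pole(self):
        geom = ac.build_spherical_array(1, 150.0, 0.05, 1e6)
        np.testing.assert_allclose(geom.element_positions,
                                   [[0.0, 0.0, -0.05]], atol=1e-12)

    def test_nearest_neighbour_spacing_is_quasi_uniform(self, full_array):
        # brute-force pairwise distances; spacing CV < 0.3
        pos = full_array.element_positions
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert nn.std() / nn.mean() < 0.3

    def test_layout_is_deterministic(self):
        a = ac.build_spherical_array(128, 120.0, 0.03, 2e6)
        b = ac.build_spherical_array(128, 120.0, 0.03, 2e6)
        np.testing.assert_array_equal(a.element_positions,
                                      b.element_positions)

    @pytest.mark.parametrize("kwargs", [
        dict(n_elements=0), dict(coverage_deg=0.0),
        dict(coverage_deg=200.0), dict(radius=-0.04),
        dict(frequency=-1.0)])
    def test_nonphysical_inputs_rejected(self, kwargs):
        args = dict(n_elements=16, coverage_deg=150.0, radius=0.04,
                    frequency=3e6)
        args.update(kwargs)
        with pytest.raises(ValueError):
            ac.build_spherical_array(**args)


class TestDelays:
    def test_centre_of_curvature_is_equidistant(self, full_array):
        delays = ac.compute_delays(full_array, (0.0, 0.0, 0.0))
        np.testing.assert_allclose(delays, 0.0, atol=1e-15)

    def test_delays_match_a_brute_force_distance_oracle(self, small_array):
        focus = np.array([0.5e-3, -0.3e-3, 1.0e-3])
        delays = ac.compute_delays(small_array, focus)
        c = ac.WATER.sound_speed
        d = np.array([np.sqrt(((p - focus) ** 2).sum())
                      for p in small_array.element_positions])
        np.testing.assert_allclose(delays, (d.max() - d) / c, atol=1e-12)
        assert delays.min() == 0.0
        assert (delays >= 0.0).all()

    def test_mirrored_focus_mirrors_the_delay_pattern(self, small_array):
        # on a mirror-symmetric element set, mirroring the focus across the
        # x-z plane permutes the delay vector by the element mirror map
        base = small_array.element_positions
        sym = ac.ArrayGeometry(
            element_positions=np.vstack([base,
                                         base * [1.0, -1.0, 1.0]]),
            coverage_deg=150.0, radius_of_curvature=0.03, frequency=1e6)
        n = base.shape[0]
        perm = np.concatenate([np.arange(n, 2 * n), np.arange(n)])
        f = np.array([0.4e-3, 0.7e-3, 0.2e-3])
        d1 = ac.compute_delays(sym, f)
        d2 = ac.compute_delays(sym, f * np.array([1.0, -1.0, 1.0]))
        np.testing.assert_allclose(d2, d1[perm], atol=1e-15)

    def test_focus_on_an_element_is_rejected(self, small_array):
        with pytest.raises(ValueError):
            ac.compute_delays(small_array,
                              small_array.element_positions[3])

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.floats(-2e-3, 2e-3), st.floats(-2e-3, 2e-3),
           st.floats(-3e-3, 3e-3))
    def test_delay_law_properties_hold_for_arbitrary_foci(self, x, y, z):
        geom = ac.build_spherical_array(32, 150.0, 0.03, 1e6)
        delays = ac.compute_delays(geom, (x, y, z))
        assert delays.min() == 0.0
        assert np.isfinite(delays).all()
        assert (delays >= 0.0).all()


class TestPartition:
    @pytest.mark.parametrize("n_foci,per_focus,left", [
        (3, 170, 2), (5, 102, 2), (1, 512, 0)])
    def test_subset_sizes_match_the_array_splitting(self, full_array,
                                                    n_foci, per_focus,
                                                    left):
        subsets, unassigned = ac.partition_elements(full_array, n_foci,
                                                    seed=1)
        assert all(len(s) == per_focus for s in subsets)
        assert len(unassigned) == left
        joined = np.concatenate(subsets + [unassigned])
        assert len(np.unique(joined)) == 512  # disjoint cover

    def test_partition_is_reproducible_under_seed(self, full_array):
        a, _ = ac.partition_elements(full_array, 3, seed=7)
        b, _ = ac.partition_elements(full_array, 3, seed=7)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1, s2)

    def test_triangle_pattern_focus_spacing(self):
        foci = ac.pattern_foci("triangle", 0.5e-3)
        d = [np.linalg.norm(foci[i] - foci[j])
             for i in range(3) for j in range(i + 1, 3)]
        np.testing.assert_allclose(d, 0.5e-3 * np.sqrt(3.0), rtol=1e-12)

    def test_invalid_focus_counts_rejected(self, small_array):
        with pytest.raises(ValueError):
            ac.partition_elements(small_array, 0)
        with pytest.raises(ValueError):
            ac.partition_elements(small_array, 65)


class TestSynthesis:
    def test_single_element_field_spreads_as_one_over_r(self):
        geom = ac.build_spherical_array(1, 150.0, 0.03, 1e6)
        holo = ac.make_hologram(geom, "single")
        grid = ac.Grid(origin=(0.0, 0.0, -5e-3), spacing=(1e-4, 1e-4, 2e-4),
                       shape=(1, 1, 51))
        fld = ac.synthesize_field(geom, holo, grid)
        # two points along the beam axis at distances r1, r2 from the element
        r = np.abs(grid.z - (-0.03))
        ratio = np.abs(fld.pressure[0, 0, 0]) / np.abs(fld.pressure[0, 0, 50])
        assert ratio == pytest.approx(r[50] / r[0], rel=1e-9)

    def test_delay_law_brings_all_elements_in_phase_at_the_focus(
            self, small_array):
        focus = np.array([0.3e-3, 0.0, 0.5e-3])
        holo = ac.HologramSpec(
            foci=focus[None, :],
            assignments=[np.arange(small_array.n_elements)],
            unassigned=np.array([], dtype=int))
        grid = ac.Grid(origin=tuple(focus), spacing=(1e-4,) * 3,
                       shape=(1, 1, 1))
        fld = ac.synthesize_field(small_array, holo, grid)
        d = np.linalg.norm(small_array.element_positions - focus, axis=1)
        incoherent_sum = np.sum(1.0 / d)
        assert np.abs(fld.pressure[0, 0, 0]) == pytest.approx(
            incoherent_sum, rel=1e-3)

    def test_two_focus_hologram_is_the_sum_of_its_subset_fields(
            self, small_array):
        subsets, rest = ac.partition_elements(small_array, 2, seed=0)
        foci = np.array([[0.5e-3, 0.0, 0.0], [-0.5e-3, 0.0, 0.0]])
        grid = ac.Grid.centred((2e-3, 1e-3, 1e-3), 2e-4)
        both = ac.synthesize_field(small_array, ac.HologramSpec(
            foci=foci, assignments=subsets, unassigned=rest), grid)
        parts = [
            ac.synthesize_field(small_array, ac.HologramSpec(
                foci=foci[k:k + 1], assignments=[subsets[k]],
                unassigned=np.array([], dtype=int)), grid)
            for k in range(2)]
        np.testing.assert_allclose(
            both.pressure, parts[0].pressure + parts[1].pressure,
            rtol=0, atol=1e-12 * np.abs(both.pressure).max())

    def test_steering_translates_the_focal_spot(self, small_array):
        grid = ac.Grid.centred((3e-3, 1e-3, 1e-3), 2e-4)
        argmaxes = []
        for fx in (0.0, 1.0e-3):
            holo = ac.HologramSpec(
                foci=np.array([[fx, 0.0, 0.0]]),
                assignments=[np.arange(small_array.n_elements)],
                unassigned=np.array([], dtype=int))
            fld = ac.synthesize_field(small_array, holo, grid)
            argmaxes.append(np.array(fld.peak_index()))
        shift_vox = argmaxes[1] - argmaxes[0]
        np.testing.assert_array_less(
            np.abs(shift_vox - np.array([5, 0, 0])), 2)

    def test_coarse_grid_violating_sampling_rule_is_rejected(
            self, small_array):
        holo = ac.make_hologram(small_array, "single")
        grid = ac.Grid.centred((2e-3,) * 3, 4e-4)  # lambda/6 = 0.25 mm
        with pytest.raises(ValueError, match="lambda/6"):
            ac.synthesize_field(small_array, holo, grid)

    def test_triangle_hologram_produces_three_separated_maxima(
            self, full_array):
        holo = ac.make_hologram(full_array, "triangle", 0.5e-3, seed=1)
        grid = ac.Grid.centred((2.4e-3, 2.4e-3, 0.0), 40e-6)
        fld = ac.synthesize_field(full_array, holo, grid)
        from scipy import ndimage as ndi
        sl = fld.amplitude[:, :, 0]
        peaks = (sl == ndi.maximum_filter(sl, size=9)) \
            & (sl > 0.5 * sl.max())
        coords = np.argwhere(peaks)
        assert len(coords) == 3
        # each focus target has a peak within ~2 voxels
        for focus in holo.foci:
            i, j, _ = grid.index_of(focus)
            dist = np.abs(coords - [i, j]).max(axis=1).min()
            assert dist <= 2


class TestFwhm:
    def test_gaussian_profile_closed_form(self):
        grid = ac.Grid.centred((4e-3, 1e-4, 1e-4), 2e-5)
        sigma = 0.4e-3
        x = grid.x
        p = np.exp(-x**2 / (2 * sigma**2)).reshape(-1, 1, 1)
        fld = ac.ComplexField(grid=grid, pressure=p.astype(complex),
                              medium=ac.WATER, frequency=3e6)
        fwhm = ac.measure_fwhm(fld, "lateral")
        assert fwhm == pytest.approx(2.3548 * sigma, rel=0.01)

    def test_intensity_width_is_narrower_than_pressure_width(
            self, small_focus_field):
        wp = ac.measure_fwhm(small_focus_field, "lateral", "pressure")
        wi = ac.measure_fwhm(small_focus_field, "lateral", "intensity")
        assert wi <= wp

    def test_profile_that_never_halves_is_an_error(self):
        grid = ac.Grid.centred((1e-3, 1e-4, 1e-4), 5e-5)
        p = np.ones(grid.shape, dtype=complex)
        p[grid.shape[0] // 2] *= 1.2
        fld = ac.ComplexField(grid=grid, pressure=p, medium=ac.WATER,
                              frequency=3e6)
        with pytest.raises(ValueError, match="half maximum"):
            ac.measure_fwhm(fld, "lateral")


class TestIntensityPowerForce:
    def test_intensity_closed_form_at_one_megapascal(self):
        grid = ac.Grid.centred((1e-4,) * 3, 1e-4)
        fld = ac.ComplexField(
            grid=grid, pressure=np.full(grid.shape, 1e6, dtype=complex),
            medium=ac.WATER, frequency=3e6)
        i_sppa = fld.intensity()
        # 1 MPa in 1.5 MRayl water: 33.33 W/cm^2
        assert i_sppa[0, 0, 0] / 1e4 == pytest.approx(33.33, rel=1e-3)

    def test_zero_field_has_zero_power_and_force(self):
        grid = ac.Grid.centred((4e-4,) * 3, 1e-4)
        fld = ac.ComplexField(
            grid=grid, pressure=np.zeros(grid.shape, dtype=complex),
            medium=ac.Medium(attenuation=20.0), frequency=1e6,
            velocity=np.zeros(grid.shape + (3,), dtype=complex))
        _, power = ac.intensity_and_power(fld)
        assert power == 0.0
        ff = ac.radiation_force(fld, "absorption")
        np.testing.assert_array_equal(ff.total_force, 0.0)

    def test_plane_wave_power_is_intensity_times_area(self):
        fld = attenuated_plane_wave(alpha=0.0)
        _, power = ac.intensity_and_power(fld, plane_index=0)
        area = (fld.grid.shape[0] * fld.grid.spacing[0]) ** 2
        i_plane = np.abs(fld.pressure[0, 0, 0]) ** 2 / (
            2 * fld.medium.impedance)
        assert power == pytest.approx(i_plane * area, rel=0.005)

    def test_plane_wave_velocity_matches_impedance_relation(self):
        fld = attenuated_plane_wave(alpha=0.0)
        v_mag = np.linalg.norm(fld.velocity, axis=-1)
        np.testing.assert_allclose(
            v_mag, np.abs(fld.pressure) / fld.medium.impedance, rtol=0.01)

    def test_power_scales_with_drive_amplitude_squared(self, small_array):
        holo = ac.make_hologram(small_array, "single")
        grid = ac.Grid.centred((2e-3, 2e-3, 0.0), 2e-4)
        f1 = ac.synthesize_field(small_array, holo, grid,
                                 source_strength=1.0,
                                 compute_velocity=True)
        f3 = ac.synthesize_field(small_array, holo, grid,
                                 source_strength=3.0,
                                 compute_velocity=True)
        _, p1 = ac.intensity_and_power(f1)
        _, p3 = ac.intensity_and_power(f3)
        assert p3 == pytest.approx(9.0 * p1, rel=1e-9)

    def test_lossless_medium_gives_zero_absorption_force(self):
        fld = attenuated_plane_wave(alpha=0.0)
        ff = ac.radiation_force(fld, "absorption")
        np.testing.assert_array_equal(ff.total_force, 0.0)

    def test_force_methods_agree_for_an_attenuated_plane_wave(self):
        fld = attenuated_plane_wave(alpha=20.0)
        fa = ac.radiation_force(fld, "absorption")
        fm = ac.radiation_force(fld, "momentum_flux")
        # compare interior voxels (central differences are one-sided at
        # the boundary); plane-wave limit is the oracle
        inner = (slice(1, -1),) * 3
        np.testing.assert_allclose(fm.force_density[inner][..., 2],
                                   fa.force_density[inner][..., 2],
                                   rtol=0.05)

    def test_lossless_region_carries_no_net_momentum_flux_force(self):
        lossless = ac.radiation_force(attenuated_plane_wave(alpha=0.0),
                                      "momentum_flux")
        absorbing = ac.radiation_force(attenuated_plane_wave(alpha=20.0),
                                       "absorption")
        # interior sum: closed lossless region with no source
        inner = (slice(1, -1),) * 3
        vox = lossless.force_density[inner][..., 2]
        ref = absorbing.force_density[inner][..., 2]
        assert np.abs(vox.sum()) < 0.01 * np.abs(ref.sum())

    def test_total_force_is_the_integral_of_the_density(self):
        fld = attenuated_plane_wave(alpha=20.0)
        ff = ac.radiation_force(fld, "absorption")
        manual = ff.force_density.reshape(-1, 3).sum(axis=0) \
            * fld.grid.voxel_volume
        np.testing.assert_allclose(ff.total_force, manual, rtol=1e-12)

    def test_momentum_flux_needs_the_velocity_field(self):
        grid = ac.Grid.centred((4e-4,) * 3, 1e-4)
        fld = ac.ComplexField(grid=grid,
                              pressure=np.ones(grid.shape, dtype=complex),
                              medium=ac.WATER, frequency=1e6)
        with pytest.raises(ValueError, match="velocity"):
            ac.radiation_force(fld, "momentum_flux")

    def test_beam_momentum_force_is_power_over_sound_speed(self):
        fld = attenuated_plane_wave(alpha=0.0)
        _, power = ac.intensity_and_power(fld)
        assert ac.beam_momentum_force(fld) == pytest.approx(
            power / fld.medium.sound_speed, rel=1e-12)
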