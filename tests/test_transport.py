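"""Transport engines: emission sampling, propagation physics, accounting."""

import math

import numpy as np
import pytest

import paws_sim as ps
from paws_sim import _kernel
from paws_sim.transport import _empty_field


def _single_diode_source(phantom, tilt=0.0, half_angle=1e-9, spot=1e-9, power=1.0,
                         wavelength=660.0, surface="outer"):
    return ps.build_source_array(
        phantom, tilt, wavelength, power,
        n_diodes=1, spot_size_mm=spot, emission_half_angle_deg=half_angle,
        launch_surface=surface,
    )


class TestEmissionSampler:
    def test_mean_direction_along_normal_at_zero_tilt(self, default_bundle):
        phantom, _, _ = default_bundle
        diode = ps.DiodeSource(0.0, 0.0, 660.0, 3e-3)
        dirs = []
        for i in range(20_000):
            p = ps.sample_emission(diode, phantom, seed=1_000 + i)
            dirs.append((p.ux, p.uy))
        mean = np.array(dirs).mean(axis=0)
        mean /= np.linalg.norm(mean)
        angle = math.degrees(math.atan2(mean[0], mean[1]))
        assert abs(angle) < 1.0  # within 1 degree of the inward normal

    def test_positions_within_two_sigma(self, default_bundle):
        phantom, _, _ = default_bundle
        diode = ps.DiodeSource(0.0, 0.0, 660.0, 3e-3, spot_size_mm=0.3)
        sigma = 0.15e-3
        xs = np.array(
            [ps.sample_emission(diode, phantom, seed=i).x for i in range(5_000)]
        )
        assert (np.abs(xs) <= 2 * sigma + 1e-9).mean() >= 0.99

    def test_collimated_limit(self, default_bundle):
        phantom, _, _ = default_bundle
        # vanishing spot too: on a curved surface the emission axis follows
        # the local normal at the launch point
        diode = ps.DiodeSource(0.0, 30.0, 660.0, 3e-3, spot_size_mm=1e-9,
                               emission_half_angle_deg=1e-12)
        angles = set()
        for i in range(50):
            p = ps.sample_emission(diode, phantom, seed=i)
            angles.add(round(math.atan2(p.ux, p.uy), 9))
        assert len(angles) == 1  # all directions equal the tilted axis


class TestHenyeyGreenstein:
    @pytest.mark.parametrize("g", [0.0, 0.5, 0.9])
    def test_mean_deflection_cosine_equals_g(self, g):
        _kernel._seed(12345)
        cosines = [math.cos(_kernel._hg_angle(g)) for _ in range(200_000)]
        assert np.mean(cosines) == pytest.approx(g, abs=5e-3)


class TestPropagationPhysics:
    def test_mc_matches_beer_lambert_through_pure_absorber(self, slab_case):
        phantom, props = slab_case["phantom"], slab_case["props"]
        src = _single_diode_source(phantom)
        n = 200_000
        field = ps.run_transport(phantom, src, props, n_photons=n, seed=5)
        expected = slab_case["expected_transmitted_fraction"]
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(field.port_transmitted / field.launched_power - expected) < 3 * se

    def test_depth_profile_proportional_to_attenuated_absorption(self, slab_case):
        """Depth-resolved deposition in a pure absorber follows mu_a e^(-mu_a x)."""
        phantom, props = slab_case["phantom"], slab_case["props"]
        src = _single_diode_source(phantom)
        field = ps.run_transport(phantom, src, props, n_photons=300_000, seed=9)
        prof = field.grid.sum(axis=1)
        y = phantom.y_centers_mm() * 1e-3
        mu = phantom.layers[0].mu_a
        h = phantom.grid_resolution_mm * 1e-3
        expected = mu * np.exp(-mu * y) * h  # per-row absorbed fraction
        # bin rows in groups of ten to suppress per-row Monte Carlo noise
        nbin = (len(y) // 10) * 10
        prof_b = prof[:nbin].reshape(-1, 10).sum(axis=1)
        exp_b = expected[:nbin].reshape(-1, 10).sum(axis=1)
        ratio = prof_b[exp_b > 1e-4] / exp_b[exp_b > 1e-4]
        assert np.all(np.abs(ratio - 1.0) < 0.06)

    def test_no_absorption_means_no_deposition(self, fresnel_case):
        phantom, props = fresnel_case["phantom"], fresnel_case["props"]
        src = _single_diode_source(phantom)
        field = ps.run_transport(phantom, src, props, n_photons=50_000, seed=3)
        assert field.total_absorbed == 0.0
        total_out = (
            field.port_reflected + field.port_transmitted + field.escaped_lateral
        )
        assert total_out == pytest.approx(field.launched_power, rel=1e-12)

    def test_single_interface_fresnel_split(self, fresnel_case):
        phantom, props = fresnel_case["phantom"], fresnel_case["props"]
        src = _single_diode_source(phantom)
        n = 200_000
        field = ps.run_transport(phantom, src, props, n_photons=n, seed=21)
        ports = ps.port_summary(field)
        r = fresnel_case["expected_s11"]
        se = math.sqrt(r * (1 - r) / n)
        assert abs(ports.s11_power_fraction - r) < 3 * se
        assert ports.s11_power_fraction + ports.s21_power_fraction == pytest.approx(
            1.0, rel=1e-11
        )

    def test_multilayer_incoherent_fresnel_oracle(self):
        """A transparent high-index slab in air: the reflected fraction at
        normal incidence matches the incoherent multiple-reflection series
        R_tot = R (1 + T^2 / (1 - R^2))."""
        layers = (
            ps.TissueLayer("air_top", 2.0, 1.0, 0.0, 0.0, 0.5, 1000, 4000),
            ps.TissueLayer("glassy", 2.0, 1.5, 0.0, 0.0, 0.5, 1000, 4000),
            ps.TissueLayer("air_bottom", 2.0, 1.0, 0.0, 0.0, 0.5, 1000, 4000),
        )
        phantom = ps.LayeredPhantom(
            layers=layers, curvature_radius_mm=math.inf,
            lateral_extent_mm=16.5, grid_resolution_mm=0.1,
        )
        props = ps.OpticalProperties.constant(layers, anisotropy=0.0)
        src = _single_diode_source(phantom)
        n = 400_000
        field = ps.run_transport(phantom, src, props, n_photons=n, seed=33)
        r = 0.04
        t = 1.0 - r
        expected_r = r + t * t * r / (1.0 - r * r)
        se = math.sqrt(expected_r * (1 - expected_r) / n)
        assert abs(ps.port_summary(field).s11_power_fraction - expected_r) < 3 * se

    def test_propagate_single_photon_conserves_weight(self, slab_case):
        phantom, props = slab_case["phantom"], slab_case["props"]
        tally = _empty_field(phantom, "mc", 1, 0, 660.0, 1)
        photon = ps.Photon(x=0.0, y=0.0, ux=0.0, uy=1.0, weight=1.0, layer=0)
        ps.propagate(photon, phantom, props, seed=4, tally=tally)
        total = (
            tally.per_layer_totals.sum()
            + tally.port_reflected
            + tally.port_transmitted
            + tally.escaped_lateral
            + tally.residual
        )
        assert total == pytest.approx(1.0, rel=1e-9)


class TestRunTransport:
    def test_same_seed_bit_identical(self, default_bundle):
        phantom, props, source = default_bundle
        f1 = ps.run_transport(phantom, source, props, n_photons=20_000, seed=42)
        f2 = ps.run_transport(phantom, source, props, n_photons=20_000, seed=42)
        assert np.array_equal(f1.grid, f2.grid)
        assert np.array_equal(f1.per_layer_totals, f2.per_layer_totals)
        assert f1.port_reflected == f2.port_reflected

    def test_doubling_power_doubles_every_tally(self, default_bundle):
        phantom, props, _ = default_bundle
        s1 = ps.build_source_array(phantom, 10.0, 660.0, 3e-3)
        s2 = ps.build_source_array(phantom, 10.0, 660.0, 6e-3)
        f1 = ps.run_transport(phantom, s1, props, n_photons=20_000, seed=7)
        f2 = ps.run_transport(phantom, s2, props, n_photons=20_000, seed=7)
        assert np.allclose(f2.grid, 2.0 * f1.grid, rtol=1e-12, atol=0)
        assert np.allclose(f2.per_layer_totals, 2.0 * f1.per_layer_totals, rtol=1e-12)
        assert f2.port_transmitted == pytest.approx(2.0 * f1.port_transmitted, rel=1e-12)

    def test_zero_power_returns_empty_field(self, default_bundle):
        phantom, props, _ = default_bundle
        src = ps.build_source_array(phantom, 0.0, 660.0, 0.0)
        field = ps.run_transport(phantom, src, props, n_photons=1_000, seed=1)
        assert field.launched_power == 0.0
        assert field.total_absorbed == 0.0

    def test_unknown_engine_rejected(self, default_bundle):
        phantom, props, source = default_bundle
        with pytest.raises(ValueError):
            ps.run_transport(phantom, source, props, n_photons=10, seed=1, engine="fem")

    def test_mc_and_ray_agree_without_scattering(self):
        """Zero-scattering limit: the two engines are statistically
        indistinguishable in per-layer absorbed totals."""
        # index-matched stack isolates the attenuation physics from Fresnel
        layers = tuple(
            ps.TissueLayer(l.name, l.thickness_mm, 1.4,
                           mu_a=50.0 * (i + 1), mu_s=0.0,
                           thermal_conductivity=l.thermal_conductivity,
                           density=l.density, heat_capacity=l.heat_capacity)
            for i, l in enumerate(ps.DEFAULT_LAYERS)
        )
        phantom = ps.LayeredPhantom(layers=layers, curvature_radius_mm=math.inf,
                                    grid_resolution_mm=0.1)
        props = ps.OpticalProperties.constant(layers, anisotropy=0.0)
        src = _single_diode_source(phantom, power=1.0)
        n = 300_000
        mc = ps.run_transport(phantom, src, props, n_photons=n, seed=17)
        ray = ps.ray_engine(phantom, src, props, collimated=True)
        for i in range(4):
            p = ray.per_layer_totals[i]
            se = math.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(mc.per_layer_totals[i] - p) < 3 * se


class TestRayEngine:
    def test_per_layer_telescoping_beer_lambert(self):
        """Index-matched flat stack, axial ray: absorbed fractions equal the
        telescoping differences of the cumulative exponentials."""
        layers = tuple(
            ps.TissueLayer(l.name, l.thickness_mm, 1.4, mu_a=l.mu_a, mu_s=0.0,
                           thermal_conductivity=l.thermal_conductivity,
                           density=l.density, heat_capacity=l.heat_capacity)
            for l in ps.DEFAULT_LAYERS
        )
        phantom = ps.LayeredPhantom(layers=layers, curvature_radius_mm=math.inf,
                                    grid_resolution_mm=0.1)
        props = ps.OpticalProperties.constant(layers)
        src = _single_diode_source(phantom, power=1.0)
        field = ps.ray_engine(phantom, src, props, collimated=True)
        tau = np.concatenate(
            [[0.0], np.cumsum([l.mu_a * l.thickness_mm * 1e-3 for l in layers])]
        )
        expected = np.exp(-tau[:-1]) - np.exp(-tau[1:])
        assert np.allclose(field.per_layer_totals, expected, rtol=1e-9)
        assert field.port_transmitted == pytest.approx(math.exp(-tau[-1]), rel=1e-9)

    def test_oblique_path_increases_absorption(self):
        """Tilting a collimated ray lengthens the slant path (t / cos)."""
        layer = ps.TissueLayer("absorber", 7.3, 1.0, 30.0, 0.0, 0.5, 1000, 4000)
        phantom = ps.LayeredPhantom(layers=(layer,), curvature_radius_mm=math.inf,
                                    grid_resolution_mm=0.1)
        props = ps.OpticalProperties.constant((layer,))
        absorbed = []
        for tilt in (0.0, 20.0, 40.0):
            src = _single_diode_source(phantom, tilt=tilt, power=1.0)
            f = ps.ray_engine(phantom, src, props, collimated=True)
            absorbed.append(f.total_absorbed)
            t_slant = 7.3e-3 / math.cos(math.radians(tilt))
            assert f.total_absorbed == pytest.approx(1 - math.exp(-30.0 * t_slant), rel=1e-9)
        assert absorbed[0] < absorbed[1] < absorbed[2]

    def test_transparent_stack_fully_transmits(self, fresnel_case):
        phantom, props = fresnel_case["phantom"], fresnel_case["props"]
        src = _single_diode_source(phantom)
        field = ps.ray_engine(phantom, src, props, collimated=True)
        ports = ps.port_summary(field)
        assert ports.s21_power_fraction == pytest.approx(0.96, rel=1e-12)
        assert ports.s11_power_fraction == pytest.approx(0.04, rel=1e-12)

    def test_raising_mu_a_does_not_decrease_layer_total(self, default_bundle):
        phantom, _, source = default_bundle
        base = ps.OpticalProperties.constant(phantom.layers)
        f0 = ps.ray_engine(phantom, source, base)
        import dataclasses

        bumped_layers = list(phantom.layers)
        bumped_layers[3] = dataclasses.replace(bumped_layers[3], mu_a=10 * bumped_layers[3].mu_a)
        bumped = ps.OpticalProperties.constant(tuple(bumped_layers))
        f1 = ps.ray_engine(phantom, source, bumped)
        assert f1.per_layer_totals[3] >= f0.per_layer_totals[3]


class TestSummaries:
    def test_port_summary_requires_launched_power(self, default_bundle):
        phantom, props, _ = default_bundle
        src = ps.build_source_array(phantom, 0.0, 660.0, 0.0)
        field = ps.run_transport(phantom, src, props, n_photons=100, seed=1)
        with pytest.raises(ValueError):
            ps.port_summary(field)

    def test_absorption_rate_closed_form_single_slab(self):
        """1 - e^(-mu_a t) for a lone absorbing slab at normal incidence."""
        layer = ps.TissueLayer("absorber", 10.0, 1.0, 100.0, 0.0, 0.5, 1000, 4000)
        phantom = ps.LayeredPhantom(layers=(layer,), curvature_radius_mm=math.inf,
                                    grid_resolution_mm=0.1)
        props = ps.OpticalProperties.constant((layer,))
        src = _single_diode_source(phantom, power=1.0)
        field = ps.ray_engine(phantom, src, props, collimated=True)
        assert ps.absorption_rate(field, 0) == pytest.approx(1 - math.exp(-1.0), rel=1e-9)
        assert ps.absorption_rate(field, "all") == pytest.approx(1 - math.exp(-1.0), rel=1e-9)

    def test_absorption_rate_undefined_when_region_unreached(self, fresnel_case):
        phantom, props = fresnel_case["phantom"], fresnel_case["props"]
        field = _empty_field(phantom, "mc", 0, 0, 660.0, 1)
        field.launched_power = 1.0
        with pytest.raises(ValueError):
            ps.absorption_rate(field, 1)

    def test_absorptance_profile_symmetry_and_total(self, literature_field):
        xs, prof = ps.absorptance_profile(literature_field)
        assert prof.sum() == pytest.approx(literature_field.total_absorbed, rel=1e-9)
        # symmetric sources at tilt 0 -> symmetric profile within MC noise
        asym = np.abs(prof - prof[::-1]).sum() / prof.sum()
        assert asym < 0.12

    def test_four_maxima_in_low_scattering_regime(self, default_bundle):
        """The deterministic ray fan resolves one absorptance lobe per diode."""
        phantom, props, source = default_bundle
        field = ps.ray_engine(phantom, source, props)
        xs, prof = ps.absorptance_profile(field)
        centers = [d.arc_offset_mm for d in source.diodes]
        for c in centers:
            near = (np.abs(xs - c) < 0.4)
            far = (np.abs(xs - c) >= 0.4) & (np.abs(xs - c) < 0.75)
            assert prof[near].max() > prof[far].max()
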