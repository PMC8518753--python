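"""Transport-solver tests: geometry validation, flow field, boundary
conditions, global mass balance, and the well-mixed (CSTR) oracle limit."""

import numpy as np
import pytest
from dataclasses import replace

from phipflow.chip_transport import (
    GeometryError,
    TransportConfig,
    TransportError,
    build_geometry,
    build_mesh,
    chamber_mean,
    compute_flow_field,
    config_from_yaml,
    config_to_yaml,
    pathway_profile,
    solution_to_csv,
    solve_steady_transport,
    _FLUID,
    _MEMBRANE,
)
from phipflow.reaction_kinetics import (
    CALIBRATED_RATE_CONSTANTS,
    SPECIES,
    SPECIES_INDEX,
    build_network,
    mass_action_rhs,
)

ZERO_KINETICS = build_network(np.zeros(6))


def solve_reactions_off(geometry, config):
    config = replace(config, inlet_mM={})
    flow = compute_flow_field(geometry, config)
    return solve_steady_transport(geometry, flow, ZERO_KINETICS, config)


class TestGeometry:
    def test_default_dimensions(self):
        geo = build_geometry()
        assert geo.membrane_length_mm == 25.0
        assert geo.chamber_length_mm == 2.0
        assert geo.liquid_volume_uL == pytest.approx(8.82)

    def test_chamber_shift_moves_midpoint(self):
        geo = build_geometry(chamber_shift_mm=-12.5)
        ref = build_geometry()
        mid = 0.5 * (geo.chamber_start_mm + geo.chamber_end_mm)
        mid_ref = 0.5 * (ref.chamber_start_mm + ref.chamber_end_mm)
        assert mid == pytest.approx(mid_ref - 12.5)

    def test_degenerate_membrane_rejected(self):
        with pytest.raises(GeometryError):
            build_geometry(membrane_length_mm=0.0)

    def test_chamber_membrane_overlap_rejected(self):
        with pytest.raises(GeometryError):
            build_geometry(chamber_shift_mm=-30.0)

    def test_chamber_must_be_wider_than_channel(self):
        with pytest.raises(GeometryError):
            build_geometry(chamber_width_mm=0.05)

    def test_yaml_round_trip(self):
        geo = build_geometry(chamber_shift_mm=-12.5)
        cfg = TransportConfig(flow_uL_min=7.0, h_pdms_mM=40.0)
        geo2, cfg2 = config_from_yaml(config_to_yaml(geo, cfg))
        assert geo2 == geo
        assert cfg2.flow_uL_min == 7.0 and cfg2.h_pdms_mM == 40.0

    def test_flow_rate_outside_range_rejected(self):
        with pytest.raises(ValueError):
            TransportConfig(flow_uL_min=60.0)


class TestFlowField:
    def test_mean_velocity_at_reference_flow(self):
        # Q/(w*d) = 1.4e-10 m^3/s / 1.4e-7 m^2 = 1.0e-3 m/s
        geo = build_geometry()
        cfg = TransportConfig(flow_uL_min=8.4)
        flow = compute_flow_field(geo, cfg)
        mesh = flow.mesh
        i = mesh.nx // 4  # inside the plain channel
        mean_u = np.sum(flow.u_face[i] * mesh.dy) / (geo.channel_width_mm * 1e-3)
        assert mean_u == pytest.approx(1.0e-3, rel=1e-6)

    def test_centreline_is_1_5x_mean(self):
        from phipflow.chip_transport import _poiseuille_cell_means

        edges = np.linspace(0.0, 1e-4, 401)
        u = _poiseuille_cell_means(edges, 1e-4, 1e-7)
        assert u.max() == pytest.approx(1.5 * 1e-3, rel=1e-4)

    def test_flux_identical_through_random_cross_sections(self, rng):
        geo = build_geometry()
        cfg = TransportConfig(flow_uL_min=5.0)
        flow = compute_flow_field(geo, cfg)
        q = cfg.flow_m3_s
        for i in rng.integers(0, flow.mesh.nx + 1, size=10):
            assert flow.cross_section_flux(int(i)) == pytest.approx(q, rel=1e-3)

    def test_velocity_zero_in_membrane(self):
        geo = build_geometry()
        flow = compute_flow_field(geo, TransportConfig(flow_uL_min=5.0))
        assert np.all(flow.u_cell[flow.mesh.cell_type == _MEMBRANE] == 0.0)

    def test_chamber_velocity_rescales_with_width(self):
        geo = build_geometry()
        cfg = TransportConfig(flow_uL_min=8.4)
        flow = compute_flow_field(geo, cfg)
        mesh = flow.mesh
        xc = mesh.x_centers * 1e3
        cham = np.nonzero((xc > 48.5) & (xc < 49.5))[0]
        mean_u = np.sum(flow.u_face[cham[0]] * mesh.dy) / (geo.chamber_width_mm * 1e-3)
        assert mean_u == pytest.approx(1.0e-3 / 5.0, rel=1e-6)


class TestSteadyTransport:
    def test_zero_flow_pure_diffusion_saturates_domain(self, small_geometry):
        cfg = TransportConfig(flow_uL_min=0.0, dx_mm=0.25, n_across_channel=4, n_across_upper=4)
        sol = solve_reactions_off(small_geometry, cfg)
        h2 = sol.field("2")
        assert np.nanmax(np.abs(h2 - 20.0)) < 1e-6

    def test_global_hydrogen_mass_balance(self, small_geometry, small_config):
        """Reactions off: integrated membrane influx equals the advective
        outflux of hydrogen at the outlet (steady state, closed walls)."""
        sol = solve_reactions_off(small_geometry, small_config)
        mesh, geo, cfg = sol.mesh, sol.geometry, sol.config
        depth = geo.depth_mm * 1e-3
        flow = compute_flow_field(geo, replace(cfg, inlet_mM={}), mesh)
        h2 = sol.field("2")
        # outlet advective flux
        j = np.nonzero(mesh.cell_type[-1] == _FLUID)[0]
        out = np.sum(flow.u_face[mesh.nx, j] * mesh.dy[j] * depth * h2[-1, j])
        # membrane Dirichlet influx through the outer boundary
        mem = mesh.cell_type == _MEMBRANE
        influx = 0.0
        for i in range(mesh.nx):
            jj = np.nonzero(mem[i])[0]
            if jj.size == 0:
                continue
            jtop = jj.max()
            g = cfg.diffusion_m2_s * mesh.dx[i] * depth / (
                mesh.y_edges[jtop + 1] - mesh.y_centers[jtop]
            )
            influx += g * (cfg.h_pdms_mM - h2[i, jtop])
        assert out == pytest.approx(influx, rel=5e-3)

    def test_low_flow_saturates_upstream_of_membrane_end(self):
        geo = build_geometry()
        cfg = TransportConfig(flow_uL_min=0.5)
        sol = solve_reactions_off(geo, cfg)
        x, prof = pathway_profile(sol, "2")
        # the 99%-saturation point lies several mm before the membrane ends
        crossing = x[np.argmax(prof > 0.99 * 20.0)]
        assert crossing < geo.membrane_end_mm - 5.0
        seg_end = (x > geo.membrane_end_mm - 2.0) & (x < geo.membrane_end_mm)
        assert np.all(prof[seg_end] > 0.99 * 20.0)

    def test_high_flow_stays_below_saturation(self):
        geo = build_geometry()
        sol = solve_reactions_off(geo, TransportConfig(flow_uL_min=20.0))
        x, prof = pathway_profile(sol, "2")
        assert np.all(prof[x > 1.0] < 20.0)
        # profile rises monotonically along the membrane segment
        seg = (x > geo.membrane_start_mm) & (x < geo.membrane_end_mm)
        assert np.all(np.diff(prof[seg]) > -1e-9)

    def test_hydrogen_bounded_by_h_pdms(self, small_geometry, small_config):
        sol = solve_reactions_off(small_geometry, small_config)
        h2 = sol.field("2")
        assert np.nanmin(h2) >= 0.0
        assert np.nanmax(h2) <= small_config.h_pdms_mM + 1e-6

    def test_grid_convergence_of_chamber_mean(self):
        geo = build_geometry()
        means = []
        for refine in (1, 2):
            cfg = TransportConfig(flow_uL_min=8.0, refine=refine)
            sol = solve_reactions_off(geo, cfg)
            means.append(chamber_mean(sol, "2"))
        assert abs(means[1] - means[0]) / means[0] < 0.02

    def test_solver_is_deterministic(self, small_geometry, small_config):
        net = build_network(
            dict(CALIBRATED_RATE_CONSTANTS, k6=0.14), relaxation_enabled=True
        )
        flow = compute_flow_field(small_geometry, small_config)
        a = solve_steady_transport(small_geometry, flow, net, small_config)
        b = solve_steady_transport(small_geometry, flow, net, small_config)
        assert np.array_equal(
            np.nan_to_num(a.field("4")), np.nan_to_num(b.field("4"))
        )

    def test_central_scheme_warns_at_high_peclet(self, small_geometry):
        cfg = TransportConfig(
            flow_uL_min=10.0, dx_mm=0.25, n_across_channel=4,
            n_across_upper=4, scheme="central",
        )
        cfg = replace(cfg, inlet_mM={})
        flow = compute_flow_field(small_geometry, cfg)
        with pytest.warns(UserWarning, match="Peclet"):
            solve_steady_transport(small_geometry, flow, ZERO_KINETICS, cfg)

    def test_transversely_mixed_limit_matches_kinetic_ode(self, small_geometry):
        """Chip solver vs the space-independent kinetic model.

        With hydrogen clamped and transverse diffusion fast compared with
        residence (cross-section well mixed), the width-averaged profile
        must follow the kinetic ODE in residence time tau(x) = V(0..x)/Q —
        the independent oracle is the adaptive ODE integrator."""
        from phipflow.reaction_kinetics import integrate

        cfg = TransportConfig(
            flow_uL_min=2.0, diffusion_m2_s=1e-8, dx_mm=0.25,
            n_across_channel=4, n_across_upper=4,
        )
        net = build_network(hydrogen_clamp=20.0)
        flow = compute_flow_field(small_geometry, cfg)
        sol = solve_steady_transport(small_geometry, flow, net, cfg)
        mesh = sol.mesh
        colvol = (mesh.cell_volumes() * (mesh.cell_type == _FLUID)).sum(axis=1)
        tau = (np.cumsum(colvol) - 0.5 * colvol) / cfg.flow_m3_s
        ode = integrate(
            net, {"1": 5.0, "3": 20.0, "2": 20.0}, np.concatenate(([0.0], tau))
        )
        for s in ("1", "1a", "3", "4", "5", "6"):
            x, prof = pathway_profile(sol, s)
            ref = np.interp(tau, ode.times, ode.species(s))
            pre_chamber = x < small_geometry.chamber_start_mm - 0.5
            # within 2.5% of the 20 mM scale (upwind numerical diffusion)
            assert np.abs(prof[pre_chamber] - ref[pre_chamber]).max() < 0.5

    def test_unknown_species_raises(self, small_geometry, small_config):
        sol = solve_reactions_off(small_geometry, small_config)
        with pytest.raises(KeyError):
            chamber_mean(sol, "xx")

    def test_solution_csv_export(self, small_geometry, small_config, tmp_path):
        import pandas as pd

        sol = solve_reactions_off(small_geometry, small_config)
        path = tmp_path / "fields.csv"
        solution_to_csv(sol, path)
        frame = pd.read_csv(path)
        assert set(frame.columns) == {"x_mm", "y_mm", "species", "concentration_mM"}
        assert set(frame.species.unique()) == set(SPECIES)


class TestChamberMean:
    def test_uniform_field(self, small_geometry, small_config):
        sol = solve_reactions_off(small_geometry, replace(small_config, flow_uL_min=0.0))
        assert chamber_mean(sol, "2") == pytest.approx(20.0, abs=1e-6)

    def test_linear_gradient_gives_midpoint(self, small_geometry, small_config):
        sol = solve_reactions_off(small_geometry, small_config)
        mesh = sol.mesh
        f = sol.fields["2"]
        grad = np.broadcast_to(mesh.x_centers[:, None], f.shape).copy()
        grad[~np.isfinite(f)] = np.nan
        sol.fields["2"] = grad
        g = sol.geometry
        mid = 0.5 * (g.chamber_start_mm + g.chamber_end_mm) * 1e-3
        assert chamber_mean(sol, "2") == pytest.approx(mid, rel=1e-6)
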