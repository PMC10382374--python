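"""Skin diffusion solver: grid construction, analytic verification,
conservation and grid convergence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchtwin.parameters import SkinGeometry, TransportParameters
from patchtwin.skin import (
    build_grid,
    cell_properties,
    diffusion_rhs,
    flux_out,
    initialize_site,
    richardson_convergence,
    simulate_site,
    site_mass,
)


@pytest.fixture(scope="module")
def geometry() -> SkinGeometry:
    return SkinGeometry(
        d_sc=18.9e-6,
        d_vep=29.7e-6,
        d_edm=242.6e-6,
        d_patch=50.8e-6,
        patch_area=31.5e-4,
        patch_load=12.6e6,
        age_scaling_ratio=0.134,
    )


@pytest.fixture(scope="module")
def transport() -> TransportParameters:
    return TransportParameters(
        D_patch=6.91e-16,
        D_sc=3.02e-14,
        D_vep=3.02e-14,
        D_dermis=3.84e-11,
        K_patch=1.0,
        K_sc=3.4,
        K_vep=3.4,
        K_dermis=3.4,
    )


def uniform_transport(D: float) -> TransportParameters:
    return TransportParameters(
        D_patch=D, D_sc=D, D_vep=D, D_dermis=D, K_patch=1, K_sc=1, K_vep=1, K_dermis=1
    )


class TestGrid:
    def test_partition_is_exact(self, geometry):
        grid = build_grid(geometry, [25, 25, 25, 25])
        total = geometry.d_patch + geometry.d_sc + geometry.d_vep + geometry.d_edm
        assert grid.total_thickness == pytest.approx(total, rel=1e-14)
        assert (grid.widths > 0).all()

    def test_faces_at_layer_boundaries(self, geometry):
        grid = build_grid(geometry, [8, 8, 8, 8])
        faces = grid.faces
        boundary = geometry.d_patch
        for d in (geometry.d_sc, geometry.d_vep, geometry.d_edm):
            assert np.min(np.abs(faces - boundary)) < 1e-18
            boundary += d

    def test_uniform_at_refinement_one(self, geometry):
        grid = build_grid(geometry, [10, 10, 10, 10], interface_refinement=1.0)
        for lid in range(4):
            w = grid.widths[grid.layer_id == lid]
            assert np.allclose(w, w[0])

    def test_refined_widths_grow_away_from_interfaces(self, geometry):
        grid = build_grid(geometry, [12, 12, 12, 12], interface_refinement=1.2)
        w = grid.widths[grid.layer_id == 0]
        half = len(w) // 2
        assert (np.diff(w[:half]) > 0).all()  # growing toward the centre
        assert (np.diff(w[half:]) < 0).all()  # shrinking toward the far face
        assert np.allclose(w, w[::-1])  # symmetric within the layer

    def test_too_few_cells_rejected(self, geometry):
        with pytest.raises(ValueError, match="at least 4"):
            build_grid(geometry, [3, 8, 8, 8])

    def test_degenerate_layer_rejected(self, geometry, transport):
        bad = SkinGeometry(
            d_sc=1e-9,
            d_vep=geometry.d_vep,
            d_edm=geometry.d_edm,
            d_patch=geometry.d_patch,
            patch_area=geometry.patch_area,
            patch_load=geometry.patch_load,
            age_scaling_ratio=1.0,
        )
        # zero thickness cannot even construct the geometry
        with pytest.raises(ValueError):
            SkinGeometry(
                d_sc=0.0,
                d_vep=geometry.d_vep,
                d_edm=geometry.d_edm,
                d_patch=geometry.d_patch,
                patch_area=geometry.patch_area,
                patch_load=geometry.patch_load,
                age_scaling_ratio=1.0,
            )
        assert build_grid(bad, [4, 4, 4, 4]).n_cells == 16


class TestInitialization:
    def test_initial_patch_concentration(self, geometry, transport):
        grid = build_grid(geometry, [8, 8, 8, 8])
        state = initialize_site(grid, transport, geometry.patch_load, geometry.patch_area)
        c0 = 12.6e6 / (31.5e-4 * 50.8e-6)  # ng/m3
        patch_cells = grid.layer_id == 0
        assert np.allclose(state.psi[patch_cells] * transport.K_patch, c0)
        assert (state.psi[~patch_cells] == 0).all()

    def test_zero_load_gives_zero_state(self, geometry, transport):
        grid = build_grid(geometry, [8, 8, 8, 8])
        state = initialize_site(grid, transport, 0.0, geometry.patch_area)
        assert (state.psi == 0).all()

    def test_initial_mass_equals_load_exactly(self, geometry, transport):
        grid = build_grid(geometry, [16, 8, 8, 8])
        state = initialize_site(grid, transport, geometry.patch_load, geometry.patch_area)
        assert site_mass(state.psi, grid, transport, geometry.patch_area) == pytest.approx(
            geometry.patch_load, rel=1e-12
        )


class TestDiffusion:
    def test_equilibrium_state_is_stationary(self, geometry, transport):
        grid = build_grid(geometry, [8, 8, 8, 8])
        psi = np.full(grid.n_cells, 3.7e10)
        dpsi = diffusion_rhs(psi, grid, transport, bottom_psi=3.7e10)
        assert np.allclose(dpsi, 0.0, atol=1e-6)

    def test_zero_state_has_zero_flux(self, geometry, transport):
        grid = build_grid(geometry, [8, 8, 8, 8])
        rec = flux_out(np.zeros(grid.n_cells), grid, transport, bottom_psi=0.0)
        assert rec.flux == 0.0

    @staticmethod
    def _steady_state(grid, transport, top_psi, bottom_psi):
        """Independent route to the steady state: solve the linear system
        implied by the probed affine RHS."""
        n = grid.n_cells
        b = diffusion_rhs(np.zeros(n), grid, transport, bottom_psi, top_psi=top_psi)
        A = np.column_stack(
            [
                diffusion_rhs(e, grid, transport, bottom_psi, top_psi=top_psi) - b
                for e in np.eye(n)
            ]
        )
        return np.linalg.solve(A, -b)

    def test_single_layer_steady_flux_matches_slab_formula(self):
        D, K, L = 1e-12, 2.0, 100e-6
        tp = TransportParameters(
            D_patch=D, D_sc=D, D_vep=D, D_dermis=D, K_patch=K, K_sc=K, K_vep=K, K_dermis=K
        )
        geometry = SkinGeometry(
            d_sc=L / 4,
            d_vep=L / 4,
            d_edm=L / 4,
            d_patch=L / 4,
            patch_area=1e-4,
            patch_load=0.0,
            age_scaling_ratio=1.0,
        )
        grid = build_grid(geometry, [8, 8, 8, 8])
        top, bottom = 5e9, 1e9
        psi = self._steady_state(grid, tp, top, bottom)
        rec = flux_out(psi, grid, tp, bottom)
        analytic = D * K * (top - bottom) / L
        assert rec.flux == pytest.approx(analytic, rel=5e-3)

    def test_two_layer_interface_concentration_jump(self, geometry, transport):
        """At steady state the concentration ratio across the patch/SC
        interface equals the printed partition coefficient 0.29."""
        grid = build_grid(geometry, [24, 24, 24, 24], interface_refinement=1.0)
        psi = self._steady_state(grid, transport, top_psi=1e12, bottom_psi=0.0)
        _, K = cell_properties(grid, transport)
        c = K * psi
        x = grid.centers
        last_patch = np.flatnonzero(grid.layer_id == 0)[-1]
        x_int = grid.faces[last_patch + 1]

        def extrapolate(i, j):
            # steady-state concentration is linear within a layer
            slope = (c[j] - c[i]) / (x[j] - x[i])
            return c[j] + slope * (x_int - x[j])

        c_patch_side = extrapolate(last_patch - 1, last_patch)
        c_sc_side = extrapolate(last_patch + 2, last_patch + 1)
        ratio = c_patch_side / c_sc_side
        assert ratio == pytest.approx(transport.K_patch / transport.K_sc, rel=0.02)

    def test_transient_slab_matches_analytic_series(self):
        """Uniform initial load, no-flux top, absorbing bottom: the solver
        tracks the classical eigenfunction series within 0.5% pointwise."""
        D, L, c0 = 3e-14, 60e-6, 1e12
        tp = uniform_transport(D)
        geometry = SkinGeometry(
            d_sc=L / 4,
            d_vep=L / 4,
            d_edm=L / 4,
            d_patch=L / 4,
            patch_area=1e-4,
            patch_load=0.0,
            age_scaling_ratio=1.0,
        )
        grid = build_grid(geometry, [12, 12, 12, 12])
        psi0 = np.full(grid.n_cells, c0)
        times = np.array([0.0, 0.02, 0.1, 0.5]) * L**2 / D
        psi_t, flux, _ = simulate_site(grid, tp, psi0, times, bottom_psi=0.0, rtol=1e-10)

        def series(x, t, terms=200):
            m = np.arange(terms)
            lam = (2 * m + 1) * np.pi / (2 * L)
            amp = 2 * c0 * (-1) ** m / (lam * L)
            return (
                amp[None, :] * np.cos(np.outer(x, lam)) * np.exp(-D * lam**2 * t)
            ).sum(axis=1)

        x = grid.centers
        for k, t in enumerate(times[1:], start=1):
            exact = series(x, t)
            assert np.max(np.abs(psi_t[k] - exact)) < 0.005 * c0

    def test_mass_balance_sealed_bottom_72h(self, geometry, transport):
        """Patch + skin mass plus cumulative bottom outflux returns the
        12.6 mg load to well within 0.1% over 72 h."""
        grid = build_grid(geometry, [28, 20, 20, 32])
        state = initialize_site(grid, transport, geometry.patch_load, geometry.patch_area)
        t_eval = np.array([0.0, 72 * 3600.0])
        psi_t, _, cum = simulate_site(
            grid, transport, state.psi, t_eval, bottom_psi=0.0, rtol=1e-8,
            area=geometry.patch_area,
        )
        final = site_mass(psi_t[-1], grid, transport, geometry.patch_area)
        assert final + cum[-1] == pytest.approx(geometry.patch_load, rel=1e-3)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        bottom=st.floats(0.0, 1e12),
    )
    def test_non_negativity_preserved(self, geometry, transport, seed, bottom):
        """psi >= 0 initial data and boundary keep psi >= 0 at all times."""
        grid = build_grid(geometry, [6, 6, 6, 6])
        rng = np.random.default_rng(seed)
        psi0 = rng.uniform(0, 1e13, grid.n_cells)
        times = np.array([0.0, 3600.0, 24 * 3600.0])
        psi_t, _, _ = simulate_site(grid, transport, psi0, times, bottom_psi=bottom, rtol=1e-8)
        assert psi_t.min() >= -1e-4 * psi0.max()


class TestRichardson:
    def test_second_order_convergence(self, geometry, transport):
        result = richardson_convergence(geometry, transport, [14, 10, 10, 16], levels=3)
        assert result["monotone"]
        assert result["observed_order"] == pytest.approx(2.0, abs=0.4)
        assert result["errors"][-1] < 1e-3

    def test_identical_fluxes_error_path(self, geometry, transport, monkeypatch):
        import patchtwin.skin as skin_mod

        monkeypatch.setattr(
            skin_mod,
            "simulate_site",
            lambda *a, **k: (None, np.array([0.0, 1.0]), None),
        )
        with pytest.raises(ValueError, match="order undefined"):
            richardson_convergence(geometry, transport, [4, 4, 4, 4], levels=3)

    def test_too_few_levels_rejected(self, geometry, transport):
        with pytest.raises(ValueError, match="3 grid levels"):
            richardson_convergence(geometry, transport, [4, 4, 4, 4], levels=2)
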