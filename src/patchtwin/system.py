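"""Monolithic coupled system: active skin sites + PK + effect compartments.

Between patch events the full model is a linear, time-invariant ODE
system: skin diffusion is linear in the potentials, the PK balance is
linear in the concentrations, the effect lag is linear, and the two
couplings (Dirichlet bottom potential = plasma concentration / dermis
capacity; plasma input = summed bottom flux x area / V_central) are linear
too.  The assembler therefore probes the composed right-hand side with
unit vectors to build the exact sparse system matrix once per segment and
hands it to a stiff implicit integrator (BDF) with an analytic Jacobian.

State layout: for each active site, its cell potentials followed by one
cumulative-outflux state [ng]; then the five PK concentrations; then the
two effect concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import csc_matrix

from . import pkpd, skin
from .parameters import TwinParameters
from .skin import NG_PER_ML_TO_NG_PER_M3, Grid1D

_NEGATIVE_TOL = -1e-6  # ng/ml (or ng/m3) below which a state is an error


@dataclass
class Site:
    """One application site: its grid, current potentials, bookkeeping."""

    grid: Grid1D
    psi: np.ndarray
    cumulative_outflux: float = 0.0
    applied_at_h: float = 0.0
    patch_attached: bool = True
    initial_load: float = 0.0
    retired: bool = False  # no longer part of the state vector
    _cache: tuple | None = None  # (face conductances, K * widths), per grid

    def operators(self, transport) -> tuple[np.ndarray, np.ndarray]:
        if self._cache is None:
            G = skin.face_conductances(self.grid, transport)
            _, K = skin.cell_properties(self.grid, transport)
            self._cache = (G, K * self.grid.widths)
        return self._cache


class TwinSystem:
    """Assembles and integrates the coupled skin-PK-PD state for one twin."""

    def __init__(self, twin: TwinParameters, numerics: dict):
        self.twin = twin
        self.numerics = numerics
        self.sites: list[Site] = []
        self.pk_state = np.zeros(5)
        self.effect_state = np.zeros(2)

    # -- site management -------------------------------------------------
    def apply_patch(self, time_h: float) -> None:
        """Attach a fresh, fully loaded patch at a new site."""
        grid = skin.build_grid(
            self.twin.skin,
            self.numerics["n_cells_per_layer"],
            self.numerics["interface_refinement"],
        )
        state = skin.initialize_site(
            grid, self.twin.transport, self.twin.skin.patch_load, self.twin.skin.patch_area
        )
        self.sites.append(
            Site(
                grid=grid,
                psi=state.psi,
                applied_at_h=time_h,
                initial_load=self.twin.skin.patch_load,
            )
        )

    def remove_patch(self, site: Site) -> None:
        """Remove the patch from a site.

        With the residual-depot option the skin layers keep their drug and
        keep releasing (top of the SC becomes no-flux); otherwise the site
        is retired outright.
        """
        if not site.patch_attached:
            return
        if self.numerics.get("residual_depot", True):
            pid = site.grid.layers.index("patch")
            keep = site.grid.layer_id != pid
            site.grid = skin.build_grid(
                self.twin.skin,
                self.numerics["n_cells_per_layer"],
                self.numerics["interface_refinement"],
                include_patch=False,
            )
            site.psi = site.psi[keep]
            site.patch_attached = False
            site._cache = None
        else:
            site.patch_attached = False
            site.retired = True

    @property
    def active_sites(self) -> list[Site]:
        return [s for s in self.sites if not s.retired]

    # -- state vector ----------------------------------------------------
    def _layout(self) -> tuple[list[tuple[Site, slice, int]], int, int]:
        blocks = []
        off = 0
        for site in self.active_sites:
            n = site.grid.n_cells
            blocks.append((site, slice(off, off + n), off + n))
            off += n + 1
        return blocks, off, off + 5

    def get_state(self) -> np.ndarray:
        blocks, pk_off, eff_off = self._layout()
        y = np.zeros(eff_off + 2)
        for site, sl, cum_idx in blocks:
            y[sl] = site.psi
            y[cum_idx] = site.cumulative_outflux
        y[pk_off : pk_off + 5] = self.pk_state
        y[eff_off :] = self.effect_state
        return y

    def set_state(self, y: np.ndarray) -> None:
        blocks, pk_off, eff_off = self._layout()
        for site, sl, cum_idx in blocks:
            site.psi = y[sl].copy()
            site.cumulative_outflux = float(y[cum_idx])
        self.pk_state = y[pk_off : pk_off + 5].copy()
        self.effect_state = y[eff_off :].copy()

    # -- dynamics --------------------------------------------------------
    def rhs(self, y: np.ndarray) -> np.ndarray:
        """Composed right-hand side over the current site configuration."""
        blocks, pk_off, eff_off = self._layout()
        tp = self.twin.transport
        area = self.twin.skin.patch_area
        c_p = y[pk_off]
        bottom_psi = c_p * NG_PER_ML_TO_NG_PER_M3 / tp.K_dermis
        dy = np.zeros_like(y)
        total_mass_rate = 0.0  # ng/s into blood over all sites
        for site, sl, cum_idx in blocks:
            psi = y[sl]
            G, kw = site.operators(tp)
            face_flux = np.empty(psi.size + 1)
            face_flux[0] = 0.0  # no-flux top
            face_flux[1:-1] = G[:-1] * (psi[:-1] - psi[1:])
            face_flux[-1] = G[-1] * (psi[-1] - bottom_psi)
            dy[sl] = (face_flux[:-1] - face_flux[1:]) / kw
            dy[cum_idx] = face_flux[-1] * area
            total_mass_rate += face_flux[-1] * area
        dy[pk_off : pk_off + 5] = pkpd.pk_rhs(
            y[pk_off : pk_off + 5], self.twin.pk, total_mass_rate / area, area
        )
        dy[eff_off :] = pkpd.effect_rhs(y[eff_off :], c_p, self.twin.pd)
        return dy

    def assemble_matrix(self) -> csc_matrix:
        """Exact system matrix, built by probing the linear RHS."""
        n = self.get_state().size
        basis = np.zeros(n)
        cols = []
        for j in range(n):
            basis[j] = 1.0
            cols.append(self.rhs(basis))
            basis[j] = 0.0
        return csc_matrix(np.column_stack(cols))

    def integrate(self, t0_h: float, t1_h: float, t_eval_h: np.ndarray) -> np.ndarray:
        """Advance the coupled state from t0 to t1 (hours), returning the
        state trajectory at ``t_eval_h`` (shape (n_times, n_states))."""
        y0 = self.get_state()
        if t1_h <= t0_h:
            return y0[None, :]
        A = self.assemble_matrix()
        # Per-block absolute tolerances: the configured atol is on the ng/ml
        # scale; potentials live on the ng/m3 scale and cumulative outflux on
        # the scale of the patch load.
        atol_conc = self.numerics.get("atol", 1e-9)
        atol = np.full_like(y0, atol_conc)
        blocks, pk_off, _ = self._layout()
        for _, sl, cum_idx in blocks:
            atol[sl] = atol_conc * NG_PER_ML_TO_NG_PER_M3
            atol[cum_idx] = max(self.twin.skin.patch_load * 1e-9, atol_conc)
        # The system is autonomous, so integrate on a segment-local clock:
        # restarting at t = 0 keeps the stiff solver's initial-step choice
        # clear of the eps * |t| floor after a patch-event discontinuity.
        sol = solve_ivp(
            lambda t, y: A @ y,
            (0.0, (t1_h - t0_h) * 3600.0),
            y0,
            method="BDF",
            t_eval=(np.asarray(t_eval_h) - t0_h) * 3600.0,
            jac=lambda t, y: A,
            rtol=self.numerics.get("rtol", 1e-6),
            atol=atol,
            max_step=self.numerics.get("max_step_h", 6.0) * 3600.0,
        )
        if not sol.success:
            last_t = sol.t[-1] / 3600.0 + t0_h if len(sol.t) else t0_h
            raise RuntimeError(f"integration failed at t = {last_t:.2f} h: {sol.message}")
        traj = sol.y.T
        # negative-concentration guard, per block scale (potentials live on
        # the ng/m3 scale, PK and effect concentrations on ng/ml)
        conc = traj[:, pk_off:]
        if conc.min() < _NEGATIVE_TOL * max(1.0, np.abs(conc).max()):
            raise RuntimeError("negative concentrations beyond tolerance during integration")
        for _, sl, _ in blocks:
            psi = traj[:, sl]
            if psi.min() < _NEGATIVE_TOL * max(1.0, np.abs(psi).max()):
                raise RuntimeError("negative potentials beyond tolerance during integration")
        self.set_state(traj[-1])
        return traj

    # -- observables -----------------------------------------------------
    def observe(self, y: np.ndarray) -> dict:
        """Clinical observables for one state vector."""
        blocks, pk_off, eff_off = self._layout()
        tp = self.twin.transport
        c_p = float(y[pk_off])
        bottom_psi = c_p * NG_PER_ML_TO_NG_PER_M3 / tp.K_dermis
        flux_total = sum(
            skin.flux_out(y[sl], site.grid, tp, bottom_psi).flux for site, sl, _ in blocks
        )
        eff = pkpd.clinical_effects(y[eff_off :], self.twin.pd)
        return {
            "c_p_ng_ml": c_p,
            "c_e_vas": float(y[eff_off]),
            "c_e_rd": float(y[eff_off + 1]),
            "vas": eff.vas,
            "ventilation_L_min": eff.ventilation,
            "flux_ng_per_m2_s": float(flux_total),
            "n_active_sites": len(blocks),
        }

    def current_vas(self) -> float:
        return pkpd.clinical_effects(self.effect_state, self.twin.pd).vas

    def mass_audit(self) -> list[dict]:
        """Per-site mass bookkeeping [ng] (includes retired sites)."""
        tp = self.twin.transport
        area = self.twin.skin.patch_area
        audit = []
        for i, site in enumerate(self.sites):
            entry = {
                "site": i,
                "applied_at_h": site.applied_at_h,
                "patch_attached": site.patch_attached,
                "retired": site.retired,
                "initial_load_ng": site.initial_load,
                "cumulative_outflux_ng": site.cumulative_outflux,
            }
            if not site.retired:
                entry["mass_patch_ng"] = skin.layer_mass(site.psi, site.grid, tp, area, "patch")
                entry["mass_skin_ng"] = skin.site_mass(site.psi, site.grid, tp, area) - entry[
                    "mass_patch_ng"
                ]
            audit.append(entry)
        return audit
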