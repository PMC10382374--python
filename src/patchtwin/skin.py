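"""Transient Fickian diffusion through patch and layered skin.

One application site is a 1-D stack of patch, stratum corneum, viable
epidermis and equivalent dermis.  Lateral boundaries carry no flux and all
data are laterally uniform, so the governing 2-D problem reduces exactly
to 1-D.  The solver works in the drug-potential formulation psi = c / K
(potential is continuous across layer interfaces while concentration jumps
by the partition coefficient), discretized by a conservative finite-volume
scheme: cell balance d(K psi)/dt = d/dx (D K dpsi/dx), interface face
conductances composed in series (harmonic), no-flux at the top face and a
Dirichlet potential at the bottom face where the dermis meets the
capillary bed (psi_bottom = c_plasma / K_dermis).

Internal units: meters, seconds, potentials and concentrations in ng/m3
(1 ng/ml = 1e6 ng/m3), fluxes in ng m-2 s-1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import SkinGeometry, TransportParameters

NG_PER_ML_TO_NG_PER_M3 = 1e6

LAYERS = ("patch", "sc", "vep", "dermis")


@dataclass(frozen=True)
class Grid1D:
    """Finite-volume grid over the layer stack.

    Faces coincide with every layer boundary; within a layer, cell widths
    grade geometrically toward both interfaces (refinement factor > 1
    means finer cells at the interfaces).
    """

    widths: np.ndarray  # cell widths [m]
    layer_id: np.ndarray  # index into `layers` per cell
    layers: tuple[str, ...]
    layer_thickness: tuple[float, ...]

    @property
    def n_cells(self) -> int:
        return self.widths.size

    @property
    def centers(self) -> np.ndarray:
        faces = self.faces
        return 0.5 * (faces[:-1] + faces[1:])

    @property
    def faces(self) -> np.ndarray:
        return np.concatenate(([0.0], np.cumsum(self.widths)))

    @property
    def total_thickness(self) -> float:
        return float(self.widths.sum())


@dataclass
class SkinState:
    """Drug potential per cell plus the cumulative mass delivered to blood."""

    psi: np.ndarray  # [ng/m3]
    cumulative_outflux: float = 0.0  # [ng]
    site_active: bool = True


@dataclass(frozen=True)
class FluxRecord:
    flux: float  # bottom-boundary flux density [ng m-2 s-1], positive into blood
    time: float  # [s]


def _graded_widths(thickness: float, n: int, refinement: float) -> np.ndarray:
    """Cell widths in one layer, graded toward both layer interfaces.

    Cell faces follow the smooth stretching s(xi) = xi - beta sin(2 pi xi)
    / (2 pi) with beta = 1 - 1/refinement, so widths are smallest at both
    interfaces and grow monotonically toward the layer centre; refinement
    1.0 gives uniform cells.  The mapping is independent of n, so doubling
    the cell count refines the *same* grid family (geometrically similar
    nested grids, as a Richardson study requires).
    """
    if refinement < 1.0:
        raise ValueError("interface refinement factor must be >= 1")
    beta = 1.0 - 1.0 / refinement
    xi = np.linspace(0.0, 1.0, n + 1)
    s = xi - beta * np.sin(2 * np.pi * xi) / (2 * np.pi)
    return thickness * np.diff(s)


def build_grid(
    geometry: SkinGeometry,
    n_cells_per_layer: Sequence[int],
    interface_refinement: float = 2.0,
    include_patch: bool = True,
) -> Grid1D:
    """Grid over (patch +) SC + viable epidermis + dermis.

    ``include_patch=False`` builds the grid of a site whose patch has been
    removed (the residual skin depot keeps its three layers).
    """
    names = LAYERS if include_patch else LAYERS[1:]
    thicknesses = {
        "patch": geometry.d_patch,
        "sc": geometry.d_sc,
        "vep": geometry.d_vep,
        "dermis": geometry.d_edm,
    }
    counts = list(n_cells_per_layer)
    if not include_patch and len(counts) == len(LAYERS):
        counts = counts[1:]
    if len(counts) != len(names):
        raise ValueError(f"need one cell count per layer ({names})")
    widths, ids = [], []
    for idx, name in enumerate(names):
        d = thicknesses[name]
        n = counts[idx]
        if d <= 0:
            raise ValueError(f"layer {name!r} has non-positive thickness {d}")
        if n < 4:
            raise ValueError(f"need at least 4 cells per layer, got {n} for {name!r}")
        widths.append(_graded_widths(d, n, interface_refinement))
        ids.append(np.full(n, idx))
    return Grid1D(
        widths=np.concatenate(widths),
        layer_id=np.concatenate(ids),
        layers=tuple(names),
        layer_thickness=tuple(thicknesses[n] for n in names),
    )


def cell_properties(grid: Grid1D, transport: TransportParameters) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell diffusivity and capacity arrays."""
    dmap = {
        "patch": transport.D_patch,
        "sc": transport.D_sc,
        "vep": transport.D_vep,
        "dermis": transport.D_dermis,
    }
    kmap = {
        "patch": transport.K_patch,
        "sc": transport.K_sc,
        "vep": transport.K_vep,
        "dermis": transport.K_dermis,
    }
    D = np.asarray([dmap[grid.layers[i]] for i in grid.layer_id])
    K = np.asarray([kmap[grid.layers[i]] for i in grid.layer_id])
    return D, K


def face_conductances(grid: Grid1D, transport: TransportParameters) -> np.ndarray:
    """Series (harmonic) conductance of every interior face plus the bottom
    half-cell conductance, in m/s acting on potential differences.

    Element j (j = 0..n-2) connects cells j and j+1; the last element is
    the bottom-face conductance toward the Dirichlet boundary.  Composing
    half-cell resistances in series enforces flux continuity and the
    partition-coefficient concentration jump at layer interfaces.
    """
    D, K = cell_properties(grid, transport)
    dk = D * K
    h = grid.widths
    inner = 1.0 / (h[:-1] / (2 * dk[:-1]) + h[1:] / (2 * dk[1:]))
    bottom = dk[-1] / (h[-1] / 2)
    if (inner <= 0).any() or bottom <= 0:
        raise AssertionError("non-positive face conductance")
    return np.concatenate([inner, [bottom]])


def initialize_site(
    grid: Grid1D,
    transport: TransportParameters,
    patch_load: float,
    patch_area: float,
) -> SkinState:
    """Uniform drug loading in the patch cells, drug-free skin.

    The patch concentration is load / (area x patch thickness) [ng/m3],
    converted to potential through the patch capacity, so the integral of
    K psi over the patch equals the load exactly at t = 0.
    """
    psi = np.zeros(grid.n_cells)
    if "patch" in grid.layers:
        pid = grid.layers.index("patch")
        mask = grid.layer_id == pid
        d_patch = grid.widths[mask].sum()
        if patch_load > 0:
            c0 = patch_load / (patch_area * d_patch)
            psi[mask] = c0 / transport.K_patch
    return SkinState(psi=psi)


def diffusion_rhs(
    psi: np.ndarray,
    grid: Grid1D,
    transport: TransportParameters,
    bottom_psi: float,
    top_psi: float | None = None,
) -> np.ndarray:
    """Time derivative of the potential field.

    No-flux at the top face unless ``top_psi`` imposes a Dirichlet
    potential there (used by verification tests); Dirichlet ``bottom_psi``
    (= c_plasma / K_dermis) at the bottom face.
    """
    _, K = cell_properties(grid, transport)
    G = face_conductances(grid, transport)
    flux = np.empty(grid.n_cells + 1)  # flux density through each face, downward positive
    flux[1:-1] = G[:-1] * (psi[:-1] - psi[1:])
    flux[-1] = G[-1] * (psi[-1] - bottom_psi)
    if top_psi is None:
        flux[0] = 0.0
    else:
        D, _ = cell_properties(grid, transport)
        g_top = D[0] * K[0] / (grid.widths[0] / 2)
        flux[0] = g_top * (top_psi - psi[0])
    return (flux[:-1] - flux[1:]) / (K * grid.widths)


def flux_out(
    psi: np.ndarray,
    grid: Grid1D,
    transport: TransportParameters,
    bottom_psi: float,
    time: float = 0.0,
) -> FluxRecord:
    """Diffusive flux density through the bottom face, positive into blood."""
    G = face_conductances(grid, transport)
    return FluxRecord(flux=float(G[-1] * (psi[-1] - bottom_psi)), time=time)


def site_mass(psi: np.ndarray, grid: Grid1D, transport: TransportParameters, area: float) -> float:
    """Total drug mass [ng] currently held in the site."""
    _, K = cell_properties(grid, transport)
    return float(np.sum(K * psi * grid.widths) * area)


def layer_mass(
    psi: np.ndarray, grid: Grid1D, transport: TransportParameters, area: float, layer: str
) -> float:
    _, K = cell_properties(grid, transport)
    if layer not in grid.layers:
        return 0.0
    mask = grid.layer_id == grid.layers.index(layer)
    return float(np.sum((K * psi * grid.widths)[mask]) * area)


def simulate_site(
    grid: Grid1D,
    transport: TransportParameters,
    psi0: np.ndarray,
    t_eval: np.ndarray,
    bottom_psi: float = 0.0,
    rtol: float = 1e-8,
    atol: float = 1e-4,
    max_step: float = np.inf,
    area: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Integrate a single decoupled site (fixed bottom potential).

    Returns (psi trajectory with shape (n_times, n_cells), bottom flux
    density per output time, cumulative outflux [ng] per output time,
    integrated by the solver alongside the field).  Used by the
    convergence study and the analytic-verification tests; the coupled
    therapy simulation lives in ``patchtwin.system``.
    """
    _, K = cell_properties(grid, transport)
    G = face_conductances(grid, transport)
    n = grid.n_cells
    # Linear operator: dpsi/dt = A psi + b (b from the Dirichlet bottom),
    # plus one quadrature state for the cumulative bottom outflux.
    main = np.zeros(n)
    lower = np.zeros(n - 1)
    upper = np.zeros(n - 1)
    kw = K * grid.widths
    main[:-1] -= G[:-1] / kw[:-1]
    main[1:] -= G[:-1] / kw[1:]
    lower[:] = G[:-1] / kw[1:]
    upper[:] = G[:-1] / kw[:-1]
    main[-1] -= G[-1] / kw[-1]
    from scipy.sparse import lil_matrix

    A = lil_matrix((n + 1, n + 1))
    A[np.arange(n), np.arange(n)] = main
    A[np.arange(1, n), np.arange(n - 1)] = lower
    A[np.arange(n - 1), np.arange(1, n)] = upper
    A[n, n - 1] = G[-1] * area
    A = A.tocsc()
    b = np.zeros(n + 1)
    b[-2] = G[-1] * bottom_psi / kw[-1]
    b[-1] = -G[-1] * bottom_psi * area

    y0 = np.concatenate([psi0, [0.0]])
    atol_vec = np.full(n + 1, atol)
    atol_vec[-1] = max(abs(float(np.max(psi0))) * 1e-9, atol)
    sol = solve_ivp(
        lambda t, y: A @ y + b,
        (float(t_eval[0]), float(t_eval[-1])),
        y0,
        method="BDF",
        t_eval=t_eval,
        jac=lambda t, y: A,
        rtol=rtol,
        atol=atol_vec,
        max_step=max_step,
    )
    if not sol.success:
        raise RuntimeError(f"site integration failed: {sol.message}")
    psi_t = sol.y[:-1].T
    cumout = sol.y[-1]
    flux = G[-1] * (psi_t[:, -1] - bottom_psi)
    return psi_t, flux, cumout


def richardson_convergence(
    geometry: SkinGeometry,
    transport: TransportParameters,
    base_cells_per_layer: Sequence[int],
    levels: int = 3,
    interface_refinement: float = 2.0,
    time_h: float = 24.0,
    rtol: float = 1e-10,
) -> dict:
    """Grid-convergence study of the bottom-flux functional.

    Runs the drug-release problem (loaded patch, drug-free skin, zero
    bottom potential) on ``levels`` nested grids (cell counts doubled per
    level), evaluates the bottom flux density at ``time_h``, and estimates
    the observed order and Richardson-extrapolated flux.  Grids whose
    error against the extrapolate exceeds 0.1% are flagged.
    """
    if levels < 3:
        raise ValueError("need at least 3 grid levels")
    t_end = time_h * 3600.0
    t_eval = np.array([0.0, t_end])
    fluxes, counts = [], []
    for lvl in range(levels):
        cells = [int(c) * 2**lvl for c in base_cells_per_layer]
        grid = build_grid(geometry, cells, interface_refinement)
        state = initialize_site(grid, transport, geometry.patch_load, geometry.patch_area)
        _, flux, _ = simulate_site(grid, transport, state.psi, t_eval, bottom_psi=0.0, rtol=rtol)
        fluxes.append(float(flux[-1]))
        counts.append(sum(cells))
    f = np.asarray(fluxes)
    d1, d2 = f[-2] - f[-3], f[-1] - f[-2]
    if d1 == d2 == 0.0:
        raise ValueError("identical fluxes across grid levels; order undefined")
    result: dict = {"n_cells": counts, "flux": fluxes}
    if d2 == 0.0 or d1 / d2 <= 1.0:
        result.update(observed_order=None, extrapolated=None, monotone=False, errors=None)
        return result
    order = float(np.log2(d1 / d2))
    extrapolated = f[-1] + d2 / (2**order - 1)
    errors = np.abs(f - extrapolated) / abs(extrapolated)
    result.update(
        observed_order=order,
        extrapolated=float(extrapolated),
        monotone=True,
        errors=errors.tolist(),
        flagged=[c for c, e in zip(counts, errors) if e > 1e-3],
    )
    return result
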