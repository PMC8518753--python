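"""Steady 2D advection-diffusion-reaction model of the PHIP microfluidic chip.

The device is represented by its 2D mid-plane: a straight reaction pathway
(55 mm x 0.1 mm) carrying the liquid, a PDMS membrane slab (25 mm x 0.4 mm)
sitting on one channel wall through which hydrogen diffuses from the gas
side, and a widened sample-detection chamber (2 mm x 0.5 mm) downstream.
An out-of-plane depth of 1.4 mm converts 2D fluxes into volumetric ones.

Physics
-------
* Flow: the channel Reynolds number is << 1 and the geometry is a straight
  duct, so the velocity field is prescribed analytically as plane
  Poiseuille flow across the local liquid width, rescaled segment by
  segment so the volumetric flux equals the inlet flow rate everywhere.
  Transverse velocities at the chamber transitions are reconstructed from
  discrete continuity, making the face velocity field exactly
  divergence-free on the mesh.
* Species transport: steady finite-volume discretisation of
  div(u c_i) - div(D grad c_i) = R_i on a structured rectilinear mesh,
  with first-order upwinding for convection (axial cell Peclet numbers are
  in the hundreds).  All species share D = 1e-9 m^2/s.
* Membrane: hydrogen alone is transported inside the membrane subdomain
  (diffusion only, zero velocity).  A Dirichlet condition h_pdms holds on
  the membrane's outer boundary, and concentration is continuous across
  the membrane/liquid interface; the through-thickness diffusive
  resistance of the membrane is what throttles hydrogen uptake at high
  flow.  Other species see the interface as a wall.
* Kinetics: the mass-action source terms of
  :mod:`phipflow.reaction_kinetics`, with hydrogen free (membrane-fed); the
  relaxation sink k6 converts hyperpolarised allyl acetate to its relaxed
  form wherever it resides.
* Boundary conditions: Dirichlet inlet concentrations, advective outflow
  (zero diffusive flux) at the outlet, no-flux walls.

The nonlinear steady system is solved by Newton iteration with
pseudo-transient continuation (SER time-step ramping) and a sparse LU
factorisation of the coupled Jacobian.  Species that never appear as
reactants decouple and are recovered afterwards by single linear solves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .reaction_kinetics import (
    N_SPECIES,
    SPECIES,
    SPECIES_INDEX,
    ReactionNetwork,
    reaction_fluxes,
    rhs_jacobian,
)
from .reaction_kinetics import _REACTANT_IDX, STOICHIOMETRY  # noqa: F401

__all__ = [
    "ChipGeometry",
    "TransportConfig",
    "FlowField",
    "FieldSolution",
    "GeometryError",
    "TransportError",
    "build_geometry",
    "build_mesh",
    "compute_flow_field",
    "solve_steady_transport",
    "chamber_mean",
    "pathway_profile",
    "config_to_yaml",
    "config_from_yaml",
    "solution_to_csv",
    "profile_to_csv",
]

_MM = 1e-3  # mm -> m


class GeometryError(ValueError):
    """Invalid chip geometry."""


class TransportError(RuntimeError):
    """Steady transport solve failed."""

    def __init__(self, message: str, residual_history: Sequence[float] = ()):  # noqa: D107
        super().__init__(message)
        self.residual_history = list(residual_history)


@dataclass(frozen=True)
class ChipGeometry:
    """Axial layout of the 2D simulation domain (all lengths in mm).

    The channel runs from x = 0 (inlet) to x = channel_length (outlet)
    along one wall at y = 0.  The membrane occupies
    [membrane_start, membrane_start + membrane_length] x
    [channel_width, channel_width + membrane_thickness]; the chamber
    widens the liquid to ``chamber_width`` over
    [chamber_start, chamber_start + chamber_length].  The default axial
    layout (inlet development 2 mm, membrane 2-27 mm, chamber 48-50 mm)
    is chosen so the liquid volume matches the real chip's ~8.5 uL at the
    1.4 mm out-of-plane depth.
    """

    channel_length_mm: float = 55.0
    channel_width_mm: float = 0.1
    membrane_start_mm: float = 2.0
    membrane_length_mm: float = 25.0
    membrane_thickness_mm: float = 0.4
    chamber_start_mm: float = 48.0
    chamber_length_mm: float = 2.0
    chamber_width_mm: float = 0.5
    depth_mm: float = 1.4

    def __post_init__(self) -> None:
        for name in (
            "channel_length_mm",
            "channel_width_mm",
            "membrane_length_mm",
            "membrane_thickness_mm",
            "chamber_length_mm",
            "chamber_width_mm",
            "depth_mm",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.chamber_width_mm <= self.channel_width_mm:
            raise GeometryError("chamber must be wider than the channel")
        if not (0 <= self.membrane_start_mm < self.membrane_end_mm <= self.channel_length_mm):
            raise GeometryError("membrane must lie within the channel extent")
        if not (0 <= self.chamber_start_mm < self.chamber_end_mm <= self.channel_length_mm):
            raise GeometryError("chamber must lie within the channel extent")
        if self.chamber_start_mm < self.membrane_start_mm:
            raise GeometryError("chamber must start downstream of the membrane start")
        if self.chamber_start_mm < self.membrane_end_mm:
            raise GeometryError("chamber overlaps the membrane segment")

    @property
    def membrane_end_mm(self) -> float:
        return self.membrane_start_mm + self.membrane_length_mm

    @property
    def chamber_end_mm(self) -> float:
        return self.chamber_start_mm + self.chamber_length_mm

    @property
    def liquid_volume_uL(self) -> float:
        area_mm2 = (
            self.channel_length_mm * self.channel_width_mm
            + self.chamber_length_mm * (self.chamber_width_mm - self.channel_width_mm)
        )
        return area_mm2 * self.depth_mm  # 1 mm^3 = 1 uL


def build_geometry(chamber_shift_mm: float = 0.0, **params) -> ChipGeometry:
    """Construct a :class:`ChipGeometry`, optionally shifting the chamber.

    ``chamber_shift_mm`` moves the chamber along the channel axis (negative
    = upstream, e.g. -12.5 for the relocated-chamber scenario); all other
    dimensions stay fixed.  Geometry invariants are validated.
    """
    geo = ChipGeometry(**params)
    if chamber_shift_mm:
        geo = replace(geo, chamber_start_mm=geo.chamber_start_mm + chamber_shift_mm)
    return geo


@dataclass(frozen=True)
class TransportConfig:
    """Transport parameters and mesh resolution.

    Flow rate in uL/min (simulated range 0-50); one diffusion coefficient
    for every species (1e-9 m^2/s); hydrogen concentration h_pdms on the
    membrane outer boundary; inlet concentrations in mM.  ``dx_mm`` is the
    target axial cell size; ``n_across_channel`` / ``n_across_upper`` the
    transverse cell counts in the channel strip and the membrane/chamber
    strip.  ``refine`` scales all three for mesh-convergence studies.
    """

    flow_uL_min: float = 8.4
    diffusion_m2_s: float = 1e-9
    h_pdms_mM: float = 20.0
    inlet_mM: Mapping[str, float] = field(
        default_factory=lambda: {"1": 5.0, "3": 20.0}
    )
    density_kg_m3: float = 789.0
    temperature_K: float = 298.15
    dx_mm: float = 0.1
    n_across_channel: int = 8
    n_across_upper: int = 8
    refine: int = 1
    scheme: str = "upwind"

    def __post_init__(self) -> None:
        if not 0.0 <= self.flow_uL_min <= 50.0:
            raise ValueError("flow rate must be within the simulated range 0-50 uL/min")
        if self.diffusion_m2_s <= 0:
            raise ValueError("diffusion coefficient must be positive")
        if self.h_pdms_mM < 0:
            raise ValueError("h_pdms must be non-negative")
        unknown = set(self.inlet_mM) - set(SPECIES)
        if unknown:
            raise ValueError(f"unknown inlet species: {sorted(unknown)}")
        if self.scheme not in ("upwind", "central"):
            raise ValueError("scheme must be 'upwind' or 'central'")
        if self.refine < 1 or self.n_across_channel < 4:
            raise ValueError("need refine >= 1 and >= 4 cells across the channel")

    @property
    def flow_m3_s(self) -> float:
        return self.flow_uL_min * 1e-9 / 60.0

    def inlet_vector(self) -> np.ndarray:
        c = np.zeros(N_SPECIES)
        for s, v in self.inlet_mM.items():
            c[SPECIES_INDEX[s]] = v
        return c


# cell types
_INACTIVE, _FLUID, _MEMBRANE = 0, 1, 2


@dataclass
class Mesh:
    """Structured rectilinear mesh with fluid/membrane/inactive cell mask."""

    x_edges: np.ndarray  # (nx+1,) m
    y_edges: np.ndarray  # (ny+1,) m
    cell_type: np.ndarray  # (nx, ny) int8
    n_channel_rows: int
    geometry: ChipGeometry

    @property
    def nx(self) -> int:
        return self.x_edges.size - 1

    @property
    def ny(self) -> int:
        return self.y_edges.size - 1

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def dx(self) -> np.ndarray:
        return np.diff(self.x_edges)

    @property
    def dy(self) -> np.ndarray:
        return np.diff(self.y_edges)

    def cell_volumes(self) -> np.ndarray:
        depth = self.geometry.depth_mm * _MM
        return np.outer(self.dx, self.dy) * depth


def _segmented_edges(breaks: Sequence[float], target: float) -> np.ndarray:
    """Subdivide [breaks[0], breaks[-1]] so every breakpoint is a mesh edge."""
    edges = [np.array([breaks[0]])]
    for a, b in zip(breaks[:-1], breaks[1:]):
        n = max(1, round((b - a) / target))
        edges.append(np.linspace(a, b, n + 1)[1:])
    return np.concatenate(edges)


def build_mesh(geometry: ChipGeometry, config: TransportConfig) -> Mesh:
    g = geometry
    dx = config.dx_mm * _MM / config.refine
    xb = sorted(
        {
            0.0,
            g.membrane_start_mm * _MM,
            g.membrane_end_mm * _MM,
            g.chamber_start_mm * _MM,
            g.chamber_end_mm * _MM,
            g.channel_length_mm * _MM,
        }
    )
    x_edges = _segmented_edges(xb, dx)

    w = g.channel_width_mm * _MM
    mem_top = (g.channel_width_mm + g.membrane_thickness_mm) * _MM
    cham_top = g.chamber_width_mm * _MM
    y_top = max(mem_top, cham_top)
    n_ch = config.n_across_channel * config.refine
    yb_upper = sorted({w, mem_top, cham_top, y_top})
    dy_upper = (y_top - w) / (config.n_across_upper * config.refine)
    y_edges = np.concatenate(
        [np.linspace(0.0, w, n_ch + 1), _segmented_edges(yb_upper, dy_upper)[1:]]
    )

    nx, ny = x_edges.size - 1, y_edges.size - 1
    xc = 0.5 * (x_edges[:-1] + x_edges[1:])
    yc = 0.5 * (y_edges[:-1] + y_edges[1:])
    cell_type = np.zeros((nx, ny), dtype=np.int8)
    cell_type[:, :n_ch] = _FLUID
    in_mem_x = (xc > g.membrane_start_mm * _MM) & (xc < g.membrane_end_mm * _MM)
    in_cham_x = (xc > g.chamber_start_mm * _MM) & (xc < g.chamber_end_mm * _MM)
    upper = yc > w
    cell_type[np.ix_(in_mem_x, upper & (yc < mem_top))] = _MEMBRANE
    cell_type[np.ix_(in_cham_x, upper & (yc < cham_top))] = _FLUID
    return Mesh(x_edges, y_edges, cell_type, n_ch, geometry)


@dataclass
class FlowField:
    """Prescribed, discretely divergence-free velocity field.

    ``u_face[i, j]`` is the axial velocity on the vertical face at
    ``x_edges[i]`` spanning row j; ``v_face[i, j]`` the transverse velocity
    on the horizontal face at ``y_edges[j]`` of column i.  ``u_cell`` is
    the cell-centred axial velocity (zero in the membrane subdomain).
    """

    mesh: Mesh
    config: TransportConfig
    u_face: np.ndarray  # (nx+1, ny)
    v_face: np.ndarray  # (nx, ny+1)
    u_cell: np.ndarray  # (nx, ny)

    def cross_section_flux(self, i_face: int) -> float:
        """Volumetric flux (m^3/s) through vertical-face column ``i_face``."""
        depth = self.mesh.geometry.depth_mm * _MM
        return float(np.sum(self.u_face[i_face] * self.mesh.dy) * depth)


def _poiseuille_cell_means(y_edges: np.ndarray, height: float, q2d: float) -> np.ndarray:
    """Exact cell averages of a plane-Poiseuille profile on [0, height].

    The parabola u(y) = 6 u_mean (y/H)(1 - y/H) integrates to q2d = u_mean*H;
    cells above the opening get zero.  The result is renormalised so the
    discrete flux equals q2d exactly.
    """
    if height <= 0 or q2d == 0:
        return np.zeros(y_edges.size - 1)
    u_mean = q2d / height
    y = np.clip(y_edges, 0.0, height)

    def antideriv(yy: np.ndarray) -> np.ndarray:
        return 6.0 * u_mean * (yy**2 / (2.0 * height) - yy**3 / (3.0 * height**2))

    dy = np.diff(y_edges)
    means = np.where(dy > 0, (antideriv(y[1:]) - antideriv(y[:-1])) / dy, 0.0)
    flux = float(np.sum(means * dy))
    if flux > 0:
        means *= q2d / flux
    return means


def compute_flow_field(
    geometry: ChipGeometry, config: TransportConfig, mesh: Mesh | None = None
) -> FlowField:
    """Plane-Poiseuille flow per axial segment with exact flux continuity."""
    if mesh is None:
        mesh = build_mesh(geometry, config)
    nx, ny = mesh.nx, mesh.ny
    dy, dx = mesh.dy, mesh.dx
    q2d = config.flow_m3_s / (geometry.depth_mm * _MM)  # m^2/s

    fluid = mesh.cell_type == _FLUID
    # liquid opening height of each column (fluid cells are contiguous from y=0)
    col_height = np.array(
        [mesh.y_edges[np.max(np.nonzero(fluid[i])[0]) + 1] if fluid[i].any() else 0.0
         for i in range(nx)]
    )

    u_face = np.zeros((nx + 1, ny))
    for i in range(nx + 1):
        if i == 0:
            h = col_height[0]
        elif i == nx:
            h = col_height[-1]
        else:
            h = min(col_height[i - 1], col_height[i])  # opening between columns
        u_face[i] = _poiseuille_cell_means(mesh.y_edges, h, q2d)

    # transverse velocities from discrete continuity, swept from the y=0 wall
    v_face = np.zeros((nx, ny + 1))
    for i in range(nx):
        for j in range(ny):
            if not fluid[i, j]:
                break
            net_axial = (u_face[i + 1, j] - u_face[i, j]) * dy[j]
            v_face[i, j + 1] = v_face[i, j] - net_axial / dx[i]
    # kill roundoff on the topmost open face
    v_face[np.abs(v_face) < 1e-18] = 0.0

    u_cell = 0.5 * (u_face[:-1] + u_face[1:])
    u_cell[~fluid] = 0.0
    return FlowField(mesh, config, u_face, v_face, u_cell)


# ---------------------------------------------------------------------------
# finite-volume operators


def _domain_ids(mask: np.ndarray) -> np.ndarray:
    ids = np.full(mask.shape, -1, dtype=int)
    ids[mask] = np.arange(int(mask.sum()))
    return ids


class _TransportOperator:
    """Linear steady operator A c = b for one species domain.

    b = inlet_weight * c_inlet + membrane_weight * h_pdms.
    """

    def __init__(
        self,
        mesh: Mesh,
        flow: FlowField,
        D: float,
        mask: np.ndarray,
        membrane_dirichlet: bool,
        scheme: str,
    ) -> None:
        nx, ny = mesh.nx, mesh.ny
        depth = mesh.geometry.depth_mm * _MM
        dx, dy = mesh.dx, mesh.dy
        xc, yc = mesh.x_centers, mesh.y_centers
        ids = _domain_ids(mask)
        n = int(mask.sum())
        self.ids = ids
        self.n = n

        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        diag = np.zeros(n)
        inlet_w = np.zeros(n)
        mem_w = np.zeros(n)

        def add(r, c, v):
            rows.append(np.asarray(r, dtype=int))
            cols.append(np.asarray(c, dtype=int))
            vals.append(np.asarray(v, dtype=float))

        upwind = scheme == "upwind"
        max_pe = 0.0

        # vertical (x-normal) internal faces
        for i in range(1, nx):
            both = mask[i - 1] & mask[i]
            if not both.any():
                continue
            j = np.nonzero(both)[0]
            area = dy[j] * depth
            g = D * area / (xc[i] - xc[i - 1])
            m = flow.u_face[i, j] * area
            max_pe = max(max_pe, float(np.max(np.abs(m) / np.maximum(g, 1e-300))))
            p, q = ids[i - 1, j], ids[i, j]
            if upwind:
                mp, mm = np.maximum(m, 0.0), np.maximum(-m, 0.0)
                add(p, p, g + mp)
                add(p, q, -(g + mm))
                add(q, q, g + mm)
                add(q, p, -(g + mp))
            else:  # central differencing (diagnostic use only)
                add(p, p, g + 0.5 * m)
                add(p, q, -g + 0.5 * m)
                add(q, q, g - 0.5 * m)
                add(q, p, -g - 0.5 * m)

        # horizontal (y-normal) internal faces
        for j in range(1, ny):
            both = mask[:, j - 1] & mask[:, j]
            if not both.any():
                continue
            i = np.nonzero(both)[0]
            area = dx[i] * depth
            g = D * area / (yc[j] - yc[j - 1])
            m = flow.v_face[i, j] * area
            p, q = ids[i, j - 1], ids[i, j]
            mp, mm = np.maximum(m, 0.0), np.maximum(-m, 0.0)
            add(p, p, g + mp)
            add(p, q, -(g + mm))
            add(q, q, g + mm)
            add(q, p, -(g + mp))

        # inlet (x = 0) and outlet (x = L) boundary faces, fluid rows only;
        # at zero flow the inlet port is treated as closed (no-flux)
        if flow.config.flow_uL_min > 0:
            j0 = np.nonzero(mask[0] & (mesh.cell_type[0] == _FLUID))[0]
            area = dy[j0] * depth
            g_in = D * area / xc[0]
            m_in = flow.u_face[0, j0] * area
            p = ids[0, j0]
            diag[p] += g_in
            inlet_w[p] += g_in + m_in

        j1 = np.nonzero(mask[-1] & (mesh.cell_type[-1] == _FLUID))[0]
        m_out = flow.u_face[nx, j1] * dy[j1] * depth
        diag[ids[-1, j1]] += m_out

        # membrane outer-boundary Dirichlet (topmost membrane cell per column)
        if membrane_dirichlet:
            mem = mesh.cell_type == _MEMBRANE
            for i in range(nx):
                jj = np.nonzero(mem[i] & mask[i])[0]
                if jj.size == 0:
                    continue
                jtop = jj.max()
                y_outer = mesh.y_edges[jtop + 1]
                g_m = D * dx[i] * depth / (y_outer - yc[jtop])
                pid = ids[i, jtop]
                diag[pid] += g_m
                mem_w[pid] += g_m

        if not upwind and max_pe > 2:
            warnings.warn(
                f"cell Peclet number {max_pe:.1f} > 2 with central differencing; "
                "expect oscillations (use scheme='upwind')",
                stacklevel=3,
            )

        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        self.A = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        self.inlet_weight = inlet_w
        self.membrane_weight = mem_w
        self.max_cell_peclet = max_pe


@dataclass
class FieldSolution:
    """Steady per-species concentration fields on the chip mesh.

    ``fields[species]`` is an (nx, ny) array in mM, NaN outside the
    species' domain (membrane cells belong to hydrogen only).
    """

    mesh: Mesh
    geometry: ChipGeometry
    config: TransportConfig
    network: ReactionNetwork
    fields: dict[str, np.ndarray]
    residual_norm: float
    residual_history: list[float]
    newton_iterations: int

    def field(self, species: str) -> np.ndarray:
        if species not in self.fields:
            raise KeyError(f"unknown species {species!r}")
        return self.fields[species]


def _nonlinear_species(network: ReactionNetwork) -> list[str]:
    active: set[int] = set()
    for j in range(network.k.size):
        if network.k[j] > 0:
            for idx in _REACTANT_IDX[j]:
                if idx >= 0:
                    active.add(int(idx))
    if network.hydrogen_clamped:
        active.discard(SPECIES_INDEX["2"])
    return [s for s in SPECIES if SPECIES_INDEX[s] in active]


def solve_steady_transport(
    geometry: ChipGeometry,
    flow: FlowField,
    network: ReactionNetwork,
    config: TransportConfig,
    initial_guess: "FieldSolution | None" = None,
    rtol: float = 1e-8,
    max_iter: int = 200,
) -> FieldSolution:
    """Solve the steady coupled transport-reaction problem.

    Hydrogen is free (membrane-fed) unless the network clamps it, in which
    case the hydrogen field is held uniform at the clamp value (used for
    well-mixed-limit verification).  Returns fields for all ten species.
    Convergence is measured as the 2-norm of the finite-volume residual
    relative to the problem's advective/diffusive flux scale.
    """
    mesh = flow.mesh
    D = config.diffusion_m2_s
    scheme = config.scheme
    fluid = mesh.cell_type == _FLUID
    h2_mask = fluid | (mesh.cell_type == _MEMBRANE)
    n_fluid = int(fluid.sum())
    fl_i, fl_j = np.nonzero(fluid)
    vol = mesh.cell_volumes()
    v_fluid = vol[fluid]

    op_fluid = _TransportOperator(mesh, flow, D, fluid, False, scheme)
    clamped = network.hydrogen_clamped
    op_h2 = None if clamped else _TransportOperator(mesh, flow, D, h2_mask, True, scheme)

    c_in = config.inlet_vector()
    h2 = SPECIES_INDEX["2"]

    def operator_for(s: str) -> _TransportOperator:
        return op_h2 if (s == "2" and not clamped) else op_fluid  # type: ignore[return-value]

    def rhs_for(s: str, op: _TransportOperator) -> np.ndarray:
        b = op.inlet_weight * c_in[SPECIES_INDEX[s]]
        if s == "2" and not clamped:
            b = b + op.membrane_weight * config.h_pdms_mM
        return b

    nl_species = _nonlinear_species(network)
    n_nl = len(nl_species)

    _lu_cache: dict[str, object] = {}

    def lu_fluid():
        if "lu" not in _lu_cache:
            _lu_cache["lu"] = splu(op_fluid.A.tocsc())
        return _lu_cache["lu"]

    fields: dict[str, np.ndarray] = {}
    residual_history: list[float] = []
    iterations = 0

    # concentrations at fluid cells for rate evaluation
    conc_fluid = np.zeros((N_SPECIES, n_fluid))
    if clamped:
        conc_fluid[h2] = network.hydrogen_clamp

    if n_nl:
        ops = {s: operator_for(s) for s in nl_species}
        sizes = [ops[s].n for s in nl_species]
        offsets = np.concatenate(([0], np.cumsum(sizes)))
        n_unknowns = int(offsets[-1])
        A_big = sp.block_diag([ops[s].A for s in nl_species], format="csr")
        b_big = np.concatenate([rhs_for(s, ops[s]) for s in nl_species])

        # map fluid cells into each species' unknown block
        fluid_in_dom = [
            offsets[a] + ops[s].ids[fl_i, fl_j] for a, s in enumerate(nl_species)
        ]
        nl_idx = np.array([SPECIES_INDEX[s] for s in nl_species])

        # Jacobian scatter pattern: all species-pair couplings at each fluid
        # cell, ordered to match vals[a, b, cell].reshape(-1)
        jr_rows = np.concatenate([np.tile(fluid_in_dom[a], n_nl) for a in range(n_nl)])
        jr_cols = np.tile(np.concatenate(fluid_in_dom), n_nl)
        vol_per_unknown = np.zeros(n_unknowns)
        for a, s in enumerate(nl_species):
            dom_mask = h2_mask if (s == "2" and not clamped) else fluid
            vol_per_unknown[offsets[a]: offsets[a + 1]] = vol[dom_mask]

        def unpack(u: np.ndarray) -> None:
            for a, s in enumerate(nl_species):
                conc_fluid[nl_idx[a]] = u[fluid_in_dom[a]]

        def reaction_terms(u: np.ndarray):
            unpack(u)
            v = reaction_fluxes(conc_fluid, network)  # (6, n_fluid)
            R = STOICHIOMETRY.astype(float) @ v      # (10, n_fluid) mM/s
            r_big = np.zeros(n_unknowns)
            for a in range(n_nl):
                r_big[fluid_in_dom[a]] = R[nl_idx[a]] * v_fluid
            return r_big

        def reaction_jacobian(u: np.ndarray) -> sp.csr_matrix:
            unpack(u)
            jac = rhs_jacobian(conc_fluid, network)  # (10, 10, n_fluid)
            vals = np.empty((n_nl, n_nl, n_fluid))
            for a in range(n_nl):
                for b in range(n_nl):
                    vals[a, b] = jac[nl_idx[a], nl_idx[b]] * v_fluid
            return sp.csr_matrix(
                (vals.reshape(n_nl * n_nl * n_fluid), (jr_rows, jr_cols)),
                shape=(n_unknowns, n_unknowns),
            )

        # --- initial guess ---------------------------------------------------
        u0 = np.zeros(n_unknowns)
        if initial_guess is not None:
            for a, s in enumerate(nl_species):
                dom_mask = h2_mask if (s == "2" and not clamped) else fluid
                prev = initial_guess.fields[s][dom_mask]
                u0[offsets[a]: offsets[a + 1]] = np.nan_to_num(prev)
        else:
            for a, s in enumerate(nl_species):
                sl = slice(offsets[a], offsets[a + 1])
                if s == "2" and not clamped:
                    h2_lin = splu(op_h2.A.tocsc()).solve(rhs_for("2", op_h2))
                    u0[sl] = h2_lin
                elif c_in[SPECIES_INDEX[s]] > 0:
                    u0[sl] = c_in[SPECIES_INDEX[s]]

        # --- Newton iteration with pseudo-transient continuation -------------
        def resid(v: np.ndarray) -> tuple[np.ndarray, float]:
            with np.errstate(over="ignore", invalid="ignore"):
                r = A_big @ v - b_big - reaction_terms(v)
                return r, float(np.linalg.norm(r))

        u = u0
        res, norm = resid(u)
        norm0 = norm
        residual_history.append(norm)
        tol = rtol * max(norm, float(np.linalg.norm(b_big)), 1e-250)
        converged = norm <= tol

        # phase 1: damped plain Newton projected onto non-negative
        # concentrations (large negative excursions make the mass-action
        # Jacobian near-singular and break the sparse factorisation)
        newton_ok = True
        while not converged and newton_ok and iterations < max_iter:
            J = A_big - reaction_jacobian(u)
            delta = splu(J.tocsc()).solve(-res)
            step, accepted = 1.0, False
            for _ in range(5):
                u_new = np.maximum(u + step * delta, 0.0)
                res_new, norm_new = resid(u_new)
                if np.isfinite(norm_new) and (
                    norm_new < norm * (1.0 - 1e-4 * step) or norm_new <= tol
                ):
                    accepted = True
                    break
                step *= 0.5
            iterations += 1
            if accepted:
                u, res, norm = u_new, res_new, norm_new
                residual_history.append(norm)
                converged = norm <= tol
            else:
                newton_ok = False  # stagnated: fall back to pseudo-transient

        # phase 2: pseudo-transient continuation with SER time-step control;
        # steps advance pseudo-time unconditionally (the steady residual may
        # rise transiently), with projection onto non-negative concentrations
        dtau = 0.1  # s
        while not converged and iterations < max_iter:
            J = A_big - reaction_jacobian(u) + sp.diags(vol_per_unknown / dtau)
            delta = splu(J.tocsc()).solve(-res)
            u_new = np.maximum(u + delta, 0.0)
            res_new, norm_new = resid(u_new)
            iterations += 1
            if np.isfinite(norm_new) and norm_new < 1e4 * norm0:
                ratio = norm / max(norm_new, 1e-300)
                dtau = min(dtau * min(max(ratio, 0.3), 3.0), 1e9)
                u, res, norm = u_new, res_new, norm_new
                residual_history.append(norm)
                converged = norm <= tol
            else:
                dtau *= 0.25
                if dtau < 1e-10:
                    raise TransportError(
                        "pseudo-transient continuation stalled "
                        f"(residual {norm:.3e}, tol {tol:.3e})",
                        residual_history,
                    )
        if not converged:
            raise TransportError(
                f"steady transport did not converge in {iterations} iterations "
                f"(residual {norm:.3e}, tol {tol:.3e})",
                residual_history,
            )
        unpack(u)
        for a, s in enumerate(nl_species):
            dom_mask = h2_mask if (s == "2" and not clamped) else fluid
            f = np.full(mesh.cell_type.shape, np.nan)
            f[dom_mask] = u[offsets[a]: offsets[a + 1]]
            fields[s] = f
        final_norm = norm
    else:
        final_norm = 0.0

    # --- passive / linear species -------------------------------------------
    v_rates = reaction_fluxes(conc_fluid, network)
    R_all = STOICHIOMETRY.astype(float) @ v_rates
    for s in SPECIES:
        if s in fields:
            continue
        if s == "2" and clamped:
            f = np.full(mesh.cell_type.shape, np.nan)
            f[fluid] = network.hydrogen_clamp
            fields[s] = f
            continue
        op = operator_for(s)
        b = rhs_for(s, op)
        src = np.zeros(op.n)
        src[op.ids[fl_i, fl_j]] = R_all[SPECIES_INDEX[s]] * v_fluid
        rhs_vec = b + src
        if not np.any(rhs_vec):
            sol = np.zeros(op.n)  # nothing enters or is produced
        elif s == "2":
            sol = splu(op.A.tocsc()).solve(rhs_vec)
        else:
            sol = lu_fluid().solve(rhs_vec)
        f = np.full(mesh.cell_type.shape, np.nan)
        f[op.ids >= 0] = sol
        fields[s] = f
        residual_history.append(0.0)

    # tidy tiny negative undershoots from the linear solves
    for f in fields.values():
        np.clip(f, -1e-6, None, out=f)
        f[(f < 0) & (f > -1e-7)] = 0.0

    return FieldSolution(
        mesh=mesh,
        geometry=geometry,
        config=config,
        network=network,
        fields=fields,
        residual_norm=final_norm,
        residual_history=residual_history,
        newton_iterations=iterations,
    )


def chamber_mean(solution: FieldSolution, species: str = "4") -> float:
    """Volume-weighted mean concentration over the sample chamber (mM)."""
    f = solution.field(species)
    mesh = solution.mesh
    g = solution.geometry
    xc = mesh.x_centers
    in_cham = (xc > g.chamber_start_mm * _MM) & (xc < g.chamber_end_mm * _MM)
    mask = (mesh.cell_type == _FLUID) & in_cham[:, None] & np.isfinite(f)
    if not mask.any():
        raise TransportError("solution has no chamber cells")
    vol = mesh.cell_volumes()
    return float(np.sum(f[mask] * vol[mask]) / np.sum(vol[mask]))


def pathway_profile(solution: FieldSolution, species: str = "2"):
    """Width-averaged concentration along the channel axis.

    Returns (x_mm, concentration_mM) arrays; the average at each axial
    position runs over the local liquid cross-section.
    """
    f = solution.field(species)
    mesh = solution.mesh
    fluid = mesh.cell_type == _FLUID
    vals = np.where(fluid & np.isfinite(f), f, 0.0)
    weights = np.where(fluid & np.isfinite(f), mesh.dy[None, :], 0.0)
    prof = vals * weights
    with np.errstate(invalid="ignore"):
        avg = prof.sum(axis=1) / weights.sum(axis=1)
    return mesh.x_centers / _MM, avg


# ---------------------------------------------------------------------------
# YAML / CSV interfaces


def config_to_yaml(geometry: ChipGeometry, config: TransportConfig) -> str:
    import yaml

    doc = {
        "geometry": {
            "channel_length_mm": geometry.channel_length_mm,
            "channel_width_mm": geometry.channel_width_mm,
            "membrane_start_mm": geometry.membrane_start_mm,
            "membrane_length_mm": geometry.membrane_length_mm,
            "membrane_thickness_mm": geometry.membrane_thickness_mm,
            "chamber_start_mm": geometry.chamber_start_mm,
            "chamber_length_mm": geometry.chamber_length_mm,
            "chamber_width_mm": geometry.chamber_width_mm,
            "depth_mm": geometry.depth_mm,
        },
        "transport": {
            "flow_uL_min": config.flow_uL_min,
            "diffusion_m2_s": config.diffusion_m2_s,
            "h_pdms_mM": config.h_pdms_mM,
            "inlet_mM": dict(config.inlet_mM),
            "density_kg_m3": config.density_kg_m3,
            "temperature_K": config.temperature_K,
            "dx_mm": config.dx_mm,
            "n_across_channel": config.n_across_channel,
            "n_across_upper": config.n_across_upper,
            "scheme": config.scheme,
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)


def config_from_yaml(text: str) -> tuple[ChipGeometry, TransportConfig]:
    import yaml

    doc = yaml.safe_load(text)
    geo = ChipGeometry(**doc.get("geometry", {}))
    cfg = TransportConfig(**doc.get("transport", {}))
    return geo, cfg


def solution_to_csv(solution: FieldSolution, path) -> None:
    """Tidy CSV of all fields: x_mm, y_mm, species, concentration_mM."""
    import pandas as pd

    mesh = solution.mesh
    xs = np.repeat(mesh.x_centers / _MM, mesh.ny)
    ys = np.tile(mesh.y_centers / _MM, mesh.nx)
    frames = []
    for s, f in solution.fields.items():
        keep = np.isfinite(f).ravel()
        frames.append(
            pd.DataFrame(
                {
                    "x_mm": xs[keep],
                    "y_mm": ys[keep],
                    "species": s,
                    "concentration_mM": f.ravel()[keep],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def profile_to_csv(x_mm: np.ndarray, conc_mM: np.ndarray, path) -> None:
    import pandas as pd

    pd.DataFrame({"x_mm": x_mm, "concentration_mM": conc_mM}).to_csv(path, index=False)
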