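"""Time-domain elastodynamic stepping on regular voxel grids (1D/2D/3D).

The scheme is the local-interaction family member obtained by
discretising the Navier equation

    mu lap(W) + (lambda + mu) grad(div W) = rho Wtt

in conservative (stress-flux) form with second-order central
differences and per-cell constant material properties.  Material
constants enter through edge- and node-averaged tables (the
sharp-interface averaging of the cells meeting at a node), so that

* in a homogeneous region the update reduces exactly to the textbook
  central-difference stencil of the Navier equation,
* at a material interface each adjacent cell contributes with its own
  (lambda, mu, rho),
* outside (vacuum) cells carry zero stiffness and zero density, which
  makes the outer surface traction-free with no extra code.

Time integration is leapfrog:

    W^{n+1} = 2 W^n - W^{n-1} + dt^2 * a(W^n),

with prescribed-displacement excitation and fixed-component boundary
conditions applied after every update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, InstabilityError, MeshError, ShapeError
from .grid import BoundarySpec, ExcitationSpec, PhantomGrid, _axis_index, _node_average
from .materials import ElasticMaterial, wave_speeds

__all__ = [
    "NodeStencilSet",
    "SimulationState",
    "ProbeRecords",
    "build_stencils",
    "step",
    "run",
    "default_time_step",
]


# ---------------------------------------------------------------------------
# low-level axis operators


def _shift(a: np.ndarray, axis: int, offset: int, fill=0.0) -> np.ndarray:
    """a[..., i + offset, ...] with constant fill outside the array."""
    out = np.full_like(a, fill)
    src = [slice(None)] * a.ndim
    dst = [slice(None)] * a.ndim
    if offset > 0:
        src[axis] = slice(offset, None)
        dst[axis] = slice(0, -offset)
    elif offset < 0:
        src[axis] = slice(0, offset)
        dst[axis] = slice(-offset, None)
    else:
        return a.copy()
    out[tuple(dst)] = a[tuple(src)]
    return out


def _edge_diff(u: np.ndarray, axis: int, dx: float, periodic: bool) -> np.ndarray:
    """Forward difference onto edge centres along *axis*."""
    if periodic:
        return (np.roll(u, -1, axis=axis) - u) / dx
    return np.diff(u, axis=axis) / dx


def _edge_avg(q: np.ndarray, axis: int, periodic: bool) -> np.ndarray:
    """Average a node-centred array onto edge centres along *axis*."""
    if periodic:
        return 0.5 * (q + np.roll(q, -1, axis=axis))
    lo = [slice(None)] * q.ndim
    hi = [slice(None)] * q.ndim
    lo[axis] = slice(0, -1)
    hi[axis] = slice(1, None)
    return 0.5 * (q[tuple(lo)] + q[tuple(hi)])


def _flux_div(f: np.ndarray, axis: int, dx: float, periodic: bool) -> np.ndarray:
    """Divergence of an edge-centred flux back onto nodes.

    Non-periodic axes assume zero flux beyond the outermost edges
    (traction-free outer surface).
    """
    if periodic:
        return (f - np.roll(f, 1, axis=axis)) / dx
    pad = [(0, 0)] * f.ndim
    pad[axis] = (1, 1)
    fp = np.pad(f, pad)
    return np.diff(fp, axis=axis) / dx


def _cell_to_edge(cells: np.ndarray, axis: int, periodic) -> np.ndarray:
    """Average a cell array onto the edges aligned with *axis*.

    An edge along *axis* is shared by the 2^(d-1) adjacent cells; the
    average runs over every axis except *axis* itself.  Vacuum cells
    enter the average with value zero.
    """
    out = cells
    for ax in range(cells.ndim):
        if ax != axis:
            out = _node_average(out, ax, periodic[ax])
    return out


# ---------------------------------------------------------------------------
# stencil tables


@dataclass
class NodeStencilSet:
    """Precomputed per-node/per-edge coefficient tables of the scheme.

    ``m_edge[b]`` and ``l_edge[b]`` hold lambda+2mu and lambda averaged
    onto the edges along axis b; ``mu_edge[b]`` likewise for mu;
    ``rho_node`` is the density averaged over the cells meeting at each
    node (zero outside the sample).  Coefficients therefore depend only
    on the adjacent cells' (lambda, mu, rho) and on the spacings.
    """

    spacings: tuple
    periodic: tuple
    m_edge: list
    l_edge: list
    mu_edge: list
    rho_node: np.ndarray
    inside: np.ndarray  # nodes carrying material

    @property
    def ndim(self) -> int:
        return len(self.spacings)

    def _node_gradients(self, u: np.ndarray) -> dict:
        """d u_comp / d axis at nodes, one-sided at the sample surface."""
        d = self.ndim
        grads = {}
        m = self.inside
        for comp in range(d):
            for ax in range(d):
                dx = self.spacings[ax]
                if self.periodic[ax]:
                    grads[comp, ax] = (
                        np.roll(u[comp], -1, axis=ax) - np.roll(u[comp], 1, axis=ax)
                    ) / (2.0 * dx)
                    continue
                up = _shift(u[comp], ax, 1)
                um = _shift(u[comp], ax, -1)
                up2 = _shift(u[comp], ax, 2)
                um2 = _shift(u[comp], ax, -2)
                mp = _shift(m, ax, 1, fill=False)
                mm = _shift(m, ax, -1, fill=False)
                mp2 = _shift(m, ax, 2, fill=False)
                mm2 = _shift(m, ax, -2, fill=False)
                fwd_ok = m & mp
                bwd_ok = m & mm
                both = fwd_ok & bwd_ok
                # one-sided at the sample surface: second order where two
                # neighbours exist, first order otherwise
                fwd2 = fwd_ok & ~bwd_ok & mp2
                bwd2 = bwd_ok & ~fwd_ok & mm2
                g = np.where(
                    both,
                    (up - um) / (2.0 * dx),
                    np.where(
                        fwd2,
                        (-3.0 * u[comp] + 4.0 * up - up2) / (2.0 * dx),
                        np.where(
                            bwd2,
                            (3.0 * u[comp] - 4.0 * um + um2) / (2.0 * dx),
                            np.where(
                                fwd_ok,
                                (up - u[comp]) / dx,
                                np.where(bwd_ok, (u[comp] - um) / dx, 0.0),
                            ),
                        ),
                    ),
                )
                grads[comp, ax] = g
        return grads

    def acceleration(self, u: np.ndarray) -> np.ndarray:
        """Nodal acceleration a(W) = div(sigma)/rho for displacement u.

        ``u`` has shape (ndim, *node_shape).  Nodes outside the sample
        return zero.
        """
        d = self.ndim
        if u.shape[0] != d or u.shape[1:] != self.rho_node.shape:
            raise ShapeError(
                f"displacement shape {u.shape} does not match the stencil grid"
            )
        grads = self._node_gradients(u)
        rho_safe = np.where(self.inside, self.rho_node, 1.0)
        acc = np.zeros_like(u)
        for a in range(d):
            total = np.zeros(self.rho_node.shape)
            for b in range(d):
                per = self.periodic[b]
                dxb = self.spacings[b]
                dua_db = _edge_diff(u[a], b, dxb, per)
                if a == b:
                    flux = self.m_edge[b] * dua_db
                    if d > 1:
                        others = sum(
                            grads[c, c] for c in range(d) if c != b
                        )
                        flux = flux + self.l_edge[b] * _edge_avg(others, b, per)
                else:
                    flux = self.mu_edge[b] * (
                        dua_db + _edge_avg(grads[b, a], b, per)
                    )
                total += _flux_div(flux, b, dxb, per)
            acc[a] = np.where(self.inside, total / rho_safe, 0.0)
        return acc


def build_stencils(grid: PhantomGrid, materials) -> NodeStencilSet:
    """Assemble the coefficient tables for *grid*.

    ``materials`` is a single :class:`ElasticMaterial` or a sequence
    indexed by ``grid.cell_material``.
    """
    if isinstance(materials, ElasticMaterial):
        materials = [materials]
    lam_tab = np.array([m.lame_lambda for m in materials])
    mu_tab = np.array([m.lame_mu for m in materials])
    rho_tab = np.array([m.density for m in materials])
    idx = grid.cell_material
    inside_cells = idx >= 0
    safe = np.where(inside_cells, idx, 0)
    lam = np.where(inside_cells, lam_tab[safe], 0.0)
    mu = np.where(inside_cells, mu_tab[safe], 0.0)
    rho = np.where(inside_cells, rho_tab[safe], 0.0)

    rho_node = rho
    for ax, per in enumerate(grid.periodic):
        rho_node = _node_average(rho_node, ax, per)

    if not inside_cells.any():
        raise MeshError("grid contains no material cells")
    node_mask = grid.node_mask
    if not np.array_equal(node_mask, rho_node > 0):
        raise MeshError("node mask inconsistent with cell materials")

    m_edge, l_edge, mu_edge = [], [], []
    for b in range(grid.ndim):
        m_edge.append(_cell_to_edge(lam + 2.0 * mu, b, grid.periodic))
        l_edge.append(_cell_to_edge(lam, b, grid.periodic))
        mu_edge.append(_cell_to_edge(mu, b, grid.periodic))
    return NodeStencilSet(
        spacings=tuple(grid.spacings),
        periodic=tuple(grid.periodic),
        m_edge=m_edge,
        l_edge=l_edge,
        mu_edge=mu_edge,
        rho_node=rho_node,
        inside=node_mask,
    )


# ---------------------------------------------------------------------------
# time stepping


@dataclass
class SimulationState:
    """Displacement fields at two consecutive time levels."""

    u: np.ndarray  # (ndim, *node_shape), time level n
    u_prev: np.ndarray  # time level n - 1
    dt: float
    step_index: int = 0

    @property
    def time(self) -> float:
        return self.step_index * self.dt


def default_time_step(
    material: ElasticMaterial, spacings, safety: float = 0.9
) -> float:
    """Default dt = safety * min(dx) / (V_L * sqrt(3)).

    Conservative for every dimensionality (the sqrt(3) factor is the
    3D scalar-scheme bound, stricter than the collocated elastic
    stencil actually requires).
    """
    v_l = wave_speeds(material).longitudinal
    return safety * min(spacings) / (v_l * math.sqrt(3.0))


def _resolve_bcs(grid: PhantomGrid, bcs) -> list:
    resolved = []
    for bc in bcs:
        mask = grid.region_mask(bc.region)
        for comp in bc.fixed_components:
            resolved.append((_axis_index(comp, grid.ndim), mask))
    return resolved


def _apply_constraints(u_next, stencils, resolved_bcs, excitation, t):
    u_next[:, ~stencils.inside] = 0.0
    for comp, mask in resolved_bcs:
        u_next[comp][mask] = 0.0
    if excitation is not None:
        val = excitation.values(t)
        comp = excitation.component
        for node in excitation.nodes:
            u_next[(comp, *node)] = val


def step(
    state: SimulationState,
    stencils: NodeStencilSet,
    excitation: ExcitationSpec | None = None,
    resolved_bcs=(),
) -> SimulationState:
    """Advance one leapfrog step; returns the new state.

    Raises :class:`InstabilityError` if the update produces non-finite
    values.
    """
    acc = stencils.acceleration(state.u)
    u_next = 2.0 * state.u - state.u_prev + state.dt * state.dt * acc
    t_next = (state.step_index + 1) * state.dt
    _apply_constraints(u_next, stencils, resolved_bcs, excitation, t_next)
    if not np.isfinite(u_next).all():
        raise InstabilityError(state.step_index + 1)
    return SimulationState(
        u=u_next, u_prev=state.u, dt=state.dt, step_index=state.step_index + 1
    )


@dataclass
class ProbeRecords:
    """Outputs collected during :func:`run`."""

    snapshots: dict = field(default_factory=dict)  # step -> (ndim, *nodes) array
    point_series: dict = field(default_factory=dict)  # (node, comp) -> list
    times: dict = field(default_factory=dict)  # step -> physical time


def run(
    grid: PhantomGrid,
    materials,
    excitation: ExcitationSpec | None,
    bcs,
    dt: float,
    n_steps: int,
    snapshot_steps=(),
    point_probes=(),
    initial=None,
    check_every: int = 50,
    max_amplitude: float = 1e6,
) -> tuple[SimulationState, ProbeRecords]:
    """Drive the engine for ``n_steps`` and collect probe records.

    ``point_probes`` is a sequence of ``(node_index_tuple, component)``
    pairs recorded at every step; ``snapshot_steps`` lists step indices
    whose full displacement fields are stored.  ``initial`` optionally
    provides ``(u, u_prev)`` fields (e.g. a plane-wave seed); fields
    start at rest otherwise.  Deterministic: identical inputs produce
    bit-identical records.

    ``max_amplitude`` (relative to the excitation amplitude, or
    absolute when running from an initial condition) aborts obviously
    divergent runs early with :class:`InstabilityError`.
    """
    if n_steps < 1:
        raise DomainError("n_steps must be >= 1")
    stencils = build_stencils(grid, materials)
    shape = (grid.ndim, *grid.node_shape)
    if initial is None:
        u = np.zeros(shape)
        u_prev = np.zeros(shape)
    else:
        u = np.array(initial[0], dtype=float)
        u_prev = np.array(initial[1], dtype=float)
        if u.shape != shape or u_prev.shape != shape:
            raise ShapeError(f"initial fields must have shape {shape}")
    state = SimulationState(u=u, u_prev=u_prev, dt=dt)
    resolved = _resolve_bcs(grid, bcs)
    _apply_constraints(state.u, stencils, resolved, None, 0.0)

    records = ProbeRecords()
    probes = [((tuple(node)), _axis_index(comp, grid.ndim)) for node, comp in point_probes]
    for node, comp in probes:
        records.point_series[(node, comp)] = []
    snapshot_steps = set(int(s) for s in snapshot_steps)
    scale = excitation.amplitude if excitation is not None else max(
        1e-300, float(np.abs(u).max())
    )

    if 0 in snapshot_steps:
        records.snapshots[0] = state.u.copy()
        records.times[0] = 0.0
    for _ in range(n_steps):
        state = step(state, stencils, excitation, resolved)
        for node, comp in probes:
            records.point_series[(node, comp)].append(state.u[(comp, *node)])
        if state.step_index in snapshot_steps:
            records.snapshots[state.step_index] = state.u.copy()
            records.times[state.step_index] = state.time
        if state.step_index % check_every == 0:
            if np.abs(state.u).max() > max_amplitude * scale:
                raise InstabilityError(
                    state.step_index,
                    f"field exceeded {max_amplitude:g} x the input scale "
                    f"at step {state.step_index}",
                )
    for key, series in records.point_series.items():
        records.point_series[key] = np.asarray(series)
    return state, records
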