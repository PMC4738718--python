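import math

import numpy as np
import pytest

from lisawave.engine import (
    SimulationState,
    build_stencils,
    default_time_step,
    run,
    step,
)
from lisawave.errors import (
    DegenerateGeometryError,
    DomainError,
    InstabilityError,
)
from lisawave.grid import (
    BoundarySpec,
    ExcitationSpec,
    PhantomGrid,
    bar_grid,
    box_grid,
    strip_grid,
    top_center_excitation,
    voxelize_cylinder,
)
from lisawave.materials import ElasticMaterial, wave_speeds
from lisawave.scenarios import strip_wavelength
from lisawave.stability import scheme_stability_limit_dt, step_1d


class TestVoxelization:
    @pytest.mark.parametrize(
        "diameter, thickness, spacing",
        [(0.2, 0.02, 1e-3), (0.15, 0.02, 1e-3)],
    )
    def test_inside_cell_count_matches_analytic_volume(self, diameter, thickness, spacing):
        grid = voxelize_cylinder(diameter, thickness, spacing)
        analytic = math.pi * (diameter / 2) ** 2 * thickness / spacing**3
        assert grid.n_inside_cells == pytest.approx(analytic, rel=0.02)

    def test_two_cell_cylinder_enumerable(self):
        # 2 x 2 cross-section: all four cell centres lie at radius
        # dx/sqrt(2) < d/2 = dx, so every cell is inside
        dx = 1e-3
        grid = voxelize_cylinder(2 * dx, 2 * dx, dx)
        assert grid.cell_shape == (2, 2, 2)
        assert grid.n_inside_cells == 8

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            voxelize_cylinder(1e-3, 0.02, 2e-3)


def _textbook_acceleration(u, lam, mu, rho, dx):
    """Independent central-difference discretisation of the Navier
    operator: mu lap(W) + (lam + mu) grad(div W), interior nodes only."""
    d = u.shape[0]
    acc = np.zeros_like(u)

    def d2(f, ax):
        out = np.zeros_like(f)
        sl = [slice(1, -1)] * f.ndim
        lo, hi, ce = list(sl), list(sl), list(sl)
        lo[ax], hi[ax] = slice(0, -2), slice(2, None)
        out[tuple(sl)] = (f[tuple(hi)] - 2 * f[tuple(ce)] + f[tuple(lo)]) / dx**2
        return out

    def dmixed(f, ax1, ax2):
        out = np.zeros_like(f)
        sl = [slice(1, -1)] * f.ndim

        def s(o1, o2):
            q = list(sl)
            q[ax1] = slice(1 + o1, (-1 + o1) or None)
            q[ax2] = slice(1 + o2, (-1 + o2) or None)
            return f[tuple(q)]

        out[tuple(sl)] = (s(1, 1) - s(1, -1) - s(-1, 1) + s(-1, -1)) / (4 * dx**2)
        return out

    for a in range(d):
        lap = sum(d2(u[a], ax) for ax in range(d))
        graddiv = sum(
            d2(u[b], a) if b == a else dmixed(u[b], a, b) for b in range(d)
        )
        acc[a] = (mu * lap + (lam + mu) * graddiv) / rho
    return acc


class TestStencils:
    def test_homogeneous_reduction_to_textbook_stencil(self, gel_90k):
        # in a uniform medium the engine's node update must equal the
        # standard second-order central-difference Navier discretisation
        dx = 1e-3
        grid = box_grid((8, 8, 8), dx)
        st = build_stencils(grid, gel_90k)
        rng = np.random.default_rng(3)
        u = rng.normal(0.0, 1.0, (3, *grid.node_shape))
        acc = st.acceleration(u)
        ref = _textbook_acceleration(
            u, gel_90k.lame_lambda, gel_90k.lame_mu, gel_90k.density, dx
        )
        interior = (slice(None), slice(1, -1), slice(1, -1), slice(1, -1))
        scale = np.abs(ref[interior]).max()
        assert np.allclose(acc[interior], ref[interior], atol=1e-9 * scale)

    def test_zero_stiffness_gives_free_inertia(self):
        # vanishing moduli: the update degenerates to u' = 2u - u_prev
        soft = ElasticMaterial(1e-20, 0.0, 1000.0)
        grid = box_grid((4, 4, 4), 1e-3)
        st = build_stencils(grid, soft)
        rng = np.random.default_rng(0)
        u = rng.normal(0.0, 1.0, (3, *grid.node_shape))
        assert np.abs(st.acceleration(u)).max() < 1e-12
        state = SimulationState(u=u.copy(), u_prev=0.5 * u, dt=1e-6)
        out = step(state, st)
        assert np.allclose(out.u, 2 * u - 0.5 * u, atol=1e-20)

    def test_1d_bar_equivalence_with_reference_scheme(self, gel_90k):
        # a 1 x 1 x N cell bar with suppressed lateral components must
        # reproduce the 1D leapfrog scheme step for step
        n, dx = 60, 1e-3
        grid = bar_grid(n, dx)
        st = build_stencils(grid, gel_90k)
        c = 0.5
        dt = c * dx / wave_speeds(gel_90k).longitudinal
        w0 = np.zeros(n + 1)
        w0[n // 2 - 4 : n // 2 + 5] = np.hanning(9)
        u = np.zeros((3, *grid.node_shape))
        u[2] = w0[None, None, :]
        state = SimulationState(u=u.copy(), u_prev=u.copy(), dt=dt)
        a, b = w0.copy(), w0.copy()
        worst = 0.0
        for _ in range(500):
            state = step(state, st)
            state.u[0] = 0.0
            state.u[1] = 0.0
            b, a = step_1d(a, b, c, boundary="free"), b
            worst = max(worst, np.abs(state.u[2][0, 0, :] - b).max())
        assert worst < 1e-12


def _plane_wave_speed(material, pol, nodes_per_wl=20, n_cells=40, ndim=3, steps=200):
    """Measured phase speed of a plane wave in a periodic box."""
    v = wave_speeds(material)
    speed = v.transverse if pol != 0 else v.longitudinal
    shape = tuple(n_cells if ax == 0 else 4 for ax in range(ndim))
    dx = 1e-3
    grid = box_grid(shape, dx, periodic=(True,) * ndim)
    st = build_stencils(grid, material)
    k = 2 * math.pi / (nodes_per_wl * dx)
    x = np.arange(n_cells) * dx
    dt = 0.3 * dx / v.longitudinal
    u = np.zeros((ndim, *grid.node_shape))
    u_prev = np.zeros_like(u)
    sh = [1] * ndim
    sh[0] = -1
    u[pol] = np.sin(k * x).reshape(sh)
    u_prev[pol] = np.sin(k * (x - speed * dt)).reshape(sh)
    state = SimulationState(u=u, u_prev=u_prev, dt=dt)
    line = lambda s: s[pol][(slice(None),) + (0,) * (ndim - 1)]
    m = round(n_cells / nodes_per_wl)
    prev = np.fft.fft(line(state.u))[m]
    total = 0.0
    for _ in range(steps):
        state = step(state, st)
        cur = np.fft.fft(line(state.u))[m]
        total += np.angle(cur / prev)
        prev = cur
    return abs(total) / (k * steps * dt)


class TestPlaneWaves:
    @pytest.mark.parametrize("ndim", [2, 3])
    @pytest.mark.parametrize("pol", [0, 1])
    def test_phase_speed_within_one_percent(self, gel_90k, ndim, pol):
        v = wave_speeds(gel_90k)
        expected = v.longitudinal if pol == 0 else v.transverse
        measured = _plane_wave_speed(gel_90k, pol, ndim=ndim)
        assert measured == pytest.approx(expected, rel=0.01)

    def test_shear_speed_error_at_least_halves_when_dx_halves(self, gel_90k):
        # halving the spacing at fixed wavelength (10 -> 20 nodes per
        # wavelength) must cut the phase-speed error at least in half
        v_t = wave_speeds(gel_90k).transverse
        err10 = abs(_plane_wave_speed(gel_90k, 1, nodes_per_wl=10, ndim=2) - v_t)
        err20 = abs(_plane_wave_speed(gel_90k, 1, nodes_per_wl=20, ndim=2) - v_t)
        assert err20 <= 0.6 * err10


class TestStepAndRun:
    def test_zero_fields_stay_zero(self, gel_90k):
        grid = strip_grid(0.02, 0.01, 1e-3)
        dt = default_time_step(gel_90k, grid.spacings)
        state, rec = run(grid, gel_90k, None, [], dt, 20, snapshot_steps=[20])
        assert np.all(rec.snapshots[20] == 0.0)

    def test_excitation_and_bc_enforced(self, gel_90k):
        grid = strip_grid(0.04, 0.01, 1e-3)
        f = 150.0
        exc = top_center_excitation(grid, frequency=f, amplitude=1e-6)
        bcs = [BoundarySpec("bottom", ("y",))]
        dt = default_time_step(gel_90k, grid.spacings)
        n = 75
        state, _ = run(grid, gel_90k, exc, bcs, dt, n)
        centre = grid.top_center_node()
        assert state.u[1][centre] == pytest.approx(
            1e-6 * math.sin(2 * math.pi * f * n * dt), rel=1e-12
        )
        assert np.all(state.u[1][:, 0] == 0.0)  # fixed bottom, y component
        assert np.any(state.u[0][:, 0] != 0.0)  # x stays free there

    def test_instability_abort_names_step(self, gel_90k):
        grid = box_grid((8, 8, 8), 1e-3, periodic=(True,) * 3)
        dt = 3.0 * scheme_stability_limit_dt(gel_90k, grid.spacings)
        rng = np.random.default_rng(2)
        u0 = rng.normal(0.0, 1.0, (3, *grid.node_shape))
        with pytest.raises(InstabilityError) as exc_info:
            run(grid, gel_90k, None, [], dt, 2000, initial=(u0, u0))
        assert exc_info.value.step_index > 0

    def test_n_steps_validated(self, gel_90k):
        grid = strip_grid(0.02, 0.01, 1e-3)
        with pytest.raises(DomainError):
            run(grid, gel_90k, None, [], 1e-6, 0)

    def test_determinism_bit_identical(self, gel_90k):
        grid = strip_grid(0.05, 0.01, 1e-3)
        exc = top_center_excitation(grid, frequency=150.0)
        bcs = [BoundarySpec("bottom", ("y",))]
        dt = default_time_step(gel_90k, grid.spacings)
        probes = [((10, 10), "y")]
        outs = []
        for _ in range(2):
            _, rec = run(
                grid, gel_90k, exc, bcs, dt, 120,
                snapshot_steps=[120], point_probes=probes,
            )
            outs.append(rec)
        assert np.array_equal(outs[0].snapshots[120], outs[1].snapshots[120])
        key = ((10, 10), 1)
        assert np.array_equal(outs[0].point_series[key], outs[1].point_series[key])


class TestCflDichotomy:
    def test_bounded_below_and_divergent_above_the_limit(self, gel_90k):
        grid = box_grid((8, 8, 8), 1e-3, periodic=(True,) * 3)
        st = build_stencils(grid, gel_90k)
        rng = np.random.default_rng(1)
        u0 = rng.normal(0.0, 1.0, (3, *grid.node_shape))
        m0 = np.abs(u0).max()

        def growth(dt, n_steps):
            state = SimulationState(u=u0.copy(), u_prev=u0.copy(), dt=dt)
            for _ in range(n_steps):
                state = step(state, st)
                peak = np.abs(state.u).max()
                if not np.isfinite(peak) or peak > 1e9 * m0:
                    return math.inf
            return np.abs(state.u).max() / m0

        v_l = wave_speeds(gel_90k).longitudinal
        dt_scalar = 1e-3 / (v_l * math.sqrt(3.0))
        assert growth(0.95 * dt_scalar, 2000) <= 10.0
        # the collocated stencil's own von Neumann limit is laxer than
        # the scalar-scheme 1/sqrt(3); 5% above it the scheme blows up
        dt_lim = scheme_stability_limit_dt(gel_90k, grid.spacings)
        assert growth(1.05 * dt_lim, 600) > 1e6


class TestStripScenario:
    def test_bottom_bc_ordering_matches_published_trend(self, gel_90k):
        # fixing the bottom in y lengthens the measured wavelength
        # relative to a fully free layer (20 mm strip at 150 Hz)
        lam_fixed = strip_wavelength(gel_90k, bottom_fixed=("y",)).mean
        lam_free = strip_wavelength(gel_90k, bottom_fixed=()).mean
        assert lam_fixed > lam_free
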