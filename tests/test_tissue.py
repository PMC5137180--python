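"""Implicit diffusion schemes vs analytic solutions; conduction physiology."""
import numpy as np
import pytest

from cardiosim.cell_core import ConfigurationError, make_reference_cell
from cardiosim.protocols import CurrentClampProtocol
from cardiosim.tissue import (
    FiberGeometry,
    GridGeometry,
    activation_map,
    adi_step,
    cn_step,
    conduction_velocity,
    diffusion_coefficient,
    make_node,
    simulate_fiber,
)
from conftest import passive_fiber, passive_grid, set_fiber_vm, set_grid_vm


class TestDiffusionCoefficient:
    def test_closed_form_and_units(self):
        fib = passive_fiber(2, d=0.001, Ri=0.15, cm=1.0)
        # D = d/(4*Ri*Cm): cm / (kΩ·cm · µF/cm²) = cm²/ms
        assert diffusion_coefficient(fib) == pytest.approx(0.001 / (4 * 0.15 * 1.0))

    def test_zero_diameter_uncouples(self):
        fib = passive_fiber(5, d=0.0)
        set_fiber_vm(fib, [0, 10, -20, 5, 0])
        v = cn_step(fib, 0.5)
        np.testing.assert_allclose(v, [0, 10, -20, 5, 0], atol=1e-12)

    def test_doubling_ri_halves_d(self):
        a = diffusion_coefficient(passive_fiber(2, Ri=0.15))
        b = diffusion_coefficient(passive_fiber(2, Ri=0.30))
        assert a == pytest.approx(2 * b)

    def test_geometry_validation(self):
        with pytest.raises(ConfigurationError):
            passive_fiber(1)
        with pytest.raises(ConfigurationError):
            passive_fiber(3, dx=-0.01)


def eigenmode_fiber(n, dx=0.01):
    fib = passive_fiber(n, dx=dx)
    L = n * dx
    x = (np.arange(n) + 0.5) * dx
    v0 = np.cos(np.pi * x / L)
    set_fiber_vm(fib, v0)
    lam = diffusion_coefficient(fib) * (np.pi / L) ** 2
    return fib, v0, lam


class TestCrankNicolson:
    def test_uniform_vm_is_a_fixed_point(self):
        fib = passive_fiber(30)
        set_fiber_vm(fib, np.full(30, -37.5))
        for _ in range(5):
            v = cn_step(fib, 0.1)
        np.testing.assert_allclose(v, -37.5, atol=1e-12)

    def test_eigenmode_decay_matches_analytic(self):
        fib, v0, lam = eigenmode_fiber(100)
        dt = 0.01
        steps = int(round(1.0 / lam / dt))
        for _ in range(steps):
            v = cn_step(fib, dt)
        exact = np.exp(-lam * steps * dt) * v0
        rel = np.max(np.abs(v - exact)) / np.max(np.abs(exact))
        assert rel < 1e-3

    def test_unconditional_stability_at_huge_dt(self):
        fib, v0, _ = eigenmode_fiber(40)
        for _ in range(50):
            v = cn_step(fib, 1000.0)
        assert np.all(np.isfinite(v))
        assert np.max(np.abs(v)) <= np.max(np.abs(v0)) + 1e-9

    def test_mean_vm_conserved_over_1000_steps(self):
        fib = passive_fiber(50)
        rng = np.random.default_rng(3)
        v0 = rng.normal(0.0, 20.0, 50)
        set_fiber_vm(fib, v0)
        for _ in range(1000):
            v = cn_step(fib, 0.05)
        assert abs(v.mean() - v0.mean()) < 1e-10

    def test_second_order_spatial_accuracy(self):
        errs, dxs = [], []
        for n in (25, 50, 100):
            dx = 1.0 / n  # fixed physical length
            fib, v0, lam = eigenmode_fiber(n, dx=dx)
            dt = 0.002  # small enough that time error is negligible
            steps = int(round(0.5 / lam / dt))
            for _ in range(steps):
                v = cn_step(fib, dt)
            exact = np.exp(-lam * steps * dt) * v0
            errs.append(np.max(np.abs(v - exact)))
            dxs.append(dx)
        slope = np.polyfit(np.log(dxs), np.log(errs), 1)[0]
        assert 1.8 < slope < 2.2


class TestADI:
    def test_degenerate_row_equals_cn(self):
        n = 20
        fib = passive_fiber(n)
        grid = passive_grid(1, n)
        v0 = np.sin(np.arange(n))
        set_fiber_vm(fib, v0)
        set_grid_vm(grid, v0[None, :])
        for _ in range(100):
            va = cn_step(fib, 0.02)
            vb = adi_step(grid, 0.02)
        assert np.max(np.abs(va - vb.ravel())) < 1e-10

    def test_degenerate_column_equals_cn(self):
        n = 20
        fib = passive_fiber(n)
        grid = passive_grid(n, 1)
        v0 = np.cos(np.arange(n) / 3.0)
        set_fiber_vm(fib, v0)
        set_grid_vm(grid, v0[:, None])
        for _ in range(100):
            va = cn_step(fib, 0.02)
            vb = adi_step(grid, 0.02)
        assert np.max(np.abs(va - vb.ravel())) < 1e-10

    def test_symmetry_preserved_about_center_row(self):
        grid = passive_grid(11, 8)
        rng = np.random.default_rng(5)
        half = rng.normal(0, 15, (6, 8))
        v0 = np.vstack([half, half[-2::-1]])  # mirror about row 5
        set_grid_vm(grid, v0)
        for _ in range(30):
            v = adi_step(grid, 0.05)
            assert np.max(np.abs(v - v[::-1, :])) < 1e-10

    def test_separable_mode_decay(self):
        nr, nc = 40, 30
        grid = passive_grid(nr, nc)
        Lx, Ly = nc * grid.dx, nr * grid.dy
        xs = (np.arange(nc) + 0.5) * grid.dx
        ys = (np.arange(nr) + 0.5) * grid.dy
        v0 = np.outer(np.cos(np.pi * ys / Ly), np.cos(np.pi * xs / Lx))
        set_grid_vm(grid, v0)
        D = diffusion_coefficient(grid)
        lam = D * ((np.pi / Lx) ** 2 + (np.pi / Ly) ** 2)
        dt = 0.01
        steps = int(round(1.0 / lam / dt))
        for _ in range(steps):
            v = adi_step(grid, dt)
        exact = np.exp(-lam * steps * dt) * v0
        rel = np.max(np.abs(v - exact)) / np.max(np.abs(exact))
        assert rel < 1e-3

    def test_mean_conserved(self):
        grid = passive_grid(12, 9)
        rng = np.random.default_rng(8)
        v0 = rng.normal(0, 20, (12, 9))
        set_grid_vm(grid, v0)
        for _ in range(1000):
            v = adi_step(grid, 0.05)
        assert abs(v.mean() - v0.mean()) < 1e-10

    def test_identically_built_grids_agree_bitwise(self):
        def build():
            g = passive_grid(4, 6)
            set_grid_vm(g, np.arange(24.0).reshape(4, 6))
            return g

        a, b = build(), build()
        for _ in range(10):
            va = adi_step(a, 0.05)
            vb = adi_step(b, 0.05)
        np.testing.assert_array_equal(va, vb)


def reference_fiber(n, Ri=0.15, n_stim=3):
    return FiberGeometry(
        [make_node(make_reference_cell(), stimulate=(i < n_stim)) for i in range(n)],
        dx=0.01, d=0.0011, Ri=Ri,
    )


PACE_ONE = CurrentClampProtocol(tMax=35.0, numstims=1, stimval=60.0,
                                stimdur=1.0, writeint=0.2)


class TestActivation:
    def test_unactivated_node_flagged_nan(self):
        times = np.arange(0.0, 10.0, 0.5)
        vm = np.full((len(times), 2), -85.0)
        vm[:, 0] = np.linspace(-85.0, 30.0, len(times))
        act = activation_map(times, vm, threshold=-20.0)
        assert np.isfinite(act[0])
        assert np.isnan(act[1])

    def test_interpolated_crossing_exact_on_linear_ramp(self):
        times = np.array([0.0, 1.0, 2.0])
        vm = np.array([[-85.0], [-85.0], [15.0]])
        act = activation_map(times, vm, threshold=-35.0)
        assert act[0] == pytest.approx(1.5)

    def test_planar_wave_activation_affine_in_position(self):
        times, vm = simulate_fiber(reference_fiber(30), PACE_ONE, dt=0.01)
        act = activation_map(times, vm)
        inner = act[5:-5]
        assert np.all(np.isfinite(inner))
        idx = np.arange(inner.size)
        resid = inner - np.polyval(np.polyfit(idx, inner, 1), idx)
        assert np.max(np.abs(resid)) < 0.25  # affine within sampling jitter

    def test_cv_decreases_when_ri_doubles(self):
        times1, vm1 = simulate_fiber(reference_fiber(30, Ri=0.15), PACE_ONE, dt=0.01)
        times2, vm2 = simulate_fiber(reference_fiber(30, Ri=0.30), PACE_ONE, dt=0.01)
        cv1 = conduction_velocity(activation_map(times1, vm1), 0.01, skip=5)
        cv2 = conduction_velocity(activation_map(times2, vm2), 0.01, skip=5)
        assert cv2 < cv1
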