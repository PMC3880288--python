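"""Explicit transport stepper against a naive triple-loop reference."""

import numpy as np
import pytest

import tumorsim as ts
from tumorsim import ScalarField, StabilityError, TransportSpec
from tumorsim.transport import advance, advance_scalar, stability_substeps


def naive_step(values, D, bc, dt, h, velocity=None, source=None, sink=None):
    """Triple-loop forward-Euler reference: 7-point Laplacian, first-order
    upwind flux-form convection, Dirichlet faces, clip at zero."""
    v = values
    nx, ny, nz = v.shape
    out = v.copy()
    for x in range(1, nx - 1):
        for y in range(1, ny - 1):
            for z in range(1, nz - 1):
                lap = (v[x + 1, y, z] + v[x - 1, y, z]
                       + v[x, y + 1, z] + v[x, y - 1, z]
                       + v[x, y, z + 1] + v[x, y, z - 1]
                       - 6.0 * v[x, y, z]) / h ** 2
                rhs = D * lap
                if velocity is not None:
                    div = 0.0
                    for axis in range(3):
                        u = velocity[axis]
                        lo = [x, y, z]
                        hi = [x, y, z]
                        lo[axis] -= 1
                        hi[axis] += 1
                        lo, hi = tuple(lo), tuple(hi)
                        u_hi = 0.5 * (u[x, y, z] + u[hi])
                        u_lo = 0.5 * (u[lo] + u[x, y, z])
                        f_hi = u_hi * v[x, y, z] if u_hi >= 0 else u_hi * v[hi]
                        f_lo = u_lo * v[lo] if u_lo >= 0 else u_lo * v[x, y, z]
                        div += (f_hi - f_lo) / h
                    rhs -= div
                if source is not None:
                    rhs += source[x, y, z]
                if sink is not None:
                    rhs -= sink[x, y, z]
                out[x, y, z] = v[x, y, z] + dt * rhs
    out[0, :, :] = out[-1, :, :] = bc
    out[:, 0, :] = out[:, -1, :] = bc
    out[:, :, 0] = out[:, :, -1] = bc
    return np.clip(out, 0.0, None)


class TestOracleEquivalence:
    def test_hundred_steps_on_8cubed(self):
        """Production stepper matches the naive reference over 100 steps."""
        rng = np.random.default_rng(42)
        n, h, D, bc = 8, 5e-5, 8e-14, 1.0
        dt = 2000.0
        values = rng.random((n, n, n)) + 0.5
        source = rng.random((n, n, n)) * 1e-5
        sink = rng.random((n, n, n)) * 1e-5
        umax = 0.03 * h / dt  # keep convection within the stability budget
        velocity = tuple(rng.uniform(-umax, umax, (n, n, n)) for _ in range(3))

        field = ScalarField(values.copy(), boundary_value=bc, species="oxygen")
        spec = TransportSpec(D=D, bc_value=bc, source=source, sink=sink)
        ref = values.copy()
        for _ in range(100):
            advance_scalar(field, spec, dt, h, velocity)
            ref = naive_step(ref, D, bc, dt, h, velocity, source, sink)
        assert np.allclose(field.values, ref, rtol=1e-10, atol=1e-14)


class TestFixedPoints:
    def test_uniform_field_is_fixed_point(self):
        field = ScalarField.uniform((8, 8, 8), 1.0, "oxygen")
        spec = TransportSpec(D=8e-14, bc_value=1.0)
        before = field.values.copy()
        for _ in range(20):
            advance_scalar(field, spec, 1000.0, 5e-5)
        assert np.allclose(field.values, before, atol=1e-12)

    def test_no_physics_is_identity(self):
        rng = np.random.default_rng(1)
        values = rng.random((8, 8, 8))
        field = ScalarField(values.copy(), boundary_value=0.0, species="taf")
        advance_scalar(field, TransportSpec(D=0.0, bc_value=0.0), 100.0, 5e-5)
        inner = (slice(1, -1),) * 3
        assert np.array_equal(field.values[inner], values[inner])

    def test_single_voxel_source_one_step(self):
        field = ScalarField.uniform((8, 8, 8), 0.0, "drug")
        source = np.zeros((8, 8, 8))
        source[4, 4, 4] = 3e-6
        dt = 500.0
        advance_scalar(field, TransportSpec(D=0.0, bc_value=0.0,
                                            source=source), dt, 5e-5)
        assert field.values[4, 4, 4] == pytest.approx(3e-6 * dt, rel=1e-14)
        assert np.count_nonzero(field.values) == 1


class TestStability:
    def test_no_physics_single_substep(self):
        assert stability_substeps(TransportSpec(D=0.0, bc_value=0.0),
                                  1000.0, 5e-5) == 1

    def test_diffusion_bound_arithmetic(self):
        """6 D dt / h^2 = 3 requires exactly 6 sub-steps."""
        h, dt = 1e-4, 1000.0
        D = 3.0 * h ** 2 / (6.0 * dt)
        assert stability_substeps(TransportSpec(D=D, bc_value=0.0), dt, h) == 6

    def test_substeps_monotone_in_D(self):
        h, dt = 1e-4, 1000.0
        D = 3.0 * h ** 2 / (6.0 * dt)
        m1 = stability_substeps(TransportSpec(D=D, bc_value=0.0), dt, h)
        m2 = stability_substeps(TransportSpec(D=2 * D, bc_value=0.0), dt, h)
        assert m2 == 2 * m1

    def test_unstable_step_raises(self):
        field = ScalarField.uniform((8, 8, 8), 1.0, "oxygen")
        with pytest.raises(StabilityError):
            advance_scalar(field, TransportSpec(D=1e-10, bc_value=1.0),
                           86400.0, 5e-5)

    def test_advance_substeps_transparently(self):
        field = ScalarField.uniform((8, 8, 8), 1.0, "oxygen")
        advance(field, TransportSpec(D=1e-10, bc_value=1.0), 86400.0, 5e-5)
        assert np.allclose(field.values, 1.0)


class TestAnalyticLimits:
    def test_1d_steady_diffusion_linear_profile(self):
        """Steady diffusion between two Dirichlet planes is linear in x.

        The x = 0 face is held at 1, the x = L face at 0, and the lateral
        faces carry the linear profile itself so the problem stays exactly
        one-dimensional; the production stepper must converge to the linear
        solution.
        """
        n, h, D = 16, 1e-4, 1e-12
        exact_x = np.linspace(1.0, 0.0, n)
        lateral = np.broadcast_to(exact_x[:, None], (n, n))
        field = ScalarField(np.zeros((n, n, n)), boundary_value=0.0,
                            species="oxygen",
                            face_values={"x0": 1.0, "x1": 0.0,
                                         "y0": lateral, "y1": lateral,
                                         "z0": lateral, "z1": lateral})
        spec = TransportSpec(D=D, bc_value=0.0)
        dt = 0.4 * h ** 2 / (6 * D)
        for _ in range(6000):
            advance_scalar(field, spec, dt, h)
        exact = np.broadcast_to(exact_x[:, None, None], (n, n, n))
        assert np.max(np.abs(field.values - exact)) <= 1e-6

    def test_nonnegativity_preserved(self):
        rng = np.random.default_rng(9)
        field = ScalarField(rng.random((10, 10, 10)) * 0.1,
                            boundary_value=0.0, species="co2")
        sink = np.full((10, 10, 10), 1e-4)  # aggressive sink forces clipping
        spec = TransportSpec(D=4e-14, bc_value=0.0, sink=sink)
        for _ in range(50):
            advance_scalar(field, spec, 2000.0, 5e-5)
        assert np.all(field.values >= 0.0)
        assert field.clipped_mass > 0.0
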