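"""Spectral-solver unit and property tests.

Independent oracles used here: direct dense solves of the per-bin continuity
system, a separately derived single-layer Green's function, and high-order
finite differences for the axial ODE residual.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermolock.model import (BoundarySpec, Layer, LayerStack, ModulationSpec,
                              SourceSpec, SpectralGrid, EdgeDecayWarning,
                              axial_wavenumber, boundary_coeffs, depth_profile,
                              interface_matrix, source_spectrum_tq,
                              split_into_sublayers, surface_field,
                              surface_spectrum, total_transfer, tpsf)

# ---------------------------------------------------------------- oracles


def dense_surface_solve(stack, bc, k_sq, omega, q_tilde, z_s,
                        t_up=0.0, t_dn=0.0):
    """Solve the full 2N x 2N per-bin continuity system directly.

    Unknowns (A_1, B_1, ..., A_N, B_N); equations are the top Robin
    condition, temperature + flux continuity at each interface, and the
    bottom Robin condition including the particular solution of a planar
    sheet at z_s.  Independent of the transfer-matrix code path.
    """
    n = len(stack)
    mus = [np.sqrt(complex(k_sq) + 1j * omega / la.diffusivity)
           for la in stack.layers]
    kaps = [la.conductivity for la in stack.layers]
    zc = stack.cumulative_depths
    a = np.zeros((2 * n, 2 * n), dtype=complex)
    b = np.zeros(2 * n, dtype=complex)
    # top: -k1 mu1 (A1 - B1) = h_up (t_up - (A1 + B1))
    a[0, 0] = -kaps[0] * mus[0] + bc.h_up
    a[0, 1] = kaps[0] * mus[0] + bc.h_up
    b[0] = bc.h_up * t_up
    row = 1
    for i in range(n - 1):
        zi = zc[i]
        ep, em = np.exp(mus[i] * zi), np.exp(-mus[i] * zi)
        fp, fm = np.exp(mus[i + 1] * zi), np.exp(-mus[i + 1] * zi)
        a[row, 2 * i:2 * i + 4] = [ep, em, -fp, -fm]
        row += 1
        a[row, 2 * i:2 * i + 4] = [
            kaps[i] * mus[i] * ep, -kaps[i] * mus[i] * em,
            -kaps[i + 1] * mus[i + 1] * fp, kaps[i + 1] * mus[i + 1] * fm]
        row += 1
    # bottom with the particular solution of the source sheet
    mu_n, kap_n, zn = mus[-1], kaps[-1], zc[-1]
    ep, em = np.exp(mu_n * zn), np.exp(-mu_n * zn)
    a[row, 2 * n - 2] = kap_n * mu_n * ep + bc.h_dn * ep
    a[row, 2 * n - 1] = -kap_n * mu_n * em + bc.h_dn * em
    tp = -(q_tilde / (mu_n * kap_n)) * np.sinh(mu_n * (zn - z_s))
    dtp = -(q_tilde / kap_n) * np.cosh(mu_n * (zn - z_s))
    b[row] = bc.h_dn * t_dn - kap_n * dtp - bc.h_dn * tp
    coeffs = np.linalg.solve(a, b)
    return coeffs  # (A_1, B_1, ..., A_N, B_N)


def single_layer_green_surface(layer, h_up, z_n, z_s, k_sq, omega, q_tilde):
    """Surface response of one slab, Robin top / insulated bottom.

    Green's-function derivation independent of the transfer-matrix route:
    u satisfies the top condition, v the bottom one, and the source jump
    fixes the scale: T(0) = q cosh(mu (zN - zs)) / (h cosh(mu zN) +
    kappa mu sinh(mu zN)).
    """
    mu = np.sqrt(complex(k_sq) + 1j * omega / layer.diffusivity)
    kap = layer.conductivity
    return q_tilde * np.cosh(mu * (z_n - z_s)) / (
        h_up * np.cosh(mu * z_n) + kap * mu * np.sinh(mu * z_n))


def reconstruct_matrix(m_hat, log_scale):
    return m_hat * np.exp(log_scale)


# ------------------------------------------------------------ wavenumber


def test_wavenumber_dc_limits():
    assert axial_wavenumber(0.0, 0.0, 1e-7) == 0.0
    assert axial_wavenumber(4.0, 0.0, 1e-7) == pytest.approx(2.0)


def test_wavenumber_pure_ac_identity():
    d = 8.52e-8
    omega = 2 * np.pi * 0.1
    mu = axial_wavenumber(0.0, omega, d)
    expected = np.sqrt(omega / (2 * d))
    assert mu.real == pytest.approx(expected, rel=1e-12)
    assert mu.imag == pytest.approx(expected, rel=1e-12)
    assert abs(mu) ** 2 * d == pytest.approx(omega, rel=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(k_sq=st.floats(0, 1e8), f=st.floats(0, 10.0),
       d=st.floats(1e-8, 1e-5))
def test_wavenumber_branch_is_decaying(k_sq, f, d):
    mu = axial_wavenumber(k_sq, 2 * np.pi * f, d)
    assert mu.real >= 0


def test_wavenumber_rejects_bad_diffusivity():
    with pytest.raises(ValueError):
        axial_wavenumber(1.0, 1.0, 0.0)


# ------------------------------------------------------- interface matrix


def test_interface_matrix_identity_for_equal_layers():
    la = Layer(3e-3, 0.5, 1000, 3500)
    mu = axial_wavenumber(2.5e5, 2 * np.pi * 0.05, la.diffusivity)
    m_hat, s = interface_matrix(la, la, 2e-3, mu, mu)
    np.testing.assert_allclose(reconstruct_matrix(m_hat, s), np.eye(2),
                               atol=1e-12)


def test_interface_matrix_enforces_continuity(rng):
    """Random coefficients mapped across the interface keep T and flux equal."""
    la = Layer(2e-3, 0.37, 1100, 3400)
    lb = Layer(4e-3, 0.21, 920, 2300)
    z_i = 2e-3
    omega = 2 * np.pi * 0.08
    mu_a = axial_wavenumber(4.0e4, omega, la.diffusivity)
    mu_b = axial_wavenumber(4.0e4, omega, lb.diffusivity)
    m_hat, s = interface_matrix(la, lb, z_i, mu_a, mu_b)
    m = reconstruct_matrix(m_hat, s)
    ab = rng.normal(size=2) + 1j * rng.normal(size=2)
    ab2 = m @ ab
    t_a = ab[0] * np.exp(mu_a * z_i) + ab[1] * np.exp(-mu_a * z_i)
    t_b = ab2[0] * np.exp(mu_b * z_i) + ab2[1] * np.exp(-mu_b * z_i)
    f_a = la.conductivity * mu_a * (ab[0] * np.exp(mu_a * z_i)
                                    - ab[1] * np.exp(-mu_a * z_i))
    f_b = lb.conductivity * mu_b * (ab2[0] * np.exp(mu_b * z_i)
                                    - ab2[1] * np.exp(-mu_b * z_i))
    assert abs(t_a - t_b) <= 1e-10 * abs(t_a)
    assert abs(f_a - f_b) <= 1e-10 * abs(f_a)


def test_interface_matrix_vs_linear_solve_oracle(rng):
    """Entrywise agreement with the 2x2 continuity system solved directly."""
    la = Layer(2e-3, 0.37, 1100, 3400)
    lb = Layer(4e-3, 0.21, 920, 2300)
    z_i = 2e-3
    omega = 2 * np.pi * 0.03
    mu_a = axial_wavenumber(9.0e4, omega, la.diffusivity)
    mu_b = axial_wavenumber(9.0e4, omega, lb.diffusivity)
    m = reconstruct_matrix(*interface_matrix(la, lb, z_i, mu_a, mu_b))
    # columns of M are the images of (1, 0) and (0, 1)
    for ab in (np.array([1.0, 0j]), np.array([0j, 1.0])):
        rhs = np.array([
            ab[0] * np.exp(mu_a * z_i) + ab[1] * np.exp(-mu_a * z_i),
            la.conductivity * mu_a * (ab[0] * np.exp(mu_a * z_i)
                                      - ab[1] * np.exp(-mu_a * z_i))])
        sys = np.array([
            [np.exp(mu_b * z_i), np.exp(-mu_b * z_i)],
            [lb.conductivity * mu_b * np.exp(mu_b * z_i),
             -lb.conductivity * mu_b * np.exp(-mu_b * z_i)]])
        expected = np.linalg.solve(sys, rhs)
        np.testing.assert_allclose(m @ ab, expected, rtol=1e-10)


def test_interface_matrix_never_overflows():
    """Huge |mu| z stays finite thanks to the log-scale factorisation."""
    la = Layer(10e-3, 0.5, 1000, 3500)
    mu = axial_wavenumber(1e10, 0.0, la.diffusivity)  # |mu| z ~ 1000
    m_hat, s = interface_matrix(la, Layer(10e-3, 0.2, 900, 2000), 10e-3, mu, mu)
    assert np.all(np.isfinite(m_hat))
    assert np.isfinite(s)


# ------------------------------------------------------- total transfer


def test_total_transfer_single_layer_is_identity(polyester_stack):
    m_hat, s, mus = total_transfer(polyester_stack, 1e4, 0.5)
    np.testing.assert_allclose(reconstruct_matrix(m_hat, s), np.eye(2),
                               atol=1e-14)
    assert len(mus) == 1


def test_total_transfer_sublayer_invariance(polyester_stack):
    """An artificial interface inside a uniform medium is a physical no-op."""
    split = split_into_sublayers(polyester_stack, 0, 3)
    m_hat, s, _ = total_transfer(split, 3.0e5, 2 * np.pi * 0.1)
    np.testing.assert_allclose(reconstruct_matrix(m_hat, s), np.eye(2),
                               atol=1e-9)


def test_multilayer_surface_vs_dense_oracle(three_layer_stack):
    """Transfer-matrix surface field vs the dense 6x6 continuity solve."""
    bc = BoundarySpec(h_up=15.0, h_dn=5.0, tau_up=0.0, tau_dn=0.0)
    omega = 2 * np.pi * 0.05
    z_s = 12e-3
    q = 1.0
    for k_sq in (0.0, 2.0e4, 4.0e5):
        coeffs = dense_surface_solve(three_layer_stack, bc, k_sq, omega, q, z_s)
        expected = coeffs[0] + coeffs[1]
        # single-bin evaluation through the production path
        grid = SpectralGrid(2, 2, 1e-3)
        k_arr = np.full(grid.shape, k_sq)
        mhat, ls, mus = total_transfer(three_layer_stack, k_arr, omega)
        c = boundary_coeffs(three_layer_stack, bc, k_arr, omega, mus)
        src = SourceSpec.planar(np.ones(grid.shape), z_s)
        tq = source_spectrum_tq(src, three_layer_stack, k_arr, omega,
                                qk=np.full(grid.shape, q), coeffs=c)
        denom = (mhat[0, 1] - c.gamma * mhat[1, 1]) - c.alpha * (
            c.gamma * mhat[1, 0] - mhat[0, 0])
        got = ((c.alpha + 1) * tq * np.exp(-ls) / denom)[0, 0]
        assert got == pytest.approx(expected, rel=1e-8)


# ------------------------------------------------------ boundary coeffs


def test_boundary_coeffs_insulated_faces(polyester_stack):
    bc = BoundarySpec(h_up=0.0, h_dn=0.0)
    k_sq = np.array(4.0e4)
    c = boundary_coeffs(polyester_stack, bc, k_sq, 0.0)
    mu = np.sqrt(4.0e4)
    zn = polyester_stack.total_thickness
    assert c.alpha == pytest.approx(1.0)
    assert c.beta == pytest.approx(0.0)
    assert c.delta == pytest.approx(0.0)
    assert c.gamma == pytest.approx(np.exp(-2 * mu * zn), rel=1e-12)


def test_boundary_coeffs_zero_mu_limit(polyester_stack):
    """mu -> 0 with convection: alpha -> -1, beta -> +1 as forced by the formula."""
    bc = BoundarySpec(h_up=10.0, h_dn=0.0)
    c = boundary_coeffs(polyester_stack, bc, np.array(0.0), 0.0)
    assert c.alpha == pytest.approx(-1.0)
    assert c.beta == pytest.approx(1.0)


def test_boundary_coeffs_satisfy_robin_conditions(three_layer_stack):
    """Round-trip residual: substituted into the boundary conditions."""
    bc = BoundarySpec(h_up=12.0, h_dn=7.0)
    omega = 2 * np.pi * 0.07
    k_sq = np.array(1.0e4)
    c = boundary_coeffs(three_layer_stack, bc, k_sq, omega)
    k1 = three_layer_stack.layers[0].conductivity
    kn = three_layer_stack.bottom.conductivity
    zn = three_layer_stack.total_thickness
    t_up, t_dn = 1.3, -0.4
    b1 = 0.8 + 0.1j
    a1 = c.alpha * b1 + c.beta * t_up
    # top Robin: -k1 mu1 (A1 - B1) = h_up (t_up - (A1 + B1))
    lhs = -k1 * c.mu_top * (a1 - b1)
    rhs = bc.h_up * (t_up - (a1 + b1))
    assert abs(lhs - rhs) <= 1e-10 * max(abs(lhs), 1.0)
    # bottom Robin for the homogeneous solution (T_Q = 0 case)
    bn = 0.5 - 0.2j
    an = c.gamma * bn + c.delta * t_dn
    ep, em = np.exp(c.mu_bot * zn), np.exp(-c.mu_bot * zn)
    lhs = kn * c.mu_bot * (an * ep - bn * em)
    rhs = bc.h_dn * (t_dn - (an * ep + bn * em))
    assert abs(lhs - rhs) <= 1e-10 * max(abs(lhs), 1.0)


def test_singular_bin_is_perturbed_not_fatal(polyester_stack):
    """k exactly at kappa1*mu1 == h_up resolves via the retry rule."""
    bc = BoundarySpec(h_up=10.0)
    k_star = bc.h_up / polyester_stack.layers[0].conductivity
    c = boundary_coeffs(polyester_stack, bc, np.array(k_star ** 2), 0.0)
    assert np.all(np.isfinite(c.alpha))


# ------------------------------------------------------ source spectrum


def test_zero_source_gives_zero_tq(polyester_stack, convective_bc):
    grid = SpectralGrid(8, 8, 1e-3)
    src = SourceSpec.planar(np.zeros(grid.shape), 10e-3)
    tq = source_spectrum_tq(src, polyester_stack, grid.k_sq, 0.5,
                            grid=grid, bc=convective_bc)
    assert np.all(tq == 0)


def test_volumetric_constant_profile_vs_antiderivative(polyester_stack,
                                                       convective_bc):
    """Trapezoid quadrature vs the elementary antiderivative of the bracket."""
    grid = SpectralGrid(4, 4, 20e-3)  # coarse k so the trapezoid fully converges
    omega = 2 * np.pi * 5e-4
    a, b = 9e-3, 11e-3
    zn = polyester_stack.total_thickness
    kap = polyester_stack.bottom.conductivity
    nodes = np.linspace(a, b, 8001)
    q0 = 2.5e4  # W/m^3
    src = SourceSpec.volumetric(np.full((nodes.size,) + grid.shape, q0), nodes)
    c = boundary_coeffs(polyester_stack, convective_bc, grid.k_sq, omega)
    got = source_spectrum_tq(src, polyester_stack, grid.k_sq, omega,
                             qk=np.full((nodes.size,) + grid.shape, q0),
                             coeffs=c)
    mu, r = c.mu_bot, c.ratio_dn
    analytic = (q0 / (2 * kap * mu)) * (
        (np.exp(-mu * a) - np.exp(-mu * b)) / mu
        + r * (np.exp(-mu * (2 * zn - b)) - np.exp(-mu * (2 * zn - a))) / mu)
    np.testing.assert_allclose(got, analytic, rtol=1e-9)


def test_narrow_gaussian_converges_to_planar(polyester_stack, convective_bc):
    """Volumetric quadrature over a shrinking Gaussian approaches the sheet."""
    grid = SpectralGrid(4, 4, 20e-3)
    omega = 2 * np.pi * 0.001
    z_s = 10e-3
    c = boundary_coeffs(polyester_stack, convective_bc, grid.k_sq, omega)
    planar = source_spectrum_tq(SourceSpec.planar(np.ones(grid.shape), z_s),
                                polyester_stack, grid.k_sq, omega,
                                qk=np.ones(grid.shape), coeffs=c)
    errs = []
    for width in (8e-4, 4e-4, 2e-4):
        nodes = np.linspace(z_s - 4 * width, z_s + 4 * width, 401)
        prof = np.exp(-0.5 * ((nodes - z_s) / width) ** 2)
        prof /= np.trapezoid(prof, nodes)
        qk = prof[:, None, None] * np.ones(grid.shape)
        vol = SourceSpec.volumetric(qk, nodes)
        got = source_spectrum_tq(vol, polyester_stack, grid.k_sq, omega,
                                 qk=qk, coeffs=c)
        errs.append(np.max(np.abs(got - planar) / np.abs(planar)))
    assert errs[2] < errs[0]
    assert errs[2] < 5e-3


def test_source_outside_bottom_layer_rejected(three_layer_stack):
    grid = SpectralGrid(4, 4, 1e-3)
    src = SourceSpec.planar(np.ones(grid.shape), 3e-3)  # inside layer 2, not 3
    with pytest.raises(ValueError, match="outside bottom layer"):
        source_spectrum_tq(src, three_layer_stack, grid.k_sq, 0.5, grid=grid,
                           bc=BoundarySpec())


# ------------------------------------------------------ surface spectrum


def test_no_drive_no_field(polyester_stack, small_grid):
    bc = BoundarySpec(h_up=10.0, tau_up=0.0, tau_dn=0.0)
    spec = surface_spectrum(polyester_stack, bc, None, ModulationSpec(0.1),
                            small_grid)
    assert np.all(spec.total == 0)


def test_single_layer_vs_green_function_oracle(polyester_stack, convective_bc):
    """Production spectrum vs the independently derived closed form."""
    grid = SpectralGrid(32, 32, 1e-3)
    z_s = 5e-3
    src = SourceSpec.planar_rect(grid, (0, 0), (2e-3, 3e-3), 0.2, z_s)
    for f in (0.0, 0.05):
        spec = surface_spectrum(polyester_stack, convective_bc, src,
                                ModulationSpec(f), grid)
        qk = grid.forward(src.q_map)
        expected = np.empty(grid.shape, dtype=complex)
        for iy in range(grid.ny):
            for ix in range(grid.nx):
                k_sq = grid.k_sq[iy, ix]
                if f == 0.0 and k_sq == 0.0:
                    k_sq = (1e-7 / polyester_stack.total_thickness) ** 2
                expected[iy, ix] = single_layer_green_surface(
                    polyester_stack.layers[0], convective_bc.h_up,
                    polyester_stack.total_thickness, z_s, k_sq,
                    2 * np.pi * f, qk[iy, ix])
        np.testing.assert_allclose(spec.total, expected, rtol=1e-8)


def test_dc_spectrum_matches_dedicated_dc_branch(polyester_stack,
                                                 convective_bc, small_grid):
    """f_mod = 0 equals a separately coded real-arithmetic DC evaluation."""
    z_s = 6e-3
    src = SourceSpec.planar_rect(small_grid, (0, 0), (2e-3, 2e-3), 0.1, z_s)
    spec = surface_spectrum(polyester_stack, convective_bc, src,
                            ModulationSpec(0.0), small_grid)
    qk = small_grid.forward(src.q_map)
    la = polyester_stack.layers[0]
    zn = polyester_stack.total_thickness
    k = np.sqrt(np.where(small_grid.k_sq == 0.0,
                         (1e-7 / zn) ** 2, small_grid.k_sq))  # real mu = |k|
    expected = qk * np.cosh(k * (zn - z_s)) / (
        convective_bc.h_up * np.cosh(k * zn)
        + la.conductivity * k * np.sinh(k * zn))
    err = np.abs(spec.total - expected) / np.maximum(np.abs(expected), 1e-300)
    # the regularised origin bin loses a few digits to the removable
    # (alpha + 1) cancellation of the printed parameterisation
    assert err[0, 0] <= 1e-8
    err[0, 0] = 0.0
    assert err.max() <= 1e-10


def test_sublayer_invariance_of_surface_field(polyester_stack, convective_bc):
    grid = SpectralGrid(48, 48, 1e-3)
    # source inside the deepest of the 4 sublayers (10.5-14 mm)
    src = SourceSpec.planar_rect(grid, (0, 0), (2e-3, 3e-3), 0.2, 12.5e-3)
    mod = ModulationSpec(0.1)
    ref = surface_spectrum(polyester_stack, convective_bc, src, mod, grid)
    split = split_into_sublayers(polyester_stack, 0, 4)
    got = surface_spectrum(split, convective_bc, src, mod, grid)
    np.testing.assert_allclose(got.total, ref.total,
                               rtol=1e-8, atol=1e-8 * np.abs(ref.total).max())


def test_linearity_in_source_and_ambients(polyester_stack, small_grid):
    bc = BoundarySpec(h_up=10.0, h_dn=3.0, tau_up=0.7, tau_dn=-0.3)
    src = SourceSpec.planar_rect(small_grid, (0, 0), (2e-3, 2e-3), 0.1, 5e-3)
    mod = ModulationSpec(0.05)
    base = surface_spectrum(polyester_stack, bc, src, mod, small_grid)
    doubled = SourceSpec.planar(src.q_map, src.z_s, amplitude=2.0)
    got = surface_spectrum(polyester_stack, bc, doubled, mod, small_grid)
    np.testing.assert_allclose(got.source_term, 2 * base.source_term, rtol=1e-12)
    np.testing.assert_allclose(got.bc_term, base.bc_term, rtol=1e-12)
    bc2 = BoundarySpec(h_up=10.0, h_dn=3.0, tau_up=1.4, tau_dn=-0.6)
    got2 = surface_spectrum(polyester_stack, bc2, src, mod, small_grid)
    np.testing.assert_allclose(got2.bc_term, 2 * base.bc_term, rtol=1e-12)


def test_diffusion_scaling_invariance(convective_bc):
    """Lengths x s, time x s^2 (f / s^2), h / s leaves the TPSF kernel s-scaled."""
    s = 2.0
    la = Layer(10e-3, 0.4, 1000, 3000)
    stack1 = LayerStack([la])
    stack2 = LayerStack([Layer(la.thickness * s, la.conductivity,
                               la.density, la.heat_capacity)])
    g1 = SpectralGrid(32, 32, 1e-3)
    g2 = SpectralGrid(32, 32, 1e-3 * s)
    bc1 = BoundarySpec(h_up=10.0)
    bc2 = BoundarySpec(h_up=10.0 / s)
    f = 0.08
    k1 = tpsf(stack1, bc1, 4e-3, ModulationSpec(f), g1)
    k2 = tpsf(stack2, bc2, 4e-3 * s, ModulationSpec(f / s ** 2), g2)
    np.testing.assert_allclose(k2.spectrum, s * k1.spectrum, rtol=1e-9)


# -------------------------------------------------------- surface field


def test_transform_round_trip(small_grid, rng):
    img = rng.normal(size=small_grid.shape)
    back = small_grid.inverse(small_grid.forward(img))
    np.testing.assert_allclose(back.real, img, atol=1e-12)
    assert np.abs(back.imag).max() < 1e-12


def test_centered_source_peaks_at_center(polyester_stack, convective_bc):
    grid = SpectralGrid(64, 64, 1e-3)
    src = SourceSpec.planar_rect(grid, (0, 0), (2e-3, 2e-3), 0.2, 3e-3)
    fld = surface_field(polyester_stack, convective_bc, src,
                        ModulationSpec(0.1), grid)
    mag = np.abs(fld.source.data)
    iy, ix = np.unravel_index(np.argmax(mag), mag.shape)
    assert (iy, ix) == (grid.ny // 2, grid.nx // 2)


def test_edge_leakage_warns(polyester_stack, convective_bc):
    tiny = SpectralGrid(16, 16, 1e-3)  # DC field cannot decay in 16 mm
    src = SourceSpec.planar_rect(tiny, (0, 0), (2e-3, 2e-3), 0.2, 3e-3)
    with pytest.warns(EdgeDecayWarning):
        surface_field(polyester_stack, convective_bc, src,
                      ModulationSpec(0.0), tiny)


# -------------------------------------------------------- depth profile


def test_depth_profile_surface_consistency(polyester_stack, convective_bc):
    grid = SpectralGrid(32, 32, 1e-3)
    src = SourceSpec.planar_rect(grid, (0, 0), (2e-3, 2e-3), 0.2, 5e-3)
    mod = ModulationSpec(0.05)
    spec = surface_spectrum(polyester_stack, convective_bc, src, mod, grid)
    prof = depth_profile(polyester_stack, convective_bc, src, mod, grid, 0.0)
    np.testing.assert_allclose(prof, spec.total, rtol=1e-10)


def test_depth_profile_interface_continuity(three_layer_stack, rng):
    """One-sided limits at each interface agree (quadratic extrapolation in z
    removes the smooth variation of the field across the +/- eps probes)."""
    bc = BoundarySpec(h_up=12.0, h_dn=4.0)
    grid = SpectralGrid(16, 16, 2e-3)
    src = SourceSpec.planar(rng.uniform(0, 2e3, grid.shape), 12e-3)
    mod = ModulationSpec(0.05)
    eps = 1e-7

    def limit(z_i, sign):
        vals = [depth_profile(three_layer_stack, bc, src, mod, grid,
                              z_i + sign * m * eps, return_flux=True)
                for m in (1, 2, 3)]
        t = 3 * vals[0][0] - 3 * vals[1][0] + vals[2][0]
        f = 3 * vals[0][1] - 3 * vals[1][1] + vals[2][1]
        return t, f

    for z_i in three_layer_stack.cumulative_depths[:-1]:
        t_up, f_up = limit(float(z_i), -1)
        t_dn, f_dn = limit(float(z_i), +1)
        assert np.abs(t_up - t_dn).max() <= 1e-9 * np.abs(t_up).max()
        assert np.abs(f_up - f_dn).max() <= 1e-9 * np.abs(f_up).max()


def test_depth_profile_ode_residual(polyester_stack, convective_bc):
    """Total solution satisfies d2T/dz2 - (k^2 + j w/D) T = 0 off the sheet.

    Fifth-point central differences at moderate |mu| keep the combined
    truncation + roundoff error below the 1e-7 target.
    """
    grid = SpectralGrid(4, 4, 20e-3)  # small k keeps the stencil accurate
    rng = np.random.default_rng(7)
    src = SourceSpec.planar(rng.uniform(0.5e3, 2e3, grid.shape), 10e-3)
    mod = ModulationSpec(0.001)
    la = polyester_stack.layers[0]
    mu_sq = grid.k_sq + 1j * mod.omega / la.diffusivity

    def t_at(z):
        return depth_profile(polyester_stack, convective_bc, src, mod, grid, z)

    h = 1e-4
    for z0 in (3e-3, 7e-3, 12e-3):  # above and below the sheet at 10 mm
        stencil = [t_at(z0 + m * h) for m in (-2, -1, 0, 1, 2)]
        d2 = (-stencil[0] + 16 * stencil[1] - 30 * stencil[2]
              + 16 * stencil[3] - stencil[4]) / (12 * h ** 2)
        residual = d2 - mu_sq * stencil[2]
        scale = np.abs(mu_sq * stencil[2])
        assert np.max(np.abs(residual) / scale) <= 1e-7


def test_depth_profile_source_flux_jump(polyester_stack, convective_bc):
    """Conductive flux jumps by the sheet strength across the source plane."""
    grid = SpectralGrid(8, 8, 2e-3)
    q0 = 1.7e3
    z_s = 9e-3
    src = SourceSpec.planar(np.full(grid.shape, q0), z_s)
    mod = ModulationSpec(0.02)
    eps = 1e-9
    _, f_above = depth_profile(polyester_stack, convective_bc, src, mod, grid,
                               z_s - eps, return_flux=True)
    _, f_below = depth_profile(polyester_stack, convective_bc, src, mod, grid,
                               z_s + eps, return_flux=True)
    qk = grid.forward(src.q_map)
    # flux = -kappa dT/dz; the sheet adds q_tilde to the downward flux jump
    # (the origin bin loses a few digits to cancellation of large fluxes)
    np.testing.assert_allclose(f_below - f_above, qk, rtol=1e-5)


def test_depth_profile_rejects_out_of_range(polyester_stack, convective_bc,
                                            small_grid):
    with pytest.raises(ValueError, match="outside"):
        depth_profile(polyester_stack, convective_bc, None,
                      ModulationSpec(0.1), small_grid, 20e-3)


# ----------------------------------------------------------------- TPSF


def test_tpsf_convolution_matches_surface_field(polyester_stack, convective_bc):
    """Convolving the TPSF with the source map reproduces tau_source."""
    grid = SpectralGrid(64, 64, 1e-3)
    z_s = 4e-3
    mod = ModulationSpec(0.1)
    src = SourceSpec.planar_rect(grid, (3e-3, -2e-3), (2e-3, 3e-3), 0.2, z_s)
    fld = surface_field(polyester_stack, convective_bc, src, mod, grid)
    kernel = tpsf(polyester_stack, convective_bc, z_s, mod, grid)
    via_kernel = grid.inverse(kernel.spectrum * grid.forward(src.q_map))
    np.testing.assert_allclose(via_kernel, fld.source.data, rtol=1e-8,
                               atol=1e-8 * np.abs(fld.source.data).max())


def test_tpsf_fwhm_monotone_in_depth_and_frequency(polyester_stack,
                                                   convective_bc):
    grid = SpectralGrid(96, 96, 0.5e-3)
    widths_depth = [tpsf(polyester_stack, convective_bc, z, ModulationSpec(0.1),
                         grid).fwhm_mm() for z in (3e-3, 5e-3, 7e-3)]
    assert widths_depth[0] < widths_depth[1] < widths_depth[2]
    widths_freq = [tpsf(polyester_stack, convective_bc, 5e-3, ModulationSpec(f),
                        grid).fwhm_mm() for f in (0.02, 0.05, 0.1)]
    assert widths_freq[0] > widths_freq[1] > widths_freq[2]


def test_tpsf_peak_magnitude_decays_with_frequency(polyester_stack,
                                                   convective_bc):
    grid = SpectralGrid(64, 64, 1e-3)
    peaks = [tpsf(polyester_stack, convective_bc, 5e-3, ModulationSpec(f),
                  grid).peak_magnitude() for f in (0.02, 0.05, 0.1, 0.2)]
    assert all(a > b for a, b in zip(peaks, peaks[1:]))


def test_tpsf_rejects_depth_outside_bottom_layer(polyester_stack,
                                                 convective_bc, small_grid):
    with pytest.raises(ValueError):
        tpsf(polyester_stack, convective_bc, 20e-3, ModulationSpec(0.1),
             small_grid)


# ----------------------------------------------------------- data types


def test_layer_validation():
    with pytest.raises(ValueError):
        Layer(0.0, 0.5, 1000, 3500)
    la = Layer(1e-3, 0.155, 1090, 1670)
    assert la.diffusivity == pytest.approx(8.52e-8, rel=2e-3)


def test_stack_depths_strictly_increasing(three_layer_stack):
    zc = three_layer_stack.cumulative_depths
    assert np.all(np.diff(zc) > 0)
    assert zc[-1] == pytest.approx(16e-3)
    assert three_layer_stack.layer_index_at(2e-3) == 0
    assert three_layer_stack.layer_index_at(2.1e-3) == 1
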