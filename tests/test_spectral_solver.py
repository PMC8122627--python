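import copy

import numpy as np
import pytest

from sfbrelax.spectral_solver import (
    bd_oracle,
    build_operator,
    converged_j_matrix,
    correlation_function,
    effective_diffusion,
    favro_correlation,
    favro_rates,
    favro_rigid,
    hermite_basis,
    j_matrix,
    mode_reduction,
    spectral_density,
)

TEMP = 298.0


class TestBasisAndOperator:
    def test_rigid_rotor_basis_count(self, rigid_sphere_high_friction):
        op = build_operator(rigid_sphere_high_friction["params"], nu_max=1)
        # (ground + 3 single excitations) x 5 m-states
        assert op.n_hermite == 4
        assert op.dim == 20

    def test_hermite_basis_size(self):
        # C(N + nu, nu) states for N modes
        assert len(hermite_basis(9, 4)) == 715
        assert len(hermite_basis(0, 4)) == 1
        assert len(hermite_basis(3, 2)) == 10

    def test_ground_state_stationary(self, tri_bead_system):
        op = build_operator(tri_bead_system["params"], nu_max=2)
        v0 = op.start_vector(0)
        # the Wigner part is not acted on by Gamma_0; only Gamma_int moves the
        # ground Hermite state, by exactly one excitation
        out = op.gamma @ v0
        ground_rows = [op.index_of(m, (0,) * op.n_modes) for m in range(-2, 3)]
        assert np.abs(out[ground_rows]).max() < 1e-12 * np.abs(op.gamma.data).max()

    def test_rank0_ground_state_annihilated(self, tri_bead_system):
        op = build_operator(tri_bead_system["params"], nu_max=2, L=0)
        v0 = np.zeros(op.dim)
        v0[op.index_of(0, (0,) * op.n_modes)] = 1.0
        assert np.abs(op.gamma @ v0).max() < 1e-12 * np.abs(op.gamma.data).max()

    def test_excitation_change_bounded(self, tri_bead_system):
        op = build_operator(tri_bead_system["params"], nu_max=3)
        totals = np.array([sum(s) for s in op.states] * 5)
        coo = op.gamma.tocoo()
        deltas = np.abs(totals[coo.row % op.n_hermite + 0] - totals[coo.col % op.n_hermite])
        assert deltas.max() <= 1

    def test_memory_budget(self, tri_bead_system):
        with pytest.raises(MemoryError, match="mode_reduction"):
            build_operator(tri_bead_system["params"], nu_max=3, max_dim=100)


class TestSpectralDensity:
    def test_rigid_sphere_diffusive_limit(self, rigid_sphere_high_friction):
        sys = rigid_sphere_high_friction
        assert sys["xi"] / np.sqrt(sys["inertia"] ** 2 * sys["params"].omega_int[0, 0] ** 2) > 1e3
        op = build_operator(sys["params"], nu_max=4)
        jset = spectral_density(op, 0, 0, 0, 0, [0.0])
        expected = 0.2 * sys["tau"]
        assert jset.values[0, 0].real == pytest.approx(expected, rel=0.01)

    def test_high_frequency_decay(self, rigid_sphere_high_friction):
        sys = rigid_sphere_high_friction
        op = build_operator(sys["params"], nu_max=3)
        jm = j_matrix(op, [0.0, 1e6 / sys["tau"]])
        assert np.abs(jm[1, 2, 2]) < 1e-4 * np.abs(jm[0, 2, 2])

    def test_isotropic_off_diagonal_zero(self, rigid_sphere_high_friction):
        op = build_operator(rigid_sphere_high_friction["params"], nu_max=3)
        jm = j_matrix(op, [0.0])[0]
        diag = np.abs(np.diag(jm)).max()
        off = np.abs(jm - np.diag(np.diag(jm))).max()
        assert off < 1e-10 * diag

    def test_k_block_equivalence(self, rigid_sphere_high_friction):
        op = build_operator(rigid_sphere_high_friction["params"], nu_max=2)
        j_k0 = spectral_density(op, 0, 0, 0, 0, [0.0]).values[0, 0]
        j_k2 = spectral_density(op, 2, 2, 0, 0, [0.0]).values[0, 0]
        assert j_k0 == pytest.approx(j_k2, rel=1e-12)

    def test_time_rescaling_linearity(self, tri_bead_system):
        params = tri_bead_system["params"]
        scale = 3.0
        scaled = copy.deepcopy(params)
        scaled.omega_io = params.omega_io * scale
        scaled.omega_int = params.omega_int * scale
        omega = 1.0 / tri_bead_system["params"].diffusion.tau_c
        j_base = j_matrix(build_operator(params, nu_max=3), [omega / scale])[0]
        j_scaled = j_matrix(build_operator(scaled, nu_max=3), [omega])[0]
        np.testing.assert_allclose(j_scaled, j_base / scale, rtol=1e-8)

    def test_hermitian_symmetry(self, tri_bead_system):
        # time reversal with orientation-even observables gives
        # j_{m,m'}(w) = conj(j_{m',m}(-w)); at w = 0 the matrix is Hermitian
        op = build_operator(tri_bead_system["params"], nu_max=3)
        w = 1.0 / tri_bead_system["params"].diffusion.tau_c
        j_pos, j_neg, j_zero = j_matrix(op, [w, -w, 0.0])
        scale = np.abs(j_zero).max()
        np.testing.assert_allclose(j_pos, j_neg.conj().T, atol=1e-8 * scale)
        np.testing.assert_allclose(j_zero, j_zero.conj().T, atol=1e-8 * scale)

    @pytest.mark.parametrize("system,nus", [("tri_bead_system", (2, 3)), ("bead_pair_system", (4, 5))])
    def test_nu_convergence(self, system, nus, request):
        params = request.getfixturevalue(system)["params"]
        omegas = np.array([0.0, 1e11, 1e12])  # spans the slow orientational band
        lo = j_matrix(build_operator(params, nu_max=nus[0]), omegas)
        hi = j_matrix(build_operator(params, nu_max=nus[1]), omegas)
        diag_lo = np.diagonal(lo, axis1=1, axis2=2).real
        diag_hi = np.diagonal(hi, axis1=1, axis2=2).real
        assert np.abs(diag_hi - diag_lo).max() / np.abs(diag_lo).max() < 0.005

    def test_converged_j_matrix(self, bead_pair_system):
        params = bead_pair_system["params"]
        jm, nu = converged_j_matrix(params, [0.0, 1e11])
        assert nu <= 6
        ref = j_matrix(build_operator(params, nu_max=nu + 1), [0.0, 1e11])
        np.testing.assert_allclose(jm[:, 2, 2].real, ref[:, 2, 2].real, rtol=0.005)

    def test_rank0_singular_at_zero(self, tri_bead_system):
        op = build_operator(tri_bead_system["params"], nu_max=2, L=0)
        with pytest.raises(ValueError, match="singular"):
            spectral_density(op, 0, 0, 0, 0, [0.0])


class TestCorrelationFunction:
    def test_g0_is_one_fifth(self, tri_bead_system):
        op = build_operator(tri_bead_system["params"], nu_max=2)
        for m in (-2, 0, 1):
            g = correlation_function(op, 0, m, [0.0])
            assert g[0].real == pytest.approx(0.2, abs=1e-12)

    def test_rigid_diffusive_exponential(self, rigid_sphere_high_friction):
        sys = rigid_sphere_high_friction
        op = build_operator(sys["params"], nu_max=3)
        t = np.linspace(0, 3 * sys["tau"], 7)
        g = correlation_function(op, 0, 0, t)
        np.testing.assert_allclose(g.real, 0.2 * np.exp(-t / sys["tau"]), rtol=0.01)

    def test_bounded_by_g0(self, tri_bead_system):
        op = build_operator(tri_bead_system["params"], nu_max=2)
        tau = tri_bead_system["params"].diffusion.tau_c
        for m in range(-2, 3):
            g = correlation_function(op, 0, m, np.linspace(0, 4 * tau, 12))
            assert np.all(np.abs(g) <= 0.2 + 1e-12)


class TestFavro:
    def test_isotropic_lorentzian(self):
        d = 1e10
        tau = 1 / (6 * d)
        omegas = np.array([0.0, 1 / tau, 5 / tau])
        jset = favro_rigid(np.full(3, d), omegas)
        np.testing.assert_allclose(
            jset.get(0, 0, 0, 0).real, 0.2 * tau / (1 + (omegas * tau) ** 2), rtol=1e-12
        )

    def test_axial_rates(self):
        rates = favro_rates([1.0, 1.0, 2.0])
        np.testing.assert_allclose(rates, [6.0, 7.0, 7.0, 10.0, 10.0], atol=1e-12)

    def test_fully_anisotropic_rates(self):
        d1, d2, d3 = 1.0, 2.0, 3.0
        rates = favro_rates([d1, d2, d3])
        dd = d1 + d2 + d3
        delta = np.sqrt(d1**2 + d2**2 + d3**2 - d1 * d2 - d1 * d3 - d2 * d3)
        expected = np.sort([
            4 * d1 + d2 + d3, d1 + 4 * d2 + d3, d1 + d2 + 4 * d3,
            2 * dd - 2 * delta, 2 * dd + 2 * delta,
        ])
        np.testing.assert_allclose(rates, expected, rtol=1e-12)

    def test_parseval_initial_value(self):
        # (2/pi) integral of Re j(w) dw = G(0) = 1/5
        dvals = np.array([0.7e10, 1.1e10, 2.9e10])
        rate_max = 6 * dvals.max()
        omegas = np.linspace(0, 400 * rate_max, 60_000)
        j00 = favro_rigid(dvals, omegas).get(0, 0, 0, 0).real
        integral = (2 / np.pi) * np.trapezoid(j00, omegas)
        assert integral == pytest.approx(0.2, rel=1e-3)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            favro_rigid([1.0, -1.0, 1.0], [0.0])


class TestSerialization:
    def test_spectral_density_csv_round_trip(self, tmp_path):
        jset = favro_rigid([1e10, 1.5e10, 2e10], [0.0, 5e9, 2e10])
        path = tmp_path / "j.csv"
        jset.to_csv(path)
        back = type(jset).from_csv(path)
        np.testing.assert_allclose(back.omegas, jset.omegas)
        np.testing.assert_allclose(
            back.get(0, 0, 0, 0), jset.get(0, 0, 0, 0), rtol=1e-12
        )
        np.testing.assert_allclose(
            back.get(0, 0, 2, 0), jset.get(0, 0, 2, 0), atol=1e-18
        )


class TestBDOracle:
    def test_equilibrium_variance(self, tri_bead_system):
        tau = tri_bead_system["params"].diffusion.tau_c
        res = bd_oracle(tri_bead_system["params"], seed=11, n_traj=800, dt=tau / 50,
                        t_max=2 * tau, sample_stride=10)
        dev = np.abs(res.x_variance - 1.0) / np.maximum(res.x_variance_se, 1e-12)
        assert np.all(dev < 3.0)

    def test_rigid_rotor_matches_favro(self, rigid_sphere_high_friction):
        sys = rigid_sphere_high_friction
        res = bd_oracle(sys["params"], seed=21, n_traj=2000, dt=sys["tau"] / 60,
                        t_max=2 * sys["tau"], sample_stride=12)
        gf = favro_correlation(np.full(3, sys["D"]), res.tgrid).T
        dev = np.abs(res.G - gf) / np.maximum(res.stderr, 1e-15)
        assert dev.max() < 3.0

    def test_fixed_seed_bit_identical(self, tri_bead_system):
        tau = tri_bead_system["params"].diffusion.tau_c
        kwargs = dict(seed=3, n_traj=100, dt=tau / 50, t_max=tau, sample_stride=10)
        r1 = bd_oracle(tri_bead_system["params"], **kwargs)
        r2 = bd_oracle(tri_bead_system["params"], **kwargs)
        np.testing.assert_array_equal(r1.G, r2.G)

    def test_step_size_guard(self, rigid_sphere_high_friction):
        sys = rigid_sphere_high_friction
        with pytest.raises(ValueError, match="rms step rotation"):
            bd_oracle(sys["params"], seed=1, n_traj=10, dt=50 * sys["tau"], t_max=100 * sys["tau"])


class TestModeReduction:
    def test_rigid_rotor_identity(self, rigid_sphere_high_friction):
        report = mode_reduction(rigid_sphere_high_friction["params"], budget=3)
        assert report.retained_weight == 1.0
        np.testing.assert_array_equal(
            report.params.omega_io, rigid_sphere_high_friction["params"].omega_io
        )

    def test_bead_pair_reduces_to_rigid_rotor(self, bead_pair_system):
        # the stretch mode of a symmetric pair carries no rotational coupling
        params = bead_pair_system["params"]
        report = mode_reduction(params, budget=2)
        assert report.params.N == 2
        assert report.retained_weight == 1.0  # dropped weight is exactly zero
        j_red = j_matrix(build_operator(report.params, nu_max=4), [0.0])[0]
        j_full = j_matrix(build_operator(params, nu_max=4), [0.0])[0]
        np.testing.assert_allclose(j_red[2, 2], j_full[2, 2], rtol=1e-6)

    def test_retained_weight_controls_j_shift(self, tri_bead_system):
        params = tri_bead_system["params"]
        tau = params.diffusion.tau_c
        omegas = np.array([0.0, 1.0 / tau])
        j_full = j_matrix(build_operator(params, nu_max=3), omegas)
        for budget in (3, 5, 7, 9):
            report = mode_reduction(params, budget=budget)
            j_red = j_matrix(build_operator(report.params, nu_max=3), omegas)
            shift = np.abs(
                np.diagonal(j_red, axis1=1, axis2=2).real
                - np.diagonal(j_full, axis1=1, axis2=2).real
            ).max() / np.abs(j_full[0, 2, 2].real)
            if report.retained_weight >= 0.99:
                assert shift < 0.02

    def test_budget_too_small(self, tri_bead_system):
        with pytest.raises(ValueError, match="angular"):
            mode_reduction(tri_bead_system["params"], budget=2)


class TestMarkovianFastPath:
    def test_rigid_body_exact(self, rigid_sphere_high_friction):
        sys = rigid_sphere_high_friction
        diff = effective_diffusion(sys["params"])
        np.testing.assert_allclose(diff.principal_values, np.full(3, sys["D"]), rtol=1e-8)

    def test_within_5_percent_of_reference(self, tri_bead_system):
        params = tri_bead_system["params"]
        tau = params.diffusion.tau_c
        omegas = np.array([0.0, 1.0 / tau, 3.0 / tau])
        j_ref = j_matrix(build_operator(params, nu_max=3), omegas)
        j_fast = favro_rigid(effective_diffusion(params), omegas)
        for i, w in enumerate(omegas):
            ref = j_ref[i, 2, 2].real
            fast = j_fast.get(0, 0, 0, 0)[i].real
            assert fast == pytest.approx(ref, rel=0.05)
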