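"""Orientational correlation functions and spectral densities under the SFB operator.

The operator is discretized in the product basis of rank-L Wigner functions
(body index m = -L..L; the lab index k is conserved and never enters the
matrix) and normalized multi-mode Hermite states with total excitation
<= nu_max. In that basis the mode part is the number-conserving boson form
``sum_ij omega_io[i,j] b_i^+ b_j`` and the rotational coupling is
``i * sum_ip omega_int[i,p] x_i M_p`` with x tridiagonal in the Hermite index.

Spectral densities are normalized as pure orientational quantities: the
diagonal rigid isotropic value is j(omega) = (1/5) tau / (1 + omega^2 tau^2)
and G(0) = 1/5. Interaction constants live in :mod:`sfbrelax.relaxation`.

Besides the sparse resolvent reference solver, the module provides the Favro
closed form for rigid anisotropic diffusion, a Brownian-dynamics simulation
oracle, a coupling-weight mode reduction and a Markovian (adiabatic
elimination) fast path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.linalg import expm
from scipy.spatial.transform import Rotation

from .hydrodynamics import DiffusionTensor
from .rotations import body_angular_momentum, reduced_d2
from .sfb_model import SFBParameters

__all__ = [
    "OperatorMatrix",
    "SpectralDensitySet",
    "hermite_basis",
    "build_operator",
    "spectral_density",
    "j_matrix",
    "converged_j_matrix",
    "correlation_function",
    "favro_rigid",
    "favro_rates",
    "favro_correlation",
    "bd_oracle",
    "BDResult",
    "mode_reduction",
    "ReductionReport",
    "effective_diffusion",
]

#: default memory guard: maximum product-basis dimension
MAX_BASIS_DIM = 2_000_000


def hermite_basis(n_modes: int, nu_max: int) -> list[tuple[int, ...]]:
    """All Hermite multi-indices with total excitation <= nu_max, graded order."""
    if nu_max < 0:
        raise ValueError("nu_max must be >= 0")
    if n_modes == 0:
        return [()]
    states: list[tuple[int, ...]] = []

    def fill(prefix, remaining, left):
        if remaining == 1:
            states.append(tuple(prefix + [left]))
            return
        for v in range(left + 1):
            fill(prefix + [v], remaining - 1, left - v)

    for total in range(nu_max + 1):
        fill([], n_modes, total)
    return states


@dataclass
class OperatorMatrix:
    """Sparse discretized operator Gamma with its basis bookkeeping."""

    gamma: sp.csc_matrix
    L: int
    n_modes: int
    nu_max: int
    states: list[tuple[int, ...]]
    state_index: dict = field(repr=False, default_factory=dict)

    @property
    def n_hermite(self) -> int:
        return len(self.states)

    @property
    def dim(self) -> int:
        return (2 * self.L + 1) * self.n_hermite

    def index_of(self, m: int, nu: tuple[int, ...]) -> int:
        return (m + self.L) * self.n_hermite + self.state_index[nu]

    def start_vector(self, m: int) -> np.ndarray:
        """Equilibrium-weighted Wigner starting vector (unit basis vector)."""
        v = np.zeros(self.dim, dtype=complex)
        v[self.index_of(m, (0,) * self.n_modes)] = 1.0
        return v


def build_operator(params: SFBParameters, nu_max: int, L: int = 2,
                   max_dim: int = MAX_BASIS_DIM) -> OperatorMatrix:
    """Discretize Gamma = Gamma_0 + Gamma_int in the Wigner x Hermite basis.

    Gamma_0 conserves total Hermite excitation (plus an excitation-raising
    b^+ b^+ term if ``params.noise_cov`` deviates from sym(omega_io));
    Gamma_int changes the excitation by +-1 and the body index m by 0 or +-1.
    """
    if nu_max < 1:
        raise ValueError("nu_max must be >= 1")
    n = params.N
    states = hermite_basis(n, nu_max)
    n_h = len(states)
    dim = (2 * L + 1) * n_h
    if dim > max_dim:
        raise MemoryError(
            f"basis dimension {dim} exceeds budget {max_dim}; "
            "reduce nu_max or apply mode_reduction"
        )
    index = {s: i for i, s in enumerate(states)}

    omega_io = params.omega_io
    rows, cols, vals = [], [], []
    fd_break = params.noise_cov is not None
    delta = params.symmetric_noise() - 0.5 * (omega_io + omega_io.T) if fd_break else None
    for col, nu in enumerate(states):
        for j in range(n):
            if nu[j] == 0:
                continue
            amp_j = np.sqrt(nu[j])
            lowered = list(nu)
            lowered[j] -= 1
            for i in range(n):
                w = omega_io[i, j]
                if w == 0.0:
                    continue
                target = lowered.copy()
                target[i] += 1
                rows.append(index[tuple(target)])
                cols.append(col)
                vals.append(w * amp_j * np.sqrt(lowered[i] + 1))
        if fd_break:
            for i in range(n):
                for j in range(n):
                    w = -delta[i, j]
                    if w == 0.0:
                        continue
                    target = list(nu)
                    target[j] += 1
                    amp = np.sqrt(target[j])
                    target[i] += 1
                    amp *= np.sqrt(target[i])
                    key = tuple(target)
                    if key in index:
                        rows.append(index[key])
                        cols.append(col)
                        vals.append(w * amp)
    gamma0 = sp.csc_matrix((vals, (rows, cols)), shape=(n_h, n_h))

    m_ops = body_angular_momentum(L)
    gamma = sp.kron(sp.identity(2 * L + 1), gamma0, format="csc").astype(complex)
    for p in range(3):
        coeff = params.omega_int[:, p]
        if not np.any(coeff):
            continue
        rows, cols, vals = [], [], []
        for col, nu in enumerate(states):
            for i in np.nonzero(coeff)[0]:
                c = coeff[i]
                if nu[i] > 0:  # lowering part of x_i
                    target = list(nu)
                    target[i] -= 1
                    rows.append(index[tuple(target)])
                    cols.append(col)
                    vals.append(c * np.sqrt(nu[i]))
                target = list(nu)
                target[i] += 1
                key = tuple(target)
                if key in index:  # raising part, truncated at nu_max
                    rows.append(index[key])
                    cols.append(col)
                    vals.append(c * np.sqrt(target[i]))
        x_p = sp.csc_matrix((vals, (rows, cols)), shape=(n_h, n_h))
        gamma = gamma + 1j * sp.kron(m_ops[p], x_p, format="csc")
    return OperatorMatrix(
        gamma=gamma.tocsc(), L=L, n_modes=n, nu_max=nu_max,
        states=states, state_index=index,
    )


@dataclass
class SpectralDensitySet:
    """Complex orientational spectral densities j_{m,m'}^{(k,k')}(omega).

    One-sided Fourier-Laplace transforms of the equilibrium Wigner correlation
    functions; diagonal entries have Re j >= 0 and vanish as omega -> infinity.
    Time reversal gives j_{m,m'}(omega) = conj(j_{m',m}(-omega)), so the matrix
    is Hermitian at omega = 0.
    """

    entries: list[tuple[int, int, int, int]]  # (k, k', m, m')
    omegas: np.ndarray  # rad/s
    values: np.ndarray  # (n_entries, n_omega) complex, units s

    def get(self, k: int, kp: int, m: int, mp: int) -> np.ndarray:
        idx = self.entries.index((k, kp, m, mp))
        return self.values[idx]

    def to_csv(self, path) -> None:
        import pandas as pd

        records = []
        for (k, kp, m, mp), row in zip(self.entries, self.values):
            for omega, v in zip(self.omegas, row):
                records.append((k, kp, m, mp, omega, v.real, v.imag))
        pd.DataFrame(
            records, columns=["k", "k'", "m", "m'", "omega_rad_s", "re_j_s", "im_j_s"]
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpectralDensitySet":
        import pandas as pd

        df = pd.read_csv(path)
        omegas = np.array(sorted(df["omega_rad_s"].unique()))
        entries, values = [], []
        for key, grp in df.groupby(["k", "k'", "m", "m'"], sort=False):
            grp = grp.sort_values("omega_rad_s")
            entries.append(tuple(int(v) for v in key))
            values.append(grp["re_j_s"].to_numpy() + 1j * grp["im_j_s"].to_numpy())
        return cls(entries=entries, omegas=omegas, values=np.array(values))


def _resolve(op: OperatorMatrix, omegas, rhs_columns: np.ndarray) -> np.ndarray:
    """Solve (i omega I + Gamma) Y = rhs for each omega; returns (n_omega, dim, n_rhs)."""
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    eye = sp.identity(op.dim, dtype=complex, format="csc")
    out = np.empty((len(omegas), op.dim, rhs_columns.shape[1]), dtype=complex)
    for w_idx, omega in enumerate(omegas):
        lu = spla.splu((1j * omega * eye + op.gamma).tocsc())
        out[w_idx] = lu.solve(rhs_columns)
        resid = np.abs(
            (1j * omega * eye + op.gamma) @ out[w_idx] - rhs_columns
        ).max()
        if not np.isfinite(resid) or resid > 1e-8:
            raise ArithmeticError(f"resolvent solve residual {resid:.2e} at omega={omega:.3e}")
    return out


def spectral_density(op: OperatorMatrix, k: int, kp: int, m: int, mp: int,
                     omegas) -> SpectralDensitySet:
    """j_{m,m'}^{(k,k')}(omega) = (1/5) <v_m' | (i omega + Gamma)^-1 | v_m>.

    The operator is block diagonal and identical across the lab index k, so k
    and k' only label the output (j is k-independent for the isotropic
    equilibrium); they must lie in -L..L.
    """
    for label in (k, kp, m, mp):
        if not -op.L <= label <= op.L:
            raise ValueError("indices must lie in -L..L")
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    if np.any(omegas == 0.0) and op.L == 0:
        raise ValueError("Gamma is singular at omega=0 on the rank-0 block")
    rhs = op.start_vector(m)[:, None]
    sol = _resolve(op, omegas, rhs)
    row = sol[:, op.index_of(mp, (0,) * op.n_modes), 0] / (2 * op.L + 1)
    return SpectralDensitySet(entries=[(k, kp, m, mp)], omegas=omegas, values=row[None, :])


def j_matrix(op: OperatorMatrix, omegas) -> np.ndarray:
    """Full (n_omega, 2L+1, 2L+1) matrix of j_{m,m'}(omega), index order m' x m."""
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    size = 2 * op.L + 1
    rhs = np.column_stack([op.start_vector(m) for m in range(-op.L, op.L + 1)])
    sol = _resolve(op, omegas, rhs)
    ground_rows = [op.index_of(m, (0,) * op.n_modes) for m in range(-op.L, op.L + 1)]
    out = np.empty((len(omegas), size, size), dtype=complex)
    for w_idx in range(len(omegas)):
        out[w_idx] = sol[w_idx][ground_rows, :] / size
    return out


def converged_j_matrix(params: SFBParameters, omegas, nu_start: int = 2,
                       rtol: float = 0.005, nu_cap: int = 12) -> tuple[np.ndarray, int]:
    """Increase nu_max until the diagonal of j changes by less than ``rtol``.

    Returns (j matrix at the converged nu_max, nu_max used). Raises if the
    cap is reached without convergence.
    """
    prev = None
    for nu in range(nu_start, nu_cap + 1):
        cur = j_matrix(build_operator(params, nu_max=nu), omegas)
        if prev is not None:
            diag_prev = np.abs(np.diagonal(prev, axis1=1, axis2=2))
            diag_cur = np.abs(np.diagonal(cur, axis1=1, axis2=2))
            change = np.max(np.abs(diag_cur - diag_prev) / np.maximum(diag_cur.max(), 1e-300))
            if change < rtol:
                return cur, nu
        prev = cur
    raise ArithmeticError(f"spectral densities not converged at nu_max={nu_cap}")


def correlation_function(op: OperatorMatrix, k: int, m: int, tgrid,
                         m_end: int | None = None) -> np.ndarray:
    """G(t) = (1/(2L+1)) <v_m_end | exp(-Gamma t) | v_m> on a uniform t >= 0 grid."""
    tgrid = np.atleast_1d(np.asarray(tgrid, dtype=float))
    if np.any(tgrid < 0):
        raise ValueError("t grid must be nonnegative")
    if m_end is None:
        m_end = m
    v = op.start_vector(m)
    probe_row = op.index_of(m_end, (0,) * op.n_modes)
    if len(tgrid) > 1:
        steps = np.diff(tgrid)
        if not np.allclose(steps, steps[0], rtol=1e-8):
            raise ValueError("t grid must be uniform")
    if op.dim <= 1600:
        # dense stepping handles stiff operators far better than expm_multiply
        dt = tgrid[0] if len(tgrid) == 1 else tgrid[1] - tgrid[0]
        step_mat = expm(-op.gamma.toarray() * dt)
        state = v if tgrid[0] == 0 else expm(-op.gamma.toarray() * tgrid[0]) @ v
        states = np.empty((len(tgrid), op.dim), dtype=complex)
        states[0] = state
        for i in range(1, len(tgrid)):
            states[i] = step_mat @ states[i - 1]
    elif len(tgrid) == 1:
        states = spla.expm_multiply(-op.gamma * tgrid[0], v)[None, :]
    else:
        states = spla.expm_multiply(
            -op.gamma, v, start=tgrid[0], stop=tgrid[-1], num=len(tgrid), endpoint=True
        )
    if not np.all(np.isfinite(states)):
        raise ArithmeticError("propagation produced non-finite values (stiff operator?)")
    return states[:, probe_row] / (2 * op.L + 1)


# ---------------------------------------------------------------------------
# Rigid-diffusion closed form (Favro)
# ---------------------------------------------------------------------------

def _principal_values(d) -> np.ndarray:
    if isinstance(d, DiffusionTensor):
        return np.asarray(d.principal_values, dtype=float)
    d = np.asarray(d, dtype=float)
    if d.shape == (3, 3):
        return np.linalg.eigvalsh(d)
    if d.shape == (3,):
        return d
    if d.shape == ():
        return np.full(3, float(d))
    raise ValueError("expected a DiffusionTensor, 3x3 tensor, 3 principal values or a scalar")


def _favro_generator(d) -> np.ndarray:
    dvals = _principal_values(d)
    if np.any(dvals <= 0):
        raise ValueError("diffusion tensor must be positive definite")
    m1, m2, m3 = body_angular_momentum(2)
    gen = dvals[0] * (m1 @ m1) + dvals[1] * (m2 @ m2) + dvals[2] * (m3 @ m3)
    return np.real(gen)


def favro_rates(d) -> np.ndarray:
    """The five rank-2 decay rates of rigid anisotropic rotational diffusion.

    Axial tensors (D1 = D2 = Dperp, D3 = Dpar) give 6Dperp, 5Dperp + Dpar and
    2Dperp + 4Dpar.
    """
    return np.sort(np.linalg.eigvalsh(_favro_generator(d)))


def favro_rigid(d, omegas) -> SpectralDensitySet:
    """Closed-form rank-2 spectral densities of a rigid diffusive rotator.

    Returns the full m, m' set (k = k' = 0 labels); the isotropic limit is a
    single Lorentzian (1/5) tau / (1 + omega^2 tau^2) with tau = 1/(6D).
    """
    gen = _favro_generator(d)
    omegas = np.atleast_1d(np.asarray(omegas, dtype=float))
    entries = [(0, 0, m, mp) for m in range(-2, 3) for mp in range(-2, 3)]
    values = np.empty((25, len(omegas)), dtype=complex)
    for w_idx, omega in enumerate(omegas):
        res = np.linalg.inv(1j * omega * np.eye(5) + gen) / 5.0
        values[:, w_idx] = np.array(
            [res[mp + 2, m + 2] for (_, _, m, mp) in entries]
        )
    return SpectralDensitySet(entries=entries, omegas=omegas, values=values)


def favro_correlation(d, tgrid) -> np.ndarray:
    """Diagonal G_m(t) of the rigid diffusive rotator, shape (nt, 5)."""
    gen = _favro_generator(d)
    tgrid = np.atleast_1d(np.asarray(tgrid, dtype=float))
    return np.array([np.diag(expm(-gen * t)) / 5.0 for t in tgrid])


# ---------------------------------------------------------------------------
# Brownian-dynamics oracle
# ---------------------------------------------------------------------------

@dataclass
class BDResult:
    tgrid: np.ndarray
    G: np.ndarray  # (5, nt) real part of (1/5) E[D2_mm]
    stderr: np.ndarray  # (5, nt)
    x_variance: np.ndarray  # (N,)
    x_variance_se: np.ndarray
    n_traj: int


def _discrete_gaussian_step(a_aug: np.ndarray, qc_aug: np.ndarray, dt: float):
    """Exact one-step propagator and noise covariance of dy = -A y dt + noise.

    Uses the Van Loan block-exponential construction; returns (Phi, chol) with
    Phi = expm(-A dt) and chol the Cholesky factor of the step covariance.
    """
    n = a_aug.shape[0]
    # Van Loan overflows for stiff steps (it exponentiates +A^T dt), so build
    # the step at a sub-interval with |A| h <~ 0.25 and double the covariance:
    # Q(2t) = Q(t) + Phi(t) Q(t) Phi(t)^T, Phi(2t) = Phi(t)^2.
    scale = float(np.linalg.norm(a_aug, 2)) * dt
    n_doublings = max(0, int(np.ceil(np.log2(max(scale, 1e-12) / 0.25))))
    h = dt / 2**n_doublings
    block = np.zeros((2 * n, 2 * n))
    block[:n, :n] = -a_aug * h
    block[:n, n:] = qc_aug * h
    block[n:, n:] = a_aug.T * h
    e = expm(block)
    phi = e[:n, :n]
    q = e[:n, n:] @ phi.T
    q = 0.5 * (q + q.T)
    for _ in range(n_doublings):
        q = q + phi @ q @ phi.T
        q = 0.5 * (q + q.T)
        phi = phi @ phi
    eigval, eigvec = np.linalg.eigh(q)
    eigval = np.clip(eigval, 0.0, None)
    chol = eigvec * np.sqrt(eigval)
    return phi, chol


def _rodrigues(theta: np.ndarray) -> np.ndarray:
    """Batch rotation matrices exp([theta]_x) for rotation vectors (n, 3)."""
    return Rotation.from_rotvec(theta).as_matrix()


def bd_oracle(params: SFBParameters, seed: int, n_traj: int, dt: float,
              t_max: float, sample_stride: int = 1) -> BDResult:
    """Estimate the diagonal orientational correlation functions by simulation.

    The joint Gaussian update of the modes x and the per-step integrated
    rotation angle is sampled exactly (augmented Ornstein-Uhlenbeck propagator);
    the only discretization error is the non-commutativity of rotation
    increments, so dt needs to be small against the tumbling time, not against
    the fastest mode. Deterministic for a fixed seed.
    """
    a = params.omega_io
    n = params.N
    w_map = params.omega_int.T  # (3, N): angular velocity = w_map @ x
    a_aug = np.zeros((n + 3, n + 3))
    a_aug[:n, :n] = a
    a_aug[n:, :n] = -w_map
    qc = np.zeros((n + 3, n + 3))
    qc[:n, :n] = 2.0 * params.symmetric_noise()
    phi, chol = _discrete_gaussian_step(a_aug, qc, dt)
    # non-commutativity of rotation increments is the only discretization error;
    # keep the per-step rms angle small (mean part + stochastic part)
    step_cov = chol @ chol.T
    theta_rms = float(
        np.sqrt(np.trace(step_cov[n:, n:]) + np.sum((phi[n:, :n]) ** 2))
    )
    if theta_rms > 0.5:
        raise ValueError(
            f"dt={dt:.2e} gives rms step rotation {theta_rms:.2f} rad; reduce dt"
        )

    n_steps = int(round(t_max / dt))
    sample_steps = np.arange(0, n_steps + 1, sample_stride)
    tgrid = sample_steps * dt
    nt = len(tgrid)

    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_traj, n))
    rot = np.broadcast_to(np.eye(3), (n_traj, 3, 3)).copy()

    d_sum = np.zeros((5, nt))
    d_sumsq = np.zeros((5, nt))
    xsq_traj = np.zeros((n_traj, n))  # per-trajectory time-average of x^2
    m_idx = np.arange(-2, 3)

    def record(slot):
        import warnings

        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Gimbal lock")
            euler = Rotation.from_matrix(rot).as_euler("ZYZ")
        alpha, beta, gamma = euler[:, 0], euler[:, 1], euler[:, 2]
        diag = np.diagonal(reduced_d2(beta), axis1=-2, axis2=-1)  # (n_traj, 5)
        phase = np.cos(np.outer(alpha + gamma, m_idx))
        vals = diag * phase
        d_sum[:, slot] += vals.sum(axis=0)
        d_sumsq[:, slot] += (vals**2).sum(axis=0)
        xsq_traj[:] += x**2

    slot = 0
    record(slot)
    for step in range(1, n_steps + 1):
        noise = rng.standard_normal((n_traj, n + 3)) @ chol.T
        y = x @ phi[:, :n].T + noise  # theta component of the state starts at 0
        x = y[:, :n]
        theta = y[:, n:]
        rot = rot @ _rodrigues(theta)
        if slot + 1 < nt and step == sample_steps[slot + 1]:
            slot += 1
            record(slot)

    total = n_traj
    mean = d_sum / total
    var = d_sumsq / total - mean**2
    stderr = np.sqrt(np.clip(var, 0, None) / total) / 5.0
    # per-trajectory variance estimates are independent across trajectories,
    # unlike the time-correlated samples within one trajectory
    xsq_traj /= nt
    xvar = xsq_traj.mean(axis=0)
    xvar_se = xsq_traj.std(axis=0, ddof=1) / np.sqrt(n_traj)
    return BDResult(
        tgrid=tgrid, G=mean / 5.0, stderr=stderr,
        x_variance=xvar, x_variance_se=xvar_se, n_traj=n_traj,
    )


# ---------------------------------------------------------------------------
# Mode reduction and Markovian fast path
# ---------------------------------------------------------------------------

@dataclass
class ReductionReport:
    params: SFBParameters
    retained_weight: float
    kept_pairs: list[int]
    dropped_pairs: list[int]


def mode_reduction(params: SFBParameters, budget: int) -> ReductionReport:
    """Drop weakly coupled internal q/p pairs down to at most ``budget`` modes.

    Pairs are ranked by the Frobenius norm of their momentum row/column blocks
    coupling to the angular-momentum modes through omega_io; angular-momentum
    modes are always kept. Reports the retained fraction of total coupling
    weight (1.0 when nothing is dropped).
    """
    n_ang = params.n_angular
    if budget < n_ang:
        raise ValueError(f"budget must be at least {n_ang} (angular modes are always kept)")
    k = params.mode_types.count("q")
    sl_l = slice(2 * k, 2 * k + n_ang)
    weights = np.array([
        np.linalg.norm(params.omega_io[k + i, sl_l]) + np.linalg.norm(params.omega_io[sl_l, k + i])
        for i in range(k)
    ])
    keep_pairs = min(k, (budget - n_ang) // 2)
    order = np.argsort(weights)[::-1]
    kept = sorted(order[:keep_pairs].tolist())
    dropped = sorted(order[keep_pairs:].tolist())
    total = float(weights.sum())
    retained = 1.0 if total == 0 else float(weights[kept].sum()) / total

    idx = kept + [k + i for i in kept] + list(range(2 * k, 2 * k + n_ang))
    sub = np.ix_(idx, idx)
    reduced = SFBParameters(
        omega_io=params.omega_io[sub],
        omega_int=params.omega_int[idx, :],
        mode_types=[params.mode_types[i] for i in idx],
        temperature_K=params.temperature_K,
        af_axes=params.af_axes,
        inertia_af=params.inertia_af,
        diffusion=params.diffusion,
        mode_frequencies=params.mode_frequencies[kept],
        noise_cov=None if params.noise_cov is None else params.noise_cov[sub],
        metadata={**params.metadata, "reduced_from": params.N},
    )
    return ReductionReport(
        params=reduced, retained_weight=retained, kept_pairs=kept, dropped_pairs=dropped
    )


def effective_diffusion(params: SFBParameters) -> DiffusionTensor:
    """Markovian fast path: effective rotational diffusion from mode elimination.

    Second-order adiabatic elimination of all x modes gives the rigid-rotator
    generator sum_pq D_pq M_p M_q with
    D = sym(omega_int^T omega_io^-1 omega_int); for a rigid body this reduces
    to k_B T Xi_RR^-1 exactly. Feed the result to :func:`favro_rigid`;
    agreement with the reference solver degrades as the mode-rotation coupling
    leaves the perturbative regime. Nonlinear geometries only (the reduced
    tensor is singular for linear ones).
    """
    d = params.omega_int.T @ np.linalg.solve(params.omega_io, params.omega_int)
    d = 0.5 * (d + d.T)
    vals, vecs = np.linalg.eigh(d)
    if vals[0] <= 0 or vals[0] < 1e-12 * vals[-1]:
        raise ValueError("effective diffusion tensor is singular (linear geometry?)")
    for col in range(2):
        pivot = int(np.argmax(np.abs(vecs[:, col])))
        if vecs[pivot, col] < 0:
            vecs[:, col] = -vecs[:, col]
    vecs[:, 2] = np.cross(vecs[:, 0], vecs[:, 1])
    return DiffusionTensor(tensor=d, principal_values=vals, axes=vecs)
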