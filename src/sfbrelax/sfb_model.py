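"""Assembly of the semi-flexible Brownian drift matrices from structure + Hessian + friction.

The dynamical state is a set of N dimensionless Gaussian modes
x = (q, p, L): scaled internal normal-mode coordinates, their conjugate
momenta, and body-frame angular-momentum components (N = 6n-9 for a nonlinear
n-atom molecule). ``omega_io`` is the (generally non-symmetric) N x N drift
matrix of x; ``omega_int`` couples the momentum-type modes to the body-frame
rotation generators. Precession (omega x L) terms are dropped.

Scalings: q_k = Q_k omega_k / sqrt(kT), p_k = P_k / sqrt(kT) for mass-weighted
normal coordinates Q_k, and L = (kT)^(-1/2) I^(-1/2) L_vec with I the inertia
tensor in the attached frame, so every mode has unit equilibrium variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import sqrtm

from .constants import K_B
from .hydrodynamics import DiffusionTensor, FrictionTensor, diffusion_tensor
from .molecule_io import (
    HessianMatrix,
    MolecularStructure,
    mode_count,
    rigid_body_basis,
    validate_minimum,
)

__all__ = [
    "InternalModes",
    "SFBParameters",
    "internal_modes",
    "build_sfb",
    "stationarity_residual",
]


@dataclass
class InternalModes:
    """Positive-frequency internal normal modes of the projected mass-weighted Hessian."""

    frequencies: np.ndarray  # (K,) rad/s
    vectors: np.ndarray  # (3n, K) orthonormal mass-weighted eigenvectors
    fields: np.ndarray  # (K, n, 3) Cartesian velocity per unit mode velocity, 1/sqrt(kg)

    @property
    def n_modes(self) -> int:
        return len(self.frequencies)


def internal_modes(hessian: HessianMatrix | None, structure: MolecularStructure,
                   tol: float = 1e-6) -> InternalModes:
    """Diagonalize the Eckart-projected mass-weighted Hessian.

    Returns the 3n-6 (or 3n-5 for linear geometries) positive-frequency modes;
    a rigid structure (``structure.rigid`` or ``hessian is None``) yields zero
    modes. A projected eigenvalue below -tol (relative) raises: the structure
    is not at a minimum.
    """
    n = structure.n_atoms
    if structure.rigid or hessian is None:
        return InternalModes(np.zeros(0), np.zeros((3 * n, 0)), np.zeros((0, n, 3)))
    report = validate_minimum(hessian, structure, tol=tol)
    if not report.is_minimum:
        raise ValueError(
            f"Hessian has a negative projected eigenvalue ({report.smallest_eigenvalue:.3e});"
            " not a local minimum"
        )
    sqrtm_inv = 1.0 / np.sqrt(np.repeat(structure.masses_kg, 3))
    hmw = hessian.matrix * np.outer(sqrtm_inv, sqrtm_inv)
    basis = rigid_body_basis(structure)
    proj = np.eye(3 * n) - basis @ basis.T
    eigval, eigvec = np.linalg.eigh(proj @ hmw @ proj)
    scale = max(float(np.abs(eigval).max()), 1e-300)
    keep = eigval > tol * scale
    freqs = np.sqrt(eigval[keep])
    vecs = eigvec[:, keep]
    # deterministic sign: largest-magnitude component of each eigenvector positive
    for k in range(vecs.shape[1]):
        pivot = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[pivot, k] < 0:
            vecs[:, k] = -vecs[:, k]
    fields = (vecs * sqrtm_inv[:, None]).T.reshape(-1, n, 3)
    return InternalModes(frequencies=freqs, vectors=vecs, fields=fields)


@dataclass
class SFBParameters:
    """Drift (omega_io) and rotational-coupling (omega_int) matrices of the mode set."""

    omega_io: np.ndarray  # (N, N), 1/s
    omega_int: np.ndarray  # (N, 3), 1/s; nonzero rows only for angular-momentum modes
    mode_types: list[str]  # per mode: "q", "p" or "L"
    temperature_K: float
    af_axes: np.ndarray = field(default_factory=lambda: np.eye(3))
    inertia_af: np.ndarray | None = None
    diffusion: DiffusionTensor | None = None
    mode_frequencies: np.ndarray = field(default_factory=lambda: np.zeros(0))
    noise_cov: np.ndarray | None = None  # defaults to sym(omega_io); set to break FD
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.omega_io = np.asarray(self.omega_io, dtype=float)
        self.omega_int = np.asarray(self.omega_int, dtype=float)
        if self.omega_io.shape != (self.N, self.N):
            raise ValueError("omega_io must be N x N")
        if self.omega_int.shape != (self.N, 3):
            raise ValueError("omega_int must be N x 3")

    @property
    def N(self) -> int:
        return len(self.mode_types)

    @property
    def n_angular(self) -> int:
        return self.mode_types.count("L")

    def symmetric_noise(self) -> np.ndarray:
        if self.noise_cov is not None:
            return np.asarray(self.noise_cov, dtype=float)
        return 0.5 * (self.omega_io + self.omega_io.T)

    # -- plain-text serialization ------------------------------------------
    def to_dict(self) -> dict:
        return {
            "omega_io": self.omega_io.tolist(),
            "omega_int": self.omega_int.tolist(),
            "mode_types": self.mode_types,
            "temperature_K": self.temperature_K,
            "af_axes": self.af_axes.tolist(),
            "inertia_af": None if self.inertia_af is None else self.inertia_af.tolist(),
            "mode_frequencies": self.mode_frequencies.tolist(),
            "noise_cov": None if self.noise_cov is None else np.asarray(self.noise_cov).tolist(),
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SFBParameters":
        return cls(
            omega_io=np.array(data["omega_io"]),
            omega_int=np.array(data["omega_int"]),
            mode_types=list(data["mode_types"]),
            temperature_K=float(data["temperature_K"]),
            af_axes=np.array(data["af_axes"]),
            inertia_af=None if data.get("inertia_af") is None else np.array(data["inertia_af"]),
            mode_frequencies=np.array(data.get("mode_frequencies", [])),
            noise_cov=None if data.get("noise_cov") is None else np.array(data["noise_cov"]),
            metadata=data.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "SFBParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _angular_frame(structure: MolecularStructure, friction: FrictionTensor,
                   temperature_K: float):
    """AF axes, active angular axes and diffusion information.

    Nonlinear: principal axes of the rotational diffusion tensor, 3 active axes.
    Linear: AF z along the molecular axis (the null direction of Xi_RR), only
    the two perpendicular axes are active.
    """
    if not structure.is_linear():
        diff = diffusion_tensor(friction.xi_rr, temperature_K)
        return diff.axes, 3, diff
    vals, vecs = np.linalg.eigh(friction.xi_rr)  # ascending; first = molecular axis
    axes = np.column_stack([vecs[:, 1], vecs[:, 2], vecs[:, 0]])
    for col in range(2):
        pivot = int(np.argmax(np.abs(axes[:, col])))
        if axes[pivot, col] < 0:
            axes[:, col] = -axes[:, col]
    axes[:, 2] = np.cross(axes[:, 0], axes[:, 1])
    return axes, 2, None


def build_sfb(structure: MolecularStructure, hessian: HessianMatrix | None,
              friction: FrictionTensor, temperature_K: float,
              zero_ri_coupling: bool = False) -> SFBParameters:
    """Assemble SFBParameters from the reference structure, Hessian and friction.

    The internal q/p pairs stream antisymmetrically at the normal-mode rates;
    dissipation enters the momentum block through the friction blocks mapped to
    mode coordinates and, for the angular-momentum block, through
    I^(-1/2) Xi_RR I^(-1/2) in the attached frame. ``zero_ri_coupling``
    suppresses the internal-rotational friction coupling (diagnostics only).
    """
    modes = internal_modes(hessian, structure)
    k = modes.n_modes
    if friction.n_internal != k:
        raise ValueError(
            f"friction tensor has {friction.n_internal} internal modes, Hessian gives {k}"
        )
    axes, n_ang, diff = _angular_frame(structure, friction, temperature_K)
    if not (structure.rigid or hessian is None):
        counts = mode_count(structure.n_atoms, linear=structure.is_linear())
        if k != counts.n_coordinates:
            raise ValueError(f"found {k} internal modes, expected {counts.n_coordinates}")
    n_total = 2 * k + n_ang

    inertia_af = axes.T @ structure.inertia_tensor() @ axes
    sub = np.ix_(range(n_ang), range(n_ang))
    inertia_sub = inertia_af[sub]
    i_inv_sqrt = np.linalg.inv(np.real(sqrtm(inertia_sub)))

    xi_rr_af = (axes.T @ friction.xi_rr @ axes)[sub]
    xi_ri_af = (axes.T @ friction.xi_ri)[:n_ang, :]
    if zero_ri_coupling:
        xi_ri_af = np.zeros_like(xi_ri_af)

    omega_io = np.zeros((n_total, n_total))
    sl_q = slice(0, k)
    sl_p = slice(k, 2 * k)
    sl_l = slice(2 * k, n_total)
    w = np.diag(modes.frequencies)
    omega_io[sl_q, sl_p] = -w
    omega_io[sl_p, sl_q] = w
    omega_io[sl_p, sl_p] = friction.xi_ii
    omega_io[sl_p, sl_l] = xi_ri_af.T @ i_inv_sqrt
    omega_io[sl_l, sl_p] = i_inv_sqrt @ xi_ri_af
    omega_io[sl_l, sl_l] = i_inv_sqrt @ xi_rr_af @ i_inv_sqrt

    omega_int = np.zeros((n_total, 3))
    omega_int[sl_l, :n_ang] = np.sqrt(K_B * temperature_K) * i_inv_sqrt

    return SFBParameters(
        omega_io=omega_io,
        omega_int=omega_int,
        mode_types=["q"] * k + ["p"] * k + ["L"] * n_ang,
        temperature_K=temperature_K,
        af_axes=axes,
        inertia_af=inertia_af,
        diffusion=diff,
        mode_frequencies=modes.frequencies,
        metadata={
            "n_atoms": structure.n_atoms,
            "linear": structure.is_linear(),
            "reff_A": friction.reff_A,
            "eta": friction.eta,
            "boundary": friction.boundary,
            "zero_ri_coupling": zero_ri_coupling,
        },
    )


def stationarity_residual(params: SFBParameters, nu_max: int = 4) -> float:
    """Relative residual of the discretized operator applied to equilibrium.

    Builds the rank-0 block of the operator (the orientational ground state),
    applies it to the zero-excitation basis vector and returns
    ``norm(Gamma e0) / norm(Gamma)``; by construction this is ~0 unless the
    fluctuation-dissipation scaling of the parameters is broken (e.g. through a
    mismatched ``noise_cov``).
    """
    from .spectral_solver import build_operator  # local import avoids a cycle

    op = build_operator(params, nu_max=nu_max, L=0)
    gamma = op.gamma
    e0 = np.zeros(gamma.shape[0])
    e0[op.index_of(0, (0,) * params.N)] = 1.0
    residual = float(np.linalg.norm(gamma @ e0))
    norm = float(np.abs(gamma).max()) if gamma.nnz else 1.0
    return residual / max(norm, 1e-300)
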