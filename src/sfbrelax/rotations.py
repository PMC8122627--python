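"""Rank-2 Wigner rotation algebra, ZYZ Euler angles and body-frame generators.

Conventions (fixed once, used everywhere): active ZYZ rotations,
``D^L_{k,m}(alpha, beta, gamma) = exp(-i k alpha) d^L_{k,m}(beta) exp(-i m gamma)``,
with the reduced matrix in the Brink-Satchler phase convention, so that
``d^2_{0,0}(pi/2) = -1/2``, ``d^2_{+-1,0}(pi/2) = 0`` and
``d^2_{+-2,0}(pi/2) = sqrt(3/8)``.

Indices of rank-2 blocks run m = -2..2 (array index m + 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "EulerAngles",
    "WignerBlock",
    "reduced_d2",
    "wigner_d",
    "wigner_D2",
    "body_angular_momentum",
    "probe_frame_angles",
    "compose",
]


@dataclass(frozen=True)
class EulerAngles:
    """Active ZYZ Euler angles in radians."""

    alpha: float
    beta: float
    gamma: float

    def canonical(self) -> "EulerAngles":
        """Equivalent angles with beta in [0, pi] and alpha, gamma in [0, 2pi)."""
        return EulerAngles(*Rotation.from_matrix(self.to_matrix()).as_euler("ZYZ"))

    def to_matrix(self) -> np.ndarray:
        return Rotation.from_euler("ZYZ", [self.alpha, self.beta, self.gamma]).as_matrix()

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "EulerAngles":
        a, b, g = Rotation.from_matrix(matrix).as_euler("ZYZ")
        return cls(a, b, g)


def compose(first: EulerAngles, second: EulerAngles) -> EulerAngles:
    """Euler angles of the composed rotation R(first) @ R(second)."""
    return EulerAngles.from_matrix(first.to_matrix() @ second.to_matrix())


def wigner_d(L: int, beta: float) -> np.ndarray:
    """Reduced Wigner matrix d^L_{k,m}(beta) via the explicit factorial sum.

    Rows/columns are ordered k, m = -L..L. This is the slow reference route;
    rank-2 callers should prefer :func:`reduced_d2`.
    """
    if L < 0 or L != int(L):
        raise ValueError("L must be a nonnegative integer")
    size = 2 * L + 1
    out = np.zeros((size, size))
    c, s = np.cos(beta / 2.0), np.sin(beta / 2.0)
    for ki, k in enumerate(range(-L, L + 1)):
        for mi, m in enumerate(range(-L, L + 1)):
            pref = np.sqrt(
                factorial(L + k) * factorial(L - k) * factorial(L + m) * factorial(L - m)
            )
            total = 0.0
            for t in range(max(0, m - k), min(L - k, L + m) + 1):
                num = (-1.0) ** (k - m + t)
                den = (
                    factorial(L + m - t)
                    * factorial(L - k - t)
                    * factorial(t)
                    * factorial(t + k - m)
                )
                total += num / den * c ** (2 * L + m - k - 2 * t) * s ** (k - m + 2 * t)
            out[ki, mi] = pref * total
    return out


def reduced_d2(beta) -> np.ndarray:
    """Rank-2 reduced Wigner matrix d^2_{k,m}(beta), vectorized over beta.

    Returns shape (..., 5, 5) with both indices ordered -2..2.
    """
    beta = np.asarray(beta, dtype=float)
    c = np.cos(beta)
    s = np.sin(beta)
    d = np.zeros(beta.shape + (5, 5))

    def put(k, m, val):
        # d_{k,m} plus the symmetry partners d_{m,k} = (-1)^{k-m} d_{k,m}
        # and d_{-m,-k} = d_{k,m}.
        phase = (-1.0) ** (k - m)
        d[..., k + 2, m + 2] = val
        d[..., m + 2, k + 2] = phase * val
        d[..., -m + 2, -k + 2] = val
        d[..., -k + 2, -m + 2] = phase * val

    put(2, 2, ((1 + c) / 2) ** 2)
    put(2, 1, -(1 + c) * s / 2)
    put(2, 0, np.sqrt(3.0 / 8.0) * s**2)
    put(2, -1, -(1 - c) * s / 2)
    put(2, -2, ((1 - c) / 2) ** 2)
    put(1, 1, (1 + c) * (2 * c - 1) / 2)
    put(1, 0, -np.sqrt(3.0 / 2.0) * s * c)
    put(1, -1, (1 - c) * (2 * c + 1) / 2)
    put(0, 0, (3 * c**2 - 1) / 2)
    return d


@dataclass(frozen=True)
class WignerBlock:
    """A (2L+1)x(2L+1) block of Wigner rotation matrix elements D^L_{k,m}."""

    L: int
    matrix: np.ndarray

    def __post_init__(self):
        size = 2 * self.L + 1
        if self.matrix.shape != (size, size):
            raise ValueError("Wigner block has wrong shape for its rank")


def wigner_D2(omega: EulerAngles) -> WignerBlock:
    """Full rank-2 rotation matrix D^2_{k,m}(alpha, beta, gamma)."""
    m = np.arange(-2, 3)
    phase_k = np.exp(-1j * m * omega.alpha)
    phase_m = np.exp(-1j * m * omega.gamma)
    matrix = phase_k[:, None] * reduced_d2(omega.beta) * phase_m[None, :]
    return WignerBlock(L=2, matrix=matrix)


def body_angular_momentum(L: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Body-frame angular-momentum component matrices (M_1, M_2, M_3) of rank L.

    They act on the body index m of D^L_{k,m}, are Hermitian, and obey the
    anomalous commutation relation [M_1, M_2] = -i M_3 (and cyclic), with
    M_1^2 + M_2^2 + M_3^2 = L(L+1).
    """
    if L < 0 or L != int(L):
        raise ValueError("L must be a nonnegative integer")
    m = np.arange(-L, L + 1, dtype=float)
    jz = np.diag(m)
    raise_amp = np.sqrt(L * (L + 1) - m[:-1] * (m[:-1] + 1))
    jplus = np.zeros((2 * L + 1, 2 * L + 1), dtype=complex)
    jplus[np.arange(1, 2 * L + 1), np.arange(2 * L)] = raise_amp
    j1 = (jplus + jplus.conj().T) / 2
    j2 = (jplus - jplus.conj().T) / (2j)
    # flipping the sign of the 2-component converts the standard commutation
    # [J1, J2] = +i J3 into the body-fixed (anomalous) one
    return j1, -j2, jz.astype(complex)


def probe_frame_angles(structure, probe, af_axes: np.ndarray) -> EulerAngles:
    """Euler angles rotating the attached frame into a C->H dipolar frame.

    ``af_axes`` columns are the attached-frame axes expressed in the structure's
    coordinate frame (as produced by the diffusion-tensor principal axes). The
    returned gamma is a gauge choice and set to 0; a bond along the AF z-axis
    returns (0, 0, 0).
    """
    h_index = probe.h_indices[0] if hasattr(probe, "h_indices") else probe[1]
    c_index = probe.c_index if hasattr(probe, "c_index") else probe[0]
    bond = structure.positions[h_index] - structure.positions[c_index]
    norm = np.linalg.norm(bond)
    if norm < 1e-12:
        raise ValueError("zero-length C-H vector")
    u = af_axes.T @ (bond / norm)  # bond direction in AF coordinates
    beta = float(np.arccos(np.clip(u[2], -1.0, 1.0)))
    alpha = 0.0 if abs(u[2]) > 1.0 - 1e-12 else float(np.arctan2(u[1], u[0]))
    return EulerAngles(alpha, beta, 0.0)
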