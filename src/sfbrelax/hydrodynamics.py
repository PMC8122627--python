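"""Bead-model friction and rotational diffusion tensors at the reference structure.

The default hydrodynamic model is free-draining (non-interacting beads), with
the per-bead translational friction set by the Stokes law and the effective
atomic radius Reff; an optional Rotne-Prager pairwise correction is available
behind a flag. Rotational quantities are referenced to the friction-weighted
centroid (the center of diffusion for equal beads).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ANGSTROM, K_B
from .molecule_io import MolecularStructure

__all__ = [
    "FrictionTensor",
    "DiffusionTensor",
    "bead_friction",
    "friction_tensor",
    "diffusion_tensor",
]

_BOUNDARY_FACTOR = {"stick": 6.0, "slip": 4.0}


def bead_friction(reff_A: float, eta: float, bc: str = "stick") -> float:
    """Per-bead translational friction (kg/s): C pi eta Reff, C = 6 (stick) / 4 (slip)."""
    if reff_A <= 0 or eta <= 0:
        raise ValueError("Reff and viscosity must be positive")
    try:
        factor = _BOUNDARY_FACTOR[bc]
    except KeyError:
        raise ValueError(f"boundary condition must be 'stick' or 'slip', got {bc!r}") from None
    return factor * np.pi * eta * reff_A * ANGSTROM


@dataclass
class FrictionTensor:
    """Generalized friction blocks at the reference structure (SI units).

    xi_rr is the 3x3 rotational block (J s), xi_ii the internal-mode block
    (1/s, mass-weighted mode velocities), xi_ri the 3 x n_modes coupling block.
    """

    xi_rr: np.ndarray
    xi_ii: np.ndarray
    xi_ri: np.ndarray
    center_A: np.ndarray
    boundary: str = "stick"
    reff_A: float = 0.0
    eta: float = 0.0
    metadata: dict = field(default_factory=dict)

    @property
    def n_internal(self) -> int:
        return self.xi_ii.shape[0]

    def assembled(self) -> np.ndarray:
        """Full symmetric (3 + n_modes) matrix [[RR, RI], [IR, II]]."""
        return np.block([[self.xi_rr, self.xi_ri], [self.xi_ri.T, self.xi_ii]])


def _bead_selection(structure: MolecularStructure, selection: str) -> np.ndarray:
    if selection == "all":
        return np.ones(structure.n_atoms, dtype=bool)
    if selection == "heavy":
        mask = np.array([el not in ("H", "D") for el in structure.elements])
        if not mask.any():
            raise ValueError("heavy-atom bead selection removed every bead")
        return mask
    raise ValueError(f"bead_selection must be 'all' or 'heavy', got {selection!r}")


def _rotne_prager_friction(r_m: np.ndarray, zeta: float, radius_m: float) -> np.ndarray:
    """Invert the Rotne-Prager-Yamakawa mobility for identical beads -> 3n x 3n friction."""
    n = r_m.shape[0]
    mob = np.zeros((3 * n, 3 * n))
    eye = np.eye(3)
    for i in range(n):
        mob[3 * i:3 * i + 3, 3 * i:3 * i + 3] = eye / zeta
        for j in range(i + 1, n):
            dr = r_m[i] - r_m[j]
            dist = np.linalg.norm(dr)
            u = np.outer(dr, dr) / dist**2
            if dist >= 2 * radius_m:
                a2 = radius_m**2 / dist**2
                block = ((1 + 2 * a2 / 3) * eye + (1 - 2 * a2) * u) / (
                    8 * np.pi * (zeta / (6 * np.pi * radius_m)) * dist
                )
            else:  # overlapping beads, regularized RPY form
                block = (
                    (1 - 9 * dist / (32 * radius_m)) * eye + 3 * dist / (32 * radius_m) * u
                ) / zeta
            mob[3 * i:3 * i + 3, 3 * j:3 * j + 3] = block
            mob[3 * j:3 * j + 3, 3 * i:3 * i + 3] = block
    return np.linalg.inv(mob)


def friction_tensor(
    structure: MolecularStructure,
    mode_fields: np.ndarray | None,
    reff_A: float,
    eta: float,
    bc: str = "stick",
    bead_selection: str = "all",
    hydrodynamic_interaction: str = "none",
) -> FrictionTensor:
    """Assemble the generalized friction tensor Xi = B^T Z B.

    ``mode_fields`` holds the Cartesian velocity field of each internal mode per
    unit (mass-weighted) mode velocity, shape (n_modes, n_atoms, 3) in 1/sqrt(kg);
    pass None or an empty array for a rigid body. B stacks the rotational lever
    arms about the friction-weighted centroid with those fields; Z is the
    per-bead friction (block-diagonal for the free-draining default).
    """
    if hydrodynamic_interaction not in ("none", "rotne_prager"):
        raise ValueError("hydrodynamic_interaction must be 'none' or 'rotne_prager'")
    zeta = bead_friction(reff_A, eta, bc)
    mask = _bead_selection(structure, bead_selection)
    zetas = np.where(mask, zeta, 0.0)
    center = zetas @ structure.positions / zetas.sum()
    r = (structure.positions - center) * ANGSTROM

    if mode_fields is None:
        mode_fields = np.zeros((0, structure.n_atoms, 3))
    mode_fields = np.asarray(mode_fields, dtype=float)
    n_modes = mode_fields.shape[0]
    if n_modes and mode_fields.shape[1:] != (structure.n_atoms, 3):
        raise ValueError("mode_fields must have shape (n_modes, n_atoms, 3)")

    # rotational lever fields: v_a = e_p x r_a
    lever = np.zeros((3, structure.n_atoms, 3))
    for p in range(3):
        axis = np.zeros(3)
        axis[p] = 1.0
        lever[p] = np.cross(np.broadcast_to(axis, r.shape), r)

    if hydrodynamic_interaction == "none":
        xi_rr = np.einsum("a,pai,qai->pq", zetas, lever, lever)
        xi_ri = np.einsum("a,pai,kai->pk", zetas, lever, mode_fields)
        xi_ii = np.einsum("a,kai,lai->kl", zetas, mode_fields, mode_fields)
    else:
        idx = np.where(mask)[0]
        z_full = _rotne_prager_friction(r[idx], zeta, reff_A * ANGSTROM)
        b_rot = lever[:, idx, :].reshape(3, -1)
        b_int = mode_fields[:, idx, :].reshape(n_modes, -1) if n_modes else np.zeros((0, 3 * len(idx)))
        xi_rr = b_rot @ z_full @ b_rot.T
        xi_ri = b_rot @ z_full @ b_int.T
        xi_ii = b_int @ z_full @ b_int.T

    if n_modes:
        cond = np.linalg.cond(xi_ii)
        if not np.isfinite(cond):
            bad = int(np.argmin(np.linalg.eigvalsh(xi_ii)))
            raise ValueError(f"rank-deficient internal friction block (mode {bad})")
    return FrictionTensor(
        xi_rr=xi_rr,
        xi_ii=xi_ii,
        xi_ri=xi_ri,
        center_A=center,
        boundary=bc,
        reff_A=reff_A,
        eta=eta,
        metadata={
            "bead_selection": bead_selection,
            "hydrodynamic_interaction": hydrodynamic_interaction,
        },
    )


@dataclass
class DiffusionTensor:
    """Rotational diffusion tensor D = k_B T Xi_RR^-1 with principal decomposition."""

    tensor: np.ndarray  # 3x3, 1/s
    principal_values: np.ndarray  # ascending D1 <= D2 <= D3
    axes: np.ndarray  # columns = principal axes, right-handed

    @property
    def isotropic(self) -> float:
        return float(self.principal_values.mean())

    @property
    def tau_c(self) -> float:
        """Isotropic-equivalent tumbling time 1/(6 D_iso)."""
        return 1.0 / (6.0 * self.isotropic)


def diffusion_tensor(xi_rr: np.ndarray, temperature_K: float) -> DiffusionTensor:
    """D = k_B T Xi_RR^-1 with deterministic principal axes.

    Axis sign is fixed by making each axis' largest-magnitude component
    positive; the third axis is rebuilt as a cross product so the frame is
    always right-handed.
    """
    xi_rr = np.asarray(xi_rr, dtype=float)
    eigvals = np.linalg.eigvalsh(xi_rr)
    if eigvals[0] <= 0 or eigvals[0] < 1e-12 * eigvals[-1]:
        raise ValueError("singular rotational friction block (collinear beads?)")
    d = K_B * temperature_K * np.linalg.inv(xi_rr)
    vals, vecs = np.linalg.eigh(d)  # ascending
    for col in range(2):
        pivot = int(np.argmax(np.abs(vecs[:, col])))
        if vecs[pivot, col] < 0:
            vecs[:, col] = -vecs[:, col]
    vecs[:, 2] = np.cross(vecs[:, 0], vecs[:, 1])
    return DiffusionTensor(tensor=d, principal_values=vals, axes=vecs)
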