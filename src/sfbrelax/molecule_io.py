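"""Structure and Hessian ingestion, mode counting, minimum validation and fixtures.

Structures come from PDB files (ATOM/HETATM records only, first altloc wins);
Hessians from plain-text dense matrices or upper-triangle ``i j value`` triples.
The fixture generator produces small bead systems with positive-semidefinite
Hessians so every downstream stage can be exercised without external input.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .constants import ANGSTROM, ATOMIC_MASS, HESSIAN_UNITS, element_mass

__all__ = [
    "MolecularStructure",
    "HessianMatrix",
    "ExperimentDescriptor",
    "Probe",
    "ModeCount",
    "MinimumReport",
    "read_pdb",
    "write_pdb",
    "mode_count",
    "read_hessian",
    "validate_minimum",
    "make_fixture",
]

#: relative tolerance used to classify projected rigid-body eigenvalues as zero
ZERO_MODE_RTOL = 1e-8
#: relative threshold for the linearity test on inertia eigenvalues
LINEARITY_RTOL = 1e-8


@dataclass(frozen=True)
class Probe:
    """A 13C relaxation probe: one carbon and its attached proton(s) (0-based indices)."""

    c_index: int
    h_indices: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "h_indices", tuple(self.h_indices))
        if len(self.h_indices) not in (1, 2):
            raise ValueError("a probe carries one (CH) or two (CH2) protons")

    @property
    def probe_type(self) -> str:
        return "CH" if len(self.h_indices) == 1 else "CH2"


@dataclass
class MolecularStructure:
    """Atoms of a reference structure: identities, masses (u) and positions (Angstrom)."""

    atom_ids: list[int]
    elements: list[str]
    masses: np.ndarray  # (n,) u
    positions: np.ndarray  # (n, 3) Angstrom
    atom_names: list[str] = field(default_factory=list)
    probes: list[Probe] = field(default_factory=list)
    rigid: bool = False

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.n_atoms < 2:
            raise ValueError("a structure needs at least 2 atoms")
        if self.positions.shape != (self.n_atoms, 3):
            raise ValueError("positions must have shape (n, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        if not self.atom_names:
            # unique names: PDB readers collapse duplicate names within a residue
            self.atom_names = [f"{el}{i + 1}" for i, el in enumerate(self.elements)]
        for probe in self.probes:
            self.validate_probe(probe)

    @property
    def n_atoms(self) -> int:
        return len(self.masses)

    @property
    def masses_kg(self) -> np.ndarray:
        return self.masses * ATOMIC_MASS

    @property
    def positions_m(self) -> np.ndarray:
        return self.positions * ANGSTROM

    def center_of_mass(self) -> np.ndarray:
        """Mass-weighted centroid in Angstrom."""
        return self.masses @ self.positions / self.masses.sum()

    def inertia_tensor(self) -> np.ndarray:
        """Inertia tensor about the center of mass, kg m^2."""
        r = (self.positions - self.center_of_mass()) * ANGSTROM
        m = self.masses_kg
        r2 = np.einsum("ai,ai->a", r, r)
        return np.einsum("a,a,ij->ij", m, r2, np.eye(3)) - np.einsum("a,ai,aj->ij", m, r, r)

    def is_linear(self, rtol: float = LINEARITY_RTOL) -> bool:
        eig = np.linalg.eigvalsh(self.inertia_tensor())
        return bool(eig[0] < rtol * max(eig[-1], 1e-300))

    def validate_probe(self, probe: Probe) -> None:
        n = self.n_atoms
        for idx in (probe.c_index, *probe.h_indices):
            if not 0 <= idx < n:
                raise ValueError(f"probe references missing atom index {idx}")
        for h in probe.h_indices:
            d = float(np.linalg.norm(self.positions[probe.c_index] - self.positions[h]))
            if not 0.8 <= d <= 1.5:
                raise ValueError(
                    f"probe C-H distance {d:.3f} A outside the 0.8-1.5 A validation window"
                )

    def add_probe(self, c_index: int, h_indices) -> Probe:
        probe = Probe(c_index, tuple(h_indices))
        self.validate_probe(probe)
        self.probes.append(probe)
        return probe


@dataclass
class HessianMatrix:
    """Cartesian second-derivative matrix at the reference structure, stored in J/m^2."""

    matrix: np.ndarray  # (3n, 3n), symmetrized, SI
    max_asymmetry: float = 0.0
    units: str = "J_m2"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("Hessian must be square")
        if self.matrix.shape[0] % 3:
            raise ValueError("Hessian dimension must be a multiple of 3")

    @property
    def n_atoms(self) -> int:
        return self.matrix.shape[0] // 3


@dataclass
class ExperimentDescriptor:
    """Experimental conditions and model settings for one relaxation data set."""

    temperature_K: float
    viscosity_Pa_s: float
    spectrometer_MHz: float
    boundary: str = "stick"
    reff_A: float | str = 2.0
    probe_type: str = "CH"

    def __post_init__(self):
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if self.viscosity_Pa_s <= 0:
            raise ValueError("viscosity must be positive")
        if self.spectrometer_MHz <= 0:
            raise ValueError("spectrometer frequency must be positive")
        if self.boundary not in ("stick", "slip"):
            raise ValueError("boundary condition must be 'stick' or 'slip'")
        if self.reff_A != "fit" and float(self.reff_A) <= 0:
            raise ValueError("Reff must be positive or 'fit'")
        if self.probe_type not in ("CH", "CH2"):
            raise ValueError("probe_type must be 'CH' or 'CH2'")


@dataclass(frozen=True)
class ModeCount:
    """Breakdown of the harmonic-mode count N for an n-atom (non)linear molecule."""

    total: int
    n_coordinates: int
    n_momenta: int
    n_angular: int


def mode_count(n: int, linear: bool = False) -> ModeCount:
    """Number of dimensionless modes: N = 6n-9 (nonlinear), with its breakdown.

    Linear geometries use 3n-5 internal coordinates and 2 angular-momentum
    components instead.
    """
    if n < 2:
        raise ValueError("mode counting requires n >= 2")
    if linear:
        n_int = 3 * n - 5
        n_ang = 2
    else:
        n_int = max(3 * n - 6, 0)
        n_ang = 3
    return ModeCount(2 * n_int + n_ang, n_int, n_int, n_ang)


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _infer_element(atom_name: str) -> str:
    name = atom_name.strip()
    if len(name) >= 2 and name[:2].upper() in ("CL", "BR", "NA", "MG", "ZN", "FE", "CA"):
        return name[:2].upper()
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer an element from atom name {atom_name!r}")


def read_pdb(path) -> MolecularStructure:
    """Read ATOM/HETATM records into a MolecularStructure (file order preserved).

    The element column is used when present, falling back to inference from the
    atom name; an unresolvable element raises ValueError naming the record.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        model = parser.get_structure("mol", str(path))
    atom_ids, elements, masses, positions, names = [], [], [], [], []
    for atom in model.get_atoms():
        if atom.get_altloc() not in (" ", "", "A"):
            continue  # first altloc wins
        element = (atom.element or "").strip()
        if not element or not element.isalpha():
            element = _infer_element(atom.get_name())
        try:
            mass = element_mass(element)
        except KeyError:
            raise ValueError(
                f"unresolvable element {element!r} for atom serial "
                f"{atom.get_serial_number()} ({atom.get_name()!r})"
            ) from None
        atom_ids.append(int(atom.get_serial_number()))
        elements.append(element.upper())
        names.append(atom.get_name())
        masses.append(mass)
        positions.append(atom.get_coord().astype(float))
    if len(masses) < 2:
        raise ValueError(f"{path}: fewer than 2 atoms found")
    return MolecularStructure(
        atom_ids=atom_ids,
        elements=elements,
        masses=np.array(masses),
        positions=np.array(positions),
        atom_names=names,
    )


def write_pdb(structure: MolecularStructure, path) -> None:
    """Write a minimal single-model PDB file for a structure."""
    buf = io.StringIO()
    for i in range(structure.n_atoms):
        x, y, z = structure.positions[i]
        name = structure.atom_names[i][:4]
        element = structure.elements[i][:2].rjust(2)
        buf.write(
            f"HETATM{structure.atom_ids[i]:5d} {name:<4s} LIG A   1    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element}\n"
        )
    buf.write("END\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Hessian ingestion
# ---------------------------------------------------------------------------

def read_hessian(path, n: int, units: str = "kcal_mol_A2",
                 asym_rtol: float = 1e-6) -> HessianMatrix:
    """Read a 3n x 3n Hessian from a dense matrix or ``i j value`` triples file.

    The matrix is symmetrized as (H + H^T)/2; the maximum relative asymmetry is
    recorded and a warning is emitted when it exceeds ``asym_rtol``. Values are
    converted from ``units`` (default Tinker-style kcal/mol/A^2) to J/m^2.
    """
    if units not in HESSIAN_UNITS:
        raise ValueError(f"unknown Hessian units {units!r}")
    dim = 3 * n
    try:
        raw = np.loadtxt(str(path), dtype=float, delimiter=None, comments="#")
    except ValueError:
        try:
            raw = np.loadtxt(str(path), dtype=float, delimiter=",", comments="#")
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric token in Hessian file: {exc}") from None
    raw = np.atleast_2d(raw)
    if raw.shape == (dim, dim):
        matrix = raw
    elif raw.shape[1] == 3 and dim != 3:
        # upper-triangle triples "i j value", 1-based indices
        matrix = np.zeros((dim, dim))
        ii = raw[:, 0].astype(int) - 1
        jj = raw[:, 1].astype(int) - 1
        if ii.min() < 0 or ii.max() >= dim or jj.min() < 0 or jj.max() >= dim:
            raise ValueError(f"{path}: triple indices outside 1..{dim}")
        matrix[ii, jj] = raw[:, 2]
        matrix[jj, ii] = raw[:, 2]
    else:
        raise ValueError(
            f"{path}: expected a {dim}x{dim} matrix or 'i j value' triples, got shape {raw.shape}"
        )
    scale = max(float(np.abs(matrix).max()), 1e-300)
    asym = float(np.abs(matrix - matrix.T).max()) / scale
    if asym > asym_rtol:
        warnings.warn(f"Hessian asymmetry {asym:.2e} exceeds {asym_rtol:.0e}; symmetrizing")
    sym = 0.5 * (matrix + matrix.T) * HESSIAN_UNITS[units]
    return HessianMatrix(matrix=sym, max_asymmetry=asym, units="J_m2")


# ---------------------------------------------------------------------------
# Minimum validation
# ---------------------------------------------------------------------------

def rigid_body_basis(structure: MolecularStructure) -> np.ndarray:
    """Orthonormal mass-weighted translation + rotation vectors, shape (3n, r).

    r is 6 for nonlinear and 5 for linear geometries (detected by rank).
    """
    n = structure.n_atoms
    m = structure.masses_kg
    r = (structure.positions - structure.center_of_mass()) * ANGSTROM
    vecs = []
    sqrtm = np.sqrt(m)
    for p in range(3):
        t = np.zeros((n, 3))
        t[:, p] = sqrtm
        vecs.append(t.ravel())
    for p in range(3):
        axis = np.zeros(3)
        axis[p] = 1.0
        rot = np.cross(np.broadcast_to(axis, (n, 3)), r) * sqrtm[:, None]
        vecs.append(rot.ravel())
    basis = np.array(vecs).T
    norms = np.linalg.norm(basis, axis=0)
    basis = basis[:, norms > 0] / norms[norms > 0]
    u, s, _ = np.linalg.svd(basis, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-8))
    return u[:, :rank]


@dataclass(frozen=True)
class MinimumReport:
    smallest_eigenvalue: float  # rad^2/s^2 (mass-weighted, projected)
    n_zero_modes: int
    n_rigid_expected: int
    is_minimum: bool
    degenerate: bool
    eigenvalues: np.ndarray


def validate_minimum(hessian: HessianMatrix, structure: MolecularStructure,
                     tol: float = 1e-6) -> MinimumReport:
    """Check that the Hessian describes a local minimum.

    Rigid-body motions are removed with mass-weighted Eckart projectors; the
    smallest remaining eigenvalue must exceed ``-tol`` times the largest one.
    More near-zero modes than rigid-body degrees of freedom raise a degeneracy
    warning (possible linear or disconnected geometry).
    """
    if hessian.n_atoms != structure.n_atoms:
        raise ValueError(
            f"Hessian is for {hessian.n_atoms} atoms, structure has {structure.n_atoms}"
        )
    sqrtm_inv = 1.0 / np.sqrt(np.repeat(structure.masses_kg, 3))
    hmw = hessian.matrix * np.outer(sqrtm_inv, sqrtm_inv)
    basis = rigid_body_basis(structure)
    proj = np.eye(hmw.shape[0]) - basis @ basis.T
    eig = np.linalg.eigvalsh(proj @ hmw @ proj)
    scale = max(float(np.abs(eig).max()), 1e-300)
    n_rigid = basis.shape[1]
    n_zero = int(np.sum(np.abs(eig) < tol * scale))
    smallest_internal = float(eig[np.abs(eig) >= tol * scale].min()) if n_zero < len(eig) else 0.0
    degenerate = n_zero > n_rigid
    if degenerate:
        warnings.warn(
            f"{n_zero} near-zero modes found, expected {n_rigid}: "
            "possible linear or disconnected geometry"
        )
    return MinimumReport(
        smallest_eigenvalue=smallest_internal,
        n_zero_modes=n_zero,
        n_rigid_expected=n_rigid,
        is_minimum=smallest_internal > -tol * scale,
        degenerate=degenerate,
        eigenvalues=eig,
    )


# ---------------------------------------------------------------------------
# Synthetic fixtures
# ---------------------------------------------------------------------------

def _rigid_rotor(seed, inertia=(1e-45, 1e-45, 1e-45), mass_u: float = 12.011):
    """Six point beads on the coordinate axes matching a requested inertia tensor."""
    i1, i2, i3 = (float(v) for v in inertia)
    m = mass_u * ATOMIC_MASS
    pos = []
    for p, (ia, ib, ic) in enumerate([(i1, i2, i3), (i2, i3, i1), (i3, i1, i2)]):
        a2 = (ib + ic - ia) / (4.0 * m)
        if a2 < -1e-12 * max(i1, i2, i3) / m:
            raise ValueError("requested inertia violates the triangle inequality")
        a = np.sqrt(max(a2, 0.0)) / ANGSTROM
        for sign in (1.0, -1.0):
            v = np.zeros(3)
            v[p] = sign * a
            pos.append(v)
    structure = MolecularStructure(
        atom_ids=list(range(1, 7)),
        elements=["C"] * 6,
        masses=np.full(6, mass_u),
        positions=np.array(pos),
        rigid=True,
    )
    return structure, None


def _bead_pair(seed, k: float = 5.0, d: float = 1.5, mass_u: float = 12.011):
    """Two beads joined by a harmonic bond of stiffness k (N/m) at separation d (A)."""
    positions = np.array([[0.0, 0.0, -d / 2], [0.0, 0.0, d / 2]])
    structure = MolecularStructure(
        atom_ids=[1, 2],
        elements=["C", "C"],
        masses=np.array([mass_u, mass_u]),
        positions=positions,
    )
    u = np.array([0.0, 0.0, 1.0])
    p = k * np.outer(u, u)
    hess = np.block([[p, -p], [-p, p]])
    return structure, HessianMatrix(matrix=hess, units="J_m2")


def _finite_difference_hessian(potential, x0: np.ndarray, h: float = 1e-5) -> np.ndarray:
    dim = x0.size
    hess = np.zeros((dim, dim))
    for i in range(dim):
        for j in range(i, dim):
            xpp = x0.copy(); xpp[i] += h; xpp[j] += h
            xpm = x0.copy(); xpm[i] += h; xpm[j] -= h
            xmp = x0.copy(); xmp[i] -= h; xmp[j] += h
            xmm = x0.copy(); xmm[i] -= h; xmm[j] -= h
            val = (potential(xpp) - potential(xpm) - potential(xmp) + potential(xmm)) / (4 * h * h)
            hess[i, j] = hess[j, i] = val
    return hess


def _tri_bead(seed, k_bond: float = 5.0, k_angle: float = 5e-19, d: float = 1.09,
              theta0_deg: float = 109.47, masses_u=(12.011, 12.011, 1.008)):
    """Bent three-bead molecule with two bonds (N/m) and an angle spring (J/rad^2).

    Bead 1 is the central atom; bead 2 (default a hydrogen) can serve as the
    proton of a CH probe on the central bead.
    """
    theta0 = np.deg2rad(theta0_deg)
    half = theta0 / 2
    positions = np.array([
        [0.0, 0.0, 0.0],
        [d * np.sin(half), 0.0, d * np.cos(half)],
        [-d * np.sin(half), 0.0, d * np.cos(half)],
    ])

    def potential(flat):  # coordinates in A, energy in J
        r = flat.reshape(3, 3)
        b1 = r[1] - r[0]
        b2 = r[2] - r[0]
        l1 = np.linalg.norm(b1)
        l2 = np.linalg.norm(b2)
        cosang = np.clip(b1 @ b2 / (l1 * l2), -1.0, 1.0)
        theta = np.arccos(cosang)
        return (0.5 * k_bond * ((l1 - d) * ANGSTROM) ** 2
                + 0.5 * k_bond * ((l2 - d) * ANGSTROM) ** 2
                + 0.5 * k_angle * (theta - theta0) ** 2)

    hess_per_a2 = _finite_difference_hessian(potential, positions.ravel())
    structure = MolecularStructure(
        atom_ids=[1, 2, 3],
        elements=["C", "C", "H"][: 3],
        masses=np.array(masses_u, dtype=float),
        positions=positions,
    )
    return structure, HessianMatrix(matrix=hess_per_a2 / ANGSTROM**2, units="J_m2")


def _random_psd(seed, n: int = 4, stiffness: float = 5.0, box: float = 2.0):
    """Random bead cluster with a PSD Hessian built as a projected A^T A form."""
    rng = np.random.default_rng(seed)
    if n < 3:
        raise ValueError("random_psd needs n >= 3")
    while True:
        positions = rng.uniform(-box, box, size=(n, 3))
        spread = np.linalg.svd(positions - positions.mean(axis=0), compute_uv=False)
        if spread[1] > 0.2 * box:  # reject near-collinear draws
            break
    masses = np.full(n, 12.011)
    structure = MolecularStructure(
        atom_ids=list(range(1, n + 1)),
        elements=["C"] * n,
        masses=masses,
        positions=positions,
    )
    a = rng.normal(size=(3 * n, 3 * n))
    hmw_unscaled = a.T @ a / (3 * n)
    basis = rigid_body_basis(structure)
    proj = np.eye(3 * n) - basis @ basis.T
    # scale so mode frequencies land near sqrt(stiffness/mass)
    mass_scale = masses.mean() * ATOMIC_MASS
    hmw = proj @ hmw_unscaled @ proj * stiffness / mass_scale
    sqrtm = np.sqrt(np.repeat(structure.masses_kg, 3))
    hess = hmw * np.outer(sqrtm, sqrtm)
    return structure, HessianMatrix(matrix=hess, units="J_m2")


_FIXTURES = {
    "rigid_rotor": _rigid_rotor,
    "bead_pair": _bead_pair,
    "tri_bead": _tri_bead,
    "random_psd": _random_psd,
}


def make_fixture(name: str, seed: int = 0, **params):
    """Build a named synthetic (structure, hessian) pair; deterministic per seed.

    Known names: ``rigid_rotor`` (hessian is None, structure flagged rigid),
    ``bead_pair``, ``tri_bead``, ``random_psd``.
    """
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}"
        ) from None
    return builder(seed, **params)
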