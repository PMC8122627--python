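"""13C T1/T2/NOE from orientational spectral densities, deviation statistics and Reff fitting.

Spectral densities arriving here are pure orientational quantities with the
(1/5)-normalization of :mod:`sfbrelax.spectral_solver`; this module applies the
interaction-frame weights, doubles the one-sided transform to the physical
J(omega) (rigid isotropic form (2/5) tau / (1 + omega^2 tau^2)) and evaluates
the standard 13C-1H dipolar relaxation expressions:

    1/T1 = (d^2/4) [J(wH-wC) + 3 J(wC) + 6 J(wH+wC)]
    1/T2 = (d^2/8) [4 J(0) + J(wH-wC) + 3 J(wC) + 6 J(wH+wC) + 6 J(wH)]
    NOE  = 1 + (gH/gC) (d^2/4) [6 J(wH+wC) - J(wH-wC)] T1

with d = (mu0/4pi) hbar gH gC / r_CH^3. CH2 probes add the dipolar rates of
the two protons, each with its own geometry (cross-correlation neglected).
An axial CSA contribution is available but disabled by default.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .constants import (
    ANGSTROM,
    GAMMA_C13,
    GAMMA_H1,
    H_BAR,
    MU0_OVER_4PI,
    larmor_frequencies,
)
from .hydrodynamics import friction_tensor
from .molecule_io import (
    HessianMatrix,
    MolecularStructure,
    Probe,
    make_fixture,
    read_hessian,
    read_pdb,
)
from .rotations import EulerAngles, probe_frame_angles, wigner_D2
from .sfb_model import build_sfb, internal_modes
from .spectral_solver import (
    SpectralDensitySet,
    build_operator,
    converged_j_matrix,
    j_matrix,
    mode_reduction,
)

__all__ = [
    "DipolarInteraction",
    "CSAInteraction",
    "RelaxationResult",
    "DeviationReport",
    "assemble_J",
    "relaxation_observables",
    "percentage_deviation",
    "deviation_summary",
    "fit_reff",
    "FitResult",
    "run_pipeline",
    "PipelineResult",
]

R_CH_DEFAULT_A = 1.09  # aliphatic C-H bond length; T1 scales as r^6, override in config

OBSERVABLES = ("T1", "T2", "NOE")


@dataclass(frozen=True)
class DipolarInteraction:
    """13C-1H dipolar coupling for one proton of a probe."""

    r_ch_A: float = R_CH_DEFAULT_A
    omega_AD: EulerAngles = EulerAngles(0.0, 0.0, 0.0)

    def __post_init__(self):
        if not 0.8 <= self.r_ch_A <= 1.5:
            raise ValueError("r_CH outside the 0.8-1.5 A validation window")

    @property
    def coupling_rad_s(self) -> float:
        """d = (mu0/4pi) hbar gammaC gammaH / r^3."""
        return MU0_OVER_4PI * H_BAR * GAMMA_C13 * GAMMA_H1 / (self.r_ch_A * ANGSTROM) ** 3


@dataclass(frozen=True)
class CSAInteraction:
    """Axial 13C chemical-shift anisotropy; disabled unless explicitly configured."""

    delta_sigma_ppm: float
    omega_AD: EulerAngles = EulerAngles(0.0, 0.0, 0.0)


@dataclass
class RelaxationResult:
    t1_ms: float
    t2_ms: float
    noe: float
    spectrometer_MHz: float
    probe_type: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.t1_ms <= 0 or self.t2_ms <= 0:
            raise ValueError("computed relaxation times must be positive")


def assemble_J(jset, omega_AD: EulerAngles, C: float = 1.0) -> np.ndarray:
    """Contract j_{m,m'}(omega) with the interaction-frame Wigner weights.

    ``jset`` is either a full (n_omega, 5, 5) matrix from
    :func:`sfbrelax.spectral_solver.j_matrix` or a SpectralDensitySet covering
    all 25 (m, m') pairs. Weights are D^2_{m,0}(Omega_AD); for
    Omega_AD = (0, pi/2, 0) only m in {0, +-2} survive with reduced-d values
    (-1/2 and sqrt(3/8)), and the rigid isotropic result is independent of
    Omega_AD. Returns complex J(omega) of length n_omega (no factor 2 yet).
    """
    if isinstance(jset, SpectralDensitySet):
        mat = np.empty((len(jset.omegas), 5, 5), dtype=complex)
        for m in range(-2, 3):
            for mp in range(-2, 3):
                mat[:, m + 2, mp + 2] = jset.get(0, 0, m, mp)
    else:
        mat = np.asarray(jset, dtype=complex)
        if mat.ndim == 2:
            mat = mat[None, :, :]
        if mat.shape[-2:] != (5, 5):
            raise ValueError("expected (n_omega, 5, 5) spectral-density values")
    weights = wigner_D2(omega_AD).matrix[:, 2]  # D^2_{m,0}, m = -2..2
    return C * np.einsum("m,wmn,n->w", np.conj(weights), mat, weights)


def dipolar_omegas(spectrometer_MHz: float) -> dict[str, float]:
    """The five angular frequencies entering the dipolar rates, rad/s."""
    wh, wc = larmor_frequencies(spectrometer_MHz)
    return {"zero": 0.0, "wc": wc, "wh_minus_wc": wh - wc, "wh": wh, "wh_plus_wc": wh + wc}


def relaxation_observables(
    j_funcs,
    spectrometer_MHz: float,
    probe_type: str | None = None,
    interactions: list[DipolarInteraction] | None = None,
    csa: CSAInteraction | None = None,
    csa_j_func=None,
) -> RelaxationResult:
    """Evaluate T1 (ms), T2 (ms) and the NOE from per-proton spectral densities.

    ``j_funcs`` maps each proton to a callable omega -> complex orientational
    J (already weighted by its Omega_AD, normalized so the rigid isotropic
    value at omega=0 is tau/5). Rates from several protons add.
    """
    n_protons = len(j_funcs)
    if probe_type is None:
        probe_type = "CH" if n_protons == 1 else "CH2"
    if {"CH": 1, "CH2": 2}[probe_type] != n_protons:
        raise ValueError(f"{probe_type} probe needs {'1' if probe_type == 'CH' else '2'} proton(s)")
    if interactions is None:
        interactions = [DipolarInteraction()] * n_protons
    freqs = dipolar_omegas(spectrometer_MHz)

    r1 = r2 = sigma = 0.0
    for jw, inter in zip(j_funcs, interactions):
        jd = {key: 2.0 * float(np.real(jw(w))) for key, w in freqs.items()}
        d2 = inter.coupling_rad_s**2
        r1 += (d2 / 4.0) * (jd["wh_minus_wc"] + 3 * jd["wc"] + 6 * jd["wh_plus_wc"])
        r2 += (d2 / 8.0) * (
            4 * jd["zero"] + jd["wh_minus_wc"] + 3 * jd["wc"]
            + 6 * jd["wh_plus_wc"] + 6 * jd["wh"]
        )
        sigma += (d2 / 4.0) * (6 * jd["wh_plus_wc"] - jd["wh_minus_wc"])

    if csa is not None:
        jc = csa_j_func if csa_j_func is not None else j_funcs[0]
        wc = freqs["wc"]
        c2 = (wc * csa.delta_sigma_ppm * 1e-6) ** 2 / 3.0
        jd0 = 2.0 * float(np.real(jc(0.0)))
        jdc = 2.0 * float(np.real(jc(wc)))
        r1 += c2 * jdc
        r2 += (c2 / 6.0) * (4 * jd0 + 3 * jdc)

    if r1 <= 0 or r2 <= 0:
        raise ArithmeticError("nonpositive relaxation rate; inconsistent spectral densities")
    return RelaxationResult(
        t1_ms=1000.0 / r1,
        t2_ms=1000.0 / r2,
        noe=1.0 + (GAMMA_H1 / GAMMA_C13) * sigma / r1,
        spectrometer_MHz=spectrometer_MHz,
        probe_type=probe_type,
    )


# ---------------------------------------------------------------------------
# Deviation statistics
# ---------------------------------------------------------------------------

def percentage_deviation(exp_value: float, calc_value: float) -> float:
    """e = 100 |calc - exp| / exp, rounded half-up to one decimal.

    Exact decimal arithmetic on the printed digits is used so that e.g.
    (440.0, 449.9) -> 2.3 rather than the float artifact 2.2499...9 -> 2.2.
    """
    if exp_value <= 0:
        raise ValueError("experimental value must be positive")
    e = 100 * abs(Decimal(str(calc_value)) - Decimal(str(exp_value))) / Decimal(str(exp_value))
    return float(e.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def _raw_percentage(exp_value: float, calc_value: float) -> float:
    return 100.0 * abs(calc_value - exp_value) / exp_value


@dataclass
class DeviationReport:
    """Per-observable percentage deviations with their means, maxima and Sum e^2."""

    entries: dict[str, list[float]]  # rounded per-entry e values
    mean: dict[str, float]
    max: dict[str, float]
    sum_squared: float  # from unrounded deviations; the Reff fitting objective


def deviation_summary(table: dict[str, list[tuple[float, float]]]) -> DeviationReport:
    """Aggregate (exp, calc) pairs per observable into a DeviationReport.

    ``table`` maps observable names (e.g. "T1") to lists of (exp, calc) pairs;
    empty lists are allowed but at least one pair must be present overall.
    """
    if not any(table.values()):
        raise ValueError("deviation summary needs at least one (exp, calc) pair")
    entries: dict[str, list[float]] = {}
    mean: dict[str, float] = {}
    mx: dict[str, float] = {}
    sum_sq = 0.0
    for obs, pairs in table.items():
        es = [percentage_deviation(exp, calc) for exp, calc in pairs]
        entries[obs] = es
        if es:
            mean[obs] = float(np.mean(es))
            mx[obs] = float(np.max(es))
        sum_sq += sum(_raw_percentage(exp, calc) ** 2 for exp, calc in pairs)
    return DeviationReport(entries=entries, mean=mean, max=mx, sum_squared=sum_sq)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    results: list[RelaxationResult]
    reff_A: float
    metadata: dict
    deviations: DeviationReport | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append({
                "probe": r.metadata.get("probe_label", ""),
                "probe_type": r.probe_type,
                "freq_MHz": r.spectrometer_MHz,
                "calc_T1_ms": r.t1_ms,
                "calc_T2_ms": r.t2_ms,
                "calc_NOE": r.noe,
            })
        return pd.DataFrame(rows)


def _resolve_probe(structure: MolecularStructure, spec) -> Probe:
    if isinstance(spec, Probe):
        return spec
    if isinstance(spec, dict):
        c = spec["c"]
        hs = spec["h"] if isinstance(spec["h"], (list, tuple)) else [spec["h"]]
    else:
        c, hs = spec[0], list(spec[1]) if isinstance(spec[1], (list, tuple)) else [spec[1]]
    serials = {sid: i for i, sid in enumerate(structure.atom_ids)}
    probe = Probe(serials[c], tuple(serials[h] for h in hs))
    structure.validate_probe(probe)
    return probe


def compute_observables(
    structure: MolecularStructure,
    hessian: HessianMatrix | None,
    probes: list[Probe],
    temperature_K: float,
    viscosity_Pa_s: float,
    reff_A: float,
    spectrometer_MHz,
    boundary: str = "stick",
    r_ch_A: float | None = None,
    nu_max: int = 4,
    adaptive: bool = False,
    max_modes: int | None = None,
    bead_selection: str = "all",
    hydrodynamic_interaction: str = "none",
    csa: CSAInteraction | None = None,
) -> tuple[list[RelaxationResult], dict]:
    """Run the full chain structure -> friction -> SFB -> j(omega) -> observables."""
    freqs_mhz = np.atleast_1d(np.asarray(spectrometer_MHz, dtype=float))
    modes = internal_modes(hessian, structure)
    friction = friction_tensor(
        structure, modes.fields, reff_A, viscosity_Pa_s, boundary,
        bead_selection=bead_selection, hydrodynamic_interaction=hydrodynamic_interaction,
    )
    params = build_sfb(structure, hessian, friction, temperature_K)
    retained_weight = 1.0
    if max_modes is not None and params.N > max_modes:
        report = mode_reduction(params, max_modes)
        params, retained_weight = report.params, report.retained_weight

    omega_set = sorted({w for mhz in freqs_mhz for w in dipolar_omegas(mhz).values()})
    omega_arr = np.array(omega_set)
    if adaptive:
        jmat, nu_used = converged_j_matrix(params, omega_arr, nu_start=max(2, nu_max - 2))
    else:
        jmat = j_matrix(build_operator(params, nu_max=nu_max), omega_arr)
        nu_used = nu_max
    lookup = {w: jmat[i] for i, w in enumerate(omega_set)}

    def make_j_func(omega_ad: EulerAngles):
        weighted = {w: complex(assemble_J(mat[None, :, :], omega_ad)[0])
                    for w, mat in lookup.items()}

        def jw(omega: float) -> complex:
            return weighted[min(weighted, key=lambda w: abs(w - omega))]

        return jw

    results = []
    for probe in probes:
        interactions, j_funcs = [], []
        for h in probe.h_indices:
            omega_ad = probe_frame_angles(structure, (probe.c_index, h), params.af_axes)
            interactions.append(
                DipolarInteraction(
                    r_ch_A=r_ch_A if r_ch_A is not None else R_CH_DEFAULT_A,
                    omega_AD=omega_ad,
                )
            )
            j_funcs.append(make_j_func(omega_ad))
        for mhz in freqs_mhz:
            res = relaxation_observables(
                j_funcs, float(mhz), probe_type=probe.probe_type,
                interactions=interactions, csa=csa,
            )
            res.metadata["probe_label"] = f"C{structure.atom_ids[probe.c_index]}"
            res.metadata["reff_A"] = reff_A
            results.append(res)
    meta = {
        "N": params.N,
        "nu_max_used": nu_used,
        "retained_weight": retained_weight,
        "temperature_K": temperature_K,
        "viscosity_Pa_s": viscosity_Pa_s,
        "boundary": boundary,
        "reff_A": reff_A,
        "af_axes": params.af_axes.tolist(),
        "diffusion_principal_s^-1":
            None if params.diffusion is None else params.diffusion.principal_values.tolist(),
    }
    return results, meta


@dataclass
class FitResult:
    reff_A: float
    objective: float
    trace: list[tuple[float, float]]  # (Reff, sum of squared percentage deviations)
    report: DeviationReport
    at_boundary: bool


def fit_reff(
    structure: MolecularStructure,
    hessian: HessianMatrix | None,
    probes: list[Probe],
    experiments: list[dict],
    bounds: tuple[float, float] = (1.0, 3.0),
    step: float = 0.1,
    **solver_kwargs,
) -> FitResult:
    """Grid-search Reff minimizing the sum of squared percentage deviations.

    ``experiments`` rows carry temperature_K, viscosity_Pa_s, freq_MHz,
    optional boundary, probe (index into ``probes``) and any of T1_ms, T2_ms,
    NOE. Ties break deterministically toward the smaller Reff; an optimum on
    the boundary of ``bounds`` is flagged.
    """
    rmin, rmax = bounds
    if not (rmin > 0 and rmin < rmax):
        raise ValueError("bounds must be positive with Rmin < Rmax")
    if not experiments:
        raise ValueError("experimental table is empty")
    grid = np.round(np.arange(rmin, rmax + step / 2, step), 10)
    trace = []
    best = None
    for reff in grid:
        table = _deviation_table(structure, hessian, probes, experiments, float(reff),
                                 **solver_kwargs)
        report = deviation_summary(table)
        sse = report.sum_squared
        trace.append((float(reff), sse))
        if np.isfinite(sse) and (best is None or sse < best[1]):
            best = (float(reff), sse, report)
    if best is None:
        raise ArithmeticError("objective non-finite at every grid point")
    reff, sse, report = best
    at_boundary = reff in (float(grid[0]), float(grid[-1]))
    if at_boundary:
        import warnings

        warnings.warn(f"optimal Reff {reff} lies on the search boundary {bounds}")
    return FitResult(reff_A=reff, objective=sse, trace=trace, report=report,
                     at_boundary=at_boundary)


def _deviation_table(structure, hessian, probes, experiments, reff_A, **solver_kwargs):
    """(exp, calc) pairs per observable for one Reff over all experiment rows."""
    by_condition: dict[tuple, list[int]] = {}
    for i, row in enumerate(experiments):
        key = (row["temperature_K"], row["viscosity_Pa_s"], row.get("boundary", "stick"))
        by_condition.setdefault(key, []).append(i)
    table = {obs: [] for obs in OBSERVABLES}
    for (temp, eta, bc), indices in by_condition.items():
        freqs = sorted({experiments[i]["freq_MHz"] for i in indices})
        probe_ids = sorted({experiments[i].get("probe", 0) for i in indices})
        results, _ = compute_observables(
            structure, hessian, [probes[p] for p in probe_ids], temp, eta, reff_A,
            freqs, boundary=bc, **solver_kwargs,
        )
        lookup = {}
        for res, probe_id in zip(results, np.repeat(probe_ids, len(freqs))):
            lookup[(probe_id, res.spectrometer_MHz)] = res
        for i in indices:
            row = experiments[i]
            res = lookup[(row.get("probe", 0), row["freq_MHz"])]
            for obs, attr in (("T1", "t1_ms"), ("T2", "t2_ms"), ("NOE", "noe")):
                key = {"T1": "T1_ms", "T2": "T2_ms", "NOE": "NOE"}[obs]
                if row.get(key) is not None and not pd.isna(row.get(key)):
                    table[obs].append((float(row[key]), getattr(res, attr)))
    return table


def _file_checksum(path) -> str:
    with open(path, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


def run_pipeline(config: dict, out_prefix: str | None = None) -> PipelineResult:
    """Execute the end-to-end pipeline from a configuration mapping.

    Config keys: either ``pdb``/``hessian`` paths (with ``hessian_units``) or a
    ``fixture`` mapping {name, seed, params}; ``probes`` (atom serial numbers,
    {"c": int, "h": [int, ...]}); the experiment block ``temperature_K``,
    ``viscosity_Pa_s``, ``boundary``, ``reff_A``, ``spectrometer_MHz`` (scalar
    or list); optional ``r_ch_A``, ``csa`` {delta_sigma_ppm}, solver settings
    ``nu_max``, ``adaptive``, ``max_modes``, ``bead_selection``,
    ``hydrodynamic_interaction``; optional ``experimental_table`` (CSV path
    with freq_MHz, probe, T1_ms, T2_ms, NOE) for deviation statistics or, with
    reff_A set to "fit", for fitting over ``reff_bounds``/``reff_step``.

    With ``out_prefix`` set, writes <prefix>_results.csv and <prefix>_meta.json
    (deterministic content, no timestamps).
    """
    checksums = {}
    try:
        if "fixture" in config:
            fx = config["fixture"]
            structure, hessian = make_fixture(
                fx["name"], seed=int(fx.get("seed", 0)), **fx.get("params", {})
            )
        else:
            structure = read_pdb(config["pdb"])
            checksums["pdb"] = _file_checksum(config["pdb"])
            hessian = None
            if config.get("hessian"):
                hessian = read_hessian(
                    config["hessian"], structure.n_atoms,
                    units=config.get("hessian_units", "kcal_mol_A2"),
                )
                checksums["hessian"] = _file_checksum(config["hessian"])
            else:
                structure.rigid = True
    except Exception as exc:
        raise RuntimeError(f"[molecule_io] {exc}") from exc

    probes = [_resolve_probe(structure, p) for p in config["probes"]]
    solver_kwargs = {
        "boundary": config.get("boundary", "stick"),
        "r_ch_A": config.get("r_ch_A"),
        "nu_max": int(config.get("nu_max", 4)),
        "adaptive": bool(config.get("adaptive", False)),
        "max_modes": config.get("max_modes"),
        "bead_selection": config.get("bead_selection", "all"),
        "hydrodynamic_interaction": config.get("hydrodynamic_interaction", "none"),
    }
    if config.get("csa"):
        solver_kwargs["csa"] = CSAInteraction(float(config["csa"]["delta_sigma_ppm"]))

    exp_rows = None
    if config.get("experimental_table"):
        df = pd.read_csv(config["experimental_table"])
        checksums["experimental_table"] = _file_checksum(config["experimental_table"])
        exp_rows = df.to_dict("records")
        for row in exp_rows:
            row.setdefault("temperature_K", config["temperature_K"])
            row.setdefault("viscosity_Pa_s", config["viscosity_Pa_s"])

    deviations = None
    if config.get("reff_A") == "fit":
        if not exp_rows:
            raise RuntimeError("[relaxation] Reff fitting requires an experimental table")
        bounds = tuple(config.get("reff_bounds", (1.0, 3.0)))
        fit_kwargs = {k: v for k, v in solver_kwargs.items() if k != "boundary"}
        fit = fit_reff(structure, hessian, probes, exp_rows, bounds=bounds,
                       step=float(config.get("reff_step", 0.1)), **fit_kwargs)
        reff = fit.reff_A
        deviations = fit.report
    else:
        reff = float(config["reff_A"])

    results, meta = compute_observables(
        structure, hessian, probes,
        float(config["temperature_K"]), float(config["viscosity_Pa_s"]), reff,
        config["spectrometer_MHz"], **solver_kwargs,
    )
    if deviations is None and exp_rows:
        table = _deviation_table(structure, hessian, probes, exp_rows, reff, **solver_kwargs)
        deviations = deviation_summary(table)
    meta["input_checksums"] = checksums
    meta["config"] = {k: v for k, v in config.items() if k not in ("probes",)}
    result = PipelineResult(results=results, reff_A=reff, metadata=meta, deviations=deviations)

    if out_prefix:
        result.to_frame().to_csv(f"{out_prefix}_results.csv", index=False)
        with open(f"{out_prefix}_meta.json", "w") as fh:
            json.dump(meta, fh, indent=1, default=str)
    return result
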