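# sfbrelax

Stochastic modelling of ¹³C NMR spin relaxation (T1, T2, heteronuclear NOE)
for semi-rigid molecules in solution.

The package implements a semi-flexible Brownian (SFB) description of a
tumbling molecule: the orientation is coupled to N = 6n−9 dimensionless
harmonic modes built from the internal normal-mode coordinates, their
conjugate momenta and the body-frame angular momentum. The drift and coupling
matrices of the Fokker–Planck operator are assembled from three inputs only —
a reference (local-minimum) structure, its Cartesian Hessian, and a bead
hydrodynamic model whose single free parameter is the effective atomic radius
Reff. Rank-2 orientational spectral densities are computed with a sparse
resolvent solver in a Wigner × Hermite product basis and mapped to ¹³C–¹H
dipolar relaxation observables for CH and CH₂ probes.

## Layout

| module | role |
|---|---|
| `sfbrelax.molecule_io` | PDB/Hessian ingestion, mode counting, minimum validation, synthetic fixtures |
| `sfbrelax.rotations` | rank-2 Wigner algebra (ZYZ, active), body-frame rotation generators, probe frame angles |
| `sfbrelax.hydrodynamics` | bead friction tensor (free-draining or Rotne–Prager), rotational diffusion tensor |
| `sfbrelax.sfb_model` | mode construction and assembly of the drift (ω_io) and coupling (ω_int) matrices |
| `sfbrelax.spectral_solver` | sparse-operator spectral densities and correlation functions, Favro closed form, Brownian-dynamics oracle, mode reduction, Markovian fast path |
| `sfbrelax.relaxation` | observable mapping (T1/T2/NOE), deviation statistics, Reff fitting, pipeline driver |
| `sfbrelax.benchmark` | bundled 32-row oligosaccharide benchmark table (experimental + reference calculated values) |

## CLI

```bash
# generate a synthetic fixture (structure + Hessian)
sfbrelax fixtures --name tri_bead --out fx

# run the full pipeline from a YAML config
sfbrelax run --config config.yaml --out results

# fit Reff against an experimental table (CSV: freq_MHz, probe, T1_ms, T2_ms, NOE)
sfbrelax fit-reff --config config.yaml --exp exp.csv --rmin 1.0 --rmax 3.0 --step 0.1

# deviation statistics for the bundled benchmark (or any exp/calc CSV)
sfbrelax deviations
```

A minimal config:

```yaml
pdb: molecule.pdb
hessian: hessian.txt          # dense 3n x 3n or "i j value" triples
hessian_units: kcal_mol_A2    # Tinker convention; also J_m2
probes: [{c: 5, h: [12]}]     # atom serial numbers; two h entries -> CH2
temperature_K: 298.2
viscosity_Pa_s: 2.19e-3
boundary: stick               # or slip
reff_A: 2.0                   # or "fit" with experimental_table set
spectrometer_MHz: [600.1, 700.0]
nu_max: 4                     # Hermite excitation cutoff (adaptive: true to auto-converge)
```

## Conventions and caveats

- Euler angles are ZYZ active; `D^L_{k,m} = e^{-ik alpha} d^L_{k,m}(beta) e^{-im gamma}`
  with `d^2_{0,0}(pi/2) = -1/2` and `d^2_{+-2,0}(pi/2) = sqrt(3/8)` (the value is
  sometimes typeset without the radical; the radical is correct).
- Spectral densities are pure orientational quantities, G(0) = 1/5; all
  interaction prefactors live in `sfbrelax.relaxation`.
- The default C–H bond length is 1.09 Å and the computed T1 scales as r⁶ —
  override `r_ch_A` deliberately.
- The attached frame is the principal frame of the rotational diffusion
  tensor, centered at the friction-weighted centroid.
- CSA relaxation is implemented but off by default; CH₂ probes add the two
  proton dipolar rates (cross-correlation neglected).
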