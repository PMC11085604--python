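# cgnano

Coarse-grained simulation and analysis of protein–fullerene (C60)
interactions in a united-residue protein representation.

## The problem

C60 fullerenes bind proteins — blocking enzyme active sites, occupying
hydrophobic pockets — and understanding those interactions at relevant
timescales is out of reach for all-atom molecular dynamics.  `cgnano`
implements a reduced protein model (one Cα, one united side chain, and
one united peptide group per residue, geometry defined by virtual bond
angles θ, dihedrals γ, and side-chain placement angles α, β) together
with two C60 models:

- **explicit**: 20 alanine-like interaction centers at the vertices of a
  regular dodecahedron (circumradius 3.55 Å, so the center-to-center
  diameter matches C60's 0.71 nm), each with an inward-facing Cα anchor;
  harmonic restraints (k = 10 kcal mol⁻¹ Å⁻²) over all 190 anchor pairs
  keep the particle sphere-like while it translates, rotates, and
  deforms freely.  It interacts with the protein through the Gay–Berne
  potential
  `U = 4ε[(σ₀/(r−σ+σ₀))¹² − (σ₀/(r−σ+σ₀))⁶]`
  (plain Lennard–Jones in the spherical limit σ = σ₀ used by default);
- **implicit**: an immobile sphere of hard-core radius R₀ = 3.5 Å
  interacting with every protein site through the Kihara potential
  `U = 4ε[(σ/(r−R₀))¹² − (σ/(r−R₀))⁶]`,
  zero at r = R₀+σ and −ε at r = R₀+2^{1/6}σ.  Fast, but rigid and
  fixed in space; at most one per system.

The effective energy is a weighted sum of side-chain–side-chain,
side-chain–peptide-group, peptide–peptide, bonded, rotamer, torsional,
and dynamic disulfide terms, with temperature coefficients f_n(T)
scaling the second- and third-order cumulant terms.  On top sit
thermostatted velocity-Verlet dynamics (Berendsen or Langevin, 260 K
default), L-BFGS energy minimization, binding-energy estimation
(`E_binding = E_complex − (E_protein + E_nano)` on frozen frames, with
dissociated trajectories excluded from averages), and a trajectory
analysis suite: contact probabilities from the fullerene and protein
perspectives (8 Å cutoff), contact counts, superposed RMSD,
mass-weighted RMSF, radius of gyration, coarse-grained Shrake–Rupley
SASA, native-contact fractions, and disulfide-distance distributions.

The shipped per-residue parameters are a documented surrogate set (the
functional forms are faithful; published parameter tables are not
reproduced) — see `docs/methods.md`.

## Worked example

```bash
python examples/03_md_and_binding.py
```

builds a 10-residue horseshoe peptide around the explicit C60 particle,
minimizes it, runs 3000 thermostatted MD steps, and prints:

```
minimized: 72.3 -> -35.7 kcal/mol in 400 iterations
MD: 3000 steps x 4.89 fs, 31 frames, mean T = 257.0 K (setpoint 260 K)
reported laboratory time: 14.670 ns (1000x coarse-grained speed-up bookkeeping)

binding energy (second half of trajectory): -15.78 +/- 2.52 kcal/mol
dissociated: False
```

The minimization relaxes the built complex into the Gay–Berne wells; the
Berendsen thermostat holds the mean temperature near the 260 K setpoint;
the binding energy is negative because deleting the particle from the
frozen frames removes favourable cross-interaction energy.  The other
examples cover internal-coordinate round trips (`01`), the two C60
models' geometry and landmarks (`02`), and ensemble contact-probability
and RMSF analysis (`04`).

A thin CLI mirrors the library:

```bash
cgnano fixtures --kind toy_pocket_complex --n 10 --out cplx
cgnano run cplx.pdb --model explicit --seed 7 --steps 10000 --out run1
cgnano analyze contacts --trajectories run1.traj.pdb --system-pdb cplx.pdb --out contacts.tsv
cgnano correlate energies.tsv
```

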