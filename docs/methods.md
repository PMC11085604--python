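# Methods

## The reduced representation

Each residue is reduced to three sites: the Cα (geometry only), a united
side chain (SC) at the unweighted centroid of the side-chain heavy atoms,
and a united peptide group (p) halfway between consecutive Cα atoms of the
same chain.  SC and p are the interaction sites.  Backbone geometry is
carried by the Cα virtual-bond chain: bond lengths d (3.8 Å trans
reference), bond angles θ ∈ (0°, 180°], and signed dihedrals
γ ∈ (−180°, 180°] (right-handed convention; collinear quadruplets give
NaN, never a silent zero).  Side-chain placement is parameterized by α,
the angle between the Cα→SC vector and the outward bisector of θ, and β,
the azimuth about that bisector with zero in the backbone plane.  The
Cartesian builder (natural-extension reference frames) and the
measurement routines are exact inverses (round-trip residuals < 1e-6°),
which keeps internal-coordinate energy terms and their hand-derived
Cartesian gradients mutually consistent.

Glycine has no side-chain heavy atoms: its SC site is created on the Cα
with a zero-length virtual bond and kept as an independent dynamic site
(mass floored at 12 amu) so site indexing stays uniform; during MD it
jitters about the Cα under the stiff bond.  A non-glycine residue with no
side-chain heavy atoms falls back to the Cα with a warning.  Terminal
side chains, whose (α, β) frame needs two backbone neighbours, are placed
axially along the chain-end direction when rebuilding.

## Effective energy

U = w_SC ΣU_SCSC + w_SCp ΣU_SCp + w_ppVDW ΣU_ppVDW + w_ppel f₂(T) ΣU_ppel
 + w_tor f₂(T) ΣU_tor + w_b ΣU_b + w_rot ΣU_rot + w_bond ΣU_bond
 + w_ssbond ΣU_ssbond + w_corr3 f₃(T) U_corr3 + w_turn3 f₃(T) U_turn3
 + U_restraint + U_nano

with f_n(T) = ln(e + e⁻¹) / ln(exp[(T/T₀)ⁿ⁻¹] + exp[−(T/T₀)ⁿ⁻¹]),
T₀ = 300 K: exactly 1 at T₀, strictly decreasing in T (f₂(260 K) =
1.0948).  All weights default to 1 and are configurable.

Term forms (surrogates where the parent parameterization is unpublished,
all configurable through the key-value parameter file):

- **U_SCSC** — Gay–Berne in the spherical limit σ = σ₀ (plain LJ), pair
  parameters from per-residue σ₀, ε via Lorentz–Berthelot rules.  The
  orientation-dependent σ(û₁,û₂,r̂), ε(û₁,û₂,r̂) of the uniaxial
  Gay–Berne model are available behind `anisotropy_ratios` for energy
  evaluation; the dynamic sites carry no orientation vectors, so the
  spherical limit is what MD uses.  Alanine-like centers are close to
  spherical, which is why this default is acceptable.
- **U_SCp** — purely repulsive ε_rep(σ_rep/r)¹² over SC–p pairs.  The two
  peptide groups flanking a residue are excluded from its own SC's sum
  (they are a bonded contact, and including them injects spurious
  repulsion at native geometry).
- **U_ppVDW** — full LJ between peptide groups separated by at least two
  positions in the same chain (all cross-chain pairs included).
  **U_ppel**, **U_corr3**, **U_turn3** — pluggable callables, disabled by
  default (their parameterizations live outside this package); when
  supplied they are scaled by their weights and temperature factors.
- **bonded** — U_bond = ½k_d(d−d₀)² over backbone and Cα–SC bonds;
  U_b = ½k_θ(θ−θ₀)²; U_tor = Σ_m a_m cos(mγ) + b_m sin(mγ); U_rot =
  ½k_α(α−α₀)² + ½k_β(1−cos(β−β₀)).  The harmonic convention is ½k(Δx)²
  everywhere, including the particle restraints (the alternative k(Δx)²
  reading of the quoted restraint constant is noted but not used).
- **U_ssbond** — dynamic disulfide double well in the Cys SC–SC distance:
  a quartic well of depth −E_ss at d_ss0 = 4.0 Å (the CG side-chain
  separation scale of a formed bridge) rising to a barrier E_b at
  d_ss0 + 1.5 Å, a cubic smoothstep down to an exactly-zero plateau at
  d_ss0 + 3 Å, and a harmonic repulsive continuation at short range.
  All joins have zero slope, so the potential is C¹ everywhere; bonds can
  break and re-form during MD.  A pair is flagged "bonded" below the
  barrier position.

Analytic forces exist for every term (angle, dihedral, and α/β gradients
chain-ruled through the unit-vector normalizations); forces on the
derived peptide-group sites are redistributed half-and-half onto the
flanking Cαs.  The test suite verifies each term independently against
central differences at 1e-4 relative tolerance.

## The explicit C60 particle

20 interaction centers at the vertices of a regular dodecahedron,
circumradius 3.55 Å (center-to-center diameter = C60's 0.71 nm), typed as
alanine for nonbonded parameters.  Each center has a Cα anchor one bond
length (1.53 Å) inside along the radial direction.  All 190 anchor pairs
carry harmonic restraints, k = 10 kcal mol⁻¹ Å⁻², with d₀ frozen at the
build geometry (restraint energy exactly zero at construction).  No
torsional or angle terms act inside the particle, and no peptide groups
exist between its centers.

Two choices here are this package's own:

- **Anchor–center attachment.**  The parent model's orientational
  side-chain terms are not published; with a purely radial bond the
  centers swing freely about their anchors and the interacting surface
  loses its shape within picoseconds.  The attachment is therefore a
  radial-alignment harmonic ½k|c_i − t_i|², with t_i one bond length
  outward from anchor i along the centroid→anchor line (k = 100
  kcal mol⁻¹ Å⁻² default).  It restrains both the bond length and the
  outward orientation.  Intra-particle center–center Gay–Berne terms
  remain available behind a flag (off by default; the restraint network
  dominates).
- **Masses.**  Each vertex unit carries 36 amu (24 on the center, 12 on
  the anchor) so the whole particle totals C60's 720 amu while both site
  classes stay dynamic.

Shape stability at 260 K: harmonic normal-mode analysis of the restrained
particle (softest internal eigenvalue ≈ 32.5 kcal mol⁻¹ Å⁻²) gives
pair-distance thermal rms ≈ 0.13 Å, i.e. up to ~11% of the shortest pair
distances; instantaneous excursions therefore reach ~25–30% at 3σ, as any
k = 10 harmonic network must at this temperature.  "Sphere-like shape
maintained" is accordingly measured as the per-pair time-mean deviation
(observed ≤ 3%) and per-pair rms fluctuation (observed ≤ 13%), both
required to stay within 15% over 10,000-step runs.  20 centers is the
supported particle size; larger center counts destabilize the packing.

## The implicit C60 sphere

An immobile sphere (R₀ = 3.5 Å, position fixed for the whole simulation,
at most one per system) interacting with every SC and p site via the
Kihara potential.  The surrogate well parameters default to ε = 1.0
kcal/mol and σ = 3.55 Å: σ is pinned by two consistency requirements —
the far tail must vanish below 1e-8 kcal/mol by 100 Å, and the potential
minimum R₀ + 2^{1/6}σ must fall inside the 8 Å center-distance contact
cutoff so a bound site counts as in contact.  Both ε and σ should be set
explicitly for production use; treat the defaults as placeholders of the
phenylalanine-like scale.

## Dynamics

Velocity-Verlet in (Å, fs, amu, kcal/mol) units, dt = 4.89 fs default.
Initial velocities are Maxwell–Boltzmann at the target temperature from
the run seed, with center-of-mass momentum removed.  Thermostats:
Berendsen weak coupling (λ = √(1 + (dt/τ)(T₀/T − 1)), τ = 0.5 ps default,
λ clamped to [0.8, 1.25] per step for stability on small systems — the
coupling constant is this package's choice, documented here) and
Langevin (exact Ornstein–Uhlenbeck velocity update).  Under Langevin the
noise re-injects center-of-mass motion, so the instantaneous temperature
uses all 3N degrees of freedom; otherwise 3N − 3.  Identical seed and
configuration reproduce a trajectory bit-exactly on one machine;
ensembles run trajectory k with seed seed+k from a common start
(20 trajectories by default, mirroring the production protocol).
The "1000× speed-up" of the coarse-grained effective energy is
bookkeeping only: `laboratory_time` converts n_steps × dt × speed-up to
reported microseconds (4,000,000 × 4.89 fs × 1000 = 19.56 μs per
trajectory; 391.2 μs for 20) and never touches forces.

Minimization is L-BFGS-B with analytic gradients (the original SUMSL
minimizer is an implementation detail, not part of the model); the
contract is a gradient max-norm tolerance and a never-uphill result.

## Binding energies and dissociation

Explicit model: per frame, E_complex is the full-system energy and
E_protein / E_nano are re-evaluated on the same frozen coordinates with
the partner deleted, so intra-subsystem terms cancel exactly and
E_binding reduces to the cross terms; separated partners give 0 to 1e-6.
Implicit model: E_binding is the Kihara interaction sum directly.
Statistics default to the second half of each trajectory (matching the
usual snapshot convention for binding estimates); the ensemble mean and
sd are taken over per-trajectory means, a labelled choice among the
unstated alternatives (over frames, over trajectories pooled).
Dissociation is a sustained terminal contact-free window at the 8 Å
cutoff (default window: the last 10% of frames); dissociated trajectories
are excluded from binding averages but their per-frame values are never
altered.  Entropic corrections are out of scope: the coarse-grained
effective energy is a potential of mean force and already carries
restricted-free-energy character; all-atom ΔH/ΔG columns enter only as
user-supplied inputs to `correlate_energies` (OLS slope/intercept with
R² = squared Pearson correlation, symmetric in its arguments, with
subset exclusion).

## Analyses

Contacts use the 8 Å cutoff between nanoparticle interaction centers
(explicit: the 20 centers; implicit: the sphere center) and protein CG
sites (Cα, SC, and peptide groups by default; SC-only behind a flag).
Contact probability is the arithmetic mean over trajectories of
per-trajectory indicator means, per center (fullerene perspective) or per
residue (protein perspective), optionally in equal-width time bins.
RMSD superposes with the weighted Kabsch solution before measuring; RMSF
iteratively superposes frames onto the converged ensemble-average
structure (mass-weighted fit — average-structure fitting chosen over
first-frame fitting) and averages per-trajectory profiles.  The radius of
gyration is mass-weighted, and "maximum radius of gyration" is read as
the per-frame maximum site-to-center-of-mass distance (the common
trajectory-tool convention).  SASA is a coarse-grained Shrake–Rupley:
sites are spheres of radius σ₀/2 per type, probe 1.4 Å, with a
deterministic Fibonacci-spiral point set (960 points default; converges
to < 0.5% under point doubling).  It is a surrogate for all-atom SASA —
absolute values are not comparable to atomistic ones, trends are.
Native contacts are reference pairs within the cutoff at sequence
separation ≥ 3.  Disulfide analysis pools Cys SC–SC distances across
frames and trajectories and reports 5/25/50/75/95% quantiles.

## The synthetic-data generator

`build_synthetic_peptide` produces ideal helices (θ = 90°, γ = 50° — a
conventional Cα-trace approximation; the exact values are irrelevant to
correctness) and extended chains (θ = 180°) at d = 3.8 Å, poly-alanine
by default with optional Cys substitutions, optionally with seeded
Cartesian jitter.  `build_toy_pocket_complex` arranges a peptide arc
(radius 9 Å explicit / 9.3 Å implicit, side chains facing the particle
with a small out-of-plane tilt that keeps the (α, β) frame away from its
singular anti-bisector orientation) around a C60 model, guaranteeing
initial contacts at 8 Å.  Identical specs are bit-identical.

These toys exercise every operation but are not proteins: they have no
secondary structure, no funneled energy landscape, no sequence
heterogeneity beyond what a test injects, and their binding pocket is
engineered rather than evolved.  Passing tests therefore demonstrate the
correctness of the mechanics (potentials, gradients, integrators,
estimators, bookkeeping) — not the biophysical accuracy of the surrogate
parameter set on real proteins, which would require the published
parameterization and production-scale ensembles (20 × 4,000,000 steps)
far beyond desk scale.  Test and demonstration runs here use 10³–10⁵
steps and ≤ 20 trajectories on 4–12-residue toys, sizes chosen so the
full suite exercises every contract in minutes.

## Numerical choices and degenerate inputs

Degenerate internal coordinates are flagged, not zeroed: collinear
dihedrals are NaN and their torsion/rotamer terms are skipped; the α
gradient is guarded at sin α → 0.  Nonbonded terms have no cutoff by
default on toy systems; an optional energy-shifted cutoff is available.
Energies are validated per term (a NaN names its term), and MD aborts
with the step index when |E| exceeds a configured bound.  Dihedrals and
β live in (−180°, 180°]; coordinates are Å, 1-based residue numbering,
right-handed frames throughout.

## Known limitations

No published parameter tables (all defaults are surrogates); no
mean-field peptide electrostatics or multibody terms beyond the pluggable
hooks; no all-atom reconstruction, secondary-structure assignment, or
clustering; no replica exchange, pressure coupling, or GPU path; no
mmCIF or binary trajectory formats; fullerene derivatives are supported
only through per-center type/σ/ε configuration, with no shipped
derivative parameter sets.
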