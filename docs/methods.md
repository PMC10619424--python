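# Methods

This note records the models implemented in dehalokit, the conventions and
defaults that matter, what the synthetic fixtures do and do not emulate,
and the numerical choices made where the design was genuinely open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinate handling

Structures are parsed from PDB (and mmCIF) via gemmi into a flat ordered
atom list indexed by chain and residue. Coordinates stay in Å in the file's
orthogonal frame and residue numbers are taken verbatim — catalytic-site
declarations cite author numbering (e.g. the nucleophile Asp95, the
halide-stabilizing Trp96 and Asn28), so renumbering would silently break
them. Alternate locations: only blank or 'A' altlocs are kept by default,
so downstream geometry is deterministic. Multi-MODEL files (how docking
ensembles arrive) yield the first model unless another is requested.
Waters are retained and flagged by residue name; they are excluded from
SASA but required for water-bridge detection.

Superposition is the SVD-based least-squares rigid fit with the
determinant correction that forbids reflections; near-collinear point sets
warn (the rotation about the common axis is then undetermined) but still
return the least-squares solution.

### L5 loop classification

Across dimeric HLDs the L5 surface loop falls into a short (18-residue)
cluster and a long (20–22-residue) cluster. A loop carrying a
solvent-exposed phenylalanine is the hallmark of the back-to-back
dimerizing variant and takes precedence over the length rule. Because loop
boundary definitions vary between secondary-structure assignments, the
loop span is always supplied explicitly (config / function argument)
rather than inferred. `phe_exposed` is supplied by the caller or derived
from a relative side-chain SASA threshold of 0.3.

## NAC grading

Strict criteria: d(O···C) ≤ 3.41 Å, attack angle ∠(O–C–X) ≥ 157°, and
halide stabilization d(X···H) ≤ 3.0 Å. Boundary equalities satisfy the
criteria. Conventions adopted where usage is ambiguous:

- d(O···C) is minimised over the declared carboxylate oxygens, and the
  attack angle is computed with that same oxygen; the alternative (best
  angle over all oxygens) is not used.
- Both stabilizer donors must satisfy the distance rule
  (`require_all_donors=True`); a looser any-donor policy is available.
- When the structure has no hydrogens, distances are measured to the donor
  heavy atom (N) and the d(X···H) cutoffs relax by +1.0 Å.
- The halogen is auto-detected by element in the priority order Br, Cl, I,
  F, so the element actually present in the ligand always wins.
- Quasi-NAC bounds default to 3.8 Å / 140° / 3.5 Å. These are package
  defaults (no published values exist for the "small margin" notion) and
  are configurable; the invariant `quasi ⊇ strict` is enforced.

Ensemble screening never aborts on a single bad pose: a pose whose site
declaration does not resolve is reported non-productive with an error note
and the rest of the ensemble is classified normally.

## SASA and interfaces

SASA is the Shrake–Rupley construction: each atom's sphere of radius
(r_vdW + 1.4 Å) is sampled at n deterministic points (a Fibonacci spiral,
so results are bit-reproducible at fixed n); the accessible fraction is
the share of points outside every neighbour's expanded sphere. Defaults:
probe 1.4 Å, 960 points, vdW radii C 1.70, N 1.55, O 1.52, S/P 1.80,
halogens per element, fallback 1.70 Å with a warning. The 960-point
default reproduces the isolated-sphere closed form within 1% and a
100 000-point refinement within 2% on overlapping pairs; absolute areas on
real structures depend on the (unpublished) radii sets of reference
servers and should only be compared loosely (≤5%).

Interface area uses the PISA convention — half the surface buried on
association, `(SASA_A + SASA_B − SASA_AB)/2` — because published
interface/total percentages are reproduced by that arithmetic.

Contacts are typed by heavy-atom distance rules emulating a PLIP-style
inventory without hydrogens: hydrogen bonds are N/O pairs across groups
within 3.5 Å (no H-angle term, since deposited crystal structures carry no
hydrogens); hydrophobic contacts are counted once per residue pair as the
closest side-chain carbon–carbon distance within 4.25 Å between residues
in {ALA, VAL, LEU, ILE, PRO, PHE, MET, TRP} — the cutoff is 4.25 rather
than 4.0 Å so that packing contacts in the 4.0–4.1 Å range, which
published inventories count, are admitted; water bridges are a water
oxygen within 3.5 Å of a polar atom in each group. Whether reference tools
count hydrophobic contacts per atom pair or per residue pair is not
documented; this package counts residue pairs. π-stacking, salt-bridge and
halogen-bond typing, and any assembly-significance scoring (CSS, ΔG_diss
estimation) are out of scope; dissociation energies are consumed, not
produced.

## Crystal contents

Cell volume uses the general triclinic metric formula. The space-group
general-position multiplicity is resolved through gemmi's symmetry tables,
with printed-symbol normalization ("P12₁1", "P 1 21 1", "P21" all resolve
to Z = 2). The Matthews coefficient is `(V_cell/Z)/(n·M)` and the solvent
fraction `1 − 1.23/V_M` (inverse protein partial specific volume
convention, configurable), floored at zero. Matthews probability
distributions are not computed.

## Thermokinetics

Barrier extraction takes a 1-D reaction-coordinate profile (conventionally
the O···C distance decreasing in 0.025 Å steps; direction is defined by
point order, not coordinate sign). The transition state is the highest
interior local maximum; the ground state is the energy minimum strictly on
the reactant side of it, so a deeper product basin can never be chosen as
"ground state". By default the energies of both stationary points are
refined by a local quadratic fit over ±2 grid points (vertex clamped to
one grid step): picking raw extrema selects the most favourably noisy
sample and biases the barrier upward by roughly one noise standard
deviation per endpoint, which the fit suppresses; `refine_window=0`
restores raw point values. The QM/MM machinery that produces such
profiles is out of scope — only its two-column output is consumed.

Conversions use R = 1.987204 × 10⁻³ kcal mol⁻¹ K⁻¹ at a default 298.15 K
(no temperature is attached to published conversions of this kind; with
this choice both a 4.8 kcal mol⁻¹ barrier difference → 3.3 × 10³-fold rate
ratio and −4.6 kcal mol⁻¹ → K_d ≈ 2.3–2.4 × 10³ come out at their printed
2-significant-figure values). The enantiomer stability ratio is the
Boltzmann population ratio `exp(−(ΔG_R − ΔG_S)/RT)`; how published
"thermodynamic stability ratios" were computed is not documented, so this
definition is a package choice and is flagged as such.

Melting-transition extraction: the F350/F330 ratio is moving-average
smoothed (default 5 points), differentiated by central differences, and
derivative peaks with prominence above 20% of the global maximum are
reported. Each midpoint is refined as the centroid of the derivative above
its half maximum — for a logistic transition the derivative is symmetric,
so the centroid is unbiased while averaging away grid- and noise-jitter
that a 3-point parabolic refinement cannot. A flat curve returns an empty
list rather than an error.

## SAXS

The Debye double sum is evaluated exactly (O(N²) pairs) with sin(x)/x → 1
at the self/zero-angle limit, so I(0) = (Σf)² always. Form-factor modes:
POINT (f = 1), ELEMENT (electron counts at the q → 0 scale) and the
default RESIDUE_BEAD (one bead per residue at Cα with the residue electron
count; for Cα-less bead files every atom is a bead). ~600 beads — a dimer
of typical HLD size — stays desk-scale. No hydration shell and no
excluded-volume contrast term are modelled, so absolute χ² against real
detector data is not comparable to solution-scattering packages that model
them; the supported claim is relative discrimination between oligomeric
models of the same experiment. The default q grid is 0.01–0.5 Å⁻¹ with
250 points, a typical BioSAXS range.

Guinier analysis fits ln I against q² restricted iteratively to
q·Rg ≤ 1.3. Note the window convention itself carries a ~+2% bias for
compact globular shapes (the sphere's ln I is slightly concave inside the
window); tests therefore use a 2% tolerance against the uniform-sphere
closed form Rg = R√(3/5). χ² fitting uses the analytic weighted
least-squares scale `c = Σ(I_e I_c/σ²)/Σ(I_c²/σ²)` and an N−1 reduced-χ²
denominator. Model ranking is ascending in χ² with ties broken by name;
candidates whose curve cannot be computed are excluded with a note.

## Synthetic fixtures: what they do and do not show

All generators are seed-deterministic (NumPy PCG64) and emit the standard
file formats the analysis modules consume, plus machine-readable truth.
Noise is Gaussian everywhere; no published error model exists for any of
the emulated measurements. Receptors and dimers are minimal atom
constellations, not folded proteins: every classifier and geometry
operator in the package is coordinate-local, so folded-protein realism
would change nothing about what a passing test demonstrates. Consequences:
passing tests establish the correctness of the geometric rules,
surface-area bookkeeping, spectral/peak analysis and fitting machinery on
inputs with known truth — they do not establish force-field accuracy,
docking quality, or detector-level SAXS realism.

- **Pose ensembles**: a minimal catalytic constellation (carboxylate O
  pair, two donor H atoms placed 2.6 Å from the ideal halide site) plus
  ligand poses (attacked C, Br, two dummy carbons). Requested NAC poses
  sample d(O···C) in 3.00–3.35 Å and attack tilt ≤ 8°; non-productive
  poses either sit 4.2–6.0 Å away or attack at 75–110°. The generator
  verifies each pose's category with its own inline threshold comparisons
  (not the classifier under test) and rejection-samples until the intended
  category is realised, recording measured geometry as truth.
- **Toy dimer**: chain A is a confined random walk (3.8 Å steps inside a
  6.5 Å sphere, Gly Cα atoms) plus planted contact atoms near the two-fold
  axis; chain B is the 180° rotation of chain A about z, which realises
  each planted contact at its requested distance exactly. A 3×3 carbon pad
  either side of the axis buries a substantial, contact-inert surface
  (Gly-like carbons cannot type as hydrogen-bonding or hydrophobic
  contacts, so the planted inventory stays exact). Water-bridge legs are
  solved geometrically; the direct polar–polar pair is kept at 4.0 Å so it
  cannot register as a hydrogen bond. Truth buried area is measured with a
  10 000-point SASA oracle.
- **Energy profiles**: reactant well (Gaussian dip, depth 2 kcal mol⁻¹ at
  3.0 Å), Gaussian barrier at 2.2 Å scaled so the well-to-peak difference
  equals the requested barrier, sigmoid product drop, sampled at 0.025 Å
  decrements from 3.3 to 1.6 Å. A localized (curved) reactant well keeps
  the minimum identifiable under noise; a flat plateau would make
  "minimum-energy point" an order statistic over ~30 equivalent samples
  and inflate recovery error. Truth is the barrier measured on the
  noiseless samples by the extraction definition itself.
- **Melting curves**: baseline 0.8 plus logistic sigmoids, default
  amplitude 0.25 per transition and width 1.2 °C on a 20–80 °C grid at
  0.25 °C — the F350/F330 excursion and transition sharpness of a typical
  well-behaved nanoDSF run.
- **Scattering experiments**: Debye curve of a bead model with
  σ = frac·I + floor (default frac 0.02) and exactly-matching Gaussian
  noise, so refitting the source model yields reduced χ² ≈ 1 by
  construction. Bead globules are cubic-lattice spheres (spacing chosen
  for the requested bead count) so the sample Rg matches the continuum
  value; the lattice period is far outside the default q range.

## Problem sizes and tolerances used in the checks

Matthews and percentage checks are exact arithmetic at printed rounding.
Recovery checks run 20 noise realisations each: barriers within
0.2 kcal mol⁻¹ at σ = 0.05, melting midpoints within 0.5 °C at σ = 0.002.
SASA uses 960 points against closed forms (1%) and a 10⁵-point oracle
(2%). SAXS discrimination uses a 150-bead monomer vs its 300-bead dimer on
250 q points: the dimer-sourced experiment must fit the dimer at χ² ≈ 1
and the monomer at ≥ 10× that — the published pattern of a decisive
dimer/monomer χ² split — while absolute published χ² values against real
detector data are out of reach without the (undeposited) experimental
curves and a contrast model, and are deliberately not claimed.

## Known limitations

- No hydrogen-aware hydrogen-bond geometry; donor/acceptor typing is by
  element and atom name only.
- Interface analysis does not expand crystallographic symmetry mates; the
  two groups must be present in the file.
- The Debye evaluation is exact but O(N²); all-atom curves for large
  complexes should use the residue-bead mode.
- Barrier extraction assumes a single dominant barrier; profiles with
  comparable multiple maxima report the highest and ignore intermediates.
- Melting extraction reports derivative peaks, not a thermodynamic fit; it
  cannot separate transitions closer than roughly the transition width.
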