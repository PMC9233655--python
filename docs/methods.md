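# Methods

## The docking-sweep procedure

The pipeline analyses rigid-body docking sweeps of cholesterol (or other
sterols) over the transmembrane surface of an OPM-oriented membrane protein.
Because sterol hydroxyls on TM surfaces hydrogen-bond to the bilayer's
polar–hydrophobic interfaces rather than to the protein, the receptor is
augmented with planar layers of hydrogen-bond donors at the two interface
planes: each OPM `DUM` marker is replaced in place by an NH₃ group. The
nitrogen keeps the marker's exact coordinate; the three hydrogens are placed
at N–H = 1.01 Å in a tetrahedral umbrella (half-angle 70.53°) whose axis
points along the membrane normal away from the slab midplane. The orientation
is a modelling choice — only the donor density at the plane matters to the
scoring function — and pointing away from the hydrophobic core keeps the
donors at the interface. Pseudo-atoms are never counted as protein in contact
tables.

The membrane frame is derived from the marker layers by a 2-means split on z
(implemented as the largest gap in the sorted z values) with two validity
requirements: the inter-layer gap must exceed 5 Å and each layer must be
planar within ±1.5 Å. OPM layers are separated by the full hydrophobic core
(~30 Å), so these thresholds only reject genuinely malformed inputs.
Interface planes are the layer means; the normal is +z by the OPM convention,
with the cytosolic side at +z for this system.

Docking runs separately for the cytosolic and luminal halves of the membrane,
each half covered by two overlapping search boxes so that no site is missed
at a box face. Box extents are a design choice (the procedure states the two
overlapping boxes but not their dimensions): in z each box spans from the
half's interface plane to the midplane with a 3 Å margin on each face; in x
the protein's bounding rectangle (plus margin) is split at its midline with
25% of the width shared. Coverage plus overlap de-duplication makes the
precise split harmless. Duplicate poses from the overlap region are removed
within each (study, run): among cross-box poses with pairwise rmsd below
1.0 Å, only the most favourable-energy pose survives (ties broken by the
(study, run, box, model) key). The 1.0 Å duplicate threshold is deliberately
far below the 4 Å clustering threshold: duplicates are near-identical
placements of the same pose, not merely nearby sites. Poses from the same box
are never merged.

Two scoring regimes are supported. Transmembrane docking uses
hydrophobic-effect and hydrogen-bond weights of −0.001 and −2.0, appropriate
when ligand and receptor are both already in a hydrophobic environment;
docking to water-exposed domains uses the engine defaults of −0.0351 and
−0.587. The regime also controls pose selection: TM poses must have at least
8 protein residues with a heavy atom within 4 Å of a ligand heavy atom and a
fused-ring long axis tilted less than 30° from the bilayer normal (the
geometry of interfacial cholesterol sites resolved crystallographically on
many membrane proteins); aqueous-regime docking applies no selection. The
ring long axis is operationalized as the first principal component of the
centered coordinates of the 17 fused-ring carbons, with the acute angle taken
via the absolute cosine. Membrane-half assignment uses the ring centroid
relative to the midplane — hydroxyl-based assignment would misclassify
tail-down decoys.

Selected poses pooled across five independent docking studies are sorted into
clusters by simple threshold clustering: poses are visited in ascending
energy order and join the first cluster whose representative lies within the
4 Å rmsd cutoff, otherwise they seed a new cluster. Seeding by best energy
makes the representative rule (most favourable member) consistent with
membership and guarantees every member is within the cutoff of its
representative. The rmsd is computed over name-matched heavy atoms in the
common receptor frame without superposition, because superposition would
erase the spatial distinctness of sites. Only clusters containing a member
from every study are accepted: the engine's stochastic search occasionally
leaves a genuine site unoccupied in one study, and the five-study consensus
removes both this noise and spurious single-study sites. Whether selection
pools studies directly or pre-clusters within each study first is exposed as
a flag (`prestudy_cluster`); both orderings give the same consensus sites on
the synthetic campaigns, and direct pooling is the default.

Matching of poses to crystallographically resolved sterols uses the ring
centroid distance with a configurable threshold, default 3 Å; the threshold
is a reporting choice (no numeric criterion accompanies published match
statements) and is echoed in every match table.

## The energy chain

Docking energies (kcal/mol, molar standard state) convert to mole-fraction
binding constants in three steps. (1) The molar → mole-fraction standard-state
shift is a constant −0.7 kcal/mol; it is implemented as a configurable
offset rather than re-derived, since the tabulated energies show a uniform
−0.7 shift for this ligand/solvent combination and the closed form lives in
prior work on membrane-ligand standard states. (2) A sterol hydroxyl at the
interface forms a *multiplex* hydrogen bond — one acceptor engaging several
donors — taken as 60% stronger than the canonical −6.5 kcal/mol hydrogen
bond in a hydrophobic environment, hence 1.6 × (−6.5) = −10.4 kcal/mol;
subtracting it leaves the binding energy to the protein alone. (3)
K_a = exp(−ΔG°/RT) at 298.15 K (RT = 0.5925 kcal/mol), the temperature that
reconciles every tabulated (ΔG°, K_a) pair; K_a is displayed at two
significant figures with full precision retained internally. Occupancy is
f = K_a·x/(1 + K_a·x) with x the cholesterol mole fraction, so 100/K_a is
the half-occupancy level in mol%.

Applied to the three interfacial sites, the chain gives −16.8 → −17.5 → −7.1
→ 1.6 × 10⁵ for the Scap–Insig dimer site, −14.0 → −14.7 → −4.3 → 1.4 × 10³
for the equivalent site on the Insig monomer, and −12.5 → −13.2 → −2.8 →
1.1 × 10² for the Scap monomer (dimer conformation). The dimer-site corrected
energy equals the sum of the two monomer-site values: the half-site
contributions are additive, with the sterol acting as molecular glue between
independent Scap and Insig half-sites.

## The dimerization equilibrium

Speciation is computed in mole-fraction units for free Scap S, free Insig I,
the apo dimer SI, and the cholesterol-bound dimer D, with the free-cholesterol
mole fraction x_chol as an independent variable (protein-bound sterol is a
negligible cholesterol sink at protein mole fractions of ~10⁻³). Mass action
reads

    x_SI = K_SI · x_S · x_I
    x_D  = K_SI · K_a · x_S · x_I · x_chol^n

with n = 2 by default. The second-order sterol dependence encodes the
half-site picture established by the energy additivity above: forming the
sterol-glued dimer from free monomers involves a sterol interaction with each
of the two half-sites, and the dimer-site constant K_a is the product of the
half-site constants. This choice is also the quantitative one: with the
stated constants (K_SI = 4, K_a = 1.6 × 10⁵) and Scap and Insig mole
fractions of 0.001, the n = 2 scheme places half-maximal cholesterol-bound
dimer at 5.6 mol% cholesterol, reproducing the measured half-maximal SREBP
processing level (≈ 5.5 mol%; exact agreement corresponds to K_SI ≈ 4.15,
i.e. the quoted K_SI = 4 to one significant figure). A first-order scheme
(n = 1, a single SI + chol ⇌ SI·chol step) would require K_SI ≈ 0.23 to match
the same observation and with K_SI = 4 predicts 0.31 mol%; it remains
available via `n_sterol=1`, as do switches for the apo dimer and for a
cholesterol-bound free-Insig species (association constant 1.4 × 10³). The
Insig-monomer pathway is off by default: as a mass-action species it
sequesters free Insig strongly enough that the bound-dimer fraction plateaus
near 25% and a 50% level is never reached — such sequestration is therefore
incompatible with the observed dimerization and the species is interpreted as
an on-pathway intermediate (its step constant follows from the thermodynamic
cycle, K_step = K_SI·K_a/K_I, and is verified as such) rather than an
equilibrium sink.

The solver eliminates free Insig analytically (the Insig conservation law is
linear in x_I given x_S) and finds free Scap by Brent bracketing of the Scap
conservation residual on (0, x_S,total]; conservation must hold to 1e-10
relative or the solver raises. The half-maximal cholesterol level is the
bisection root of the bound-dimer fraction minus 0.5, resolved to 1e-10 in
mole fraction; bisection over Newton because the fraction is monotone and
bracketed. The fraction is defined relative to total Scap, which under equal
totals equals the fraction of all Scap and Insig molecules in cholesterol-
bound dimers, and makes the "half-maximal decreases with Insig level"
monotonicity well-defined for unequal totals.

## The synthetic-data generator

The generator emulates only what the pipeline consumes. The membrane-protein
fixture is a bundle of 8 backbone-only poly-alanine helices (N, CA, C, O per
residue; 1.5 Å rise, 100° twist, helix radius 2.3 Å) standing on a 12 Å
circle through a 28.4 Å slab — the hydrophobic thickness computed for the
Scap–Insig dimer — flanked by two 5 Å-spaced square grids of DUM markers.
Surface hollows between adjacent helices serve as plantable sterol sites with
~13–15 contact residues. The sterol is a rigid template (17 ring pseudo-
carbons in two puckered strands, hydroxyl oxygen, 8-atom tail proxy) whose
ring principal axis is aligned to +z exactly at build time, so a requested
tilt is reproduced to machine precision before jitter.

Campaigns plant: two sites present in all five studies (one of them inside
the lateral box-overlap band, generating cross-box duplicate poses), one site
present in only four studies, tilt decoys (tilt 60°, azimuth chosen per decoy
so the ring stays well-contacted — failing *only* the tilt criterion), and
contact decoys (5.5 Å off the bundle surface, upright — failing *only* the
contact criterion). Planted energies are drawn from Normal(−14.2, 1.1)
truncated to [−18, −10] kcal/mol, the observed distribution of accepted TM
pose energies; decoys draw from Uniform(−9.8, −8.5). The generator verifies
its own truth table with the selection module at build time and raises if any
decoy fails the wrong criterion or any planted site fails selection, and all
randomness flows from one seeded NumPy generator, so a seed fully determines
the campaign bytes.

What the generator does not emulate: physically realistic energies (values
are statistical stand-ins, not force-field output), ligand flexibility,
side chains, engine search stochasticity within a study, or correlations
between pose geometry and energy. Passing the planted-recovery tests
therefore demonstrates that the *selection, clustering, dedup and consensus
logic* is correct, not that the docking engine would find these sites in real
structures.

## Numerical choices and limitations

* Energy ties anywhere (dedupe, cluster seeding, representatives) are broken
  by the lexicographic (study, run, box, model) key, making every stage
  deterministic.
* Contact counting uses a k-d tree over protein heavy atoms; hydrogens and
  pseudo-layer atoms are excluded; a residue counts once regardless of how
  many atom pairs qualify.
* Tilt is undefined (and an error) for fewer than 3 ring atoms or collinear
  ring coordinates; empty pose lists are errors for energy summaries and an
  empty resolved set is an error for matching.
* The speciation grid-search cross-check and the planted-recovery suite run
  at deliberately small problem sizes (a ~750-atom bundle, tens of poses per
  campaign, 20 seeded campaigns, 100 random parameter draws) chosen so the
  whole test suite completes in seconds while still exercising every code
  path.
* Docking-engine invocation is intentionally out of scope for testing: the
  adapter writes configurations and reads pose files, so no engine binary is
  required anywhere in the package.
* Protonation, rotamer repair, and membrane-thickness prediction are not
  reimplemented; inputs are assumed already prepared (OPM orientation, any
  side-chain repair done upstream).
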