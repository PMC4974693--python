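# Methods

This note records the statistical model behind each stage, the
numerical choices, and what the synthetic benchmark does and does not
establish about real crystal structures.

## The analysis object

A *unit* is one protein copy restricted to a fixed author-numbering
span (default 41–764, i.e. up to 724 residues), the single inhibitor
bound at its active centre, and the water oxygens within 4 Å of any
protein heavy atom. All distances throughout the package are between
heavy atoms; hydrogens are discarded at parse time. Alternate
locations are resolved to the highest-occupancy copy (ties go to the
lexicographically first altloc label), a deterministic rule chosen
because occupancy is the crystallographer's own statement of which
conformer dominates. A span residue with no resolved heavy atom
counts as *disordered*; a chain with ≥ 6 disordered residues (or no
ligand at the active centre, in inhibitor-bound mode) is rejected
with an explicit reason. "Bound at the active centre" is
operationalised as ≥ 1 ligand heavy atom within 4 Å of any heavy atom
of the catalytic serine's residue — the same 4 Å scale used for all
contact statements. Insertion codes are rejected rather than guessed
at; none occur for the study protein.

One PDB entry can hold several protein copies. The pipeline default
accepts every qualifying chain of an entry (that is how 68 entries
yield ~147 units in the motivating data set); `all_chains=False` plus
per-entry `chain_overrides` restores one-unit-per-entry selection.

## Superposition and RMSD

For matched coordinate sets the package minimises

    RMSD = sqrt( (1/N) Σ_i χ_i² )

over proper rigid motions with the SVD form of the Kabsch algorithm,
including the determinant correction that forbids reflections. The
least-squares optimum is unique for non-degenerate point sets, so the
result coincides with any correct minimiser regardless of software.
Collinear inputs leave a free rotation and raise an
"underdetermined" error (second singular value of the centred
coordinates below 1e-8 relative). The test suite checks the optimum
against an independent derivative-free rotation search (coarse
axis–angle grid, then pattern-search refinement) to 1e-6 Å, and
checks that mirrored chiral inputs never beat the proper-rotation
optimum. Cα correspondence across units is by author residue number;
each pair uses the intersection of residues present in both units,
and no outlier-rejection cycles are performed (plain minimisation).

## Variation between units

For atom *i* and unit pair *k*, let δ_ik be the atom's distance
between the two units after superposition; the variation of atom *i*
is (1/M) Σ_k δ_ik over the M pairs in which the atom is present in
both units (pairs with the residue missing simply do not contribute
to that residue's M).

* **Cα variation** superposes each pair globally on all shared Cα
  atoms, so it measures internal main-chain deformation after the
  rigid-body difference is removed.
* **Side-chain variation** refits each pair on the three main-chain
  atoms (N, Cα, C) of the residue under study and tracks a *reporter
  atom* — the side-chain atom furthest from the main chain for that
  amino-acid type (Arg Nη, Tyr Oη, Ser Oγ, Val Cγ, Asn Nδ2, Glu Oε,
  His Nε2, Phe Cζ, Trp Cη2, …). Symmetric terminal pairs
  (Arg Nη1/Nη2, Glu Oε1/Oε2, Val Cγ1/Cγ2, …) are measured with fixed
  name correspondence and the two values averaged; no symmetry-swap
  minimisation is attempted, so a 180° terminal flip registers as
  variation. The alternative (minimising over the swap) would hide
  genuine amide flips such as the Asn Oδ/Nδ switching the analysis is
  meant to expose.

The per-type baseline ("average of the equivalent amino acids") is
the unweighted mean over residues of the same type.

Under the generator's model — iid isotropic Gaussian displacement of
SD σ per atom — the difference of two noisy copies is Gaussian with
per-coordinate variance 2σ², so post-superposition distances follow a
Maxwell distribution with mean 4σ/√π ≈ 2.257σ, and E[RMSD²] = 6σ²
(RMSD ≈ σ√6). These closed forms anchor the recovery tests: the
fitted σ̂ = variation·√π/4. Because one residue's variation at
M = 45 pairs carries ~6 % sampling noise (Maxwell SD divided by √45),
the 5 % recovery bound is asserted on the mean over ≥ 180 residues,
where sampling noise is ~0.5 %. Rank recovery is checked two ways: a
graded σ ramp must give Spearman ρ > 0.9 between planted and measured
profiles (a flat-plus-spikes profile cannot, purely because of rank
ties), and a flat profile with ten 5× spikes must put exactly those
ten residues at the top. The global fit absorbs six rigid degrees of
freedom out of 3N coordinates, biasing both statistics low by
~6/(2·3N) (≈ 0.6 % at N = 180); this sits inside the 5 % band and is
why small-N toys are not used for scale recovery.

## Binding area and binding modes

A residue's contact fraction is the share of distinct inhibitor
compounds (deduplicated by chemical-component identifier — the
motivating data set has 68 compounds across ~147 units) with ≥ 1
heavy-atom pair < 4 Å to that residue; a compound counts as soon as
any of its units makes the contact. Membership is strict
(fraction > 0.70 core, > 0.30 extended), so the degenerate setting
high = low = 0 admits every residue with at least one contact, and
per-unit raw counts are always emitted alongside for cross-checking.

Binding modes are fixed geometric motifs, evaluated against a
configurable `site_map` (role → residue number) so synthetic systems
with arbitrary numbering can be classified:

* **amine network** — one primary/secondary amine N of the ligand
  simultaneously < 4 Å to a Glu205 Oε, < 4 Å to a Glu206 Oε and
  < 5 Å to the Tyr662 Oη. Amine detection is valence-based and
  geometry-free: a ligand nitrogen with 1–2 heavy-atom neighbours
  within a 1.8 Å bond distance (tertiary N, with 3 neighbours, never
  qualifies; a ligand with no nitrogen trivially fails).
* **polar anchor** — a ligand O/N/halogen atom < 4 Å to an Arg125 Nη
  *or* to the Asn710 Nδ2/Oδ1 (both amide atoms accepted because the
  Oδ/Nδ assignment swaps between deposits). Separate per-partner
  flags are recorded so a conjunctive reading can be recovered.
* **covalent Ser630** — Ser630 Oγ < 3 Å from a ligand carbon
  (nitrile warheads).

## Conserved waters

Pairwise identity ("water oxygens within 1 Å are identical") is
extended to a multi-unit consensus by greedy centroid clustering in
the frame of a reference unit (default: the first unit; any unit id
can be configured). All waters are mapped into that frame through the
global Cα superposition, then repeatedly: the pooled water with the
most neighbours within the identity radius seeds a site (ties broken
by lowest unit id, then lowest water serial); at most one water per
unit joins (nearest first); the centroid is recomputed once and
members re-assigned around it, which keeps every member within the
radius of the reported centroid; members leave the pool. The
procedure partitions the pool, so site supports sum to the total
water count, is deterministic given input order, and is stable (±1
support) under reference change on synthetic data. Units that
deposited no waters are excluded from the support denominator; the
default support floor is the fraction 0.427 of water-bearing units,
converted to a count by rounding (61 of 143 in the motivating set).

Annotation measures proximity in each member's own original
coordinates (not the consensus frame): a site is near the binding
area when any member lies < 4 Å from a heavy atom of an extended-set
residue of its own unit, and the near-ligand count is the number of
member units whose ligand comes within 5 Å of the member water. The
B-factor flags compare the site's mean member B with the mean B of
all water oxygens and of all protein heavy atoms over the member
units — conserved hydration water typically sits below both, unlike
incidental crystal water.

## Exposed surface area

Shrake–Rupley sphere sampling with a deterministic spherical
Fibonacci lattice (default 960 points, probe 1.4 Å) and the radii
table C 1.70, N 1.55, O 1.52, S 1.80 Å (plus halogens/P/Se for
completeness). Waters and the ligand are stripped first, so the
profile describes the apo protein surface. Per-residue areas are atom
sums; the ensemble profile averages over the units where the residue
is present. Closed forms pin the sampler: an isolated atom matches
4π(r+p)² to < 1 %, an intersecting pair matches the spherical-cap
formula to < 2 %, and a fully enclosed atom scores exactly 0.
Translation invariance is exact because the lattice translates with
each atom centre; rotating the molecule against the fixed lattice
reproduces areas only to sampling resolution (≈ 1.5 Å² per atom at
480 points, shrinking with the lattice), which is the standard
behaviour of sampled SASA; downstream use is ordering residues, and
the ranking is stable under ± 5 % radii perturbation. Absolute values
are not calibrated to any external server, so only orderings should
be compared across programs.

## Synthetic ensembles

The generator emulates the statistical, not chemical, structure of a
redundant cocrystal ensemble: an idealized α-helical backbone
template (N/Cα/C plus Cβ and reporter pseudo-atoms; 2.3 Å radius,
100° twist, 1.5 Å rise) with designated role residues around a pocket
point; a planted ligand whose amine nitrogen sits at configurable
distances from the role reporter atoms (defaults 3.2/3.5/4.6 Å to the
two glutamate Oε and the tyrosine Oη — inside the 4/4/5 Å motif with
margin comparable to the noise), a nitrile carbon 2.8 Å from the
serine Oγ and an anchor oxygen 3.4 Å from the arginine Nη; per-unit
iid Gaussian atom displacement with a per-residue σ profile (default
0.2 Å, chosen so default ensembles reproduce the ~0.5 Å inter-unit
Cα RMSD scale typical of redundant cocrystal sets); uniform random
rigid poses (≤ 30°, ≤ 5 Å); optional missing residues; planted water
sites present in a chosen fraction of units (exact count, default
0.8) with 0.2 Å jitter and low B (10 Å² vs 25 Å² protein), plus 50
decoy waters per unit uniform in a 40 Å box (clearing atoms by
2.4 Å, B ≈ 40 Å²) — decoys outside the 4 Å retention distance are
discarded at unit building, as in real structures where only
first-shell waters are deposited near the chain. A single seeded
generator drives all draws in a fixed order (site positions → site
support → per unit: missing mask, protein noise, ligand noise, water
jitter, decoys, pose), so ensembles are bit-identical across runs.
Units are written as legal PDB text and re-parsed, so every test
exercises the real I/O path.

What passing the synthetic benchmark shows: the estimators recover
known displacement scales, orderings, planted contacts and planted
water sites under the noise model, and every threshold behaves
exactly at its boundary. What it does not show: correctness of any
chemical assumption (no rotamer libraries, no force field, no
correlated backbone motion, no resolution-dependent water
completeness), nor agreement of absolute SASA values with any
particular server. Conclusions about a real ensemble still depend on
the crystal structures themselves.

## Problem sizes and determinism

Default verification scales — chosen as the smallest sizes at which
the closed-form statistics are inside their bands with margin — are
10 units × 180 residues (≈ 850 atoms) for scale recovery (20 seeds ×
3 σ values), 10 units × 120 residues for the end-to-end stages, and
20 seeds for water-site recovery. The acceptance script derives all
sub-seeds from a single `--seed` and recomputes every reported number
at run time; the pipeline's `report.json` is byte-identical across
reruns except for its timestamp.
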