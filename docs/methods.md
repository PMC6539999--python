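# Methods

This note documents the models, parameters and design choices behind
`focusforge`, and what its synthetic fixtures do and do not establish about
real structures.

## Scope of the re-implementation

The package engineers the *pipeline logic* of computational focused-library
design — conformer diversification, geometric matching, annealed repacking,
filtering/clustering, profile curation, and exact diversity/coverage
arithmetic — not the physics of a production force field. The original
workflow ran on Rosetta's enzyme-design machinery with OpenEye Omega
conformers and a minimized crystal-structure scaffold; all three are replaced
here by declared, reproducible stand-ins (a grid sampler, a three-term score,
and as-is input structures). Counts that depend on the production energy
function (matches found in the real pocket, filter survivors, orientation
clusters) are therefore exercised on planted fixtures and checked against
exhaustive enumeration, while the combinatorial bookkeeping — 500→1000
conformers, 143 × 25 = 3575 models, the 17-position library of diversity
1.6 × 10^8, coverage >99% at 4 × 10^9 transformants — is reproduced exactly.

## Ligand model and conformer sampling

A ligand template is a declared atom table (name, element, coordinates) with
a bond graph, named χ dihedrals, a rigid core (peptide backbone plus central
phenyl ring) and named polar groups (`nitro`, `m_hydroxy`, `carboxylate`).
There is no chemical perception; protons, if present, are ignored by clash
checks. Conformers are produced by rigid rotation about χ axes only, so bond
lengths and angles are template-invariant (asserted to 1e-6 Å in tests).
Dihedrals follow the IUPAC sign convention, degrees in [−180, 180), validated
against MDAnalysis.

Sampling pins χ1–2 to the values observed for the native substrate in the
scaffold and draws χ3–5 from a uniform grid (default six 60°-spaced values)
with ±15° stratified jitter, rejecting duplicates (all components within 1°)
and intramolecular heavy-atom contacts below 2.4 Å (1-2/1-3 pairs excluded).
Grid density and jitter are free parameters: the upstream tool's energy
window and RMSD-deduplication settings are not public, so no attempt is made
to mimic its specific ensembles — only the contract (n distinct, clash-free,
χ1–2 fixed) matters downstream. The χ2 flip appends a 180°-rotated twin of
every member, preserving the originals in order.

## Scaffold conventions

PDB I/O goes through biotite. Author numbering is preserved verbatim (library
positions such as 32, 65 … 188 refer to it); insertion codes are rejected;
alternate locations resolve by occupancy; waters are dropped. Scaffold
pre-minimization is deliberately not performed — fixtures are constructed
clash-free, and user structures are taken as-is. Shells use half-open
intervals on the minimum side-chain-heavy-atom distance to any ligand heavy
atom: first shell [0, 6 Å), second [6, 9 Å); Cβ counts as side chain and
glycine falls back to Cα. Which residues are catalytic ("fixed") is a config
input, never inferred.

## Reduced side-chain chemistry

Residue identities map to linear heavy-atom stubs built outward from the
backbone by internal coordinates (Cβ bond 1.53 Å, chain angle 111°), with up
to three more chain atoms, element-typed bond lengths, vdW radii (C 1.70,
N 1.55, O 1.52, S 1.80 Å) and donor/acceptor flags on the terminal atom.
Rotamers live on the sp3 grid {−60°, 60°, 180°} per rotatable bond — a
declared stand-in for a backbone-dependent rotamer library. This collapses
rings and branches into chains, which keeps every matching and packing state
space exhaustively enumerable in tests; the cost is that identities with
identical stub chains (S and T, V and P) are geometrically degenerate, so
fixture constraints use identity sets with pairwise-distinct chain lengths.

## Matching

A constraint declares a ligand polar group, an allowed identity set, and
closed ranges for donor–acceptor distance, the angle at each partner, and an
optional torsion. "Standard H bond" defaults: distance 2.6–3.2 Å, both angles
≥120°. The carboxylate constraint is built by measuring the scaffold's native
glutamine–anchor geometry and allowing ±0.3 Å / ±20° around it
(`native-only` policy: only the wild-type side chain in its crystallographic
state, also at positions held fixed for design). For `full`-policy
constraints every non-fixed position hosts every allowed identity at every
grid rotamer. A match assigns one candidate per constraint at pairwise
distinct positions with no heavy-atom pair below 0.8× the vdW-radius sum
(against the ligand or each other); matches are deduplicated to
sequence-unique signatures, keeping the lexicographically smallest
(conformer index, position tuple) representative. Plain enumeration is used
throughout — at fixture scale nothing faster is needed.

## Scoring and annealed redesign

The score is three terms, all parameters in code constants:

* **Steric** — per heavy-atom pair with contact distance r0 (sum of vdW
  radii): a quadratic repulsive well 4·((r0−r)/r0)² that is exactly zero at
  r0 and switches to a matched linear ramp below 0.8·r0 (the overlap
  softening), plus a shallow attraction of depth 0.05 centred at r0+0.25 Å
  with half-width 1 Å.
* **H bond** — a geometric well worth −1 at ideal geometry (2.9 Å, 180°/180°)
  tapering linearly to 0 at the range edges; ligand polar atoms act as both
  donors and acceptors in this reduced model, residue tips use their declared
  flags.
* **Constraint** — harmonic penalty, spring constant 1 per unit of violation
  (Å or degree), evaluated against the best-fitting atom of the ligand group.

Reported components: `interface` (ligand↔protein steric+H-bond), `internal`
(protein↔protein among repacked side chains and the static environment, plus
flat per-identity reference offsets), `constraint`; `total` is their exact
sum. Environment self-energy is a constant and excluded, so scores are
comparable only within a scaffold.

Redesign packs (identity, rotamer) choices at all positions within 9 Å of the
ligand, excluding fixed and match-assigned positions, via precomputed
single-body and pairwise energy tables. Annealing uses geometric cooling from
T=5 to T=0.1 score units over 200 sweeps (one proposed move per position per
sweep), followed by a zero-temperature greedy quench to convergence; the best
state visited is returned, so the final total never exceeds the initial one.
With `sweeps=0` the wild-type state is returned unmoved, scored. Repeat r of
match m runs with seed = SHA-256(base_seed, match id, r) truncated to 64
bits; identical inputs and seed give identical models. On systems small
enough to enumerate, the annealer recovers the exhaustive optimum in ≥95% of
seeded runs (verified at 100 seeds in the suite).

Variant modeling threads a given sequence, repacks rotamers with identities
fixed, anchors the ligand by least-squares core superposition (scipy's
Kabsch), and reports every donor/acceptor pair passing H-bond geometry,
residue–ligand and residue–residue alike.

## Triage

Preorganization removes the ligand, repacks the active-site side chains
(identities fixed, same annealer, designed rotamers injected into the option
set), and reports the heavy-atom RMS between designed and ligand-free side
chains over the designable ∪ match-assigned positions — side-chain heavy
atoms only, a declared choice. Filters keep models with interface ≤ 0,
constraint ≤ 1.0 and preorganization RMS ≤ 1.0 Å by default; the upstream
thresholds were never published, so these are tunable config inputs logged
with each run. Clustering is greedy leader clustering on ligand heavy-atom
RMSD without re-superposition (poses already share the scaffold frame),
cutoff 2.0 Å, visiting models best score first (lowest total, ties by model
id) — chosen over hierarchical clustering for determinism and O(nk) cost.
Ties between equal-sized clusters resolve to the smallest leader id.

## Library arithmetic

Diversity is the exact product of per-position allowed-set sizes, computed on
Python integers end to end (scientific-notation rendering uses 2 significant
figures). Curation applies, in this declared order: (1) drop identities below
5% frequency; (2) drop listed distal conservative identities; (3) collapse
each similarity group ({S,T}, {V,I,L}) present at a position to its
highest-frequency member, ties alphabetical; (4) add wild type at the
reinstatement positions. Positions reduced to wild type alone leave the
library table — this is how 26 designable positions become the 17 diversified
ones. Every edit is logged, and replaying the log against the raw profile
reproduces the curated specification (tested). The fixed D286R background
mutation is export metadata, never counted toward diversity. Coverage uses
the with-replacement expectation 1 − (1 − 1/V)^N through log1p/expm1 for
numerical stability at N, V ~ 10^8–10^10.

## Synthetic fixtures and what they show

The toy ligand mimics a photocaged tyrosine's shape: backbone, phenyl
hexagon (1.39 Å bonds), ring hydroxyl, and an ether-linked caging arm ending
in a nitro group, with χ1–5 spanning the rotatable bonds. Toy scaffolds are
built backwards from the answer: satisfying residue placements are
constructed by inverse kinematics (tip placed at the intended H-bond
geometry, the chain walked back to the backbone with the planted grid χ
values, exploiting the reversal symmetry of dihedrals), decoy residues are
marched to exact distance-band positions, and the generator verifies by a
flat exhaustive sweep that exactly the planted placements satisfy the
constraints, retrying placement otherwise. Profile fixtures are constructed
as inverse images of the curation rules, including a raw 26-position profile
whose set sizes (sixteen 10s, then 4, 3, 7, and seven 1s) multiply to
8.4 × 10^17 exactly.

Passing tests on these fixtures establish that the algorithms implement
their declared semantics — matcher output equals brute-force enumeration,
filters and clustering obey their laws, curation is auditable, the annealer
finds enumerable optima. They do not establish accuracy on real proteins: the
stub chemistry has no rings, branches, electrostatics or solvation, the
score is not calibrated against experiment, and a real pocket's match and
survivor counts depend on physics this package deliberately does not model.

## Problem sizes

The default test and acceptance runs use the shipped pocket fixture (nine
residues, three planted matches), 500-member ensembles, and the full
143 × 25 = 3575-model design-stage bookkeeping with two-identity restrictions
and short anneals — sizes chosen so the complete suite runs in well under a
minute of compute while still exercising every stage at the workflow's true
bookkeeping scale.
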