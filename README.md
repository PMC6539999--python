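# focusforge

Focused combinatorial library design for enzyme active-site redesign.

Engineering an aminoacyl-tRNA synthetase (aaRS) to charge a noncanonical
amino acid (ncAA) means reshaping an active site of ~26–30 interdependent
first- and second-shell residues. Full randomization of that many sites is a
sequence space of 20^26 ≈ 6.7 × 10^33 — about 26 orders of magnitude beyond
what bacterial transformation (~10^8–10^9 recombinants) can screen.
`focusforge` implements, at desk scale, the computational workflow that closes
this gap for a photocaged tyrosine (*ortho*-nitrobenzyl tyrosine, ONBY)
recognized by an engineered *Mj*TyrRS: it whittles the design space down to a
focused library of ~10^8 computationally vetted sequences that standard
double-sieve selection can exhaust.

The pipeline stages, each an importable module and a CLI subcommand:

1. **Conformer ensemble** (`ligand`) — the ncAA is a user-declared atom
   template with χ1–5 dihedrals; χ1–2 stay pinned to the substrate-anchor
   values while χ3–5 are diversified on a jittered grid (500 members), then a
   χ2-flipped twin of every member doubles the ensemble to 1000.
2. **Geometric matching** (`matcher`) — enumerate sequence-unique placements
   of H-bonding residues (S/T/Y/N/Q/W-type identities on a discrete rotamer
   grid) satisfying declared distance/angle constraints to the ncAA's nitro
   and *m*-hydroxy groups, with a native-geometry constraint for the
   carboxylate-coordinating glutamine.
3. **Redesign** (`designer`) — simulated-annealing rotamer/identity packing of
   every shell position within 9 Å of the ligand under a simple three-term
   score (soft steric well, geometric H-bond well, harmonic constraint
   penalties), 25 repeats per match with SHA-256-mixed seeds.
4. **Triage** (`triage`) — filter by ligand-interface score, constraint score,
   and preorganization (side-chain RMS after repacking without the ligand);
   cluster survivors by ligand-orientation RMSD; keep the largest cluster.
5. **Library building** (`library`) — compile the per-position sequence
   profile, curate it (drop identities <5%, drop distal conservative
   mutations, collapse similar identities such as S/T or V/I/L, reinstate
   wild type where *m*-hydroxy contacts were introduced), and compute the
   exact library diversity (arbitrary-precision product of allowed-set sizes),
   the expected transformant coverage 1 − (1 − 1/V)^N, and per-variant
   mutation counts.

A `fixtures` module generates synthetic scaffolds, ligands and profiles with
planted ground truth (constructed by inverse kinematics from the intended
answer), so every stage is testable against exhaustive enumeration with no
external downloads. The curated 17-position ONBY library and the selected
high-activity variant are shipped as reference data.

## Worked example

The built-in reference summary reproduces the library arithmetic end to end:

```
$ focusforge reference
diversified positions: 17
library diversity: 159252480 (1.6e+08)
design space at 26 positions: 6.7e+33
reduction: 26 orders of magnitude
selected variant mutations: 10
coverage by 4e9 transformants: 100.00%
```

Reading: curation left 17 of 26 designable positions diversified; the product
of their allowed-set sizes is exactly 159,252,480 ≈ 1.6 × 10^8 sequences —
26 orders of magnitude below the unconstrained 20^26 space — and a
transformation yielding 4 × 10^9 colonies samples >99% of those members. The
selected synthetase variant differs from wild type at 10 of the 17 positions.

A full synthetic-pocket run, from fixture generation to a curated library:

```
focusforge fixture --seed 1 -o fx
focusforge conformers --template fx/template.yaml --n 500 --flip-chi2 --seed 2 -o ens.pdb
focusforge match    --scaffold fx/scaffold.pdb --template fx/template.yaml \
                    --ensemble ens.pdb --constraints fx/constraints.yaml \
                    --fixed 73 -o matches.json
focusforge design   --scaffold fx/scaffold.pdb --template fx/template.yaml \
                    --constraints fx/constraints.yaml --matches matches.json \
                    --repeats 25 --fixed 73 --seed 3 -o designs.json
focusforge triage   --scaffold fx/scaffold.pdb --template fx/template.yaml \
                    --constraints fx/constraints.yaml --matches matches.json \
                    --designs designs.json --fixed 73 -o survivors.json
focusforge library  --profile profile.json --rules rules.yaml -o lib/
focusforge coverage --transformants 4e9 --diversity 1.6e8
```

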