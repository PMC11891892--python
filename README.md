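# alchemid

Pairwise chemical-intermediate generation for alchemical free-energy
perturbation (FEP) networks.

## The problem

Relative binding and hydration free-energy calculations transform one ligand
into another along a nonphysical (alchemical) path. When the two end states
differ by many atoms, phase-space overlap is poor, convergence is slow, and
results degrade. A standard remedy is to insert a *chemical intermediate* I
between the parents A and B — a real molecule that shares more structure
with each parent than they share with one another — and run two easier legs
A→I and I→B instead of one hard A→B edge.

`alchemid` constructs such intermediates automatically for a parent pair
(or every pair of a congeneric series):

1. **Core identification** — the maximum common substructure (MCS) of the
   two parents is found (elements and exact bond orders must match, rings
   map completely and ring-system-consistently) and mapped deterministically
   onto both molecules.
2. **R-group table** — every core atom with a non-core neighbor becomes an
   attachment site; substituents are excised by cutting only the single
   bonds crossing the core boundary. Sites whose substituents share a ring
   with the core (fused rings) are frozen into one group, so no ring is ever
   cut. A site where one parent carries only hydrogen contributes an
   explicit H group.
3. **Enumeration and reassembly** — for k differing substituent groups, all
   2^k − 2 cross-parent combinations are rebuilt on the core. Reassembly
   preserves stereochemistry: tetrahedral parities are recorded with their
   neighbor order before detachment and restored after bond formation
   (RDKit's `molzip` drops this information, so the join is done with
   explicit bookkeeping), and double-bond stereo is remapped onto the atoms
   occupying the same geometric slots. Both parents are also rebuilt from
   their own substituents; a pair whose parents do not come back
   byte-identical by isomeric canonical SMILES is flagged.
4. **Pruning and ranking** — each candidate is scored against *both*
   parents with Tanimoto similarity (radius-2, 2048-bit circular
   fingerprints), a LOMAP-style MCS score exp(−β·(N_c + N_p − 2·N_mcs)),
   and optionally a pluggable 3D shape/color backend. Per-parent scores are
   combined by sum, weighted sum or harmonic mean 2ab/(a+b) (optionally
   after min–max normalization); a heavy-atom filter can remove candidates
   with too-small or too-large R-groups.

Small analysis helpers for FEP paths through an intermediate are included:
ΔΔG summation with root-sum-square uncertainty propagation, cycle-closure
discrepancy (A→I→B vs A→B), and the convergence time of a ΔG(t) series
(earliest time after which ΔG changes at most 0.1 kcal/mol over any 2 ns
window, by default).

## Worked example

```python
from alchemid import (MoleculeRecord, PruneConfig, generate_intermediates,
                      rank_intermediates, summarize_pair)

parent_a = MoleculeRecord.from_smiles("Fc1cc(C)cc(OC)c1", "parentA")
parent_b = MoleculeRecord.from_smiles("Clc1cccc(N)c1", "parentB")

iset = generate_intermediates(parent_a, parent_b, pair_id="demo")
print(f"differing site groups: {iset.table.n_differing}")
print(f"intermediates:         {len(iset.candidates)}")
print(f"parents regenerated:   {iset.parents_reconstructed}")

table = rank_intermediates(iset, PruneConfig(metrics=("lomap", "tanimoto")))
print(table.ranked[["name", "canonical_form", "lomap_combined", "rank"]]
      .to_string(index=False))

s = summarize_pair(iset, "lomap")
print(f"parent-parent LOMAP score: {s.parent_pair_score:.3f}")
print(f"best intermediate (harmonic mean): {s.max_hm:.3f}")
```

prints

```
differing site groups: 3
intermediates:         6
parents regenerated:   True
  name    canonical_form  lomap_combined  rank
demoI5    COc1cccc(Cl)c1        0.740818     1
demoI0   Cc1cc(N)cc(F)c1        0.740818     2
demoI3 COc1cc(C)cc(Cl)c1        0.737130     3
demoI2      Nc1cccc(F)c1        0.737130     4
demoI1     COc1cccc(F)c1        0.726245     5
demoI4  Cc1cc(N)cc(Cl)c1        0.726245     6
parent-parent LOMAP score: 0.549
best intermediate (harmonic mean): 0.741
```

The parents differ at three substituent positions (F/Cl, CH3/H, OCH3/NH2)
on a shared benzene core, so recombination yields 2³ − 2 = 6 new molecules.
Every intermediate is closer to both parents (best harmonic-mean LOMAP
score 0.741) than the parents are to each other (0.549) — exactly the
property that makes it a useful stepping stone in a perturbation network.

## Command line

```bash
alchemid pair parents.sdf --pair-id set1 --outdir out \
    --metric lomap --metric tanimoto --combiner harmonic_mean
alchemid series ligands.smi --outdir out
alchemid score intermediates.sdf --parents parents.sdf
alchemid fixtures -k 3 --stereo --seed 7 --out demo_pair
alchemid analyze path legs.csv --direct AB
alchemid analyze convergence dg_timeseries.csv --threshold 0.1 --window 2.0
```

A pair run writes `<pair>_intermediates.sdf` (scores attached as SDF
properties), `<pair>_scores.csv` and `<pair>_report.json`; parents are named
`<pair>PA`/`<pair>PB` and intermediates `<pair>I0`, `<pair>I1`, … A series
run sweeps all unordered pairs and adds `series_summary.csv` plus
`series_stats.json` with the mean and best harmonic-mean similarity per
metric against the parent-pair baseline.

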