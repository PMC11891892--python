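# Methods

## Model and procedure

An intermediate for a parent pair (A, B) is a molecule whose scaffold is
the maximum common substructure (MCS) of the parents and whose substituents
are drawn site-by-site from either parent. With k substituent site groups
at which the parents differ, the cross combinations number 2^k − 2 (the
all-A and all-B vectors reproduce the parents and are excluded). The
generator is fully deterministic: for fixed inputs and configuration the
same candidate set is produced in the same order, and swapping the argument
order yields the same set of canonical structures.

### MCS search

Atoms match by element, bonds by exact order (an aromatic bond never
matches a single bond), ring atoms only match ring atoms, rings must be
complete in the core, and ring systems must map ring-by-ring
(`MatchFusedRingsStrict`). The last constraint matters: without it the
search can match the 10-atom *perimeter* of a fused bicycle as a single
large ring, silently misaligning the cores of two quinoline-like parents.
Chirality is deliberately not matched during the search — stereocenters are
handled downstream, and a pair whose shared-core stereocenters genuinely
disagree is caught by the parent-reconstruction check and flagged.

The MCS query is then placed onto each parent with all substructure
matches considered (up to 4096), keeping only placements whose induced
subgraph contains exactly the query's bonds (a placement with extra
induced bonds would make the "common" core structurally different in the
two parents). Ties among placements are broken by (1) fewest resulting
attachment sites — fewer sites means fewer spurious differences — then
(2) lexicographically smallest index maps, for determinism.

Defaults: `min_core_atoms = 3`, `timeout_s = 10` (generation for a pair of
drug-sized molecules takes well under a second; the cap only guards
pathological inputs).

### Site grouping and the fused-ring policy

Substituent sites whose non-core atoms are connected to each other outside
the core fall into one group. Because the core is connected, any such
connection closes a ring through the core, so this connected-component rule
is exactly the fused-ring rule: a ring fused to the core travels as one
substituent, whole, from one parent — no candidate ever contains a broken
ring. Groupings are computed per parent and merged (union of equivalence
relations): a group frozen in either parent is frozen overall.

Crossing bonds must be single bonds. A differing group with a double,
triple or aromatic crossing bond raises `UnsupportedBond`: cutting such a
bond would create ambiguous valence or stereochemistry. This also means an
*aromatic* ring fused to the core (e.g. a naphthalene extension of a
benzene core) cannot be treated as a removable substituent; saturated
fusions are fully supported.

### Stereochemistry-preserving reassembly

RDKit stores tetrahedral chirality as a parity relative to the order of an
atom's bond list, so deleting a substituent bond and appending a new one
scrambles parity unless corrected. Before detachment, every substituent
stereocenter's chiral tag and ordered neighbor list are recorded; the
product is grown from parent A's skeleton by deleting each differing
group's A-substituent and attaching the assigned fragment. After editing,
each stereocenter's recorded neighbor order is mapped onto the product
(the atom across a cut corresponds to the junction partner that took its
slot) and the tag is inverted when the permutation between recorded and
rebuilt order is odd. Three special cases:

- A chiral core atom that *loses* a substituent to hydrogen gets an
  explicit H as its junction partner (removed at the end with the
  chirality-safe `RemoveHs`), keeping its parity defined.
- A chiral core atom that *gains* a substituent where parent A had only
  hydrogen has its implicit H made explicit first, and the new bond takes
  the H's slot.
- Double-bond stereo is restored by re-imposing the recorded stereo flag
  with the stereo-reference atoms remapped to the atoms in the same
  geometric slots; if a reference atom vanished without replacement, the
  endpoint's other neighbor is used and the flag flipped. Restored stereo
  is materialized as directional bonds before the final cleanup pass so
  re-perception confirms rather than discards it.

The A-assignments of differing groups are *also* excised and reattached,
so the identity reconstructions genuinely exercise the machinery: the pair
is flagged (`parents_reconstructed = False`) unless both parents come back
byte-identical by isomeric canonical SMILES. Candidates are deduplicated
by isomeric canonical SMILES (first assembly in enumeration order wins)
and any candidate identical to a parent is dropped. Individual sanitization
failures are recorded per assignment, never raised.

Parents differing in formal charge are allowed through with a logged
warning; excluding charge perturbations is a policy choice left to the
caller.

## Scoring

Each candidate is scored against both parents:

- **tanimoto** — Tanimoto coefficient over 2048-bit, radius-2 circular
  fingerprint bit sets (ECFP4-equivalent). The test suite pins this to an
  explicit enumeration of circular environments; folded-bit hash
  collisions are possible in principle but absent for the tested sizes.
- **lomap** — exp(−β·(N_c + N_p − 2·N_mcs)) with β = 0.1 by default, the
  conventional decay constant; N are heavy-atom counts and the MCS is
  computed with the same settings as core identification. This is the
  MCS-distance term only: the LOMAP rule-based penalty multipliers
  (ring-size rules, net-charge rules) are intentionally not applied, so
  absolute values are not comparable to a full LOMAP implementation.
  No common substructure scores 0 with a warning.
- **shape_color** — delegated to a registered plugin
  (`register_shape_backend(name, fn)`) returning a score in [0, 1], e.g.
  a ROCS-style shape+feature overlay. A naive fallback named `"grid"`
  ships for testing only: voxel-occupancy Tanimoto (0.4 Å voxels, 1.7 Å
  atom spheres) of pre-aligned conformers, shape only, no alignment
  search. It is not a ROCS reproduction.

Per-parent scores are combined by `sum`, `weighted_sum` (weights ≥ 0, not
both zero) or `harmonic_mean` (2ab/(a+b), defined as 0 at (0,0), which
penalizes candidates resembling only one parent). With `normalize = True`
each metric's per-parent column is min–max normalized over the surviving
candidate pool first; a constant column maps to all zeros (it carries no
ranking information and avoids 0/0). Ranking sorts by the first listed
metric's combined score, descending, ties broken by canonical SMILES, so
the order is stable under permutation of the candidate list; other metrics
are reported alongside. The heavy-atom filter removes candidates whose
R-groups fall outside configured bounds (the implicit-H group counts 0
heavy atoms) and runs before normalization so filtered rows cannot distort
the pool.

Per-pair summaries report the parent–parent score as baseline and the mean
and maximum over candidates of the harmonic mean of each candidate's two
per-parent scores; series summaries average these over pairs. "Best"
means best by that metric's harmonic mean.

## Path analysis

Legs combine as ΔΔG = Σᵢ ΔΔGᵢ with sd = √(Σᵢ sdᵢ²) (independent runs);
the operation is associative over chains. Cycle closure reports
(via − direct) with the same root-sum-square propagation. Convergence of a
ΔG(t) series on a uniform grid is the earliest time t such that *every*
full window [u, u + w], u ≥ t satisfies the change bound — a transient
early plateau before a later jump does not count. "Change" is the max−min
spread within the window by default; an endpoint-difference variant
(`mode="endpoint"`) is provided because the plain-language definition
admits both readings. Defaults: threshold 0.1 kcal/mol, window 2.0 ns.
No interpolation is performed; the grid is taken as given. A series
shorter than the window raises `WindowTooLong`; a series whose final full
window violates the bound returns the `NOT_CONVERGED` sentinel.

## Synthetic fixtures

`alchemid.fixtures` builds parent pairs with a planted core and an exact,
known number of differing site groups: a scaffold template (benzene,
pyridine, an asymmetric quinoline for up to five sites, and a
benzene-with-adjacent-sites variant whose fused form carries a saturated
trimethylene bridge) decorated from a pool of small neutral substituents
(H, halogens, CH3, CF3, phenyl, OCH3, NH2, SCH3, and a chiral
sec-alcohol attached through its stereocenter). Two safeguards make the
planted difference count provable: substituents at differing sites always
start with different elements (so the MCS cannot grow into a difference),
and on symmetric scaffolds an element class is never reused across
differing sites — nor is a substituent name shared between the two
parents' differing picks — so the MCS cannot realign the ring to trade
one difference for another. Pairs are reproducible from a seed; the same
seed gives the same pair, different seeds the same difference count.

What the fixtures do *not* emulate: medicinal-chemistry-scale scaffolds
(cores here are 6–10 heavy atoms), charged or tautomeric substituents,
conformational strain, and 3D coordinates. Passing tests therefore
demonstrate graph-level correctness (counts, stereo parity, ring policy,
round trips), not chemical plausibility of intermediates for any real
target, and not the similarity statistics of any published benchmark
series.

## Test and script problem sizes

The test suite runs 50 generated pairs for the round-trip, stereo and
fused-ring checks, five values of k (1–5, up to 30 assemblies per pair)
for the count law, and 25 random-walk series for the convergence oracle —
sizes chosen so the full suite completes in a few seconds while touching
every code path. `scripts/acceptance.py` uses the canonical
three-differing-site pair, the smallest input that exercises the complete
workflow end to end.

## Known limitations

- One intermediate layer per pair: no recursive insertion of intermediates
  between A and I, and no multi-molecule (>2) simultaneous MCS.
- No 3D pose handling: cores are identified on the molecular graph, and
  the shipped shape backend assumes pre-aligned conformers.
- Aromatic-fused differing substituents are rejected rather than
  enumerated (see above).
- The LOMAP-style score omits the rule-based penalties; use it for
  relative ranking, not as a drop-in LOMAP replacement.
- Protonation-state and formal-charge handling is pass-through.
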