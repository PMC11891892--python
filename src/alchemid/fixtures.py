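"""Synthetic parent pairs with a planted core and controlled differences.

Each pair shares a scaffold exactly and differs at a known number of
substituent-site groups, so the whole pipeline (core identification,
grouping, enumeration, stereo preservation, pruning) is testable without
external data.  Substituents at differing sites are drawn from pools whose
first heavy atoms are element-distinct, and scaffolds with ring symmetry
additionally never reuse an element class across differing sites, so the
maximum common substructure cannot extend into, or realign across, the
planted differences: the number of differing site groups is known by
construction.

The pool is restricted to neutral single-attachment groups plus one
two-attachment trimethylene bridge used to close a ring fused to the core,
so pairs never differ in formal charge.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import InfeasibleSpec
from .records import MoleculeRecord

#: substituent name -> (SMILES branch text, element class).  ``H`` is the
#: implicit-hydrogen group; ``chiral`` carries a stereocenter at the
#: attachment atom.
SUBSTITUENT_POOL: dict[str, tuple[str, str]] = {
    "H": ("", "H"),
    "F": ("(F)", "F"),
    "Cl": ("(Cl)", "Cl"),
    "Br": ("(Br)", "Br"),
    "I": ("(I)", "I"),
    "CH3": ("(C)", "C"),
    "CF3": ("(C(F)(F)F)", "C"),
    "phenyl": ("(-c9ccccc9)", "C"),
    "chiral": ("([C@@H](O)CC)", "C"),
    "OCH3": ("(OC)", "O"),
    "NH2": ("(N)", "N"),
    "SCH3": ("(SC)", "S"),
}

#: scaffold name -> (format template, number of slots, has ring symmetry)
CORE_TEMPLATES: dict[str, tuple[str, int, bool]] = {
    # substituent slots at ring positions 1, 3, 5
    "benzene": ("c1c{0}cc{1}cc1{2}", 3, True),
    # slots on the carbons at positions 3, 5, 6; the ring N pins most maps
    "pyridine": ("c1nc{0}cc{1}c1{2}", 3, True),
    # asymmetric bicyclic, five slots, trivial automorphism group
    "quinoline": ("c1{0}c{1}c{2}c2nc{3}c{4}cc2c1", 5, False),
    # benzene with slots 0 and 1 on adjacent carbons (fusable) and slot 2 across
    "benzene_adjacent": ("c1cc{0}c{1}cc1{2}", 3, True),
}

#: same scaffold as ``benzene_adjacent`` with slots 0/1 replaced by a
#: saturated trimethylene bridge closing a ring fused to the core
_FUSED_TEMPLATE = "c1cc2c(cc1{0})CCC2"


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic parent pair."""

    core_template: str = "auto"
    n_sites: int = 3
    substituent_pool: tuple[str, ...] = tuple(SUBSTITUENT_POOL)
    differing_sites: int = 2
    with_stereocenter: bool = False
    with_fused_ring: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.differing_sites < 0:
            raise InfeasibleSpec("differing_sites must be >= 0")
        unknown = set(self.substituent_pool) - set(SUBSTITUENT_POOL)
        if unknown:
            raise InfeasibleSpec(f"unknown pool entries: {sorted(unknown)}")


def _resolve_template(spec: FixtureSpec) -> tuple[str, int, bool]:
    name = spec.core_template
    if spec.with_fused_ring:
        if name not in ("auto", "benzene_adjacent"):
            raise InfeasibleSpec("fused-ring fixtures use the benzene_adjacent core")
        name = "benzene_adjacent"
    elif name == "auto":
        name = "benzene" if spec.n_sites <= 3 else "quinoline"
    if name not in CORE_TEMPLATES:
        raise InfeasibleSpec(f"unknown core template {name!r}")
    tpl, max_sites, symmetric = CORE_TEMPLATES[name]
    if not 1 <= spec.n_sites <= max_sites:
        raise InfeasibleSpec(
            f"core {name!r} supports 1..{max_sites} sites, got {spec.n_sites}"
        )
    return tpl, max_sites, symmetric


def make_pair(spec: FixtureSpec) -> tuple[MoleculeRecord, MoleculeRecord, int]:
    """Build a parent pair differing at exactly ``spec.differing_sites``
    site groups (a fused-ring group counts as one); reproducible for a fixed
    seed.  Returns (parent_a, parent_b, expected_k)."""
    rng = random.Random(spec.seed)
    tpl, max_slots, symmetric = _resolve_template(spec)
    k = spec.differing_sites
    pool = {n: SUBSTITUENT_POOL[n] for n in spec.substituent_pool}

    n_groups = spec.n_sites - 1 if spec.with_fused_ring else spec.n_sites
    if spec.with_fused_ring:
        if spec.n_sites < 2:
            raise InfeasibleSpec("fused fixtures need at least 2 sites")
        if k < 1:
            raise InfeasibleSpec("the fused group always differs; need k >= 1")
    if k > n_groups:
        raise InfeasibleSpec(f"cannot realize {k} differences over {n_groups} groups")

    # group 0 is the (possibly fused) adjacent pair when fused; else each
    # slot is its own group
    group_ids = list(range(n_groups))
    if spec.with_fused_ring:
        differing = [0] + sorted(rng.sample(range(1, n_groups), k - 1))
    else:
        differing = sorted(rng.sample(group_ids, k))

    used_classes: set[str] = set()

    def draw(
        exclude: set[str], allow_h: bool = True, exclude_names: set[str] = frozenset()
    ) -> str:
        names = [
            n
            for n, (_b, cls) in pool.items()
            if cls not in exclude and (allow_h or n != "H") and n not in exclude_names
        ]
        if not names:
            raise InfeasibleSpec("substituent pool exhausted under class constraints")
        return rng.choice(sorted(names))

    picks_a: dict[int, str] = {}
    picks_b: dict[int, str] = {}
    stereo_slot = None
    reserved: set[str] = set()
    if spec.with_stereocenter:
        candidates = [g for g in differing if not (spec.with_fused_ring and g == 0)]
        if not candidates:
            raise InfeasibleSpec("no single-attachment differing site for a stereocenter")
        if "chiral" not in pool:
            raise InfeasibleSpec("pool lacks the chiral substituent")
        stereo_slot = rng.choice(candidates)
        reserved = {pool["chiral"][1]}  # keep the carbon class free for it

    # a substituent name used at a differing site of one parent never
    # reappears at any differing site of the other parent, so no common
    # fragment can invite a core realignment
    names_a: set[str] = set()
    names_b: set[str] = set()

    for g in group_ids:
        if spec.with_fused_ring and g == 0:
            continue  # handled by the template choice below
        if g in differing:
            if g == stereo_slot:
                a = "chiral"
            else:
                base = (used_classes | reserved) if symmetric else reserved
                a = draw(base, exclude_names=names_b)
            cls_a = pool[a][1]
            exclude = (used_classes | {cls_a}) if symmetric else {cls_a}
            b = draw(exclude, exclude_names=names_a | {a})
            if symmetric:
                used_classes |= {cls_a, pool[b][1]}
            picks_a[g], picks_b[g] = a, b
            names_a.add(a)
            names_b.add(b)
        else:
            base = (used_classes | reserved) if symmetric else reserved
            shared = draw(base, exclude_names=names_a | names_b)
            if symmetric:
                used_classes.add(pool[shared][1])
            picks_a[g] = picks_b[g] = shared

    def render(picks: dict[int, str], fused: bool) -> str:
        if spec.with_fused_ring:
            extra = [pool[picks[g]][0] for g in group_ids if g != 0]
            if fused:
                return _FUSED_TEMPLATE.format(*extra)
            # parent A: independent substituents at the two adjacent slots
            return tpl.format(picks_a_adj[0], picks_a_adj[1], *extra)
        subs = [pool[picks[g]][0] for g in group_ids]
        subs += [""] * (max_slots - len(subs))
        return tpl.format(*subs)

    picks_a_adj: list[str] = []
    if spec.with_fused_ring:
        # two independent single-attachment groups on parent A where parent B
        # carries the intact fused ring; the bridge is all-carbon and cyclic,
        # ring-membership matching keeps it out of any MCS extension
        for _ in range(2):
            name = draw(used_classes if symmetric else set(), allow_h=False)
            if symmetric:
                used_classes.add(pool[name][1])
            picks_a_adj.append(pool[name][0])

    smi_a = render(picks_a, fused=False)
    smi_b = render(picks_b, fused=spec.with_fused_ring)
    rec_a = MoleculeRecord.from_smiles(smi_a, f"fixA_s{spec.seed}")
    rec_b = MoleculeRecord.from_smiles(smi_b, f"fixB_s{spec.seed}")
    return rec_a, rec_b, k


def make_series(
    n_molecules: int,
    n_sites: int = 2,
    pool: Optional[Sequence[str]] = None,
    seed: int = 0,
) -> list[MoleculeRecord]:
    """A combinatorial congeneric family: every molecule is the benzene
    scaffold with one substituent per site drawn from a small per-site menu,
    so leave-one-out recovery through intermediates is guaranteed by
    combinatorics."""
    if n_sites > 3:
        raise InfeasibleSpec("series scaffold supports up to 3 sites")
    menus = {0: ["F", "Cl"], 1: ["CH3", "NH2"], 2: ["OCH3", "H"]}
    tpl, _slots, _sym = CORE_TEMPLATES["benzene"]
    rng = random.Random(seed)
    import itertools as _it

    all_combos = list(_it.product(*[menus[i] for i in range(n_sites)]))
    if n_molecules > len(all_combos):
        raise InfeasibleSpec(
            f"at most {len(all_combos)} distinct members with {n_sites} sites"
        )
    chosen = rng.sample(all_combos, n_molecules)
    out = []
    for i, combo in enumerate(sorted(chosen)):
        subs = [SUBSTITUENT_POOL[name][0] for name in combo]
        subs += [""] * (3 - len(subs))
        out.append(
            MoleculeRecord.from_smiles(tpl.format(*subs), f"member{i}")
        )
    return out
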