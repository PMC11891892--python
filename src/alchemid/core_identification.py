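"""Maximum-common-substructure core identification for a parent pair.

The common core of the two parents is the scaffold every intermediate is
built on.  This module finds the MCS, maps it onto both parents, locates the
attachment sites (core atoms with at least one non-core neighbor in either
parent) and groups sites whose substituents share a ring with the core, so
that enumeration never introduces a ring break.

Ring policy: the MCS search requires complete rings and ring-atoms matching
ring-atoms, so a ring is either entirely inside the core or entirely outside
of it in the mapped region; substituent rings that close back onto the core
(fused rings) are detected afterwards and frozen into a single site group.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Optional

from rdkit import Chem, rdBase
from rdkit.Chem import rdFMCS

from .errors import CoreTooSmall, McsTimeout
from .records import MoleculeRecord

logger = logging.getLogger(__name__)

#: cap on substructure matches considered per parent during tie-breaking
_MAX_MATCHES = 4096


@dataclass(frozen=True)
class McsConfig:
    """Settings for the MCS search.

    ``complete_rings_only`` and ``ring_matches_ring_only`` default to on:
    partial-ring cores would force ring cuts during enumeration, which the
    generator never performs.  Chirality is not matched during the search by
    default; stereo is restored later during reassembly.
    """

    ring_matches_ring_only: bool = True
    complete_rings_only: bool = True
    match_chiral_tag: bool = False
    timeout_s: int = 10
    min_core_atoms: int = 3

    def __post_init__(self) -> None:
        if self.timeout_s <= 0:
            raise ValueError("timeout_s must be positive")
        if self.min_core_atoms < 1:
            raise ValueError("min_core_atoms must be >= 1")


@dataclass(frozen=True)
class AttachmentSite:
    """A core atom where substituents attach, with the bonds crossing from
    core to non-core in each parent (pairs of parent atom indices,
    ``(core_side, substituent_side)``)."""

    core_atom: int
    label: int
    crossing_a: tuple[tuple[int, int], ...] = ()
    crossing_b: tuple[tuple[int, int], ...] = ()


@dataclass(frozen=True)
class CoreScaffold:
    """The MCS of a parent pair mapped onto both parents."""

    core_mol: Chem.Mol
    map_to_a: tuple[int, ...]  # core atom i -> parent A atom index
    map_to_b: tuple[int, ...]
    attachment_sites: tuple[AttachmentSite, ...] = ()
    smarts: str = ""

    @property
    def num_atoms(self) -> int:
        return len(self.map_to_a)

    def site_by_label(self, label: int) -> AttachmentSite:
        for site in self.attachment_sites:
            if site.label == label:
                return site
        raise KeyError(label)

    def to_debug_dict(self) -> dict:
        """Annotated SMARTS plus a JSON-ready site map, for debugging."""
        return {
            "smarts": self.smarts,
            "core_smiles": Chem.MolToSmiles(self.core_mol),
            "map_to_a": list(self.map_to_a),
            "map_to_b": list(self.map_to_b),
            "attachment_sites": [
                {
                    "label": s.label,
                    "core_atom": s.core_atom,
                    "crossing_a": [list(p) for p in s.crossing_a],
                    "crossing_b": [list(p) for p in s.crossing_b],
                }
                for s in self.attachment_sites
            ],
        }


def _mcs_params(cfg: McsConfig) -> rdFMCS.MCSParameters:
    p = rdFMCS.MCSParameters()
    p.AtomTyper = rdFMCS.AtomCompare.CompareElements
    p.BondTyper = rdFMCS.BondCompare.CompareOrderExact
    p.AtomCompareParameters.RingMatchesRingOnly = cfg.ring_matches_ring_only
    p.AtomCompareParameters.MatchChiralTag = cfg.match_chiral_tag
    p.BondCompareParameters.RingMatchesRingOnly = cfg.ring_matches_ring_only
    p.BondCompareParameters.CompleteRingsOnly = cfg.complete_rings_only
    # ring systems must map ring-by-ring; otherwise the search can match the
    # perimeter of a fused bicycle as one large ring and misalign the cores
    p.BondCompareParameters.MatchFusedRings = cfg.complete_rings_only
    p.BondCompareParameters.MatchFusedRingsStrict = cfg.complete_rings_only
    p.Timeout = int(cfg.timeout_s)
    return p


def _crossing_bonds(mol: Chem.Mol, core_atoms: set[int]) -> list[tuple[int, int]]:
    """Bonds (core_side, non_core_side) crossing the core boundary, sorted."""
    out = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if (i in core_atoms) != (j in core_atoms):
            c, s = (i, j) if i in core_atoms else (j, i)
            out.append((c, s))
    return sorted(out)


def _n_sites(mol_a: Chem.Mol, mol_b: Chem.Mol, match_a, match_b) -> int:
    """Number of distinct attachment sites a candidate mapping would produce."""
    sites: set[int] = set()
    for mol, match in ((mol_a, match_a), (mol_b, match_b)):
        core = set(match)
        pos = {a: i for i, a in enumerate(match)}
        for c, _s in _crossing_bonds(mol, core):
            sites.add(pos[c])
    return len(sites)


def find_core(
    mol_a: MoleculeRecord, mol_b: MoleculeRecord, cfg: Optional[McsConfig] = None
) -> CoreScaffold:
    """Find the MCS of two parents and map it deterministically onto both.

    When several maximal atom mappings exist the one producing the fewest
    attachment sites is chosen, then the lexicographically smallest pair of
    index maps, so repeated runs agree.

    Raises
    ------
    CoreTooSmall
        if the MCS has fewer than ``cfg.min_core_atoms`` atoms.
    McsTimeout
        if the search was cancelled by the time budget.
    """
    cfg = cfg or McsConfig()
    res = rdFMCS.FindMCS([mol_a.mol, mol_b.mol], _mcs_params(cfg))
    if res.canceled:
        raise McsTimeout(f"MCS search exceeded {cfg.timeout_s}s")
    if res.numAtoms < cfg.min_core_atoms:
        raise CoreTooSmall(
            f"MCS has {res.numAtoms} atoms; minimum is {cfg.min_core_atoms}"
        )
    query = res.queryMol
    qbonds = {
        frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx())) for b in query.GetBonds()
    }

    def consistent(mol: Chem.Mol, match) -> bool:
        # the induced subgraph on the matched atoms must contain exactly the
        # query's bonds; extra bonds would make the "common" core differ
        # between the two parents
        mset = set(match)
        pos = {a: i for i, a in enumerate(match)}
        induced = {
            frozenset((pos[b.GetBeginAtomIdx()], pos[b.GetEndAtomIdx()]))
            for b in mol.GetBonds()
            if b.GetBeginAtomIdx() in mset and b.GetEndAtomIdx() in mset
        }
        return induced == qbonds

    matches_a = [
        m
        for m in mol_a.mol.GetSubstructMatches(
            query,
            uniquify=False,
            maxMatches=_MAX_MATCHES,
            useChirality=cfg.match_chiral_tag,
        )
        if consistent(mol_a.mol, m)
    ]
    matches_b = [
        m
        for m in mol_b.mol.GetSubstructMatches(
            query,
            uniquify=False,
            maxMatches=_MAX_MATCHES,
            useChirality=cfg.match_chiral_tag,
        )
        if consistent(mol_b.mol, m)
    ]
    if not matches_a or not matches_b:
        raise CoreTooSmall(
            "no bond-consistent placement of the MCS on both parents"
        )

    best = min(
        itertools.product(sorted(matches_a), sorted(matches_b)),
        key=lambda ab: (_n_sites(mol_a.mol, mol_b.mol, ab[0], ab[1]), ab[0], ab[1]),
    )
    map_a, map_b = best

    core_mol = _extract_core(mol_a.mol, map_a)
    scaffold = CoreScaffold(
        core_mol=core_mol,
        map_to_a=tuple(map_a),
        map_to_b=tuple(map_b),
        smarts=res.smartsString,
    )
    return locate_attachment_sites(scaffold, mol_a, mol_b)


def _extract_core(mol: Chem.Mol, match) -> Chem.Mol:
    """Chemical subgraph of ``mol`` induced by the matched atoms, with core
    atom order following the match order."""
    emol = Chem.RWMol()
    old2new = {}
    for new_i, old_i in enumerate(match):
        atom = mol.GetAtomWithIdx(old_i)
        na = Chem.Atom(atom.GetAtomicNum())
        na.SetFormalCharge(atom.GetFormalCharge())
        na.SetIsAromatic(atom.GetIsAromatic())
        na.SetNoImplicit(True)
        emol.AddAtom(na)
        old2new[old_i] = new_i
    core = set(match)
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in core and j in core:
            emol.AddBond(old2new[i], old2new[j], bond.GetBondType())
    m = emol.GetMol()
    with rdBase.BlockLogs():
        try:
            Chem.SanitizeMol(
                m,
                Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE,
            )
        except Exception:  # pragma: no cover - core extract is permissive
            pass
    return m


def locate_attachment_sites(
    core: CoreScaffold, mol_a: MoleculeRecord, mol_b: MoleculeRecord
) -> CoreScaffold:
    """Fill in the attachment sites of an already-mapped core.

    A site is a core atom with at least one bonded neighbor outside the
    mapped core in either parent; it carries the crossing bonds per parent.
    Labels are unique positive integers assigned in core-atom order.
    """
    core_a = set(core.map_to_a)
    core_b = set(core.map_to_b)
    pos_a = {a: i for i, a in enumerate(core.map_to_a)}
    pos_b = {b: i for i, b in enumerate(core.map_to_b)}

    per_core: dict[int, dict[str, list[tuple[int, int]]]] = {}
    for which, mol, cset, pos in (
        ("a", mol_a.mol, core_a, pos_a),
        ("b", mol_b.mol, core_b, pos_b),
    ):
        for c, s in _crossing_bonds(mol, cset):
            entry = per_core.setdefault(pos[c], {"a": [], "b": []})
            entry[which].append((c, s))

    sites = []
    for label, core_atom in enumerate(sorted(per_core), start=1):
        entry = per_core[core_atom]
        sites.append(
            AttachmentSite(
                core_atom=core_atom,
                label=label,
                crossing_a=tuple(entry["a"]),
                crossing_b=tuple(entry["b"]),
            )
        )
    return replace(core, attachment_sites=tuple(sites))


def group_fused_sites(
    core: CoreScaffold, mol: MoleculeRecord, which: str = "A"
) -> list[set[int]]:
    """Partition site labels for one parent: sites fall in the same group
    iff their substituent atoms are connected outside the core.

    Because the core is connected, any non-core path linking two core atoms
    closes a ring through the core; freezing such sites into one group is
    exactly the fused-ring policy — the attached ring travels as one
    substituent and no ring is ever cut.  Sites with no fused partner are
    singleton groups.
    """
    which = which.upper()
    if which not in ("A", "B"):
        raise ValueError("which must be 'A' or 'B'")
    m = mol.mol
    core_atoms = set(core.map_to_a if which == "A" else core.map_to_b)

    # connected components of the non-core atoms
    comp: dict[int, int] = {}
    next_comp = 0
    for atom in m.GetAtoms():
        i = atom.GetIdx()
        if i in core_atoms or i in comp:
            continue
        stack = [i]
        comp[i] = next_comp
        while stack:
            j = stack.pop()
            for nbr in m.GetAtomWithIdx(j).GetNeighbors():
                k = nbr.GetIdx()
                if k not in core_atoms and k not in comp:
                    comp[k] = next_comp
                    stack.append(k)
        next_comp += 1

    comp_to_sites: dict[int, set[int]] = {}
    grouped: set[int] = set()
    for site in core.attachment_sites:
        crossing = site.crossing_a if which == "A" else site.crossing_b
        for _c, s in crossing:
            comp_to_sites.setdefault(comp[s], set()).add(site.label)
            grouped.add(site.label)

    partition = [sites for sites in comp_to_sites.values()]
    # sites with no substituent in this parent (implicit H side) are singletons
    for site in core.attachment_sites:
        if site.label not in grouped:
            partition.append({site.label})
    return sorted(partition, key=min)


def merge_partitions(*partitions: list[set[int]]) -> list[set[int]]:
    """Union of equivalence relations: a group frozen in either parent is
    frozen overall.  Result is sorted by smallest member; groups are disjoint
    and cover all labels."""
    parent: dict[int, int] = {}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for part in partitions:
        for group in part:
            members = sorted(group)
            for m in members:
                parent.setdefault(m, m)
            for m in members[1:]:
                union(members[0], m)

    out: dict[int, set[int]] = {}
    for x in parent:
        out.setdefault(find(x), set()).add(x)
    return sorted(out.values(), key=min)


def site_partition(
    core: CoreScaffold, mol_a: MoleculeRecord, mol_b: MoleculeRecord
) -> list[set[int]]:
    """Merged fused-site partition over both parents."""
    return merge_partitions(
        group_fused_sites(core, mol_a, "A"), group_fused_sites(core, mol_b, "B")
    )
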