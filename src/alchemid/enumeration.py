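"""R-group table construction, enumeration and stereo-preserving reassembly.

Given a mapped core, each parent's substituents are excised by cutting only
the single bonds crossing from core to non-core (grouped so that rings fused
to the core travel as one substituent and are never cut).  Intermediates are
then built by re-forming those bonds for every cross-parent combination of
the differing substituent groups.

RDKit's ``molzip`` joins labeled fragments but drops tetrahedral parity and
double-bond stereo at the junction, so reassembly here is done with explicit
bookkeeping: for every stereocenter the ordered neighbor list is recorded
before detachment, and after the new bonds are formed the chiral tag is
flipped whenever the permutation between the recorded and the rebuilt
neighbor order is odd.  Double-bond stereo is restored by remapping the
stereo-reference atoms onto the atoms occupying the same geometric slot in
the product.  Correctness is checked globally by rebuilding both parents
from their own substituents and comparing isomeric canonical SMILES.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdkit import Chem, rdBase

from .core_identification import (
    AttachmentSite,
    CoreScaffold,
    McsConfig,
    find_core,
    site_partition,
)
from .errors import AssemblyFailure, RingCutRequired, UnsupportedBond
from .records import MoleculeRecord

logger = logging.getLogger(__name__)

_FLIP_TAG = {
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: Chem.ChiralType.CHI_TETRAHEDRAL_CCW,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: Chem.ChiralType.CHI_TETRAHEDRAL_CW,
}

_FLIP_BOND = {
    Chem.BondStereo.STEREOZ: Chem.BondStereo.STEREOE,
    Chem.BondStereo.STEREOE: Chem.BondStereo.STEREOZ,
    Chem.BondStereo.STEREOCIS: Chem.BondStereo.STEREOTRANS,
    Chem.BondStereo.STEREOTRANS: Chem.BondStereo.STEREOCIS,
}


def _perm_parity(src: Sequence[int], dst: Sequence[int]) -> int:
    """Parity (0/1) of the permutation carrying ``src`` onto ``dst``."""
    if sorted(src) != sorted(dst):
        raise ValueError("lists are not permutations of each other")
    pos = {v: i for i, v in enumerate(dst)}
    perm = [pos[v] for v in src]
    inv = sum(
        1
        for i in range(len(perm))
        for j in range(i + 1, len(perm))
        if perm[i] > perm[j]
    )
    return inv % 2


@dataclass(frozen=True)
class RGroup:
    """One parent's substituent at a site group, with one open valence per
    crossing bond and the stereo captured before detachment."""

    parent_origin: str  # "A" | "B"
    site_group: frozenset[int]
    atom_indices: tuple[int, ...]  # parent atom indices; empty = implicit H
    #: (site_label, core_side_parent_idx, substituent_side_parent_idx)
    crossing: tuple[tuple[int, int, int], ...]
    #: substituent atom idx -> (chiral tag, ordered neighbor parent idxs)
    stereo_record: dict[int, tuple[Chem.ChiralType, tuple[int, ...]]] = field(
        default_factory=dict
    )
    #: (begin, end, bond stereo, (stereo_atom_1, stereo_atom_2))
    bond_stereo_record: tuple[tuple[int, int, Chem.BondStereo, tuple[int, int]], ...] = ()
    fragment_smiles: str = ""

    @property
    def heavy_atom_count(self) -> int:
        return len(self.atom_indices)

    @property
    def is_implicit_h(self) -> bool:
        return not self.atom_indices

    def crossing_at(self, label: int) -> list[tuple[int, int, int]]:
        return [c for c in self.crossing if c[0] == label]


@dataclass(frozen=True)
class RGroupTable:
    """Per-site-group substituents of both parents on a shared core."""

    parent_a: MoleculeRecord
    parent_b: MoleculeRecord
    core: CoreScaffold
    site_groups: tuple[frozenset[int], ...]
    entries: tuple[tuple[RGroup, RGroup], ...]  # (from A, from B) per group
    differing: tuple[bool, ...]

    @property
    def differing_indices(self) -> tuple[int, ...]:
        return tuple(i for i, d in enumerate(self.differing) if d)

    @property
    def n_differing(self) -> int:
        return sum(self.differing)


@dataclass
class IntermediateSet:
    """Assembled, sanitized, deduplicated candidates for one parent pair."""

    pair_id: str
    parent_a: MoleculeRecord
    parent_b: MoleculeRecord
    core: CoreScaffold
    table: RGroupTable
    candidates: list[MoleculeRecord]
    parents_reconstructed: bool
    failures: list[tuple[tuple[str, ...], str]] = field(default_factory=list)

    @property
    def provenance(self) -> dict[str, tuple[str, ...]]:
        """Candidate name -> per-differing-group origin vector."""
        return {c.name: tuple(c.meta["assignment"]) for c in self.candidates}

    def rgroups_of(self, candidate: MoleculeRecord) -> list[RGroup]:
        """The substituent chosen at every site group of a candidate."""
        assignment = candidate.meta["assignment"]
        chosen = dict(zip(self.table.differing_indices, assignment))
        out = []
        for gi, (rg_a, rg_b) in enumerate(self.table.entries):
            origin = chosen.get(gi, "A")
            out.append(rg_a if origin == "A" else rg_b)
        return out


# ---------------------------------------------------------------------------
# R-group table construction
# ---------------------------------------------------------------------------


def _component_from(mol: Chem.Mol, seeds: set[int], core: set[int]) -> set[int]:
    """All non-core atoms reachable from the seed atoms without crossing core."""
    seen = set(seeds)
    stack = list(seeds)
    while stack:
        i = stack.pop()
        for nbr in mol.GetAtomWithIdx(i).GetNeighbors():
            j = nbr.GetIdx()
            if j not in core and j not in seen:
                seen.add(j)
                stack.append(j)
    return seen


def _capture_stereo(
    mol: Chem.Mol, atoms: set[int]
) -> tuple[dict, tuple]:
    """Record tetrahedral tags (with neighbor order) and double-bond stereo
    for the substituent atoms, in parent index space."""
    stereo: dict[int, tuple[Chem.ChiralType, tuple[int, ...]]] = {}
    for i in atoms:
        atom = mol.GetAtomWithIdx(i)
        tag = atom.GetChiralTag()
        if tag in _FLIP_TAG:
            order = tuple(
                b.GetOtherAtomIdx(i) for b in atom.GetBonds()
            )
            stereo[i] = (tag, order)
    bonds = []
    for bond in mol.GetBonds():
        if bond.GetStereo() == Chem.BondStereo.STEREONONE:
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in atoms and j in atoms:
            sa = tuple(bond.GetStereoAtoms())
            if len(sa) == 2:
                bonds.append((i, j, bond.GetStereo(), (sa[0], sa[1])))
    return stereo, tuple(bonds)


def _fragment_smiles(
    mol: Chem.Mol, rg_atoms: tuple[int, ...], crossing
) -> str:
    """Canonical labeled-fragment SMILES with one ``[*:label]`` dummy per
    crossing bond; used to decide whether two parents' substituents differ."""
    if not rg_atoms:
        labels = sorted({c[0] for c in crossing})
        return "H:" + ",".join(str(l) for l in labels) if labels else "H"
    emol = Chem.RWMol()
    new = {}
    for i in sorted(rg_atoms):
        a = mol.GetAtomWithIdx(i)
        na = Chem.Atom(a.GetAtomicNum())
        na.SetFormalCharge(a.GetFormalCharge())
        na.SetChiralTag(a.GetChiralTag())
        na.SetNumExplicitHs(a.GetNumExplicitHs())
        na.SetIsAromatic(a.GetIsAromatic())
        new[i] = emol.AddAtom(na)
    atom_set = set(rg_atoms)
    for bond in sorted(mol.GetBonds(), key=lambda b: b.GetIdx()):
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in atom_set and j in atom_set:
            emol.AddBond(new[i], new[j], bond.GetBondType())
    # one labeled dummy per crossing bond, mapped onto the core neighbor slot
    dummy_for: dict[tuple[int, int], int] = {}
    for label, c_idx, s_idx in sorted(crossing):
        d = Chem.Atom(0)
        d.SetAtomMapNum(label)
        di = emol.AddAtom(d)
        emol.AddBond(new[s_idx], di, Chem.BondType.SINGLE)
        dummy_for[(s_idx, c_idx)] = di
    # fix tetrahedral parity relative to the new neighbor ordering
    for i in rg_atoms:
        a = mol.GetAtomWithIdx(i)
        tag = a.GetChiralTag()
        if tag not in _FLIP_TAG:
            continue
        src = []
        for b in a.GetBonds():
            n = b.GetOtherAtomIdx(i)
            src.append(new[n] if n in atom_set else dummy_for[(i, n)])
        prod_atom = emol.GetAtomWithIdx(new[i])
        dst = [b.GetOtherAtomIdx(new[i]) for b in prod_atom.GetBonds()]
        if _perm_parity(src, dst):
            prod_atom.SetChiralTag(_FLIP_TAG[tag])
    # restore double-bond stereo with remapped reference atoms
    for bond in mol.GetBonds():
        if bond.GetStereo() == Chem.BondStereo.STEREONONE:
            continue
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if i in atom_set and j in atom_set:
            sa = list(bond.GetStereoAtoms())
            if len(sa) != 2:
                continue
            mapped = []
            for s, end in zip(sa, (i, j)):
                if s in atom_set:
                    mapped.append(new[s])
                elif (end, s) in dummy_for:
                    mapped.append(dummy_for[(end, s)])
                else:
                    mapped = []
                    break
            if mapped:
                nb = emol.GetBondBetweenAtoms(new[i], new[j])
                nb.SetStereoAtoms(mapped[0], mapped[1])
                nb.SetStereo(bond.GetStereo())
    frag = emol.GetMol()
    with rdBase.BlockLogs():
        try:
            Chem.SanitizeMol(frag)
        except Exception:
            Chem.SanitizeMol(
                frag,
                Chem.SanitizeFlags.SANITIZE_ALL
                ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
                ^ Chem.SanitizeFlags.SANITIZE_SETAROMATICITY,
            )
    return Chem.MolToSmiles(frag)


def _excise(
    mol: Chem.Mol,
    origin: str,
    group: frozenset[int],
    sites: dict[int, AttachmentSite],
    core_atoms: set[int],
) -> RGroup:
    crossing = []
    seeds = set()
    for label in sorted(group):
        site = sites[label]
        cross = site.crossing_a if origin == "A" else site.crossing_b
        for c, s in cross:
            crossing.append((label, c, s))
            seeds.add(s)
    atoms = tuple(sorted(_component_from(mol, seeds, core_atoms))) if seeds else ()
    stereo, bond_stereo = _capture_stereo(mol, set(atoms))
    return RGroup(
        parent_origin=origin,
        site_group=group,
        atom_indices=atoms,
        crossing=tuple(sorted(crossing)),
        stereo_record=stereo,
        bond_stereo_record=bond_stereo,
        fragment_smiles=_fragment_smiles(mol, atoms, tuple(sorted(crossing))),
    )


def build_rgroup_table(
    mol_a: MoleculeRecord,
    mol_b: MoleculeRecord,
    core: CoreScaffold,
    partition: Optional[list[set[int]]] = None,
) -> RGroupTable:
    """Excise both parents' substituents per site group and flag the groups
    where the two fragments differ (canonical labeled-fragment comparison,
    stereo included).

    Raises
    ------
    UnsupportedBond
        if a differing group has a crossing bond of order > 1 (aromatic
        included); cutting it would create ambiguous valence or stereo.
    RingCutRequired
        if a ring's crossing bonds span more than one site group, which
        would force a ring cut (indicates a grouping bug).
    """
    if partition is None:
        partition = site_partition(core, mol_a, mol_b)
    sites = {s.label: s for s in core.attachment_sites}
    core_a, core_b = set(core.map_to_a), set(core.map_to_b)

    groups = tuple(frozenset(g) for g in sorted(partition, key=min))
    entries = []
    differing = []
    for group in groups:
        rg_a = _excise(mol_a.mol, "A", group, sites, core_a)
        rg_b = _excise(mol_b.mol, "B", group, sites, core_b)
        entries.append((rg_a, rg_b))
        differing.append(rg_a.fragment_smiles != rg_b.fragment_smiles)

    table = RGroupTable(
        parent_a=mol_a,
        parent_b=mol_b,
        core=core,
        site_groups=groups,
        entries=tuple(entries),
        differing=tuple(differing),
    )
    _check_cuttable(table)
    return table


def _check_cuttable(table: RGroupTable) -> None:
    for gi in table.differing_indices:
        for rg, rec in (
            (table.entries[gi][0], table.parent_a),
            (table.entries[gi][1], table.parent_b),
        ):
            mol = rec.mol
            cut_bonds = set()
            for _label, c, s in rg.crossing:
                bond = mol.GetBondBetweenAtoms(c, s)
                if bond.GetBondType() != Chem.BondType.SINGLE:
                    raise UnsupportedBond(
                        f"crossing bond {c}-{s} in parent {rg.parent_origin} "
                        f"has order {bond.GetBondTypeAsDouble()}"
                    )
                cut_bonds.add(bond.GetIdx())
            # every ring touched by a cut must have all its crossings in this group
            ri = mol.GetRingInfo()
            for ring in ri.BondRings():
                ring_set = set(ring)
                if ring_set & cut_bonds:
                    core_atoms = set(
                        table.core.map_to_a
                        if rg.parent_origin == "A"
                        else table.core.map_to_b
                    )
                    for b_idx in ring_set - cut_bonds:
                        b = mol.GetBondWithIdx(b_idx)
                        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
                        if (i in core_atoms) != (j in core_atoms):
                            raise RingCutRequired(
                                f"ring crossing bond {i}-{j} outside group "
                                f"{sorted(rg.site_group)}"
                            )


# ---------------------------------------------------------------------------
# Enumeration
# ---------------------------------------------------------------------------


def enumerate_assignments(table: RGroupTable) -> list[tuple[str, ...]]:
    """All 2^k - 2 cross-parent origin vectors over the k differing site
    groups, in binary counting order with A = 0; the all-A and all-B vectors
    (the parents themselves) are excluded."""
    k = table.n_differing
    if k == 0:
        return []
    out = []
    for vec in itertools.product("AB", repeat=k):
        if len(set(vec)) == 1:
            continue
        out.append(vec)
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble(
    core: CoreScaffold,
    assignment: Sequence[str],
    table: RGroupTable,
    stereo_records: bool = True,
) -> MoleculeRecord:
    """Reattach one substituent per site group onto the core and restore the
    stereochemistry observed in the source parents.

    The product is grown from parent A's skeleton: every differing group's
    A-substituent is removed and the assigned parent's substituent is
    attached in its place (the A-assignments too, so that reassembly is
    genuinely exercised and the parents can be verified by reconstruction).
    ``stereo_records=False`` skips parity restoration for fragment
    stereocenters (used for fault-injection tests).

    Raises
    ------
    AssemblyFailure
        on valence or sanitization failure.
    """
    diff = table.differing_indices
    if len(assignment) != len(diff):
        raise ValueError("assignment length must equal number of differing groups")
    chosen = {
        gi: table.entries[gi][0 if origin == "A" else 1]
        for gi, origin in zip(diff, assignment)
    }
    mol_a = table.parent_a.mol
    mol_b = table.parent_b.mol
    b_to_a = {b: a for a, b in zip(table.core.map_to_a, table.core.map_to_b)}
    sites = {s.label: s for s in core.attachment_sites}

    # core atoms (A index space) that will gain more bonds than they lose and
    # are chiral need their implicit Hs made explicit so parity can be tracked
    needs_h = []
    for gi, rg in chosen.items():
        rg_a = table.entries[gi][0]
        for label in sorted(rg.site_group):
            n_new = len(rg.crossing_at(label))
            n_old = len(rg_a.crossing_at(label))
            if n_new > n_old:
                c_a = core.map_to_a[sites[label].core_atom]
                if mol_a.GetAtomWithIdx(c_a).GetChiralTag() in _FLIP_TAG:
                    needs_h.extend([c_a] * (n_new - n_old))

    skel = Chem.Mol(mol_a)
    for atom in skel.GetAtoms():
        atom.SetIntProp("_ai_skel", atom.GetIdx())
    if needs_h:
        skel = Chem.AddHs(skel, onlyOnAtoms=sorted(set(needs_h)))
        for atom in skel.GetAtoms():
            if not atom.HasProp("_ai_skel"):
                atom.SetIntProp("_ai_skel", atom.GetIdx())

    # pre-edit records for the skeleton (A index space of `skel`)
    skel_order = {
        i: tuple(b.GetOtherAtomIdx(i) for b in skel.GetAtomWithIdx(i).GetBonds())
        for i in range(skel.GetNumAtoms())
        if skel.GetAtomWithIdx(i).GetChiralTag() in _FLIP_TAG
    }
    skel_bond_stereo = []
    for bond in skel.GetBonds():
        if bond.GetStereo() != Chem.BondStereo.STEREONONE:
            sa = tuple(bond.GetStereoAtoms())
            if len(sa) == 2:
                skel_bond_stereo.append(
                    (bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), bond.GetStereo(), sa)
                )

    rw = Chem.RWMol(skel)
    handle = [0]

    def new_handle(atom: Chem.Atom) -> int:
        handle[0] += 1
        atom.SetIntProp("_ai_h", handle[0])
        return handle[0]

    for atom in rw.GetAtoms():
        new_handle(atom)
    skel_handle = {
        atom.GetIntProp("_ai_skel"): atom.GetIntProp("_ai_h") for atom in rw.GetAtoms()
    }

    to_delete: set[int] = set()  # rw indices (stable until batch commit)
    partner_of_deleted: dict[int, int] = {}  # skel idx -> partner handle
    frag_core_partner: dict[tuple[int, int, int], int] = {}  # (gi, f_src, c_src) -> handle
    frag_handle: dict[tuple[int, int], int] = {}  # (gi, src_idx) -> handle
    frag_meta: dict[int, tuple[int, str]] = {}  # handle -> (gi, origin)
    consumed_h: dict[int, list[int]] = {}  # core rw idx -> available explicit H idxs

    for c_a in set(needs_h):
        hs = [
            n.GetIdx()
            for n in rw.GetAtomWithIdx(c_a).GetNeighbors()
            if n.GetAtomicNum() == 1
        ]
        consumed_h[c_a] = hs

    for gi in diff:
        rg_a = table.entries[gi][0]
        rg = chosen[gi]
        src_mol = mol_a if rg.parent_origin == "A" else mol_b
        to_delete.update(rg_a.atom_indices)  # skel heavy indices == molA indices

        # copy fragment atoms
        new_idx: dict[int, int] = {}
        for f in rg.atom_indices:
            a = src_mol.GetAtomWithIdx(f)
            na = Chem.Atom(a.GetAtomicNum())
            na.SetFormalCharge(a.GetFormalCharge())
            na.SetChiralTag(a.GetChiralTag())
            na.SetNumExplicitHs(a.GetNumExplicitHs())
            na.SetNoImplicit(a.GetNoImplicit())
            na.SetIsAromatic(a.GetIsAromatic())
            idx = rw.AddAtom(na)
            new_idx[f] = idx
            h = new_handle(rw.GetAtomWithIdx(idx))
            frag_handle[(gi, f)] = h
            frag_meta[h] = (gi, rg.parent_origin)
        atom_set = set(rg.atom_indices)
        for bond in sorted(src_mol.GetBonds(), key=lambda b: b.GetIdx()):
            i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
            if i in atom_set and j in atom_set:
                rw.AddBond(new_idx[i], new_idx[j], bond.GetBondType())
                rw.GetBondBetweenAtoms(new_idx[i], new_idx[j]).SetIsAromatic(
                    bond.GetIsAromatic()
                )

        # junctions, paired per site label by position
        for label in sorted(rg.site_group):
            list_a = rg_a.crossing_at(label)
            list_c = rg.crossing_at(label)
            c_rw = core.map_to_a[sites[label].core_atom]
            for i in range(max(len(list_a), len(list_c))):
                a_entry = list_a[i] if i < len(list_a) else None
                c_entry = list_c[i] if i < len(list_c) else None
                if c_entry is not None:
                    _label, c_src, f_src = c_entry
                    f_rw = new_idx[f_src]
                    if a_entry is not None:
                        partner_of_deleted[a_entry[2]] = frag_handle[(gi, f_src)]
                        rw.AddBond(c_rw, f_rw, Chem.BondType.SINGLE)
                    else:
                        # parent A had only H here: consume an explicit H if
                        # one was prepared (chiral core atom), else rely on
                        # implicit-H bookkeeping
                        core_atom = rw.GetAtomWithIdx(c_rw)
                        if consumed_h.get(c_rw):
                            h_idx = consumed_h[c_rw].pop()
                            to_delete.add(h_idx)
                            partner_of_deleted[
                                rw.GetAtomWithIdx(h_idx).GetIntProp("_ai_skel")
                            ] = frag_handle[(gi, f_src)]
                        elif core_atom.GetNumExplicitHs() > 0:
                            core_atom.SetNumExplicitHs(
                                core_atom.GetNumExplicitHs() - 1
                            )
                        rw.AddBond(c_rw, f_rw, Chem.BondType.SINGLE)
                    frag_core_partner[(gi, f_src, c_src)] = skel_handle[c_rw]
                else:
                    # substituent removed, nothing attached: H fills in; give
                    # a chiral core atom an explicit H partner so its parity
                    # stays defined
                    f_a = a_entry[2]
                    core_atom = rw.GetAtomWithIdx(c_rw)
                    if core_atom.GetChiralTag() in _FLIP_TAG:
                        h_atom = Chem.Atom(1)
                        h_idx = rw.AddAtom(h_atom)
                        h_h = new_handle(rw.GetAtomWithIdx(h_idx))
                        rw.AddBond(c_rw, h_idx, Chem.BondType.SINGLE)
                        partner_of_deleted[f_a] = h_h
                    else:
                        core_atom.SetNumExplicitHs(core_atom.GetNumExplicitHs() + 1)

    rw.BeginBatchEdit()
    for idx in to_delete:
        rw.RemoveAtom(int(idx))
    rw.CommitBatchEdit()

    h_to_idx = {a.GetIntProp("_ai_h"): a.GetIdx() for a in rw.GetAtoms()}
    surviving_skel = {
        a.GetIntProp("_ai_skel"): a.GetIdx()
        for a in rw.GetAtoms()
        if a.HasProp("_ai_skel")
    }

    def map_skel_neighbor(n: int) -> Optional[int]:
        if n in surviving_skel:
            return surviving_skel[n]
        h = partner_of_deleted.get(n)
        return h_to_idx.get(h) if h is not None else None

    def map_frag_neighbor(gi: int, rg: RGroup, f: int, n: int) -> Optional[int]:
        if (gi, n) in frag_handle:
            return h_to_idx.get(frag_handle[(gi, n)])
        h = frag_core_partner.get((gi, f, n))
        return h_to_idx.get(h) if h is not None else None

    # --- tetrahedral parity restoration -----------------------------------
    for atom in rw.GetAtoms():
        tag = atom.GetChiralTag()
        if tag not in _FLIP_TAG:
            continue
        idx = atom.GetIdx()
        if atom.HasProp("_ai_skel"):
            skel_idx = atom.GetIntProp("_ai_skel")
            src = [map_skel_neighbor(n) for n in skel_order.get(skel_idx, ())]
        else:
            gi, _origin = frag_meta[atom.GetIntProp("_ai_h")]
            rg = chosen[gi]
            f = next(s for (g, s), h in frag_handle.items()
                     if g == gi and h == atom.GetIntProp("_ai_h"))
            if f not in rg.stereo_record or not stereo_records:
                continue  # no record: parity left as copied
            _tag, order = rg.stereo_record[f]
            src = [map_frag_neighbor(gi, rg, f, n) for n in order]
        dst = [b.GetOtherAtomIdx(idx) for b in atom.GetBonds()]
        if None in src or sorted(src) != sorted(dst):
            continue  # defensive: leave parity untouched if unmappable
        if _perm_parity(src, dst):
            atom.SetChiralTag(_FLIP_TAG[tag])

    # --- double-bond stereo restoration ------------------------------------
    def restore_bond(i: int, j: int, stereo, sa_pair, mapper) -> None:
        """``mapper(end_src, n)`` maps source neighbor ``n`` of source atom
        ``end_src`` onto its product index (or None)."""
        pi, pj = mapper(j, i), mapper(i, j)
        if pi is None or pj is None:
            return
        bond = rw.GetBondBetweenAtoms(pi, pj)
        if bond is None or bond.GetBondType() == Chem.BondType.SINGLE:
            return
        mapped = []
        flip = False
        for s, end_src, end_prod in zip(sa_pair, (i, j), (pi, pj)):
            ps = mapper(end_src, s)
            if ps is None:
                # reference neighbor vanished without replacement: use the
                # endpoint's other heavy neighbor, on the opposite side
                others = [
                    b.GetOtherAtomIdx(end_prod)
                    for b in rw.GetAtomWithIdx(end_prod).GetBonds()
                    if b.GetOtherAtomIdx(end_prod) not in (pi, pj)
                ]
                if not others:
                    return
                ps = others[0]
                flip = not flip
            mapped.append(ps)
        bond.SetStereoAtoms(mapped[0], mapped[1])
        bond.SetStereo(_FLIP_BOND[stereo] if flip else stereo)

    for i, j, stereo, sa in skel_bond_stereo:
        restore_bond(i, j, stereo, sa, lambda _end, n: map_skel_neighbor(n))
    for gi in diff:
        rg = chosen[gi]
        for i, j, stereo, sa in rg.bond_stereo_record:
            restore_bond(
                i, j, stereo, sa,
                lambda end, n, gi=gi, rg=rg: map_frag_neighbor(gi, rg, end, n),
            )

    mol = rw.GetMol()
    # provenance annotations (survive into the final record)
    for atom in mol.GetAtoms():
        if atom.HasProp("_ai_skel"):
            skel_idx = atom.GetIntProp("_ai_skel")
            role = "core" if skel_idx in set(core.map_to_a) else "shared"
            atom.SetProp("ai_role", role)
            atom.SetProp("ai_origin", "A")
            atom.SetIntProp("ai_parent_idx", skel_idx)
        else:
            gi, origin = frag_meta[atom.GetIntProp("_ai_h")]
            f = next(
                s for (g, s), h in frag_handle.items()
                if g == gi and h == atom.GetIntProp("_ai_h")
            )
            atom.SetProp("ai_role", "rgroup")
            atom.SetProp("ai_origin", origin)
            atom.SetIntProp("ai_parent_idx", f)
            atom.SetIntProp("ai_group", gi)

    try:
        Chem.SanitizeMol(mol)
        # materialize directional single bonds from the restored stereo enums
        # so the cleanup pass below can re-derive (not discard) them
        Chem.SetDoubleBondNeighborDirections(mol)
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
        mol = Chem.RemoveHs(mol)
    except Exception as exc:
        raise AssemblyFailure(str(exc)) from exc
    if len(Chem.GetMolFrags(mol)) != 1:
        raise AssemblyFailure("assembly produced a disconnected molecule")
    return MoleculeRecord(mol=mol, name="", meta={"assignment": tuple(assignment)})


def verify_parent_reconstruction(
    mol_a: MoleculeRecord,
    mol_b: MoleculeRecord,
    core: CoreScaffold,
    table: RGroupTable,
    stereo_records: bool = True,
) -> bool:
    """True iff reattaching each parent's own substituents onto the core
    regenerates that parent exactly (isomeric canonical SMILES)."""
    k = table.n_differing
    for origin, rec in (("A", mol_a), ("B", mol_b)):
        try:
            rebuilt = assemble(
                core, (origin,) * k, table, stereo_records=stereo_records
            )
        except AssemblyFailure as exc:
            logger.warning("parent %s reconstruction failed: %s", origin, exc)
            return False
        if rebuilt.canonical_form != rec.canonical_form:
            logger.warning(
                "parent %s not regenerated: %s != %s",
                origin,
                rebuilt.canonical_form,
                rec.canonical_form,
            )
            return False
    return True


def generate_intermediates(
    mol_a: MoleculeRecord,
    mol_b: MoleculeRecord,
    cfg: Optional[McsConfig] = None,
    pair_id: Optional[str] = None,
) -> IntermediateSet:
    """End-to-end generation for one parent pair.

    Workflow: find the MCS core, locate and group attachment sites, build
    the R-group table, enumerate all cross-parent combinations of the
    differing groups, reassemble with stereo restored, sanitize, drop
    duplicates and parent-identical products, and verify that both parents
    are regenerated from their own substituents.  Individual assembly
    failures are recorded, never raised.
    """
    if pair_id is None:
        pair_id = f"{mol_a.name}~{mol_b.name}" if mol_a.name or mol_b.name else "pair"
    charge_a = Chem.GetFormalCharge(mol_a.mol)
    charge_b = Chem.GetFormalCharge(mol_b.mol)
    if charge_a != charge_b:
        logger.warning(
            "parents of pair %s differ in formal charge (%d vs %d); intermediates "
            "may mix charge states",
            pair_id,
            charge_a,
            charge_b,
        )
    core = find_core(mol_a, mol_b, cfg)
    partition = site_partition(core, mol_a, mol_b)
    table = build_rgroup_table(mol_a, mol_b, core, partition)

    candidates: list[MoleculeRecord] = []
    failures: list[tuple[tuple[str, ...], str]] = []
    seen = {mol_a.canonical_form, mol_b.canonical_form}
    for assignment in enumerate_assignments(table):
        try:
            cand = assemble(core, assignment, table)
        except AssemblyFailure as exc:
            failures.append((assignment, str(exc)))
            continue
        key = cand.canonical_form
        if key in seen:
            continue
        seen.add(key)
        cand.name = f"{pair_id}I{len(candidates)}"
        candidates.append(cand)

    reconstructed = verify_parent_reconstruction(mol_a, mol_b, core, table)
    if not reconstructed:
        logger.warning("pair %s flagged: parents not regenerated", pair_id)
    return IntermediateSet(
        pair_id=pair_id,
        parent_a=mol_a,
        parent_b=mol_b,
        core=core,
        table=table,
        candidates=candidates,
        parents_reconstructed=reconstructed,
        failures=failures,
    )
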