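"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive and self-contained so it can serve as
ground truth for the package's optimized paths: exhaustive common-subgraph
search, explicit circular-environment enumeration for fingerprint Tanimoto,
an RDKit R-group-decomposition + molzip recombination route, and a direct
window scan for convergence times.
"""

from __future__ import annotations

import itertools

import networkx as nx
from networkx.algorithms import isomorphism
from rdkit import Chem


# ---------------------------------------------------------------------------
# Exhaustive maximum common connected subgraph (tiny molecules only)
# ---------------------------------------------------------------------------


def _to_nx(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), z=atom.GetAtomicNum())
    for bond in mol.GetBonds():
        g.add_edge(
            bond.GetBeginAtomIdx(),
            bond.GetEndAtomIdx(),
            order=bond.GetBondTypeAsDouble(),
        )
    return g


def _connected_subsets(g: nx.Graph, size: int):
    """All connected node subsets of the given size (exponential; tiny only)."""
    seen = set()
    for start in g.nodes:
        frontier = [frozenset([start])]
        while frontier:
            cur = frontier.pop()
            if len(cur) == size:
                if cur not in seen:
                    seen.add(cur)
                    yield cur
                continue
            grow = {n for c in cur for n in g.neighbors(c)} - cur
            for n in grow:
                nxt = cur | {n}
                if len(nxt) <= size and nxt not in seen or len(nxt) < size:
                    frontier.append(nxt)
    return


def max_common_subgraph_size(smiles_a: str, smiles_b: str, max_atoms: int = 12) -> int:
    """Size (atom count) of the largest connected induced common subgraph
    under element and exact bond-order matching.  Exhaustive enumeration;
    only usable for molecules up to ~12 heavy atoms."""
    ga = _to_nx(Chem.MolFromSmiles(smiles_a))
    gb = _to_nx(Chem.MolFromSmiles(smiles_b))
    node_match = isomorphism.categorical_node_match("z", 0)
    edge_match = isomorphism.categorical_edge_match("order", 0)
    upper = min(len(ga), len(gb), max_atoms)
    for size in range(upper, 0, -1):
        for nodes in {frozenset(s) for s in _connected_subsets(ga, size)}:
            sub = ga.subgraph(nodes)
            gm = isomorphism.GraphMatcher(
                gb, sub, node_match=node_match, edge_match=edge_match
            )
            if gm.subgraph_is_isomorphic():
                return size
    return 0


# ---------------------------------------------------------------------------
# Circular-environment Tanimoto
# ---------------------------------------------------------------------------


def _invariant_labels(mols) -> dict:
    """Assign one small integer per distinct heavy-atom invariant tuple
    (element, degree, total Hs, charge, ring membership) across molecules."""
    labels: dict[tuple, int] = {}
    for mol in mols:
        for atom in mol.GetAtoms():
            key = (
                atom.GetAtomicNum(),
                atom.GetDegree(),
                atom.GetTotalNumHs(),
                atom.GetFormalCharge(),
                atom.IsInRing(),
            )
            labels.setdefault(key, len(labels) + 1)
    return labels


def environment_set(mol: Chem.Mol, labels: dict, radius: int = 2) -> set[str]:
    """The set of canonical radius-0..r circular environments, with atoms
    tagged by their full-molecule invariant label (mirrors what a circular
    fingerprint hashes, without the hashing)."""
    tagged = Chem.Mol(mol)
    for atom in tagged.GetAtoms():
        key = (
            atom.GetAtomicNum(),
            atom.GetDegree(),
            atom.GetTotalNumHs(),
            atom.GetFormalCharge(),
            atom.IsInRing(),
        )
        atom.SetAtomMapNum(labels[key])
    # circular fingerprints deduplicate environments globally by bond set,
    # keeping the occurrence with the smallest radius; emulate that, then
    # name each surviving environment by its rooted canonical form
    envs: set[str] = set()
    seen_bond_sets: set[frozenset[int]] = set()
    for r in range(radius + 1):
        for atom in tagged.GetAtoms():
            if r == 0:
                envs.add(f"r0:{atom.GetAtomMapNum()}")
                continue
            bond_ids = frozenset(
                Chem.FindAtomEnvironmentOfRadiusN(tagged, r, atom.GetIdx(), useHs=False)
            )
            if not bond_ids or bond_ids in seen_bond_sets:
                continue
            seen_bond_sets.add(bond_ids)
            atoms = {atom.GetIdx()}
            for b in bond_ids:
                bond = tagged.GetBondWithIdx(b)
                atoms.update((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
            smi = Chem.MolFragmentToSmiles(
                tagged,
                atomsToUse=sorted(atoms),
                bondsToUse=sorted(bond_ids),
                rootedAtAtom=atom.GetIdx(),
                canonical=True,
            )
            envs.add(f"r{r}:{smi}")
    return envs


def environment_tanimoto(smiles_a: str, smiles_b: str, radius: int = 2) -> float:
    """Jaccard index of explicitly enumerated circular-environment sets."""
    ma, mb = Chem.MolFromSmiles(smiles_a), Chem.MolFromSmiles(smiles_b)
    labels = _invariant_labels([ma, mb])
    ea, eb = environment_set(ma, labels, radius), environment_set(mb, labels, radius)
    return len(ea & eb) / len(ea | eb)


# ---------------------------------------------------------------------------
# R-group decomposition + molzip recombination (achiral constitution only)
# ---------------------------------------------------------------------------


def molzip_recombinations(
    smiles_a: str, smiles_b: str, core_smarts: str
) -> set[str]:
    """All cross recombinations of the two parents' R-groups on the given
    core, built with RDKit's own R-group decomposition and molzip.  Returns
    non-isomeric canonical SMILES excluding the parents themselves; an
    independent route to the same constitution set (stereo not preserved,
    which is why the package does not use molzip)."""
    from rdkit.Chem import rdRGroupDecomposition as rgd

    core = Chem.MolFromSmarts(core_smarts)
    mols = [Chem.MolFromSmiles(smiles_a), Chem.MolFromSmiles(smiles_b)]
    result, unmatched = rgd.RGroupDecompose([core], mols, asSmiles=False)
    assert not unmatched, "oracle: parents did not match the core"
    rows = result
    labels = sorted({k for row in rows for k in row if k != "Core"})
    parents_plain = set()
    for m in mols:
        m2 = Chem.Mol(m)
        Chem.RemoveStereochemistry(m2)
        parents_plain.add(Chem.MolToSmiles(m2))
    out: set[str] = set()
    for combo in itertools.product((0, 1), repeat=len(labels)):
        pieces = [rows[0]["Core"]]
        for which, label in zip(combo, labels):
            pieces.append(rows[which][label])
        combined = pieces[0]
        for p in pieces[1:]:
            combined = Chem.CombineMols(combined, p)
        zipped = Chem.molzip(combined)
        Chem.SanitizeMol(zipped)
        zipped = Chem.RemoveHs(zipped)
        Chem.RemoveStereochemistry(zipped)
        smi = Chem.MolToSmiles(zipped)
        if smi not in parents_plain:
            out.add(smi)
    return out


# ---------------------------------------------------------------------------
# Convergence window scan
# ---------------------------------------------------------------------------


def convergence_scan(times, values, threshold: float, window: float) -> float | None:
    """Direct O(n * w) scan: earliest t such that every full window starting
    at or after t has max-min spread <= threshold.  None = not converged."""
    n = len(times)
    dt = times[1] - times[0]
    w = int(round(window / dt))
    ok = []
    for i in range(n - w):
        seg = list(values[i : i + w + 1])
        ok.append(max(seg) - min(seg) <= threshold + 1e-12)
    if not ok:
        return None
    last_bad = -1
    for i, good in enumerate(ok):
        if not good:
            last_bad = i
    if last_bad == -1:
        return times[0]
    if last_bad + 1 >= len(ok):
        return None
    return times[last_bad + 1]
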