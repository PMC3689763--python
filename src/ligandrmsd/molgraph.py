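"""Element-labeled molecular graphs and atom correspondences.

Comparing two bound copies of a ligand needs an atom-to-atom correspondence.
Three routes are tried in priority order:

1. **name match** — both copies are the same chemical component and their
   PDB atom names correspond one-to-one;
2. **graph isomorphism** — the element-labeled bond graphs are isomorphic
   (covers renamed/renumbered atoms and, importantly, yields all
   automorphisms of symmetric molecules such as benzamidine's ring flip);
3. **maximum common subgraph (MCS)** — the largest connected element-matched
   substructure shared by the two graphs (covers different compounds).

When several candidate mappings exist (automorphisms, multiple MCS
embeddings), up to ``max_candidates`` are enumerated in a deterministic
order and the one minimizing the optimal superposition RMSD is chosen —
this is the symmetry correction that keeps an RMSD from being inflated by
an arbitrary labeling of equivalent atoms.

Bond orders are deliberately ignored (PDB files carry no reliable orders);
a node is its element, an edge is a bond.  MCS detection is delegated to
RDKit's FMCS; everything is exercised against an exhaustive-search oracle
in the test suite.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import gemmi
import networkx as nx
import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFMCS

from .pdb_io import LigandInstance
from .superpose import DegenerateGeometryError, SuperpositionResult, kabsch

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "MolecularGraph",
    "AtomMapping",
    "UnmappableLigandsError",
    "build_graph",
    "graph_from_elements",
    "name_correspondence",
    "enumerate_mappings",
    "match_atoms",
    "map_ligand_atoms",
    "best_superposition",
    "rotatable_bonds",
    "molecular_weight",
    "parse_formula",
]

MIN_MAPPING_SIZE = 3


class UnmappableLigandsError(ValueError):
    """No usable atom correspondence (fewer than 3 atoms, or degenerate)."""


@dataclass
class MolecularGraph:
    """Simple undirected graph; node attribute ``element``, ring edges cached."""

    graph: nx.Graph
    ring_edges: frozenset[frozenset[int]]

    @property
    def n_atoms(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_bonds(self) -> int:
        return self.graph.number_of_edges()

    def element(self, node: int) -> str:
        return self.graph.nodes[node]["element"]

    @property
    def elements(self) -> list[str]:
        return [self.element(i) for i in sorted(self.graph.nodes)]

    def is_ring_edge(self, u: int, v: int) -> bool:
        return frozenset((u, v)) in self.ring_edges


@dataclass
class AtomMapping:
    """Injective atom correspondence between two ligands.

    ``pairs[k] = (index in A, index in B)``; ``source`` records which route
    produced it (``name-match``, ``isomorphism`` or ``mcs``).
    """

    pairs: tuple[tuple[int, int], ...]
    source: str

    def __post_init__(self) -> None:
        self.pairs = tuple((int(a), int(b)) for a, b in self.pairs)

    @property
    def size(self) -> int:
        return len(self.pairs)

    def reversed(self) -> "AtomMapping":
        return AtomMapping(tuple((b, a) for a, b in self.pairs), self.source)


def graph_from_elements(
    elements: Sequence[str], bonds: Iterable[tuple[int, int]]
) -> MolecularGraph:
    g = nx.Graph()
    for i, e in enumerate(elements):
        g.add_node(i, element=e)
    for i, j in bonds:
        if i == j:
            continue
        g.add_edge(int(i), int(j))
    # an edge lies on a cycle iff it is not a bridge
    bridges = {frozenset(e) for e in nx.bridges(g)}
    ring = frozenset(frozenset(e) for e in g.edges if frozenset(e) not in bridges)
    return MolecularGraph(graph=g, ring_edges=ring)


def build_graph(ligand: LigandInstance) -> MolecularGraph:
    """Molecular graph of a ligand's heavy atoms (bonds must be inferred)."""
    return graph_from_elements(ligand.elements, ligand.bonds)


def name_correspondence(
    ligA: LigandInstance, ligB: LigandInstance
) -> list[tuple[int, int]] | None:
    """Atom-name based correspondence for two copies of the same component."""
    if ligA.chem_comp_id != ligB.chem_comp_id:
        return None
    namesA = {a.name: i for i, a in enumerate(ligA.atoms)}
    namesB = {a.name: i for i, a in enumerate(ligB.atoms)}
    if len(namesA) != len(ligA.atoms) or len(namesB) != len(ligB.atoms):
        return None  # duplicated names, not trustworthy
    common = sorted(set(namesA) & set(namesB))
    pairs = [(namesA[n], namesB[n]) for n in common]
    return pairs or None


# ---------------------------------------------------------------------------
# candidate enumeration


def _to_rdkit(g: MolecularGraph) -> Chem.Mol:
    m = Chem.RWMol()
    order = sorted(g.graph.nodes)
    for node in order:
        a = Chem.Atom(g.element(node))
        a.SetNoImplicit(True)
        m.AddAtom(a)
    index = {node: k for k, node in enumerate(order)}
    for u, v in g.graph.edges:
        m.AddBond(index[u], index[v], Chem.BondType.SINGLE)
    mol = m.GetMol()
    Chem.SanitizeMol(mol, Chem.SanitizeFlags.SANITIZE_NONE)
    return mol


def _elements_match(n1: dict, n2: dict) -> bool:
    return n1["element"] == n2["element"]


def _mapping_connected(g: MolecularGraph, nodes: Iterable[int]) -> bool:
    sub = g.graph.subgraph(list(nodes))
    return sub.number_of_nodes() > 0 and nx.is_connected(sub)


def _isomorphism_candidates(
    gA: MolecularGraph, gB: MolecularGraph, cap: int
) -> list[tuple[tuple[int, int], ...]]:
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        gA.graph, gB.graph, node_match=_elements_match
    )
    out = []
    for iso in itertools.islice(matcher.isomorphisms_iter(), cap):
        out.append(tuple(sorted(iso.items())))
    return out


def _mcs_candidates(
    gA: MolecularGraph, gB: MolecularGraph, cap: int
) -> list[tuple[tuple[int, int], ...]]:
    molA, molB = _to_rdkit(gA), _to_rdkit(gB)
    params = rdFMCS.MCSParameters()
    params.MaximizeBonds = False  # maximize atom count
    params.AtomTyper = rdFMCS.AtomCompare.CompareElements
    params.BondTyper = rdFMCS.BondCompare.CompareAny
    params.Timeout = 30
    res = rdFMCS.FindMCS([molA, molB], params)
    if res.canceled or res.numAtoms < MIN_MAPPING_SIZE:
        return []
    query = Chem.MolFromSmarts(res.smartsString)
    kwargs = dict(uniquify=False, maxMatches=cap, useChirality=False)
    matchesA = molA.GetSubstructMatches(query, **kwargs)
    matchesB = molB.GetSubstructMatches(query, **kwargs)
    seen: dict[frozenset, tuple] = {}
    for ma, mb in itertools.product(matchesA, matchesB):
        pairs = tuple(sorted(zip(ma, mb)))
        key = frozenset(pairs)
        if key not in seen:
            seen[key] = pairs
        if len(seen) >= cap:
            break
    return list(seen.values())


def enumerate_mappings(
    gA: MolecularGraph,
    gB: MolecularGraph,
    name_map: Sequence[tuple[int, int]] | None = None,
    max_candidates: int = 1000,
) -> tuple[list[tuple[tuple[int, int], ...]], str]:
    """All candidate atom correspondences, in deterministic order.

    Returns ``(candidates, source)`` where each candidate is a sorted tuple
    of (A-index, B-index) pairs.  Routes are tried in priority order:
    name match, full isomorphism, MCS.
    """
    if gA.n_atoms == 0 or gB.n_atoms == 0:
        raise UnmappableLigandsError("empty molecular graph")
    if name_map is not None:
        pairs = tuple(sorted((int(a), int(b)) for a, b in name_map))
        ok = (
            len(pairs) >= MIN_MAPPING_SIZE
            and len({a for a, _ in pairs}) == len(pairs)
            and len({b for _, b in pairs}) == len(pairs)
            and all(gA.element(a) == gB.element(b) for a, b in pairs)
            and _mapping_connected(gA, (a for a, _ in pairs))
        )
        if ok:
            return [pairs], "name-match"
    candidates = _isomorphism_candidates(gA, gB, max_candidates)
    if candidates:
        source = "isomorphism"
    else:
        candidates = _mcs_candidates(gA, gB, max_candidates)
        source = "mcs"
    if not candidates:
        raise UnmappableLigandsError(
            "no common substructure of at least "
            f"{MIN_MAPPING_SIZE} atoms between the two ligands"
        )
    return sorted(candidates), source


def best_superposition(
    coordsA: np.ndarray,
    coordsB: np.ndarray,
    candidates: Sequence[tuple[tuple[int, int], ...]],
    source: str,
) -> tuple[AtomMapping, SuperpositionResult]:
    """Pick the candidate mapping minimizing the optimal superposition RMSD."""
    best: tuple[AtomMapping, SuperpositionResult] | None = None
    for pairs in candidates:
        try:
            sup = kabsch(coordsA, coordsB, pairs)
        except DegenerateGeometryError:
            continue
        if best is None or sup.rmsd < best[1].rmsd - 1e-12:
            best = (AtomMapping(pairs, source), sup)
    if best is None:
        raise UnmappableLigandsError(
            "all candidate mappings are degenerate (collinear atoms)"
        )
    return best


def match_atoms(
    gA: MolecularGraph,
    gB: MolecularGraph,
    coordsA: np.ndarray,
    coordsB: np.ndarray,
    name_map: Sequence[tuple[int, int]] | None = None,
    max_candidates: int = 1000,
) -> AtomMapping:
    """Atom correspondence between two ligands (see module docstring)."""
    candidates, source = enumerate_mappings(gA, gB, name_map, max_candidates)
    mapping, _sup = best_superposition(coordsA, coordsB, candidates, source)
    return mapping


def map_ligand_atoms(
    ligA: LigandInstance, ligB: LigandInstance, max_candidates: int = 1000
) -> AtomMapping:
    """Convenience wrapper: graphs, name correspondence and matching in one."""
    gA, gB = build_graph(ligA), build_graph(ligB)
    nm = name_correspondence(ligA, ligB)
    return match_atoms(gA, gB, ligA.coords, ligB.coords, nm, max_candidates)


# ---------------------------------------------------------------------------
# descriptors


def rotatable_bonds(g: MolecularGraph) -> tuple[int, float]:
    """(absolute count, ratio to total bonds) of rotatable bonds.

    A bond is rotatable iff it is not in a ring and neither endpoint is
    terminal (heavy-atom degree >= 2 on both sides).  Ring bonds are never
    rotatable.
    """
    if g.n_atoms == 0:
        raise ValueError("empty graph")
    count = 0
    for u, v in g.graph.edges:
        if g.is_ring_edge(u, v):
            continue
        if g.graph.degree(u) >= 2 and g.graph.degree(v) >= 2:
            count += 1
    total = g.n_bonds
    return count, (count / total if total else 0.0)


_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula like ``C7H8N2`` into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
        pos = m.end()
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def _atomic_mass(symbol: str) -> float:
    el = gemmi.Element(symbol)
    if el.atomic_number == 0:
        raise ValueError(f"unknown element symbol {symbol!r}")
    return el.weight


def molecular_weight(
    ligand: LigandInstance,
    formula_override: Mapping[str, int] | str | None = None,
) -> float:
    """Molecular weight in g/mol.

    Sums standard atomic masses over the atoms present in the file, or over
    ``formula_override`` (an element-count map or a formula string) when one
    is provided.  Note that file-derived weights omit hydrogens, which PDB
    X-ray entries usually lack.
    """
    if isinstance(formula_override, str):
        formula_override = parse_formula(formula_override)
    if formula_override:
        return float(
            sum(_atomic_mass(el) * n for el, n in formula_override.items())
        )
    return float(sum(_atomic_mass(a.element) for a in ligand.atoms))
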