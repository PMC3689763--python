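"""Global sequence alignment and 95%-identity clustering of drug targets.

Counting how many targets a drug binds requires collapsing near-identical
chains (point mutants, species orthologs at >95% identity, re-deposited
structures) to one *non-redundant target*.  Chains are aligned globally
(Needleman–Wunsch, BLOSUM62, gap open 10 / extension 0.5, end gaps
penalized like internal gaps) and clustered by single-linkage transitive
closure over pairs at or above the identity cut.  A drug's promiscuity
degree is the number of clusters containing at least one chain it is
co-crystallized with; three or more makes it promiscuous.

Percent identity is the number of identical alignment columns divided by
the full alignment length (gap columns included).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "GlobalAlignment",
    "TargetCluster",
    "global_align",
    "percent_identity",
    "cluster_targets",
    "promiscuity_degree",
    "target_chain_for_ligand",
    "cluster_membership_table",
]

GAP_OPEN = 10.0
GAP_EXTEND = 0.5

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class GlobalAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float


@dataclass
class TargetCluster:
    cluster_id: int
    representative: str
    members: list[str]
    drug_links: set[str] = field(default_factory=set)


@lru_cache(maxsize=1)
def _blosum62_x_neutral():
    """BLOSUM62 with the X (unknown residue) row/column rescored to 0."""
    m = substitution_matrices.load("BLOSUM62")
    arr = np.array(m)
    alphabet = m.alphabet
    xi = alphabet.index("X")
    arr[xi, :] = 0.0
    arr[:, xi] = 0.0
    return substitution_matrices.Array(alphabet=alphabet, dims=2, data=arr)


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.substitution_matrix = _blosum62_x_neutral()
    # first gapped position costs GAP_OPEN, each further one GAP_EXTEND:
    # a gap of length L costs 10 + (L-1) * 0.5; end gaps cost the same
    al.open_gap_score = -GAP_OPEN
    al.extend_gap_score = -GAP_EXTEND
    return al


def _sanitize(seq: str) -> str:
    seq = seq.upper()
    return "".join(c if c in STANDARD_AA else "X" for c in seq)


def global_align(seq_a: str, seq_b: str) -> GlobalAlignment:
    """Affine-gap Needleman–Wunsch optimum for two amino-acid sequences.

    Nonstandard residues are mapped to X and score 0 against everything.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    sa, sb = _sanitize(seq_a), _sanitize(seq_b)
    alignments = _aligner().align(sa, sb)
    aln = alignments[0]
    ga, gb = _gapped_strings(aln, sa, sb)
    n_ident = sum(1 for x, y in zip(ga, gb) if x == y and x != "-")
    identity = 100.0 * n_ident / len(ga)
    return GlobalAlignment(ga, gb, float(aln.score), identity)


def _gapped_strings(aln, sa: str, sb: str) -> tuple[str, str]:
    ia, ib = aln.indices  # -1 marks a gap
    ga = "".join(sa[i] if i >= 0 else "-" for i in ia)
    gb = "".join(sb[i] if i >= 0 else "-" for i in ib)
    return ga, gb


def percent_identity(seq_a: str, seq_b: str) -> float:
    return global_align(seq_a, seq_b).identity_pct


def cluster_targets(
    chains: Mapping[str, str],
    identity_cut: float = 95.0,
    chain_drugs: Mapping[str, set[str]] | None = None,
) -> list[TargetCluster]:
    """Single-linkage clustering of chains at ``identity_cut`` % identity.

    ``chains`` maps chain identifier -> sequence.  The transitive closure is
    taken: A~B and B~C puts A, B, C in one cluster even if A~C falls below
    the cut.  The representative is the longest member sequence (ties:
    lexicographically smallest identifier).
    """
    if not chains:
        raise ValueError("no chains to cluster")
    ids = sorted(chains)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if percent_identity(chains[a], chains[b]) >= identity_cut:
                g.add_edge(a, b)
    clusters = []
    components = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for cid, comp in enumerate(components):
        members = sorted(comp)
        rep = sorted(members, key=lambda m: (-len(chains[m]), m))[0]
        links: set[str] = set()
        if chain_drugs:
            for m in members:
                links |= set(chain_drugs.get(m, ()))
        clusters.append(TargetCluster(cid, rep, members, links))
    return clusters


def promiscuity_degree(drug: str, clusters: Sequence[TargetCluster]) -> int:
    """Number of distinct target clusters binding ``drug``."""
    if not any(drug in c.drug_links for c in clusters):
        raise KeyError(f"drug {drug!r} not bound by any clustered chain")
    return sum(1 for c in clusters if drug in c.drug_links)


def target_chain_for_ligand(chains, ligand, radius: float = 5.0):
    """The chain with the most heavy atoms within ``radius`` Å of the ligand.

    Used to assign each ligand copy to the protein chain forming its site.
    Returns None when no chain atom is within range.
    """
    lig_coords = ligand.coords
    best_chain, best_count = None, 0
    for ch in chains:
        coords = np.array(
            [a.coords for _rn, _num, atoms in ch.residues for a in atoms]
        )
        if coords.size == 0:
            continue
        d2 = np.sum(
            (coords[:, None, :] - lig_coords[None, :, :]) ** 2, axis=2
        )
        count = int(np.sum(d2.min(axis=1) <= radius * radius))
        if count > best_count:
            best_chain, best_count = ch, count
    return best_chain


def cluster_membership_table(
    clusters: Sequence[TargetCluster], chains: Mapping[str, str]
) -> pd.DataFrame:
    """TSV-ready membership table with identity to the representative."""
    rows = []
    for c in clusters:
        for m in c.members:
            ident = (
                100.0
                if m == c.representative
                else percent_identity(chains[m], chains[c.representative])
            )
            rows.append(
                {
                    "cluster_id": c.cluster_id,
                    "representative": c.representative,
                    "member": m,
                    "identity_to_representative": round(ident, 2),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "representative", "member", "identity_to_representative"],
    )
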