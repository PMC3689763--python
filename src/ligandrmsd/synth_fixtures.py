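"""Seeded generators for every input of the analysis pipeline.

The original study ran on a PDB snapshot, an external binding-site aligner
and a commercial descriptor engine — none of which are needed to exercise
the method.  This module fabricates, with ground truth attached:

* toy protein–ligand complexes and rigidly transformed, optionally noised
  copies (with the exact inverse motion as truth) — for scoring tests;
* conformer sets with planted cluster structure (intra-cluster RMSD below,
  inter-cluster RMSD above stated bounds, verified with the same distance
  engine the analysis uses) — for flexibility tests;
* whole drug–target cohorts: drugs with planted promiscuity degrees,
  target clusters with member structures and controlled sequence identity,
  alignment records whose transforms put the LigandRMSD on the intended
  side of the similarity cut, and descriptor tables with a planted
  correlation between promiscuity and similar-site counts.

All geometry is deliberately schematic (zigzag chains, helical backbones,
Gaussian conformer clouds): the generators emulate the *information
structure* of the study's data, not protein physics.  Everything is
deterministic under the seed.
"""

from __future__ import annotations

import itertools
import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.SeqUtils import seq3
from scipy.spatial.transform import Rotation

from .ligand_rmsd import AlignmentRecord, SiteRef
from .molgraph import build_graph, molecular_weight, rotatable_bonds
from .pdb_io import Atom, LigandInstance
from .superpose import RigidTransform

__all__ = [
    "LigandSpec",
    "chain_ligand_spec",
    "ring_tail_ligand_spec",
    "random_ligand_spec",
    "spec_to_instance",
    "perturb_torsion",
    "make_complex_pair",
    "make_conformer_set",
    "make_cohort",
    "CohortBundle",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
BOND_LENGTH = 1.52
#: element repertoire for generated ligands (C-rich, like real drugs)
ELEMENT_POOL = ["C", "C", "C", "N", "O", "S"]


@dataclass
class LigandSpec:
    """Blueprint of a synthetic ligand: topology plus reference geometry."""

    comp_id: str
    elements: list[str]
    bonds: list[tuple[int, int]]
    coords: np.ndarray  # (n, 3) reference conformer

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.elements) != len(self.coords):
            raise ValueError("elements and coords disagree in length")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


def _zigzag(n: int) -> np.ndarray:
    """Planar zigzag chain with tetrahedral-ish angles, bond length 1.52 Å."""
    coords = np.zeros((n, 3))
    step = BOND_LENGTH * np.sin(np.deg2rad(111) / 2)
    rise = BOND_LENGTH * np.cos(np.deg2rad(111) / 2)
    for i in range(n):
        coords[i] = (i * step, rise * (i % 2), 0.15 * np.sin(i))  # slight 3D twist
    return coords


def _asymmetric_elements(n: int, rng: np.random.Generator) -> list[str]:
    """Element sequence for a chain, guaranteed non-palindromic."""
    while True:
        elements = [str(rng.choice(ELEMENT_POOL)) for _ in range(n)]
        if elements != elements[::-1]:
            return elements


def chain_ligand_spec(n_atoms: int = 10, comp_id: str = "LIG", seed: int = 0) -> LigandSpec:
    """Unbranched chain molecule with an asymmetric element pattern.

    The asymmetry makes the identity the only graph automorphism, so atom
    mappings are unique — convenient for tests with analytic expectations.
    """
    if n_atoms < 4:
        raise ValueError("need at least 4 atoms")
    rng = np.random.default_rng(seed)
    elements = _asymmetric_elements(n_atoms, rng)
    bonds = [(i, i + 1) for i in range(n_atoms - 1)]
    return LigandSpec(comp_id, elements, bonds, _zigzag(n_atoms))


def ring_tail_ligand_spec(comp_id: str = "BZM") -> LigandSpec:
    """Benzamidine-like molecule: a 6-ring of carbons with a C(N)(N) tail.

    The ring flip symmetry gives several graph automorphisms, exercising
    the symmetry-corrected mapping selection.
    """
    elements = ["C"] * 6 + ["C", "N", "N"]
    bonds = [(i, (i + 1) % 6) for i in range(6)] + [(0, 6), (6, 7), (6, 8)]
    r = BOND_LENGTH / (2 * np.sin(np.pi / 6))
    coords = np.zeros((9, 3))
    for i in range(6):
        ang = np.pi / 3 * i
        coords[i] = (r * np.cos(ang), r * np.sin(ang), 0.0)
    coords[6] = (r + BOND_LENGTH, 0.0, 0.0)
    coords[7] = (r + BOND_LENGTH + 0.7, 1.2, 0.1)
    coords[8] = (r + BOND_LENGTH + 0.7, -1.2, -0.1)
    return LigandSpec(comp_id, elements, bonds, coords)


def random_ligand_spec(
    rng: np.random.Generator, n_atoms: int | None = None, comp_id: str = "RND"
) -> LigandSpec:
    """Random tree-shaped molecule with jittered zigzag geometry."""
    if n_atoms is None:
        n_atoms = int(rng.integers(6, 13))
    elements = _asymmetric_elements(n_atoms, rng)
    bonds = [(i, i + 1) for i in range(n_atoms - 1)]
    # occasionally re-route a bond to make a branch (keeps a tree)
    for i in range(3, n_atoms - 1):
        if rng.random() < 0.25:
            parent = int(rng.integers(max(0, i - 3), i))
            bonds[i] = (parent, i + 1)
    coords = _zigzag(n_atoms) + rng.normal(scale=0.25, size=(n_atoms, 3))
    return LigandSpec(comp_id, elements, bonds, coords)


def spec_to_instance(
    spec: LigandSpec,
    pdb_id: str = "SYNT",
    chain_id: str = "A",
    residue_number: int = 900,
    coords: np.ndarray | None = None,
    serial_start: int = 1,
) -> LigandInstance:
    coords = spec.coords if coords is None else np.asarray(coords, dtype=float)
    atoms = [
        Atom(
            serial=serial_start + i,
            name=f"{el}{i + 1}",
            element=el,
            coords=coords[i],
        )
        for i, el in enumerate(spec.elements)
    ]
    return LigandInstance(
        pdb_id=pdb_id,
        chem_comp_id=spec.comp_id,
        chain_id=chain_id,
        residue_number=residue_number,
        atoms=atoms,
        bonds=list(spec.bonds),
    )


def perturb_torsion(
    coords: np.ndarray,
    bonds: list[tuple[int, int]],
    bond: tuple[int, int],
    angle_deg: float,
) -> np.ndarray:
    """Rotate everything on the far side of ``bond`` about its axis."""
    import networkx as nx

    i, j = bond
    g = nx.Graph(bonds)
    g.remove_edge(i, j)
    moving = nx.node_connected_component(g, j)
    axis = coords[j] - coords[i]
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ValueError("degenerate bond axis")
    rot = Rotation.from_rotvec(np.deg2rad(angle_deg) * axis / norm)
    out = np.array(coords, dtype=float)
    for k in moving:
        out[k] = coords[i] + rot.apply(coords[k] - coords[i])
    return out


def _random_transform(
    rng: np.random.Generator, rotation_deg: float | None = None, box: float = 20.0
) -> RigidTransform:
    if rotation_deg is None:
        R = Rotation.random(rng=rng).as_matrix()
    else:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        R = Rotation.from_rotvec(np.deg2rad(rotation_deg) * axis).as_matrix()
    t = rng.uniform(-box / 2, box / 2, size=3)
    return RigidTransform(R, t)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


# ---------------------------------------------------------------------------
# PDB text generation


def _helix_backbone(n_residues: int) -> np.ndarray:
    """(n, 4, 3) backbone coordinates (N, CA, C, O) of an ideal-ish helix."""
    out = np.zeros((n_residues, 4, 3))
    for i in range(n_residues):
        ang = np.deg2rad(100.0) * i
        ca = np.array([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * i])
        out[i, 1] = ca
        out[i, 0] = ca + np.array([-0.8, 0.9, -0.9])  # N
        out[i, 2] = ca + np.array([1.0, 0.6, 0.9])  # C
        out[i, 3] = ca + np.array([1.2, 1.6, 1.1])  # O
    return out


def format_structure(
    pdb_id: str,
    chain_id: str,
    sequence: str,
    backbone: np.ndarray,
    ligand: LigandInstance | None = None,
) -> str:
    """Write a one-chain structure (plus optional ligand) as PDB text."""
    lines = [f"HEADER    SYNTHETIC COMPLEX                       {pdb_id:>4}"]
    serial = 1
    atom_names = ("N", "CA", "C", "O")
    elements = ("N", "C", "C", "O")
    for i, aa in enumerate(sequence):
        resname = seq3(aa).upper()
        for k in range(4):
            x, y, z = backbone[i, k]
            lines.append(
                "ATOM  %5d  %-3s %3s %1s%4d    %8.3f%8.3f%8.3f%6.2f%6.2f          %2s"
                % (serial, atom_names[k], resname, chain_id, i + 1, x, y, z, 1.0, 0.0,
                   elements[k])
            )
            serial += 1
    lines.append("TER")
    if ligand is not None:
        serial_map = {}
        for i, a in enumerate(ligand.atoms):
            name = f" {a.name:<3}" if len(a.name) < 4 else a.name[:4]
            lines.append(
                "HETATM%5d %s %3s %1s%4d    %8.3f%8.3f%8.3f%6.2f%6.2f          %2s"
                % (serial, name, ligand.chem_comp_id, ligand.chain_id,
                   ligand.residue_number, a.coords[0], a.coords[1], a.coords[2],
                   1.0, 0.0, a.element.rjust(2))
            )
            serial_map[i] = serial
            serial += 1
        for i, j in ligand.bonds:
            lines.append("CONECT%5d%5d" % (serial_map[i], serial_map[j]))
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_complex_pair(
    seed: int,
    n_residues: int = 12,
    ligand_spec: LigandSpec | None = None,
    rotation_deg: float = 40.0,
    translation: tuple[float, float, float] = (6.0, -3.0, 4.0),
    coord_noise_sigma: float = 0.0,
) -> tuple[str, str, RigidTransform]:
    """A complex and a rigidly moved (optionally noised) copy.

    Returns ``(pdb_a, pdb_b, transform)`` where ``transform`` is the exact
    inverse motion: it carries B-frame coordinates back onto A.
    """
    if n_residues < 5:
        raise ValueError("need at least 5 residues")
    spec = ligand_spec or chain_ligand_spec(9, seed=seed)
    if spec.n_atoms < 4:
        raise ValueError("ligand_spec must have at least 4 heavy atoms")
    centered = spec.coords - spec.coords.mean(axis=0)
    if np.linalg.svd(centered, compute_uv=False)[1] < 1e-6:
        raise ValueError("ligand_spec geometry is collinear")
    rng = np.random.default_rng(seed)
    backbone = _helix_backbone(n_residues)
    lig_coords = spec.coords + backbone[:, 1].mean(axis=0) + np.array([5.0, 0.0, 0.0])
    sequence = "".join(rng.choice(list(AMINO_ACIDS), size=n_residues))

    axis = _random_unit(rng)
    R0 = Rotation.from_rotvec(np.deg2rad(rotation_deg) * axis).as_matrix()
    t0 = np.asarray(translation, dtype=float)
    motion = RigidTransform(R0, t0)

    backbone_b = motion.apply(backbone.reshape(-1, 3)).reshape(backbone.shape)
    lig_b = motion.apply(lig_coords)
    if coord_noise_sigma > 0:
        backbone_b = backbone_b + rng.normal(scale=coord_noise_sigma, size=backbone_b.shape)
        lig_b = lig_b + rng.normal(scale=coord_noise_sigma, size=lig_b.shape)

    lig_a_inst = spec_to_instance(spec, "SYNA", "A", 900, lig_coords)
    lig_b_inst = spec_to_instance(spec, "SYNB", "A", 900, lig_b)
    pdb_a = format_structure("SYNA", "A", sequence, backbone, lig_a_inst)
    pdb_b = format_structure("SYNB", "A", sequence, backbone_b, lig_b_inst)
    return pdb_a, pdb_b, motion.inverse()


# ---------------------------------------------------------------------------
# conformer sets


def make_conformer_set(
    seed: int,
    ligand_spec: LigandSpec | None = None,
    k_clusters: int = 3,
    members_per_cluster: int = 3,
    intra_rmsd_max: float = 0.5,
    inter_rmsd_min: float = 3.0,
    max_retries: int = 500,
) -> tuple[list[LigandInstance], np.ndarray]:
    """Conformer instances with planted cluster structure.

    Pairwise optimal RMSDs are verified with the analysis' own distance
    engine: members of one cluster sit within ``intra_rmsd_max`` of each
    other, members of different clusters at least ``inter_rmsd_min`` apart.
    Candidate geometries violating the margins are regenerated (bounded
    retries).  Returns ``(instances, planted labels)``.
    """
    from .conformers import conformer_distance

    if intra_rmsd_max >= inter_rmsd_min:
        raise ValueError("intra_rmsd_max must be below inter_rmsd_min")
    spec = ligand_spec or chain_ligand_spec(12, comp_id="CNF", seed=seed)
    rng = np.random.default_rng(seed)
    n = spec.n_atoms
    sep = inter_rmsd_min + 2 * intra_rmsd_max + 0.2  # triangle-inequality margin

    def center_instance(coords):
        return spec_to_instance(spec, "CTMP", coords=coords)

    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < k_clusters:
        if tries > max_retries:
            raise RuntimeError("could not place well-separated conformer clusters")
        tries += 1
        if not centers:
            cand = spec.coords.copy()
        else:
            cand = rng.normal(scale=2.6, size=(n, 3))
        ok = all(
            conformer_distance(center_instance(cand), center_instance(c)) >= sep
            for c in centers
        )
        if ok:
            centers.append(cand)

    sigma = intra_rmsd_max / (2.0 * np.sqrt(3.0))
    instances: list[LigandInstance] = []
    labels: list[int] = []
    idx = 0
    for c_id, center in enumerate(centers):
        for _m in range(members_per_cluster):
            tries = 0
            while True:
                if tries > max_retries:
                    raise RuntimeError("could not sample a tight cluster member")
                tries += 1
                member = center + rng.normal(scale=sigma, size=(n, 3))
                d = conformer_distance(center_instance(member), center_instance(center))
                if d <= intra_rmsd_max / 2:
                    break
            instances.append(
                spec_to_instance(spec, pdb_id=f"C{idx:03d}", coords=member)
            )
            labels.append(c_id)
            idx += 1

    # final verification of every pairwise bound
    for i in range(len(instances)):
        for j in range(i + 1, len(instances)):
            d = conformer_distance(instances[i], instances[j])
            if labels[i] == labels[j] and d > intra_rmsd_max:
                raise RuntimeError("intra-cluster bound violated after sampling")
            if labels[i] != labels[j] and d < inter_rmsd_min:
                raise RuntimeError("inter-cluster bound violated after sampling")
    return instances, np.array(labels, dtype=int)


# ---------------------------------------------------------------------------
# cohorts


def _drug_ids(n: int) -> list[str]:
    letters = string.ascii_uppercase
    out = []
    for combo in itertools.product(letters, repeat=3):
        out.append("".join(combo))
        if len(out) == n:
            return out
    raise ValueError("too many drugs requested")


def _default_degrees(rng: np.random.Generator, n_drugs: int) -> np.ndarray:
    """Promiscuity degrees: geometric tail starting at 3, capped at 20."""
    return np.minimum(2 + rng.geometric(0.35, size=n_drugs), 20)


@dataclass
class CohortBundle:
    """A synthetic drug–target cohort with ground truth.

    Attributes mirror the pipeline's inputs: alignment ``records``, bound
    ligand copies keyed by site, per-chain ``sequences``, planted
    ``cluster_of_chain`` assignments, descriptor table and truth record.
    """

    seed: int
    records: list[AlignmentRecord]
    ligands: dict[tuple[str, str, int], LigandInstance]
    sequences: dict[str, str]  # chain key "PDBID_CHAIN" -> sequence
    cluster_of_chain: dict[str, str]  # chain key -> cluster key "drug/c#"
    chain_drugs: dict[str, set[str]]
    descriptors: "object"  # pandas DataFrame indexed by drug
    pfam_of_chain: dict[str, str]
    truth: dict
    specs: dict[str, LigandSpec] = field(default_factory=dict)

    def ligand_for(self, site: SiteRef) -> LigandInstance:
        return self.ligands[(site.pdb_id, site.chain_id, site.residue_number)]

    def write(self, out_dir: str | Path) -> None:
        """Materialize the bundle as a self-contained fixture directory."""
        out = Path(out_dir)
        (out / "structures").mkdir(parents=True, exist_ok=True)
        for chain_key, seq in sorted(self.sequences.items()):
            pdb_id, chain_id = chain_key.rsplit("_", 1)
            lig = next(
                (l for (pid, _c, _r), l in sorted(self.ligands.items()) if pid == pdb_id),
                None,
            )
            struct_rng = np.random.default_rng([self.seed % (2**31), _stable_hash(pdb_id)])
            backbone = _helix_backbone(len(seq))
            if lig is not None:
                # park the helix next to the ligand pose
                offset = lig.coords.mean(axis=0) - backbone[:, 1].mean(axis=0)
                backbone = backbone + offset + struct_rng.normal(scale=0.01, size=3) + np.array([6.0, 0, 0])
            text = format_structure(pdb_id, chain_id, seq, backbone, lig)
            (out / "structures" / f"{pdb_id}.pdb").write_text(text)
        with open(out / "alignments.jsonl", "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec.to_dict()) + "\n")
        with open(out / "sequences.fasta", "w") as fh:
            for chain_key, seq in sorted(self.sequences.items()):
                fh.write(f">{chain_key}\n{seq}\n")
        self.descriptors.reset_index().rename(columns={"index": "drug"}).to_csv(
            out / "descriptors.tsv", sep="\t", index=False
        )
        with open(out / "pfam.tsv", "w") as fh:
            fh.write("chain\tfamily\n")
            for chain_key, fam in sorted(self.pfam_of_chain.items()):
                fh.write(f"{chain_key}\t{fam}\n")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True, default=_jsonable)
            fh.write("\n")


def _stable_hash(s: str) -> int:
    h = 0
    for ch in s:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def _plant_similar_counts(
    rng: np.random.Generator,
    degrees: np.ndarray,
    rho: float | None,
    fraction_with_similar: float | None,
    fraction_all_similar: float | None,
) -> np.ndarray:
    """Similar-pair counts per drug, planting either a correlation or fractions."""
    n_drugs = len(degrees)
    max_pairs = degrees * (degrees - 1) // 2
    if fraction_with_similar is not None or fraction_all_similar is not None:
        fw = 1.0 if fraction_with_similar is None else fraction_with_similar
        fa = 0.0 if fraction_all_similar is None else fraction_all_similar
        if not 0.0 <= fa <= fw <= 1.0:
            raise ValueError("need 0 <= fraction_all <= fraction_with <= 1")
        n_with = int(round(fw * n_drugs))
        n_all = int(round(fa * n_drugs))
        order = rng.permutation(n_drugs)
        s = np.zeros(n_drugs, dtype=int)
        for k, i in enumerate(order):
            if k < n_all:
                s[i] = max_pairs[i]
            elif k < n_with:
                # partial: 1..P-1 so the drug counts as with- but not all-similar
                s[i] = int(rng.integers(1, max_pairs[i])) if max_pairs[i] > 1 else 1
        return s
    rho = 0.6 if rho is None else rho
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must be in (-1, 1)")
    u = (degrees - degrees.mean()) / max(degrees.std(), 1e-9)
    eps = rng.normal(size=n_drugs)
    z = rho * u + np.sqrt(1.0 - rho**2) * eps
    # latent sqrt-count scale chosen so that integer rounding/clipping leaves
    # the realized correlation essentially unbiased at the requested rho
    sqrt_s = np.maximum(1.0 + 0.75 * z, 0.0)
    return np.clip(np.round(sqrt_s**2), 0, max_pairs).astype(int)


def make_cohort(
    seed: int,
    n_drugs: int = 164,
    degrees: np.ndarray | None = None,
    rho: float | None = 0.6,
    fraction_with_similar: float | None = None,
    fraction_all_similar: float | None = None,
    redundancy: float = 1.0,
    seq_length: int = 60,
) -> CohortBundle:
    """A full synthetic drug–target cohort (see module docstring).

    ``redundancy`` is the mean number of member structures per target
    cluster (1.0 reproduces a non-redundant dataset; ~3.2 reproduces a
    cohort whose non-redundant pair count is roughly a tenth of the raw
    alignment count).  ``rho`` plants a correlation between the promiscuity
    degree and the square root of the similar-pair count; the fraction
    arguments instead plant exact cohort-level fractions.  The truth record
    carries both the requested and the realized values.
    """
    rng = np.random.default_rng(seed)
    drug_ids = _drug_ids(n_drugs)
    if degrees is None:
        degrees = _default_degrees(rng, n_drugs)
    degrees = np.asarray(degrees, dtype=int)
    if degrees.min() < 2:
        raise ValueError("degrees below 2 make no pairs to align")
    similar_counts = _plant_similar_counts(
        rng, degrees, rho, fraction_with_similar, fraction_all_similar
    )

    specs: dict[str, LigandSpec] = {}
    records: list[AlignmentRecord] = []
    ligands: dict[tuple[str, str, int], LigandInstance] = {}
    sequences: dict[str, str] = {}
    cluster_of_chain: dict[str, str] = {}
    chain_drugs: dict[str, set[str]] = {}
    pfam_of_chain: dict[str, str] = {}
    desc_rows = []
    similar_pairs_truth: dict[str, list[list[int]]] = {}
    poses: dict[str, RigidTransform] = {}
    struct_counter = 0
    n_nonredundant_pairs = 0

    import pandas as pd

    for d_idx, drug in enumerate(drug_ids):
        n = int(degrees[d_idx])
        spec = chain_ligand_spec(
            n_atoms=int(rng.integers(8, 15)), comp_id=drug, seed=int(rng.integers(2**31))
        )
        specs[drug] = spec

        # target clusters, each with >= 1 member structure
        members: list[list[str]] = []
        for c in range(n):
            m = 1 + (rng.poisson(redundancy - 1.0) if redundancy > 1.0 else 0)
            cluster_key = f"{drug}/c{c}"
            base_seq = "".join(rng.choice(list(AMINO_ACIDS), size=seq_length))
            ids = []
            for _k in range(m):
                pdb_id = f"S{struct_counter:04d}"
                struct_counter += 1
                seq = list(base_seq)
                pos = int(rng.integers(seq_length))
                seq[pos] = str(rng.choice(list(AMINO_ACIDS.replace(seq[pos], ""))))
                chain_key = f"{pdb_id}_A"
                sequences[chain_key] = "".join(seq)
                cluster_of_chain[chain_key] = cluster_key
                chain_drugs.setdefault(chain_key, set()).add(drug)
                pfam_of_chain[chain_key] = f"FAM{d_idx:03d}_{c // 2}"
                pose = _random_transform(rng, box=40.0)
                coords = pose.apply(spec.coords)
                inst = spec_to_instance(spec, pdb_id, "A", 900, coords)
                ligands[(pdb_id, "A", 900)] = inst
                poses[pdb_id] = pose
                ids.append(pdb_id)
            members.append(ids)

        # which cluster pairs are similar
        pair_list = list(itertools.combinations(range(n), 2))
        n_nonredundant_pairs += len(pair_list)
        s = int(similar_counts[d_idx])
        chosen = rng.choice(len(pair_list), size=s, replace=False) if s else []
        similar_set = {pair_list[int(k)] for k in np.asarray(chosen).ravel()}
        similar_pairs_truth[drug] = sorted([list(p) for p in similar_set])

        for (c1, c2) in pair_list:
            is_similar_pair = (c1, c2) in similar_set
            first = True
            for pa in members[c1]:
                for pb in members[c2]:
                    # optimal transform between two rigid copies of the spec
                    t_opt = poses[pa].compose(poses[pb].inverse())
                    if is_similar_pair and first:
                        delta = rng.uniform(0.8, 2.2)
                        pval = float(rng.uniform(0.0, 0.15))
                    else:
                        delta = rng.uniform(4.0, 6.0)
                        pval = float(rng.uniform(0.02, 1.0))
                    first = False
                    offset = RigidTransform(np.eye(3), delta * _random_unit(rng))
                    records.append(
                        AlignmentRecord(
                            drug=drug,
                            site_a=SiteRef(pa, "A", 900),
                            site_b=SiteRef(pb, "A", 900),
                            transform=offset.compose(t_opt),
                            aligner_pvalue=pval,
                            tm_score=float(rng.uniform(0.2, 0.95)),
                            aligner_name="synthetic",
                        )
                    )

        g = build_graph(spec_to_instance(spec))
        rot_abs, rot_rel = rotatable_bonds(g)
        desc_rows.append(
            {
                "drug": drug,
                "mw": round(molecular_weight(spec_to_instance(spec)), 2),
                "logp": round(float(rng.normal(2.0, 2.0)), 2),
                "rotatable_abs": rot_abs,
                "rotatable_rel": round(rot_rel, 4),
            }
        )

    descriptors = pd.DataFrame(desc_rows).set_index("drug")
    sqrt_s = np.sqrt(similar_counts.astype(float))
    if degrees.std() > 0 and sqrt_s.std() > 0:
        rho_realized = float(np.corrcoef(degrees, sqrt_s)[0, 1])
    else:
        rho_realized = 0.0
    truth = {
        "seed": seed,
        "n_drugs": n_drugs,
        "rho_requested": rho,
        "rho_realized": rho_realized,
        "fraction_with_similar_requested": fraction_with_similar,
        "fraction_all_similar_requested": fraction_all_similar,
        "fraction_with_similar_realized": float(np.mean(similar_counts >= 1)),
        "fraction_all_similar_realized": float(
            np.mean(similar_counts == degrees * (degrees - 1) // 2)
        ),
        "degrees": {d: int(n) for d, n in zip(drug_ids, degrees)},
        "similar_pair_counts": {d: int(s) for d, s in zip(drug_ids, similar_counts)},
        "similar_pairs": similar_pairs_truth,
        "n_structures": struct_counter,
        "n_raw_records": len(records),
        "n_nonredundant_pairs": n_nonredundant_pairs,
        "n_similar_pairs": int(similar_counts.sum()),
    }
    return CohortBundle(
        seed=seed,
        records=records,
        ligands=ligands,
        sequences=sequences,
        cluster_of_chain=cluster_of_chain,
        chain_drugs=chain_drugs,
        descriptors=descriptors,
        pfam_of_chain=pfam_of_chain,
        truth=truth,
        specs=specs,
    )


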