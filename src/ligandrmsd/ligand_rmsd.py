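"""LigandRMSD: scoring a binding-site alignment by its ligand superposition.

A binding-site aligner (SMAP, TM-align, ...) superposes two pockets that
bind the same drug and reports a rigid transform between the two structure
frames.  Whether that alignment is *biologically* meaningful can be judged
from the ligands alone: if the pockets really bind the drug the same way,
the alignment must carry one bound ligand copy onto the other.

Given an atom correspondence m between the two ligand copies:

* ``RMSD'``  — the ligand–ligand RMSD induced by the aligner's transform
  (no re-fitting);
* ``RMSD''`` — the optimal (Kabsch) superposition RMSD of the same two
  ligands under the same correspondence;
* ``LigandRMSD = RMSD' − RMSD''``.

Subtracting the optimum makes the score independent of conformational
differences between the two bound copies: a flexible drug bound in two
different shapes can still score 0 if the aligner matched the poses as well
as is geometrically possible.  Two binding sites are called similar when
``LigandRMSD <= 3 Å`` (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .molgraph import (
    AtomMapping,
    best_superposition,
    build_graph,
    enumerate_mappings,
    name_correspondence,
)
from .pdb_io import LigandInstance
from .superpose import RigidTransform, SuperpositionResult, rmsd_under_transform

__all__ = [
    "Thresholds",
    "SiteRef",
    "AlignmentRecord",
    "LigandRMSDResult",
    "FilterComparison",
    "ligand_rmsd",
    "optimal_transform",
    "site_pair_similarity",
    "compare_filters",
]


@dataclass
class Thresholds:
    """All cut-offs of the analysis, in one place.

    ligand_rmsd_max       similarity verdict cut (Å), inclusive
    conformer_cut         conformer dendrogram cut height (Å), inclusive
    identity_cluster      sequence-identity clustering cut (percent)
    tm_similar            TM-score at/above which global folds are similar
    promiscuity_min_targets  minimum non-redundant targets to call a drug
                             promiscuous
    aligner_pvalue_cut    external aligner P-value cut; only used by
                          :func:`compare_filters` and has no default — it is
                          a property of the external aligner, not of this
                          method
    """

    ligand_rmsd_max: float = 3.0
    conformer_cut: float = 1.4
    identity_cluster: float = 95.0
    tm_similar: float = 0.5
    promiscuity_min_targets: int = 3
    aligner_pvalue_cut: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "ligand_rmsd_max",
            "conformer_cut",
            "identity_cluster",
            "tm_similar",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.promiscuity_min_targets < 1:
            raise ValueError("promiscuity_min_targets must be >= 1")

    def to_dict(self) -> dict:
        return {
            "ligand_rmsd_max": self.ligand_rmsd_max,
            "conformer_cut": self.conformer_cut,
            "identity_cluster": self.identity_cluster,
            "tm_similar": self.tm_similar,
            "promiscuity_min_targets": self.promiscuity_min_targets,
            "aligner_pvalue_cut": self.aligner_pvalue_cut,
        }


@dataclass(frozen=True)
class SiteRef:
    """One binding site: a ligand copy in a structure."""

    pdb_id: str
    chain_id: str
    residue_number: int

    def to_dict(self) -> dict:
        return {
            "pdb_id": self.pdb_id,
            "chain_id": self.chain_id,
            "residue_number": self.residue_number,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SiteRef":
        return cls(d["pdb_id"], d["chain_id"], int(d["residue_number"]))


@dataclass
class AlignmentRecord:
    """One binding-site alignment produced by an external aligner."""

    drug: str
    site_a: SiteRef
    site_b: SiteRef
    transform: RigidTransform
    aligner_pvalue: float | None = None
    tm_score: float | None = None
    aligner_name: str = ""

    def __post_init__(self) -> None:
        if self.aligner_pvalue is not None and not 0.0 <= self.aligner_pvalue <= 1.0:
            raise ValueError("aligner_pvalue must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "site_a": self.site_a.to_dict(),
            "site_b": self.site_b.to_dict(),
            "transform": self.transform.to_dict(),
            "aligner_pvalue": self.aligner_pvalue,
            "tm_score": self.tm_score,
            "aligner_name": self.aligner_name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlignmentRecord":
        return cls(
            drug=d["drug"],
            site_a=SiteRef.from_dict(d["site_a"]),
            site_b=SiteRef.from_dict(d["site_b"]),
            transform=RigidTransform.from_dict(d["transform"]),
            aligner_pvalue=d.get("aligner_pvalue"),
            tm_score=d.get("tm_score"),
            aligner_name=d.get("aligner_name", ""),
        )


@dataclass
class LigandRMSDResult:
    rmsd_aligned: float  # RMSD' (Å)
    rmsd_optimal: float  # RMSD'' (Å)
    ligand_rmsd: float  # RMSD' - RMSD'' (Å)
    mapping_size: int
    mapping_source: str
    similar: bool


def _candidates_for(ligA: LigandInstance, ligB: LigandInstance, max_candidates: int):
    gA, gB = build_graph(ligA), build_graph(ligB)
    nm = name_correspondence(ligA, ligB)
    try:
        return enumerate_mappings(gA, gB, nm, max_candidates)
    except Exception as exc:
        raise type(exc)(
            f"{ligA.chem_comp_id} vs {ligB.chem_comp_id}: {exc}"
        ) from exc


def ligand_rmsd(
    ligA: LigandInstance,
    ligB: LigandInstance,
    transform: RigidTransform,
    thresholds: Thresholds | None = None,
    max_candidates: int = 1000,
    _candidates: tuple | None = None,
) -> LigandRMSDResult:
    """Score one binding-site alignment of two copies of a drug.

    ``transform`` must carry B-frame coordinates into the A frame
    (``y = R x + t``).  The same atom mapping — the candidate minimizing
    the optimal superposition RMSD — is used for both RMSD' and RMSD'';
    the subtraction is only meaningful on a shared correspondence.

    ``_candidates`` allows a caller scoring many records of the same drug
    to reuse a pre-enumerated candidate list.
    """
    thresholds = thresholds or Thresholds()
    if _candidates is None:
        _candidates = _candidates_for(ligA, ligB, max_candidates)
    candidates, source = _candidates
    mapping, sup = best_superposition(ligA.coords, ligB.coords, candidates, source)
    rmsd_aligned = rmsd_under_transform(ligA.coords, ligB.coords, mapping, transform)
    score = rmsd_aligned - sup.rmsd
    return LigandRMSDResult(
        rmsd_aligned=rmsd_aligned,
        rmsd_optimal=sup.rmsd,
        ligand_rmsd=score,
        mapping_size=mapping.size,
        mapping_source=mapping.source,
        similar=bool(score <= thresholds.ligand_rmsd_max),
    )


def optimal_transform(
    ligA: LigandInstance, ligB: LigandInstance, max_candidates: int = 1000
) -> tuple[AtomMapping, SuperpositionResult]:
    """Mapping-optimal superposition of ligand B onto ligand A."""
    candidates, source = _candidates_for(ligA, ligB, max_candidates)
    return best_superposition(ligA.coords, ligB.coords, candidates, source)


def site_pair_similarity(results: Iterable[LigandRMSDResult]) -> bool:
    """Similarity verdict for one non-redundant target pair.

    The pair of 95%-identity clusters is similar iff at least one
    member-structure alignment scored similar.
    """
    results = list(results)
    if not results:
        raise ValueError("no scored alignment records for this target pair")
    return any(r.similar for r in results)


@dataclass
class FilterComparison:
    """LigandRMSD verdicts cross-tabulated against an aligner P-value cut."""

    n_similar_both: int
    n_similar_ligand_only: int
    n_similar_pvalue_only: int
    n_similar_neither: int
    #: LigandRMSD-similar pairs missed by the P-value cut, as a percentage
    #: of the pairs the P-value cut accepts (None when it accepts nothing).
    additional_detection_pct: float | None = field(default=None)

    @property
    def contingency(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return (
            (self.n_similar_both, self.n_similar_ligand_only),
            (self.n_similar_pvalue_only, self.n_similar_neither),
        )


def compare_filters(
    scored: Sequence[tuple[AlignmentRecord, LigandRMSDResult]],
    pvalue_cut: float,
    thresholds: Thresholds | None = None,
) -> FilterComparison:
    """Compare the LigandRMSD filter against an aligner P-value filter."""
    if not scored:
        raise ValueError("no scored records")
    missing = [rec for rec, _res in scored if rec.aligner_pvalue is None]
    if missing:
        ids = ", ".join(f"{r.drug}:{r.site_a.pdb_id}-{r.site_b.pdb_id}" for r in missing[:5])
        raise ValueError(f"records without aligner P-value: {ids}")
    counts = [[0, 0], [0, 0]]
    for rec, res in scored:
        by_lig = res.similar
        by_p = rec.aligner_pvalue <= pvalue_cut
        counts[0 if by_p else 1][0 if by_lig else 1] += 1
    n_both = counts[0][0]
    n_lig_only = counts[1][0]
    n_p_only = counts[0][1]
    n_neither = counts[1][1]
    n_pass_p = n_both + n_p_only
    pct = 100.0 * n_lig_only / n_pass_p if n_pass_p else None
    return FilterComparison(
        n_similar_both=n_both,
        n_similar_ligand_only=n_lig_only,
        n_similar_pvalue_only=n_p_only,
        n_similar_neither=n_neither,
        additional_detection_pct=pct,
    )
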