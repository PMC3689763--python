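"""Three-stage binding-site similarity pipeline and cohort analysis.

Stage 1  score every alignment record (one per aligned structure pair of a
         drug) with LigandRMSD;
Stage 2  collapse structure pairs to non-redundant target pairs via
         95%-identity clusters (a target pair is similar if at least one
         member-structure alignment is);
Stage 3  filter by LigandRMSD <= 3 Å and run the promiscuity statistics on
         the surviving pairs.

The pipeline consumes the *outputs* of an external binding-site or global
structure aligner (rigid transforms with optional P-values/TM-scores); it
never produces alignments itself.  It runs either on an in-memory
:class:`~ligandrmsd.synth_fixtures.CohortBundle` (:func:`analyze_cohort`)
or on a fixture directory of PDB files, FASTA sequences and JSON-lines
alignment records (:func:`run_pipeline`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .conformers import cluster_conformers, conformer_stats
from .ligand_rmsd import (
    AlignmentRecord,
    LigandRMSDResult,
    Thresholds,
    _candidates_for,
    compare_filters,
    ligand_rmsd,
    site_pair_similarity,
)
from .pdb_io import BlacklistConfig, extract_ligands, is_blacklisted, ligand_inventory
from .promiscuity_stats import (
    build_table,
    correlate,
    ks_compare,
    regress_combined,
    summarize_drugs,
)
from .seqcluster import cluster_targets, target_chain_for_ligand

logger = logging.getLogger("ligandrmsd")

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    structures_dir: str
    alignments_path: str
    sequences_path: str
    out_dir: str
    descriptors_path: str | None = None
    pfam_path: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    log_level: str = "INFO"
    recompute_clusters: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        thr = Thresholds(**data.pop("thresholds", {}))
        return cls(thresholds=thr, **data)

    def to_dict(self) -> dict:
        return {
            "structures_dir": self.structures_dir,
            "alignments_path": self.alignments_path,
            "sequences_path": self.sequences_path,
            "out_dir": self.out_dir,
            "descriptors_path": self.descriptors_path,
            "pfam_path": self.pfam_path,
            "thresholds": self.thresholds.to_dict(),
            "seed": self.seed,
            "log_level": self.log_level,
            "recompute_clusters": self.recompute_clusters,
        }


# ---------------------------------------------------------------------------
# scoring


def score_records(
    records: Sequence[AlignmentRecord],
    ligand_lookup,
    thresholds: Thresholds | None = None,
    max_candidates: int = 1000,
) -> list[tuple[AlignmentRecord, LigandRMSDResult]]:
    """Score every alignment record; candidate mappings cached per ligand pair."""
    thresholds = thresholds or Thresholds()
    cache: dict[tuple, tuple] = {}
    out = []
    for rec in records:
        la = ligand_lookup(rec.site_a)
        lb = ligand_lookup(rec.site_b)
        key = (
            rec.drug,
            tuple(a.name for a in la.atoms),
            tuple(a.name for a in lb.atoms),
        )
        if key not in cache:
            cache[key] = _candidates_for(la, lb, max_candidates)
        res = ligand_rmsd(la, lb, rec.transform, thresholds, _candidates=cache[key])
        out.append((rec, res))
    return out


def collapse_to_target_pairs(
    scored: Sequence[tuple[AlignmentRecord, LigandRMSDResult]],
    cluster_of_structure: Mapping[str, str],
) -> dict[tuple[str, str, str], list[tuple[AlignmentRecord, LigandRMSDResult]]]:
    """Group scored structure pairs by (drug, cluster pair), order-normalized."""
    groups: dict[tuple[str, str, str], list] = {}
    for rec, res in scored:
        ca = cluster_of_structure[rec.site_a.pdb_id]
        cb = cluster_of_structure[rec.site_b.pdb_id]
        if ca == cb:
            continue  # same non-redundant target; not a target pair
        key = (rec.drug, *sorted((ca, cb)))
        groups.setdefault(key, []).append((rec, res))
    return groups


# ---------------------------------------------------------------------------
# cohort analysis (in-memory)


def analyze_cohort(
    bundle,
    thresholds: Thresholds | None = None,
    recompute_clusters: bool = False,
    compute_conformers: bool = True,
) -> dict:
    """Run scoring, collapsing, filtering and statistics on a cohort.

    ``bundle`` provides records, ligand instances, sequences, descriptor
    table and (optionally planted) cluster assignments; see
    :class:`~ligandrmsd.synth_fixtures.CohortBundle`.  With
    ``recompute_clusters`` the 95%-identity clustering is recomputed from
    the sequences instead of taking the planted assignment.
    """
    thresholds = thresholds or Thresholds()

    if recompute_clusters or not getattr(bundle, "cluster_of_chain", None):
        cluster_of_chain = _recluster(bundle, thresholds)
    else:
        cluster_of_chain = dict(bundle.cluster_of_chain)
    cluster_of_structure = {ck.rsplit("_", 1)[0]: c for ck, c in cluster_of_chain.items()}

    # promiscuity degrees from cluster/drug links
    cluster_drugs: dict[str, set[str]] = {}
    for chain_key, cluster in cluster_of_chain.items():
        for drug in bundle.chain_drugs.get(chain_key, ()):
            cluster_drugs.setdefault(cluster, set()).add(drug)
    degrees: dict[str, int] = {}
    for cluster, drugs in cluster_drugs.items():
        for drug in drugs:
            degrees[drug] = degrees.get(drug, 0) + 1

    scored = score_records(bundle.records, bundle.ligand_for, thresholds)
    groups = collapse_to_target_pairs(scored, cluster_of_structure)

    similar_counts: dict[str, int] = {d: 0 for d in degrees}
    structural_counts: dict[str, int] = {d: 0 for d in degrees}
    pair_rows = []
    for (drug, ca, cb), members in sorted(groups.items()):
        similar = site_pair_similarity([res for _r, res in members])
        tms = [r.tm_score for r, _ in members if r.tm_score is not None]
        structurally_similar = similar and bool(tms) and max(tms) >= thresholds.tm_similar
        if similar:
            similar_counts[drug] = similar_counts.get(drug, 0) + 1
        if structurally_similar:
            structural_counts[drug] = structural_counts.get(drug, 0) + 1
        best = min(res.ligand_rmsd for _r, res in members)
        pair_rows.append(
            {
                "drug": drug,
                "cluster_a": ca,
                "cluster_b": cb,
                "n_member_alignments": len(members),
                "best_ligand_rmsd": round(best, 2),
                "similar": similar,
            }
        )
    site_pairs = pd.DataFrame(
        pair_rows,
        columns=[
            "drug", "cluster_a", "cluster_b", "n_member_alignments",
            "best_ligand_rmsd", "similar",
        ],
    )

    conformer_counts: dict[str, int] = {}
    flexibility = None
    if compute_conformers:
        by_drug: dict[str, list] = {}
        for _site, lig in sorted(bundle.ligands.items()):
            by_drug.setdefault(lig.chem_comp_id, []).append(lig)
        clusterings = {}
        for drug, instances in sorted(by_drug.items()):
            cl = cluster_conformers(instances, cut=thresholds.conformer_cut)
            clusterings[drug] = cl
            conformer_counts[drug] = cl.n_clusters
        flexibility = conformer_stats(clusterings)

    pfam_counts = _pfam_counts(bundle, cluster_of_chain)

    table = build_table(
        degrees=degrees,
        similar_pair_counts=similar_counts,
        conformer_counts=conformer_counts,
        descriptors=bundle.descriptors,
        pfam_counts=pfam_counts,
        structural_similar_counts=structural_counts,
        min_targets=thresholds.promiscuity_min_targets,
    )

    report = {
        "thresholds": thresholds.to_dict(),
        "funnel": {
            "n_raw_alignments": len(scored),
            "n_nonredundant_pairs": len(groups),
            "n_similar_pairs": int(site_pairs["similar"].sum()) if len(site_pairs) else 0,
        },
        "correlations": _correlation_panels(table),
        "distribution_tests": _distribution_tests(table),
        "regression": _safe_regression(table),
        "summary": summarize_drugs(table),
        "n_promiscuous_drugs": int(len(table)),
    }
    funnel = report["funnel"]
    funnel["nonredundant_fraction"] = (
        funnel["n_nonredundant_pairs"] / funnel["n_raw_alignments"]
        if funnel["n_raw_alignments"]
        else None
    )
    funnel["similar_fraction_of_nonredundant"] = (
        funnel["n_similar_pairs"] / funnel["n_nonredundant_pairs"]
        if funnel["n_nonredundant_pairs"]
        else None
    )

    pvals = [r.aligner_pvalue for r in bundle.records]
    if thresholds.aligner_pvalue_cut is not None and all(p is not None for p in pvals):
        fc = compare_filters(scored, thresholds.aligner_pvalue_cut, thresholds)
        report["filter_comparison"] = {
            "pvalue_cut": thresholds.aligner_pvalue_cut,
            "contingency": fc.contingency,
            "additional_detection_pct": fc.additional_detection_pct,
        }

    report["_tables"] = {
        "promiscuity_table": table,
        "site_pairs": site_pairs,
        "flexibility": flexibility,
        "scored": scored,
    }
    return report


def _recluster(bundle, thresholds: Thresholds) -> dict[str, str]:
    """Recompute 95%-identity clusters per drug from the sequences."""
    chains_by_drug: dict[str, dict[str, str]] = {}
    for chain_key, drugs in bundle.chain_drugs.items():
        for drug in drugs:
            chains_by_drug.setdefault(drug, {})[chain_key] = bundle.sequences[chain_key]
    out: dict[str, str] = {}
    for drug, chains in sorted(chains_by_drug.items()):
        clusters = cluster_targets(chains, identity_cut=thresholds.identity_cluster)
        for c in clusters:
            for m in c.members:
                out[m] = f"{drug}/c{c.cluster_id}"
    return out


def _pfam_counts(bundle, cluster_of_chain) -> dict[str, int] | None:
    pfam = getattr(bundle, "pfam_of_chain", None)
    if not pfam:
        return None
    fams: dict[str, set[str]] = {}
    for chain_key, fam in pfam.items():
        for drug in bundle.chain_drugs.get(chain_key, ()):
            fams.setdefault(drug, set()).add(fam)
    return {d: len(f) for d, f in fams.items()}


def _panel(table: pd.DataFrame, column: str, transform: str = "none") -> dict | None:
    data = table[["target_count", column]].dropna()
    if len(data) < 3:
        return {"skipped": "fewer than 3 complete rows"}
    try:
        rep = correlate(data["target_count"], data[column], y_transform=transform)
    except ValueError as exc:
        return {"skipped": str(exc)}
    return {"r": rep.r, "p_value": rep.p_value, "n": rep.n, "y_transform": rep.y_transform}


def _correlation_panels(table: pd.DataFrame) -> dict:
    return {
        "molecular_weight": _panel(table, "mw"),
        "logp": _panel(table, "logp"),
        "conformer_clusters": _panel(table, "conformer_cluster_count"),
        "pfam_families": _panel(table, "pfam_family_count"),
        "structural_similar_sqrt": _panel(table, "structural_similar_pair_count", "sqrt"),
        "similar_sites_sqrt": _panel(table, "similar_pair_count", "sqrt"),
    }


def _distribution_tests(table: pd.DataFrame) -> dict:
    out = {}
    with_sim = table[table["similar_pair_count"] >= 1]
    without = table[table["similar_pair_count"] == 0]
    for col in ("mw", "logp"):
        a = with_sim[col].dropna()
        b = without[col].dropna()
        if len(a) and len(b):
            cmp = ks_compare(a, b)
            out[f"{col}_with_vs_without_similar"] = {
                "D": cmp.statistic,
                "p_value": cmp.p_value,
                "n_a": cmp.n_a,
                "n_b": cmp.n_b,
            }
        else:
            out[f"{col}_with_vs_without_similar"] = {"skipped": "a group is empty"}
    return out


def _safe_regression(table: pd.DataFrame) -> dict:
    from .promiscuity_stats import REGRESSION_PREDICTORS

    usable = [
        p
        for p in REGRESSION_PREDICTORS
        if p in table and table[p].dropna().nunique() > 1
    ]
    dropped = [p for p in REGRESSION_PREDICTORS if p not in usable]
    if len(usable) < 1:
        return {"skipped": "no predictor with variance", "dropped": dropped}
    try:
        rep = regress_combined(table, predictors=usable)
    except ValueError as exc:
        return {"skipped": str(exc), "dropped": dropped}
    return {
        "coefficients": rep.coefficients,
        "r_squared": rep.r_squared,
        "f_pvalue": rep.f_pvalue,
        "n": rep.n,
        "dropped": dropped,
    }


# ---------------------------------------------------------------------------
# file-based pipeline


@dataclass
class _FileCohort:
    records: list[AlignmentRecord]
    ligands: dict[tuple[str, str, int], object]
    sequences: dict[str, str]
    cluster_of_chain: dict[str, str] | None
    chain_drugs: dict[str, set[str]]
    descriptors: pd.DataFrame
    pfam_of_chain: dict[str, str]
    inventory: pd.DataFrame

    def ligand_for(self, site):
        return self.ligands[(site.pdb_id, site.chain_id, site.residue_number)]


def load_fixture_dir(
    path: str | Path, blacklist: BlacklistConfig | None = None
) -> _FileCohort:
    """Read a fixture directory (structures/, alignments.jsonl, sequences.fasta)."""
    from Bio import SeqIO

    path = Path(path)
    blacklist = blacklist or BlacklistConfig()
    ligands: dict[tuple[str, str, int], object] = {}
    chain_drugs: dict[str, set[str]] = {}
    all_ligs = []
    for pdb_file in sorted((path / "structures").glob("*.pdb")):
        pdb_id = pdb_file.stem
        chains, ligs = extract_ligands(pdb_file.read_text(), pdb_id)
        for lig in ligs:
            all_ligs.append(lig)
            if is_blacklisted(lig, blacklist):
                continue
            ligands[lig.site] = lig
            target = target_chain_for_ligand(chains, lig) or (chains[0] if chains else None)
            if target is not None:
                chain_key = f"{pdb_id}_{target.chain_id}"
                chain_drugs.setdefault(chain_key, set()).add(lig.chem_comp_id)
    sequences = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(str(path / "sequences.fasta"), "fasta")
    }
    records = [
        AlignmentRecord.from_dict(json.loads(line))
        for line in (path / "alignments.jsonl").read_text().splitlines()
        if line.strip()
    ]
    desc_path = path / "descriptors.tsv"
    if desc_path.exists():
        descriptors = pd.read_csv(desc_path, sep="\t").set_index("drug")
    else:
        descriptors = pd.DataFrame(columns=["mw", "logp", "rotatable_abs", "rotatable_rel"])
    pfam_path = path / "pfam.tsv"
    pfam = {}
    if pfam_path.exists():
        pf = pd.read_csv(pfam_path, sep="\t")
        pfam = dict(zip(pf["chain"], pf["family"]))
    return _FileCohort(
        records=records,
        ligands=ligands,
        sequences=sequences,
        cluster_of_chain=None,
        chain_drugs=chain_drugs,
        descriptors=descriptors,
        pfam_of_chain=pfam,
        inventory=ligand_inventory(all_ligs, blacklist),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full three-stage pipeline on files and write a report bundle."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fixture_dir = Path(config.structures_dir).parent
    logger.info("stage 0: loading inputs from %s", fixture_dir)
    cohort = load_fixture_dir(fixture_dir)
    logger.info(
        "loaded %d ligand instances, %d alignment records, %d sequences",
        len(cohort.ligands), len(cohort.records), len(cohort.sequences),
    )
    report = analyze_cohort(
        cohort,
        thresholds=config.thresholds,
        recompute_clusters=config.recompute_clusters,
        compute_conformers=True,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = report.pop("_tables")
    cohort.inventory.to_csv(out / "inventory.tsv", sep="\t", index=False)
    tables["promiscuity_table"].to_csv(out / "promiscuity_table.tsv", sep="\t", index=False)
    tables["site_pairs"].to_csv(out / "site_pairs.tsv", sep="\t", index=False)
    if tables["flexibility"] is not None:
        tables["flexibility"].to_csv(out / "flexibility.tsv", sep="\t", index=False)
    _write_scored(tables["scored"], out / "scored_pairs.tsv")
    with open(out / "analysis.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    manifest = {
        "package": "ligandrmsd",
        "version": __version__,
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "config": config.to_dict(),
        "funnel": report["funnel"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    report["_tables"] = tables
    return report


def _write_scored(scored, path: Path) -> None:
    rows = []
    for rec, res in scored:
        rows.append(
            {
                "drug": rec.drug,
                "site_a": f"{rec.site_a.pdb_id}:{rec.site_a.chain_id}:{rec.site_a.residue_number}",
                "site_b": f"{rec.site_b.pdb_id}:{rec.site_b.chain_id}:{rec.site_b.residue_number}",
                "rmsd_aligned": round(res.rmsd_aligned, 2),
                "rmsd_optimal": round(res.rmsd_optimal, 2),
                "ligand_rmsd": round(res.ligand_rmsd, 2),
                "mapping_size": res.mapping_size,
                "mapping_source": res.mapping_source,
                "similar": res.similar,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _json_default(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, pd.DataFrame):
        return x.to_dict("records")
    raise TypeError(f"not JSON-serializable: {type(x)}")
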