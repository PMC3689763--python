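# ligandrmsd

Scoring protein binding-site structural alignments by ligand superposition,
plus the statistics machinery for structure-based drug-promiscuity analysis.

## The problem

A promiscuous drug — one that binds three or more distinct protein targets —
is the raw material of drug repositioning and the cause of many off-target
effects. Structural data lets us ask *why* a drug is promiscuous: is the
molecule flexible enough to adapt to different pockets, or do its targets
share similar binding sites even when their sequences and folds differ?

Binding-site aligners (SMAP, and global tools like TM-align) superpose two
pockets and report a rigid transform between the structure frames, but their
own scores do not tell you whether the two sites actually bind the drug *in
the same way*. When both pockets hold a copy of the same ligand, the ligands
themselves are the ideal yardstick.

## The score

For two bound copies `l_a`, `l_b` of a drug and an alignment transform `T`
(convention `y = R·x + t`, carrying frame B into frame A), an atom
correspondence `m` between the copies is found by atom-name matching, graph
isomorphism, or maximum common subgraph (MCS) for non-identical compounds.
Then

```
RMSD'  = RMSD over m of (l_a, T·l_b)        # induced by the alignment
RMSD'' = min over rigid G of RMSD(l_a, G·l_b)   # Kabsch optimum, same m
LigandRMSD = RMSD' − RMSD''
```

Subtracting the optimum makes the score independent of conformational
differences between the two bound copies: a flexible drug bound in two
shapes still scores 0 when the aligner matched the poses as well as
geometrically possible. Two binding sites are **similar** when
`LigandRMSD ≤ 3 Å`. When a molecule is symmetric, up to 1000 candidate
mappings (automorphisms / MCS embeddings) are enumerated and the one
minimizing `RMSD''` is used for both terms, so arbitrary labels of
equivalent atoms never inflate the score.

Around the score, the package implements the full analysis pipeline:

* `pdb_io` — PDB parsing, ligand extraction (heavy atoms, altloc
  resolution), bond inference, and the dataset blacklist (≤ 5 heavy atoms
  or a listed cofactor/detergent/solute);
* `molgraph` — element-labeled molecular graphs, atom mapping, rotatable
  bonds and molecular weight;
* `superpose` — Kabsch superposition (proper rotations only) and RMSD
  under a fixed transform;
* `conformers` — symmetry-corrected conformer RMSDs and average-linkage
  clustering cut at 1.4 Å to count a drug's bound shapes;
* `seqcluster` — Needleman–Wunsch (BLOSUM62, gap 10/0.5), 95 %-identity
  single-linkage clustering into non-redundant targets, promiscuity degree;
* `promiscuity_stats` — Pearson correlations (with √-transformed pair
  counts), Kolmogorov–Smirnov comparisons, OLS regression, drug summaries;
* `synth_fixtures` — seeded generators for every pipeline input, with
  ground truth attached;
* `pipeline` / `cli` — the three-stage pipeline (score → collapse to
  non-redundant target pairs → filter by LigandRMSD) with TSV/JSON reports.

## Worked example

```pycon
>>> import numpy as np
>>> from ligandrmsd import ligand_rmsd, optimal_transform, RigidTransform
>>> from ligandrmsd.synth_fixtures import chain_ligand_spec, spec_to_instance, perturb_torsion
>>> spec = chain_ligand_spec(10, seed=5)            # a 10-heavy-atom drug
>>> lig_a = spec_to_instance(spec, "AAAA")
>>> bent = perturb_torsion(spec.coords, spec.bonds, (4, 5), 60.0)
>>> lig_b = spec_to_instance(spec, "BBBB", coords=bent)   # other conformer
>>> _m, sup = optimal_transform(lig_a, lig_b)
>>> res = ligand_rmsd(lig_a, lig_b, sup.transform)  # a perfect alignment
>>> print(f"RMSD'={res.rmsd_aligned:.2f}  RMSD''={res.rmsd_optimal:.2f}  "
...       f"LigandRMSD={res.ligand_rmsd:.2f}  similar={res.similar}")
RMSD'=0.55  RMSD''=0.55  LigandRMSD=0.00  similar=True
>>> copy = spec_to_instance(spec, "CCCC")                 # exact rigid copy
>>> _m, sup2 = optimal_transform(lig_a, copy)
>>> off = RigidTransform(np.eye(3), np.array([0., 0., 3.5]))  # a bad alignment
>>> res = ligand_rmsd(lig_a, copy, off.compose(sup2.transform))
>>> print(f"LigandRMSD={res.ligand_rmsd:.2f}  similar={res.similar}")
LigandRMSD=3.50  similar=False
```

The score reads 0 for the perfectly aligned pair although the two copies
are different conformers (`RMSD'' = 0.55 Å`), and misplacing an identical
copy by 3.5 Å scores exactly 3.5 Å — beyond the 3 Å similarity cut.

A full synthetic cohort, end to end:

```bash
ligandrmsd simulate --seed 5 --n-drugs 8 --out fixture/
ligandrmsd run --fixture-dir fixture/ --out report/ --seed 5
# raw alignments: 216  non-redundant pairs: 57  similar pairs: 18
```

`report/` then contains the scored pairs, the non-redundant site pairs,
per-drug flexibility and promiscuity tables, the correlation/KS/regression
panels (`analysis.json`) and a run manifest.

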