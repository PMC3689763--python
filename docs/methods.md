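# Methods

This note records the models, conventions and design decisions behind the
package, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The LigandRMSD score

An external binding-site (or global structure) aligner superposes two
pockets that bind the same drug and reports a rigid transform `T` between
the two structure frames. The score judges `T` by the two bound ligand
copies alone:

* a single atom correspondence `m` is chosen between the two copies
  (see *Atom mapping* below);
* `RMSD'` is the root-mean-square deviation over `m` after applying `T`
  to the second copy — no re-fitting;
* `RMSD''` is the Kabsch-optimal superposition RMSD of the same two
  copies under the same `m`;
* `LigandRMSD = RMSD' − RMSD''`, and a pair of binding sites is *similar*
  when `LigandRMSD ≤ 3 Å` (inclusive, like every threshold comparison in
  the package).

Using the *same* mapping for both terms is essential — the subtraction is
only meaningful on a shared correspondence — and makes the score
nonnegative up to floating-point error, since `RMSD''` is the optimum of
the quantity `RMSD'` evaluates. Because the optimum absorbs any
conformational difference between the two copies, the score measures only
the quality of the alignment: for identical rigid copies, composing the
optimal transform with a pure translation of length `d` gives exactly
`LigandRMSD = d` (centroids coincide at the optimum, so
`RMSD'² = RMSD''² + d²` with `RMSD'' = 0`). This analytic identity anchors
several tests.

The transform convention is `y = R·x + t`, frame B → frame A, stated in
every serialized transform. Rotations are proper (`det R = +1`);
reflections are rejected at construction and never produced by the Kabsch
solver (SVD of the cross-covariance with determinant sign correction), as
physical ligands cannot be mirrored.

## Atom mapping

Three routes, in priority order:

1. **name match** — both copies are the same chemical component with
   corresponding atom names;
2. **graph isomorphism** of the element-labeled bond graphs;
3. **maximum common connected element-matched subgraph** (RDKit FMCS,
   atom-count maximized), for chemically different compounds.

Bond orders are ignored: PDB files carry no reliable orders, and
element-level matching is robust for the identical-drug comparisons that
dominate the analysis. The MCS is required to be connected — disconnected
fragments yield geometrically meaningless superpositions. Whenever more
than one candidate mapping exists (molecular symmetry, multiple MCS
embeddings), up to 1000 candidates are enumerated in a deterministic
sorted order and the one minimizing `RMSD''` is selected; this is the
standard symmetry correction that stops an arbitrary labeling of
equivalent atoms (e.g. a flipped aromatic ring) from inflating an RMSD.
The choice of the `RMSD''`-minimizing candidate among equally sized MCS
embeddings is this package's own convention. A mapping needs ≥ 3
non-collinear atoms; below that a rigid superposition is under-determined
and the pair is reported as unmappable.

## Ligand extraction and the blacklist

Heavy atoms only, everywhere: X-ray structures usually lack hydrogens and
all dataset rules count non-hydrogen atoms. Alternate locations resolve to
the highest occupancy (ties: altloc `A`, then blank). Waters are never
ligands; neither are modified amino-acid residues that are peptide-linked
into a polymer chain (detected by tabulated residue type plus a ≤ 1.9 Å
C–N linkage to a neighbouring residue). CONECT records define ligand
bonds when present; otherwise bonds are inferred at ≤ (sum of covalent
radii + 0.45 Å), the usual crystallographic heuristic.

A ligand is blacklisted when it has ≤ 5 heavy atoms or its component id is
on the excluded list (`data/blacklist.yaml`). The shipped list covers
common cryoprotectants, buffers, detergents, reducing agents, ubiquitous
cofactors and glycosylation sugars; it is deliberately an editable config
file, since no canonical list exists and dataset stringency is a study
choice.

## Conformer clustering

All bound copies of a drug are compared pairwise by the symmetry-corrected
optimal superposition RMSD (minimum over the enumerated candidate
mappings of the Kabsch RMSD — a single RMSD engine with a min-over-mappings
guard against suboptimal correspondences). The distance matrix is
clustered by average-linkage agglomeration and the dendrogram cut at
**1.4 Å, inclusive** (a merge at exactly the cut height joins). The cut
stays well below the ~2.5 Å still accepted as "same pose" in docking
practice, so clusters correspond to genuinely distinct bound shapes. Ties
between merge candidates are broken deterministically (scipy's linkage on
a fixed instance order; labels renumbered by smallest member index).
Average linkage on RMSDs carries no metric-space guarantee; determinism is
the property relied upon.

## Sequence clustering and promiscuity degree

Chains are aligned globally (Needleman–Wunsch) with BLOSUM62, gap open 10,
gap extension 0.5 — a gap of length L costs `10 + (L−1)·0.5` — and end
gaps penalized like internal gaps. Nonstandard residues map to `X`, scored
0 against everything. Percent identity uses the full alignment length
(gap columns included) as denominator; the alternative short-sequence
denominator was rejected for reproducibility, since the identity cut then
depends on which sequence is called "short". Chains at ≥ 95 % identity are
merged by single-linkage transitive closure into non-redundant targets
(representative: longest sequence, ties lexicographic). Clustering is
recomputed internally rather than consumed from an external resource, so
the pipeline runs self-contained. A drug's promiscuity degree is the
number of clusters containing a chain it is co-crystallized with;
**degree ≥ 3 defines a promiscuous drug**. The target chain of a ligand
copy is the chain with the most heavy atoms within 5 Å.

## Statistics

* Pearson correlations with the two-sided t-test p-value
  (`t = r·√((n−2)/(1−r²))`, n−2 df — the `cor.test` convention); a
  permutation test serves as oracle in the test suite only.
* Pair-count responses (similar-site pairs, structurally similar pairs)
  are square-root transformed before correlating: a drug with n targets
  has up to `n(n−1)/2` pairs, so counts grow quadratically in the degree.
* Two-sample Kolmogorov–Smirnov comparisons with the asymptotic p-value;
  at the group sizes used here (≈ 100 per group) the asymptotic rejection
  rate at α = 0.05 is calibrated within ±0.02 (verified in the suite).
* OLS regression of the degree on all drug properties jointly (logP, MW,
  conformer-cluster count, relative and absolute rotatable-bond counts),
  with R² and overall F-test; rank-deficient designs are rejected with the
  collinear columns named.
* Missing optional descriptors are excluded pairwise per analysis, not
  listwise, maximizing the n of each panel. The promiscuity table contains
  promiscuous drugs only (degree ≥ 3); this scope is configurable.

Rotatable bonds: an acyclic bond whose endpoints both have heavy-atom
degree ≥ 2; ring bonds never count; the relative count divides by the
total bond count. Molecular weight sums standard atomic masses over the
atoms present (hydrogens are absent from the files; a formula override
gives hydrogen-complete weights when needed).

## Synthetic data: what it emulates, what it does not

The generators reproduce the *information structure* of a structural
drug–target study, not protein physics:

* **complex pairs** — a schematic helical protein plus a ligand, rigidly
  moved with optional isotropic Gaussian coordinate noise; the exact
  inverse motion is returned as ground truth. Isotropic noise makes the
  expected inflation of `RMSD'` analytically predictable (≈ σ√6 for two
  noised copies), which the tests bound. PDB serialization rounds
  coordinates to 3 decimals, so file-round-tripped scores are exact only
  to a few 10⁻³ Å; full-precision in-memory instances are used where
  1 µÅ-level identities are asserted.
* **conformer sets** — cluster centers are random point clouds over the
  molecule's topology, members add small Gaussian jitter; all pairwise
  bounds (intra ≤ 0.5 Å, inter ≥ 3 Å by default) are *verified* with the
  package's own distance engine, with margin-based accept/reject sampling
  and bounded retries.
* **cohorts** — drugs receive promiscuity degrees from a geometric-tailed
  distribution starting at 3 (capped at 20, matching the shape of a
  heavily skewed real degree distribution); target clusters receive
  member structures (Poisson redundancy), within-cluster sequences at
  ~98 % identity and across-cluster sequences at background identity;
  each alignment record's transform is the true optimal transform
  composed with a translation that lands the score on the intended side
  of the 3 Å cut (0.8–2.2 Å for similar, 4–6 Å for dissimilar). A planted
  correlation ρ between degree and √(similar-pair count) is realized
  through a Gaussian latent construction; the latent scale (0.75) was set
  during generator design so integer rounding/clipping leaves the
  realized correlation essentially unbiased, and the truth record carries
  both the requested and the realized value. Cohort drugs carry a single
  rigid conformer so the planted offsets are exact; consequently the
  conformer-count correlation panel is degenerate on cohorts and the
  pipeline skips zero-variance panels with a note — conformer-flexibility
  behaviour is exercised by the dedicated conformer-set generator
  instead.

Passing tests on these fixtures demonstrate the correctness of the
algorithms and the pipeline bookkeeping — they do not validate biological
conclusions on real PDB data, which additionally face disorder, missing
atoms, covalent ligands and aligner idiosyncrasies.

## Problem sizes and numerical choices

The test and acceptance workloads use sizes chosen to exercise each
property at meaningful statistical strength: 1000 random draws for score
nonnegativity; 100 point sets against a rotation-grid + local-polish
brute force (agreement within 10⁻³ Å); 200 random graph pairs (≤ 8 nodes)
against exhaustive common-subgraph search; 50 seeds per planted conformer
count k ∈ {1, 3, 9}; 500 short sequence pairs against exhaustive alignment
enumeration; 2000 KS null trials; 200 cohorts of 164 drugs for planted-
correlation recovery (±0.15 band). Degenerate inputs (collinear mappings,
empty samples, zero-variance vectors, rank-deficient designs) raise typed
errors rather than returning numbers. All acceptance-script randomness
derives from the single `--seed` via spawned subseeds.

## Known limitations

* PDB only; no mmCIF, no protonation or charge assignment, no
  aromaticity/stereochemistry perception.
* The score presumes the two sites bind the *same or substructure-related*
  compound; with a tiny MCS (< 3 atoms) pairs are unmappable by design.
* The external aligner's P-value model is consumed, never reproduced; the
  P-value cut for filter comparisons is a required user setting with no
  shipped default.
* The blacklist is an editable approximation, not a canonical list.
* Average-linkage merge heights are not monotone-metric guaranteed;
  results are deterministic but can depend on tie order in pathological
  distance matrices.
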