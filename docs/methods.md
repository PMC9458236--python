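# Methods

## Scope and data flow

The package post-processes receptor-ensemble docking output; it never runs
a docking engine, MD, or structure preparation. Inputs are prepared
receptor structures (PDB/PDBQT), docked ligand poses (multi-model PDBQT
with `REMARK VINA RESULT` score lines, or MOL2), reference ligands for
pocket definition, and SMILES-with-name activity lists (carried as opaque
bookkeeping text, never interpreted chemically). The pipeline is

    poses ─► PLIF per pose ─► ensPLIF fractions per compound ─► table
                                                                  │
    pocket residues ◄─ reference ligand                           ▼
                                              score-cutoff eval / CART

## Pocket definition

A residue belongs to the pocket if any of its heavy atoms lies within a
cutoff (default 5 Å) of any reference-ligand heavy atom. This is a plain
heavy-atom distance criterion; no solvent-accessible-surface computation is
done. Per-receptor lists are merged into a consensus list as the sorted
union keyed by (residue number, insertion code); the fingerprint length is
therefore fixed across the ensemble. The docking box is an explicit,
documented approximation: centered on the reference-ligand heavy-atom
centroid, sized to the selected residues' axis-aligned extent plus
2 × padding (default 5 Å) per dimension, floored at the ligand extent. The
box only feeds an external docking engine and never enters the fingerprint
math, so this choice does not affect any downstream number.

## Chemical perception

Protein residues are perceived from hand-curated templates over the 20
canonical amino acids (PDB atom naming): aromatic rings (Phe, Tyr, His
imidazole, Trp's two fused rings), donors with their polar hydrogens,
acceptors, cation groups (Lys NZ, Arg guanidinium), anion groups (Asp/Glu
carboxylates), and apolar atoms (side-chain C/S with no O/N neighbor in
the template). Main-chain carbonyl O (acceptor) and amide N (donor) are
included so that backbone interactions exist to be switched off. Fixed
protonation conventions: Asp/Glu anionic, Lys/Arg cationic, His neutral
with donor/acceptor roles read from which ring hydrogens (HD1/HE2) the
records contain — cationic only when both are present, and assumed
NE2-protonated when neither is.

Ligands are perceived rule-driven because docking-output PDBQT has no bond
records: bonds by the covalent-radius criterion d ≤ rᵢ + rⱼ + 0.45 Å (MOL2
bonds trusted when present); rings from a minimum cycle basis, aromatic if
5–6-membered, all C/N/O/S, planar within 7.5° mean out-of-plane deviation,
members with ≤ 3 heavy neighbors; donors are N/O with ≥ 1 bound H;
acceptors are N/O not positively charged; cations are tetravalent N or
charge ≥ +0.30 e; anions are terminal-O pairs on a common C/P/S center or
O with charge ≤ −0.30 e; apolar are C/S bonded only to C/S/H, plus
halogens (the scheme has no halogen-bond class, so halogens count as
hydrophobic contact partners). These ligand-typing rules are a documented
approximation of SMARTS-based typing and are isolated in one module so
they can be swapped without touching detection.

## Interaction detection

Seven classes per residue, fixed block order (apolar, aromatic
face-to-face, aromatic edge-to-face, H-bond residue-donor, H-bond
residue-acceptor, ionic residue-cation, ionic residue-anion). This order
is load-bearing: descriptor `N` of the output table is bit `N` of the
fingerprint, and the packaged AChE examples (e.g. 22 = Asp72 hydrophobic,
158 = Ser122 donor H-bond, 374 = Tyr442 edge-to-face) depend on it.

Geometric defaults (all configurable, logged into output headers):

| parameter                 | default | meaning                                  |
|---------------------------|--------:|------------------------------------------|
| `apolar_cutoff`           |  4.5 Å  | max apolar heavy-atom distance            |
| `aromatic_centroid_cutoff`|  4.0 Å  | max ring-centroid separation              |
| `f2f_max_plane_angle`     |   30°   | plane angle ≤ → face-to-face, else edge   |
| `hbond_da_cutoff`         |  3.5 Å  | max donor–acceptor distance               |
| `hbond_min_dha_angle`     |  135°   | min D–H···A angle when H is recorded      |
| `ionic_cutoff`            |  4.0 Å  | max closest inter-group distance          |

These follow the classical structural interaction-fingerprint scheme.
Plane angles use absolute values (ring-normal sign is arbitrary). When a
donor has no recorded polar hydrogen the angle test is skipped and the
H-bond is distance-only; this is intentional and logged, since docking
outputs vary in hydrogen handling. With `nobb` (the default) receptor
atoms are restricted to side-chain atoms *before* any detection, so
`nobb` bits are always a subset of full bits. Glycine consequently can
contribute nothing under `nobb` (its only non-backbone content is
nothing), which is accepted behavior.

## Ensemble aggregation

ensPLIF value = fraction of all aggregated poses (receptors × replicates ×
modes) in which the bit is set; with the standard 2 × 3 × 5 protocol every
value is k/30. `dg` is the mean over runs of each run's best (lowest)
score. An optional score cutoff drops poses with score > cutoff before
aggregation; the denominator is then the retained pose count, and a
compound with no retained pose gets an all-zero descriptor row (flagged in
the log) with `dg` kept from the unfiltered runs. The boundary convention
is `score ≤ cutoff` ("maximum cutoff docking score"). Pose-level filtering
and compound-level gating (`classify_by_score` on `dg`) are both provided,
as they answer different questions and published protocols are not always
explicit about which they used.

## Prior-weighted CART

`PriorDecisionTreeClassifier` implements binary CART with class priors
`(π₀, π₁)`: prior-adjusted node proportions
p(j|t) = π_j·n_j(t)/N_j / Σ_k π_k·n_k(t)/N_k drive the Gini impurity, and
the node label is argmax_j π_j·n_j(t)/N_j. Internally this is realized
exactly as weighted CART with per-class sample weights w_j = π_j/N_j
(algebraically identical), so with priors equal to empirical frequencies
the estimator reduces to plain unweighted Gini CART — a property used as a
test oracle against scikit-learn's tree, while R's `rpart` with matched
control parameters serves as the independent cross-check for the
prior-weighted case.

Defaults follow recursive-partitioning convention: `min_split` 20,
`min_leaf` 7, `cp` 0.01, `max_depth` 30. Candidate thresholds are
midpoints between consecutive distinct observed values per column; ties on
impurity gain break toward the lowest column index, then the lowest
threshold, making fits deterministic. Growth stops on the size/depth
limits; the grown tree is then cost-complexity pruned with
α = cp · R(root), where R is the prior-weighted misclassification risk.
There are no surrogate splits and no missing-value handling — descriptor
tables are complete by construction — and exact numeric replication of the
R library's internals is a non-goal.

Prior convention: priors are written (inactive, active), so "0.9:0.1" puts
0.1 on the actives — which still up-weights them roughly six-fold relative
to a ~1.7% prevalence. Grid searches cover both orderings; selection
maximizes training BA subject to a training-F1 floor, breaking ties toward
the less extreme prior.

Validity checks: (1) overfitting — stratified k-fold CV (default 5),
flagged when train BA − CV BA > 0.1; (2) cross-correlation — Pearson |r|
between the fitted tree's split descriptors, flagged above 0.8,
zero-variance columns reported as 0 with a warning; (3) chance
correlation — y-scrambling (default 20 refits on permuted labels from one
seeded generator), flagged when the real training BA fails to exceed the
95th percentile of the scrambled distribution. On heavily imbalanced
tables with many descriptors, *training* BA on scrambled labels can sit
well above 0.5 (trees fit noise); the chance-correlation comparison is
against that empirical null, not against 0.5, precisely for this reason.

## Screening statistics

EF is defined as sensitivity divided by the false-positive rate — the
positive likelihood ratio. This is deliberate and documented prominently:
for whole-library binary classification it is the unique simple ratio
consistent with the published AChE benchmark values this package
reproduces in its tests (the common top-fraction "precision/prevalence"
definition does not reproduce them). EF is +∞ for a classifier with
TP > 0 and FP = 0, and 0 when TP = 0. The cutoff scan evaluates F1 at
every distinct score, ties toward the stricter (more negative) cutoff.
The replication rule picks the smallest replicate count within `tolerance`
(default 0) of the best F1 — the protocol-economy rule that fixed the
standard protocol at 3 replicates × 2 clusters = 6 runs per compound.
Compounds that fail structure preparation upstream are accepted as
forced-negative predictions when counting confusion matrices.

## Synthetic generators

The generators exist to give every stage a ground truth without external
data, and are first-class tested code:

* **Planted complexes** — single side chains on a short backbone stub,
  one residue per planted contact, spaced 30 Å apart (far beyond every
  cutoff) so contacts never cross-talk; probe fragments (bare C, charged
  N/O, aromatic ring, hydroxyl donor/acceptor) are placed at exact
  distances/angles. Aromatic probes carry radial O substituents so a
  stacking spec plants exactly the aromatic bit without an apolar
  side-channel. Geometries are chemically minimal, not physically
  realistic: they exercise detector semantics, not force fields, so
  passing tests demonstrate correct geometry classification — not docking
  accuracy on real complexes.
* **Emulated docking output** — multi-model PDBQT with score lines, scores
  sorted ascending within each run, byte-reproducible under a seed.
* **Planted tables** — descriptors quantized to k/30 with a planted
  decision rule (actives satisfy all conditions, decoys violate at least
  one, both sides subject to a configurable noise rate) and
  class-conditional normal docking scores, by default actives
  N(−9.5, 0.5) and decoys N(−7.5, 0.7) kcal/mol so that a cutoff near
  −8.7 separates the classes imperfectly and the cutoff scan is exercised
  realistically. What planted tables do *not* emulate: correlated
  descriptors from shared binding modes, per-receptor heterogeneity, and
  compounds lost to preparation failures.

Test problem sizes are chosen desk-scale: oracle equivalence of the
fingerprint detector is checked on 200 randomized planted complexes;
tree checks use tables of a few hundred to a few thousand compounds at
the campaign's ~1.7% prevalence, which is where the prior-weighting effect
is visible while fits stay sub-second.

## Known limitations

* Ligand typing is geometric/charge-based, not SMARTS-based; unusual
  functional groups (ylides, metal complexes) will be mistyped. MOL2 bond
  orders are trusted when present.
* Only the seven interaction classes are detected: no halogen bonds,
  water bridges, or metal coordination.
* The docking-box rule is one of several reasonable conventions and is
  not guaranteed to reproduce box dimensions from other tools.
* Alternate locations keep the first altloc (with a warning); occupancies
  are ignored.
* The CART implementation matches the reference R implementation's
  predictions on matched settings in tests, but cp scaling and deep-tie
  behavior are not guaranteed bit-identical to `rpart`.
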