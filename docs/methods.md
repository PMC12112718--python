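# Methods

`cryptohot` implements the analysis layer of cosolvent-probe cryptic-site
prediction: everything downstream of the molecular-dynamics engine. This
note records the models and procedures, the parameters that matter, what
the synthetic generators do and do not emulate, and the numerical choices
made where the design was genuinely open.

## Cryptic-site definition (apo/holo steric clash)

A cryptic site is a pocket that is closed or occluded in the ligand-free
(apo) crystal structure and opens on ligand binding. Operationally, the
holo structure is superposed onto the apo structure, the holo ligand is
carried into the apo frame, and every apo residue with a heavy atom
**strictly** closer than 2.5 Å to any ligand heavy atom is a *clashing
residue*; the clash set is the cryptic site. Choices:

* Superposition matches Cα atoms of residues shared by chain and residue
  number (insertion codes concatenated into the residue key), solved by
  the Kabsch SVD construction with the determinant correction, so the
  returned rotation is always proper even for mirror-degenerate inputs.
  An all-heavy-atom matching mode exists; Cα is the default because it is
  robust to apo/holo side-chain differences. Exact clash sets can be
  mildly sensitive to this choice.
* Hydrogens are excluded everywhere; waters and monoatomic ions are
  dropped at parse time. Alternate locations resolve to the highest
  occupancy, ties broken toward altloc 'A'.
* The inequality is strict (< 2.5 Å), matching the definitional wording
  "less than"; a ligand atom at exactly 2.5 Å does not clash.

## Probe occupancy grids and grid free energy

Probe heavy atoms from all pooled runs are binned on an axis-aligned cubic
lattice (1 Å spacing) covering the protein plus 8 Å padding; the origin is
snapped down to the spacing lattice so grids from shifted references stay
commensurate. Voxels are half-open boxes, so no atom is double counted;
atoms outside the box are tallied as *spill*, giving the conservation
identity Σ counts + spill = frames × probe atoms. Frames can be rigidly
re-superposed onto a reference before binning (occupancy must be
protein-relative); runs are pooled with equal frame weight, and selecting
an analysis window (e.g. the final half of each run) is an explicit caller
operation.

Occupancy is normalised per voxel as raw count / (n_frames × heavy atoms
per probe molecule), which makes probes of different sizes comparable and
is the scale on which the default detection threshold 0.0004 is defined.
Whether that normalisation is per-frame probability or per-simulation
count is not fixed by the upstream mapping tools; this package defines it
as above and exposes the threshold as a parameter.

Grid free energy is GFE(v) = −k_B·T·ln(occupancy(v)/bulk), T = 300 K by
default. Bulk occupancy has no universal definition; here it defaults to
the mean occupancy of solvent voxels (centers > 5 Å from any protein heavy
atom), the usual cosolvent-mapping convention. Empty voxels take the cap
(+3 kcal/mol), which also bounds enrichment-free noise; GFE is strictly
decreasing in occupancy below the cap.

## Hotspot detection and labeling

Voxels with occupancy strictly above the threshold are clustered per probe
with DBSCAN (Euclidean metric over voxel centers, ε = 3.0 Å,
min_samples = 7; noise discarded; input in lattice order so border-point
assignment is deterministic). Clusters from all probes are merged when
their voxel-set overlap exceeds 20%. The overlap denominator is the
smaller cluster, so containment always merges (Jaccard is available by
flag); merging takes connected components of the overlap graph, which
makes the result independent of input order. Voxel-count and volume
overlap coincide at fixed spacing. Hotspot ids are assigned by descending
total occupancy, ties broken by lexicographic centroid, so reports are
reproducible. On real systems these defaults are tuned to yield roughly
20–30 hotspots per protein; the count is reported, never asserted.

A hotspot is labeled cryptic when (1) at least 80% of its voxel centers
lie within 3.5 Å of a heavy atom of a clashing residue — inclusive at
exactly 80% — and (2) at least one voxel center lies within 4.5 Å of a
ligand heavy atom. A third criterion, manual inspection, is inherently
human; it is stored as an annotation and never set automatically. An empty
clash set labels everything non-cryptic with a warning.

## Surface-patch features

The patch of a hotspot is the set of residues with a heavy atom within
4.5 Å of any hotspot voxel center (hotspots are voxel objects, so "heavy
atom in the hotspot" is read as voxel centers). Features, all imputed to 0
with a warning when a patch is empty or has zero area:

* **size** — Shrake–Rupley solvent-accessible surface area (probe 1.4 Å,
  element vdW radii C 1.70 / N 1.55 / O 1.52 / S 1.80 Å) summed over patch
  residues and averaged over trajectory frames at a configurable stride.
* **compactness** — mean over residue pairs of the closest heavy-atom
  distance.
* **protrusion** — fraction of patch residues with fewer than 120 protein
  heavy atoms in the half-open (8, 12] Å shell around the residue
  heavy-atom centroid.
* **convexity** — mean, over adjacent residue pairs (centroids < 8 Å), of
  the ratio of the closest solvent-exposed heavy-atom distance (exposed =
  per-atom SASA > 0) to the centroid distance. The literature definition
  is a paraphrase ("expected centroid distances"); this is one faithful
  reading, validated by ordering tests (concave pockets score higher than
  convex bulges), not claimed to be bit-identical to any other code.
* **hydrophobicity** — mean Kyte–Doolittle index of patch residues
  (composition-based, hence trajectory-constant); the scale is swappable.
* **charge density** — (nArg + nLys − nAsp − nGlu) / size with His neutral
  and the trajectory-averaged size in the denominator, in e/Å².
* **flexibility** — mean per-residue Cα RMSF over the patch, one value per
  probe simulation. RMSF uses two-pass alignment (align to the first
  frame, form the mean, re-align to the mean, take fluctuations); a
  rigidly translating trajectory therefore has RMSF 0. Alignment can be
  disabled for trajectories already expressed in the protein frame.
* **per-probe GFE and molecule count** — mean GFE over hotspot voxels
  (minimum available by option) and the frame-averaged number of distinct
  probe molecules with ≥ 1 heavy atom inside the hotspot voxel set.

A hotspot with no accumulation for some probe is not missing data: it is
imputed with the GFE cap and zero molecule count, because absence of
accumulation is informative. Water-environment counterparts of every
feature are produced by running the same operations on a water-only
trajectory and stored under a `water_` prefix.

## Classifier harness

Feature tables (60 cryptic / 125 non-cryptic hotspots in the reference
configuration) feed five classifier families: RBF-kernel SVM, random
forest, two gradient-boosted-tree variants (xgboost / lightgbm backends),
and AdaBoost over shallow decision trees. AdaBoost defaults to its tuned
operating point: base tree max_depth 4, min_samples_leaf 2,
min_samples_split 15, learning_rate 0.0112, 190 estimators. Features are
standardized to zero mean, unit variance; in every cross-validation fold
the scaler is refitted on the training rows only, so held-out rows cannot
leak into the scaling (directly assertable via the returned per-fold
statistics). Evaluation is leave-one-out CV, with repeated stratified
10-fold CV (stratified because the positive class is small) as the
overfitting check; metrics are accuracy, precision, recall, F1,
specificity at a configurable 0.5 probability threshold, trapezoidal ROC
AUC, and step-wise (average-precision) PR AUC, which is conservative
relative to interpolated variants. Two consensus modes exist: arithmetic
averaging of the five base probabilities, and logistic-regression stacking
trained on out-of-fold base probabilities and itself evaluated
out-of-fold. Hyperparameter search is a seeded random/exhaustive search
over declared per-algorithm spaces maximizing CV ROC AUC.

One caveat the tests document: with completely uninformative (constant)
features, pooled out-of-fold LOOCV probabilities show the known class-prior
artifact (leaving out a positive lowers the positive prior), so the LOOCV
AUC collapses rather than sitting at 0.5; chance behaviour holds in-sample
and for informative-feature nulls.

Probabilities double as ranking scores: per protein, hotspots are ordered
by descending probability, ties share the minimum rank (required so that
genuinely tied probabilities are reported as joint top-1), and the top-N
report counts proteins whose best cryptic hotspot ranks ≤ N, with
percentages reported to the nearest integer percent.

## External-predictor mapping

Residue-level predictors are compared at hotspot level: a hotspot is
surface-contacting when strictly more than 80% of its voxel centers lie
within 5.0 Å of a protein heavy atom; for contacting hotspots the mean
score of all residues with a heavy atom within 5.0 Å of a voxel center is
the hotspot score. Non-contacting hotspots are excluded from
classification metrics and sink to the bottom of rankings (−inf).
Classification uses each method's recommended threshold (10.0 CryptoSite,
0.7 PocketMiner), compared inclusively (score ≥ threshold; the boundary
rule is configurable and documented).

## Synthetic data: what it emulates, what it does not

The generators are pure functions of their seed and write the same text
formats the real pipeline reads, so fixtures and real data are
interchangeable.

* **Toy protein** — poly-alanine on an ideal α-helix (2.3 Å radius, 1.5 Å
  rise, 100°/residue, consecutive Cα ≈ 3.8 Å) or a 6 Å cubic lattice;
  optional isotropic Gaussian jitter produces trajectories with known
  per-residue RMSF (≈ σ√3).
* **Probe trajectories** — ideal dilute cosolvent: Poisson-uniform
  background molecules at 0.25 M (the standard probe concentration for
  this kind of mapping), with rigid ring-shaped molecules of the probe's
  heavy-atom count, plus Gaussian accumulation clouds (default 18 probe
  atoms/frame, 1.5 Å spread) at planted sites. Default pooled window:
  20 runs × 200 frames. Not emulated: solvent structure, excluded volume
  (background molecules may overlap the protein), probe–protein
  energetics, conformational change. Passing tests therefore demonstrate
  the correctness of the mapping/clustering/labeling machinery and its
  statistical behaviour under a known ground truth — not force-field
  realism.
* **Apo/holo pairs** — a rigid 5-atom carbon cross (the smallest shape
  with controllable clash geometry) is placed by seeded search over
  outward offsets and orientations so that *exactly* the planted residues
  clash at 2.5 Å; the holo is the apo plus ligand under a random rigid
  transform, so the full superpose → transfer → clash route is exercised.
* **Feature tables** — two spherical unit Gaussians separated by a
  Mahalanobis distance Δ along a seeded random direction; 60 positives
  over 34 proteins, 125 negatives over 10 proteins by default. The
  single-feature Bayes ROC AUC is Φ(Δ/√2) (≈ 0.983 at Δ = 3), so a sound
  learner should approach but not exceed that.

## Problem sizes and numerical choices

Desk-scale defaults used by the test suite and the reproduction script:
probe maps are accumulated from 4 000 pooled frames (20 × 200) on toy
proteins of 40–60 residues — enough that the 0.0004 occupancy threshold
separates planted accumulation (voxel occupancies ~0.05) from the 0.25 M
background (~1.5 × 10⁻⁴) with a comfortable Poisson margin; planted-site
recovery is evaluated over 100 seeded replicates. The ML layer is
exercised at the reference dataset shape (n = 185) with LOOCV, and
repeated 10-fold CV uses 50 repetitions — enough to estimate the spread
while keeping a laptop-scale run. Tie-breaking, degenerate inputs and
imputation rules are stated above next to each operation; every random
draw in the package flows through a caller-supplied seed.

## Known limitations

* Periodic-boundary imaging is assumed already resolved by the trajectory
  reader; no re-imaging is attempted.
* The convexity formula is one reading of a paraphrased definition (see
  above) and is validated by ordering, not by numeric identity with other
  implementations.
* Hotspot counts per protein on real systems depend on simulation length
  and probe chemistry; the defaults here reproduce the intended regime on
  synthetic data but are exposed as parameters for real use.
* The synthetic background ignores excluded volume, so absolute bulk
  occupancies run slightly high relative to a real solvated box; GFE
  values on synthetic data are meaningful relatively, not absolutely.
* LOOCV on small imbalanced tables carries the class-prior artifact noted
  above; repeated stratified k-fold is provided as the more robust
  estimate.
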