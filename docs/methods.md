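# Methods

This note records the model, the numerical conventions and the design
choices behind `semihot`, in the spirit of the model documentation of
statsmodels or msprime: what is computed, under which assumptions, and what
the synthetic benchmarks do and do not show.

## The semi-supervised boosting classifier

**Setting.** Binary classification of interface residues with
y ∈ {+1 hot spot, −1 non-hot spot} and a (typically much larger) pool of
unlabeled residues.  The central assumption is the *cluster assumption*:
points that are close in feature space — labeled or not — tend to share a
label.  It is encoded in a Gaussian similarity graph
S_ij = exp(−‖x_i − x_j‖² / 2σ²) between unlabeled and labeled points
(S^ul) and among unlabeled points (S^uu).

**Confidences.** At each boosting round every unlabeled point i receives a
positive confidence p_i and a negative confidence q_i (module docstring of
`semihot.semiboost` gives the formulas).  Three conventions matter:

* *Row normalization* (the default "normalized" variant): each row of S^ul
  and S^uu is divided by its sum, so that with H ≡ 0 and C = 0 the
  identities p_i + q_i = 1 and p_i, q_i ∈ [0, 1] hold exactly; the test
  suite asserts them to 1e−12.  The unnormalized "original" variant is
  available as `confidence="original"`.
* *The boosting weight attaches to the unlabeled point's own score.*  The
  labeled term of p_i carries e^(−2H_i) and that of q_i carries e^(+2H_i),
  which is what the minimized objective exp(−2 y_j (H_i + α h_i)) dictates.
  This choice makes (p, q) swap when all labels and scores flip sign —
  the antisymmetry the tests assert.  Writing e^(−2H) with the same sign
  into both confidences (a reading the source literature's typeset
  equations invite) destroys that antisymmetry; the ensemble then drifts
  toward whichever class it currently favours on the labeled set, and in
  our benchmarks the boosted model falls *below* its supervised base
  (held-out F1 0.687 vs 0.739 over 10 draws).  The implemented form
  recovers a positive gain (see below).
* φ = 1/(1 + C/2) and ψ = (C/2)/(1 + C/2), so φ + ψ = 1 and the
  original variant's C/2 factor is preserved.  C defaults to n_l/n_u.

**Pseudo-label sampling.** Candidates must satisfy |p_i − q_i| ≥ τ
(τ = 0.3); of the candidates, the ⌈0.10 · n_u⌉ largest margins are kept
(threshold first, then top fraction — the two published criteria combined
as an intersection), ties broken by index, zero margins never selected.
Pseudo-labels are recomputed from scratch each round rather than
accumulated; an empty selection trains the round on the labeled set alone.

**Ensemble.** Stage weight α_t = ¼ ln(agreement/disagreement mass); a
round with α_t ≤ 0 stops the loop without being appended, so all stored
weights are positive and the stage count never exceeds T (default 20).
If already the first round yields α ≤ 0 — the graph contradicts the
supervised classifier — that classifier is retained with unit weight so
the ensemble is never empty; a single stage's prediction is unaffected by
its weight.  A vanishing disagreement mass caps α at 50.  Prediction is
sign(H(x)) with H = 0 resolving to +1.

**Base learner and scaling.** The base classifier is an RBF-kernel SVM
with library defaults, injectable via a zero-argument factory.  All
labeled points enter every round's training set (the published hard
constraint h(x_j) = y_j is not expressible for a generic SVM; including
the labels every round enforces it softly).  Features are z-scored on
labeled + unlabeled rows before the similarity graph is built — a σ grid
of 1…10 is only meaningful on standardized features.

## Similarity scale σ

σ is the one hyper-parameter that matters.  The package default is 3 with
a built-in cross-validated grid search over 1…10 (`sigma_grid_search`),
mirroring the published protocol of selecting σ per dataset.  On the 10-d
standardized synthetic benchmark, pairwise distances concentrate near
√(2d) ≈ 4.5, and the margin |p − q| rarely reaches τ = 0.3 when σ = 3 —
few points are pseudo-labeled and part of the semi-supervised benefit
comes from standardizing with the unlabeled pool.  At σ ≈ 2 the sampling
engages (tens of pseudo-labels per fit) with a similar mean gain; the
README example uses σ = 2 for that reason.

## Structure features

* **SASA** is Shrake–Rupley with a 1.4 Å water probe and 960 deterministic
  Fibonacci-distributed test points per atom (biotite's implementation,
  with this package's radius table: C 1.87, N 1.65, O 1.40, S 1.85,
  P 1.90, default 1.80 Å).  Hydrogens, waters and HETATM groups are
  excluded; alternate locations resolve to the highest-occupancy atom.
* **Unbound state** = the chain group extracted verbatim from the complex
  (no re-folding), so bound ASA ≤ unbound ASA holds by construction.
* **Interface residue**: total ASA grows by > 0.1 Å² upon extraction.
  The list is ordered by chain then residue number; its 1-based rank i and
  length N feed the POS_PER feature.
* **Depth (DPX)**: distance to the nearest solvent-accessible atom; atoms
  with ASA > 0 Å² (configurable threshold) are accessible and have depth 0.
* **Protrusion (PI)**: V_ext/V_int in a 10 Å sphere with a mean atomic
  volume of 20.1 Å³ (CX convention); an overfull sphere clamps PI to 0.
* **Aggregation**: ASA/RASA aggregate as sums over the atom subsets
  (total / backbone / side-chain / polar = N,O / non-polar = C; sulfur
  counts to neither polarity class); DPX/PI aggregate as total mean,
  side-chain mean, max, min.  Glycine's side-chain aggregates are 0.
* **RASA reference**: shipped as `rasa_reference_synthetic.tsv`, a
  *constructed* table (total = Tien 2013 theoretical maxASA, nominal 40 Å²
  extended backbone, polarity split by heavy-atom composition) because no
  exact per-attribute Gly-X-Gly reference is published in usable form; the
  file header documents the construction and the table is overridable.
* **Ambiguous typeset fractions**: SA_RATIO5 is read as
  DELTA_TOT × maxASA / ASA_unb and PLASTr as (WT_ROTr/ATMNr) × maxASA;
  the alternative readings are selectable (`sa_ratio_form`, `plast_form`).
* **WT_ROT weighting**: w(d) = 1 − d/r at the neighbour's closest-approach
  distance d (the literature never defines "weighted"; this linear decay
  is the package's documented choice).
* **FP9N/FP9E/FP10N/FP10E**: atomic-density stand-ins — counts of
  non-target atoms within 9/10 Å of the residue centroid, and the same
  counts divided by the sphere volume.  The original FADE grid algorithm
  is not re-implemented.
* Zero denominators in relative changes and PLAST report 0 with a log
  message; a residue type missing from a lookup table yields NA (never a
  silent default).

The schema file `semihot/data/feature_schema.tsv` enumerates all 73
feature columns (36 per-state + 13 relative changes + 18 burial /
neighbourhood + 6 sequence) and notes that the nominal "6 + 62" inventory
of the hot-spot literature does not enumerate exactly.

## Sequence features

Pure table lookup, shipped as `sequence_features.tsv`: heavy-atom count,
Veljkovic electron-ion interaction potential, Kyte–Doolittle
hydrophobicity, Hopp–Woods hydrophilicity, Chou–Fasman α-helix propensity
(the literature says only "propensity"; the header records the choice) and
the free-amino-acid isoelectric point.  Non-standard residues raise unless
explicitly mapped (MSE→MET etc.).

## Feature selection

Random forest (500 trees) plus permutation importance — the mean decrease
in accuracy when one feature's values are permuted, averaged over repeats
with a fixed seed.  This uses whole-training-set permutation importance
rather than Breiman's out-of-bag variant; for ranking purposes the two
agree on the synthetic benchmarks, and determinism per seed is exact.
The top-k (default 10) candidates feed an exhaustive subset search up to
size 6 (both published feature subsets have 6 members; 12 candidates ×
size ≤ 6 bounds the enumeration), scored by stratified cross-validated F1,
ties resolved toward smaller subsets then lexicographic order.  The two
published subsets ship as presets `dataset1-subset` and `dataset2-subset`,
mapped onto this package's schema; where the published name does not fix
the state ("total RASA"), the unbound state is used.

## Evaluation protocols

Metrics follow the universal definitions — in particular recall =
TP/(TP+FN); the source literature's printed TP/(TN+FP) contradicts both
the standard definition and its own usage and is treated as a typo.
0/0 ratios report 0.  ROC/AUC uses a full threshold sweep with rank-averaged
ties, so AUC equals the Mann–Whitney pair-counting statistic (asserted
exactly against a brute-force oracle).  ΔΔG labeling assigns the 2.0
kcal/mol boundary to the hot-spot class.

k-fold cross-validation is stratified and *transductive*: each held-out
fold's features join training as the unlabeled pool.  Predictions are
pooled over folds before scoring (micro); per-fold and averaged (macro)
variants are retained in the report.  The random-20 protocol draws 20
labeled samples (redrawing single-class draws), uses the remainder as both
unlabeled pool and test set, and averages over 10 repeats.

## Synthetic benchmarks — what they show

`generate_clusters` draws two isotropic unit-variance Gaussians separated
along one axis, a 50/50 unlabeled pool from the same mixture, and optional
label noise — the minimal geometry exercising the cluster assumption.  The
reference gain experiment uses 20 labeled + 200 unlabeled points at 2.5 SD
separation (Bayes error ≈ 10.6 %).  Over 100 independent draws the boosted
model beats its labeled-only base SVM by +0.017 F1 on average (σ = 3,
one-sample p < 1e−4), but the per-draw SD is ≈ 0.05, so 20-draw paired
tests are only moderately powered; the acceptance script therefore averages
60 draws with 1000-point held-out sets.  `generate_toy_complex` builds a
two-chain poly-alanine complex with controllable contacting and remote
residue pairs for the geometric oracles.

None of this emulates real interfaces: feature correlations, class
imbalance (hot spots are rare), per-complex structure and ΔΔG measurement
noise are absent.  Passing these benchmarks shows the machinery is
implemented correctly and that the semi-supervised mechanism helps when
the cluster assumption holds — not that any particular accuracy will be
reached on real alanine-scanning data.

## Problem sizes and runtime

Default test and acceptance runs use: 960 sphere points (240 in the slower
pipeline tests), toy complexes of ≤ 12 residues per chain, cluster sets of
≤ 320 points, 20-seed recovery/gain loops, and 60-draw gain estimation in
the acceptance script.  The full test suite runs in about two minutes on
one CPU; the acceptance script in about one.

## Known limitations

* No protonation, missing-atom repair or energy-based ΔΔG computation.
* The RASA reference and the FADE-style densities are documented
  stand-ins, not reproductions of PSAIA/NACCESS/FADE outputs.
* Binary classification only; no probability calibration (ROC scores are
  raw ensemble margins H(x)).
* The unlabeled pool is taken as given; the package does not decide which
  residues of a proteome to include.
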