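# Methods

`hypometab` implements an integrative analysis of the crosstalk between
tumor hypoxia and global metabolism in bulk expression cohorts: per-sample
hypoxia scoring, pathway-deregulation scoring, metabolic subtyping,
per-subtype correlation fingerprints, and survival stratification. This
note records the models, the parameters that matter, the numerical
choices, and what the synthetic cohorts do and do not emulate.

## Hypoxia score (HS)

For a signature of k genes, each gene g contributes a call
c_g(s) = +1 if x_gs > median_g and −1 otherwise, where median_g is the
median of g **within the cohort being scored**. The hypoxia score is
HS(s) = Σ_g c_g(s), and samples with HS > 0 form the HS-high group
(HS = 0 is low). Two signatures ship built in: the 8-gene
hypoxia-responsive panel (DDIT4, LDHA, MXI1, NDRG1, P4HA1, PGK1, SLC2A1,
VEGFA) and the 15-gene Buffa metagene used for replication.

Consequences worth knowing:

* **Parity.** With k genes found, HS ∈ {−k, −k+2, …, k}. The 15-gene
  score is odd and never 0, so its high/low split has no boundary cases.
* **Cohort dependence.** Medians are recomputed on whichever sample set
  is scored; a sample's HS changes when the cohort around it changes.
  This is intrinsic to the method, not an implementation artifact.
* **Ties.** A value exactly at the median is called −1 by default
  (`tie_rule="le_minus"`), mirroring the conservative "HS ≤ 0 → low"
  rule; `strict_half` (ties → +1) is exposed for sensitivity analysis.
  Continuous expression data make exact ties rare.
* **Missing data.** Signature genes absent from the matrix are skipped
  (the found count is reported); an NA expression value yields a −1
  call, the deterministic conservative choice.

## Pathway-deregulation score

For each gene set: (1) z-score each member gene against the normal
reference samples (whole cohort when none are given); (2) PCA to the
smallest number of components explaining ≥ 85% of variance, capped at
10; (3) fit a principal curve; (4) anchor an origin t₀ at the median
arc-length of the normal samples — without normals, at the projection of
the cohort's coordinate-wise median point; (5) score each sample as its
arc-length distance |t − t₀|, min-max normalized so every retained
pathway spans [0, 1]. Pathways with fewer than `min_genes` (default 3)
found genes are skipped and listed with a reason, never scored.

The principal curve is fitted by the Hastie–Stuetzle alternation:
initialize on the first principal component, then alternate projection
onto the current polyline with smoothing of each coordinate against arc
length. The smoother is a centered running mean with span 0.3·n — the
simplest smoother that leaves colinear data exactly on its line, which
gives the degenerate-case oracle: on colinear input the scores equal
min-max-normalized |PC1 − t₀| to machine precision. Projection onto the
terminal segments extrapolates, so extreme samples are not clamped to
the curve ends. Iterations use fast nearest-node projection; one exact
segment-level projection produces the final coordinates. The stage has
no random element: SVD initialization plus a fixed PCA sign convention
(the largest-magnitude loading of each component is made nonnegative)
make repeated runs bitwise identical.

This is a reimplementation of the pathway-deregulation concept
popularized by Pathifier, not a port: bootstrap stability filtering and
minimum-spanning-tree sample filtering are deliberately absent, since
downstream stages consume only the scores and acceptance is
property-based. Known limitation: with strongly curved manifolds whose
quadratic component dominates PC1, the initialization can fold the
ordering; at the curvature levels the synthetic cohorts plant, recovery
of the latent ordering is Spearman ≥ 0.95.

Scores are anchored on the cohort they are computed in. Comparing scores
across separately scored cohorts (e.g. tumors vs a cell-line panel)
therefore carries a cohort-anchor shift unless both are scored jointly
or against a shared normal reference; label transfer works best in the
joint mode.

## Metabolic typing

Samples are clustered on their deregulation profiles (k-means with 20
restarts from an explicit seed by default; Ward's linkage as the
deterministic alternative) into k = 3 clusters, then relabeled M1, M2,
M3 in ascending order of cluster-mean deregulation. The ordering
convention is total and asserted on every run: M1 is always the least,
M3 the most deregulated type. Labels transfer to new panels by nearest
centroid (Euclidean, over shared pathways), with the margin to the
runner-up centroid reported to flag ambiguous assignments.

## Correlation fingerprints

Pearson r between HS and each feature (pathway deregulation score or
metabolite abundance), with the exact t reference distribution (df =
n − 2) for two-sided p-values, computed on all samples and within each
metabolic type. HS enters as a numeric covariate despite its
discreteness, matching the scoring model's intent; Spearman can be
obtained by rank-transforming inputs upstream. The default significance
rule is raw p < 0.05 per feature (`multiplicity="none"`); the
Benjamini–Hochberg mode (`"bh"`) is provided and recommended when the
screen's false-discovery rate matters more than reproducing the
raw-threshold convention. Constant features yield r = NA and are
excluded from counts. The two-cohort consistency rule counts a feature
only if significant with the same sign in both fingerprints. Fingerprint
breadth orders the types by their count of significant features
(descending; ties keep label order and are flagged).

Group comparisons follow the gated battery: Shapiro–Wilk normality at
α = 0.05 per group; two groups → unpaired two-tailed t-test when both
pass, Mann–Whitney U otherwise; more than two groups → Kruskal–Wallis
with Dunn's post hoc, implemented as pairwise z-statistics from pooled
mean ranks with tie correction and Bonferroni adjustment over pairs.

## Survival

Kaplan–Meier estimation and the two-group log-rank test delegate to
lifelines (deaths precede censorings at tied times). The Cox
proportional-hazards model is fitted in-package by Newton maximization
of the **Breslow** partial likelihood (backtracking line search,
convergence at gradient norm < 1e-8, standardized internally for
stability), with Wald confidence intervals and p-values. Breslow was
chosen as the simplest consistent tie treatment; R's survival package
defaults to Efron, a known small numerical difference on tied data —
the two agree exactly on tie-free data, which the test suite checks
against lifelines. Non-convergence and suspected separation (runaway
standardized coefficients) are reported as flags, not exceptions.
Categorical covariates (grade, stage, PAM50) are one-hot encoded with
the most frequent category as reference level.

## Synthetic cohorts

The generator plants exactly the structure the analysis assumes, with
full ground truth:

* latent hypoxia h ~ Normal(μ_type, 1), with μ = 0 for M1 and M2 and
  μ = `hypoxia_shift_m3` (default 1.0) for M3;
* signature genes (both panels) = `coupling`·h + Normal(0, `noise_sd`),
  defaults 0.6 and 0.5;
* per-pathway latents u: for a sample of type t, the first `breadth[t]`
  pathways (defaults 30/18/7 of 90) have u = coupling·h +
  Normal(0, √(1−coupling²)); the rest are standard normal. All latents
  are scaled by 0.5 and then offset in magnitude by
  `type_separation`·{0, 1, 2} (default step 0.25) per type — the
  planted M1 < M2 < M3 deregulation ordering. The latent scale fixes
  how far apart the three deregulation levels sit relative to
  within-type spread; at 0.5 the planted types are recoverable from the
  deregulation matrix (ARI ≈ 0.95), which is the regime the analysis
  is designed for;
* pathway genes (8–15 per pathway) = Uniform(0.6, 1)·u +
  Normal(0, noise_sd); 50 metabolites mirror the breadth pattern scaled
  to the panel (17/10/4);
* survival: exponential with monthly baseline hazard 0.006 and
  log-hazard slope 0.4 per unit h, censored Uniform(0, 120 months),
  giving roughly 30% events; grade leans on h (softmax logits
  0/0.4h/0.8h), stage and PAM50 are unrelated draws;
* everything flows from one seed; equal seeds give bitwise-equal
  cohorts.

What the generator does **not** emulate: microarray platform noise,
batch effects, probe-level structure, realistic marginal distributions,
negatively hypoxia-coupled pathways (all planted couplings are
positive; the correlation screen's sign handling is exercised with
separately constructed features in the tests), or correlated gene-gene
noise within pathways. Passing tests therefore demonstrate that the
pipeline recovers planted structure of this linear-Gaussian kind at
realistic sizes — not that it is robust to every artifact of real
cohort data. Note also that the deregulation score is a folded
(|t − t₀|) transform, so within-type correlations between HS and
deregulation are attenuated relative to the planted linear couplings;
the breadth ordering survives the folding, the effect sizes do not.

The tiny worked example (8 genes × 10 samples) uses row permutations of
1..10, so each gene's median is 5.5 and every call is unambiguous; its
expected score table (+8, −8, eight zeros) is hand-verified and frozen
with the fixture.

## Problem sizes and tolerances in the test suite

Simulation-based checks run at the cohort sizes the analyses target
(n = 600 default cohort; 200–500 replicates for calibration and power;
n = 1000 for Cox recovery), chosen so each check completes in seconds
to a few minutes. Calibration bands are binomial (3 standard errors on
aggregates, ±0.02 on single rates); exactness checks (worked example,
colinear oracle, closed-form Kaplan–Meier) use machine-precision or
1e-8 tolerances. Determinism checks compare bytes, not values.
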