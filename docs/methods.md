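# Methods and design notes

This note records the statistical model behind `diopower`, the defaults
and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical conventions a maintainer needs to
know. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study model

A study has two arms (liraglutide vs vehicle) and a latent partition of
the mice into gut-microbiota clusters, drawn independently of the arm.
The treatment effect on each endpoint is cluster-conditional: within
cluster c the treated Δ-value is N(μ_c, σ_c²), the vehicle Δ is
N(drift, σ_c²) with drift 0 by default. Marginally over clusters the
treated arm therefore has variance σ² + Var(μ_c): the between-cluster
spread of effect means is exactly the variance a cluster blocking factor
can remove, and the entire power gain of the adjusted design comes from
it. When all μ_c are equal the two designs coincide asymptotically
(the factorial design pays (k − 1) denominator df for nothing).

Endpoints: HbA1c (mmol/mol), OGTT area under the curve (mmol/L·min, by
trapezoid over samples at 0/15/30/60/90/120 min), body weight (g) and
fasting glucose (mmol/L, the t = 0 point of each OGTT) enter as
Δ-values, (post − pre)/pre × 100. Insulin and leptin (pg/ml) are
terminal-only and analysed on the raw scale; leptin is right-censored at
the 100,000 pg/ml assay ceiling and stored at the ceiling.

## Clustering chain

- **Rarefaction** to 10,000 reads, sampling without replacement
  (multivariate hypergeometric), one seed per run recorded in the output
  metadata. A mouse with exactly 10,000 reads is retained unchanged —
  the threshold is inclusive. Mice below it are excluded and every
  downstream table reports the reduced effective n.
- **Normalized weighted UniFrac.** The normalized variant (dividing by
  Σ ℓ_b (p_A + p_B)) keeps values in [0, 1] and is the common default of
  the ecosystem this pipeline mirrors; the computation is delegated to
  scikit-bio and is checked in the test suite against a naive per-branch
  oracle to 1e-10.
- **Ward linkage** is applied directly to the UniFrac matrix with
  ward.D2 semantics (squared dissimilarities inside the Lance–Williams
  update), via scipy. No Euclidean embedding is performed first; UniFrac
  is a semimetric and the resulting merge heights are monotone, which is
  all the cut rule needs. Tie handling among exactly equal merge
  criteria follows scipy's deterministic nearest-neighbor-chain order;
  with continuous dissimilarities exact ties have measure zero.
- **Cluster count.** k is the largest value in 1..k_max (default
  k_max = 8) for which every cluster of the k-cut contains at least one
  mouse of each arm; k = 1 is always feasible. Note the rule is about
  design validity, not about recovering a "true" number of communities:
  on synthetic data with k* well-separated planted clusters the selected
  k is frequently larger than k* (Ward will happily split a tight
  cluster, and the split parts often still contain both arms). The
  recovery guarantees in the test suite are therefore stated at the
  planted k — the dendrogram restricted to k* groups reproduces the
  planted partition — while the selected-k labels are only required to
  remain consistent with it. For power estimation over-splitting is
  benign: it costs one denominator df per extra cluster but never
  inflates the pooled within-cluster variance.
- **PERMANOVA** uses Anderson's pseudo-F computed directly from the
  distance matrix and p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) under
  random relabelling (default 999 permutations, seeded). The pseudo-F is
  cross-checked against scikit-bio's implementation in the tests; the
  in-package version exists so permutations are seedable and cheap.
- The optional `arm_label_stability` report (distribution of the
  selected k under arm-label permutation) is offered as a diagnostic
  interpretation of an otherwise under-specified permutation step and is
  flagged as such in its docstring; nothing downstream consumes it.

## ANOVA conventions

- One-tailed direction is fixed a priori per endpoint (the intervention
  lowers every endpoint considered); the one-tailed p is p/2 when the
  observed difference has that sign, 1 − p/2 otherwise, and exactly 0.5
  at zero observed difference. Two-tailed p-values are always reported
  alongside.
- The two-way model is additive (treatment + factor, no interaction),
  fitted by least squares with Type-II sums of squares, appropriate for
  the unbalanced cells that read-depth exclusions create. With a
  single-level factor the code short-circuits to the one-way fit, making
  the two designs exactly equal in that degenerate case.
- The assumption gate ranks the pooled endpoint vector (midranks for
  ties) when any arm fails Anderson–Darling normality at α = 0.05 *or*
  Levene (median-centered) finds unequal variances. A constant group has
  no defined normality and is conservatively flagged non-Gaussian.
- STR-allele factors: genotype levels present in only one arm are pooled
  into an `"other"` level rather than dropped, preserving n; a factor
  fully aliased with the arm is an error.

## Power model

The treatment test in both designs is an F(1, df) test with
noncentrality λ = n·d²/(2σ²) at n mice per arm. The one-way design uses
the observed marginal difference and pooled across-arm s.d. with
df = 2n − 2. The cluster-adjusted ("general full factorial") design uses

- d_w = Σ n_c d_c / Σ n_c — the cluster-size-weighted mean of the
  per-cluster treated−vehicle differences (a deliberately conservative
  aggregate; the maximum per-cluster effect would give smaller n but
  assumes the best-responding cluster generalizes),
- σ_pooled² = Σ (n_c − 2) s_c² / Σ (n_c − 2), pooling the within-cluster
  residual variances around the two arm means (hence df weight
  n_c − 2),
- df = 2n − 2 − (k − 1) for the k-level block factor.

No closed formula for the original factorial power routine is available,
so this definition is validated against brute-force simulation of
additive two-way ANOVAs: analytic and empirical rejection rates agree
within 3 Monte-Carlo s.e. across the tested grid (see
`test_power_functions_match_simulated_rejection_rates`). Minimum group
size is found by doubling-then-bisection on the monotone power curve,
capped at 10,000 with an explicit "infeasible" error; every returned n
satisfies power(n) ≥ target > power(n − 1).

## Synthetic-data generator

What it emulates, and the defaults:

- **Design**: 16 mice per arm (configurable; the two colonies this
  pipeline was shaped around used 16 and 23), three latent clusters with
  uniform mixing, two microbiota sampling timepoints.
- **Communities**: Dirichlet-multinomial counts around cluster-specific
  centroids. Centroids share a lognormal baseline profile with a
  disjoint block of zOTUs boosted per cluster; `cluster_separation`
  (default 2.0) scales the boost and `dirichlet_concentration` (default
  200) sets within-cluster tightness. The defaults were chosen so that
  between-cluster weighted UniFrac (≈ 0.24 on average) is roughly four
  times the within-cluster value (≈ 0.06) — clearly separated community
  states of the kind the clustering step presumes, comparable to
  enterotype-scale separation in rodent fecal data. PERMANOVA pseudo-F
  grows monotonically with the separation parameter.
- **Sequencing depth**: lognormal (log-mean ln 30,000, log-sd 0.35),
  truncated below at the 10,000-read threshold except for a
  `dropout_fraction` (default 0.10) of mice whose library is drawn
  uniformly below it. Dropout is Bernoulli per mouse, so the excluded
  count is binomial — about a quarter of mice at the 0.25 fraction used
  to mimic the worst observed timepoint.
- **Effects**: canonical treated Δ means per cluster, e.g. HbA1c
  (0, −5, −15)% with within-cluster s.d. 3 points — heterogeneous enough
  that cluster adjustment roughly halves the detectable-difference
  variance. Other cluster counts interpolate these anchors linearly.
  Vehicle drift defaults to 0 but is configurable (continued DIO
  progression is not identifiable from the data the pipeline sees).
- **OGTT curves**: a fixed physiological shape (fasting baseline, peak
  at 15–30 min, slow decay) scaled per mouse so that the post curve's
  trapezoidal AUC carries the drawn OGTT Δ exactly while its t = 0 point
  carries the drawn fasting-glucose Δ exactly.
- **STR panel**: 243 markers. Each marker's most-prevalent-allele count
  over the 2N allele slots is drawn inside its assigned frequency band
  and minor alleles partition the remainder (each at most the major
  count), so the realized band spectrum equals the specification
  *exactly*, by construction, and allele summaries round-trip it. Slots
  are paired randomly into calls, producing heterozygous calls wherever
  minor alleles exist (exercising the 0.75 conformity rule). The two
  built-in spectra reproduce the published colony profiles
  (72/101/36/14/8/10/2 and 138/89/10/3/2/1/0 markers per band).
- **Phylogeny**: random coalescent topology with exponential branch
  lengths over the zOTUs. UniFrac needs only a rooted tree with
  lengths; no attempt is made to correlate phylogeny with the cluster
  blocks, which makes the UniFrac signal conservative relative to real
  communities where dominant taxa are phylogenetically coherent.

What it does **not** emulate: sequence-level noise (no reads, no
chimeras — generation starts at the zOTU table), taxon-specific biology
(no named genera), compositional correlations between endpoints beyond
the shared cluster label, cage effects, repeated-measures structure of
growth curves, or linkage between STR genotype and phenotype (STR
factors are null factors in synthetic studies by design). Passing tests
therefore demonstrate the statistical machinery under the stated model,
not the biological claim that real microbiota clusters modulate
liraglutide response.

## Degenerate inputs and numerical notes

- Rarefying a table where every mouse is below depth raises
  ("no clusterable samples"); a single remaining mouse cannot be
  clustered (Ward requires ≥ 2).
- A marker with no genotype calls is an error for consensus/summary; a
  mouse with all calls missing gets a NaN conformity score and a flag.
- Consensus ties break toward smaller allele sizes; `select_markers`
  ties break by marker ID; monomorphic markers have Shannon evenness 1
  by convention and are excluded from "most even" ranking.
- Zero within-group variance in PERMANOVA gives pseudo-F = ∞, which
  compares correctly against permuted statistics.
- Band membership uses half-open intervals [lower, upper) with the 100%
  band exact; frequencies below 40% fall into a catch-all "<40%" class
  that the generator never produces but arbitrary input tables may.
- All simulation sizes used in the test suite (e.g. 100 seeds for the
  group-size comparison, 2,000 null datasets for PERMANOVA calibration,
  30,000 replicates per power grid point) were chosen as the smallest
  sizes at which the Monte-Carlo standard error is well below the
  tolerance being asserted.

## Known limitations

- The ward.D2-on-UniFrac choice is a convention, not a theorem; other
  reasonable treatments (PCoA embedding, unsquared ward.D) can select
  different k on borderline data.
- The factorial power formula assumes the block factor is balanced
  across arms and effects are additive; strong interaction between
  treatment and cluster would make the weighted difference an
  underestimate of what the best cluster shows and an overestimate of
  the worst.
- Minimum-n estimates plug in *observed* differences and s.d.s and
  inherit their sampling noise; at pilot-scale n the estimates are
  variable, which is visible in the seed-to-seed spread of the
  acceptance script's medians.
- STR conformity assumes a meaningful modal consensus; in a heavily
  admixed colony the mode may be a poor summary.
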