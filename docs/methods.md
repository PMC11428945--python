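# Methods

This note documents the models, the parameter choices and their rationale,
the synthetic-data generator, the numerical conventions, and the known
limitations of the package.

## Data model and preprocessing

Counts are held as a samples × taxa integer matrix (`CountTable`); readers
accept taxa-as-rows (the common amplicon convention, the default) or
samples-as-rows TSV, and the dense-JSON BIOM variant. Missing cells are an
error, never silently zero — silent imputation hides upstream faults.

Filters run in a fixed order: taxa whose pooled count equals exactly 1
(singletons) are removed; then taxa at or below a fraction of the pooled
grand total are removed (default 1e-6, strict `>` at the boundary); then
every sample is rarefied to a common depth (default 31,731 reads) by
multivariate-hypergeometric subsampling — drawing reads uniformly *without*
replacement, which leaves richness unbiased where with-replacement
subsampling would not. Samples below the depth are dropped and reported,
never padded. The low-abundance fraction is interpreted against the pooled
total across all samples, not per sample, because the filter targets
globally rare taxa. The abundance filter runs before rarefaction; filtering
criteria defined on raw totals should not depend on the subsampling seed.

Aggregation to a taxonomic rank sums counts over taxa sharing the lineage
prefix; taxa unclassified at the target rank are pooled under
`unclassified_<lowest classified level>`. Aggregation conserves per-sample
totals exactly.

## Diversity

Shannon entropy is reported in nats by default (the natural log is the
common default of microbiome toolkits; a `base` argument switches it),
Simpson as `1 − Σ p²`, Chao1 in the bias-corrected form
`S_obs + F1(F1−1)/(2(F2+1))`, and ACE with the standard rare/abundant split
at 10. When a sample has no rare taxa to extrapolate from, ACE falls back to
observed richness. Beta diversity is exposed two ways: the Bray-Curtis
distance matrix (for ordination and PERMANOVA) and the Whittaker turnover
index `γ/ᾱ − 1` on presence/absence, whose `−1` offset makes identical
compositions score 0; a flag switches to the raw ratio `γ/ᾱ`.

PCoA is classical scaling of the Gower-centred `−D²/2`; axes are limited to
positive eigenvalues (negative eigenvalues are reported, not hidden), and
each axis' sign is fixed so its first nonzero loading is positive —
ordination signs are otherwise arbitrary and would break reproducibility of
plots. PERMANOVA uses the distance-based pseudo-F with a label-permutation
null and the plus-one convention `p = (1 + #{F_perm ≥ F_obs})/(1 + P)`, so p
is never exactly 0; the default is 999 permutations. The sex test runs on
Bray-Curtis.

## SparCC networks

SparCC estimates correlations of latent absolute abundances from
compositional counts. Per inner iteration, fractions are drawn from the
Dirichlet posterior (counts + pseudocount 0.5); the variation matrix
`t_ij = var(log x_i/x_j)` is formed from one covariance computation
(`t_ij = v_i + v_j − 2c_ij`); basis variances solve the sparsity
approximation `Σ_j t_ij ≈ (p−2)ω_i + Σ_j ω_j`; basis correlations follow as
`(ω_i + ω_j − t_ij) / 2√(ω_i ω_j)`. The most strongly correlated pair above
the exclusion threshold (0.1) is then removed from the system and the
variances re-solved, up to 10 rounds, so a few strong correlations do not
contaminate the variance estimates. The reported adjacency is the entrywise
median over 20 inner iterations (median, not mean, for robustness), clipped
to [−1, 1] with unit diagonal. All counts are the algorithm's published
defaults and are exposed as parameters. `n_inner_iterations=0` uses the
posterior-mean fractions with no resampling — deterministic and exactly
equivariant to taxon order, useful for testing. Below 4 taxa the linear
system is under-determined and the call errors; below 10 samples it warns.

An "economy" profile (5 inner iterations, 3 exclusion rounds) is used inside
permutation nulls, where the chain is replayed hundreds of times; the
profile is recorded in provenance wherever used.

Per-condition networks from several timepoints are integrated as a weighted
edgewise mean. Default weights are inverse-variance weights from the
Fisher-z variance of a correlation, `1/(n_t − 3)`, i.e. `w_t = n_t − 3` —
the simplest defensible univariate weighting when timepoints differ in
sample size — with an explicit `weights` override. With equal weights the
integration is the plain arithmetic mean.

Topology (degree, strength, betweenness, closeness, density) is computed on
the graph with an edge wherever `|a_ij| ≥ 0.3`, a common operating point for
SparCC networks; the threshold is a parameter everywhere it appears.

## Module detection

Modules are detected WGCNA-style: signed soft adjacency
`s_ij = ((1 + a_ij)/2)^β` with β = 6 (the signed-network convention),
topological overlap similarity, average-linkage hierarchical clustering of
the TOM dissimilarity, and a *static* cut of the dendrogram. The static cut
was chosen over the dynamic hybrid cut for determinism and fewer tunables.
The default cut height is 0.9: on TOM dissimilarity, merge heights inside
genuine modules sit around 0.4–0.7 and between modules near 1, so the cut
must sit high — 0.9 is the classic static-cut default for this
dissimilarity. (A much lower cut such as 0.25, appropriate for *eigengene
merge* heights, would fragment every module into singletons.) Clusters
smaller than `min_module_size` (5) are pooled into the unassigned "grey"
label, which is treated as an ordinary label downstream. The clustering path
contains no randomness.

Node statistics: connection strength `k_i = Σ_{j≠i} a_ij` excludes the self
term — the quantity is the node's summed connection to *other* nodes — and
module importance is within-module minus out-of-module connectivity, which
reduces to `k_i` when all of a node's connectivity is internal and to
`−k_i` for a singleton module.

## Driving-force score

Between condition networks A and B with partitions P_A and P_B, the
module-pair matrix `D(M_A, M_B)` is the Jaccard distance between member
sets; pairs with `D < 0.3` are flagged as the stable ("intersection")
modules of the transition. Membership shift *is* the transition this score
family describes, which makes the Jaccard distance the natural concrete
instantiation; the distance function is pluggable.

The per-node score sums the per-pair differential module distance
`ΔD_ij = d_B(i,j) − d_A(i,j)` (where `d_X(i,j)` is 0 if i and j share a
module in network X, else 1) over node i's neighbors in A, minus the same
sum over its neighbors in B. Two conventions matter:

* **Neighborhoods use positive supra-threshold edges** (`a_ij ≥ 0.3`), not
  `|a_ij|`. Compositional closure makes unrelated taxon guilds
  anti-correlate strongly, so under an absolute-value rule every node is
  "adjacent" to both its own guild (+1 terms) and the others (−1 terms) and
  the sums cancel; with positive edges the score isolates the co-occurrence
  neighborhood the module concept is about.
* **Significance uses the raw absolute score; the normalized score is for
  ranking only.** Scores are reported min-max normalized to [0, 1], but in
  every permuted null some node attains the normalized maximum 1 by
  construction, which would destroy per-taxon calibration; the permutation
  p-values therefore compare raw |score| between observation and null.

The score of a network against itself is identically zero (every `ΔD` term
vanishes), which holds by construction for all inputs.

Significance permutes condition labels over the pooled samples (within each
timepoint, in longitudinal mode) and replays the entire
network → partition → score chain per permutation; `p = (1 + #{null ≥
obs})/(1 + P)`, Benjamini-Hochberg FDR within each run (not pooled across
runs), and a direction label from the sign of the mean relative-abundance
difference. Below 100 permutations a warning notes the coarse p-value grid.

Two modes mirror longitudinal study designs: per-timepoint (the full chain
independently within each sampling time) and longitudinal (per-condition
networks inferred per timepoint, integrated, then scored once). An acute,
recovering perturbation concentrates discoveries at its own timepoint in
per-timepoint mode and is diluted by the unperturbed timepoints in
longitudinal mode; a persistent perturbation survives integration. Both
behaviours are verified on planted data in the test suite.

## Cross-validated ROC (netroc)

Panel features are log relative abundances (scale-free across rarefaction
depths; the log tames the heavy right tail of compositional fractions),
standardized and scored out-of-fold by a logistic model under stratified
k-fold cross-validation (default 10 folds; stratification guarantees both
classes per fold, and a class rarer than the fold count raises with advice
to lower it). The classifier is deliberately the simplest calibrated linear
scorer and is pluggable. Both the pooled out-of-fold AUC and the per-fold
AUCs are reported, since published single-number summaries rarely state
which convention they used.

## Synthetic communities

The generator emulates the post-denoising product of a two-arm longitudinal
16S study: latent log-abundances are multivariate normal with a
block-structured correlation matrix (within-block correlation
`basis_correlation_within_module`, between-block 0 — kept at exactly 0 so
planted truth is unambiguous for module-recovery tests), taxon-specific
baseline means ~ N(0, 1), and log-scale SD 1.0. Stress shifts driver means
by `driver_log2_effect · ln 2` and, when `driver_rewire` is set, moves the
drivers' correlation rows into the next block (through a PSD-safe convex
combination when the effect is partial). Per-sample depths are
rounded log-normal with mean 55,000 and CV 0.3 — above the 31,731
rarefaction depth, with a realistic spread for rarefaction to equalize —
and observed counts are multinomial draws from the normalized latent
composition, so row sums match drawn depths exactly. A log-normal basis with
multinomial sampling (rather than Dirichlet-multinomial) was chosen because
the network stage estimates log-basis correlations: the planted matrix is
exactly the estimand, making parameter-recovery tests well-posed. Sex is a
label with zero effect, providing a built-in multivariate null; defaults
(150 taxa, 30 samples per arm per timepoint, 3 timepoints) mirror a
genus-level study of ~60 animals sampled three times.

The resilience variant applies the driver effect in full at one timepoint
and scaled by `1 − recovery_fraction` afterwards, emulating a community
drifting back to baseline after an acute stressor.

What the generator does *not* emulate: phylogenetic signal, taxon-specific
sequencing bias, overdispersion beyond the log-normal layer, zero inflation
beyond multinomial sampling zeros, and real ecological interaction dynamics.
Passing tests demonstrate the pipeline's statistical validity under the
stated model, not performance on any particular real cohort.

## Numerical conventions and problem sizes

All permutation p-values use the plus-one convention. BH q-values use the
standard monotone step-up. Ranks break ties by averaging. Result files are
written with six significant digits and a deterministic column order, so
identical runs are byte-identical. A single pipeline seed is fanned out to
stages by a counter-based derivation (`(seed·1009 + 7919·k) mod 2³¹`), so
stages can be re-run independently yet reproducibly. Validation fixtures use
30–60 taxa, 30–90 samples per arm, and 100–999 permutations — sizes at which
every planted-recovery and calibration property is comfortably resolved
while the full suite runs in a few minutes; the acceptance script states the
size it used next to every number it reports.

## Known limitations

* The sparsity approximation inside SparCC biases estimates when many taxon
  pairs are truly correlated (e.g. two large blocks plus compositional
  closure); spurious between-block negatives of magnitude up to ~0.5 are
  possible. The driving-force score's positive-edge convention sidesteps
  this for module work, but reported negative edges should be read
  cautiously.
* Edge-level bootstrap p-values for the networks are not implemented.
* The Jaccard instantiation of the differential module distance ignores
  edge weights within modules; a weighted distance can be substituted
  through the pluggable interface.
* Module eigengenes, module-trait correlation and preservation statistics
  are out of scope.
* HDF5 BIOM is not supported (dense JSON only); UniFrac-type phylogenetic
  distances are out of scope.
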