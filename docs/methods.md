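# Methods

## Problem and data model

`comosub` analyzes two independent case/control expression studies (e.g.
blood from one disease, tissue from another) to find a pair of patient
subgroups — one per disease — that share gene-level biology, and to extract
the shared, same-direction candidate genes.  Inputs are gene × sample
matrices of log-scale intensities with a patient/control label per sample,
a pathway collection (GMT), and per-disease reference gene lists.

Expression values are assumed strictly positive (microarray-style
intensities); nonpositive values are a hard error rather than being
pseudo-counted, because any offset would silently change the fold-change
transform.  The transform `y_ij = log2(patient_ij / normal_i)`, with
`normal_i` the arithmetic control mean of gene *i*, is applied literally to
the stored values; whether those values are already log-scale is the
caller's responsibility and is deliberately not second-guessed.

## Convex NMF

The fold-change matrix *A* (genes × patients) is mixed-sign, so standard
NMF does not apply.  Convex NMF factorizes `A ≈ A F Hᵀ` where columns of
the basis `W = A F` are convex-ish combinations of data columns and both
factors are elementwise nonnegative.  With `K = AᵀA` split into positive
and negative parts `K = K⁺ − K⁻`, the multiplicative updates are

    H ← H ∘ sqrt( (K⁺F + H FᵀK⁻F) / (K⁻F + H FᵀK⁺F) )
    F ← F ∘ sqrt( (K⁺H + K⁻F HᵀH) / (K⁻H + K⁺F HᵀH) )

which monotonically decrease `‖A − A F Hᵀ‖²_F` (asserted to 1e-9 relative
tolerance in the test suite).  Numerical choices:

- `F`, `H` initialized from seeded uniform(0,1) draws plus a 1e-4 floor;
- a 1e-12 floor inside denominators guards degenerate all-zero rows;
- convergence when the relative objective change drops below `tol`
  (default 1e-6), with a `max_iter` cap (default 200);
- `K` is computed once per fit — the gene dimension enters only there, so
  fits cost the same for 1 000 or 20 000 genes;
- argmax ties in assignments resolve to the lowest cluster index.

Cluster labels are identifiable only up to permutation; all ground-truth
comparisons in the tests map fitted to planted clusters by majority sample
membership.

## Rank selection

For each candidate k, `n_restarts` (default 10) seeded fits are run.  Every
iteration of a run records the per-sample argmax assignment; connectivity
matrices (1 where two samples co-cluster) are averaged into a consensus
matrix C̄.  The score of k is the cophenetic correlation between the
consensus distance `1 − C̄` and the cophenetic distances of its
average-linkage dendrogram; a stable clustering makes `1 − C̄` nearly
ultrametric and the score approaches 1.  The chosen k maximizes the score,
ties toward smaller k; zero-variance distance vectors yield an undefined
(NaN) score and are excluded.

Three consensus protocols are implemented (`consensus_mode`):

- **pooled** (default): all iterations of all restarts averaged into one
  consensus per rank;
- **iterations**: one consensus (and score) per run from its own
  trajectory, scores averaged over restarts;
- **restarts**: only final assignments averaged across restarts (the
  classic consensus-clustering protocol).

The default was decided by measurement at the package's reference
conditions (planted k=3, effect 2.0, noise 0.5, 30 patients/cluster, ranks
2–6, 10 restarts): pooled recovered the planted rank in 20/20 cohorts,
restarts in 19/20, iterations in 18/20.  The per-run protocol fails
occasionally because a *wrong* rank that merges two planted clusters can
still be perfectly self-stable within a single trajectory; pooling restarts
reintroduces the between-run variability that exposes it.  `1 − C̄` uses
the ones-matrix (not the identity) so same-cluster distances go to 0;
average linkage follows the consensus-clustering literature; an optional
`burn_in` (default 0) can exclude early iterations.

`cophenetic_coefficient` is cross-checked against an independent
brute-force UPGMA implementation (explicit agglomeration and dendrogram
walk) to 1e-10; the comparison matrices carry a tiny symmetric jitter so
that merge order is unambiguous for both implementations.

## Gene-cluster filtering

Argmax/argmin assignment places *every* gene somewhere.  Genes are kept
only when their fold-change distributions actually differ across sample
clusters: per direction, a Kruskal–Wallis test (tie-corrected mid-ranks,
chi-square reference) across the k cluster groups with Bonferroni over the
genes tested in that direction; survivors then require every Dunn post-hoc
pair involving their own cluster to be significant, with Bonferroni over
the k(k−1)/2 pairs per gene.  The Dunn statistic is

    z = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − ΣT/(12(N−1))) (1/n_i + 1/n_j) )

with `ΣT = Σ(t³ − t)` over tie groups of the pooled ranks.  Degenerate
cases are defined, not errors: all-tied pools give p = 1; constant gene
rows are flagged and never selected; single-member clusters trigger a
logged warning.  The Bonferroni family choices (genes within direction for
KW; pairs within gene for Dunn) mirror the separate up/down treatment of
the two directions; k ≥ 3 is required, and rank selection warns when a
smaller k wins.

## DEG modules and candidates

All filtered genes (union over clusters and directions) are re-tested per
cluster: Welch's unequal-variance t between the cluster's patients and all
controls, on the normalized expression scale (controls have no fold-change
column by construction).  Bonferroni is applied over genes tested, per
cluster; survivors split by the sign of the patient−control mean difference
into `M_i⁺ / M_i⁻`.  Welch rather than pooled variance is the default
because subgroup sizes are typically unbalanced; a pooled switch exists.

Cross-disease pairing uses upper-tail hypergeometric enrichment
(`P(X ≥ overlap)`, Bonferroni over sets tested; universe = measured genes
of both cohorts intersected with the collection's universe).  Stage A
counts each module's enriched pathways shared with the other disease's
reference pathways; stage B enriches the same-direction common genes of
every cluster pair and counts overlap with the pathways of the joint
(intersection) reference list.  The pair maximizing the stage-B up+down
count wins (ties: stage-A counts, then lowest indices); when every
reference overlap in both stages is zero the result is an explicit
"no related pair".  The candidate set is `(M_i⁺∩M_j⁺) ∪ (M_i⁻∩M_j⁻)` of the
chosen pair, each gene tagged with its direction.  The candidate/reference
overlap test defaults its background to the measured-gene intersection of
the two cohorts, since no principled external background is available.

## Classifier validation

Candidates are evaluated as features of a deliberately plain logistic
model: weights (and intercept) start at exactly zero, full-batch gradient
ascent on the *mean* log-likelihood with a fixed learning rate (default
0.05) for a fixed epoch count (default 500), no regularization.  The epoch
count is fixed rather than convergence-based so the learning rate remains
meaningful; the mean (not sum) gradient keeps it comparable across fold
sizes.  Folds are stratified and seeded — unstratified splits on small
cohorts risk single-class folds — and features are z-scored with
training-fold statistics.  Performance is the rank-based ROC AUC
(Mann–Whitney, half-credit ties).  The random-gene baseline draws `reps`
same-size panels and compares their mean AUCs to the candidate mean AUC
with a one-sample two-sided t-test.  A one-way ANOVA helper checks numeric
covariates (e.g. age) across sample clusters.

## Synthetic data: what it emulates and what it does not

`generate_paired_study` produces two cohorts with planted structure chosen
to match the analysis' assumptions: per-gene baselines uniform on [6, 10]
log2 units; additive cluster effects ±2.0 (default) on 40-gene up/down
modules per cluster; i.i.d. Gaussian noise (sd 0.5) truncated at ±4 sd so
all values stay strictly positive; 30 patients per cluster and 30 controls;
an optional constant batch offset on a random half of samples.  Twenty
shared candidate genes (70 % up, 30 % down) are planted with identical
direction in the designated cluster pair of both diseases; all other module
slots are drawn disjointly across the two diseases so the planted
candidates are *exactly* the same-direction module intersection.  Pathway
sets are built one per planted module (≥ 80 % module members plus random
fillers) plus 20 random decoy sets; reference lists are the shared
candidates plus 30 non-module decoy genes, making the planted pair the
unique enrichment maximizer.

These defaults are the package's reference operating conditions and are
used unchanged by the test suite and `scripts/acceptance.py`.  The
generator does **not** emulate probe-level artifacts, dye bias, saturation,
correlated gene-gene noise, overlapping modules, or covariate-driven
confounding — so passing tests demonstrate that the machinery recovers the
structure it assumes, not that real cohorts satisfy those assumptions.
One consequence worth knowing: because 24 % of simulated genes are
informative for *some* subgroup, random baseline panels can outperform the
subgroup-specific candidate panel on the all-patients-vs-controls task;
in sparse real transcriptomes the baseline is far weaker.

## Problem sizes

The reference conditions (1 000 genes, 90 patients + 30 controls per
disease, ranks 2–6, 10 restarts) were chosen so that a full two-disease run
completes in a few seconds and the entire statistical acceptance suite in
about two minutes on one CPU, while keeping every planted-recovery margin
comfortable.  Because the factorization touches genes only through `AᵀA`,
runs at 15 000–20 000 genes cost little more.

## Known limitations

- Batch adjustment is per-gene batch-mean centering (a no-covariate linear
  batch model), not a covariate-preserving method.
- Bonferroni is used everywhere; no FDR variants.
- The Dunn test is the only post-hoc offered.
- Enrichment is overlap-based (hypergeometric); no ranked or
  topology-aware variants.
- Cluster labels are reported as fitted; downstream consumers needing
  planted-label alignment must map by membership.
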