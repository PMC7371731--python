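# Methods

This note documents the models, numerical conventions and design
choices behind the package, and what the synthetic validation does and
does not establish.

## Expression model and preprocessing

All inputs are log-scale expression matrices (genes × samples), the
scale on which RMA-summarized microarray data and log-transformed
RNA-seq summaries live. Gene-wise standardization ("row z-scoring")
centers each gene to mean 0 and scales to unit SD using the *n − 1*
denominator; zero-variance genes are dropped with a warning rather than
mapped to non-finite values. When cohorts from different platforms are
combined, each cohort is standardized independently first and the join
is taken over the gene intersection, so cohort-level location and scale
effects cancel by construction. Z-scores are clipped to [−5, 5] only
for heatmap-style export, never before clustering or scoring — clipping
is a display convention, not part of any statistic.

Duplicate gene rows (multiple probes per gene) are collapsed by keeping
the highest-variance row, the common probe-reduction heuristic; mean
collapse is available by option. This rule is a documented package
choice, not a claim about how any particular upstream dataset was
processed.

PCA of samples is SVD-based on caller-standardized rows, with each
component's sign fixed so its largest-magnitude gene loading is
positive; this makes coordinates reproducible across linear-algebra
backends.

## Differential expression

The per-gene statistic is the pooled-variance (Student) two-sample t
with df = n_A + n_B − 2 and two-sided p from the t distribution;
`log_fc` is mean(A) − mean(B) on the log scale. The pooled form is used
because the same t-statistics double as the classifier gene weights
(below), matching the original linear-predictor-score recipe; Welch's
form is available by flag. Genes with zero pooled variance are skipped,
not assigned infinite statistics. Multiple-testing correction is
Benjamini–Hochberg step-up, q_(i) = min_{j≥i} p_(j)·m/j. Gene selection
uses raw p < 0.01 together with |log-FC| > 1 by default; q-based
filtering is opt-in. A moderated (shrinkage) variance test is out of
scope; with the group sizes used here (≥ 15/group) the plain t is an
adequate approximation, but users with very small groups should expect
noisier gene selection.

## LPS classification

The linear predictor score of a sample is LPS(x) = Σ_j a_j x_j over the
classifier genes, with weights a_j equal to the training t-statistics.
Classifier genes are the top *n* by |t| (default 15–20; the value is a
capacity knob, not a biological constant). Class-conditional Gaussians
are fitted to the training scores by method of moments (mean and n−1
SD), priors are equal by default, and posteriors are computed in log
space so scores far outside the training range still give finite,
normalized probabilities. Samples whose maximum posterior falls below a
confidence cut (default 0.9, the cell-of-origin convention) are reported
as unclassified.

The TIS score is the posterior of the senescent class; the
responder / non-responder bands at 0.8 / 0.2 are fixed cutoffs of the
banding rule, with both boundaries falling into the unclassifiable band.

The three-class extension fits one one-vs-rest LPS axis per class
(weights from the class-vs-rest t), a two-Gaussian posterior p_k on each
axis, and normalizes p_k / Σ_l p_l. This reduces to the two-class rule
when one class is absent. It is an approximation: other constructions
(pairwise axes, a trivariate Gaussian on three scores) are possible and
could order borderline samples differently; conclusions should not hang
on samples near the decision boundary.

Cross-validation is stratified k-fold (default 10, seed 1), with gene
selection, weight estimation and Gaussian fitting all redone inside each
training fold, so reported accuracy carries no selection leakage. The
default CV rule is arg-max (a two-class sample is never unclassified);
with a stricter confidence cut, unclassified held-out samples count as
errors, which makes accuracy conservative. The arg-max default keeps
null-data CV accuracy at the chance level a permutation control expects.

## Preranked GSEA

Genes are ranked by the DE t-statistic (log-FC selectable), descending,
with ties broken lexicographically by gene ID so results are
bit-reproducible. The enrichment score is the weighted KS running sum:
at a set member, the sum rises by |metric|^w normalized over all member
weights (w = 1 by default, the standard "weighted" statistic); at a
non-member it falls by 1/(N − N_hits). The ES is the value of the
largest absolute excursion; the leading edge contains the members from
the top of the list to the peak (positive ES) or from the peak to the
bottom (negative ES). The running sum is accumulated strictly left to
right, so the profile is identical to a scalar walk and conserved to 0
at the end. If every member's metric is exactly zero the hit increments
fall back to equal steps.

The null permutes gene labels (set size preserved) rather than
phenotypes: group sizes in the intended applications are small and a
gene-permutation null applies to any preranked input. NES divides the
observed ES by the mean |ES| of same-sign null scores. The permutation
p-value is one-sided with a +1 pseudo-count, p = (1 + #{same-sign
|ES_null| ≥ |ES|}) / (#same-sign + 1); with this denominator the null
p is exactly uniform on its achievable grid, which the validation
checks. When no null score shares the observed sign, p is floored at
1/(n_perm + 1) with a warning. NES heatmaps order gene sets by
complete-linkage clustering of NES profiles under Euclidean distance,
with missing entries excluded from the distances.

## Signatures

The cross-species signature keeps genes passing the up-filter in
species A whose ortholog image passes the up-filter in species B;
many-to-many orthologs qualify if any partner passes (a recall-oriented
choice — a stricter all-partners rule would trade recall for precision).
The same machinery with the orientation reversed yields the commonly
downregulated arm.

Two-cluster stratification z-scores the signature genes, computes
sample–sample distance as 1 − Pearson correlation of the signature
profiles, agglomerates with complete linkage and cuts the tree at k = 2.
Labels are renumbered so cluster 1 is the larger (ties resolved toward
the cluster holding the lexicographically first sample), making labels
reproducible rather than heatmap-positional. Because Pearson distance
centers each sample's profile, a signature consisting only of uniformly
up-shifted genes is invisible to it; informative stratification needs
up- and down-arms (anticorrelated blocks), which is how the generator
plants signal for this step and why the cross-species workflow clusters
on the union of both arms.

The core signature is the intersection of GSEA leading edges across
comparisons. Edges from different species are translated into a common
namespace first: an edge whose members overlap the ortholog map's source
side more than its target side is mapped forward before intersecting.

## Survival statistics

Kaplan–Meier curves use the product-limit estimator over distinct event
times. The log-rank test uses the observed-minus-expected form with
hypergeometric variance; for more than two groups the full covariance
matrix is inverted (pseudo-inverse on the first k − 1 groups), df =
k − 1, asymptotic chi-square p. Kruskal–Wallis uses the tie-corrected H
statistic. The 2×2 cluster-vs-outcome association uses Fisher's exact
two-sided test. Reported p-values are floored at the smallest positive
double rather than printed as 0. Censoring at the observation horizon
is the generator's (caller's) responsibility; the tests consume
(time, event) pairs as given.

## Synthetic cohorts

The generator emulates log-scale expression cohorts: per-gene baseline
means uniform on [4, 12] (a typical log2 microarray intensity range),
i.i.d. Gaussian noise with SD 1.0, and a planted block of signature
genes shifted by `effect_size` × noise SD in the designated group. The
default study conditions are 20 samples per outcome group, 200 genes,
a 20-gene planted block at effect 2 SD (1.5 SD in the classifier
calibration checks), chosen to mirror cohort sizes of a few dozen
samples per arm with a clearly present but not trivial transcriptional
program.

Survival is exponential with hazard λ_s = hazard_rate ·
exp(hazard_log_hr · z_s), where z_s is the sample's standardized planted
signature score (mean of the up-arm minus mean of the down-arm, when a
down-arm exists), right-censored at the 100-day observation horizon of
the mouse-trial design. Defaults hazard_rate = 0.02–0.03/day give
median event times of 25–35 days, i.e. mostly observed events within
the horizon; hazard_log_hr = −0.9 makes signature-high samples survive
longer at a between-group hazard ratio of roughly e^1.8 ≈ 6, and
log(3)/2 plants a hazard ratio near 3 between cluster means. The TIS
senescence training cohort splits its planted block half up- / half
down-regulated in the senescent group; the linked application cohort
reuses the training cohort's gene baselines (same-platform emulation)
so classifier scores transfer, with independent noise and survival
draws. Paired-species cohorts live in disjoint namespaces joined by a
one-to-one ortholog map; an `overlap_fraction` controls how many planted
genes are orthologs of the other species' planted genes.

Every generator is a pure function of its config including the seed;
sub-streams for baselines, noise, survival and planted-gene choice are
spawned deterministically from it.

**What the synthetic validation does not show.** The generator has no
probe effects, batch structure, correlated gene modules,
heavy-tailed noise, informative censoring or proportional-hazards
violations. Passing tests demonstrate that the algorithms are
implemented correctly and recover signal under their stated model; they
do not certify performance on real cohorts, where effect sizes are
smaller, noise is structured and the senescence program overlaps
proliferation signatures.

## Validation design

Every nontrivial statistic is checked against an independent oracle:
the Bayesian posterior against direct density evaluation (to 1e−12),
the GSEA running sum against position-by-position enumeration
(bit-exact), the pooled t, BH, Kruskal–Wallis and Fisher tests against
brute-force formula enumeration, and log-rank/KM additionally against
lifelines. Null calibration (permutation p, log-rank p, CV accuracy
under permuted labels) is verified by simulation with fixed seeds.
Problem sizes in the test and acceptance runs (hundreds of genes, tens
of samples, ≤ 20 replicates, ≤ 1000 permutations) are chosen so the
whole validation completes in well under a minute per check while
keeping Monte-Carlo bands tight enough to be meaningful.

## Known limitations

- The plain t-test front end is not variance-moderated; very small
  groups will select noisier genes.
- The three-class LPS construction is one of several reasonable
  extensions; near-boundary assignments are construction-dependent.
- Gene-permutation GSEA nulls ignore inter-gene correlation and are
  anti-conservative on strongly co-expressed sets.
- The exponential survival link is the simplest outcome model; it is a
  test harness, not a claim about real relapse kinetics.
- Ortholog translation treats the map as ground truth; mapping errors
  propagate directly into cross-species signatures.
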