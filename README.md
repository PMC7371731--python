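# suvarness

Cross-species prediction of chemotherapy outcome from senescence gene
signatures in aggressive B-cell lymphoma.

Therapy-induced senescence (TIS) is a drug-evoked, H3K9me3-enforced
cell-cycle exit that complements apoptosis; lymphomas that can still
senesce after chemotherapy tend to stay in remission, while
senescence-incapable ones relapse. This package implements the
computational side of that idea as a reusable, fully tested pipeline for
transcriptomics cohorts: train an expression classifier for senescence
capacity on a controlled comparison, score new samples with a Bayesian
"TIS score", derive a senescence-up gene signature ("SUVARness") and its
cross-comparison core, map it between species through orthologs, and ask
whether signature-high patients survive longer. Every stage runs and is
validated on synthetic cohorts with planted signal, so the whole analysis
is reproducible on a laptop with no data downloads.

It is aimed at computational biologists working with bulk expression
cohorts (microarray or log-scale RNA-seq summaries) annotated with
treatment outcome and right-censored survival.

## The methods in brief

**Linear predictor score (LPS) classification.** For classifier genes
*j* with training two-sample t-statistics *a_j*, a sample with
expression *x* gets the score

    LPS(x) = Σ_j a_j x_j .

Class-conditional Gaussians N(μ_k, σ_k²) are fitted to the training
scores of each class and a sample's class probability follows Bayes'
rule,

    P(k | s) = π_k φ(s; μ_k, σ_k) / Σ_l π_l φ(s; μ_l, σ_l) ,

with equal priors by default. The posterior of the senescent class is
the **TIS score**; samples with TIS score > 0.8 are senescence
responders, < 0.2 non-responders, the closed band between is
unclassifiable. A one-vs-rest extension handles three-class
(consensus-cluster style) subtyping.

**Preranked GSEA.** Genes are ranked by the differential-expression
t-statistic; the enrichment score is the classic weighted
Kolmogorov–Smirnov running sum (hit increments ∝ |metric|, miss
decrement 1/(N − N_hits)), with the **leading edge** defined as the set
members between the top of the list and the running-sum peak.
Significance and NES come from a gene-permutation null.

**Signatures and survival.** The SUVARness signature is the set of
TIS-upregulated DE genes (p < 0.01, log-FC > 1); the *core* signature is
the intersection of GSEA leading edges across comparisons, translated
into a common namespace through an ortholog map. Samples are stratified
by median signature score or by two-cluster hierarchical clustering
(Pearson distance, complete linkage) and compared with Kaplan–Meier
curves, the log-rank test, Kruskal–Wallis and Fisher's exact test.

## Worked example

The numbered drivers under `analysis/` run the three studies end to end
on simulated cohorts (20 samples per outcome group, a 20-gene planted
senescence block at 2 SD effect, exponential survival tied to the
signature score, censored at 100 days, seed 1):

```sh
python analysis/01_simulate_cohorts.py
python analysis/02_tis_classifier.py
python analysis/03_suvarness_signature.py
python analysis/04_xspecies_stratification.py
```

`02_tis_classifier.py` prints:

```
training cohort: 40 samples, 200 genes tested
tenfold cross-validated accuracy: 100.0%
application calls: 20 responders, 20 non-responders, 0 unclassified
responder vs non-responder log-rank: chi2 = 19.78, p = 8.67e-06
```

meaning the classifier separates the senescent from the non-senescent
training samples perfectly under cross-validation, bands the application
cohort into responders and non-responders, and the responders' simulated
time to relapse is significantly longer — the planted survival link is
recovered. `03_suvarness_signature.py` then reports the 20-gene
signature enriched in all four comparisons (NES ≈ 2.1, permutation
p ≈ 0.001), a 20-gene core, and significant above/below-median survival
splits in both human cohorts; `04_xspecies_stratification.py` recovers
10 up- and 10 down-regulated ortholog pairs and clusters that match the
outcome groups exactly (Fisher p ≈ 1e-11).

The same stages are scriptable through the `suvarness` command-line
tool (`suvarness simulate | de | lps-train | lps-cv | gsea | xsig |
core-sig | score | stratify | survdiff | run-tis | run-suvarness |
run-xspecies`); run `suvarness --help` for details.

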