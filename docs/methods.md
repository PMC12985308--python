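# Methods

This note documents the statistical procedures, defaults and design choices
behind `cervicomp`, and what the simulation-based tests do and do not show.

## Compositional substrate

Genus tables are treated as compositions: only relative information is
interpretable. Before any log-ratio work, zeros are replaced:

- counts mode: a pseudocount (default **0.5**) is added to every count and
  rows are closed to proportions;
- proportions mode: multiplicative replacement with **δ = 1e-6** — zeros
  become δ and the non-zero parts of a row with z zeros are rescaled by
  (1 − zδ).

Both parameters are configurable and recorded in output provenance. The
centred log-ratio (CLR) uses the natural logarithm throughout; the Aitchison
distance is the Euclidean distance between CLR rows. Because the source data
pipeline's zero-handling rule is generally unknown for any given cohort,
absolute distance values depend on these choices (deeper sequencing or a
smaller pseudocount pushes absent taxa to a lower floor and inflates
distances); orderings and test decisions are far less sensitive.

## Alpha diversity and the nonparametric stack

Richness is the count of detected genera (relative abundance > 0); Shannon
diversity is −Σ pₖ ln pₖ in nats, so H′ ≤ ln S. Group differences use
Kruskal–Wallis (tie-corrected, chi-square reference) and pairwise
Mann–Whitney U tests: the exact null distribution when the smaller sample
has ≤ 8 observations and there are no ties, otherwise the normal
approximation with tie and continuity corrections. Within each metric the six
pairwise p-values form one Benjamini–Hochberg family. Cliff's delta
δ = P(X > Y) − P(X < Y) is labelled negligible/small/medium/large at
|δ| < 0.147 / 0.33 / 0.474 — the conventional thresholds, which also
reproduce every published label we checked (e.g. 0.41 → Medium,
−0.53 → Large).

## Distance-based multivariate tests

PCoA is classical metric scaling of the Gower-centred matrix −½ J D² J;
axes with eigenvalue > 1e-8 × the largest are retained and tiny negative
eigenvalues are truncated (CLR-Euclidean distances are Euclidean-embeddable,
so none are expected beyond rounding).

PERMANOVA partitions ΣᵢⱼD²ᵢⱼ into within- and between-group terms and tests
pseudo-F = (SS_B/(g−1))/(SS_W/(n−g)) by label permutation. The p-value
convention includes the observed statistic, p = (1 + #{F* ≥ F})/(1 + P),
guaranteeing p ≥ 1/(P+1); P defaults to **9999**. Pairwise comparisons are
BH-corrected across the pair family. PERMDISP uses the **group-centroid
variant**: samples are embedded by PCoA, per-sample dispersion is the
distance to the group centroid, and the one-way ANOVA F on dispersions is
compared against permutations with dispersions recomputed under each
permuted grouping. Several PERMDISP variants exist (spatial medians, total
samples vs group-size permutation schemes); the centroid-recompute variant
was chosen for its direct interpretability and its exact null calibration in
our simulations.

Host factors are screened one at a time: the single-factor PERMANOVA is run
on the samples with non-missing values, levels with fewer than two samples
are dropped (logged), and single-level factors are skipped with a warning.
Factors are treated as categorical; continuous covariates (age, parity)
should be binned by the caller. The screen makes no joint adjustment — it
mirrors an independent-factor design and should be read as exploratory.

## Bias-corrected differential abundance

Counts inform only relative abundance: each sample carries an unknown
log-scale sampling fraction. The model y_jk = d_j + β_{g(j),k} + ε is fitted
on y = ln(count + 1) by alternating least squares (offsets ↔ group means,
tolerance 1e-6 on the offsets, ≤ 100 iterations; convergence is monotone
because the updates are block coordinate descent on a quadratic). The
remaining contrast-level identifiability gap — a constant can move freely
between a group's means and its samples' offsets — is closed by assuming
most genera are non-differential: the **median of a contrast's per-genus raw
log-fold changes** estimates the bias and is subtracted from all of them.
Standard errors use per-genus within-group residual variances with the
two-group formula; Wald z-tests are BH-corrected within each contrast
family; a per-genus global chi-square Wald statistic spans all non-reference
coefficients. Significance defaults to q ≤ 0.10. Genera with zero counts in
both groups of a contrast are inestimable and excluded from that family.

This is deliberately a *method-family* re-implementation of bias-corrected
differential abundance, not a port of any specific tool: the
Gaussian-mixture E-M bias estimator is replaced by the median estimator, and
structural-zero detection, sensitivity scores and mixed models are out of
scope. Results should be compared at the level of direction and rough
magnitude, not decimal places. The pseudocount inside the log is
configurable; with strictly positive counts and pseudocount 0 the
bias-corrected log-fold changes are exactly invariant to per-sample count
rescaling (the invariance the correction targets); with pseudocount 1 the
invariance is approximate at small counts.

## Log-ratio indices and ROC

The predefined dysbiosis index is clr(*Lactobacillus*) minus the mean CLR of
a curated anaerobe panel — algebraically ln(*Lactobacillus* proportion /
geometric mean of panel proportions). The default panel is {Gardnerella,
Prevotella, Dialister, Anaerococcus, Peptoniphilus, Finegoldia, Fannyhessea,
Fusobacterium, Peptostreptococcus, Sneathia, Megasphaera, Hoylesella},
intersected with the table's columns; it is configurable because published
panels are rarely enumerated beyond a few named genera.

The composite index contrasts data-driven gene sets: a genus is "consistently
increased" (decreased) in carcinoma when its mean CLR difference versus
Normal exceeds **τ = 1.0** natural-log units (falls below −τ) and it is
detected in at least **20%** of the group where it is higher. Both
thresholds are package decisions; no published criterion exists. Either set
coming out empty is reported as an error suggesting threshold relaxation
rather than silently producing a degenerate index.

ROC analysis uses the Mann–Whitney rank formula with half credit for ties
(equivalently the trapezoidal area under the empirical curve), with the
carcinoma group as the positive class and *lower* index values oriented as
positive by default.

## Co-occurrence networks

Within each group: genera with within-group detection prevalence ≥ 30%
(≥ 40% for the small carcinoma group) and non-zero variance are kept, capped
at the 20 with highest within-group total abundance. Spearman correlations
(average ranks, t-approximation p-values) are computed on the group's CLR
rows over all retained pairs; constant-vector pairs are excluded; BH-FDR is
applied across the retained pairs of that group. Edges require |ρ| ≥ 0.60
and q < 0.05 (|ρ| ≥ 0.70 for carcinoma). Nodes include edge-less retained
genera — densities E/(N(N−1)/2) and component counts are defined over the
full filtered set, which is what makes published summary metrics exactly
recomputable from printed node counts and edge lists.

## The synthetic cohort generator

The generator emulates a published cohort's per-group genus summaries: mean
relative abundance and detection prevalence for 17 genera (plus a filler
genus `Other` absorbing each group's remainder so means sum to 1), group
sizes **25/23/24/10** (Normal/LSIL/HSIL/CCU — the denominators implied by
the published prevalence percentages), and a decreasing Dirichlet
concentration gradient **50/20/20/5** that reproduces the published
increasing within-group dispersion qualitatively. Library sizes are
lognormal (log-mean ln 50 000, log-sd 0.4 — a typical amplicon depth;
sources are silent on depth), floored at 100 reads.

Per sample: presence ~ Bernoulli(prevalence); composition ~ Dirichlet over
the present genera with parameters proportional to the (renormalised) means;
counts ~ one seeded read per present genus plus Multinomial(remaining reads).
Two deliberate refinements of this textbook recipe:

- genera that are present but have a configured mean of 0 (printed as 0.00%
  yet with positive prevalence) receive a mean floor of 2.5e-5 — half the
  print resolution — before renormalisation, since a zero Dirichlet weight
  would contradict their prevalence;
- the one-read seeding makes "drawn present" coincide exactly with
  "detected", so empirical prevalence converges to the configured prevalence
  (tested at n = 2000 within ±0.03). Without it, low-mean genera would
  often draw zero reads at finite depth and prevalence could never match.

A consequence worth knowing: for very sparse profiles the within-group
Aitchison dispersion is dominated by the presence/absence pattern and the
detection floor, not by the Dirichlet concentration, so dispersion is
monotone in concentration only when compositions are dense (the
monotonicity test therefore uses an all-present, equal-mean profile). The
generator is driven entirely by `numpy.random.default_rng` (PCG64) from one
integer seed, which output provenance records.

What passing simulation tests shows — and does not. The generator matches
group-level means, prevalences and a dispersion gradient; it does not model
sequencing error, taxonomic misclassification, host-factor structure,
between-genus correlation beyond what the Dirichlet induces, or
batch/temporal effects. Recovery of qualitative structure (log-ratio
ordering, PERMANOVA separation, differential-abundance signs) on these
cohorts therefore demonstrates correctness and power of the *methods* under
the published summary statistics, not fidelity of any particular real
dataset; published per-sample statistics (exact pseudo-F values, exact mean
distances) are not reproducible without the raw data, which is not public.

## Problem sizes and numerical choices

Simulation studies in the test suite and acceptance script use 199
permutations per PERMANOVA (p-resolution 1/200, ample for α = 0.05
decisions), 500 replicates for null calibration and 100 seeds for structure
recovery; the pipeline default for real analyses remains 9999 permutations.
Wald and chi-square p-values are floored at 1e-300 to keep BH-FDR
well-defined at extreme separation. Degenerate situations are made explicit:
all-zero samples are errors, all-identical data yields H = 0/p = 1,
all-zero dispersions set a degenerate flag, zero within-group sum of squares
is rejected as a degenerate PERMANOVA design.

## Shape of the API

The package is organised as one module per analysis stage with typed result
objects, rather than a single fitted-model class: the pipeline character of
the analysis (simulation, IO, transforms, several independent test families,
networks) fits that shape better. The one genuinely model-like component —
differential abundance — follows the Model/Results convention:
`BiasCorrectedDA(table, metadata).fit()` returns a `DAResults` with
estimates, standard errors, intervals, q-values and a `summary()`.

## Known limitations

- The differential-abundance estimator's median bias correction assumes a
  majority of non-differential genera; with few genera (< ~10) or pervasive
  signal the correction degrades.
- The host-factor screen is single-factor and categorical only.
- PERMANOVA significance can reflect dispersion differences as well as
  location shifts; PERMDISP is provided precisely to qualify that reading,
  and on these cohorts dispersion does increase with severity.
- Composite-set membership for moderately prevalent genera is noisy at a
  10-sample case group; direction recovery is high but not certain.
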