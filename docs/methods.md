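# Methods

This note documents the statistical procedures, the synthetic cohort model,
the numerical conventions, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Cohort design and data model

The package targets a four-group observational design: centenarians (CE),
lineal relatives of centenarians (CE-L), elderly controls (ELD) and young
controls (YNG), with default sizes 145/126/92/62. Three feature tables are
carried per cohort — serum metabolite intensities (arbitrary units, strictly
positive, log-normal-like) and gut and oral genus count tables from 16S
amplicon sequencing — all sharing one sample axis, plus per-sample metadata
(group, age, sex, BMI, and a frailty index for centenarians only).

In memory, tables are oriented samples × features; on disk, the common
omics dialect (features × samples, TSV) is used and transposed on read.
Metadata fields other than `group` may be missing (recorded as unknown);
`group` is mandatory, and a frailty index is required exactly for CE
samples.

## Univariate testing

Two-group comparisons default to the Wilcoxon rank-sum test (a Welch t test
is available by config switch); rank tests are invariant to monotone
transforms, which suits skewed intensities and makes the signature
classification independent of the intensity scale. In `auto` mode the exact
null distribution is used for n₁+n₂ ≤ 12 without ties, otherwise the normal
approximation with tie and continuity correction. Direction is the sign of
the median difference, falling back to the mean difference on median ties.

Multiplicity is controlled by Benjamini–Hochberg within each comparison
family (one of the six group pairs) across the features of a single omic
— not pooled across omics, so adding a table never changes another table's
q-values. Spearman correlations use mid-ranks and the t-approximation for
p (an exact permutation p would matter only below n ≈ 10; all network uses
are far larger). Group annotations on ordination axes and clinical
indicators use one-way ANOVA with Tukey HSD (studentized-range p-values)
and an insert-and-absorb compact-letter display: groups share a letter iff
their adjusted p ≥ α.

## Signature classification

Features are classified from the q-value pattern of the six pairwise
comparisons plus group medians, in fixed precedence
centenarian → family → aging, first match wins, so the labels partition the
feature set (the heatmap/Venn treatment of such signatures implies disjoint
classes; ties between rules are otherwise undefined). The clauses are
listed in the README. Two open points were resolved as follows:

- the **family** rule by default also requires the relatives to differ from
  both control groups (q(CE-L,ELD) and q(CE-L,YNG) < α) — "distinct from
  the controls" is read as a property of both family members; a permissive
  variant is available behind `family_requires_control_sig=False`;
- the **aging** rule requires strict median monotonicity over
  YNG → ELD → CE plus q(CE,YNG) < α and one adjacent significant step,
  because a "gradual increase" is otherwise untestable; CE-L is excluded
  from the aging axis.

## PLS-DA, VIP and the permutation check

PLS-DA is PLS2 by classical NIPALS: X is log-transformed (pseudocount =
half the smallest nonzero value of the table when zeros are present) and
autoscaled; Y is the column-centered one-hot class matrix. The inner loop
u → w = Xᵀu/‖Xᵀu‖ → t = Xw → q = Yᵀt/(tᵀt) → u = Yq iterates to
Δt < 1e-10 (max 500), starting deterministically from the first Y column;
both blocks are deflated by the score. Each component's sign is fixed so
its largest-magnitude X-loading is positive, making scores platform-stable.
Two components are fitted by default (score plots use the first two).

VIP over all fitted components uses SS_a = ‖q_a‖² t_aᵀt_a, giving the exact
identity Σ VIP² = p. The overfitting check permutes class labels B times
(default 99; B ≥ 19 enforced) and compares cumulative R²Y, with
p = (1 + #{null ≥ observed})/(B + 1). The per-feature p paired with VIP for
marker selection comes from the univariate rank test of the same contrast,
not from the PLS model.

## Genus screening

The two-class genus screen follows the LEfSe recipe in spirit —
Kruskal–Wallis filter plus an effect-size threshold in log₁₀ units on the
per-million scale — but replaces the bootstrap LDA score with the
deterministic proxy log₁₀(max(|mean₁ − mean₂|, 1)) on TSS-normalized
(10⁶) abundances. For a single feature with no subclass structure the
original LDA effect size is monotone in between-class mean separation, and
the deterministic proxy makes threshold behavior exactly reproducible; this
is a deliberate divergence from the bootstrap original. The ">10% relative
abundance in the cohort" filter is implemented as detection prevalence
(nonzero in strictly more than 10% of samples): a 10% mean-abundance cut
would retain only a handful of dominant genera, inconsistent with screens
that report dozens of differential genera. The mean-abundance reading
remains available via `prevalence_as_mean_abundance`.

## Diversity

Chao1 uses the classic bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1));
Shannon entropy is in nats (a log2 switch would only rescale); Pielou
evenness is H/ln S_obs with the convention that a single-genus sample has
evenness 1. Indices run on raw counts — rarefaction is deliberately not
performed. PCoA applies Gower double-centering to squared Bray–Curtis
dissimilarities and an eigendecomposition; coordinates use positive
eigenvalues only (negative eigenvalues are reported, never embedded),
proportions explained are over the positive spectrum, and axis signs follow
the largest-coordinate-positive convention.

## Panels, networks, enrichment, key metabolite

Marker panels are scored by logistic regression fitted by IRLS with a small
L2 penalty (default 1e-6) on the non-intercept coefficients to stabilize
separable panels; ROC curves group tied scores into single thresholds so
the trapezoid AUC equals the Mann–Whitney U/(n₁n₂) identity exactly, and
reported AUCs are resubstitution values (single-cohort usage; labeled as
such). Correlation networks compute all metabolite × genus Spearman
correlations via rank-transform and matrix products; edges are retained at
|ρ| ≥ 0.2 and raw p < 0.05 (the caption-level filter), with BH q reported
per edge for transparency. Over-representation is an upper-tail
hypergeometric test with the universe set to all measured features
(standard ORA practice), pathway membership intersected with the universe,
and BH across pathways.

The key-metabolite rule selects metabolites that are (a)
centenarian-signature elevated, (b) healthy-vs-frail markers with
HC-elevated direction, and (c) incident to at least one positive gut-genus
edge, ranked by (gut edge count, max ρ). The pipeline evaluates clause (c)
on a **within-centenarian** network: in a pooled four-group cohort, any
centenarian-elevated metabolite correlates with any centenarian-elevated
genus through group structure alone, so pooled edges carry no information
about a specific metabolite–microbe coupling; restricting to CE samples
removes the group axis and matches the healthy-vs-frail context of clauses
(a)–(b). The cohort-wide network is still computed and reported.

## Bioassay statistics

Kaplan–Meier estimation and the Mantel–Cox log-rank test are delegated to
lifelines. Mean lifespan is the restricted mean (area under the survival
curve up to the last observed time), which equals the arithmetic mean of
event days when nothing is censored — the relevant case for
fully-followed-up plate assays. Percent lifespan extension and viability
percentages are reported to two decimals. ΔΔCt expression is
2^−[(Ct_target − Ct_ref)_treated − (Ct_target − Ct_ref)_control]; the
dispersion of reported mean±spread lifespans is carried as given, never
recomputed.

## Synthetic cohort model

The generator emulates the study conditions with planted ground truth:

- **Metabolites**: log-intensities Normal(μ_f + shift, σ = 0.5) with
  feature baselines μ_f ~ Normal(10, 1). Planted shifts (default 1.0
  natural-log units) follow the signature patterns: centenarian features
  shift in CE only (21 elevated, 26 depleted); family features in CE and
  CE-L (36 elevated); aging features linearly over YNG (0) → ELD (½) → CE
  (1), CE-L untouched so the three patterns stay distinguishable.
- **Genus counts**: per-sample composition ~ Dirichlet(α_group), counts ~
  Multinomial at Poisson(30 000) depth. Baseline α follows a power law over
  ranks (decay 0.7) scaled to total concentration 150 (gut) / 120 (oral) —
  values in the range reported for human stool/saliva compositional
  variability, chosen so the planted recovery contract holds at the default
  group sizes. Planted genus effects multiply α in the shifted groups.
- **Genus layout**: compositional data are zero-sum, so planting elevated
  mass in CE alone depresses every other genus in CE and can turn the
  family rule's required CE ≈ CE-L equality false. Planted genera are
  therefore laid out with mixed directions so the planted mass roughly
  cancels per group: aging genera on the most abundant ranks (the half-size
  ELD step is detectable only where compositional noise is small), with
  more decreasing than increasing members (a fold elevation adds e−1 mass
  while a fold depletion removes only 1−1/e); depleted centenarian genera
  on abundant ranks and elevated ones on rarer ranks. Oral centenarian
  genera are all depleted (tooth-loss-like pattern), family genera
  elevated.
- **Frailty**: CE samples are randomly permuted and assigned frailty
  indices 0–10 (healthy, exactly 81) or 11–25 (frail, exactly 64), making
  split sizes deterministic.
- **HC markers**: 11 otherwise-null metabolites plus the key metabolite
  receive a ±½-effect healthy/frail contrast within CE (so the CE-level
  mean is preserved); only the key metabolite is both
  centenarian-elevated and HC-elevated, mirroring a single healthy-longevity
  marker.
- **Key pair**: the key metabolite's noise is coupled to the key gut
  genus's relative abundance through a Gaussian copula whose scores are
  ranked *within* groups, with the coupling weight found by deterministic
  bisection so the within-CE Spearman ρ hits the target (default 0.4). The
  key genus is a mid-abundance genus outside the planted signature blocks
  with no group effect of its own (`key_genus_effect_scale`, default 0):
  when both pair members carry full centenarian effects, group separation
  alone drives the pooled ρ far above any intended coupling target; with a
  group-null genus the pooled ρ concentrates near the target and the
  coupling is a genuine within-group association. A real marker genus would
  itself carry a longevity signature; this is a deliberate simplification
  that keeps the pooled correlation interpretable.
- One RNG stream per table, spawned from the master seed, so regenerating
  one table never perturbs the others; equal seeds give byte-identical
  bundles on disk.

What the generator does **not** emulate: batch effects and instrument
drift, phylogenetic correlation between genera, covariance among
metabolites beyond the single key pair, age as a continuous confounder
within groups, and missing samples per assay (all 425 samples have all
three tables). Passing recovery tests therefore demonstrates correctness of
the procedures under a clean, well-specified data model — not robustness to
the artifacts of real cohorts.

## Problem sizes and determinism

Default analyses run at the full synthetic design (425 samples, 808 + 250 +
200 features); the permutation check uses 99 permutations by default and the
unit-test suite uses a scaled-down cohort (72 samples, 160 features) where
full size adds nothing. Every stochastic stage is seeded from a single
master seed; pipeline outputs are pure functions of (inputs, config, seed),
and re-running a manifest reproduces identical output files.

## Known limitations

- The LDA-effect proxy is deterministic and rank-free in its magnitude
  component; absolute score values are not comparable with bootstrap LEfSe
  implementations, only the pass/fail behavior at matched thresholds is.
- Resubstitution AUCs are optimistic by construction; no cross-validation
  is performed.
- The aging rule's strict monotonicity makes it conservative for features
  with a plateau between the elderly and centenarian groups.
- ORA treats pathway membership as flat sets; no topology or abundance
  weighting.
- Signatures are unadjusted for covariates (age within group, sex, BMI).
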