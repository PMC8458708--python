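# Methods

This note documents the statistical models, rules and numerical choices
implemented in `lenvicb`, the defaults they ship with, and what the
synthetic-data generators do and do not emulate.

## Meta-analysis of proportions (`lenvicb.meta`)

**Unit of pooling.** The cohort, not the publication: basket trials
contribute one row per tumor type, matching how per-tumor-type response
rates are reported. The bundled table has 20 cohorts (1168 patients).

**Event reconstruction.** Trial tables print percentages, not counts.
Events are reconstructed as x = ⌊p/100·n + 0.5⌋ (nearest integer, ties
half up), clamped to [0, n]. Reconstruction error is at most half a
patient per cohort and is negligible relative to sampling error.

**Transform.** Freeman–Tukey double arcsine,
t = asin√(x/(n+1)) + asin√((x+1)/(n+1)), var(t) = 1/(n+½). This is the
conventional default for meta-analysis of proportions (it is what the
widely used Stata `metaprop` routine applies) and keeps variances defined
at x = 0 and x = n, both of which occur in the bundled table (one cohort
reports DCR = 100 %). A Wald-logit transform with 0.5 continuity
correction is available via `transform="logit"`.

**Heterogeneity and model selection.** Cochran's Q against fixed-effect
inverse-variance weights; I² = max(0, (Q−df)/Q)·100; DerSimonian–Laird
τ² = max(0, (Q−df)/(Σw − Σw²/Σw)). Random effects (weights 1/(vᵢ+τ²))
are selected iff I² > 50 (strict inequality), else fixed effects. On the
bundled table I² is 91 % (ORR) and 85 % (DCR), so both endpoints pool
under random effects.

**CI and back-transform.** 95 % CI as t̄ ± 1.96·√var(t̄) on the
transformed scale, then the Miller inverse evaluated at the harmonic mean
of the cohort sizes; values outside (0, π) clamp to the boundary
proportions. Per-cohort forest-plot whiskers are Clopper–Pearson exact
intervals.

**Missing endpoints** are dropped for that endpoint with a warning, never
imputed.

## Expression scoring (`lenvicb.expression`)

Per gene, a two-sided Welch t-test on log₂(x+1) of pre-normalised
TPM-like values, tumor vs normal; "up" requires a higher tumor mean and
"significantly up" additionally p < α (default 0.05). Genes with < 2
samples in either condition are untestable and excluded from counts;
zero-variance ties in both arms take p = 1 by convention.

**No multiple-testing correction is applied across the 15 genes.** The
counting rules below are defined on per-gene nominal p-values; applying a
correction would redefine the categories. This is deliberate and worth
knowing when interpreting output.

Category rule (thresholds inclusive): **high** iff ≥ 4 lenvatinib targets
AND ≥ 2 ICB targets are significantly up; **moderate** iff exactly one of
those holds; **low** iff no target of either arm is up; anything else is
**unclassified** — a fourth category added because the three named ones do
not partition all outcomes (e.g. 2 lenvatinib + 1 ICB up).

## Correlation scoring (`lenvicb.correlation`)

Pearson r on log₂(x+1) over tumor samples only, for the 11×4 cross-arm
gene pairs. A cancer's summary is the count of pairs with r ≥ 0.1
(inclusive; max 44); pairs with r ≥ 0.15 are flagged "strong". Constant
genes give NaN cells, excluded from counts rather than treated as 0.
Ranking is by count descending with alphabetical tie-break; the top
⌈k/2⌉ cancers form the high-correlation group. Pan-cancer correlation
offers `pooled` (concatenate tumor samples; default) and `mean_r`
(average per-cancer r cell-wise); pooling conflates within- and
between-cancer covariation, which is also true of portal pan-cancer
scatterplots it mirrors.

## Alteration analysis (`lenvicb.alterations`)

Distinct-sample ("altered/profiled") semantics everywhere: a sample with
several qualifying records counts once. Driver status comes from a
catalog file rather than a live annotation service, for reproducibility;
matchers are protein-change literals, class wildcards (e.g. any CD274
amplification) and gene-level "any", with everything unmatched a VUS.
Five targets (FLT1, FLT4, PDCD1, LAG3, CTLA4) lack driver-annotation
evidence and are excluded from driver-level scoring; CD274 is the only
ICB target scored, over amplification records only.

Flags (inclusive thresholds): lenvatinib-set driver frequency ≥ 0.09;
CD274 amplification frequency ≥ 0.02. Total target mutational load is
the altered-sample fraction over the full 15-gene panel including VUS
(drivers-only is available as an option); the top-m set defaults to
m = 16, matching the length of the published highest-load ranking, and is
configurable.

## Immune scoring (`lenvicb.immune`)

Gene–infiltration correlations are Spearman (the convention of the
deconvolution portals whose outputs these tables emulate); with a purity
column present, a partial Spearman is used — rank both variables, regress
each on purity ranks, Pearson-correlate the residuals. Pearson is
available by config. Box rules on the 11 lenvatinib-gene correlations per
cell type, NaN excluded: CD8 depletion iff ≥ 8 negative AND ≥ 5 at
r ≤ −0.15; suppressive-cell enrichment iff ≥ 8 positive AND ≥ 5 at
r ≥ +0.15. "More than four" is read strictly as ≥ 5.

Prognostic calls: univariate Cox proportional hazards (lifelines, Efron
tie handling) on the covariate standardized to unit variance (z and its
sign are unaffected by positive rescaling; standardization only aids
convergence). Call = risk iff p < 0.05 and z > 0, protective iff p < 0.05
and z < 0, else neutral; fewer than 10 subjects is an error, zero events
or non-convergence degrade to neutral with a warning. The Kaplan–Meier
comparison splits at the covariate median (quantile configurable), ties
at the cut going to the high group.

## Integration (`lenvicb.integrate`)

Three boolean characteristics per cancer: expression category == high;
(top-m mutational load AND lenvatinib driver flag) — a conjunction,
because high load and high driver frequency are coupled in the criterion
and the disjunctive reading over-calls; CD8 box flag. The PD-L1 ≥ 2 %
flag is reported in the table but does not enter the count. Candidate iff
≥ 2 characteristics. Missing stages default flags to false
(conservative). The bundled `published_criteria.json` transcribes the
published per-characteristic cancer lists; integrating it yields the
nine-cancer candidate set {CHOL, GBM, HNSC, KIRC, LIHC, LUAD, SKCM, STAD,
UCEC}.

## Synthetic data (`lenvicb.simulate`)

The generators emulate the *statistical structure* each stage assumes:
log-normal expression with planted multiplicative tumor shifts and a
Gaussian-copula gene correlation (PSD-validated up front); Bernoulli
per-sample alteration events with a driver catalog covering a set
fraction of generated keys; cell scores softplus(linear in standardized
gene log-expression + Gaussian noise), optionally renormalised (portal
outputs are scores of varying convention, so a strict simplex is not
forced); exponential survival with log-hazard linear in one cell's
standardized score and independent exponential censoring; cohort tables
with logit-normal between-study heterogeneity and binomial event draws.

They do **not** emulate per-cancer marginal distributions of real tumor
data, read-count noise, batch structure, copy-number segmentation or
inter-portal source heterogeneity (e.g. MDSC estimates originating from a
different deconvolution method). Passing planted-recovery tests therefore
demonstrates correctness of the statistical machinery under its own
assumptions, not performance on real portal extracts.

Determinism: every draw derives from one master seed through
`numpy.random.SeedSequence([seed, stream, cancer_index])` with fixed
stream indices (0 expression, 1 alterations, 2 infiltration/survival,
3 study table), so any stage regenerates independently and identically
across platforms (PCG64).

The bundled demonstration scenario (`example_config`) plants one
positive cancer carrying all three characteristics (six lenvatinib
targets at 4-fold and three ICB targets at 3-fold up-shift; lenvatinib
driver events with union rate ≈ 0.16; CD8 link weight −0.45 per gene;
Treg log-hazard slope 0.7) and one null cancer, at 60 tumor / 30 normal
samples each — sizes at which the planted effects are detected with
probability near 1 while a full 100-replicate end-to-end calibration run
stays fast.

## Known limitations

- The pooled-proportion CI uses the normal quantile on the transformed
  scale; no Hartung–Knapp adjustment, no publication-bias diagnostics —
  consistent with the analysis this package operationalises.
- Expression/correlation stages assume pre-normalised input; no batch
  correction.
- The candidate rule is boolean counting; it assigns no weights and no
  uncertainty to the candidate set.
- Driver calling is only as good as the supplied catalog; the bundled
  synthetic catalogs are labelled synthetic and carry no curated content.
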