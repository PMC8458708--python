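# lenvicb

Evidence integration for **immune-checkpoint blockade (ICB) + lenvatinib**
combination therapy across cancer types.

Combining a PD-1/PD-L1/CTLA-4/LAG-3 blocking antibody with lenvatinib — a
multi-target tyrosine-kinase inhibitor of VEGFR1–3 (*FLT1/KDR/FLT4*),
FGFR1–4, PDGFRα/β, *KIT* and *RET* — outperforms either monotherapy in
several advanced cancers, but only a handful of tumor types have trial
data. `lenvicb` implements, as a tested and reusable pipeline, the two
analyses that address this gap:

1. **Meta-analysis of response proportions.** Single-arm trial cohorts
   report ORR/DCR percentages and cohort sizes. Events are reconstructed
   (x = round(p·n)), stabilised with the Freeman–Tukey double-arcsine
   transform t = asin√(x/(n+1)) + asin√((x+1)/(n+1)), var = 1/(n+½),
   pooled by inverse variance with the DerSimonian–Laird between-study
   variance τ², model-selected by I² (> 50 % ⇒ random effects), and
   back-transformed (Miller inverse at the harmonic-mean n). A bundled
   20-cohort table of published ICB+lenvatinib trials ships with the
   package.
2. **Rule-based multi-omics scoring.** For the 15 target genes, each
   cancer type is scored on four portal-style analyses — tumor-vs-normal
   differential expression (Welch t on log₂(x+1)), cross-arm Pearson
   gene–gene correlation (counting pairs with r ≥ 0.1), driver-vs-VUS
   alteration frequencies (lenvatinib-set drivers ≥ 9 %, PD-L1
   amplification ≥ 2 %, distinct-sample counting), and Spearman
   correlation with immune-cell infiltration (the CD8⁺ depletion box
   rule) plus Cox/Kaplan–Meier survival classification of infiltrates.
   Cancers with **≥ 2** of the three treatment-related characteristics
   (expression-high, alteration-high, CD8-negative) are candidates for
   the combination.

A seeded synthetic-data module generates TCGA-like inputs (log-normal
expression with planted fold changes and gene–gene correlation, Bernoulli
alteration events with a driver catalog, linearly linked immune fractions,
exponential survival) so the full pipeline runs and is tested without any
download. Intended users: translational oncology and biostatistics groups
prioritising tumor types for combination-therapy trials.

## Worked example

```python
from lenvicb import ProportionMetaAnalysis, build_evidence_from_criteria, candidates
from lenvicb.io import load_published_criteria

res = ProportionMetaAnalysis.from_bundled_trials(endpoint="ORR").fit()
print(res.summary())

ev = build_evidence_from_criteria(load_published_criteria())
print(candidates(ev))
```

prints

```
Meta-analysis of proportions (ORR)
==============================================
cohorts (k)                   20
model                     random
transform         double_arcsine
pooled proportion          0.379
95% CI           [0.278, 0.484]
Q (df=19)                 217.74
I^2 (%)                     91.3
tau^2                     0.1938

['CHOL', 'GBM', 'HNSC', 'KIRC', 'LIHC', 'LUAD', 'SKCM', 'STAD', 'UCEC']
```

The pooled objective response rate across the 20 cohorts is 0.379
(95 % CI 0.278–0.484); I² = 91 % indicates strong between-cohort
heterogeneity, so the random-effects model is selected. The nine listed
cancer codes carry at least two of the three molecular characteristics
and are the prioritised candidates for ICB + lenvatinib.

The same pipeline runs from the shell:

```bash
lenvicb simulate --seed 7 --outdir fixtures     # synthetic TCGA-like inputs
lenvicb all --fixture-dir fixtures --outdir out # every stage + integration
lenvicb integrate --outdir out2                 # bundled published criteria
```

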