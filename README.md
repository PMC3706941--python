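# berryplast

Transcriptome-plasticity analysis for multi-environment fruit expression
studies.

A single grapevine clone grown in different vineyards ripens its berries
differently, and much of that phenotypic plasticity is transcriptional: some
genes track the environment (plastic genes), some track development
identically everywhere (markers), and some barely move at all (constitutive
reference genes).  `berryplast` implements the complete analysis used to
chart that landscape from a multi-vineyard, multi-stage log2 expression
matrix — for example an 11-vineyard x 3-developmental-stage x 3-replicate
microarray design — together with a synthetic-data generator that plants
each gene class with known ground truth so every step of the analysis can
be scored for recovery.

## What it computes

Given a genes x samples matrix of log2 intensities (sample names encode
vineyard, harvest year, stage 1–3 and replicate A–C, e.g. `AM082B`):

1. **Unimodal gene set** — k-means over intensity profiles with increasing
   k until exactly one low-mean cluster pools a bimodal value distribution
   (Sarle's bimodality coefficient `b = (g₁² + 1)/(g₂ + 3(n−1)²/((n−2)(n−3)))`
   with cutoff 0.555, the uniform-distribution benchmark).  The bimodal
   cluster is the array's background/low-expression mode; everything else
   is kept.
2. **Plastic genes** — tie-corrected Kruskal–Wallis across vineyard groups
   (P < 0.01) on the unimodal set, summarised against the average number of
   ripening-modulated genes per vineyard and the array content.
3. **Factor-associated genes** — the same test across the levels of an
   environmental/viticulture factor (trellis system, rootstock, area),
   with BH q-values and a permutation FDR.
4. **Harvest analysis** — multiclass SAM (`d = r/(s + s₀)`, permutation
   FDR 0.1%) across vineyards at the ripe stage, a ≥2-fold
   vineyard-to-vineyard screen, and the two-group vineyard partition induced
   by the 1−r sample dendrogram, confirmed gene-wise by t-test (α = 0.05).
5. **Developmental markers** — SAM across stages ∩ ANOVA (α = 0.01,
   Bonferroni), eight Pearson k-means profile clusters, monotone clusters
   screened at the 95th percentile of the stage-3 minus stage-1 change.
6. **Constitutive references** — genes unmodulated across vineyards at
   every stage (SAM and ANOVA both negative), intersected over stages and
   ranked by standard deviation; the lowest ~1% are the reference set.
7. **Latent-variable models** — unit-variance-scaled PCA and OPLS-DA
   (NIPALS, predictive+orthogonal+0 notation, 7-fold stratified Q²) with
   label-permutation overfitting validation.

## Worked example

```python
from berryplast import (SyntheticSpec, generate_dataset,
                        unimodal_filter, call_plastic_genes)

# default study design: 11 vineyards x 3 stages x 3 replicates, 2,000 genes
m, truth = generate_dataset(SyntheticSpec(seed=1))

part = unimodal_filter(m, k_max=15, seed=1)
print(f"unimodal set: {len(part.unimodal_set)} of {m.n_genes} genes "
      f"(sweep stopped at k={part.k})")

res = call_plastic_genes(m, part.unimodal_set, alpha=0.01)
s = res.summary
print(f"plastic genes: {s['n_plastic']}")
print(f"average modulated per vineyard: {s['avg_modulated']:.0f}")
print(f"plastic as % of modulated: {s['pct_of_modulated']:.1f}%")

planted = truth.genes_of("plastic")
print(f"recall of planted plastic genes: "
      f"{len(res.plastic.members & planted) / len(planted):.2f}")
```

prints

```
unimodal set: 1294 of 2000 genes (sweep stopped at k=3)
plastic genes: 203
average modulated per vineyard: 192
plastic as % of modulated: 105.6%
recall of planted plastic genes: 0.99
```

The sweep has removed the 700-gene planted low-intensity bimodal class
(plus the low tail of the expressed genes); the Kruskal–Wallis screen then
finds essentially all 200 planted plastic genes at a ~2% empirical false
discovery proportion.  The "% of modulated" ratio exceeds 100% here because
the synthetic design plants as many vineyard-responsive genes as
stage-responsive ones — in a real berry dataset developmental modulation
dominates and the ratio is far below one.

A command-line interface mirrors the library
(`berryplast simulate | filter-unimodal | test | cluster | mvmodel | run`);
`berryplast run --matrix m.tsv --out results/` performs the full
classification and writes gene lists, a classification table and a JSON
run manifest.

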