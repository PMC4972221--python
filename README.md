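# streamimpact

Trait-based and multivariate analysis of stream macroinvertebrate responses
to wastewater point-source disturbance, built for replicated
upstream/downstream (BACI-style) biomonitoring designs: each study stream
contributes two upstream reference reaches (U2, U1) and one reach downstream
(D) of a wastewater treatment plant outfall, so that natural longitudinal
drift between reaches can be subtracted from the downstream response.

The package is aimed at freshwater ecologists and biomonitoring analysts who
want the full chain — community descriptors, ordinations, null-corrected
change statistics, and variance-partitioning inference — as tested,
composable Python instead of a collection of R snippets. A synthetic-data
generator reproduces the statistical structure of such a study (land-use
gradients, wastewater dilution gradients, trait-mediated community shifts)
with known ground truth, so every stage can be validated by parameter
recovery.

## What it computes

**Community descriptors** (per sampling location): taxa richness, Hurlbert
rarefied richness E[S_n] = Σᵢ [1 − C(N−xᵢ, n)/C(N, n)], Pielou's
J = H′/ln S, Fisher's α (solving S = α ln(1 + N/α)), Berger–Parker
dominance, EPT metrics, and two trait-based indices:

- **Saprobic Index** SI = Σᵢ sᵢ gᵢ aᵢ / Σᵢ gᵢ aᵢ over scored taxa
  (sᵢ ∈ [1, 4] saprobic value, gᵢ indicator weight, aᵢ abundance) — rises
  with organic enrichment;
- **SPEAR index** = 100 · Σᵢ w(xᵢ) 1[spearᵢ] / Σᵢ w(xᵢ) with
  w(x) = log₁₀(4x + 1) — the abundance-damped share of pesticide-sensitive
  taxa; falls under toxicant stress.

**Disturbance gradient**: the wastewater dilution factor DF_ww = Q347 / Q_ww
(regulatory low flow over mean effluent discharge; small DF = strong
disturbance), plus PCA summaries of effluent chemistry (PC1_ww) and of
upstream–downstream habitat change (PC_habitat).

**Change statistics** (per stream): the null-corrected descriptor change
Δ = (D − U1) − (U1 − U2), and Total Community Change
TCC = ‖D − U1‖ − ‖U1 − U2‖ in two-axis NMDS space.

**Ordination engine**: Hellinger transform, PCA, NMDS (Kruskal stress-1 via
SMACOF with isotonic regression), PERMANOVA (Anderson's pseudo-F), PCNM
spatial eigenvectors, partial RDA, variation partitioning with adjusted R²,
forward selection and a collinearity pre-filter. The estimators follow
scikit-learn conventions (`fit`, trailing-underscore attributes) and the
numerical results match vegan on shared fixtures.

**Inference**: hierarchical partitioning (Chevan–Sutherland averaging of R²
increments over all 2^k predictor subsets) with randomization Z-scores
(significant at Z > 1.65, upper one-sided 95%), partial correlations,
stream-blocked ANOVA with Tukey HSD and a stream variance component, and
Cohen's d.

## Worked example

```python
from streamimpact import GeneratorParams, RunConfig, run_pipeline

cfg = RunConfig(generator=GeneratorParams(seed=1), seed=1,
                nmds_starts=10, n_perm=999, hierpart_randomizations=1000)
bundle = run_pipeline(cfg)
print(bundle.hierpart_tables["delta_spear"].round(3))
```

```
                I      J  total   pct_I      Z  significant
predictor
DF_ww       0.449  0.269  0.719  52.394  4.258         True
RD1_invert  0.225  0.077  0.301  26.183  1.596        False
PC_habitat  0.076 -0.013  0.063   8.912 -0.155        False
PC1_ww      0.064  0.096  0.160   7.444 -0.334        False
RD3_invert  0.037 -0.030  0.008   4.319 -0.521        False
RD2_invert  0.006  0.002  0.008   0.748 -0.870        False
```

The SPEAR change across the 12 synthetic streams is dominated by the
wastewater dilution factor: DF_ww contributes 52% of the explained variance
independently (I = 0.449) and is the only significant predictor
(Z = 4.26 > 1.65) — the community's pesticide-sensitivity response scales
with how much effluent the stream receives. The same run shows the
complementary pattern for the Saprobic Index (driven by the
upstream-composition axes, not by dilution), the location effect in the
blocked ANOVA (saprobic mean rising from 1.96 upstream to 2.53 downstream,
F = 25.4, p < 0.001), and a significant downstream shift in overall
composition (PERMANOVA F = 4.35, R² = 0.21, p = 0.003).

The same pipeline runs from the shell:

```bash
streamimpact simulate --seed 1 --outdir data/
streamimpact run --seed 1 --outdir reports/
streamimpact anova --abundance data/abundance.csv --traits data/traits.csv \
    --sites data/sites.csv --descriptor saprobic
```

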