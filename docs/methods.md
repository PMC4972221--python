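# Methods

## Study design and estimands

The package analyses a space-for-time BACI design: `n` streams, each sampled
at two upstream reference reaches (U2, U1) and one reach downstream (D) of a
wastewater outfall. Two stream-level hypotheses structure the inference:

* **environmental context** — communities already shaped by catchment
  agriculture are dominated by tolerant taxa and should resist further
  organic enrichment; operationalized as a dependence of descriptor change
  on upstream community composition (the first three site-score axes,
  RD1–3_invert, of an upstream-only partial RDA);
* **magnitude of disturbance** — impact should scale with the relative
  effluent load; operationalized as a dependence on the dilution factor
  DF_ww = Q347 / Q_ww and on effluent chemistry (PC1_ww).

Responses are per-stream change statistics. For scalar descriptors,
Δ = (D − U1) − (U1 − U2): the second difference subtracts the natural
drift between the two reference reaches from the downstream response, so a
stream with a smooth longitudinal trend and no wastewater effect scores
zero. For composition, Total Community Change is the analogous correction in
two-axis NMDS space, TCC = ‖D − U1‖ − ‖U1 − U2‖; it may legitimately be
negative (downstream shift smaller than reference drift) and is passed
through unfloored.

## Descriptors

Rarefaction uses the exact hypergeometric (Hurlbert) expectation, not
resampling, standardized by default to the smallest location total. Fisher's
α is solved from S = α ln(1 + N/α) by bracketed root finding (residual
< 1e-10); it diverges when all individuals are singletons, which is reported
as an error rather than a sentinel value. Pielou's J uses natural-log
entropy so uniform communities score exactly 1.

The Saprobic Index weights each scored taxon by indicator weight × abundance
term. The abundance term is the raw count; an `abundance_transform` hook
accepts a class-transform (e.g. DIN-style abundance classes) where a
protocol requires one. Taxa lacking s or g are excluded from numerator and
denominator rather than imputed. The SPEAR index uses the canonical
log-damped weight w(x) = log₁₀(4x + 1); membership is an input flag, not
derived from a trait database. Because of the log damping SPEAR is only
asymptotically invariant to uniform count scaling — the bounded invariants
(SI within the present taxa's s-range, SPEAR and EPT percentages in
[0, 100], J in [0, 1]) are asserted in the property tests instead.

## Ordination engine

All community ordinations run on Hellinger-transformed shares, where
Euclidean distance is appropriate for count data. NMDS minimizes Kruskal
stress-1 by SMACOF: isotonic regression of configuration distances on the
observed dissimilarities (ties averaged), disparities rescaled to the
configuration-distance norm each iteration (guarding against collapse), then
a Guttman update. Start 0 is the classical-scaling (PCoA) configuration and
the remaining `n_starts − 1` are random; the best final stress wins, and the
returned configuration is centered, principal-axis rotated, with a
deterministic sign convention. Defaults: k = 2, 20 starts, tolerance 1e-7,
300 iterations — convergence is reported, never silent.

PERMANOVA uses Anderson's pseudo-F from the within/between decomposition of
squared distances with free label permutation (a `strata` option restricts
permutation within blocks but is off by default) and the positively biased
estimator p = (1 + #{F* ≥ F}) / (1 + n_perm), which cannot return p = 0.
The implementation was cross-checked against vegan's `adonis2` and
scikit-bio's `permanova` on shared fixtures.

PCNM truncates the inter-site distance matrix at the longest
minimum-spanning-tree edge (keeping the neighbour graph connected), replaces
larger distances by four times the threshold, and returns the
positive-eigenvalue principal coordinates, eigenvalue-ordered; axes agree
with vegan's `pcnm` to numerical precision.

Partial RDA residualizes both the response matrix and the predictors on the
conditioning block and takes the PCA of the fitted values of the remaining
regression. Reported R² is the constrained share of the post-conditioning
variance, adjusted by Ezekiel's 1 − (1 − R²)(n − 1)/(n − p − 1) with the
conditioning-reduced sample size. The overall test permutes rows of the
conditioned response. Variation partitioning computes adjusted R² of every
block union and applies inclusion–exclusion; negative shared fractions are
reported as computed (a truncated view is provided for display) so the
identities hold to 1e-10. Forward selection adds the candidate with the
largest adjusted-R² gain, permutation-tests its marginal contribution given
the current selection, and double-stops on significance or on exceeding a
full-model adjusted-R² bound. The collinearity pre-filter drops, in the
given priority order, any column with |r| ≥ 0.6 against a retained column —
the threshold is read as "remove at or above 0.6", the orientation most
consistent with its purpose.

In the full pipeline the upstream pRDA is conditioned on the first two
broad-scale PCNM axes by default (`pcnm_axes`). Forward-selecting the
conditioning axes is available (`pcnm_selection="forward"`), but with
strongly stream-clustered site geometry it retains many axes and those axes
absorb exactly the between-stream variance that the context predictors are
meant to carry; a small fixed count of broad-scale axes controls regional
spatial trend without that side effect.

## Inference

Hierarchical partitioning fits all 2^k OLS subsets (k ≤ 12) via
per-subset orthonormal bases, then averages each predictor's R² increment
within and across hierarchy levels (Chevan–Sutherland; equivalent to the
Shapley value over entry orderings, which is the independent oracle used in
the tests). Two identities are asserted on every call: Σ I = full-model R²
and I + J = univariate R², both to 1e-10. Significance comes from
randomization: the response vector is permuted (preserving the predictor
correlation structure, which is the relevant null), I recomputed, and
Z = (I_obs − mean)/sd compared to the upper one-sided 95% limit 1.65.

The location effect on each descriptor is tested by a two-way ANOVA with
stream as a blocking factor — under the balanced design this is numerically
identical to the mixed model with a random stream intercept. The stream
variance share is the intraclass estimate (MS_stream − MS_err)/(MS_stream +
(a − 1) MS_err), floored at zero. Tukey HSD contrasts use the studentized
range with the blocked error df. Cohen's d compares D against the pooled
upstream values with the n-weighted group-pooled SD; with per-stream pairing
unavailable this is the plain two-group form.

## Synthetic-data generator

The generator parameterizes effects on the descriptor scale and maps them to
expected taxon shares, so descriptor-level ground truth is exact by
construction. Per stream: agriculture (arable + pasture) and the wastewater
fraction f = Q_ww/Q347 are evenly spaced across their ranges (0.05–0.80 and
0.23–1.33) and independently shuffled, making context and disturbance
gradients near-orthogonal. Upstream targets are
SI_U = 1.75 + 0.45·agriculture + ε (ε ~ N(0, 0.10)) and
SPEAR_U = 55 − 45·arable + ε′ (ε′ ~ N(0, 4)); the scatter terms represent
between-stream variation not explained by land use and set the upstream
regression R² near the mid-0.5s/0.8 observed in such surveys. Downstream,
SPEAR drops by 8·f points and the oligochaete share moves from
p_U = 0.10 + 0.468(SI_U − 1.9) to p_D = p_U + 0.30 − 1.368(SI_U − 1.9):
a constant enrichment plus a deficit that grows with upstream saprobity, so
cleaner streams change more — the downstream SI increase is emergent from
the oligochaete boom, not separately imposed. The upstream slope 0.468
share/SI-unit matches the reported field value; the downstream contrast is
compressed to keep expected shares feasible.

Shares are realized by exponential tilting: starting from lognormal baseline
weights (sd 2.2, with a high-baseline block of tolerant chironomid/
gammarid-like taxa), a saprobic tilt exp(θ(sᵢ − 2)) and a SPEAR tilt
exp(φ·1[spearᵢ]) are root-solved so the composition hits the SI/SPEAR
targets at the fixed oligochaete share; taxa whose expected count falls
below a detection floor of 4 individuals (at the default total of 4000 per
pooled kick-net sample) are locally absent, with the tilt re-solved on the
reduced support until stable. This floor is what keeps observed richness in
the realistic 20–30 family band while preventing rare-taxon presence flips
from dominating the SPEAR sampling noise. Counts are negative-binomial
(gamma–Poisson) around the expected shares with dispersion 50;
`dispersion=inf` gives Poisson. Chemistry responds on the log scale to
agriculture (upstream) and to f times a stream-specific effluent strength
(downstream), the latter's spread (lognormal sd 0.9 plus per-variable
variation) keeping PC1_ww below the 0.6 collinearity threshold against
DF_ww. Habitat variables are stream-level baselines with small independent
reach noise — deliberately uninformative, mirroring the habitat index's role
as an error term.

What the generator does **not** emulate: taxonomic identity and phylogeny,
seasonal/temporal structure (single-season sampling), chemistry process
dynamics (columns are phenomenological covariates), spatially autocorrelated
land use, and real detection processes beyond the fixed floor. Passing
recovery tests therefore shows the pipeline recovers descriptor-scale
structure from overdispersed counts under this design — not that field data
of any particular catchment would behave as cleanly.

Determinism: every random draw flows from `seed` through tagged
`SeedSequence` streams (traits, sites, stream effects, counts), so identical
parameters give byte-identical tables, and `ground_truth` reproduces the
exact expectations used by the abundance sampler.

## Numerical choices and degenerate inputs

Tilt equations are solved by Brent's method on [−25, 25] with unreachable
targets clamped to the nearest achievable bound. PCA sign is fixed by
orienting PC1_ww positively with total nitrogen and PC_habitat positively
with the fine-sediment change. Eigenvector signs elsewhere follow a
largest-coordinate-positive rule. Degenerate cases are explicit: all-zero
communities, S = N for Fisher's α, identical points in PERMANOVA/PCNM, zero
pooled SD for Cohen's d, and zero randomization spread for Z-scores are
errors, NaNs with warnings, or flagged results — never silent values.

Problem sizes in the validation suite (12 streams × 60 taxa, 100 replicate
datasets for recovery, 199–1000 permutations for null calibration) are the
package's test design; the same code paths run unchanged at larger sizes.

## Known limitations

* The balanced-ANOVA equivalence to the mixed model breaks under missing
  reaches; incomplete streams are excluded listwise rather than fit by REML.
* Hierarchical partitioning is exponential in the predictor count (capped at
  12) and uses OLS R² only.
* PCNM axis choice for conditioning is a design knob, not an optimized
  quantity; the default (2 broad-scale axes) suits stream-clustered
  geometries.
* The SPEAR abundance weight makes the index depend weakly on total sample
  size; comparisons should use comparable sampling effort.
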