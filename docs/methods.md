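# Methods

This note documents the models and procedures implemented in `seasonet`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the package's numerical conventions and
limitations.

## Study design and data model

The package operates on an `ExpressionStudy`: a genes × samples matrix of
non-negative FPKM-scale abundances, sample metadata (site, season ∈
{winter, summer}, sex, body length in mm) and gene annotation (immune,
core-immune and hub flags plus an orthologue symbol). All statistical
models work on log₂(FPKM + pseudocount), pseudocount 1 by default. Body
length serves as an ontogeny surrogate in confounder-adjusted models; the
intended design samples a wide, overlapping range of sizes in both
seasons so that age and season are separable.

## Differential expression and the bias classifier

Genes with mean FPKM < 0.5 or more than 50 % undetectable entries
(expression exactly 0) are excluded first. Within each site, winter vs
summer is tested per gene by a Welch two-sample t-test on log₂
expression; the log₂ fold change is winter mean − summer mean (positive
= winter-biased). This is a deliberate matrix-level substitution for
read-level negative-binomial testing: it preserves exactly what the
downstream rule consumes — a per-site p value and a direction. Rows with
zero variance in both groups get p = 1 (equal means) or p = 0 by
convention. BH-adjusted q values are reported per site for context.

The classifier calls a gene winter-biased when log₂FC > 0 at both sites
with both p < α, summer-biased in the mirrored case, otherwise none.
With independent sites and two-sided tests at α the null probability of
a call is α² = 0.0025 as an upper bound; the same-direction requirement
tightens the analytic value to ≈ 2·(α/2)² = 0.00125. Simulation at
50,000 null genes reproduces the tighter value; the package's acceptance
bound is the conservative α².

Per-gene linear models (OLS on log₂ expression with season, length, sex,
site, optionally season×term interactions) report per-term marginal
(type II) F statistics, η² = SS_term/SS_total, coefficient signs, and
F/F_crit(0.05). Main-effect statistics always come from the
main-effects-only model; interaction terms are assessed by drop-one
comparisons against the full model. Type II sums of squares were chosen
because the covariates are correlated in field data and no SS convention
is otherwise implied. Ranking metrics for enrichment are either the
per-site log₂FC ("fold") or sign(coefficient)·η² for a named term
("adjusted"), with deterministic gene-identifier tie-breaks.

## Enrichment and set overlap

Preranked GSEA: walking the ranked list, set members increment the
running sum by |metric|^w (w = 1) normalised over the set, non-members
decrement by 1/(N−N_set); ES is the maximum deviation. The null is
gene-tag permutation — random same-size sets over the same ranked list —
which is the appropriate choice for a preranked analysis at n = 36
(phenotype permutation is out of scope). NES normalises by the mean
same-sign permutation ES; nominal p is the same-sign permutation tail
with add-one smoothing; FDR is Benjamini–Hochberg across reported sets.
Minimum/maximum set sizes default to 15/500 following the cited tool's
conventions (the pipeline lowers min size to 5 because the planted
synthetic sets are small); permutation count defaults to 1000
(paper-scale) or 200 (scaled-down pipeline default).

Per-site results are combined with Fisher's method. Combining
FDR-adjusted p values mirrors the upstream analysis convention but is
statistically unorthodox (adjusted p values are not uniform under the
null), so the combination of nominal p values is always reported
alongside as `p_combined_nominal`.

Set overlaps report the one-sided hypergeometric enrichment probability
P(X ≥ observed), an odds ratio from the 2×2 membership table (Haldane
0.5 correction when a cell is zero) and the Jaccard index.

## Mutual-information networks

**Estimator.** MI is estimated on rank-transformed data (average ranks,
doubled to stay integral under ties) by recursive adaptive partitioning:
each cell splits at the marginal medians of its own points into four
quadrants, and the split is accepted only when a chi-square statistic on
the quadrant counts exceeds the critical value at `alpha_split` (default
0.05). Because median splits fix both cell margins, the quadrant counts
carry a single free degree of freedom, so the df = 1 critical value is
used. At the leaves the plug-in contribution is
p·ln(p/(p_row·p_col)), with marginal cell masses counted from the actual
rank distribution (this makes tied/discrete data behave exactly like the
discrete distribution they are: a perfect two-state dependence scores
ln 2). Cells with fewer than 8 points are not split, and recursion depth
is capped at 4 (at most a 16×16 marginal resolution). The cap bounds the
variance of the estimate and the value reported on deterministic
dependence (≈ ln 16); at co-expression sample sizes (tens of samples)
it never binds because cell counts stop the splits first. The estimator
is exactly symmetric in its arguments and returns 0 for constant input.

**Threshold calibration.** Null MI values are generated by drawing gene
pairs and permuting both genes' samples independently — a fresh pair of
permutations per draw, so the number of null draws is not limited by the
number of distinct gene pairs (at least 1000 draws are required; default
2000–3000). An exponential tail P(MI > t) = exp(−(a·t + b)) is fitted by
least squares to the positive upper decile and inverted at the target
edge probability; with marker correction the target is Bonferroni-divided
by the number of tested pairs (or genes, via `correct_by="genes"` — the
upstream description is ambiguous between the two). Thresholds are
monotone in the target probability, and held-out null exceedance rates
match the target within fit error in the range the fit covers; beyond it
the exponential extrapolation is conservative (the true tail decays
faster).

**Network construction.** MI is computed for hub-incident pairs only
(hub mode); edges above threshold survive to DPI: in every fully
connected triple, edge (i,j) is marked when
MI(i,j) < min(MI(i,k), MI(j,k))·(1 − tolerance), marks applied after the
full scan. Tolerance defaults to 0 (strict). The bootstrap consensus
resamples samples with replacement (resamples missing a season are
redrawn), rebuilds the network per resample, and keeps edges whose
support count has a one-sided binomial tail probability ≤ `edge_p_cut`
(default 10⁻⁶, the reported-edge control) under a single pooled
edge-occurrence rate — the simplest defensible consensus null.

**Per-resample threshold defaults.** The four standard network designs
(1: seasonally-biased core genes, all hubs; 2: all biased genes, core
hubs; 3: all immune genes, core hubs; 4: core + organismal genes, all
hubs) default to an uncorrected candidate p-cut of 10⁻⁴ per resample.
At n ≈ 36, a marker-corrected 10⁻⁵ cut maps through the tail fit to an
MI threshold (≈ 0.8–0.9 nats) reachable only by near-deterministic
dependence (|r| ≳ 0.97), which empties the candidate set for any
realistic co-expression strength; since the consensus cut — not the
per-resample cut — controls the error rate of reported edges, the
per-resample threshold is treated as a candidate generator. Stricter
marker-corrected cuts remain available per network through the
configuration.

**Topology and modules.** Betweenness (Brandes, normalised by
(n−1)(n−2)/2) and per-component eccentricity are computed on the
unweighted consensus graph; a hub's module is itself plus its consensus
neighbours; module-overlap meta-networks connect modules with Jaccard
similarity ≥ 0.1 and test each module for enrichment in winter-biased,
summer-biased and user-supplied organismal sets.

**Interface scores.** For each core gene: the number of consensus edges
to opposite-bias core genes (cross) and to same-bias core genes
(within). Rows are ordered by (cross desc, within desc, gene id) — this
ordering *is* the interface score. The key flag (cross ≥ 1 and within ≥
the median within-degree of the gene's own bias set) operationalises a
judgement the source analysis made by visual inspection; both knobs are
exposed because no principled default exists.

## Ordination and mediation

PCO is classical scaling (via scikit-bio) of Euclidean distances on log₂
expression; for a Euclidean metric this reproduces PCA of the samples.
Axis scores get two-sample t-tests for season, site and sex and a
Pearson correlation with length — the simplest tests consistent with the
reported per-axis probabilities; a permutation alternative was
considered unnecessary at these sample sizes. PC1 scores of a gene set
are the first eigenvector of the gene-gene correlation matrix applied to
the standardised data, sign-fixed to correlate positively with the set's
mean expression so results are platform- and seed-stable.

The mediation model standardises W (winter-set PC1, excluding interface
genes), S (summer-set PC1, likewise) and G (one interface gene's log₂
expression), then fits S ~ W + G, G ~ W and S ~ W by OLS. The Sobel
statistic is z = ab/√(b²SE_a² + a²SE_b²). The negation flag is raised
when the univariate W→S slope is significant at α but the direct slope
is not once G enters. Standardised estimation was chosen (the
covariance-scale alternative is unstated upstream) and is labelled as
such. Fits at n < 50 carry a `small_sample` caveat flag; the study-scale
n = 36 sits below common mediation power guidelines, which is why
calibration tests run at n = 100.

## qPCR computations

Endogenous-control candidates must show no seasonal bias at either site,
an overall CV < 12 % (computed on the linear FPKM scale — the scale is
configurable since the upstream convention is unstated), non-zero
expression in every sample, and mean FPKM > 5. Stability decomposes log
expression per gene into an overall level plus group-specific
deviations; stability = |intergroup deviation| + intragroup SE, so a
constant gene scores exactly 0, and the optimal pair minimises the
pair-combined value |mean deviation| + half the root-sum-square of the
two SEs over all pairs — which automatically prefers genes whose
deviations cancel.

Relative expression: replicate wells are averaged (mean Ct) first; ΔCt =
Ct_target − mean(Ct_controls) (the arithmetic mean of control Cts equals
the geometric mean of control quantities); ΔΔCt indexes to the
calibrator sample; RE = 2^−ΔΔCt assumes exactly one doubling per cycle
(primers validated to 100 ± 10 % efficiency; efficiency-corrected modes
are out of scope). `dct_cal` mode returns the per-gene
calibrator-referenced difference Ct_calibrator − Ct_sample without
control normalisation, for between-tissue comparisons where invariant
controls are unrealistic. RE is invariant to plate-wide Ct shifts.
Whether the two controls should be averaged on the Ct scale or each used
separately is unstated upstream; mean-Ct is implemented and documented.

## Synthetic-data generator

The generator emulates the field design: 2 sites × 2 seasons ×
`n_per_cell` (default 9) fish, lengths uniform on [20, 60] mm (the
deliberately wide, overlapping size range), alternating sexes, and
2000 genes by default with 5 % winter- and 3 % summer-biased. log₂
expression is baseline + seasonal shift (β, default 2.0 log₂ units,
typical of strongly biased core genes) + per-gene site and sex offsets +
a per-gene length slope + latent-factor terms + Gaussian noise (default
0.4; per-gene dispersion is a free calibration knob, as no empirical
dispersion is available for the reference design). Matrices are
exponentiated, so abundances are strictly positive; an optional dropout
probability plants exact zeros to exercise the undetectable filter.

Co-expression comes from latent per-sample winter and summer factors:
winter-biased genes load on the winter factor, summer-biased on the
summer factor, with loading set so the gene-factor correlation is
`factor_loading` (default 0.9, consistent with core genes that form
dense MI modules at this sample size). Interface genes carry the full
loading on their own season's factor and its negative on the opposite
factor: the negative sign makes the residual covariance across the
interface reinforce the anti-phase seasonal-mean covariance rather than
cancel it — with a positive cross-loading the seasonal shift exactly
offsets the planted coupling and the "interface" genes would be *less*
connected across seasons than ordinary biased genes. Three organismal
modules (growth/metabolism/stress analogues) get independent factors,
and 50 housekeeping-like stable genes (low noise, no covariate effects,
floored baseline) exist so the reference-gene screen has true positives.

What the generator does **not** emulate: read-level sampling noise and
count overdispersion, dropout-expression dependence, tissue composition
effects, gene-length biases, batch/lane effects, and non-Gaussian
expression tails. Passing planted-truth tests therefore demonstrates the
*procedures* recover the structure they target under the stated design,
not that real RNAseq data meet these assumptions.

## Numerical conventions and limitations

- Every stochastic routine takes an explicit seed; the pipeline derives
  stage seeds from one master seed and records a config hash, so a run
  is reproducible bit-for-bit from its manifest.
- Scaled-down defaults (bootstrap 200, permutations 200) keep a full
  pipeline run under a minute at default sizes; `paper_scale=True`
  (or `--paper-scale`) restores 2000/1000.
- Ties everywhere break deterministically by gene identifier.
- The classifier requires exactly two sites; multi-season (> 2 level)
  designs are out of scope.
- MI estimation at n ≈ 36 is information-limited: correlations below
  ≈ 0.5 are rarely distinguishable from the permutation null, so
  consensus networks should be read as high-confidence skeletons, not
  complete dependence maps.
- The pooled-rate binomial consensus ignores per-edge heterogeneity in
  background occurrence; edges just above the consensus cut deserve
  caution.
- Mediation at the study's native n = 36 is reported with the
  small-sample flag; negation-flag calibration holds at n = 100.
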