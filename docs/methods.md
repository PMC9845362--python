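# Methods

This note documents the statistical model behind `spnblur`, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
generator does and does not emulate.

## Generative model (`spnblur.syndata`)

Counts are negative binomial (gamma-Poisson), the standard overdispersed
law for UMI data. For gene *g* in a cell of subtype *t*, sample *s*,
phenotype *ph*, the log2 relative expression is

    log2 θ = log2 b_g + endo(g, t) + hd(g, t)·[ph = HD] + ε(g, s)

with `b_g` lognormal (`baseline_log_mean=1.0`, `baseline_log_sd=1.0`,
natural-log scale), `ε(g, s) ~ N(0, sample_effect_sd=0.05)` a per-(gene,
sample) replicate effect, and cell counts drawn NB with mean
`lib_size · θ/Σθ` and variance `μ + dispersion·μ²` (`dispersion=0.3`, a
typical gene-level value for single-nucleus data). Library sizes are
lognormal (median 5,000 UMIs). A configurable fraction of genes (1%) is
flagged mitochondrial; each cell's expected mito share is Beta(2, 98)
(mean 2%) with a 2% admixture of Beta(2, 8) outlier cells, so the QC
filter has realistic targets on both sides of the 5% mouse threshold.

**Axis structure.** 10% of genes are striosome-matrix (S-M) markers and
10% are D1-D2 markers; each carries an endogenous log2 contrast *c* with
|c| ~ |N(1.0, 0.4)| redrawn below a floor of 0.25, sign assigning the
side. The contrast is split symmetrically: +c/2 on the marker's side,
−c/2 on the other. O-D2 receives S-M effects with the striosome sign
(it sits transcriptomically closer to the striosomal identity) and D2
pathway effects. A further 5% of genes form an idiosyncratic O-D2
identity; without one, the expected O-D2 and S-D2 profiles would
coincide and disease effects could only push them apart, which would
contradict the all-pairs loss of distinction the analysis is designed to
detect.

**Disease effects.** Identity blurring cancels a fraction `blur` of a
marker's endogenous contrast, half on each side, scaled by a per-subtype
severity weight:

    shift(t) = ∓ (blur/2) · c · w_t

(negative on the marker's own side). Defaults: `blur_sm=0.5`,
`blur_d1d2=0.1`, weights O-D2 2.0 > S-D2 1.5 > M-D2 1.0 = S-D1 1.0 >
M-D1 0.8. The magnitudes are free parameters of the simulation — no
measured values exist for them — chosen once so that recovery tests are
well powered while staying in the plausible sub-unit log2FC range; the
asymmetry (0.5 vs 0.1) encodes the qualitative finding the pipeline must
recover: compartmental identity blurs, pathway identity largely holds.
Keeping `(blur/2)·(w_a + w_b) < 1` for every subtype pair guarantees the
blurring shrinks contrasts without overshooting into identity reversal.
On top of blurring, a cell-type-nonspecific shift `N(0, 0.2)` hits 30% of
genes uniformly across subtypes, providing the unidirectional
(model-idiosyncratic) component of dysregulation; it is deliberately not
scaled by severity weights, so only the bidirectional class carries the
cell-type gradient — the dissociation the cross-model concordance
statistic is meant to expose. Depletion removes HD cells by subsampling
(`round(n·retention)` per sample), never by altering expression,
matching depletion without identity switching.

Because the blurring contrast is what D1-D2 pair distances respond to, the
D1-D2 axis receives both a (small) symmetric contrast cancellation
(`blur_d1d2`) and the shared shift; a purely shared shift would cancel out
of pairwise distances entirely and leave the D1-D2 loss at zero.

**Sizes.** Defaults are 2,000 genes, 4 samples per phenotype, and 150
cells per sample per subtype (6,000 cells total) — a deliberate desk-scale
reduction of a real study (tens of thousands of genes and nuclei) that
keeps per-group pseudobulk counts deep enough for calibrated t-tests.
Ground truth records every injected effect (marker roles, per-subtype HD
log2FC, implied directionality class, depletion), and a fixed seed yields
bit-identical output.

## QC (`spnblur.qc`)

Cells are removed when mito fraction is strictly greater than the species
ceiling (5% mouse, 20% human) or unique genes fall below 500 (boundary
retained: exactly 500 passes, exactly 5% passes). Cluster-relative RNA
bounds are not specified quantitatively anywhere we could follow, so a
MAD-based per-subtype rule (k=5 on log total counts) is available behind a
flag and off by default. Removal reasons are tallied per sample with the
mito reason taking precedence for cells failing both.

## Pseudobulk DGE (`spnblur.dge`)

Aggregation sums raw counts per (sample, subtype); groups with zero cells
are absent, never zero-filled. Normalization is log2(CPM + 1) (prior count
1); the prior bounds the log at zero counts and compresses fold changes of
very low-expressed genes toward zero, a conservative choice. Per-gene
inference is least squares of log2CPM on the design, two-sided t on
residual df, BH within each contrast (per-cell-type calls, not global).
The "single-cell-level variance" weighting mode uses per-(gene, group)
weights `n_cells/(within-group count variance + 0.5)`; the floor prevents
division by near-zero variance for silent genes. The exact construction
used upstream of the published analyses is not documented; with equal
weights the mode reduces exactly to OLS, which is the default and the path
all oracle comparisons use. Zero-residual-variance genes report p = 1 and
t = 0 rather than NaN. Optional empirical-Bayes moderation was considered
and deliberately left out of the default path to keep the estimator
exactly oracle-checkable; the bootstrap (samples with replacement, then
equal cell counts per sample with replacement) is the robustness mechanism
instead.

## Markers (`spnblur.markers`)

Marker identification is a pure function of two DGE tables and thresholds.
Genes passing both defining contrasts with opposite signs are excluded
from both sides and reported separately rather than arbitrarily assigned.
Conservation requires the same side in every dataset (presence-only Venn
counts are also reported); quadrant concordance uses the mean of the two
defining log2FCs as the gene's compartmental preference. Ortholog maps are
explicit two-column inputs and must be one-to-one on the tested genes —
no symbol-case heuristics.

## Identity distance (`spnblur.identity`)

Profiles are per-cell library-normalized expression averaged over the
group and renormalized to the simplex (raw-mean and log1p-mean variants
are flag-gated; the choice matters little on simulated data but is
reported with results). JS distance uses base-2 logs so the metric lies in
[0, 1]; the base is configurable. All detected genes above a minimum
detection fraction (default 0: all genes) enter the distance. The
loss-vs-endogenous-distance regression uses pointwise confidence bands for
the mean response (not prediction intervals) at the 99% level, matching
the band a regression CI describes; pairs are unordered, self-pairs
excluded. In the per-subtype mean-loss summary, targets exclude self and,
by default, O-D2; in a five-subtype run this yields n=3 pairs per
canonical subtype and n=4 for O-D2 itself. (Published figure legends
quote n=4 and n=3 respectively, which is not consistent with the stated
exclusion rule in a five-type universe; the implementation follows the
rule, and the exclusion set is a parameter.)

## Directionality and severity (`spnblur.dysreg`)

The unidirectional gate requires |log2FC| > 0.1 and p < 0.001 in at least
one canonical subtype; the bidirectional gate requires p < 0.001 only —
the two gates follow the two published phrasings, and a harmonized mode
applies the strict gate to both. The gate p is the raw p by default
(figure-legend phrasing), switchable to FDR-adjusted. Zero log2FC sides
with the majority sign by default (`zero_policy='strict'` makes it break
unidirectionality). O-D2 enters severity summaries but not the four-type
sign pattern. ANOVA is classical one-way (genes as observations, subtypes
as groups; all-identical data returns F=0, p=1 by convention), and
pairwise comparisons use Tukey-Kramer via the studentized range with
classical equal-variance pooling. Cross-model concordance is the Kendall
tau of per-subtype mean |log2FC| vectors plus per-gene sign agreement on
genes classified in both models.

## Pipeline (`spnblur.pipeline`, `spnblur.cli`)

One global seed is fanned out to stage-local generators keyed by stable
stage labels (CRC32 of the label into a `SeedSequence`), so inserting a
stage cannot perturb earlier stages' draws. Floats are serialized with 10
significant digits; a rerun with the same config is byte-identical.

## What the simulation does not capture

No doublets, no ambient RNA, no manifold/embedding structure (the pipeline
consumes labels, not clusters), no batch effects beyond the per-sample
offset, independent genes (no co-expression modules), and a single
severity gradient shared by all blurred genes. Passing recovery tests
therefore demonstrates correctness of the estimators under the assumed
structure, not robustness to annotation error or to the correlated noise
of real tissue.
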