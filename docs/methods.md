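# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, the numerical decisions that make runs
reproducible, and what the synthetic-data validation does and does not show
about real data.

## The analysis model

The pipeline assumes its input is an already aligned, binned feature matrix:
rows are individual organisms (samples), columns are retention-time ×
mass-fragment bins, entries are non-negative abundances. Peak picking,
retention-time alignment and noise reduction are upstream concerns of the
acquisition software; this package starts where that export ends.

**Preprocessing.** Two sources of nuisance variation are removed before any
classification: global intensity differences between runs (handled by
constant-sum normalization, dividing each sample row by its total so
profiles are compositional) and scale differences between bins (handled by
autoscaling each bin column to mean 0, sample variance 1; zero-variance
columns carry no contrast and are dropped with a log message). The order is
normalize-then-scale, and all treatment groups are pooled for both steps and
for outlier analysis. Outliers are defined on the score plot of a PCA of
the scaled table: a sample is flagged when its Hotelling statistic on the
first A = 2 component scores, T²ᵢ = Σₐ t²ᵢₐ/λₐ, exceeds
A(n−1)/(n−A) · F₁₋α(A, n−A), the standard confidence-ellipse cutoff at
confidence 1−α = 0.95. "Distance outside the confidence region of a score
plot" is an informal criterion in much of the applied literature; Hotelling
T² against the F quantile is the standard formalization and is what is
implemented. Removal is a single pass (no iteration), after which scaling
is recomputed on the retained samples. Note that ~5 % of perfectly clean
samples fall outside a 95 % ellipse by construction; the procedure bounds
the false-flag rate rather than guaranteeing flagged samples are corrupt.

**Classification and ranking.** The classification task is binary — control
vs. one exposure level — with a radial-kernel SVM,
K(x, z) = exp(−γ‖x−z‖²). Cost C and width γ are grid-searched over powers
of ten spanning [10⁻¹¹, 10¹¹] (23 points per axis by default; a
`decade_step` knob coarsens the grid for large batch runs). All grid points
are scored by repeated stratified 3-fold cross-validation **on identical
fold assignments**, so the comparison across the grid is paired; ties break
toward smaller C, then smaller γ, making tuning deterministic. Tuning
happens once on the full table before elimination (re-tuning inside each
RFE round is available behind `retune_each_round` but is off by default:
with ~500+ refit rounds it multiplies cost several-hundred-fold for little
observed ranking benefit on synthetic data). Whether to nest tuning inside
each CV repeat is a genuinely open design point; the single global tune was
chosen for tractability and is recorded in the config so a nested variant
can be compared. "Bootstrapping with repeated three-fold cross-validation"
is implemented as repeated randomized stratified 3-fold CV — each repeat
reshuffles fold membership and reports the pooled held-out accuracy; 250
repeats by default.

RFE needs a per-feature importance for a *kernel* machine, where no primal
weight vector exists. The implemented criterion is the change in the fitted
dual objective when feature k is removed with the dual coefficients held
fixed. Because the squared euclidean distance is additive over features,
the kernel without feature k is K ∘ exp(γ d⁽ᵏ⁾) with d⁽ᵏ⁾ᵢⱼ = (xᵢₖ−xⱼₖ)²,
so the criterion reduces to

    J(k) = ½ | Σᵢⱼ Mᵢⱼ (1 − exp(γ d⁽ᵏ⁾ᵢⱼ)) |,   Mᵢⱼ = aᵢaⱼKᵢⱼ,

with a the (rescaled) signed dual coefficients on the support vectors.
Evaluating `1 − exp` via `expm1` matters: when tuning lands on the small-γ
corner of the grid (K ≈ all-ones, C large), the naive difference of two
near-equal quadratic forms cancels catastrophically and the ranking
degrades to noise; the `expm1` form is algebraically identical and stable
(the dual-coefficient rescaling only multiplies J(k) by a positive
constant, so the ranking is unchanged). The per-feature difference matrices
are cached once per run (float32; the cache is refused above ~1.5 GB, at
which point the `linear-weight` fallback criterion — |w|² of a linear SVM
refit per round — applies).

The elimination schedule removes 10 % of surviving bins per round down to
500 survivors, then one bin per round. Eliminating one-at-a-time from ~10⁴
bins would mean ~10⁴ SVM refits for at best marginal changes in the bulk
ranking; the chunked head matters little because only the final few hundred
ranks are consumed downstream (top-200 annotation). Ties in the criterion
break by bin position (stable sort), so rankings are exactly reproducible.
The accuracy-vs-k curve reuses one set of fold assignments across all k
(points are paired) and shares its fold-seed stream with
`repeated_cv_accuracy`, so the k = n_bins point equals the plain full-
profile repeated-CV accuracy exactly.

**Annotation.** Bin spectra are matched to library entries by a documented
open formula rather than a vendor score: peaks are paired greedily by
nearest m/z within 0.5 (unit-resolution ToF binning), each peak weighted
w = (m/z)² · I^0.5, and the similarity value is ⌊999 · cosine⌋ of the
weighted vectors (unpaired peaks contribute to the norms only). The pairing
key is symmetric, so SV(a,b) = SV(b,a), and the score is invariant to
rescaling either spectrum. Candidates must agree in retention time within
0.05 s — the tolerance reading of an ambiguous "(>0.05 s)" convention in
the applied literature; the strict acceptance rule is SV > 700. When
several bins map to one compound, all annotations are kept and the
compound-level record carries the maximum SV (the many-peaks-per-metabolite
situation is normal: fragments of one metabolite occupy several bins).

**Biomarker subset and transfer.** Compound sets from the two species are
intersected after canonical-name collapsing (case, punctuation, and a small
synonym map — library spellings of e.g. "myo-inositol" vary). The subset's
discriminative value at each concentration is measured by restricting the
scaled table to biomarker bins, subsetting samples to {control, that
concentration}, re-tuning C and γ for that contrast (class geometry changes
with dose), and running repeated stratified 3-fold CV. Per-species signs
are means on the *normalized* table (exposed minus control), with exact
ties reported as "0".

**Enrichment.** For a background universe of N compounds, a mapped query of
q, and a pathway of K with h hits, Raw p = P(X ≥ h), X ~ Hypergeom(N, K, q)
— one-tailed over-representation only — and Expected = Kq/N, so
Expected/Total is the constant q/N across every row of one analysis (a
useful end-to-end invariant). BH and Holm adjustments are computed across
all pathways in the library; BH values are probabilities by construction.
The background defaults to the library's full compound universe and is
configurable. Impact weights each pathway compound by betweenness
centrality normalized to sum to one across the pathway (uniform 1/n when
all centralities are zero, as in complete graphs) and sums the hit weights
— hits at topological bottlenecks count more than peripheral ones. The
report keeps pathways with hits ≥ 3 (inclusive).

## The synthetic generator

The generator emulates the *statistical shape* of a binned GC-MS
dose-response experiment, not its chemistry. Defaults mirror the emulated
design: exposure levels {0, 10, 50, 250, 1250} µg/L; 5 replicate tubes × 4
individuals per level (20 samples per group, 100 per species); ~10⁴ bins
(presets 11,766 and 9,723 for the two species-level alignments). On the
log2 scale each abundance is

    log2 A = base_bin + direction · effect · s(dose) + tube_offset + ε,

with base_bin ~ N(13, 2) (raw abundances ~10⁴, right-skewed after
exponentiation — log-normality matches the positivity and skew of
mass-spectral abundances), ε ~ N(0, noise_sigma²) with noise_sigma = 0.5,
and a shared per-tube offset (sd 0.1) modelling the co-housing of four
individuals per exposure tube. Whether co-housed individuals are truly
independent replicates is left open; tube_sigma exposes the clustering
strength instead of resolving it. Planted bins (default 20) shift by up to
effect_size = 2 log2 units at the top dose, scaled by
s(c) = log10(c+1)/log10(c_max+1) (linear-in-log-dose; a step-at-threshold
model is available — the effect shape below the top dose is a free choice).
Bin ids follow the `RT<seconds>_MZ<m/z>` export convention so synthetic
tables are drop-in compatible with real ones.

Companion generators produce an MSP spectral library (unit-m/z peaks, base
peak 999), per-bin measured spectra for the planted bins (their assigned
compound's library spectrum with 5 % intensity jitter and ±0.01 s RT
jitter, so a correct matcher recovers the assignment), and random pathway
sets over the same compound namespace, each with a connected random graph
(spanning tree plus shortcuts).

What passing recovery tests therefore shows: the ranking, annotation,
intersection and enrichment machinery correctly recovers signal of known
location and size under log-normal noise with mild tube clustering. What it
does not show: robustness to retention-time misalignment, co-eluting peaks,
batch drift, heteroscedastic or non-log-normal noise, correlated fragment
bins from shared metabolites, or real spectral library ambiguity — none of
which the generator emulates. Real-data accuracies (and the counts of
identified peaks) are properties of the original measurements and are not
reproducible from synthetic data; only the qualitative pattern — rank
selection raising accuracy above the full-profile baseline — carries over.

## Numerical and reproducibility choices

- PCA uses a full SVD with a fixed sign convention (the largest-|loading|
  entry of each component is made positive), so reports do not flip signs
  across runs or sample orders.
- All randomness flows from integer seeds through `numpy` generators;
  fold-assignment seed streams are tagged per purpose (tuning / repeated CV
  / curve) so stages are independently reproducible.
- Criterion, tuning and intersection tie-breaks are all deterministic
  (stable sorts by position or name).
- Degenerate inputs raise typed errors naming the offender: zero-sum sample
  rows, single-class labels, classes smaller than the fold count, unmapped
  biomarkers, out-of-range p-values, infeasible pathway size ranges.
- Match-factor floor includes a 1e-9 guard so exactly proportional spectra
  score 999 despite float rounding.

## Problem sizes used in the shipped checks

The test suite and acceptance script run the generator at reduced widths
chosen to keep the full validation cycle at desk scale on one CPU:
planted-bin recovery at 2,000 bins / 20 planted / 20 vs 20 samples over 20
seeded replicates; the rank-selection-vs-full-profile comparison at 1,000
bins / 10 planted over 10 paired seeds; the end-to-end two-species pipeline
at ~400 bins per species with 10 shared planted compounds. These preserve
the bins ≫ samples regime and the planted-to-noise ratios of the full-width
design (10⁴ bins), which the package handles identically (the RFE cache at
11,766 bins × 40 samples is ~75 MB).

## Known limitations

- The dual-objective RFE criterion holds the dual coefficients fixed when
  scoring a removal; like all RFE it is greedy and can mis-rank strongly
  correlated informative bins (one of a correlated pair may be eliminated
  early).
- Constant-sum normalization makes profiles compositional; with few bins
  and large planted effects, closure leaks signal into unplanted bins. At
  realistic widths (10³–10⁴ bins) the leakage is negligible, but recovery
  oracles on very narrow tables should plant signal directly rather than
  normalize (the unit tests do).
- Tuning once globally (not nested per CV repeat) means the reported CV
  accuracy of the *tuned* model is mildly optimistic; rankings and paired
  comparisons are unaffected.
- The annotation step assumes one spectrum per bin; deconvolution of
  co-eluting spectra is out of scope.
- The enrichment Impact score uses undirected betweenness only; directed or
  flux-weighted pathway topologies are not modelled.
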