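# Methods

## Scope and data model

The package analyses radiometric breast thermograms: rectangular grids
of skin-surface temperatures in °C (rows × columns, row 0 at top,
0-based `(row, col)` indexing), paired with a binary mask that isolates
the breast region from warmer neighbouring structures (neck, armpits).
Every analysis is per breast: the masked region is split at the
vertical midline of the mask's bounding box, columns strictly left of
the division column forming the left sample (half-open convention; the
division pixel column goes right). The bounding-box midpoint is used
rather than the image midline because subjects are not always centred
in frame; an `image-center` mode is available. A mask lying entirely on
one side of the image midline is rejected as unilateral (e.g. post-
mastectomy) rather than silently split in half.

Temperature grids are stored as plain text (one image row per line,
space- or semicolon-separated, `.` decimal; files using decimal commas
and no points are normalised with a warning). The writer prints 4
decimals, below the ~0.04 °C sensitivity of clinical IR cameras, and
read∘write is the identity at printed precision. Masks are bilevel
PNG or CSV; any value > 0 is in-mask, so {0,1} and {0,255} encodings
behave identically.

## Descriptors

Nine statistics are computed directly on the in-mask temperatures, with
population (1/n) moments: mean μ, standard deviation σ, variance σ²,
skewness γ = (μ − median)/σ (a Pearson-type coefficient, not the
standardised third moment), non-excess kurtosis k = E(x−μ)⁴/σ⁴, min,
max, CV = σ/μ·100 (%), and energy E = Σ T (°C·pixels — the temperature
sum, not the GLCM angular second moment; the latter is available as an
optional 14th feature, off by default). A constant sample has undefined
γ and k; they are reported as NaN with an `undefined-constant` warning
while every other field is still computed. A sample-moment (n−1) mode
exists behind a flag.

Texture features come from a gray-level co-occurrence matrix over
quantized levels. Quantization is affine: level =
⌊(clip(T, low, high) − low)/(high − low)·G⌋ with T = high mapping to
G − 1 and G = 256 by default. The temperature range mapped to the gray
axis is a genuine design choice with no canonical answer; the default
is each sample's own (min, max) — contrast-stretched, scale-free
texture — and a fixed range such as (20, 36) °C can be passed when
texture must be comparable across samples in absolute temperature. The
entropy histogram reuses the same quantized levels, so one quantization
decision governs both.

Co-occurrences are accumulated for each in-mask pixel and its
distance-1 neighbours in the four directions {0°, 45°, 90°, 135°},
symmetrically (both offset signs), pooled over directions and
normalised. Pairs touching an out-of-mask pixel are discarded exactly,
implemented by recoding out-of-mask pixels to a sentinel level. From
P(i,j): homogeneity Σ P/(1+(i−j)²) ∈ (0,1], contrast Σ (i−j)²P ≥ 0, and
correlation Σ (i−μₓ)(j−μᵧ)P/(σₓσᵧ) ∈ [−1,1] (reported as 1 with a
warning for a constant image, where it is formally 0/0).
`extract_features` evaluates these sums directly over the co-occurring
pair list (the probability is uniform over counted pairs, so each sum
is a mean over pairs) without materialising the G×G matrix; the matrix
route (`compute_glcm` + `glcm_features`) produces identical values and
the test suite asserts agreement between both routes and a brute-force
pair-enumeration oracle.

## Selection

Each feature is tested for a class-mean difference with the Welch
statistic using sample (n−1) variances and Welch–Satterthwaite degrees
of freedom, two-sided p-values, and a raw p < 0.05 threshold with no
multiplicity correction by default (Holm and Benjamini–Hochberg are
optional). Sample variances are used although the descriptor moments
are population-form: the Welch statistic with n−1 variances is the
standard referenced-table form; a population-variance mode exists for
exact-formula replication. Degenerate zero-variance groups yield t=0,
p=1 (equal means) or a signed infinite t with p=0 and a warning.

## Classification and validation

Four families: linear SVM and degree-2 polynomial (inhomogeneous,
coef0 = 1) SVM at unit box constraint; logistic regression by maximum
likelihood with negligible regularisation; and a "coarse" CART tree
capped at 4 internal splits (Gini), the defining constraint of the
coarse preset in common analysis environments. SVMs and LR standardise
features to zero mean / unit variance within each training fold; the
tree trains on raw features (scale-invariant). Constant training
columns are dropped with a warning. The positive class is `A`, so
recall tracks cancer sensitivity.

Stratified k-fold (k = 5 default) keeps per-fold class counts within
one sample of proportionality; at the study composition (71/194,
k = 5) every fold holds 53 samples with 14–15 positives. Fold
assignment is deterministic given the seed (default 20251013). The
default grouping keeps both breasts of a subject in one fold
(leakage-free); a per-sample mode mirrors treating each breast as an
independent case. Reported dispersion is the across-fold sample
standard deviation, stated explicitly since a bare "±" is ambiguous.

Metrics follow the confusion-count forms accuracy = (TP+TN)/total,
precision = TP/(FP+TP), recall = TP/(FN+TP), specificity = TN/(TN+FP),
F1 = TP/(TP+(FP+FN)/2) (algebraically the harmonic mean 2PR/(P+R));
undefined ratios are reported as 0 and flagged.

The bootstrap resamples pooled out-of-fold (true, predicted) pairs with
replacement, B = 2000, and reports the empirical mean and (2.5, 97.5)
percentiles. Models are not refitted per replicate: the interval
quantifies metric variability given the observed predictions, which is
cheap and matches the intended use; replicates on which a metric is
undefined are skipped and counted, with a warning above 10%.

McNemar comparisons use the exact doubled-binomial p on the discordant
counts, p = min(1, 2·P(X ≤ min(b,c))), X ~ Binomial(b+c, ½), valid at
the small discordant counts a few-hundred-sample cohort produces. The
exact p is conservative because the discordant count is discrete — at
n = 265 with exchangeable classifiers disagreeing on ~25% of samples it
has an atom of ≈ 0.12 at p = 1 — so its null distribution is
super-uniform, not uniform; the mid-p variant (`mode="midp"`) is
provided when a closer-to-uniform null is wanted, and the suite checks
validity for the exact mode and approximate uniformity for mid-p. The
per-fold difference b − c is additionally summarised by its across-fold
mean and percentile interval as a descriptive companion; the exact p is
the inferential output.

## Synthetic cohorts

The simulator is phenomenological, not a bioheat (Pennes) model. A
breast is a half-ellipse mask (two mirrored components with a gap at
the image midline); its field is baseline + a smooth lateral ramp
(warmer toward the sternum) + i.i.d. Gaussian pixel noise. An anomalous
breast adds the pointwise maximum of (a) one radially decaying Gaussian
hotspot of amplitude `hotspot_delta` at a random in-mask centre
(σ = radius/2) and (b) random-walk vessel polylines dilated to 2-pixel
width at amplitude `hotspot_delta/2`, the textural correlate of
altered vascularisation. Maximum blending keeps the peak anomaly
exactly `hotspot_delta` even where structures overlap. Everything is
clipped to `temp_clip`.

Defaults are the emulated study conditions: baseline 28 °C, lateral
span 1 °C, noise 0.2 °C, hotspot 2 °C with radius 8 px, 2 vessels,
display/clip range (20, 36) °C, grid 120×160 (desk scale; the full
480×640 camera geometry is a config value). Cohort structure: 99
control + 42 cancer subjects by default; `study_config()` uses 97
control + 42 cancer subjects of which 29 carry bilateral findings, and
dropping the 13 contralateral control breasts of unilateral cancer
subjects (`exclude_cancer_contralateral`) reproduces the 265-sample
71 A / 194 NA composition, which is not otherwise representable without
unenumerated exclusions. Determinism: one cohort seed, sub-seeded per
subject from (seed, subject index), so any subject regenerates
identically in isolation; the number of bilateral subjects is exact
(round(fraction·n), membership by seeded permutation), not binomial.

What the simulator does *not* emulate: between-subject baseline
variation (left/right breasts are independent draws, which keeps the
selection test's type-I error exactly nominal under the null — real
cohorts have within-subject correlation), anatomical breast shape,
camera optics/blur, and any dependence of anomaly morphology on
pathology. Consequently, passing tests establish that the pipeline's
statistics behave correctly under controlled conditions (nominal
type-I rate, near-certain recovery of injected mean/max/contrast
effects, valid bootstrap coverage and McNemar behaviour) — they do not
certify clinical accuracy on real thermograms, whose class separation
is far weaker than the simulator's default 2 °C hotspots.

## Problem sizes and numerical choices

Simulation-based checks use deliberately modest sizes chosen to give
adequate Monte-Carlo precision: 1000 replicate null cohorts on 36×48
grids for the type-I rate (binomial SE ≈ 0.7% at the 5% nominal rate),
100 seeds at the default 120×160 grid for signal recovery, 10 replicate
null cohorts for the null-accuracy estimate (single cohorts are noisy
estimates of the mean), 500 outer simulations at n = 200, B = 2000 for
bootstrap coverage, and 500 simulated exchangeable classifier pairs for
the McNemar null. Ties and degenerate inputs are handled explicitly as
described above; quantization is floor-based with the top endpoint
mapped to G−1; all randomness flows from user-supplied integer seeds
through `numpy.random.default_rng`.

## Known limitations

Per-breast labels are binary (`NA`/`A`); intermediate or BI-RADS-graded
classes are out of scope. Quality exclusions (blur, amputation) are not
auto-detected; the manifest carries them. The published per-feature
p-values shipped for the worked example are inputs from the emulated
clinical study, not quantities this package can recompute without that
study's images.
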