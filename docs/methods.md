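# Methods

`hepanode` re-implements, end to end and on synthetic data, an analysis
pipeline for characterizing small (< 10 mm) hypoattenuating hepatic
nodules (SHHN, "too small to characterize") on contrast-enhanced CT as
benign or malignant in patients with a known primary malignancy.  The
chain is: synthetic patch-cohort generation → geometric augmentation →
a small CNN trained under patient-grouped 5-fold cross-validation →
per-lesion probability aggregation → logistic fusion with synchronous
liver-metastasis status → reader-study statistics → region-feature
interpretability.  This note records the models, the defaults and why,
the numerical choices, and what the synthetic cohorts do and do not show.

## Synthetic cohorts

Clinical SHHN CT cohorts are not publicly shareable, so the generator
(`hepanode.synthetic`) emulates their statistical structure:

* **Hierarchy.** Patients carry 1–6 nodules (zero-truncated Poisson with
  the rate solved numerically so the capped mean equals the configured
  `mean_nodules_per_patient`, default 2.75); each nodule is rendered on
  `1 + Poisson(mean − 1)` axial slices (default mean 3.32), every slice a
  32×32 attenuation patch with a ground-truth mask.
* **Attenuation scale.** HU-like, enhanced-liver background 100 by
  default (a plausible portal-venous value).  Only relative contrasts
  matter downstream, so the absolute level is a free configuration knob.
* **Phenotypes.** A nodule is a star-shaped region whose boundary radius
  varies smoothly with angle (three Fourier harmonics with random phases,
  amplitude = `boundary_irregularity`), dropped `depth` units below
  background, Gaussian-blurred at the margin (`edge_blur_sigma`) and
  overlaid with pixel noise (default SD 6).  Class-conditional means are
  parameterized as midpoint ± `class_separation` · gap/2, with malignant
  nodules larger (radius 4.5 ± 1.0 px across classes), shallower (closer
  to liver attenuation), blurrier and more irregular — the four
  directions reported for real benign vs malignant SHHN.  The literature
  supports these orderings but not specific effect sizes, so the gaps are
  configuration knobs with `class_separation = 1` as the realistic
  default; distribution tails are clipped so every nodule stays
  hypoattenuating (core ≥ 15 HU above water), above water attenuation,
  and clear of the patch border.
* **Covariate structure.** Each patient has a binary synchronous
  ≥ 1 cm liver-metastasis status (prevalence 0.244) that shifts every one
  of their nodules' malignancy log-odds by `log(liver_met_odds_multiplier)`
  (default 8).  The baseline logit is solved by root finding so the
  marginal malignant-nodule fraction equals the configured 0.342.  This
  gives the downstream logistic fusion a known ground truth.
* **Readers.** Simulated readers call each lesion with class-conditional
  accuracy (sensitivity/specificity) and attach a 1–5 Likert confidence
  drawn from a geometric-like distribution whose decay is set by
  `confidence_spread` (0 = always maximally confident; large ≈ uniform).

Slice-level re-renders use fresh noise and a small downward radius jitter
(off-equator slices cut smaller cross-sections).  Masks are carried as
ground truth, not re-segmented.  All randomness flows from one seed
through `numpy.random.SeedSequence` spawning; identical configs are
byte-identical.

**What the generator does not emulate:** 3-D partial-volume structure,
scanner/protocol variability, liver background texture (vessels, fat,
perfusion differences), cysts and hemangiomas as distinct sub-classes,
and reader bias from context outside the patch.  Passing tests therefore
demonstrate that the *pipeline mechanics* are correct and that the
statistical machinery is calibrated — not that the CNN would reach any
particular accuracy on clinical CTs.

## Augmentation

Training inputs are 24×24 crops of the 32×32 patches: 9×9 crop offsets ×
the 8 elements of the dihedral group D4 give 648 distinct variants, every
one an exact pixel rearrangement (no interpolation; verified as a
multiset identity).  Augmentation order is crop → rotate → reflect; a
different order only re-parameterizes the same reachable set.  Per epoch,
classes are rebalanced by oversampling with replacement — benign ×2 and
malignant ×≈6 by default (the malignant class being roughly a third of
the cohort); when no plan is given the malignant factor is set to
2·n_benign/n_malignant for exact expected balance.  Epoch size is the
rounded sum of class expectations with multinomial class counts, and
every sampled patch receives an independently drawn random augmentation.

## CNN and cross-validation

The classifier is a deliberately small CNN for 24×24 grayscale inputs:
conv(16)–conv(16)–maxpool–conv(32)–conv(32)–maxpool, a single dense layer
of 64 units flanked by 50% dropout on both sides, and one sigmoid output.
It is implemented as a compact numpy engine (im2col convolutions, exact
backprop — verified against numerical differentiation — Adam, binary
cross-entropy on logits, float32 arithmetic).  Details the architecture
description leaves open are fixed as: ReLU activations, 3×3 kernels with
zero padding, 2×2 pooling, Adam at 1e-3, batch 80, 50 epochs by default,
and patch standardization by the training cohort's global pixel mean/SD.
These are this package's documented defaults, not claims about any other
implementation.

Patients are stratified into 5 groups by a longest-processing-time greedy
heuristic on per-patient patch counts (seeded tie shuffle), which keeps
patients, lesions and patches near-balanced while guaranteeing that all
lesions of a patient share one group.  Each fold model trains on the
other 4 groups only; per-fold held-out patch-level and lesion-level AUCs
and per-epoch losses are recorded.  Lesion probability is the arithmetic
mean of patch probabilities (permutation-invariant; `max` available), and
calls use a 0.5 threshold with ties going to malignant (favoring
sensitivity in an oncologic context).  Held-out predictions for the
training cohort come from each lesion's own fold model; external cohorts
are scored by averaging the 5 saved models.

## Logistic fusion and screening

The fusion model is `logit(p) = β0 + β1·X1 + β2·X2` with X1 the CNN
lesion probability on its natural [0,1] scale and X2 the liver-metastasis
indicator, fitted by maximum likelihood (statsmodels).  The clinical
effect size is reported per 10% of CNN probability, exp(0.1·β1), with
Wald CIs (pre-scaling X1 by 10 would be numerically identical).  Perfect
or quasi-perfect separation is detected (non-convergence or exploding
standard errors) and raised as an explicit error.  Screening is backward
elimination at α = 0.05, dropping the least significant candidate first
and reporting every intermediate model; in the pipeline the candidate set
is {CNN probability, liver metastasis, extrahepatic metastasis}, and the
fit is performed on the testing cohort (a same-set fit, labelled as such
in the metrics; held-out fitting is equally supported).

## Evaluation statistics

* **AUC**: Mann–Whitney pair counting with ties at ½, standard error by
  DeLong's structural-components method, Wald CI clipped to [0,1].
* **Paired AUC comparison**: DeLong's test (the standard nonparametric
  correlated-ROC method); identical score vectors short-circuit to p = 1.
* **Threshold metrics**: sensitivity/specificity/accuracy as percentages
  at threshold 0.5 with 95% Wald CIs clipped to [0,100] (Wilson optional).
* **Agreement**: unweighted Cohen's kappa with the conventional bands
  (0.41–0.60 moderate, 0.61–0.80 substantial, > 0.8 almost perfect;
  lower Landis–Koch bands fill in below).  Chance agreement of exactly 1
  is flagged as undefined.
* **Ordinal scales**: reader (call, confidence) pairs map as benign c →
  6 − c, malignant c → 5 + c (a bijection onto 1..10); CNN probabilities
  bin into right-closed deciles [0, 0.1] → 1 … (0.9, 1] → 10.  The low
  confidence zone is ordinals {4, 5, 6, 7}.
* **McNemar**: exact binomial on discordant pairs when fewer than 25 are
  discordant, otherwise chi-square *without* continuity correction — the
  corrected statistic is markedly conservative at moderate discordant
  counts, and the uncorrected version holds the nominal type-I error in
  the calibration tests.
* The "radiologist mean" row is operationalized two ways (neither is
  canonical): AUC of the per-nodule mean of the readers' ordinal scores,
  and the mean of the individual reader AUCs; both are reported.

## Interpretability

Per patch, from the ground-truth mask: **area** (pixel count), **mean
central attenuation**, **edge sharpness** (mean attenuation in the
1-pixel outer margin band minus the 1-pixel inner band; band width
configurable) and **solidity** (area / convex-hull area, via
`skimage.regionprops`).  Two numerical choices deserve note:

* The "central 9 pixels" are evaluated as a 3×3 grid of unit-spaced
  bilinear samples straddling the exact patch center (equivalently a
  [1,2,2,1]/6-weighted mean over the central 4×4 block).  An even grid
  has no center pixel, so a literal 3×3 block cannot be symmetric; the
  sampled version is exactly invariant under patch rotations and
  reflections, which the feature tests exploit.
* Rasterized small disks score solidity ≈ 0.91–1.0 depending on radius
  (the pixelated convex hull overshoots); solidity comparisons are
  therefore made relative (irregular < smooth), not against 1.

Lesions are clustered by CNN probability with 1-d k-means (k-means++
init, `n_init = 20`, seeded; k defaults to 5), relabelled by ascending
centroid.  Benign-vs-malignant feature differences are tested two-sided
with both Welch's t and Mann–Whitney U.  The 64-d dense-layer activations
("pre-softmax" features) are embedded with t-SNE (perplexity 30 default,
PCA init, seeded; requires n > 3·perplexity).

## Problem sizes and tolerances in the test suite

The suite exercises the full mechanism at sizes chosen for a laptop-class
single-CPU run: cross-validation checks use 100-patient cohorts (~900
patches) at wide class separation with 2–6 epochs — the separation is
wide enough that optimization converges almost immediately, and held-out
lesion AUC reaches ≥ 0.90 (typically 1.0) — while permuted-label controls
confirm chance-level AUC (0.5 ± 0.1).  Calibration checks use 500–1,000
replicates and accept type-I error within 0.05 ± 0.02 at α = 0.05;
oracle identities (pair-counting AUC, exhaustive 1-d k-means, hand-worked
kappa and confusion matrices) are exact to 1e-9–1e-12.  Feature-trend
checks pool Spearman rank correlations over 20 simulated 30-patient
cohorts.  Single-precision network arithmetic means cross-batch-size
predictions agree to ~1e-4 relative rather than exactly; all
reproducibility guarantees are stated at fixed batch composition.

## Known limitations

* The numpy CNN engine is single-threaded and CPU-bound; it is sized for
  hundreds of lesions, not thousands of patients.
* The generator's phenotype model is low-dimensional by design; a high
  oracle AUC on synthetic cohorts says nothing about clinical AUC.
* Feature–probability correlations (the cluster trends) are exactly
  that — correlations; no causal claim about the CNN's decision process
  is made or testable here.
* Same-set fusion fitting (the pipeline default) optimistically biases
  the combined AUC on small testing cohorts; the held-out alternative is
  exposed through the API.
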