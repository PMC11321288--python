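# Methods

`octopheno` implements a self-supervised biomarker-proposal pipeline for
fovea-centered retinal OCT B-scans, together with a synthetic cohort
generator that provides ground truth for every stage. This note records
the models, the defaults and why they were chosen, the numerical
decisions, and what the synthetic validation does and does not show.

## The synthetic OCT phantom

Real OCT cohorts of this kind are not publicly deposited, so the package
ships a layered-phantom generator whose output is *structurally* OCT-like
rather than physically realistic. A retina is four smooth per-column
boundary curves — inner limiting membrane (ILM), retinal pigment
epithelium (RPE), Bruch's membrane, and the choroid–sclera interface —
built from a band-limited sum of one-to-three-cycle sinusoids plus a
linear tilt, with a Gaussian foveal pit in the ILM (depth 4–8 px, FWHM
12–20 px at desk scale). The mediolateral pixel pitch is fixed at
23.4 µm so that physical lesion sizes convert to columns exactly as
`round(size_µm / 23.4)`; the axial pitch is configurable (7.0 µm at the
full 208 × 256 scale, 12 µm at the 64 × 64 desk scale so retina plus
choroid fit the frame).

Lesions follow the standard grading definitions qualitatively:

| class | geometry change | rendering |
|---|---|---|
| drusen (small/large/confluent) | half-cosine RPE elevation of the stated diameter | bright RPE band fills the dome |
| PED | large dome RPE elevation (~520 µm) | as drusen |
| subretinal / intraretinal fluid | lens-shaped pocket above the RPE / ellipses within the retina | hyporeflective (0.05) |
| iRORA / cRORA | 35% / 55% retinal thinning over the stated width | cRORA adds a choroidal hypertransmission column (choroid reflectivity × 2.2) |
| double-layer sign | 1.5 px RPE–Bruch separation | dark gap band |
| scarring | subretinal hyperreflective material | bright (0.92) |
| thick choroid | choroid thickness × 1.8 | — |
| poor quality | — | Gaussian blur σ ∈ [1, 2] and lateral decentration up to 15% |

Default layer reflectivities (vitreous 0.05, retina 0.45, RPE band 0.85,
choroid 0.25, sclera 0.12) reproduce the qualitative contrast ordering of
real OCT. Noise is multiplicative Gaussian speckle (SD 0.12 of signal)
plus per-acquisition scanner jitter: gain uniform in [0.85, 1.15] and
offset in ±0.05. The jitter matters: it is exactly the nuisance
variation the contrastive augmentations are designed to discard, so it
makes the raw-pixel baselines honest rather than trivially strong.

Cohorts are longitudinal: each eye keeps one fixed anatomy and lesion
across visits and is re-rendered per visit with fresh speckle and jitter.
True visual acuity is a per-class base (85 letters for healthy down to 38
for scarring, strictly decreasing in an ordinal severity score) plus
Gaussian noise (SD 5 letters), clipped to the 5–95 letter range.
Conversion times follow `t = max(0, a − b·severity) + Exp(0.5)` with
`(a, b)` = (8, 1.0) years for MNV and (10, 1.2) for cRORA. These
coefficients are study conditions of the synthetic benchmark, not claims
about AMD progression; they guarantee that class-driven, Lasso-
recoverable prognostic structure exists and that age and sex carry no
signal. Visit spacing (0.5 y) and visits per eye are configuration, as
no canonical values exist.

What the phantom does *not* emulate: real speckle statistics (fully
developed speckle is not Gaussian), scanner-specific artifacts, 3-D
context, anatomical covariance between lesions, or label noise in
grading. Passing the recovery tests therefore shows the pipeline is
correct and self-consistent, not that it would reach any particular
accuracy on clinical data.

## Contrastive pretraining

The encoder is trained with the BYOL objective: an online network
(encoder `f` → projector → predictor) predicts the projection a slowly
moving target network (EMA of encoder + projector, decay τ = 0.996)
assigns to a second augmented view; the per-pair loss is the normalized
squared distance `2 − 2·cos(p, z)`, symmetrized over the two view
orderings (both orderings are evaluated in one concatenated pass).

Augmentations span brightness (±0.2 additive), contrast (×[0.8, 1.25]
about the image mean), rotation (±10°), aspect ratio (×[0.9, 1.1]),
horizontal flip (p = 0.5), and a randomly sized and located crop
resized back to the working resolution. The crop area fraction
defaults to [0.7, 1.0]: at a 64-pixel frame, harsher crops frequently
exclude a focal lesion from one view, which pressures the encoder to
become invariant to lesion *presence*. Three OCT-specific transforms
complete the family, each motivated by a nuisance the basic set leaves
untouched: per-view multiplicative speckle (level uniform in
[0, 0.15]) — the two views otherwise share one speckle realisation, so
nothing else makes features noise-invariant; a smooth per-column
vertical warp (≤ 4 px; sinusoid plus Gaussian bump) emulating
inter-eye variation in layer position, tilt and pit shape; and a
horizontal translation (≤ 10 px). All ranges are surrogate defaults
exposed in `AugmentationPolicy`.

The desk-scale backbone is a fixed 2×2 average-pooling front end
(suppressing pixel-i.i.d. speckle before any learned filter) followed
by four 3×3 stride-2 conv → BatchNorm → ReLU blocks of widths
16-32-64-64 with reflect padding (zero padding imprints absolute
position at the borders), read out by concatenated global average and
max pooling — the max half preserves small focal lesion responses that
plain averaging washes out — giving 128 features. A ResNet-class
backbone with 2048-wide penultimate features is the full-scale
analogue; the method is backbone-agnostic and `build_encoder` exposes
widths, readout and pooling. Heads are 2-layer MLPs (hidden 128,
output 32) with BatchNorm — BatchNorm in the heads is the standard
guard against representational collapse in BYOL. Optimization is Adam
(β₁ = 0.9, learning rate 5 × 10⁻⁴, weight decay 1.5 × 10⁻⁶, no
schedule), batch 64, 2000 steps at desk scale. All tensor code is an
in-package float32 numpy/numba layer library with hand-written backward
passes (`octopheno.nn`); training is single-worker and deterministic
given the seed.

Features are read from the penultimate layer (global-average-pooled
activations) in inference mode with no augmentation.

## Clustering and similarity vectors

Features are z-scored per dimension (zero-SD dimensions pass through
unscaled) before k-means — without this, high-variance dimensions
dominate the Euclidean metric. k-means uses k-means++ with 10 restarts
and ≤300 Lloyd iterations; k defaults to the number of planted classes
at desk scale and to 30 at full scale, and is a parameter (no selection
criterion is imposed). Clusters are re-indexed by descending median
visual acuity (ties: larger cluster first, then lower raw index;
clusters without acuity data go last with a warning), giving ordered ids
C1 (best vision) … Ck (worst).

The per-image similarity vector is `softmax(−d²/T)` over distances to
the ordered centroids, with temperature `T` equal to the training-set
mean squared nearest-centroid distance. This construction was chosen
because it is a proper distribution whose argmax coincides with the
nearest-centroid assignment and whose scale is self-calibrating; raw
negative distances are available behind a flag. Exact distance ties
resolve to the lower ordered index.

## Annotation artifacts

* **Stage–cluster matrix**: P(grading stage | cluster) over labelled
  images only; rows of unlabelled clusters are NaN and flagged rather
  than silently zero. The five-stage vocabulary is healthy,
  early/intermediate AMD, MNV, cRORA 250–1000 µm, cRORA ≥ 1000 µm;
  synthetic classes map onto it by the table in `synthetic.GRADING_MAP`
  (fluid/PED/scarring → MNV, drusen/DLS → early AMD, atrophy by width,
  poor-quality unlabelled).
* **Linear probe + GradCAM**: an unregularized multinomial logistic map
  from standardized features to cluster ids (the probe only routes
  gradients, so no penalty is wanted; `tol` 10⁻⁶, ≤500 iterations).
  GradCAM is evaluated at the ReLU outputs of the final two conv
  blocks: channel weights are spatially averaged gradients of the
  cluster logit, maps are rectified, bilinearly upsampled to image
  size, averaged across the two layers (max-combine behind a flag) and
  max-normalized. An all-zero map is returned as zeros with a
  degenerate flag and warning.
* **Review panels**: per cluster, 10 "seen" + 10 "unseen" images drawn
  uniformly at patient level without replacement (one image per
  patient); clusters with fewer than 20 patients yield truncated panels
  with a warning. Panels support human review; the interviews
  themselves are out of scope.

## Prognostic benchmark

Targets are time to MNV, time to cRORA, time to late AMD (minimum of
the two), all in years, and current visual acuity in letters. A visit
enters a conversion task only when the eye's event occurs strictly
after it — there is no censoring model, because the evaluation metric
is a plain MAE in years; eyes converting before their first visit are
excluded from that task with a warning.

Systems: demographic (age + sex, OLS), grading (stage one-hot, Lasso),
clusters (similarity vectors, Lasso), fully supervised (LinearSVR with
C = 1.0 directly on the feature space). Lasso penalties are chosen by
inner 5-fold CV on the training fold. Cross-validation uses 10
independent patient-wise random 80/20 splits (a strict partition mode
would also be defensible; the independent-splits reading matches the
protocol wording and is the default). Patient disjointness is asserted
in every fold. The whole experiment — clustering, ordering, similarity
construction, folds, fits — is repeated per seed (7 at full scale, 3 at
desk scale) and MAEs are reported as mean ± SD over folds × seeds.

The visual-acuity stratification reports per-ordered-cluster means with
normal-approximation 95% CIs (mean ± 1.96·SE); single-image clusters
are flagged.

## Problem sizes and numerical choices

The desk-scale validation cohort is 2000 images (500 patients × 1 eye ×
4 visits) at 64 × 64, six planted classes (healthy, large drusen, PED,
intraretinal fluid, complete atrophy, scarring), 2000 BYOL steps. These
sizes were chosen as the smallest at which all recovery signals are
comfortably away from their thresholds. Other numerics: BatchNorm ε =
10⁻⁵ with momentum 0.1; Adam ε = 10⁻⁸; similarity temperature floored at
10⁻¹²; k-means restarts rise from 10 to 100 on instances of ≤ 32 points,
where restarts are cheap and Lloyd's local optima are otherwise easy to
hit; k-means oracle equivalence asserted at rel. 10⁻⁶; feature
extraction is batch-size invariant to 10⁻⁵ (float32).

## What desk-scale cluster recovery can and cannot show

On the 2000-image validation cohort, clustering the learned features
recovers the planted classes far better than clustering raw pixels
(adjusted Rand index ≈ 0.35 vs ≈ 0.08), the late lesion classes
(atrophy, PED, scarring) form nearly pure clusters, and a linear probe
on the features reaches the supervised ceiling of the noisy renders
(≈ 0.82 vs ≈ 0.80 for a full-resolution pixel probe). Two effects cap
the ARI well below 1 at k = number of classes, and systematic sweeps
over capacity, augmentation ranges, padding, readouts, pooling, batch
size and EMA decay all land in the 0.29–0.38 band:

* Healthy retinas, large drusen and intraretinal fluid are barely
  separable *as modes* at 64 × 64 under speckle — even a supervised
  classifier confuses this trio — so the three merge into shared
  clusters.
* Lesion eccentricity relative to the (always centred) foveal pit is
  genuine within-image geometry that no global augmentation can
  remove, so k-means spends clusters on fovea-involving versus
  peripheral lesions. This mirrors the behaviour reported for the
  clinical system, whose clusters likewise include fovea-involving
  atrophy and off-centre-scan groups; it is a property of
  unsupervised phenotype discovery, not an artifact of this
  implementation.

Passing recovery tests therefore demonstrate self-consistency and a
large margin over the pixel baseline, not clinical-grade clustering.

## Known limitations

* The numpy/numba network is CPU-bound and desk-scale; full-scale
  (2048-feature ResNet) runs would need a GPU framework implementing
  the same interfaces.
* No censoring-aware survival modelling; MAE-in-years on converting
  eyes only.
* k is user-chosen; no model-selection criterion is provided.
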