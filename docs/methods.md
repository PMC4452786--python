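# Methods

## Problem and overall design

Diabetic retinopathy (DR) screening asks a binary question per fundus
photograph: does the image show signs that warrant specialist referral?
The two earliest and most consequential sign families are **bright
lesions** (hard exudates — yellowish lipid deposits) and **red lesions**
(microaneurysms and dot/blot haemorrhages — small dark-red spots).  This
package implements a classical bag-of-visual-words (BoVW) screening
system with one binary detector per lesion family and a conservative
fusion rule, and evaluates it under a *cross-dataset* protocol: the
codebooks and classifiers are fitted on one cohort (one camera,
resolution and colour profile) and tested on a different one.  That
protocol is the point of the design — in deployment, screening images
rarely match the training camera or population.

The chain is:

1. **Low-level features.**  Points of interest (PoIs) are detected on
   the luminance channel with a multi-scale determinant-of-Hessian (DoH)
   blob detector and described by a 4 × 4 × 4 gradient-orientation
   histogram (64-D), optionally extended with the Gaussian-weighted RGB
   means of the patch (default on, D = 67), because lesions are both a
   shape and a colour event.  No rotation invariance is applied: fundus
   photographs are upright.  During training, PoIs of lesion images are
   restricted to the lesion regions of interest (ROIs); control images
   are used whole and need no region marking.
2. **Codebook.**  Per lesion family, a pool of descriptors is sampled
   per class (ROI-restricted positives, whole-image negatives) and
   clustered with Lloyd's k-means (Euclidean distance, k-means++
   seeding, farthest-point re-seeding of empty clusters); the centroids
   are the visual words.  Random word selection is available as the
   cheaper alternative.
3. **Encoding.**  Hard assignment (each descriptor to its single nearest
   word, ties to the lowest index) with sum pooling yields a k-bin
   activation histogram; l2 normalisation is applied by default before
   classification ({none, l1, l2} selectable).
4. **Decision.**  A regularised linear maximum-margin classifier
   (linear SVM, squared hinge, C = 1 by default) per lesion family;
   the score is the signed distance to the boundary, default operating
   threshold 0.
5. **Fusion.**  An image is called normal only if *both* detectors call
   it normal: `referable = flag_bright OR flag_red`, minimising false
   negatives.  For a threshold sweep of the fused system, the continuous
   multi-lesion score is the maximum of the two per-detector scores
   after each is standardised to zero median on the training normals
   (two independently trained SVMs have incomparable raw scales);
   thresholding this max at `t` is exactly the OR of per-detector flags
   at `t`.
6. **Evaluation.**  ROC curves by threshold sweep over the distinct
   scores (ties grouped into one step, degenerate endpoints included),
   AUC by the trapezoidal rule — identical to the Mann–Whitney pair
   statistic with ties counted ½, which the tests verify by brute
   force.  Sensitivity is the true-positive rate on lesion images,
   specificity the true-negative rate on normals.  Per-detector ROCs
   compare that lesion's images against normals only; the fused system
   is evaluated on the full test set ("test 1") and on the
   normals-versus-dual-lesion subset ("test 2").

## Synthetic cohorts

Real screening archives are access-restricted, so the package ships a
generator that emulates the *statistical structure* the pipeline
assumes, not photorealistic retinas.  An image is a circular
reddish-orange field with low-frequency shading, fine granular texture,
6–9 darker curvilinear vessel strokes radiating from a brighter
yellowish optic disc, and a near-black surround.  Lesions are elliptical
Gaussian-profile blobs: bright lesions add positive offsets concentrated
in R and G (yellowish, like exudates); red lesions subtract mainly G and
B (dark red, like haemorrhages).  Each lesion instance records a binary
ROI mask (its 2σ ellipse footprint), the synthetic analogue of
specialist-marked regions.

Cohort-level domain shift is modelled as exactly three effects —
resolution, per-channel colour gains, and an optional in-memory JPEG
re-encoding — the minimal stand-in for a camera/site change.  Lesion
radii are specified at a 480-line reference height and scaled with the
actual image height, so the same lesion specification is anatomically
comparable across resolutions.

Default lesion parameters (free choices; no clinical dataset reports
them): bright lesions 3–8 per image, radius 4–10 px at reference scale,
contrast 0.25–0.5; red lesions 3–10 per image, radius 2.5–7 px, contrast
0.18–0.42.  Red lesions are deliberately smaller and fainter — clinically
the subtler sign — which makes red-lesion detection the harder task and
reproduces the qualitative ordering (bright easier than red) that
motivates reporting the two detectors separately.

What the generator does **not** model: vessel branching realism, optic
disc anatomy, illumination vignetting, blur/glare, inter-patient
anatomical variation, lesion clustering along vessels.  Passing the
packaged experiments therefore demonstrates that the pipeline's
machinery (feature extraction, codebook, encoding, classification,
fusion, protocol isolation) works and generalises across the modelled
shifts; it says nothing quantitative about clinical performance.

Determinism: a cohort is a pure function of its configuration.  Image
`i` uses seed `seed + i` (so cohorts are extensible without reshuffling);
the bright and red lesion passes use fixed prime offsets from the
per-image seed.

## Reference experiment

The packaged reference experiment scales the cross-dataset protocol to
desk size:

* cohort A (training): 60 images at 640 × 480 — 30 normal, 10
  bright-only, 10 red-only, 10 with both; no JPEG, neutral colour.
* cohort B (test): 30 images at 800 × 600 — 18 normal, 7 red-only, 5
  with both lesion families (a screening-like composition in which every
  bright-lesion image also carries red lesions); channel gains
  (1.05, 0.97, 0.90); JPEG quality 90 (high quality, matching routine
  ophthalmological practice).
* pipeline: k = 96 words per detector, ≤ 4000 sampled descriptors per
  class, ≤ 60 Lloyd iterations, l2 histograms, C = 1 — sizes chosen so
  one full run takes about a minute on a single CPU.

One deliberate deviation from the package-wide default deserves note:
the reference experiment caps PoIs at **150 per image** (default 500).
On these cohorts, lesion PoIs occupy the top ~15 response ranks while
ranks beyond ~150 are low-response background texture; with a 500 cap
the pooled lesion mass falls to ~1 % of the histogram and the detectors
lose their signal after normalisation.  A tight response-rank cap is the
standard BoVW remedy (characterise the image by its most salient
structure) and is exposed as an ordinary configuration key.

## Numerical and degenerate-input policies

* Hard-assignment ties break to the lowest word index; this is fixed and
  platform-stable.
* Images with zero PoIs encode to the all-zero histogram, are flagged,
  and score the detector's bias alone — a screening run never crashes on
  a blank image.
* k-means records inertia after every assignment step; monotone descent
  is asserted in tests.  Empty clusters are re-seeded with the point
  farthest from its assigned centroid, which cannot increase the
  objective.  Convergence: total centroid movement < 1e-4 or 100
  iterations.
* ROC thresholds sweep the distinct score values plus the ±∞ endpoints;
  zero-denominator confusion ratios are reported as undefined (`None`),
  never as 0.
* The within-cohort mode uses a seeded stratified 50/50 split (strata =
  label pairs); the split procedure is a free design choice.
* Operating points maximise sensitivity subject to specificity ≥ target,
  ties resolved toward higher specificity.
* All artifacts store floats at 17 significant digits (value-exact
  round-trip); save→load of codebooks and models is bit-exact, and
  re-running any CLI stage with unchanged inputs reproduces
  byte-identical files.

## Known limitations

* The synthetic generator's simplicity means absolute AUCs on it are
  optimistic; only orderings and protocol properties transfer.
* The DoH detector responds to blobs; linear/elongated abnormalities
  (e.g. cotton-wool streaks, neovascularisation fronds) are outside its
  design.
* One codebook and one SVM per lesion family, no probability
  calibration, no severity grading, no lesion localisation at test time
  — screening only.
* With very small test sets (tens of images), AUC moves in steps of
  1/(n_pos · n_neg); single-seed results on 30-image cohorts should be
  read with that granularity in mind.
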