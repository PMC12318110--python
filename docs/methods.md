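# Methods

## Problem and model

`hccscreen` evaluates how an AI lesion detector and an AI malignancy
classifier can be inserted into ultrasound screening for hepatocellular
carcinoma (HCC). The unit of analysis is a single screening image with
ground truth (lesion present?, malignant?, lesion size class) and the
outputs of several decision agents. The positive outcome is *recall*: the
decision to call the patient back for confirmatory imaging; its ground truth
is "the image shows a malignant lesion", so benign-lesion and no-lesion
images are both negatives.

Five workflows are compared:

| id | detection | classification | radiologist reads |
|----|-----------|----------------|-------------------|
| `original` | radiologist | radiologist | every image (1 read) |
| `s1` | AI | AI score ≥ cutoff | none |
| `s2` | AI, radiologist reviews AI-negatives | AI | AI-negative images |
| `s3` | AI, radiologist reviews AI-negatives | AI-assisted radiologist | AI-negatives + all lesion-bearing |
| `s4` | AI, radiologist reviews AI-negatives | AI; radiologist reviews AI-benign calls | AI-negatives + AI-benign lesion-bearing |

Workload is the count of radiologist image-reads, one per stage: an image
read at both the detection and the classification stage counts twice, which
is the only accounting under which `s3` can exceed the cohort size
(986 detection reads + 3200 assisted classification reads = 4186 on a
4021-image cohort). Images the detection review also deems lesion-free exit
as no-recall without a classification read. A classifier score exactly at
the cutoff counts as a malignancy call (ties favour recall, consistent with
a sensitivity-preserving cutoff choice).

## Synthetic cohorts

No image data are used anywhere. The stochastic generator
(`generate_cohort`) draws image classes from a multinomial with fractions
defaulting to the published test set (2289 malignant / 731 benign / 1001
no-lesion of 4021; 7.5% of lesions < 1 cm), then samples each agent's binary
output as a Bernoulli draw from its operating point: detector 0.941/0.833,
unassisted radiologist 0.991/0.698, AI-assisted radiologist 0.916/0.869,
detection review 1.0/1.0 (the full-recovery assumption under which the
published `s3` workload arises). Classifier scores come from two Beta laws
Beta(a, b) with a fixed at `score_shape` (default 2) and b solved by
bracketed root-finding so the CDF at the cutoff (default 0.2) equals
1 − sensitivity (malignant images) or specificity (all others); the
operating point at the cutoff is therefore hit exactly in expectation.
Images are grouped into screening visits of size 1 or 2 at the published
mean of ~1.94 images per visit; all evaluation is per image, so the grouping
is bookkeeping only. All randomness flows through one `numpy` Generator
seeded from the config.

Radiologist recall probabilities (needed for the entropy analysis, which the
source study does not operationalise for human decisions) use a declared
two-point confidence model: a call concordant with ground truth is made with
confidence 0.95, a discordant one with 0.6, stored as P(recall) (so a
confident no-recall is 0.05). Because this is a stand-in, the per-strategy
entropy medians/IQRs from simulations are qualitative; only the arithmetic
of the entropy profile (medians, IQR widths, low-entropy error rates) is
treated as exact.

The deterministic fixture (`paper_fixture`) instead fixes every
class × agent-outcome cell to an integer: detector errors 165 FN (125
malignant / 40 benign, proportional split with floor for malignant) and
180 FP; classifier calls 2040/249 on malignant and 572/159 on benign
(specificity 0.783 also applied to the 1001 no-lesion images → 784/217);
unassisted radiologist 2268 true recalls and 523 false recalls (220 benign /
303 no-lesion). Joint cells are filled by largest-remainder apportionment,
so the table is fully deterministic and the published aggregates (accuracy
3676/4021, recall 2791/4021 = 0.694, workloads 0/986/4186) are identities,
not estimates. The published detector sensitivity/specificity (0.941/0.833)
are slightly inconsistent with the published error counts (165/180 imply
0.945/0.820); the fixture follows the error counts, which also reproduce the
printed accuracy, while the generator defaults keep the printed operating
point.

## Statistics

* Proportion CIs: exact Clopper–Pearson (beta quantiles), 95% by default.
* Rate differences: unpaired difference of proportions with a Wald CI by
  default; Newcombe score interval available. The pairing across strategies
  (same images) is deliberately not exploited by default — it is not needed
  for the margin logic and keeping the unpaired form makes the CI method
  explicit.
* Margins: sensitivity noninferiority with a *relative* 5% margin
  (noninferior iff the lower CI limit of new − reference exceeds
  −0.05 × reference sensitivity, strict inequality at the boundary);
  specificity superiority with an *absolute* 1% margin (lower CI limit
  > 0.01). Both verdicts are scale-invariant (percent vs proportion).
* Tests: two-sided two-proportion z-test (workload counts are compared as
  proportions of the maximum 2 reads/image), chi-square on
  correct/incorrect counts for accuracy, Mann–Whitney U (asymptotic, tie
  corrected) for entropy distributions, and the DeLong method for paired
  AUCs, implemented with the midrank structural-component algorithm;
  identical score vectors short-circuit to p = 1. Rule-based strategies have
  no natural score, so DeLong comparisons use the per-image recall
  probability. Bonferroni correction reports alpha/n.
* AUC: for a binary decision rule, the trapezoidal area of the ROC polyline
  (0,0) → (1−specificity, sensitivity) → (1,1) = (sens + spec)/2, which is
  how single operating points are placed on the ROC plane; score-based AUC
  is the empirical trapezoid (rank-midpoint ties), delegated to
  scikit-learn and cross-checked against pair counting in the tests.
* Entropy: binary Shannon entropy of the final decider's P(recall), in
  bits, with 0·log 0 = 0; the "high-certainty" subset is H < 0.1 bits
  (strict). Summaries over empty error sets are reported as missing, never
  as zero.

## Numerical choices

* Reported values are rounded half away from zero at 3 decimals (so an
  exact half like (0.991 + 0.698)/2 = 0.8445 rounds to 0.845); a guard
  re-round 7 digits deeper absorbs binary-representation noise. Internal
  computation is full precision.
* The segmentation loss stabilises the soft-IoU ratio with ε = 1e-7 in
  numerator and denominator, so an all-zero class contributes a perfect
  ratio (the unstabilised formula is 0/0 there) and a perfect one-hot
  prediction scores exactly 0.
* The attention blocks implement the bare matrix products
  QKᵀV — no softmax, no 1/√d scaling — as the reference forms; a
  `conventional=True` mode adds scaled row-softmax. The confidence gate of
  the consistency loss is a per-position indicator on the maximum class
  confidence of the weak-view prediction.
* Subgroup (lesion-size) metrics use benign lesions as the negatives by
  default, since the subgroups are defined on lesion images only;
  `include_no_lesion=True` adds no-lesion images to every subgroup's
  negative pool.

## Problem sizes

Defaults keep everything on one CPU in seconds: the fixture is 4021 rows,
calibration-recovery checks use 50,000-image cohorts, interval-coverage
checks 10,000 binomial replicates per true proportion, and the DeLong
type-I-error simulation 1000 replicates at n = 200. The low-entropy
calibration fixture defaults to 6052 high-certainty decisions with 482
errors plus 1000 maximally uncertain padding decisions (the padding size is
arbitrary and does not enter the error rate).

## Limitations

* Agent outputs are conditionally independent given the image class; real
  detector/classifier/radiologist errors correlate (e.g. small lesions are
  harder for everyone), so simulated strategy-level sensitivities and
  specificities need not match a real reader study even when the component
  operating points do. Strategy-level published values are therefore
  validation surfaces only where they are count identities (workloads,
  recall counts), not stochastic targets.
* The two-point confidence model is the simplest law consistent with "a
  radiologist decision carries some uncertainty"; reliability analysis of
  it would be circular and is out of scope.
* Per-patient aggregation, multi-lesion images, center-level covariate
  shift and reader fatigue are not modelled.
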