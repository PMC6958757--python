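# Methods

## Overview

The package analyses posed facial expressions from single apex frames.
Each frame is described by 49 facial landmarks and a 256×256 grayscale
raster; a random-forest classifier predicts which of four emotions
(neutral, happiness, anger, sadness) was targeted; forest importances are
mapped back onto the face. Because the motivating data (videos of
children) cannot be shared, a synthetic generator provides corpora whose
group structure — one group producing clear expressions, one producing
ambiguous ones — is fully known, so the pipeline's group comparisons can
be validated as parameter recovery.

## Landmark template and prototypes

The canonical face is a fixed 49-point configuration on a 256×256 canvas
(image coordinates: x rightward, y downward), mirror-symmetric about
x = 128, with regions brows (0–9), nose (10–18), eyes (19–30) and mouth
(31–48); the inter-ocular distance (IOD), the distance between the two
6-point eye centroids, is 70 canonical pixels. Emotion prototypes are
49×2 displacement fields at intensity 1, built from a left-side/midline
specification and mirrored so they are exactly symmetric:

* happiness — mouth corners up/outward (≈10 px at the corner), lower lip
  raised, lower eyelids raised; deliberately the strongest prototype,
  since smiles are the most recognisable posed expression;
* anger — inner brow ends pulled down and together (≈6 px), lips
  compressed, slight upper-lid lowering;
* sadness — inner brow ends raised (≈5 px), mouth corners pulled down,
  drooping upper lids;
* neutral — the zero field.

The numbers are fixture data chosen so expressions are distinguishable at
the default noise levels, not anatomical measurements.

## The generative model

For subject $s$ with personal neutral face $B_s$ (the template under a
random similarity transform — scale sd 0.05, rotation sd 3°, translation
sd 4 px — plus per-landmark jitter sd 1 px), a video targeting emotion
$t$ realises

$$x = B_s + I \cdot \mathrm{asym}_\kappa\!\left[(1-a')P_t + a' \textstyle\sum_{e \ne t} w_e P_e\right] + \varepsilon,$$

where

* $a' \sim \mathrm{Beta}(c\alpha, c(1-\alpha))$ with concentration
  $c = 10$, so the mean realized non-target mass equals the group's
  ambiguity $\alpha$;
* the bleed weights $w$ are Dirichlet with concentration 2 on happiness
  and 1 elsewhere (*valence mixing*: the commonest intrusion during posed
  negative expressions is smiling/laughing, so ambiguous anger acquires
  happiness components);
* intensity $I \sim \mathcal N(\mu_I, \sigma_I)$ clipped to [0, 1];
* $\mathrm{asym}_\kappa$ scales left-side displacements by $1+s$ and
  right-side by $1-s$ with $s \sim \mathcal N(0, \kappa)$;
* $\varepsilon$ is i.i.d. Gaussian landmark noise with sd $\sigma$.

**Per-emotion production difficulty.** Posed neutral and happy faces come
out far cleaner than posed anger, and sadness is hardest of all. The
corpus generator therefore multiplies $\alpha$ by per-emotion difficulty
factors (neutral 0.65, happiness 0.75, anger 1.30, sadness 1.95) whose
weighted mean under the default label proportions is ≈1, so the group's
corpus-level mean ambiguity stays at $\alpha$ while its distribution over
emotions is realistic. `sample_expression` applies no difficulty scaling
unless a map is passed, so its mean-nontarget-mass contract is exact.

**Group presets.** The clear group uses α = 0.05, σ = 1.0 px, κ = 0.05,
intensity 0.85 ± 0.10; the ambiguous group α = 0.30, σ = 1.5 px (1.5×),
κ = 0.15, intensity 0.75 ± 0.15. These three orthogonal knobs correspond
to the three reported phenomena that separate such groups — ambiguity,
production variability and facial asymmetry — and are tunable per
`GroupParams`. Default corpus shape: 157 clear and 36 ambiguous subjects,
2–23 videos each, label proportions 36.5/28.5/21.5/13.5% (neutral /
happiness / anger / sadness), three judges.

**Rendering.** Frames are drawn as anti-aliased polylines along each
region's landmark chain (eyes and lips closed), Gaussian-smoothed
(σ = 1 px), over a low-amplitude (0.05) smoothed-noise background
texture. Expression *furrows* — nasolabial folds for happiness, glabellar
lines for anger, creases under the mouth corners for sadness — are drawn
at 0.15 peak amplitude with strength proportional to the realized emotion
presence, times a per-subject skin gain (lognormal, σ = 0.4) and a
per-video jitter (uniform 0.6–1.1). Furrows displace no landmark: they are
the appearance-only cue (the analogue of wrinkles) that gives the HOG
block independent signal; without them local gradients are a deterministic
function of the landmarks and the forest ignores them entirely.

**Judge ratings.** The apparent presence of emotion $e$ is
$p_e = w_e I$ (with the undisplaced mass $1-I$ re-absorbed into the
neutral scale, since a face at intensity 0 is a perfect neutral). Judge
$j$ scores scale $e$ as
$\mathrm{clip}(\mathrm{round}(10 p_e + b_j + \eta), 0, 10)$ with per-judge
bias $b_j \sim \mathcal N(0, 0.3)$ and noise sd
$0.9 + 0.4\,(1 - w_t)$ — judges disagree more about expressions whose
displacement strays from the target prototype. On the default presets
this yields mean ICC(2,1) ≈ 0.94 for the clear group and ≈ 0.78 for the
ambiguous group; the ambiguous level saturates near 0.78 because that
group's between-video score variance is inherently smaller.

All randomness flows from one master seed through named substreams
(subjects, expressions, ratings, textures); regeneration under a fixed
config is bit-identical.

## Curation

* **Quality filter**: a video is retained iff the across-judge *mean* of
  its target-scale score is *strictly* greater than the threshold
  (default 7). Whether the original protocol used the mean, the median or
  unanimity is unknowable from the outside; the mean with strict
  inequality is the least surprising reading of "rated above 7". Subjects
  losing all videos are dropped.
* **ICC**: two-way random-effects, absolute-agreement, single-rater
  ICC(2,1) (computed by pingouin), the standard form when judges are a
  random sample and their absolute scores matter. The form is
  configurable. A zero-variance table is defined as ICC 0 with a warning.
  Note the *sample* ICC(2,1) is not exactly invariant to cloning every
  judge (the residual degrees of freedom change); it is exactly invariant
  to judge relabelling.
* **Matched subgroups**: greedy seeded matching of the reference group
  into a strictly larger source group — exact gender and site, age within
  ±1 year, minimising age difference, with ties broken in favour of
  self-matches and then of candidates covering the remaining per-emotion
  video need; the matched subjects' videos are subsampled so per-emotion
  counts equal the reference profile. Matching is only feasible when the
  source group is video-richer than the reference (a per-group
  `videos_per_subject` supports this); infeasibility raises an explicit
  error naming the unmatched subject.

## Features

1617 features per frame, fixed naming (`dist_i_j`, i<j lexicographic;
`hog_l_k`, landmark-major):

* 1176 geometric — all pairwise landmark distances / IOD. Invariant under
  any in-plane similarity transform (checked to 1e−9 over random
  transforms).
* 441 appearance — per landmark, central-difference gradients (edge
  replication) over a square window of side 0.2 × IOD rounded to the
  nearest odd integer ≥ 3 (so the centre pixel exists); 9 maps (map 0 the
  gradient magnitude; maps 1–8 the magnitude hard-assigned to 45° bins of
  the signed orientation in [0°, 360°)), each pooled to its mean over the
  window. Hard assignment preserves the exact identity
  map 0 = Σ maps 1–8, used as a structural test. The window is clipped at
  image borders; the mean pooling keeps clipped windows comparable.

Choices where the convention was open: the window is a square *side* (not
radius); orientation is signed (8 × 45° covers the full circle); pooling
is the mean rather than the sum. All are documented constants.

## Classification protocol

Forests use 500 trees, depth ≤ 16, Gini impurity, ≤ 220 candidate
features per split, ≥ 40 samples to split, inverse-frequency class
weights (the label distribution is skewed), no feature standardisation
(trees are scale-equivariant). Folds are built by shuffling *subjects*
and dealing them round-robin into k = 10 folds; every video inherits its
subject's fold, so no individual ever contributes to both training and
testing (asserted on every run). Within-group evaluation trains k fold
models; the cross-group regime trains the same k training splits and
tests each model on the entire other-group corpus, reporting the mean and
SD across the k models and the pooled confusion matrix. Forest seeds
derive deterministically from (master seed, regime, fold).

## Importance attribution

Importance is the forest's native mean impurity decrease (sums to 1).
Type contributions are the within-type sums (×100). Per-landmark weights:
`hog_l_k` accrues to landmark l; `dist_i_j` accrues half to each endpoint
(the attribution rule is a convention; half/half is the symmetric
choice), renormalised within type. The effective landmark count at mass
0.9 — the smallest number of top-ranked landmarks holding 90% of a type's
importance, ties broken by index — operationalises "how many landmarks
the classifier needs"; the threshold is configurable.

## Validation sizes and what passing shows

The acceptance suite runs five master seeds of a paired-corpus study at a
reduced scale chosen for a fast test cycle: 52 clear vs 12 ambiguous
subjects (preserving the ≈4.4:1 group imbalance of the motivating
design), 6–10 videos per subject, 100-tree forests. At this scale the
package recovers, directionally: the within-group accuracy gap (≥ 5
points), the accuracy loss when clear-trained models are tested on the
ambiguous group with happiness recall degrading least, the emergence of
anger→happiness confusion in the ambiguous group, the larger effective
landmark count of the ambiguous-group forest, the higher judge ICC for
the clear group, and the dominance of geometric over appearance
importance.

The generator emulates group structure, not faces: rasters are schematic
line drawings, landmark noise is i.i.d. (no correlated tracker error),
there are no head-pose, lighting or identity-texture effects, each video
is a single apex frame (no dynamics), and judges are conditionally
independent given the mixture. Passing therefore shows the *pipeline* is
correct and sensitive to the modelled contrast; it does not certify
accuracy levels on real video, where absolute numbers will differ.

## Numerical notes

* Degenerate inputs: coincident eye centroids, empty gradient windows,
  single-class training sets, zero-variance rating tables and infeasible
  matchings all raise explicit errors (or a defined 0 with a warning for
  the ICC case).
* Pairwise distances come from scipy's `pdist` (lexicographic pair
  order); it may differ from naive summation by 1 ulp.
* Rendering and importance maps use fixed settings so identical inputs
  produce byte-identical files.
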