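# Methods

## Problem and model

`zspose` classifies static human poses from body-worn IMU data in the
zero-shot regime: the target pose has no training recordings and is known
only through a symbolic description.  The bridge between signals and
labels is an attribute space of body-joint states.  Fourteen joints are
used; joints with several mutually exclusive states (head, the two
shoulders, the two hands, waist) are estimated by multiclass
classification and contribute a probability-simplex slice to the
attribute vector, while one-degree-of-freedom joints (elbows, wrists, hip
joints, knees) are estimated by regression and contribute one scalar in
[0, 1] (0 = straight, 1 = bent).  The default schema spans D = 33
dimensions: head 5 + 2 shoulders x 5 + 2 elbows + 2 wrists + 2 hands x 3 +
waist 4 + 2 hip joints + 2 knees.

A pose class *i* is represented by a prototype v(i) in this space: the
element-wise mean of its samples when training data exist, or the
expansion of its definition-table row (one-hot for classification joints,
the stated scalar for regression joints) when it is unseen.  A sample a
is labeled by the nearest prototype.

Two distances are implemented.  The naive metric

    d(a, v) = ( Σ_d wrc(d) |a_d − v_d|^p )^{1/p}

uses only the range-equalising weight wrc(d) — 0.5 on
classification-derived dimensions, 1 on regression dimensions — which
makes every joint's maximal contribution 1 (a simplex slice has L1
diameter 2, a unit interval has diameter 1).  The importance-weighted
metric adds a per-class binary mask wai(d, i), copied from a per-joint
importance table, and a penalty:

    d(a, v(i)) = (1/Wai(i)) ( Σ_d wai(d,i) wrc(d) |a_d − v_d(i)|^p )^{1/p}
                 + λ / Wai(i),          Wai(i) = Σ_j w′ai(j, i).

With binary weights and p = 1 the first term is the mean wrc-scaled
deviation over the class's diagnostic joints; the λ term penalises
classes whose definition constrains few joints (a class that "uses" only
5 joints should not win against one matching on 14 merely because its
average runs over fewer terms).  Defaults p = 1, λ = 0.1.  The factor
1/Wai sits outside the p-th root exactly as in the defining formula; for
p ≠ 1 the "average deviation" reading is therefore only approximate, and
the implementation keeps the formula as printed rather than the
interpretation.  Classes with Wai = 0 are rejected: their metric is
undefined, and the random baseline redraws such rows.

Ties in the arg-min break towards the first class in definition-table
order, making classification invariant to prototype input order.

## Attribute estimators

One small CNN per joint maps a 1 s sliding window (60 samples at 60 Hz,
shift 30) of the joint's sensors' channels (10 per IMU: 3 acceleration,
3 gyro, 4 quaternion) to its attribute value.  Windows are 2-D
time-by-channel images convolved with 2-D kernels, so sensor modalities
mix from the first layer.  Architecture: four valid convolutions with
25, 20, 15, 10 feature channels (kernels 3x3; 3x10 for the sensor-dense
hands, which read the hand IMU plus seven finger IMUs), batch
normalisation and leaky ReLU (slope 0.1) after each, a 100-node fully
connected layer with dropout, then a softmax head with cross-entropy loss
or a sigmoid head with mean-absolute-error loss.  Optimisation is
momentum SGD (momentum 0.9).  The networks are written directly on numpy
(im2col convolutions, analytic backward passes verified against float64
central differences in the test suite) and run in float32.

Choices the architecture itself does not fix, all configurable in
`TrainConfig` and recorded in saved-model manifests: no padding, stride 1
on both axes; per-channel z-scoring of inputs from training statistics
(quaternion and acceleration scales differ by orders of magnitude);
He-normal initialisation; defaults epochs 20, batch 64, learning rate
0.01, dropout 0.5, seed 0.  Quaternion channels enter as plain channels
without re-normalisation.  Which IMUs feed which joint estimator is part
of the schema file (`sensor_ids`) and defaults to the physically adjacent
sensors (e.g. the left-elbow estimator reads the left upper-arm and
lower-arm IMUs); the hand estimators read 8 IMUs each, all other joints
1-2.  When a training subsample cap is applied, classification joints
are capped by stratified subsampling over target categories: joint
states used by few poses (a head held "up") would otherwise almost
vanish from the training set.

## Synthetic data

The generator produces data with the statistical structure the weighted
metric targets: subjects agree on a pose's diagnostic joints and vary
freely on the others.  A variation table lists, per pose, the admissible
alternative states of its free joints (e.g. squatting with elbows bent
or straight, hands normal or grasping); poses recorded as showing no
variation have no entry.  Where the observed variation names a generic
"elbow, hand" for a one-armed pose, it is encoded on the arm the pose
leaves free; for the heel-to-back poses, on the non-lifting arm.

Attribute-level sampling starts from the expanded definition row,
replaces each free joint by a uniformly drawn alternative, then adds
truncated-Gaussian noise (sd 0.05, truncated to [0, 1]) on regression
dimensions and resamples classification slices from a Dirichlet centred
on the one-hot target with mean modal mass 0.9 (pseudo-count scale 50).
With noise 0 the samples are exact symbolic realisations.  Defaults:
590 samples per class — matching roughly 59 windows per 30 s recording
times 10 subjects — noise sd 0.05, modal mass 0.9.

Signal-level generation synthesises recordings of a held pose: each
joint's (variation-perturbed, fixed per recording) state sets a constant
offset — the category index, or the regression value — on a dedicated
3-channel block of each of the joint's sensors, plus a 0.5 Hz sinusoidal
carrier (amplitude 0.2) and white noise (sd 0.1) on all channels.
Sensors shared by several joints give each client joint a disjoint
block, keeping every joint's state injectively readable.  Recordings
carry their realised per-joint states so estimator training targets
reflect the variation actually generated.  These signatures are
deliberately simple: they are learnable and state-separable, not
biomechanically realistic, and real sensor noise characteristics are not
modelled.  `confine_variation` restricts a variation table to each
class's zero-importance joints — the exact regime the weighted metric
assumes; the observed table violates it only for the waist-twisting
poses' head variation, which their importance rows keep diagnostic.

## Evaluation protocols

Leave-one-class-out ZSL: for each fold class c, prototypes are the data
means of all other classes plus the definition expansion of c; all of
c's samples are classified over the full 22-class label space (seen
classes stay candidate outputs, each scored with its own importance
row).  All folds' predictions are pooled into one confusion matrix —
each prediction is used exactly once and precision is well defined —
before computing per-class precision, recall, F = 2PR/(P+R) (0 where
P+R = 0) and the unweighted average F.  Whether per-class F should
instead be computed per fold is an open interpretation; the aggregate
was chosen and is flagged here.

k-shot: identical except the held-out class's prototype is the mean of k
of its own samples.  A seeded permutation is cut into floor(Nc/k)
disjoint k-subsets; fold l trains on subset l and tests on the remaining
Nc − k samples; remainder samples beyond the last full subset are never
used for training.  Fold confusion rows are averaged per class (counts
become fractional) before the cross-class computation.

Random-importance baseline: the ZSL protocol rerun with fair-coin binary
weights per (class, joint), all-zero rows redrawn, averaged over R
draws (default 1000; protocol demonstrations here use R = 100).

## Problem sizes used by the packaged runs

The demonstration corpora used by the test suite and the acceptance
script are reduced-size runs of the same generators: attribute-level
protocol corpora use 60–120 samples per class and R = 100 random draws;
the end-to-end signal run trains on 3 recordings x 8 s per class
(stratified caps of 400 windows per joint, 250 for hands; 6 epochs at
learning rate 0.01 for hands, 8 at 0.02 for all other joints) and
evaluates on 2 held-out recordings per class.  Full-scale runs (590
samples per class, 30 s recordings, R = 1000) are configuration changes
only.

## What passing tests do and do not show

The synthetic corpora establish internal correctness and direction of
effect: that the weighted metric beats the naive one exactly when
intra-class variation sits on non-diagnostic joints, that a carefully
designed importance table beats random tables, and that the advantage of
importance weighting shrinks as real training shots accumulate.  They do
not establish performance on real IMU data: synthetic signatures are far
more separable than real sensor signals, and synthetic attribute noise
is far cleaner than real estimator output.  One consequence is measured
and deliberate: with near-clean attribute vectors a single real sample
is already an excellent prototype under the weighted metric, so
zero-shot does *not* beat one-shot in the weighted column on the
attribute-level corpus (it does in the naive column, where a single
sample's variation variant misleads the full-space distance).  On real
data the reported advantage of definitions over single shots rests on
attribute-estimation noise, which the attribute-level corpus
deliberately under-represents.

## Known limitations

- Importance weights are taken as given; no inference of importance from
  data or external resources.
- Only static poses; no temporal models beyond the sliding window.
- The generalized-ZSL setting with seen-class test instances is out of
  scope, as is the DAP family of baselines.
- For p ≠ 1 the weighted metric is implemented as printed (1/Wai outside
  the root); it is not a normalised mean in that case.
- Dirichlet sharpness (pseudo-count 50) and signal noise (sd 0.1) are
  conventions chosen for learnability, not estimates of real hardware.
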