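# Methods

## The problem

Point-of-care ultrasound (FAST exam) screens trauma patients for free fluid —
anechoic (dark) collections that indicate internal bleeding — at standard
abdominal scan sites such as the pelvic/bladder view (BLD) and the right upper
quadrant (RUQ, Morrison's pouch). A sweep is exported as a fixed-length clip
(30 s at the native 30 frames per second, hence 900 frames) with one binary
label per clip. Any single frame is an unreliable witness of that label: the
fluid pocket is in the imaging plane only for part of the sweep, and healthy
anatomy produces transient anechoic look-alikes (rib shadows, edge dropout,
bowel gas). Sonographers resolve this by integrating over many frames and
angles; `fastpool` gives a CNN the same opportunity.

## Frame pooling

A clip is cut into windows of `n` consecutive frames taken at stride `s`
(training default `s=15`; window sizes of interest 1, 30, 90, 150). Start
indices are every multiple of `s` strictly below the clip length `T`, so there
are `ceil(T/s)` windows; windows that run past the last frame are completed by
repeating the final frame (repeat-padding preserves intensity statistics,
whereas zero padding would inject exactly the dark signal that means fluid).
Each window is stacked along the channel axis — frame order = channel order —
and the first convolution of the backbone is patched to accept `n` input
channels, so one prediction sees up to `n` sweep angles at once. At inference
the default recipe pools one 150-frame window per 30 s of video (stride 900).

For architectures with pretrained RGB weights, the patched first layer is
initialized by channel inflation: each output filter's kernel is the mean of
its three source-channel kernels, replicated across all `n` channels and
scaled by `3/n`. On a channel-constant (gray) input this reproduces the source
layer's response exactly (linearity of convolution), and the `3/n` factor
preserves the expected activation magnitude. The alternative is Kaiming
initialization of every weight from scratch.

## Aggregation, thresholds, comparison

Every window receives a 2-class softmax confidence pair. The video score is
the arithmetic mean of the positive-class confidences over its windows, and
the clip is called positive when the score reaches the confidence threshold;
a tie at the threshold is positive ("even a suspicion" of fluid is treated as
injury). Accuracy, precision, sensitivity and F1 are computed from the video-
level confusion counts; undefined ratios are reported as NaN with a flag,
never as 0. ROC curves are traced over the unique video scores (trapezoidal
AUC, cross-checked in the tests against the exhaustive pairwise Mann–Whitney
count). `threshold_sweep` evaluates a threshold grid and selects an operating
point by F1, Youden's J, or accuracy; externally chosen operating points
(e.g. 0.75 for the pelvic view, 0.05 for the RUQ view) are passed as
overrides.

Two models evaluated on the same clips are compared with the exact McNemar
test on the discordant counts `b` (only model A correct) and `c` (only model
B): `p = min(1, 2·P(X ≤ min(b,c)))`, `X ~ Binomial(b+c, ½)`; with no
discordant clips the test is degenerate and `p = 1`. The exact variant is the
right one at tens of clips; a continuity-corrected chi-square option is
provided for cross-checking.

## The backbone

No deep-learning framework ships with this package's environment, so the
network is a small, fully deterministic numpy CNN (`fastpool.nn`): three
3×3 stride-2 convolutions (widths 16/32/64) each followed by batch
normalization and ReLU, a global average+max pooling head, and a 2-logit
linear classifier, trained with Adam on softmax cross-entropy. Three design
elements matter for trainability from scratch and were chosen after the plain
conv/GAP variant showed a long loss plateau on weak localized cues:

* inputs in [0,1] are centered to [−1,1] inside the network;
* batch normalization after each convolution;
* the pooling head concatenates the global *max* with the global average, so
  a cue covering a few cells of the final 8×8 feature map is not diluted by
  averaging over 64 positions.

Because training batches are augmented while inference inputs are not, batch-
norm running statistics are re-estimated on unaugmented training windows
after the final epoch (no parameter updates) — without this, video-score
scales drift between training and evaluation.

The EfficientNet-B0/B2 names are accepted by the configuration surface but
rejected with a clear error: materializing them requires a pretrained model
zoo. The channel-inflation rule itself is a pure weight transform and is
exercised against synthetic RGB source kernels.

## Training recipe

`TrainConfig` defaults follow the standard recipe for this task: batch 32,
Adam at learning rate 0.001, early stopping after 10 non-improving validation
epochs, at most 100 epochs — doubled to 200 when initializing from scratch
with Kaiming draws, which needs longer. Early stopping and best-epoch
selection monitor the *video-level* validation loss (cross-entropy of the
mean positive confidence per validation video against the video label):
window-level validation loss is dominated by cue-free windows of positive
videos, whose inherited labels are inherently noisy, and systematically
prefers undertrained models; the video score is what the pipeline ultimately
thresholds. Window-level validation loss and accuracy are still recorded in
the history. (The source recipe is ambiguous about
whether frame-pooled training resumed from pretrained weights or kept the
scratch initialization; both modes are implemented and selected by
`TrainConfig.init`.) Subjects are split 80/20 into train/validation within
each capture group (group-stratified), never across: a subject contributes
windows to exactly one side, asserted on every split.

Augmentation draws one random resized crop (area 80–100 %, aspect ratio
3:4–4:3), one brightness/contrast jitter (±20 %/±10 %), and one horizontal-
flip decision (p=0.5) per *window* and applies them identically to every
channel; per-frame augmentation would destroy the temporal structure pooling
relies on. Saturation jitter is drawn for parity but is a no-op on single-
intensity channels.

## The synthetic sweep generator

Real data are restricted, so `fastpool.synthetic` emulates the capture: 8-bit
grayscale sweeps with a bright tissue field (mild depth gradient), a dark
elliptical organ whose center drifts sinusoidally (probe motion, amplitude
2 px) and is jittered per video (probe placement, ±0.08 of the field),
multiplied by unit-mean Rayleigh speckle smoothed at the point-spread scale
(σ=0.8 px). Positive clips render an anechoic crescent in the dependent space
below the organ with intensity depressed by `fluid_contrast` (default 0.35),
visible in exactly `round(fluid_visibility_fraction·T)` frames as one
contiguous block whose depression ramps in and out (half-sine with floor 0.3)
— the pocket entering and leaving the imaging plane.

Both classes additionally carry transient anechoic artifacts with three
deliberate properties. First, the per-video artifact burden is drawn from
Uniform(0, 2·`artifact_rate`) (default mean 20 % of frames): shadow and
bowel-gas burden varies strongly between subjects and operators, so the rate
of dark events in one sweep carries no class information. Second, each event
(1–3 frame lifetime) is an arc — most anchored to the organ's rim in the
lower half-plane, where posterior and edge shadowing physically occur and
where fluid also collects; the rest free-floating — so on a single frame an
artifact matches a fluid pocket in shape, darkness, size *and location*.
Third, placement is identical in distribution for both classes. The
consequence is that no single-frame feature separates the classes reliably,
while a pooled window separates them trivially: the fluid cue persists across
consecutive channels at one location, artifacts flicker for a frame or two.
This persistent-vs-transient asymmetry is the multi-angle context a
sonographer uses and is the mechanism by which multi-frame pooling recovers
the clip label.

The generator also emits a per-frame ground-truth cue mask and the clean
background map as a side channel for oracle tests; the classifier path never
sees them. What the generator does *not* model: acoustic physics (attenuation,
time-gain compensation, refraction), anatomical realism of bladder/kidney
geometry, variable clip lengths, and operator behavior. Passing tests
therefore demonstrate the pipeline's correctness and the pooling mechanism
under controlled conditions, not clinical performance.

## The scaled-down pooling study

The replicate study (`pooling_benefit_experiment`,
`tests/test_acceptance.py`) runs at desk scale: 8 subjects × 4 videos,
64×64 px, T=90 frames, fluid visible in 20 % of frames, 5 replicate seeds.
Subjects form two capture groups, so the group-stratified 80/20 split yields
6 training subjects (4 fit + 2 early-stop) and 2 held-out subjects (8
videos). Per replicate, a 15-frame/stride-3 model and a single-frame model
are trained identically (Kaiming scratch, Adam at 3·10⁻³, batch 32, 30
epochs — the learning rate and length are this package's choice for the
small backbone at this resolution) and evaluated on the held-out subjects'
videos, scoring windows at stride 1. Following the real-time evaluation
protocol — where the operating threshold is identified on the evaluation
sweep itself — each model is measured at its optimal confidence threshold on
the held-out videos, so the comparison reflects how well the video scores
discriminate. The claim under test: the pooled model's video accuracy is
strictly higher in at least 4 of 5 seeds.

## Numerical and degenerate-input choices

* Frame counts must come out integral from `fps·duration_s`; anything else is
  a configuration error, as are images below 32 px or fractions outside
  [0, 1].
* A video shorter than the window size yields a single fully padded window,
  not an error; heavily padded training windows are kept.
* Padded windows contribute to the video average with equal weight.
* Ties: video score exactly at threshold → positive; threshold-sweep ties →
  lower threshold; window argmax ties in the max-pool backward route the
  gradient to the first maximum (numpy argmax).
* All randomness flows through seeded `numpy.random.Generator` instances;
  identical config + seed reproduces frame buffers, training histories and
  prediction CSVs byte-for-byte (single-threaded).
* Checkpoints are `.npz` archives holding every weight, the batch-norm
  running statistics, and the full train/augment/windowing configuration.

## Known limitations

* The numpy backbone is orders of magnitude smaller than EfficientNet-B2;
  absolute accuracies at desk scale are not comparable to GPU-scale results.
* The exact McNemar p-value is the doubled-tail convention, capped at 1; at
  `b+c=0` the comparison carries no information (flagged `degenerate`).
* The generator's artifact and speckle models are first-order; they produce
  the right *difficulty structure* (per-frame ambiguity, persistent-vs-
  transient cues) rather than physically accurate images.
* Group stratification follows the manifest's `group_tag`; a group with one
  subject cannot be split and is assigned to training with a warning.
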