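# Methods

## The model

`lazyvwfa` simulates how a location-invariant word recogniser can retain
decodable information about *where* a word was seen.  The system under
study is a three-layer feedforward network:

- **Input layer** — a retinotopic bank of localist letter detectors:
  10 horizontal × 7 vertical letter slots × 26 letters = 1820 binary
  units.  A four-letter word placed with its leftmost letter at grid
  coordinate (x, y), x, y ∈ 1..7, activates exactly four units (its letters
  at slots x..x+3 of row y).  Unit indexing is slot-major then letter:
  `((h−1)·7 + (v−1))·26 + letter`.
- **Hidden layer** — 50 sigmoid units, fully connected, no spatial
  organisation.  This layer is the model analogue of the visual word form
  area (VWFA): whatever location information survives here does so without
  any built-in retinotopy.
- **Output layer** — one sigmoid unit per vocabulary word (localist
  coding).  Recognition is argmax over output units, ties to the lowest
  index.

Training is plain online backpropagation of the squared error
E = Σ(t−o)²/2, one pattern at a time, words shuffled every epoch.  Initial
weights and biases are i.i.d. uniform on [−0.5, 0.5].

### Stimulus statistics and stopping rule

Word locations emulate reading fixations: each word's placement is drawn
from a 2-D normal centred on (4, 4) with σx = 2.5 and σy = 1.5 grid units,
rounded to integers, redrawn (not clipped) until it lands on the 7×7 grid
— clipping would pile probability mass onto the edges and distort the
exposure profile.  Placements are redrawn every 5 epochs.  Training stops
at the first epoch after which every word is recognised when presented at
the central location; a `radius1` criterion (centre plus its four
neighbours) is available in `RegimeConfig` but not used by default.

### Main-network learning rate

The backpropagation learning rate is the one substantive free parameter
of the simulation.  At lr ≤ 0.1 the network stalls indefinitely short of
criterion (the classic sigmoid/SSE output-saturation plateau: all outputs
are driven toward 0 and the error gradient vanishes).  Rates between 0.5
and 4 all converge, in roughly 600–1600 epochs for a 100-word vocabulary,
and shift the mature hidden-layer decoding levels by only a few points.
The default is **lr = 2.0**, at which networks reach criterion in ~600–800
epochs and the mature 6-class decoding accuracies and adjacency statistics
sit closest to the levels this model is known to produce.

Lexicons containing anagram pairs are the exception: at aggressive rates a
pair can cycle indefinitely — one member keeps flipping at the criterion
check each time the pair is relocated — so the anagram experiment uses its
own regime (**lr = 0.5**, ~2000 epochs to criterion; `anagram_regime` in
`ExperimentConfig`), and very small mixed vocabularies (≲50 words) need
gentler still (~0.25).  Even then an occasional weight initialisation
fails to settle within the epoch budget; the experiment runners discard
such an initialisation and train a fresh one (at most two replacements per
network, logged), which biases nothing but the initial-weight draw.

## Synthetic vocabularies

The generator (`generate_lexicon`) emulates the study's stimuli: N unique
lowercase four-letter words, drawn from an embedded pool of common English
words for face validity, with controlled anagram structure.  Exactly
`n_anagram_words` of them form disjoint anagram pairs (each annotated word
has exactly one partner that is a permutation of its letters); all other
words are pairwise non-anagrammatic by letter-multiset construction.  When
the pool cannot satisfy a request, partners are built by permuting a pool
word's letters, and random letter strings are the last resort, so requests
are feasible up to the combinatorial limit.  Only the letter-overlap
structure of the vocabulary matters to the simulations; word frequency and
orthographic-neighbourhood structure are deliberately not modelled.

## Location decoding (the MVPA analogue)

For a given network and axis, patterns are collected for words at 6 probe
placements per axis — coordinate ∈ {1, 2, 3, 5, 6, 7} with the other
coordinate fixed at 4.  The central position is excluded: it is the only
choice that leaves six positions forming two symmetric halves.  Per run,
40 words are sampled, yielding 240 labelled patterns (the raw 1820-dim
binary encodings for the input layer, the 50-dim sigmoid activations for
the hidden layer).

**Measurement noise.** Gaussian noise with mean 0 and amplitude (standard
deviation) 0.025 is added element-wise to every pattern, fresh per run,
before the train/test split — both halves are "acquired" noisily.  The
0.025 amplitude is the package's noise convention: at this level the
input-layer decodabilities reproduce the levels this architecture is
reported to support (2-class at ceiling, 6-class near ceiling), whereas an
amplitude of √0.025 ≈ 0.16 makes even an optimal linear read-out of the
sparse binary input patterns impossible at those levels.

**Classifier.** A linear perceptron (L output units, no bias, no output
nonlinearity) trained by the online delta rule Δw = r·(t−y)·x with
localist 0/1 targets, r = 10⁻⁴, on all but 6·L patterns; the held-out
6·L patterns (stratified, 6 per class) measure generalization.  Initial
weights are uniform on ±0.01 and training runs 2000 epochs.  These two
values are chosen so that the delta rule reaches its asymptotic
generalization accuracy (validated against the exact least-squares
solution on the same splits): with a large initialisation the random
weight component outside the span of the training data never decays and
acts as frozen read-out noise, and at r = 10⁻⁴ several hundred epochs are
needed before the low-variance directions of the pattern covariance are
fit.  Undertraining, not overfitting, is the failure mode of this
classifier.  Each battery repeats word sampling, noise, split and
initialisation for 10 runs and reports mean, SEM, and the summed held-out
confusion matrix.  The inner loop is compiled with numba when available
(pure-numpy fallback, identical update order).

**2-class vs 6-class.** L = 6 maps the six probe positions to six classes;
L = 2 groups the first three (left/up) against the last three
(right/down), with 12 held-out items instead of 36.

## Confusion-matrix summaries

For a 6-class confusion matrix C (rows = true class, columns = guess):

- accuracy = trace(C)/ΣC;
- adjacent share = off-diagonal mass at |guess−true| = 1 divided by total
  off-diagonal mass; reported as 1.0 with a `defined=False` flag when
  there are no misclassifications;
- adjacency index `AI = sqrt(max(0, 1−μ/μᵤ)·max(0, 1−σ/σᵤ))` where μ, σ
  are the mean and population SD of the absolute error |guess−true|
  pooled over items, and μᵤ, σᵤ the same moments under a uniform confusion
  matrix with the same true-class margins.  AI is 1 for an identity
  matrix, 0 for a uniform one, and scale-invariant (property-tested).
  Moving error mass to a nearer off-diagonal cell always lowers μ and in
  typical cases raises AI, but not universally: when the move takes an
  error away from the bulk of the error distribution, σ can grow enough
  for AI to dip — the index is a summary, not a partial order.  The
  moments use absolute rather than signed errors; the formula is isolated
  in a single function so an alternative convention can be swapped in.

## Experiments and problem sizes

- **mature** — 10 networks, one shared 100-word lexicon; input and hidden
  layers × both axes × L ∈ {2, 6}.
- **timecourse** — snapshots during training, thinned to an adaptive epoch
  grid (step doubles whenever more than 64 copies are held, keeping
  memory bounded at ~55 MB) from which 20 evenly spaced milestones (epoch
  0 to the final epoch) are selected; hidden decoding and central
  recognition at each milestone.
- **vocab** — 10 networks per vocabulary size ∈ {50, 100, 150, 200, 250},
  hidden decoding only.
- **anagram** — networks trained on 50 normal words + 25 anagram pairs;
  separate classifiers decode anagram-word and normal-word patterns.

`scripts/acceptance.py` runs the mature battery at full scale (10 networks
× 10 runs) and the vocabulary-size endpoints (50 and 250 words) and the
anagram simulation at 3 networks each.  The input-layer conditions are
computed from 30 pooled classifier runs rather than a per-network loop:
input patterns do not depend on the trained weights, so repeating them per
network is pure replication.  The test suite reruns the same pipelines at
further reduced scale (4 networks, 5 runs) and checks effect structure.

Every random draw (lexicon, weight init, placements, word sampling, noise,
splits, classifier init) derives from one master seed through spawned
`numpy` substreams; a rerun with the same seed reproduces every number.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the simulations need —
letter-position overlap between words, controlled anagram structure,
fixation-like location statistics — but not lexical frequency, word
neighbourhoods, visual acuity gradients, hemifield split, or cortical
magnification.  Passing tests therefore establish the learning-dynamics
claims (location sensitivity present before learning, peaking early,
traded away with training load, concentrated on confusable items), not
any claim about fits to human measurements.

## Known limitations

- The **early sensitivity burst** — a transient rise of hidden-layer
  location decodability after the first weight updates, before the long
  decline — is only vestigial here: under the 0.025 noise amplitude the
  untrained hidden patterns already decode near their ceiling (~75–80%
  for 6 vertical classes), and the epoch-0→epoch-1 change averages under
  one point (sign flips between networks) at every learning rate probed
  (0.25–2.0).  A pronounced burst would require a noise level high enough
  to suppress the untrained baseline — rising activation amplitudes
  during learning would then lift the patterns out of the noise — which
  is incompatible with the noise level the input-layer decodabilities
  demand.
- Hidden-layer **2-class** decoding accuracies plateau around 69–73%
  across every configuration probed (main-network lr 0.5–8, classifier at
  asymptote), several points below the ~77–80% this model is reported to
  reach, while the 6-class accuracies, adjacent shares and AI values are
  reproduced.  Raising residual location sensitivity (faster convergence)
  pushes the 6-class vertical accuracy out of range before the 2-class
  values arrive; the trade-off appears intrinsic at these conditions.
- The delta-rule classifier is run past its printed-protocol scale to
  reach asymptote (see above); results are insensitive to further epochs.
- Single lexicon per experiment: networks within an experiment share the
  vocabulary and differ only in initial weights and location draws.
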