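# Methods

This note records the model, the defaults and the design decisions behind
`gatewave`, and what its synthetic test-bed does and does not establish.

## Model and training procedure

The reconstructor is a single-hidden-layer autoencoder with logistic
sigmoid activations on both layers. One training sample is one EEG segment
flattened channel-major (channels × samples); the hidden width defaults to
half the flattened width, making the code under-complete. A binary gate θ
zeroes the blocked (DV) channels at the input; the loss is the per-feature
weighted squared error of the output against the **ungated** sample, so
gradient descent must route information from the present channels into the
blocked ones. Per-channel min–max normalisation to [0, 1] (statistics from
the training split, reapplied at inference) matches the sigmoid output
range and makes "accuracy = (1 − RMSE)·100%" well defined.

**Curriculum.** A curriculum fixes a gate mechanism and a DV count `n_dv`;
each sample is visited under every lesson, the lessons being consecutive,
non-overlapping blocks of the mechanism's channel sequence. Because the
lesson count is `floor(N / n_dv)`, the trailing `N mod n_dv` channels of
the sequence are never blocked within that curriculum; users who need full
coverage can rotate the sequence.

**Optimiser updates.** Adam throughout. Two update modes exist:

- `aggregate` (default): the gradient is accumulated over *all* lessons for
  each minibatch and applied as one step. The objective is stationary
  across steps, which keeps Adam's second-moment estimate meaningful; a
  sequential per-lesson variant was observed to freeze — the irreducible
  reconstruction errors of hard lessons inflate the second moment and
  shrink the effective step size several-fold.
- `interleave`: one sequential step per lesson in the order of the gate
  sequence, rotated round-robin across batches. In this mode the *ordering*
  of the mechanism genuinely enters the dynamics; it exists because under
  `aggregate` the gradient sum is order-invariant, so single-DV curricula
  produce bit-identical models for every mechanism. The curriculum-ordering
  experiment therefore uses `interleave`.

**Error-weight schedule.** DV channels carry weight
`floor + (initial − floor)·exp(−epoch/τ)`, IDV channels weight 1. Defaults:
initial 2, floor 1, τ = epochs/10. A lesson-balanced variant (initial equal
to the lesson count) was evaluated and is expressible through the public
parameters, but the milder default is kept: on data with many mutually
independent channels the balanced schedule amplifies pressure to fit
irreducible noise as much as it amplifies genuine dependency learning.

**Validation and early keeping.** A seeded 20% of the fit data tracks a
masked reconstruction MSE (mean over lessons); with `early_keep_best` the
weights at the validation minimum are returned. Loss and activations are
checked finite every epoch; non-finite values raise an error naming the
epoch rather than returning a NaN history. Full-scale defaults follow the
original configuration (Adam, learning rate 1e-5, 10 000 epochs, batch
1024); all reduced-scale runs below use larger rates at fewer epochs.

## Gate control mechanisms

Sequences are generated from montage geometry by rule, never hard-coded;
the published 19-channel orderings serve as the regression test of the
rules. Order-based: left-hemisphere channels by (anterior→posterior row,
then left→right within the row), then midline, then the right hemisphere
the same way. Partition-based: lobe bands in the order fronto-polar,
frontal, central/temporal, parietal, occipital; left→midline→right inside
each band. Hemispheric symmetry rotation: within each lobe band, homologue
pairs outer-first, each left electrode immediately followed by its
even-numbered partner, midline electrodes after their same-row pair.
Homologues pair labels sharing a prefix with numbers (2k−1, 2k). The random
mechanism draws one seeded permutation per curriculum (not per epoch), so
ordering is the only variable separating it from the structured
mechanisms. The 29-channel extended layout adds FC3/FCz/FC4, CP3/CPz/CP4,
PO3/POz/PO4 and Oz — a symmetric, fully homologue-pairable 10-10 subset.

## Synthetic EEG generator

Sources emit band-limited noise (white noise restricted to a band in the
spectral domain), mixed into electrodes with gain
`amplitude · exp(−distance/mixing_decay)` on a planar head map, plus a
mirrored term scaled by `symmetry ∈ [0, 1]` and per-channel Gaussian sensor
noise. This reproduces the two statistical facts the gating mechanisms rely
on — correlation decaying with inter-electrode distance, and elevated
homologue-pair correlation under symmetry — with full seed determinism.
It does not model spherical geometry, realistic lead fields, artefacts,
event-related structure or nonstationarity; conclusions drawn on it are
about the algorithmic machinery, not about physiological EEG.

The planted-dependency harness makes all channels but one independent
band-limited processes and sets the target to a fixed convex combination of
its three nearest neighbours plus Gaussian noise (stored in provenance for
oracle checks), so recovery has an exact noise floor.

## Reduced problem sizes

Training-heavy studies run on segments of 0.5 s at 16 Hz (8 samples per
channel; 152-dimensional flattened input for 19 channels), chosen so the
full curriculum experiments complete in minutes on one CPU while keeping
genuine band-limited structure. Adam learning rates of 1e-3 to 1e-2 pair
with epoch counts of 150–600 at this scale. The spectral-fidelity run uses
2-s segments at 32 Hz so 1-s Welch windows resolve the delta–beta bands.

## Observed limits of the reduced-scale test-bed

Two documented behaviours of the harness are worth stating plainly:

- **Recovery floor with independent channels.** When 18 of 19 channels are
  mutually independent, their irreducible reconstruction errors share the
  under-complete representation with the one genuine dependency. The best
  *shared* linear readout over all single-DV lessons then has a blocked-
  target RMSE of ≈0.084 on this data (a mask-aware readout reaches 0.021),
  and 500-epoch training lands at ≈0.065–0.085 — about 3–4× the noise
  floor, and the value the planted-recovery acceptance check measures. With
  a small fully inter-dependent layout (the 4-channel configuration in the
  test suite) the same pipeline recovers the blocked target within twice
  its noise floor, confirming that the gap is a property of the
  independent-channel harness, not of the implementation.
- **Ordering effects.** On fully symmetric synthetic data the paired
  difference between the hemispheric-rotation and random curricula is of
  the order ±0.003 RMSE with no consistent sign across training regimes.
  The ordering comparison is still exercised end to end (10 paired seeded
  runs, interleaved updates, a common single-channel-deletion evaluation so
  that mask difficulty cannot confound the comparison) and its sign test is
  reported as computed.

## Integration check on recorded EEG (not run here)

The pipeline accepts 64-channel, 160 Hz EDF recordings restricted to the
19- or 29-channel montages. On such data, after full-scale training
(10 000 epochs, learning rate 1e-5), blocked-channel reconstruction
accuracy is expected to exceed 91% for up to 10 missing channels;
this is an integration-level expectation for real recordings, not part of
the automated suite, which is synthetic-only by design.

## Known limitations

- Exact 0/1 endpoints of min–max normalisation demand unbounded output
  logits; the last fraction of a percent of reconstruction error near the
  per-channel extremes is irreducible for a sigmoid output layer.
- Organic training divergence is essentially impossible for this
  architecture (saturating sigmoids bound the loss); the non-finite guard
  is defensive.
- The Wilcoxon comparison uses the exact null for ≤25 informative pairs and
  the continuity-corrected normal approximation above; ties are handled by
  zero-difference exclusion, and an all-tied comparison is reported as
  degenerate without a p-value.
- Band-power nRMSE normalises by the mean original band power of the band;
  under-trained models systematically shrink reconstructed variance, so
  nRMSE falls with training length.
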