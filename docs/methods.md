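# Methods

`countda` transfers a holistic counting model — a network that maps an RGB
image directly to a real-valued object count, without localisation or density
maps — from a labelled *source* domain to an unlabelled *target* domain that
differs in two ways at once:

* **covariate shift**: the target images look different (colour, object size,
  texture), so source-trained features mis-fire on them;
* **label gap**: the target count range `[a', b']` contains values the source
  range `[a, b]` never produced, so even perfectly transferred features feed a
  regressor that was never trained to emit those numbers.

## The three-stage pipeline

**Stage A — supervised pretraining with label normalisation.**
A feature extractor `phi_S` and a regressor head `R` are trained on the source
domain with an MSE loss after mapping every label through
`y <- (y - a) / (b - a)`, where `[a, b]` is the source-label range.  The
network therefore learns to regress into `[0, 1]` regardless of the absolute
count scale; this single affine change is what makes the label gap tractable,
because the target range will later be restored by fine-tuning rather than by
asking the network to extrapolate counts it has never seen.  Early stopping
monitors the validation MSE on the original count scale with the same patience
as stage B (10 epochs).

**Stage B — adversarial feature alignment.**
`phi_S` and `R` are frozen.  A target extractor `phi_T` starts as a copy of
`phi_S` and plays a GAN-style game against a discriminator `D`: `D` is trained
with cross-entropy to output 1 on `phi_S(source)` ("real") and 0 on
`phi_T(target)` ("fake"); `phi_T` is trained to make `D` output 1 on its
features.  One discriminator step then one generator step per paired batch.
The generator objective carries an extra term

    L_gen = E_t[-log D(phi_T(t))] - lambda * Var(R(phi_T(t)))

The subtracted variance term (population form, weight `lambda`, default 0.1)
pushes against *posterior collapse*: a degenerate alignment where every target
image maps to the same prediction.  Collapse is a real failure mode here
because the discriminator can be fooled by features compressed into a small
region of feature space, and nothing else in the unsupervised game penalises
that.

**Stage C — few-shot fine-tuning.**
`R` (alone; `phi_T` stays frozen, an `unfreeze_backbone` switch exists) is
fine-tuned on k labelled target images (default 50, and k=10 is enough in the
label-budget sweep) against *raw* counts.  Because stage A trained `R` into
`[0, 1]`, this step simultaneously restores the target scale `[a', b']` — there
is no explicit denormalisation anywhere in the pipeline.

## Label-free stopping for stage B

Adversarial adaptation has no validation loss, so two unsupervised statistics
are tracked per epoch on held-out batches:

* **MMD²** between `phi_S(source)` and `phi_T(target)` features — the biased
  kernel two-sample estimator
  `(1/M²)Σk(x,x') + (1/N²)Σk(y,y') − (2/MN)Σk(x,y)`, RBF kernel with a
  median-heuristic bandwidth.  The bandwidth is computed once at the first
  evaluation and then frozen, so the statistic is comparable across epochs.
* **GGO**, the GAN global-optimality deviation `|E[D(z)] − 1/2|` over pooled
  source and target features: at the adversarial optimum the discriminator
  outputs 1/2 everywhere, so distance from 1/2 measures distance from that
  optimum.

Each statistic keeps its best value; a strict improvement (tolerance `1e-6`,
ties do not count) resets its counter.  Training stops when **both** counters
reach the patience (10 epochs).  On stop, `phi_T` is restored from the epoch
with the best MMD (ties broken by GGO); in the single-signal ablation modes
the restored epoch follows the active signal.  Since the epoch-0 state (no
adaptation) is itself a candidate snapshot, a failed adversarial run degrades
gracefully to the unadapted extractor rather than to a worse one.

The joint rule matters in practice: MMD traces at desk scale show an initial
transient where the discriminator warms up and MMD rises before the generator
pulls it into the characteristic U-shape.  An MMD-only patience rule can quit
inside that transient; the GGO signal, which keeps improving while the game
approaches its optimum, keeps training alive through it (and vice versa).

## Architectures

The regressor and discriminator are three-layer dense stacks
`F -> F/2 -> F/4 -> 1` (ReLU/ReLU/linear for `R`; LeakyReLU(0.01) twice and a
sigmoid for `D`), i.e. `2048 -> 1024 -> 512 -> 1` at full scale and
`128 -> 64 -> 32 -> 1` at the desk scale used throughout the tests.  The
feature extractor is a four-block strided 3×3 convolutional network
(channels `F/8, F/4, F/2, F`, stride 2 per block) with global average pooling.
All network machinery — layers, backpropagation, Adam — is a small
deterministic NumPy engine (`countda.nn`): float32 forward/backward passes
with seeded He-normal initialisation, bit-reproducible given the same seed,
which the checkpointing and the end-to-end determinism guarantees rely on.
Global average pooling makes the backbone nearly additive in object count,
which is exactly the inductive bias a holistic counter needs.

## Preprocessing

Images are resized to the configured side (default 64), histogram-equalised
jointly over the three channels (per image; joint rather than per-channel
equalisation preserves relative colour structure — per-channel equalisation
would amplify noise in near-empty channels into full-range artifacts), then
mapped to `[-1, 1]`.  Training-time augmentation is horizontal/vertical flips
plus multiplicative colour jitter.

## The synthetic scene generator

The generator renders fluorescence-microscopy-like scenes: Gaussian-profile
discs (optional cytoplasm-style ring halo) on a dark noisy background, placed
by rejection sampling with a hard non-overlap constraint and a packing-bound
validity check (at most half the image area in effective disc area; placement
failure raises rather than silently dropping objects).  Counts are drawn
uniformly over the configured range — the count distribution inside the range
is a free design choice here, as is the zero-overlap default; both are
configuration knobs.  Because blobs never overlap, the stored label provably
equals the number of connected foreground components of the noise-free
render, which the tests verify with an independent connected-component
labelling oracle.

A domain pair is built by perturbing a source scene specification along the
two shift axes: appearance (colour, size, halo — covariate shift) and count
range (label gap).  The desk-scale reference pair used by the test-suite and
the acceptance script is:

| | source | target |
|---|---|---|
| counts | [3, 8] | [6, 12] |
| colour | blue | red |
| radius | 4–6 px | 3–4.5 px |
| halo | off | on |
| images | 300 (55/20/25% train/val/test) | 300 |

at 64×64 pixels with feature dimension 128.  These sizes keep one full seed of
the study (pretraining, four adaptation variants, both bounds, fine-tuning,
sweep) at a few minutes on one CPU.

What the generator does *not* emulate: photometric realism, occlusion and
overlap, perspective, intra-class shape variation, annotation noise.  Desk
scale transfers surprisingly well even without adaptation — a global-average-
pooling counter largely counts foreground area, which survives this colour
shift — so upper-bound failures here are much milder than on real data.  What
passing tests show is therefore the *direction* of the effects (adaptation
plus fine-tuning moves the error from the no-adaptation bound toward the
supervised bound; the variance regulariser inflates target-output variance;
ten labels already restore the target scale), not the magnitudes of the gaps;
on individual seeds the no-adaptation bound can even sit at the task's noise
floor, where no adaptation method can strictly improve on it.

## Evaluation

With `eps_i = y_i − round(yhat_i)` (half-away-from-zero rounding, applied only
inside metrics — models always predict reals): mean/std of `|eps|`, mean/std
of `eps`, mean of `eps²`, and the percentage of exact agreements.  Standard
deviations are population form.  `evaluate_bounds` brackets the pipeline
("Ours") between the **upper bound** — the pretrained source model applied to
the target with its outputs mapped back through the *source* normaliser, no
adaptation — and the **lower bound** — a model trained fully supervised on the
target.  (The source paper's upper-bound numbers are large enough to suggest
raw normalised outputs were scored there instead; we denormalise so that the
upper bound coincides with the lower bound when source and target are
identical, which makes the bracket interpretable.)  `label_budget_sweep`
re-runs stage C per label budget k from the same adapted checkpoint with
seeded subset draws.

## Numerical and design choices

* `lambda = 0.1` by default; the regulariser must be explicit and sweepable
  since its weight is otherwise unidentified.
* Desk-scale optimisation: Adam throughout; pretraining/fine-tuning at 2e-3;
  stage B at 3e-4 (discriminator) and 2e-5 (generator).  The asymmetry is
  deliberate: with faster generator rates the discriminator overpowers the
  game and MMD rises monotonically from epoch 0, so the monitors correctly
  refuse to adapt; the slow generator produces the U-shaped MMD curve the
  stopping rule is designed around.
* Cross-entropy probabilities are clipped at `1e-7`; MMD is computed in
  float64 and clipped at zero against negative round-off.
* Degenerate inputs fail loudly: constant source labels (no normaliser),
  empty batches/splits, batch size 1 with the variance regulariser, NaN
  losses or monitor values.
* Report CSVs are written with `%.17g` and read with pandas' round-trip
  parser, so write→read is value-identical and reruns are byte-identical.

## Known limitations

* The scene generator's simplicity caps how much covariate shift can hurt a
  desk-scale counter; upper-bound degradation is correspondingly mild.
* The probe accuracy reported by the acceptance script (a freshly trained
  discriminator on frozen features) measures linear-ish separability, which
  adversarial alignment does not directly minimise; it can stay high even
  when MMD drops.
* The choice of snapshot to restore at stopping is under-determined by the
  joint rule; we restore the best-MMD epoch (GGO breaking ties).  At desk
  scale the best-GGO epoch generalises comparably — differences are within a
  few rounding quanta of a 75-image test split — so the selection rule's
  effect is only measurable at larger problem sizes.
* Only the cross-entropy adversarial loss is implemented; least-squares and
  Wasserstein variants are out of scope, as are density-map heads and the
  ImageNet-initialised ResNet-50 backbone of the full-scale setting.
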