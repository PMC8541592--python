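# countda

Semi-supervised domain adaptation for **holistic counting**: transferring an
image-to-count regression model `f(x) -> y` from a labelled source domain to a
target domain that both *looks* different (covariate shift) and *counts*
different (label gap — the target range `[a', b']` contains values the source
range `[a, b]` never produced).  Typical users: people counting cells in
microscopy, leaves in plant phenotyping, or pedestrians in surveillance
footage, who have labels for one imaging setup and want the model to work on
another.

## Method

Three stages:

1. **Pretraining.** Feature extractor `phi_S` and regressor `R` are trained on
   the source with an MSE loss after normalising labels
   `y <- (y - a)/(b - a)` into `[0, 1]`, which removes the absolute count
   scale from the regression target.
2. **Adversarial alignment.** With `phi_S` and `R` frozen, a target extractor
   `phi_T` (initialised from `phi_S`) is trained so a discriminator `D` cannot
   tell `phi_T(target)` features from `phi_S(source)` features
   (cross-entropy GAN objective), plus a variance regulariser
   `-lambda * Var(R(phi_T(x)))` that prevents posterior collapse.  Training
   stops when neither of two label-free monitors — the kernel two-sample
   statistic `MMD^2(phi_S(X_S), phi_T(X_T))` and the GAN-optimality deviation
   `GGO = |E[D(z)] - 1/2|` — has improved for 10 epochs; the best monitored
   snapshot is restored.
3. **Few-shot fine-tuning.** `R` is fine-tuned on k labelled target images
   (k = 50 by default; k = 10 already works) against raw counts, which
   restores the target scale `[a', b']`.

Evaluation uses the counting metrics based on `eps_i = y_i - round(yhat_i)`:
|DiC| (mean |eps|), DiC (mean eps), MSE (mean eps^2) and % exact agreement,
with the pipeline bracketed between the no-adaptation transfer of the
pretrained model (UB) and fully supervised training on the target (LB).

The package ships a synthetic scene generator (non-overlapping Gaussian-disc
"cells" with configurable colour, size, halo and count range) so the whole
pipeline runs and is testable at desk scale; all network machinery is a small
deterministic NumPy engine (`countda.nn`).  See `docs/methods.md` for the
science and the design choices.

## Worked example

```bash
countda generate examples/toy_t3.yaml data/toy
countda run examples/run_toy.yaml --stage all
```

`generate` renders 300 images per domain (blue cells counting 3–8 vs smaller
red haloed cells counting 6–12) with CSV manifests.  `run` executes all three
stages and the evaluation, writing checkpoints (`pretrained.npz`,
`adapted.npz`, `finetuned.npz`), per-epoch training logs, the resolved config
and `evaluation.csv` into the run directory.  With seed 0 it prints:

```
pretrain: best val MSE 0.3199
adapt: stopped after epoch 45, restored epoch 35
finetune: k=50, final train loss 0.4761
condition  abs_dic_mean  abs_dic_std  dic_mean  dic_std      mse  pct_agree  n
       UB      0.880000     0.747618 -0.160000 1.143562 1.333333  34.666667 75
     Ours      0.813333     0.604281  0.093333 1.008938 1.026667  29.333333 75
       LB      0.760000     0.607509  0.200000 0.952190 0.946667  33.333333 75
```

Reading: pretraining converges to ~0.32 MSE on the source; the stopping rule
restores the adaptation epoch with the best monitored alignment; and the
adapted + fine-tuned model ("Ours", MSE 1.03) closes most of the gap between
the no-adaptation transfer of the source model (UB, 1.33) and fully
supervised training on the target (LB, 0.95).  Ablation switches
(`--no-variance-reg`, `--stop-mmd-only`, `--stop-ggo-only`) and
`countda sweep --k 10,20,50` reproduce the regulariser/stopping-rule ablation
and the label-budget analysis.

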