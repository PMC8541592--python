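"""The three-stage adaptation pipeline for holistic counting.

Stage A (:func:`pretrain`) trains a feature extractor ``phi_S`` and regressor
``R`` on the labelled source domain with an MSE loss, after mapping the source
labels from their native range [a, b] to [0, 1] — the label-normalisation step
that removes the label gap from the regression target.

Stage B (:func:`adapt`) freezes ``phi_S`` and ``R``, clones ``phi_S`` into a
target extractor ``phi_T``, and trains ``phi_T`` adversarially against a
discriminator ``D``: ``D`` learns to score source features as real (label 1)
and target features as fake (label 0); ``phi_T`` learns to fool it.  A
variance regulariser ``- lambda * Var(R(phi_T(x)))`` added to the generator
objective pushes the target predictions away from posterior collapse (all
inputs mapping to one output).  Epoch-level stopping is delegated to the
label-free MMD/GGO monitors.

Stage C (:func:`finetune`) trains ``R`` alone on a handful of labelled target
images with raw (unnormalised) counts, which simultaneously restores the
target label scale [a', b'] — no explicit denormalisation step exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from skimage import exposure, transform

from . import nn
from .core_models import Discriminator, FeatureExtractor, RegressorHead
from .monitors import KernelSpec, StoppingState, ggo, median_heuristic_bandwidth, mmd2, update_monitor

__all__ = [
    "ArrayDataset",
    "LabelNormalizer",
    "StageConfig",
    "MonitorConfig",
    "preprocess_images",
    "samples_to_arrays",
    "augment_batch",
    "normalize_labels",
    "variance_penalty",
    "discriminator_step",
    "generator_step",
    "pretrain",
    "adapt",
    "finetune",
    "predict",
]

_EPS = 1e-7  # probability clip inside cross-entropy


class ArrayDataset(NamedTuple):
    """A preprocessed image tensor (B, 3, H, W) in [-1, 1] plus integer labels."""

    X: np.ndarray
    y: np.ndarray

    def __len__(self) -> int:
        return self.X.shape[0]


# ---------------------------------------------------------------------------
# preprocessing and augmentation
# ---------------------------------------------------------------------------

def preprocess_images(images: np.ndarray, size: int = 64, equalize: bool = True) -> np.ndarray:
    """(N, H, W, 3) images in [0, 1] -> (N, 3, size, size) tensors in [-1, 1].

    Per image: resize to ``size`` x ``size``, joint histogram equalisation over
    all three channels (contrast normalisation that preserves relative colour
    structure), then the affine map ``2x - 1``.
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[None]
    out = np.empty((images.shape[0], 3, size, size), dtype=np.float32)
    for i, img in enumerate(images):
        if img.shape[0] != size or img.shape[1] != size:
            img = transform.resize(img, (size, size), anti_aliasing=True)
        if equalize:
            # joint histogram over all three channels preserves relative colour
            img = exposure.equalize_hist(img.ravel()).reshape(img.shape)
        out[i] = (2.0 * img - 1.0).transpose(2, 0, 1)
    return out


def samples_to_arrays(samples_with_splits, size: int = 64, equalize: bool = True):
    """Group (sample, split) pairs into per-split :class:`ArrayDataset` objects."""
    by_split: dict[str, list] = {}
    for sample, split in samples_with_splits:
        by_split.setdefault(split, []).append(sample)
    out = {}
    for split, samples in by_split.items():
        X = preprocess_images(np.stack([s.image for s in samples]), size, equalize)
        y = np.array([s.count for s in samples], dtype=np.int64)
        out[split] = ArrayDataset(X, y)
    return out


def augment_batch(X: np.ndarray, rng: np.random.Generator,
                  flips: bool = True, color_jitter: float = 0.1) -> np.ndarray:
    """Training-time augmentation: horizontal/vertical flips and colour jitter."""
    X = X.copy()
    b = X.shape[0]
    if flips:
        hflip = rng.random(b) < 0.5
        vflip = rng.random(b) < 0.5
        X[hflip] = X[hflip, :, :, ::-1]
        X[vflip] = X[vflip, :, ::-1, :]
    if color_jitter > 0:
        gain = 1.0 + rng.uniform(-color_jitter, color_jitter, (b, 3, 1, 1))
        shift = rng.uniform(-color_jitter / 2, color_jitter / 2, (b, 3, 1, 1))
        X = np.clip(X * gain + shift, -1.0, 1.0)
    return X.astype(np.float32)


# ---------------------------------------------------------------------------
# label normalisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelNormalizer:
    """Affine map of the source label range [a, b] onto [0, 1]."""

    a: float
    b: float

    def __post_init__(self):
        if self.b <= self.a:
            raise ValueError(f"label range degenerate: a={self.a}, b={self.b}")

    @classmethod
    def fit(cls, labels) -> "LabelNormalizer":
        labels = np.asarray(labels, dtype=float)
        if labels.size == 0:
            raise ValueError("cannot fit a normalizer to an empty label set")
        return cls(float(labels.min()), float(labels.max()))

    def normalize(self, labels, clamp: bool = False) -> np.ndarray:
        return normalize_labels(labels, self.a, self.b, clamp=clamp)

    def denormalize(self, values) -> np.ndarray:
        return np.asarray(values, dtype=float) * (self.b - self.a) + self.a


def normalize_labels(labels, a: float, b: float, clamp: bool = False) -> np.ndarray:
    """Element-wise ``(y - a) / (b - a)``; labels must lie in [a, b] unless clamped."""
    if b <= a:
        raise ValueError(f"invalid label range: a={a}, b={b}")
    y = np.asarray(labels, dtype=float)
    if clamp:
        outside = (y < a) | (y > b)
        if np.any(outside):
            warnings.warn(f"{int(outside.sum())} label(s) outside [{a}, {b}] clamped")
        y = np.clip(y, a, b)
    elif np.any((y < a) | (y > b)):
        raise ValueError(f"labels outside [{a}, {b}]; pass clamp=True to clip")
    return (y - a) / (b - a)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageConfig:
    """Hyperparameters for one pipeline stage.

    ``lr`` drives whichever network the stage trains (heads during stages A
    and C); ``d_lr``/``g_lr`` override it for the discriminator and the target
    extractor during stage B.  ``lam`` is the variance-regulariser weight (0
    disables it).  ``patience`` feeds stage A's early stopping and stage B's
    monitor rule.
    """

    lr: float = 1e-4
    d_lr: float | None = None
    g_lr: float = 1e-5
    batch_size: int = 32
    max_epochs: int = 100
    lam: float = 0.1
    patience: int = 10
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.batch_size < 1 or self.max_epochs < 0:
            raise ValueError("invalid batch_size/max_epochs")


@dataclass(frozen=True)
class MonitorConfig:
    """Stage-B monitor settings: kernel, patience, ablation mode, sample cap."""

    kernel: KernelSpec = KernelSpec()
    patience: int = 10
    mode: str = "both"  # "both" | "mmd" | "ggo"
    eval_size: int = 256


# ---------------------------------------------------------------------------
# loss primitives
# ---------------------------------------------------------------------------

def variance_penalty(predictions) -> float:
    """Population variance of a prediction vector (the collapse detector)."""
    p = np.asarray(predictions, dtype=np.float64).ravel()
    if p.size < 2:
        raise ValueError("variance needs at least 2 predictions")
    return float(np.mean((p - p.mean()) ** 2))


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, _EPS, 1.0 - _EPS)


def discriminator_step(d: Discriminator, phi_S: FeatureExtractor, phi_T: FeatureExtractor,
                       source_batch: np.ndarray, target_batch: np.ndarray,
                       optimizer: nn.Adam | None = None) -> float:
    """One discriminator update: real = source features, fake = target features.

    Loss is ``E_s[-log D(phi_S(s))] + E_t[-log(1 - D(phi_T(t)))]``; gradients
    touch the discriminator parameters only.  Pass ``optimizer`` (over the
    discriminator's parameters) to apply the update; omit it to just evaluate
    the loss and gradients.
    """
    if len(source_batch) == 0 or len(target_batch) == 0:
        raise ValueError("empty batch")
    fs = phi_S.forward(source_batch, train=False)
    ft = phi_T.forward(target_batch, train=False)
    m, n = fs.shape[0], ft.shape[0]
    d.zero_grad()
    p = _clip(d.forward(np.vstack([fs, ft]), train=True))
    ps, pt = p[:m], p[m:]
    loss = float(-np.log(ps).mean() - np.log(1.0 - pt).mean())
    grad = np.concatenate([-1.0 / (m * ps), 1.0 / (n * (1.0 - pt))])
    d.backward(grad.astype(np.float32))
    if optimizer is not None:
        optimizer.step()
    return loss


def generator_step(d: Discriminator, phi_T: FeatureExtractor, regressor: RegressorHead,
                   target_batch: np.ndarray, lam: float = 0.0,
                   optimizer: nn.Adam | None = None) -> float:
    """One target-extractor update: fool the discriminator, keep output variance.

    Loss is ``E_t[-log D(phi_T(t))] - lam * Var(R(phi_T(t)))``; gradients flow
    through ``D`` and ``R`` but only the target extractor's parameters are
    updated (pass ``optimizer`` over them to apply the step).
    """
    n = len(target_batch)
    if n == 0:
        raise ValueError("empty batch")
    if lam > 0 and n < 2:
        raise ValueError("variance regulariser needs batch size >= 2")
    phi_T.zero_grad()
    d.zero_grad()
    regressor.zero_grad()
    ft = phi_T.forward(target_batch, train=True)
    p = _clip(d.forward(ft, train=True))
    loss = float(-np.log(p).mean())
    gfeat = d.backward((-1.0 / (n * p)).astype(np.float32))
    if lam > 0:
        yhat = regressor.forward(ft, train=True)
        var = variance_penalty(yhat)
        loss -= lam * var
        # d(-lam * var)/d(yhat) = -lam * 2 (yhat - mean) / n
        gy = (-lam * 2.0 / n) * (yhat - yhat.mean())
        gfeat = gfeat + regressor.backward(gy)
    phi_T.backward(gfeat)
    if optimizer is not None:
        optimizer.step()
    return loss


# ---------------------------------------------------------------------------
# stage A: supervised pretraining on the source domain
# ---------------------------------------------------------------------------

@dataclass
class PretrainResult:
    fe: FeatureExtractor
    regressor: RegressorHead
    normalizer: LabelNormalizer
    history: pd.DataFrame


def _mse_step(fe, regressor, X, y_target, optimizer, train=True):
    feats = fe.forward(X, train=train)
    yhat = regressor.forward(feats, train=train)
    err = yhat - y_target
    loss = float(np.mean(err ** 2))
    if optimizer is not None:
        fe.zero_grad()
        regressor.zero_grad()
        gfeat = regressor.backward(2.0 * err / err.size)
        fe.backward(gfeat)
        optimizer.step()
    return loss


def pretrain(fe: FeatureExtractor, regressor: RegressorHead,
             source_train: ArrayDataset, source_val: ArrayDataset,
             cfg: StageConfig) -> PretrainResult:
    """Stage A: fit ``phi_S`` and ``R`` on normalised source labels.

    The label normaliser is fitted on the training labels; validation labels
    outside [a, b] are clamped with a warning.  The checkpoint with the best
    validation MSE (measured on the original count scale) is restored before
    returning, with patience-based early stopping.
    """
    if len(source_train) == 0:
        raise ValueError("empty training set")
    norm = LabelNormalizer.fit(source_train.y)
    yn_train = norm.normalize(source_train.y)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 31]))
    optimizer = nn.Adam(fe.params() + regressor.params(), lr=cfg.lr)
    best = (np.inf, fe.get_state(), regressor.get_state())
    rows = []
    stale = 0
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(source_train))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            X = source_train.X[idx]
            if cfg.augment:
                X = augment_batch(X, rng)
            losses.append(_mse_step(fe, regressor, X, yn_train[idx], optimizer))
        val_pred = norm.denormalize(predict(fe, regressor, source_val.X))
        val_mse = float(np.mean((val_pred - source_val.y) ** 2))
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses)), "val_mse": val_mse})
        if val_mse < best[0] - 1e-9:
            best = (val_mse, fe.get_state(), regressor.get_state())
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    fe.set_state(best[1])
    regressor.set_state(best[2])
    return PretrainResult(fe, regressor, norm, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# stage B: adversarial adaptation
# ---------------------------------------------------------------------------

@dataclass
class AdaptResult:
    phi_T: FeatureExtractor
    history: pd.DataFrame
    stopping: StoppingState


def _monitor_eval(phi_S, phi_T, d, source_X, target_X, kernel, eval_size):
    fs = phi_S.forward(source_X[:eval_size], train=False)
    ft = phi_T.forward(target_X[:eval_size], train=False)
    m = mmd2(fs, ft, kernel)
    pooled = _clip(d.forward(np.vstack([fs, ft]), train=False))
    return m, ggo(pooled), fs, ft


def adapt(phi_S: FeatureExtractor, regressor: RegressorHead,
          target_train: ArrayDataset, source_train: ArrayDataset,
          discriminator: Discriminator, cfg: StageConfig,
          monitors: MonitorConfig = MonitorConfig(),
          source_val: ArrayDataset | None = None,
          target_val: ArrayDataset | None = None) -> AdaptResult:
    """Stage B: align target features to the frozen source representation.

    ``phi_T`` starts as a clone of ``phi_S``.  Each epoch alternates one
    discriminator step and one generator step per paired batch; after every
    epoch the MMD and GGO monitors are evaluated on held-out features and the
    joint patience rule decides termination.  The returned extractor is the
    snapshot from the monitor-selected best epoch.  ``phi_S``, ``R`` and the
    labels are never touched.
    """
    if len(target_train) == 0:
        raise ValueError("empty target set")
    if len(source_train) == 0:
        raise ValueError("empty source set")
    sv = source_val if source_val is not None else source_train
    tv = target_val if target_val is not None else target_train
    phi_T = phi_S.clone()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 47]))
    opt_d = nn.Adam(discriminator.params(), lr=cfg.d_lr if cfg.d_lr is not None else cfg.lr)
    opt_g = nn.Adam(phi_T.params(), lr=cfg.g_lr)

    # freeze the monitor kernel bandwidth at the first evaluation so MMD
    # values are comparable across epochs
    kernel = monitors.kernel
    fs0 = phi_S.forward(sv.X[:monitors.eval_size], train=False)
    ft0 = phi_T.forward(tv.X[:monitors.eval_size], train=False)
    if kernel.bandwidth is None:
        kernel = KernelSpec(kernel.family, median_heuristic_bandwidth(fs0, ft0))

    state = StoppingState(patience=monitors.patience, mode=monitors.mode)
    mmd_val = mmd2(fs0, ft0, kernel)
    ggo_val = ggo(_clip(discriminator.forward(np.vstack([fs0, ft0]), train=False)))
    state, _ = update_monitor(state, mmd_val, ggo_val)
    snapshots = {0: phi_T.get_state()}
    rows = [{"epoch": 0, "d_loss": np.nan, "g_loss": np.nan, "mmd2": mmd_val,
             "ggo": ggo_val, "since_mmd": state.since_mmd,
             "since_ggo": state.since_ggo, "stopped": False}]

    n_batches = max(1, min(len(source_train), len(target_train)) // cfg.batch_size)
    for epoch in range(1, cfg.max_epochs + 1):
        s_order = rng.permutation(len(source_train))
        t_order = rng.permutation(len(target_train))
        d_losses, g_losses = [], []
        for b in range(n_batches):
            sb = source_train.X[s_order[b * cfg.batch_size:(b + 1) * cfg.batch_size]]
            tb = target_train.X[t_order[b * cfg.batch_size:(b + 1) * cfg.batch_size]]
            if len(sb) == 0 or len(tb) == 0:
                continue
            if cfg.augment:
                sb = augment_batch(sb, rng)
                tb = augment_batch(tb, rng)
            d_losses.append(discriminator_step(discriminator, phi_S, phi_T, sb, tb, opt_d))
            g_losses.append(generator_step(discriminator, phi_T, regressor, tb,
                                           cfg.lam, opt_g))
        d_loss, g_loss = float(np.mean(d_losses)), float(np.mean(g_losses))
        if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
            raise FloatingPointError(
                f"non-finite adversarial loss at epoch {epoch}: d={d_loss}, g={g_loss}")
        mmd_val, ggo_val, _, _ = _monitor_eval(phi_S, phi_T, discriminator,
                                               sv.X, tv.X, kernel, monitors.eval_size)
        state, stop = update_monitor(state, mmd_val, ggo_val)
        if state.best_epoch == state.epoch:
            snapshots = {state.epoch: phi_T.get_state()}  # keep only the best
        rows.append({"epoch": epoch, "d_loss": d_loss, "g_loss": g_loss,
                     "mmd2": mmd_val, "ggo": ggo_val, "since_mmd": state.since_mmd,
                     "since_ggo": state.since_ggo, "stopped": stop})
        if stop:
            break
    best_state = snapshots.get(state.best_epoch)
    if best_state is not None:
        phi_T.set_state(best_state)
    return AdaptResult(phi_T, pd.DataFrame(rows), state)


# ---------------------------------------------------------------------------
# stage C: semi-supervised fine-tuning of the regressor
# ---------------------------------------------------------------------------

@dataclass
class FinetuneResult:
    regressor: RegressorHead
    phi: FeatureExtractor
    history: pd.DataFrame


def finetune(phi_T: FeatureExtractor, regressor: RegressorHead,
             labelled_subset: ArrayDataset, cfg: StageConfig,
             unfreeze_backbone: bool = False) -> FinetuneResult:
    """Stage C: fit ``R`` on k labelled target images with raw counts.

    Training against unnormalised counts restores the target label range; the
    backbone stays frozen unless ``unfreeze_backbone`` is set.  The passed-in
    models are left untouched; fresh copies are returned.
    """
    k = len(labelled_subset)
    if k == 0:
        raise ValueError("empty labelled subset")
    reg = regressor.copy()
    phi = phi_T.clone() if unfreeze_backbone else phi_T
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 59]))
    params = reg.params() + (phi.params() if unfreeze_backbone else [])
    optimizer = nn.Adam(params, lr=cfg.lr)
    y = labelled_subset.y.astype(np.float64)
    feats = None if unfreeze_backbone else phi.forward(labelled_subset.X, train=False)
    bs = min(cfg.batch_size, k)
    rows = []
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(k)
        losses = []
        for start in range(0, k, bs):
            idx = order[start:start + bs]
            reg.zero_grad()
            if unfreeze_backbone:
                phi.zero_grad()
                f = phi.forward(labelled_subset.X[idx], train=True)
            else:
                f = feats[idx]
            yhat = reg.forward(f, train=True)
            err = yhat - y[idx]
            losses.append(float(np.mean(err ** 2)))
            gfeat = reg.backward(2.0 * err / err.size)
            if unfreeze_backbone:
                phi.backward(gfeat)
            optimizer.step()
        rows.append({"epoch": epoch, "train_loss": float(np.mean(losses))})
    return FinetuneResult(reg, phi, pd.DataFrame(rows))


def predict(phi: FeatureExtractor, regressor: RegressorHead, images: np.ndarray) -> np.ndarray:
    """Evaluation-mode counts (one real value per image)."""
    feats = phi.forward(images, train=False)
    return regressor.forward(feats, train=False)
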