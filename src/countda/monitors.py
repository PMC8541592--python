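"""Unsupervised stopping signals for adversarial adaptation.

Two label-free statistics are tracked per epoch:

* the squared **maximum mean discrepancy** (MMD^2) between held-out source and
  target feature batches — a kernel two-sample distance that acts as a proxy
  validation loss for residual covariate shift;
* the **GAN global-optimality** deviation ``|E[D(z)] - 1/2]`` over pooled
  source and target features — at the adversarial optimum the discriminator
  outputs 1/2 everywhere, so the deviation from 1/2 measures how far the
  current generator/discriminator pair is from that optimum.

Training stops when *neither* statistic has improved for ``patience`` epochs
(default 10); single-signal modes reduce to ordinary patience early-stopping
and are used for ablations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["KernelSpec", "StoppingState", "mmd2", "ggo", "update_monitor",
           "median_heuristic_bandwidth"]

IMPROVE_TOL = 1e-6


@dataclass(frozen=True)
class KernelSpec:
    """RBF kernel ``k(x, y) = exp(-||x-y||^2 / (2 s^2))``.

    With ``bandwidth=None`` the scale ``s^2`` is the median of the pooled
    pairwise squared distances (median heuristic).
    """

    family: str = "rbf"
    bandwidth: float | None = None  # fixed s; None -> median heuristic

    def __post_init__(self):
        if self.family != "rbf":
            raise ValueError(f"unsupported kernel family {self.family!r}")
        if self.bandwidth is not None and self.bandwidth <= 0:
            raise ValueError("bandwidth must be positive")


def median_heuristic_bandwidth(x: np.ndarray, y: np.ndarray) -> float:
    """Median-heuristic bandwidth ``s`` with ``s^2 = median(||a-b||^2)``."""
    z = np.vstack([x, y]).astype(np.float64)
    d2 = cdist(z, z, "sqeuclidean")
    vals = d2[np.triu_indices(len(z), k=1)]
    vals = vals[vals > 0]
    if vals.size == 0:
        return 1.0
    return float(np.sqrt(np.median(vals)))


def _rbf(a: np.ndarray, b: np.ndarray, s: float) -> np.ndarray:
    return np.exp(-cdist(a, b, "sqeuclidean") / (2.0 * s * s))


def mmd2(x: np.ndarray, y: np.ndarray, kernel: KernelSpec = KernelSpec()) -> float:
    """Biased empirical squared MMD between sample sets ``x`` (M, F), ``y`` (N, F).

    Uses the kernel expansion ``(1/M^2) sum k(xi, xj) + (1/N^2) sum k(yi, yj)
    - (2/MN) sum k(xi, yj)``, clipped at zero against negative round-off.
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    y = np.atleast_2d(np.asarray(y, dtype=np.float64))
    if x.shape[0] < 1 or y.shape[0] < 1:
        raise ValueError("both sample sets must be non-empty")
    if x.shape[1] != y.shape[1]:
        raise ValueError(f"feature widths differ: {x.shape[1]} vs {y.shape[1]}")
    s = kernel.bandwidth if kernel.bandwidth is not None else median_heuristic_bandwidth(x, y)
    m, n = x.shape[0], y.shape[0]
    val = (_rbf(x, x, s).sum() / (m * m)
           + _rbf(y, y, s).sum() / (n * n)
           - 2.0 * _rbf(x, y, s).sum() / (m * n))
    return max(0.0, float(val))


def ggo(discriminator_outputs: np.ndarray) -> float:
    """Absolute deviation of the mean discriminator output from 1/2.

    Inputs are pooled discriminator probabilities over source and target
    features; 0 at the adversarial optimum, at most 1/2.
    """
    out = np.asarray(discriminator_outputs, dtype=np.float64).ravel()
    if out.size == 0:
        raise ValueError("empty discriminator output")
    if np.any(out <= 0) or np.any(out >= 1):
        raise ValueError("discriminator outputs must lie strictly in (0, 1)")
    return abs(float(out.mean()) - 0.5)


@dataclass(frozen=True)
class StoppingState:
    """Best-so-far monitor values and per-signal no-improvement counters."""

    patience: int = 10
    mode: str = "both"  # "both" | "mmd" | "ggo"
    best_mmd: float = np.inf
    best_ggo: float = np.inf
    since_mmd: int = 0
    since_ggo: int = 0
    epoch: int = -1       # index of the last update
    best_epoch: int = -1  # snapshot to restore (best MMD; ties -> best GGO)

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.mode not in ("both", "mmd", "ggo"):
            raise ValueError(f"unknown stopping mode {self.mode!r}")


def update_monitor(state: StoppingState, epoch_mmd: float, epoch_ggo: float):
    """Fold one epoch's monitor values into the state.

    Returns ``(new_state, should_stop)``.  A signal "improves" when it drops
    strictly below its best value by more than a small tolerance; ties do not
    reset counters.  Stopping requires every active signal to have stalled
    for ``patience`` consecutive epochs.
    """
    if not (np.isfinite(epoch_mmd) and np.isfinite(epoch_ggo)):
        raise FloatingPointError(
            f"non-finite monitor value (mmd={epoch_mmd}, ggo={epoch_ggo})")
    epoch = state.epoch + 1
    best_mmd, since_mmd = state.best_mmd, state.since_mmd + 1
    best_ggo, since_ggo = state.best_ggo, state.since_ggo + 1
    best_epoch = state.best_epoch
    mmd_improved = epoch_mmd < best_mmd - IMPROVE_TOL
    ggo_improved = epoch_ggo < best_ggo - IMPROVE_TOL
    if mmd_improved:
        best_mmd, since_mmd = float(epoch_mmd), 0
    if ggo_improved:
        best_ggo, since_ggo = float(epoch_ggo), 0
    # the snapshot follows the active signal: best MMD epoch (GGO breaking
    # ties) in joint and MMD-only modes, best GGO epoch in GGO-only mode
    if state.mode == "ggo":
        if ggo_improved:
            best_epoch = epoch
    elif mmd_improved:
        best_epoch = epoch
    elif ggo_improved and abs(epoch_mmd - best_mmd) <= IMPROVE_TOL:
        best_epoch = epoch
    new = replace(state, best_mmd=best_mmd, best_ggo=best_ggo,
                  since_mmd=since_mmd, since_ggo=since_ggo,
                  epoch=epoch, best_epoch=best_epoch)
    if state.mode == "mmd":
        stop = since_mmd >= state.patience
    elif state.mode == "ggo":
        stop = since_ggo >= state.patience
    else:
        stop = since_mmd >= state.patience and since_ggo >= state.patience
    return new, bool(stop)
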