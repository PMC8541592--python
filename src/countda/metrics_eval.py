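"""Counting metrics and evaluation reports.

Per-image error is ``eps_i = y_i - round(yhat_i)`` with half-away-from-zero
rounding.  Reported metrics: mean/std of ``|eps|`` (absolute difference in
count), mean/std of ``eps`` (signed difference in count), mean squared error,
and the percentage of exact matches.  Standard deviations are population
(1/N) form.

:func:`evaluate_bounds` brackets the adapted model between the no-adaptation
transfer of the pretrained source model (upper bound, UB) and a fully
supervised model trained on the target domain (lower bound, LB).
:func:`label_budget_sweep` re-runs the fine-tuning stage for several label
budgets ``k`` from one adapted checkpoint.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_models import FeatureExtractor, RegressorHead
from .training_stages import ArrayDataset, LabelNormalizer, StageConfig, finetune, predict

__all__ = [
    "CountMetricsReport",
    "MissingCheckpointError",
    "round_half_away",
    "compute_metrics",
    "evaluate_bounds",
    "label_budget_sweep",
    "reports_to_csv",
    "reports_from_csv",
]

REPORT_COLUMNS = ["condition", "abs_dic_mean", "abs_dic_std", "dic_mean",
                  "dic_std", "mse", "pct_agree", "n"]


class MissingCheckpointError(RuntimeError):
    """A required stage checkpoint was not provided."""


def round_half_away(x) -> np.ndarray:
    """Round half away from zero (2.5 -> 3, -2.5 -> -3)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class CountMetricsReport:
    abs_dic_mean: float
    abs_dic_std: float
    dic_mean: float
    dic_std: float
    mse: float
    pct_agree: float  # percentage in [0, 100]
    n: int


def compute_metrics(y_true, y_pred) -> CountMetricsReport:
    """Counting metrics from integer ground truth and real-valued predictions."""
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError(f"shape mismatch: {y.shape} vs {p.shape}")
    if y.size == 0:
        raise ValueError("empty inputs")
    eps = y - round_half_away(p)
    return CountMetricsReport(
        abs_dic_mean=float(np.abs(eps).mean()),
        abs_dic_std=float(np.abs(eps).std()),
        dic_mean=float(eps.mean()),
        dic_std=float(eps.std()),
        mse=float(np.mean(eps ** 2)),
        pct_agree=float(100.0 * np.mean(eps == 0)),
        n=int(y.size),
    )


def reports_to_csv(reports: dict[str, CountMetricsReport], path: str | Path) -> pd.DataFrame:
    rows = [{"condition": name, **vars(rep)} for name, rep in reports.items()]
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    # %.17g guarantees exact float round-trip through the CSV
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def reports_from_csv(path: str | Path) -> dict[str, CountMetricsReport]:
    df = pd.read_csv(path, float_precision="round_trip")
    out = {}
    for row in df.itertuples(index=False):
        d = row._asdict()
        name = d.pop("condition")
        out[name] = CountMetricsReport(**{k: (int(v) if k == "n" else float(v))
                                          for k, v in d.items()})
    return out


def evaluate_bounds(target_test: ArrayDataset, models: dict, cfg=None,
                    out_csv: str | Path | None = None) -> dict[str, CountMetricsReport]:
    """UB / Ours / LB comparison on the target test split.

    ``models`` must contain:

    * ``"pretrained"``: ``(phi_S, R, LabelNormalizer)`` — UB predictions are
      the pretrained model's outputs mapped back through the source-label
      normaliser (no adaptation);
    * ``"finetuned"``: ``(phi_T, R_finetuned)`` — the full pipeline ("Ours");
    * ``"lower_bound"``: ``(phi, R, LabelNormalizer)`` — a model trained
      directly on the target domain (fully supervised reference).
    """
    if len(target_test) == 0:
        raise ValueError("empty target test split")
    for stage in ("pretrained", "finetuned", "lower_bound"):
        if stage not in models or models[stage] is None:
            raise MissingCheckpointError(f"missing checkpoint for stage: {stage}")
    fe_s, reg_s, norm_s = models["pretrained"]
    phi_t, reg_ft = models["finetuned"]
    fe_lb, reg_lb, norm_lb = models["lower_bound"]

    ub_pred = norm_s.denormalize(predict(fe_s, reg_s, target_test.X))
    ours_pred = predict(phi_t, reg_ft, target_test.X)
    lb_pred = norm_lb.denormalize(predict(fe_lb, reg_lb, target_test.X))

    reports = {
        "UB": compute_metrics(target_test.y, ub_pred),
        "Ours": compute_metrics(target_test.y, ours_pred),
        "LB": compute_metrics(target_test.y, lb_pred),
    }
    if out_csv is not None:
        reports_to_csv(reports, out_csv)
    return reports


def label_budget_sweep(k_values, phi_T: FeatureExtractor, regressor: RegressorHead,
                       target_train: ArrayDataset, target_test: ArrayDataset,
                       cfg: StageConfig, seeds=(0, 1, 2),
                       out_csv: str | Path | None = None) -> pd.DataFrame:
    """MSE as a function of the fine-tuning label budget ``k``.

    For each ``k`` the labelled subset is redrawn per seed from the target
    training pool, stage C re-runs from the same adapted extractor, and the
    per-seed test MSEs are averaged.
    """
    pool = len(target_train)
    rows = []
    for k in k_values:
        if not (1 <= k <= pool):
            raise ValueError(f"k={k} outside [1, {pool}]")
        mses = []
        for s in seeds:
            rng = np.random.default_rng(np.random.SeedSequence([int(s), int(k), 73]))
            idx = np.sort(rng.choice(pool, size=int(k), replace=False))
            subset = ArrayDataset(target_train.X[idx], target_train.y[idx])
            ft = finetune(phi_T, regressor, subset, dataclasses.replace(cfg, seed=int(s)))
            pred = predict(phi_T, ft.regressor, target_test.X)
            mses.append(compute_metrics(target_test.y, pred).mse)
        rows.append({"k": int(k), "mse_mean": float(np.mean(mses)),
                     "mse_std": float(np.std(mses)), "n_seeds": len(list(seeds))})
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
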