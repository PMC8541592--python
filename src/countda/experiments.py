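"""Desk-scale reference experiment: source -> shifted target with label gap.

Builds a miniature version of the synthetic-cell adaptation study: the source
domain has blue, medium-sized cells with counts in [3, 8]; the target domain
has smaller red cells with a cytoplasm halo and counts in [6, 12], i.e. it
exhibits both covariate shift and label gap.  The full pipeline (pretraining,
adversarial adaptation with monitor-based stopping, few-shot fine-tuning) is
run per seed together with its upper/lower-bound references and the ablation
variants of the stopping rule and the variance regulariser.

Problem sizes (300 images per domain, 64x64 pixels, feature dimension 128)
are chosen so one full seed runs in a couple of minutes on a single CPU.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_models import ModelConfig, build_models
from .metrics_eval import CountMetricsReport, evaluate_bounds, label_budget_sweep
from .monitors import KernelSpec
from .synthetic_data import SceneSpec, generate_samples, make_shifted_pair
from .training_stages import (ArrayDataset, MonitorConfig, StageConfig, adapt,
                              finetune, predict, pretrain, samples_to_arrays)

__all__ = [
    "toy_source_spec",
    "toy_pair",
    "desk_model_config",
    "desk_configs",
    "build_domain_arrays",
    "run_seed_experiment",
    "ABLATION_VARIANTS",
]

# stopping-rule / regulariser ablation grid: (use GGO, use MMD, use variance reg)
ABLATION_VARIANTS = {
    "full": {"mode": "both", "lam": 0.1},
    "no_var": {"mode": "both", "lam": 0.0},
    "mmd_only": {"mode": "mmd", "lam": 0.1},
    "ggo_only": {"mode": "ggo", "lam": 0.1},
}


def toy_source_spec(seed: int = 0, image_size: int = 64) -> SceneSpec:
    """Blue medium cells, counts in [3, 8], no halo."""
    return SceneSpec(
        image_size=image_size,
        count_range=(3, 8),
        blob_radius_range=(4.0, 6.0),
        blob_color=(0.15, 0.25, 0.85),
        halo=False,
        seed=seed,
    )


def toy_pair(seed: int = 0, image_size: int = 64):
    """(source, target) pair: target is red, smaller, haloed, counts [6, 12]."""
    src = toy_source_spec(seed=seed, image_size=image_size)
    return make_shifted_pair(
        src,
        appearance_shift={"blob_color": (0.85, 0.20, 0.20), "halo": True,
                          "blob_radius_range": (3.0, 4.5)},
        label_gap_shift={"count_range": (6, 12)},
    )


def desk_model_config() -> ModelConfig:
    return ModelConfig(backbone="small_cnn", feature_dim=128, image_size=64)


def desk_configs(seed: int) -> dict[str, StageConfig]:
    """Desk-scale stage hyperparameters (fast from-scratch training)."""
    return {
        "pretrain": StageConfig(lr=2e-3, batch_size=32, max_epochs=80,
                                patience=10, augment=True, seed=seed),
        "adapt": StageConfig(lr=3e-4, d_lr=3e-4, g_lr=2e-5, batch_size=32,
                             max_epochs=45, lam=0.1, patience=10,
                             augment=True, seed=seed),
        "finetune": StageConfig(lr=2e-3, batch_size=16, max_epochs=200,
                                augment=False, seed=seed),
    }


def build_domain_arrays(spec: SceneSpec, n: int, domain: str, image_size: int = 64):
    """Render a domain and return per-split preprocessed arrays."""
    samples = generate_samples(spec, n, (0.55, 0.20, 0.25), domain=domain)
    return samples_to_arrays(samples, size=image_size)


@dataclass
class SeedExperiment:
    """Everything one seed of the toy study produced."""

    seed: int
    reports: dict[str, dict[str, CountMetricsReport]]  # variant -> {UB, Ours, LB}
    pred_variance: dict[str, float]  # variant -> Var(R(phi_T(x))) on target test
    adapt_history: dict[str, pd.DataFrame]
    disc_acc_before: float
    disc_acc_after: float
    sweep: pd.DataFrame | None = None


def domain_probe_accuracy(phi_S, phi_T, src_train_X, tgt_train_X,
                          src_val_X, tgt_val_X, seed: int = 0,
                          epochs: int = 60) -> float:
    """Held-out accuracy of a freshly trained source-vs-target feature probe.

    Trains a new discriminator head on frozen features (source through
    ``phi_S``, target through ``phi_T``) and reports its accuracy at
    threshold 0.5 on held-out features.  Values near 0.5 mean the domains
    are indistinguishable in feature space — the goal of adaptation.
    """
    from . import nn

    fs = phi_S.forward(src_train_X, train=False)
    ft = phi_T.forward(tgt_train_X, train=False)
    X = np.vstack([fs, ft]).astype(np.float32)
    t = np.concatenate([np.ones(len(fs)), np.zeros(len(ft))])
    _, _, probe = build_models(desk_model_config(), seed=seed + 7000)
    opt = nn.Adam(probe.params(), lr=1e-3)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 91]))
    for _ in range(epochs):
        order = rng.permutation(len(X))
        for start in range(0, len(X), 64):
            idx = order[start:start + 64]
            probe.zero_grad()
            p = np.clip(probe.forward(X[idx], train=True), 1e-7, 1 - 1e-7)
            probe.backward(((p - t[idx]) / (p * (1 - p)) / len(idx)).astype(np.float32))
            opt.step()
    ps = probe.forward(phi_S.forward(src_val_X, train=False), train=False)
    pt = probe.forward(phi_T.forward(tgt_val_X, train=False), train=False)
    correct = np.sum(ps >= 0.5) + np.sum(pt < 0.5)
    return float(correct) / (len(ps) + len(pt))


def run_seed_experiment(seed: int, n_per_domain: int = 300, k_finetune: int = 50,
                        variants=("full", "no_var", "mmd_only", "ggo_only"),
                        sweep_k=None) -> SeedExperiment:
    """Run the full toy study for one seed.

    Pretraining and the lower bound are shared across variants; each variant
    re-runs adaptation (with its own stopping mode and regulariser weight) and
    fine-tuning with the same k labelled target images.
    """
    cfgs = desk_configs(seed)
    mcfg = desk_model_config()
    src_spec, tgt_spec = toy_pair(seed=1000 + seed)
    src = build_domain_arrays(src_spec, n_per_domain, "source", mcfg.image_size)
    tgt = build_domain_arrays(tgt_spec, n_per_domain, "target", mcfg.image_size)

    # stage A on the source domain
    fe, reg, _ = build_models(mcfg, seed=seed)
    pre = pretrain(fe, reg, src["train"], src["val"], cfgs["pretrain"])

    # fully supervised target reference (lower bound)
    fe_lb, reg_lb, _ = build_models(mcfg, seed=seed + 500)
    lb = pretrain(fe_lb, reg_lb, tgt["train"], tgt["val"], cfgs["pretrain"])

    # fixed fine-tuning subset per seed
    rng = np.random.default_rng(np.random.SeedSequence([seed, 83]))
    idx = rng.choice(len(tgt["train"]), size=min(k_finetune, len(tgt["train"])), replace=False)
    subset = ArrayDataset(tgt["train"].X[idx], tgt["train"].y[idx])

    reports, pred_var, histories = {}, {}, {}
    disc_before = disc_after = np.nan
    sweep = None
    for name in variants:
        v = ABLATION_VARIANTS[name]
        _, _, disc = build_models(mcfg, seed=seed + 900)
        acfg = dataclasses.replace(cfgs["adapt"], lam=v["lam"])
        mon = MonitorConfig(kernel=KernelSpec(), patience=acfg.patience, mode=v["mode"])
        res = adapt(pre.fe, pre.regressor, tgt["train"], src["train"], disc, acfg,
                    mon, source_val=src["val"], target_val=tgt["val"])
        if name == "full":
            disc_before = domain_probe_accuracy(pre.fe, pre.fe, src["train"].X,
                                                tgt["train"].X, src["val"].X,
                                                tgt["val"].X, seed=seed)
            disc_after = domain_probe_accuracy(pre.fe, res.phi_T, src["train"].X,
                                               tgt["train"].X, src["val"].X,
                                               tgt["val"].X, seed=seed)
        histories[name] = res.history
        pred_var[name] = float(np.var(predict(res.phi_T, pre.regressor, tgt["test"].X)))
        ft = finetune(res.phi_T, pre.regressor, subset, cfgs["finetune"])
        reports[name] = evaluate_bounds(tgt["test"], {
            "pretrained": (pre.fe, pre.regressor, pre.normalizer),
            "finetuned": (res.phi_T, ft.regressor),
            "lower_bound": (lb.fe, lb.regressor, lb.normalizer),
        })
        if name == "full":
            if sweep_k:
                sweep = label_budget_sweep(sweep_k, res.phi_T, pre.regressor,
                                           tgt["train"], tgt["test"],
                                           cfgs["finetune"], seeds=(seed,))
    return SeedExperiment(seed=seed, reports=reports, pred_variance=pred_var,
                          adapt_history=histories, disc_acc_before=disc_before,
                          disc_acc_after=disc_after, sweep=sweep)
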