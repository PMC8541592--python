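"""Shared fixtures: tiny domains and a once-per-session miniature pipeline."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from countda.core_models import ModelConfig, build_models
from countda.monitors import KernelSpec
from countda.synthetic_data import SceneSpec, generate_samples, make_shifted_pair
from countda.training_stages import (MonitorConfig, StageConfig, adapt, pretrain,
                                     samples_to_arrays)

TINY_SIZE = 32


@pytest.fixture(scope="session")
def tiny_specs():
    """A 32x32 source/target pair with covariate shift and label gap."""
    src = SceneSpec(image_size=TINY_SIZE, count_range=(3, 8),
                    blob_radius_range=(2.0, 3.0),
                    blob_color=(0.15, 0.25, 0.85), halo=False, seed=7)
    return make_shifted_pair(
        src,
        appearance_shift={"blob_color": (0.85, 0.2, 0.2), "halo": True,
                          "blob_radius_range": (1.5, 2.2)},
        label_gap_shift={"count_range": (6, 12)},
    )


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(backbone="small_cnn", feature_dim=16, image_size=TINY_SIZE)


@pytest.fixture(scope="session")
def tiny_domains(tiny_specs):
    src_spec, tgt_spec = tiny_specs
    src = samples_to_arrays(generate_samples(src_spec, 120, domain="source"),
                            size=TINY_SIZE)
    tgt = samples_to_arrays(generate_samples(tgt_spec, 120, domain="target"),
                            size=TINY_SIZE)
    return src, tgt


@pytest.fixture(scope="session")
def tiny_pretrained(tiny_domains, tiny_model_config):
    """Stage A on the tiny source domain (~15 s, shared across tests)."""
    src, _ = tiny_domains
    fe, reg, _ = build_models(tiny_model_config, seed=0)
    cfg = StageConfig(lr=2e-3, batch_size=32, max_epochs=30, patience=10,
                      augment=True, seed=0)
    return pretrain(fe, reg, src["train"], src["val"], cfg)


@pytest.fixture(scope="session")
def tiny_adapted(tiny_pretrained, tiny_domains, tiny_model_config):
    """Stage B on the tiny pair (shared; discriminator state kept)."""
    src, tgt = tiny_domains
    _, _, disc = build_models(tiny_model_config, seed=900)
    cfg = StageConfig(lr=3e-4, d_lr=3e-4, g_lr=5e-5, batch_size=32,
                      max_epochs=15, lam=0.1, patience=10, augment=True, seed=0)
    mon = MonitorConfig(kernel=KernelSpec(), patience=10, mode="both")
    res = adapt(tiny_pretrained.fe, tiny_pretrained.regressor,
                tgt["train"], src["train"], disc, cfg, mon,
                source_val=src["val"], target_val=tgt["val"])
    return res, disc
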