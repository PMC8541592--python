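"""Pipeline stages: label normalisation, adversarial steps, pretrain/adapt/finetune."""


import numpy as np
import pytest

from countda import nn
from countda.core_models import ModelConfig, build_models
from countda.monitors import mmd2
from countda.training_stages import (ArrayDataset, LabelNormalizer, MonitorConfig,
                                     StageConfig, adapt, discriminator_step,
                                     finetune, generator_step, normalize_labels,
                                     predict, pretrain, variance_penalty)

LN2 = float(np.log(2.0))


class TestLabelNormalisation:
    @pytest.mark.parametrize("y,expected", [(35, 0.5), (20, 0.0), (50, 1.0)])
    def test_source_range_maps_to_unit_interval(self, y, expected):
        assert normalize_labels([y], 20, 50)[0] == pytest.approx(expected)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="label range"):
            normalize_labels([5], 5, 5)

    def test_out_of_range_labels_need_explicit_clamp(self):
        with pytest.raises(ValueError, match="clamp"):
            normalize_labels([60], 20, 50)
        with pytest.warns(UserWarning, match="clamped"):
            out = normalize_labels([60], 20, 50, clamp=True)
        assert out[0] == 1.0

    def test_normalizer_round_trip(self):
        norm = LabelNormalizer.fit([3, 5, 8])
        assert (norm.a, norm.b) == (3.0, 8.0)
        y = np.array([3, 4, 8])
        np.testing.assert_allclose(norm.denormalize(norm.normalize(y)), y)

    def test_strictly_increasing(self):
        norm = LabelNormalizer(0, 10)
        vals = norm.normalize(np.arange(11))
        assert np.all(np.diff(vals) > 0)


class TestVariancePenalty:
    def test_constant_predictions_have_zero_variance(self):
        assert variance_penalty([0.7, 0.7, 0.7]) == pytest.approx(0.0, abs=1e-15)

    def test_two_point_closed_form(self):
        assert variance_penalty([0.0, 1.0]) == pytest.approx(0.25)

    def test_matches_two_pass_oracle(self):
        x = np.random.default_rng(0).normal(2, 3, 10)
        mean = sum(x) / len(x)
        oracle = sum((v - mean) ** 2 for v in x) / len(x)
        assert variance_penalty(x) == pytest.approx(oracle, rel=1e-12)

    def test_single_prediction_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            variance_penalty([1.0])


@pytest.fixture(scope="module")
def step_setup():
    cfg = ModelConfig(feature_dim=8, image_size=16)
    fe, reg, disc = build_models(cfg, seed=3)
    phi_T = fe.clone()
    rng = np.random.default_rng(0)
    src = rng.normal(0, 0.5, (4, 3, 16, 16)).astype(np.float32)
    tgt = rng.normal(0, 0.5, (4, 3, 16, 16)).astype(np.float32)
    return fe, phi_T, reg, disc, src, tgt


def force_half_output(disc):
    """Zero the final dense layer so the sigmoid emits exactly 1/2."""
    disc.net.layers[4].W.value[...] = 0.0
    disc.net.layers[4].b.value[...] = 0.0


class TestAdversarialSteps:
    def test_indifferent_discriminator_loss_is_two_ln_two(self, step_setup):
        fe, phi_T, reg, disc, src, tgt = step_setup
        state = disc.get_state()
        force_half_output(disc)
        loss = discriminator_step(disc, fe, phi_T, src, tgt)
        assert loss == pytest.approx(2 * LN2, abs=1e-6)
        disc.set_state(state)

    def test_indifferent_discriminator_generator_loss_is_ln_two(self, step_setup):
        fe, phi_T, reg, disc, src, tgt = step_setup
        state = disc.get_state()
        force_half_output(disc)
        loss = generator_step(disc, phi_T, reg, tgt, lam=0.0)
        assert loss == pytest.approx(LN2, abs=1e-6)
        disc.set_state(state)

    def test_discriminator_loss_matches_hand_computed_cross_entropy(self, step_setup):
        fe, phi_T, reg, disc, src, tgt = step_setup
        # independent arithmetic oracle: explicit matmul chain on D's weights
        fs, ft = fe.forward(src), phi_T.forward(tgt)

        def d_by_hand(z):
            (w1, b1), (w2, b2), (w3, b3) = [
                (disc.net.layers[i].W.value, disc.net.layers[i].b.value)
                for i in (0, 2, 4)]
            h = z @ w1 + b1
            h = np.where(h > 0, h, 0.01 * h)
            h = h @ w2 + b2
            h = np.where(h > 0, h, 0.01 * h)
            return 1.0 / (1.0 + np.exp(-(h @ w3 + b3)[:, 0]))

        ps, pt = d_by_hand(fs), d_by_hand(ft)
        want = float(-np.mean(np.log(ps)) - np.mean(np.log(1 - pt)))
        got = discriminator_step(disc, fe, phi_T, src, tgt)
        assert got == pytest.approx(want, abs=1e-6)

    def test_generator_loss_subtracts_population_variance(self, step_setup):
        fe, phi_T, reg, disc, src, tgt = step_setup
        lam = 0.7
        base = generator_step(disc, phi_T, reg, tgt, lam=0.0)
        with_reg = generator_step(disc, phi_T, reg, tgt, lam=lam)
        yhat = reg.forward(phi_T.forward(tgt))
        assert with_reg == pytest.approx(base - lam * variance_penalty(yhat), abs=1e-6)

    def test_zero_variance_predictions_leave_loss_unchanged(self, step_setup):
        fe, phi_T, reg, disc, src, tgt = step_setup
        state = reg.get_state()
        reg.net.layers[4].W.value[...] = 0.0  # constant regressor output
        reg.net.layers[4].b.value[...] = 0.3
        assert (generator_step(disc, phi_T, reg, tgt, lam=0.0)
                == pytest.approx(generator_step(disc, phi_T, reg, tgt, lam=2.0), abs=1e-7))
        reg.set_state(state)

    def test_variance_regulariser_needs_two_samples(self, step_setup):
        fe, phi_T, reg, disc, src, tgt = step_setup
        with pytest.raises(ValueError, match="batch size"):
            generator_step(disc, phi_T, reg, tgt[:1], lam=0.5)

    def test_empty_batches_rejected(self, step_setup):
        fe, phi_T, reg, disc, src, tgt = step_setup
        with pytest.raises(ValueError, match="empty"):
            discriminator_step(disc, fe, phi_T, src[:0], tgt)
        with pytest.raises(ValueError, match="empty"):
            generator_step(disc, phi_T, reg, tgt[:0])

    def test_steps_touch_only_their_own_parameters(self, step_setup):
        fe, phi_T, reg, disc, src, tgt = step_setup
        opt_d = nn.Adam(disc.params(), lr=1e-3)
        opt_g = nn.Adam(phi_T.params(), lr=1e-3)
        hashes = lambda: (fe.param_hash(), phi_T.param_hash(),
                          reg.param_hash(), disc.param_hash())
        h_fe, h_phi, h_reg, h_d = hashes()
        discriminator_step(disc, fe, phi_T, src, tgt, optimizer=opt_d)
        assert hashes()[:3] == (h_fe, h_phi, h_reg)   # only Psi moved
        assert disc.param_hash() != h_d
        h_d = disc.param_hash()
        generator_step(disc, phi_T, reg, tgt, lam=0.5, optimizer=opt_g)
        h2 = hashes()
        assert (h2[0], h2[2], h2[3]) == (h_fe, h_reg, h_d)  # only Theta_T moved
        assert h2[1] != h_phi


class TestPretrain:
    def test_beats_constant_mean_predictor(self, tiny_pretrained, tiny_domains):
        src, _ = tiny_domains
        pred = tiny_pretrained.normalizer.denormalize(
            predict(tiny_pretrained.fe, tiny_pretrained.regressor, src["val"].X))
        model_mse = float(np.mean((pred - src["val"].y) ** 2))
        baseline = float(np.mean((src["val"].y - src["train"].y.mean()) ** 2))
        assert model_mse < baseline

    def test_stage_a_predictions_near_unit_scale(self, tiny_pretrained, tiny_domains):
        src, _ = tiny_domains
        pred = predict(tiny_pretrained.fe, tiny_pretrained.regressor, src["val"].X)
        assert np.all(pred > -0.2) and np.all(pred < 1.2)

    def test_zero_epochs_keeps_initial_weights_but_fits_normalizer(
            self, tiny_domains, tiny_model_config):
        src, _ = tiny_domains
        fe, reg, _ = build_models(tiny_model_config, seed=5)
        w0 = fe.net.layers[0].W.value.copy()
        res = pretrain(fe, reg, src["train"], src["val"],
                       StageConfig(max_epochs=0, seed=0))
        np.testing.assert_array_equal(res.fe.net.layers[0].W.value, w0)
        assert res.normalizer.a == src["train"].y.min()
        assert res.normalizer.b == src["train"].y.max()

    def test_constant_labels_rejected(self, tiny_domains, tiny_model_config):
        src, _ = tiny_domains
        fe, reg, _ = build_models(tiny_model_config, seed=5)
        const = ArrayDataset(src["train"].X, np.full(len(src["train"]), 4))
        with pytest.raises(ValueError, match="degenerate"):
            pretrain(fe, reg, const, src["val"], StageConfig(max_epochs=1, seed=0))

    def test_empty_training_set_rejected(self, tiny_domains, tiny_model_config):
        src, _ = tiny_domains
        fe, reg, _ = build_models(tiny_model_config, seed=5)
        empty = ArrayDataset(src["train"].X[:0], src["train"].y[:0])
        with pytest.raises(ValueError, match="empty"):
            pretrain(fe, reg, empty, src["val"], StageConfig(seed=0))


class TestAdapt:
    def test_zero_epochs_returns_exact_clone(self, tiny_pretrained, tiny_domains,
                                             tiny_model_config):
        src, tgt = tiny_domains
        _, _, disc = build_models(tiny_model_config, seed=11)
        res = adapt(tiny_pretrained.fe, tiny_pretrained.regressor,
                    tgt["train"], src["train"], disc,
                    StageConfig(max_epochs=0, seed=0))
        for pa, pb in zip(res.phi_T.params(), tiny_pretrained.fe.params()):
            np.testing.assert_array_equal(pa.value, pb.value)

    def test_empty_target_rejected(self, tiny_pretrained, tiny_domains,
                                   tiny_model_config):
        src, tgt = tiny_domains
        _, _, disc = build_models(tiny_model_config, seed=11)
        empty = ArrayDataset(tgt["train"].X[:0], tgt["train"].y[:0])
        with pytest.raises(ValueError, match="empty target"):
            adapt(tiny_pretrained.fe, tiny_pretrained.regressor, empty,
                  src["train"], disc, StageConfig(seed=0))

    def test_monitor_trace_schema_and_stop_flag(self, tiny_adapted):
        res, _ = tiny_adapted
        h = res.history
        assert list(h.columns) == ["epoch", "d_loss", "g_loss", "mmd2", "ggo",
                                   "since_mmd", "since_ggo", "stopped"]
        assert (h["mmd2"] >= 0).all()
        assert h["ggo"].between(0, 0.5).all()
        assert not h["stopped"].iloc[:-1].any()

    def test_identity_domains_start_with_small_mmd(self, tiny_pretrained,
                                                   tiny_domains, tiny_model_config):
        src, _ = tiny_domains
        _, _, disc = build_models(tiny_model_config, seed=13)
        cfg = StageConfig(lr=3e-4, d_lr=3e-4, g_lr=5e-5, batch_size=32,
                          max_epochs=4, lam=0.1, seed=0)
        res = adapt(tiny_pretrained.fe, tiny_pretrained.regressor,
                    src["train"], src["train"], disc, cfg,
                    MonitorConfig(patience=10),
                    source_val=src["val"], target_val=src["val"])
        # identical domains: the epoch-0 monitor sees the same features
        assert res.history["mmd2"].iloc[0] < 1e-9
        # adaptation must not wreck the source representation
        norm = tiny_pretrained.normalizer
        before = np.mean((norm.denormalize(
            predict(tiny_pretrained.fe, tiny_pretrained.regressor, src["val"].X))
            - src["val"].y) ** 2)
        after = np.mean((norm.denormalize(
            predict(res.phi_T, tiny_pretrained.regressor, src["val"].X))
            - src["val"].y) ** 2)
        assert after < 2.0 * before + 0.5

    def test_restored_snapshot_is_never_worse_aligned_than_no_adaptation(
            self, tiny_pretrained, tiny_domains, tiny_adapted):
        # the initial clone is always a candidate snapshot, so the restored
        # extractor's monitored MMD cannot exceed the epoch-0 value
        res, _ = tiny_adapted
        h = res.history
        assert res.stopping.best_mmd == pytest.approx(h["mmd2"].min())
        assert res.stopping.best_mmd <= h["mmd2"].iloc[0] + 1e-12


class TestFinetune:
    def test_restores_target_scale(self, tiny_adapted, tiny_pretrained, tiny_domains):
        src, tgt = tiny_domains
        res, _ = tiny_adapted
        rng = np.random.default_rng(0)
        idx = rng.choice(len(tgt["train"]), 10, replace=False)
        subset = ArrayDataset(tgt["train"].X[idx], tgt["train"].y[idx])
        ft = finetune(res.phi_T, tiny_pretrained.regressor, subset,
                      StageConfig(lr=2e-3, batch_size=8, max_epochs=150,
                                  augment=False, seed=0))
        pred = predict(res.phi_T, ft.regressor, tgt["test"].X)
        lo, hi = 6, 12
        span = hi - lo
        assert lo - 0.2 * span < pred.mean() < hi + 0.2 * span

    def test_zero_epochs_leaves_regressor_unchanged(self, tiny_adapted,
                                                    tiny_pretrained, tiny_domains):
        _, tgt = tiny_domains
        res, _ = tiny_adapted
        subset = ArrayDataset(tgt["train"].X[:10], tgt["train"].y[:10])
        ft = finetune(res.phi_T, tiny_pretrained.regressor, subset,
                      StageConfig(max_epochs=0, seed=0))
        pred_before = predict(res.phi_T, tiny_pretrained.regressor, tgt["test"].X)
        pred_after = predict(res.phi_T, ft.regressor, tgt["test"].X)
        np.testing.assert_array_equal(pred_before, pred_after)
        assert np.all(pred_after > -0.5) and np.all(pred_after < 1.5)

    def test_input_models_left_untouched(self, tiny_adapted, tiny_pretrained,
                                         tiny_domains):
        _, tgt = tiny_domains
        res, _ = tiny_adapted
        h_phi = res.phi_T.param_hash()
        h_reg = tiny_pretrained.regressor.param_hash()
        subset = ArrayDataset(tgt["train"].X[:8], tgt["train"].y[:8])
        finetune(res.phi_T, tiny_pretrained.regressor, subset,
                 StageConfig(lr=1e-3, max_epochs=5, seed=0))
        assert res.phi_T.param_hash() == h_phi
        assert tiny_pretrained.regressor.param_hash() == h_reg

    def test_empty_subset_rejected(self, tiny_adapted, tiny_pretrained, tiny_domains):
        _, tgt = tiny_domains
        res, _ = tiny_adapted
        empty = ArrayDataset(tgt["train"].X[:0], tgt["train"].y[:0])
        with pytest.raises(ValueError, match="empty"):
            finetune(res.phi_T, tiny_pretrained.regressor, empty,
                     StageConfig(seed=0))


class TestPredict:
    def test_one_value_per_image_and_determinism(self, tiny_pretrained, tiny_domains):
        src, _ = tiny_domains
        batch = src["val"].X[:3]
        pred = predict(tiny_pretrained.fe, tiny_pretrained.regressor, batch)
        assert pred.shape == (3,)
        dup = predict(tiny_pretrained.fe, tiny_pretrained.regressor,
                      np.concatenate([batch[:1], batch[:1]]))
        assert dup[0] == dup[1]


def test_stage_config_validation():
    with pytest.raises(ValueError):
        StageConfig(patience=0)
    with pytest.raises(ValueError):
        StageConfig(lam=-0.1)
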