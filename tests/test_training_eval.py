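import json

import numpy as np
import pytest
from sklearn.metrics import (balanced_accuracy_score, cohen_kappa_score,
                             f1_score)

from sthma.head import smoothed_entropy_floor
from sthma.model import ModelConfig, build_model
from sthma.preprocessing import split_subjects
from sthma.synthetic_data import SyntheticTaskSpec, make_dataset
from sthma.training_eval import (Metrics, TrainConfig, compute_metrics,
                                 evaluate, export_results, patch_dataset,
                                 run_ablation, train)


class TestComputeMetrics:
    def test_perfect_predictor(self, rng):
        y = rng.integers(0, 4, 40)
        m = compute_metrics(y, y)
        assert m.balanced_accuracy == 100.0
        assert m.cohens_kappa == 100.0
        assert m.weighted_f1 == 100.0

    def test_constant_predictor_chance(self):
        # balanced 5-class labels, constant prediction -> bacc 20, kappa 0
        y = np.repeat(np.arange(5), 10)
        m = compute_metrics(y, np.zeros_like(y))
        assert np.isclose(m.balanced_accuracy, 20.0, atol=1e-10)
        assert np.isclose(m.cohens_kappa, 0.0, atol=1e-10)

    def test_hand_evaluated_confusion(self):
        # confusion [[8,2],[3,7]]: p_o=0.75, p_e=0.5 -> kappa 50.00;
        # weighted F1 74.94 (frozen from hand evaluation + sklearn)
        y_true = np.array([0] * 10 + [1] * 10)
        y_pred = np.array([0] * 8 + [1] * 2 + [0] * 3 + [1] * 7)
        m = compute_metrics(y_true, y_pred)
        np.testing.assert_array_equal(m.confusion, [[8, 2], [3, 7]])
        assert np.isclose(m.balanced_accuracy, 75.0, atol=1e-10)
        assert np.isclose(m.cohens_kappa, 50.0, atol=1e-10)
        assert np.isclose(m.weighted_f1, 74.9373, atol=1e-3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([]), np.array([]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([0, 1]), np.array([0]))

    def test_agrees_with_sklearn_on_random_vectors(self):
        # independent-library cross-check, 50 random prediction vectors
        for seed in range(50):
            r = np.random.default_rng(seed)
            k = int(r.integers(2, 6))
            n = int(r.integers(10, 60))
            y_true = r.integers(0, k, n)
            y_pred = r.integers(0, k, n)
            m = compute_metrics(y_true, y_pred, n_classes=k)
            labels = list(range(k))
            assert np.isclose(
                m.balanced_accuracy,
                100 * balanced_accuracy_score(y_true, y_pred), atol=1e-6)
            assert np.isclose(
                m.cohens_kappa,
                100 * cohen_kappa_score(y_true, y_pred, labels=labels),
                atol=1e-6)
            assert np.isclose(
                m.weighted_f1,
                100 * f1_score(y_true, y_pred, labels=labels,
                               average="weighted", zero_division=0),
                atol=1e-6)

    def test_uniform_random_predictor_chance_level(self):
        # invariant: chance baselines 100/K at n=90,000, kappa ~ 0
        r = np.random.default_rng(0)
        for k in (9, 5):
            n = 90_000
            y_true = np.tile(np.arange(k), n // k)
            y_pred = r.integers(0, k, y_true.size)
            m = compute_metrics(y_true, y_pred)
            assert abs(m.balanced_accuracy - 100.0 / k) < 0.7
            assert abs(m.cohens_kappa) < 0.7

    def test_confusion_sums(self, rng):
        y_true = rng.integers(0, 3, 30)
        y_pred = rng.integers(0, 3, 30)
        m = compute_metrics(y_true, y_pred, n_classes=3)
        np.testing.assert_array_equal(m.confusion.sum(axis=1),
                                      np.bincount(y_true, minlength=3))
        np.testing.assert_array_equal(m.confusion.sum(axis=0),
                                      np.bincount(y_pred, minlength=3))


def tiny_overfit_setup():
    spec = SyntheticTaskSpec(n_channels=2, n_classes=2, sfreq=64.0,
                             duration=1.0, noise_exponent=1.0,
                             class_bands=((8.0, 13.0), (20.0, 28.0)),
                             effect_size=4.0, seed=0)
    ds = make_dataset(spec, 16, 4, seed=0)
    cfg = ModelConfig(
        n_channels=2, n_patches=2, patch_size=32, n_classes=2,
        embedding=dict_cfg_embedding(),
        backbone=dict_cfg_backbone(),
        ssd=dict_cfg_ssd(),
        head=dict_cfg_head())
    return ds, cfg


def dict_cfg_embedding():
    from sthma.embedding import EmbeddingConfig
    return EmbeddingConfig(embed_dim=8, patch_size=32, conv_kernel=5,
                           gn_groups=2)


def dict_cfg_ssd():
    from sthma.backbone import SSDConfig
    return SSDConfig(d_state=4, n_heads=2, head_dim=8, expand=2)


def dict_cfg_backbone():
    from sthma.backbone import BackboneConfig
    return BackboneConfig(depth=1, schedule=("spatial_first",))


def dict_cfg_head():
    from sthma.head import HeadConfig
    return HeadConfig(n_classes=2, n_attn_heads=2, mlp_hidden=(32, 16),
                      dropout=(0.0, 0.0), smoothing=0.0)


class TestTrain:
    def test_overfits_tiny_dataset(self):
        # [DERIVED] overfitting sanity oracle: 32 trials, eps=0 -> 100% train
        ds, cfg = tiny_overfit_setup()
        model = build_model(cfg, seed=0)
        x, y = patch_dataset(ds, cfg.n_patches, cfg.patch_size)
        reached = False
        hist = None
        for _ in range(4):  # up to 200 epochs in 50-epoch slices
            hist, _ = train(model, (x, y), None,
                            TrainConfig(lr=3e-3, epochs=50, seed=0,
                                        smoothing=0.0))
            if hist["train_acc"][-1] == 100.0:
                reached = True
                break
        assert reached, f"final train acc {hist['train_acc'][-1]}"

    def test_zero_lr_freezes_weights(self):
        ds, cfg = tiny_overfit_setup()
        model = build_model(cfg, seed=0)
        x, y = patch_dataset(ds, cfg.n_patches, cfg.patch_size)
        before = model.state_dict()
        train(model, (x, y), None, TrainConfig(lr=0.0, weight_decay=0.0,
                                               epochs=1, seed=0))
        after = model.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_loss_never_below_smoothed_floor(self):
        ds, cfg = tiny_overfit_setup()
        model = build_model(cfg, seed=0)
        x, y = patch_dataset(ds, cfg.n_patches, cfg.patch_size)
        eps = 0.1
        hist, _ = train(model, (x, y), None,
                        TrainConfig(lr=3e-3, epochs=30, seed=0, smoothing=eps))
        floor = smoothed_entropy_floor(cfg.n_classes, eps)
        assert all(l >= floor - 1e-9 for l in hist["train_loss"])

    def test_history_records_val_metrics(self):
        ds, cfg = tiny_overfit_setup()
        model = build_model(cfg, seed=0)
        x, y = patch_dataset(ds, cfg.n_patches, cfg.patch_size)
        hist, best = train(model, (x[:24], y[:24]), (x[24:], y[24:]),
                           TrainConfig(lr=1e-3, epochs=2, seed=0))
        assert len(hist["val"]) == 2
        assert set(best) == set(model.state_dict())


class TestAblation:
    def test_full_variant_matches_default_structure(self, tiny_model_cfg):
        a = build_model(tiny_model_cfg, seed=0)
        b = build_model(tiny_model_cfg, seed=0, variant="full")
        sa, sb = a.state_dict(), b.state_dict()
        assert set(sa) == set(sb)
        for k in sa:
            np.testing.assert_array_equal(sa[k], sb[k])

    def test_no_spectral_has_fewer_parameters(self, tiny_model_cfg):
        full = build_model(tiny_model_cfg, seed=0)
        ablated = build_model(tiny_model_cfg, seed=0,
                              variant="no_spectral_stream")
        assert ablated.n_parameters() < full.n_parameters()

    def test_run_ablation_returns_metrics(self):
        ds, cfg = tiny_overfit_setup()
        m = run_ablation("no_temporal_stream", ds, ds, cfg,
                         TrainConfig(lr=1e-3, epochs=1, seed=0))
        assert isinstance(m, Metrics)
        assert m.confusion.sum() == len(ds)

    def test_unknown_variant_rejected(self, tiny_model_cfg):
        ds, cfg = tiny_overfit_setup()
        with pytest.raises(ValueError, match="variant"):
            run_ablation("no_everything", ds, ds, cfg, TrainConfig(epochs=1))

    def test_variant_wiring(self, tiny_model_cfg):
        nb = build_model(tiny_model_cfg, seed=0, variant="no_backbone")
        assert nb.backbone is None and nb.recalibration is not None
        pm = build_model(tiny_model_cfg, seed=0, variant="pure_mamba2")
        assert pm.backbone is not None and pm.recalibration is None
        nd = build_model(tiny_model_cfg, seed=0, variant="no_dual_domain")
        from sthma.embedding import LinearPatchEmbedding
        assert isinstance(nd.embedding, LinearPatchEmbedding)


class TestExportResults:
    def test_json_round_trip(self, tmp_path, rng):
        y_true = rng.integers(0, 3, 30)
        y_pred = rng.integers(0, 3, 30)
        m = compute_metrics(y_true, y_pred, n_classes=3)
        paths = export_results(m, tmp_path / "out")
        payload = json.loads(paths["json"].read_text())
        assert np.isclose(payload["balanced_accuracy"], m.balanced_accuracy)
        assert np.isclose(payload["cohens_kappa"], m.cohens_kappa)
        assert np.isclose(payload["weighted_f1"], m.weighted_f1)
        np.testing.assert_array_equal(payload["confusion"], m.confusion)

    def test_csv_sums_match_supports(self, tmp_path, rng):
        y_true = rng.integers(0, 4, 50)
        y_pred = rng.integers(0, 4, 50)
        m = compute_metrics(y_true, y_pred, n_classes=4)
        paths = export_results(m, tmp_path / "out")
        cm = np.loadtxt(paths["csv"], delimiter=",", skiprows=1, dtype=int)
        np.testing.assert_array_equal(cm.sum(axis=1),
                                      np.bincount(y_true, minlength=4))
        np.testing.assert_array_equal(cm.sum(axis=0),
                                      np.bincount(y_pred, minlength=4))

    def test_nine_class_confusion_shape(self, tmp_path, rng):
        y = rng.integers(0, 9, 90)
        m = compute_metrics(y, rng.integers(0, 9, 90), n_classes=9)
        paths = export_results(m, tmp_path / "out")
        assert np.asarray(json.loads(
            paths["json"].read_text())["confusion"]).shape == (9, 9)
        assert paths["figure"].exists()
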