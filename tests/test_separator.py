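"""Separator architecture contracts, training behaviour and checkpoints."""



import numpy as np
import pytest

from atacsep.separator import (
    SeparatorConfig,
    build_separator,
    count_parameters,
    load_checkpoint,
    save_checkpoint,
    separate,
    train_separator,
)
from atacsep.separator.network import segmentation_geometry
from tests.conftest import make_disjoint_support_set

SMALL = dict(
    n_sources=3, chunk_size=16, embed_dim=8, n_heads=2, ff_dim=24, seed=5
)


class TestArchitecture:
    def test_parameter_count_matches_analytic_oracle(self):
        for kwargs in (
            SMALL,
            dict(n_sources=6, chunk_size=250, embed_dim=64, n_heads=8, ff_dim=256),
            dict(n_sources=1, chunk_size=10, embed_dim=16, n_heads=4, ff_dim=32,
                 n_dualpath_blocks=2, n_attention_layers_per_path=2),
        ):
            cfg = SeparatorConfig(**kwargs)
            assert build_separator(cfg).n_parameters == count_parameters(cfg)

    def test_output_shape_contract(self):
        cfg = SeparatorConfig(**SMALL)
        model = build_separator(cfg)
        out = model.forward(np.random.default_rng(0).random((7, 40), dtype=np.float32))
        assert out.shape == (7, 3, 40)

    def test_single_source_autoencoder_shape(self):
        cfg = SeparatorConfig(**{**SMALL, "n_sources": 1})
        model = build_separator(cfg)
        out = model.forward(np.zeros((2, 40), dtype=np.float32))
        assert out.shape == (2, 1, 40)

    def test_same_config_and_seed_gives_identical_weights(self):
        cfg = SeparatorConfig(**SMALL)
        a = build_separator(cfg).named_parameters()
        b = build_separator(cfg).named_parameters()
        assert set(a) == set(b)
        for k in a:
            assert np.array_equal(a[k].data, b[k].data)

    def test_sequence_shorter_than_chunk_rejected(self):
        with pytest.raises(ValueError, match="shorter than chunk_size"):
            segmentation_geometry(10, 16, 0.0)

    def test_indivisible_heads_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            SeparatorConfig(embed_dim=30, n_heads=4)

    def test_permutation_equivariance_without_positional_encoding(self):
        """With positional encodings off and no chunk overlap the network is
        equivariant to permuting positions within chunks (the same way in
        every chunk) and to permuting whole chunks — the encoder is
        position-wise and the masks act multiplicatively."""
        C, K = 8, 4
        cfg = SeparatorConfig(
            n_sources=2,
            chunk_size=C,
            embed_dim=8,
            n_heads=2,
            ff_dim=16,
            chunk_overlap=0.0,
            use_positional_encoding=False,
            seed=2,
        )
        model = build_separator(cfg)
        rng = np.random.default_rng(0)
        x = rng.random((3, C * K), dtype=np.float32)
        sigma = rng.permutation(C)  # within-chunk offset permutation
        pi = rng.permutation(K)  # chunk permutation
        perm = np.concatenate([pi[k] * C + sigma for k in range(K)])
        out = model.forward(x).data
        out_perm = model.forward(x[:, perm]).data
        assert np.allclose(out[:, :, perm], out_perm, atol=1e-5)

    def test_default_hyperparameters_follow_the_recipe(self):
        cfg = SeparatorConfig()
        assert cfg.chunk_size == 250
        assert cfg.n_dualpath_blocks == 1
        assert cfg.ff_dim == 256
        assert cfg.batch_size == 32
        assert cfg.lr0 == pytest.approx(1e-3)
        assert cfg.grad_clip == 5
        assert cfg.val_fraction == pytest.approx(0.2)


class TestInference:
    @pytest.fixture(scope="class")
    def tiny_trained(self):
        ts = make_disjoint_support_set(n_pairs=96, S=3, width=16, seed=1)
        cfg = SeparatorConfig(
            n_sources=3,
            chunk_size=16,
            embed_dim=8,
            n_heads=2,
            ff_dim=24,
            max_epochs=2,
            patience=2,
            warmup_steps=10,
            seed=4,
        )
        model = build_separator(cfg)
        return train_separator(model, ts, cfg), ts

    def test_deterministic_and_batch_size_independent(self, tiny_trained):
        trained, ts = tiny_trained
        a = separate(trained, ts.bulk[:5], batch_size=1)
        b = separate(trained, ts.bulk[:5], batch_size=32)
        c = separate(trained, ts.bulk[:5], batch_size=32)
        assert np.array_equal(b, c)
        assert np.allclose(a, b, atol=1e-6)

    def test_zero_bulk_is_finite_and_small(self, tiny_trained):
        trained, ts = tiny_trained
        zero = separate(trained, np.zeros((1, ts.P), dtype=np.float32))
        some = separate(trained, ts.bulk[:8])
        assert np.all(np.isfinite(zero))
        assert zero.mean() <= some.mean()

    def test_nonnegative_output(self, tiny_trained):
        trained, ts = tiny_trained
        assert separate(trained, ts.bulk[:8]).min() >= 0

    def test_wrong_length_rejected(self, tiny_trained):
        trained, ts = tiny_trained
        with pytest.raises(ValueError, match="OCRs"):
            separate(trained, np.zeros((1, ts.P + 3), dtype=np.float32))


class TestCheckpoint:
    def test_roundtrip_predictions_bit_identical(self, tmp_path):
        ts = make_disjoint_support_set(n_pairs=64, S=2, width=16, seed=2)
        cfg = SeparatorConfig(
            n_sources=2, chunk_size=16, embed_dim=8, n_heads=2, ff_dim=16,
            max_epochs=1, warmup_steps=5, seed=6,
        )
        trained = train_separator(build_separator(cfg), ts, cfg)
        save_checkpoint(trained, tmp_path / "m.h5")
        back = load_checkpoint(tmp_path / "m.h5")
        probe = ts.bulk[:6]
        assert np.array_equal(separate(trained, probe), separate(back, probe))
        assert back.normalization_constant == trained.normalization_constant
        assert back.P == ts.P
        with pytest.raises(ValueError, match="OCRs"):
            separate(back, np.zeros((1, ts.P + 1), dtype=np.float32))


class TestTraining:
    def test_learns_disjoint_support_task(self):
        """On supports where each OCR belongs to exactly one cell type the
        trained model must cut the held-out loss far below the untrained
        one and, over the NMEA-retained OCRs, rank profiles almost
        perfectly (positions never accessible for a type have undefined
        NMEA and are excluded, exactly as in the full pipeline)."""
        from scipy.stats import spearmanr

        from atacsep.predictability import optimize_tau

        ts = make_disjoint_support_set(n_pairs=360, S=3, width=64, seed=3)
        train = ts.subset(np.arange(300))
        test = ts.subset(np.arange(300, 360))
        cfg = SeparatorConfig(
            n_sources=3,
            chunk_size=48,
            embed_dim=16,
            n_heads=1,
            ff_dim=64,
            chunk_overlap=0.0,
            warmup_steps=20,
            max_epochs=120,
            patience=20,
            lr0=5e-3,
            lr_decay=0.99,
            seed=7,
        )
        model = build_separator(cfg)
        # untrained loss from a fresh model with identical init
        fresh = build_separator(cfg)
        base = float(np.mean((fresh.forward(test.bulk).data - test.sources) ** 2))
        trained = train_separator(model, train, cfg)
        pred = separate(trained, test.bulk)
        final = float(np.mean((pred - test.sources) ** 2))
        assert final < 0.1 * base
        val = train.subset(trained.val_indices)
        pred_val = separate(trained, val.bulk)
        _, mask, _ = optimize_tau(pred_val, val.sources)
        rhos = [
            spearmanr(
                pred[n, i, mask.mask[i]], test.sources[n, i, mask.mask[i]]
            ).statistic
            for n in range(len(test))
            for i in range(test.S)
        ]
        assert np.nanmean(rhos) > 0.95

    def test_validation_defaults_and_early_stopping_contract(self):
        ts = make_disjoint_support_set(n_pairs=96, S=2, width=16, seed=4)
        cfg = SeparatorConfig(
            n_sources=2, chunk_size=16, embed_dim=8, n_heads=2, ff_dim=16,
            max_epochs=3, warmup_steps=5, seed=8,
        )
        trained = train_separator(build_separator(cfg), ts, cfg)
        assert cfg.val_fraction == pytest.approx(0.2)
        assert len(trained.val_indices) == round(0.2 * len(ts))
        hist = trained.training_history
        best = hist[-1]["best_val_loss"]
        assert best == min(h["val_loss"] for h in hist[:-1])

    def test_empty_training_set_rejected(self):
        ts = make_disjoint_support_set(n_pairs=4, S=2, width=8, seed=5)
        cfg = SeparatorConfig(n_sources=2, chunk_size=8, embed_dim=8, n_heads=2,
                              ff_dim=16, seed=1)
        with pytest.raises(ValueError):
            train_separator(build_separator(cfg), ts.subset(np.array([], dtype=int)), cfg)
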