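import math

import numpy as np
import pytest

import bis
from bis.model import (
    BisConfig,
    BisModel,
    LatentBatch,
    aggregate_to_distribution,
    bulk_consistency_kl,
    decode,
    encode,
    imq_kernel,
    impute,
    load_checkpoint,
    mmd_penalty,
    reconstruction_cost,
    sample_prior,
    save_checkpoint,
    total_loss,
    train,
)
from conftest import make_matrix

TINY_CFG = BisConfig(
    encoder_widths=(32, 16), bottleneck_dim=8, decoder_widths=(16, 32),
    epochs=30, batch_size=64, seed=0,
)


def _log_dataset(n=120, g=40, seed=0):
    ds = bis.simulate_groups(bis.SimParams(n_cells=n, n_genes=g, dropout_mid=2.0, seed=seed))
    obs = bis.filter_qc(ds.observed_counts, bis.QCThresholds(1, 1))
    return bis.log1p_transform(bis.normalize_total(obs))


class TestImqKernel:
    def test_equal_points_give_one(self):
        u = np.arange(5.0)
        assert imq_kernel(u, u, 3.0) == 1.0

    def test_half_when_sqdist_equals_C(self):
        u = np.zeros(4)
        v = np.array([2.0, 0, 0, 0])  # squared distance 4
        assert imq_kernel(u, v, 4.0) == pytest.approx(0.5)

    def test_default_kernel_constant_is_2dz_sigma2(self):
        cfg = BisConfig()
        assert cfg.C == pytest.approx(2 * 32 * 1.0**2) == 64.0


class TestSamplePrior:
    def test_moments(self):
        cfg = BisConfig(seed=9)
        z = sample_prior(10_000, cfg).codes
        # 4.5-sigma bound leaves negligible failure mass across 32 coordinates
        assert np.abs(z.mean(axis=0)).max() < 4.5 / math.sqrt(10_000)
        np.testing.assert_allclose(z.var(axis=0), 1.0, rtol=0.05)

    def test_seed_reproducible(self):
        cfg = BisConfig(seed=4)
        np.testing.assert_array_equal(
            sample_prior(50, cfg).codes, sample_prior(50, cfg).codes
        )


class TestMMD:
    def brute_force(self, a, b, C):
        n, m = len(a), len(b)
        qq = sum(imq_kernel(a[i], a[j], C) for i in range(n) for j in range(n)) / n**2
        pp = sum(imq_kernel(b[i], b[j], C) for i in range(m) for j in range(m)) / m**2
        qp = sum(imq_kernel(a[i], b[j], C) for i in range(n) for j in range(m)) / (n * m)
        return qq + pp - 2 * qp

    def test_identical_sets_give_zero(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(10, 4))
        assert mmd_penalty(LatentBatch(z), LatentBatch(z.copy(), "prior"), 8.0) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_double_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(rng.integers(2, 12), 3))
        b = rng.normal(size=(rng.integers(2, 12), 3))
        got = mmd_penalty(LatentBatch(a), LatentBatch(b, "prior"), 6.0)
        assert got == pytest.approx(self.brute_force(a, b, 6.0), abs=1e-10)

    def test_same_distribution_converges_to_zero(self):
        cfg = BisConfig(seed=1)
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, size=(2000, 32))
        b = rng.normal(0, 1, size=(2000, 32))
        assert mmd_penalty(LatentBatch(a), LatentBatch(b, "prior"), cfg.C) < 0.01

    def test_nonnegative_on_random_batches(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            a = rng.normal(size=(8, 5)) * rng.uniform(0.2, 3)
            b = rng.normal(size=(13, 5))
            assert mmd_penalty(LatentBatch(a), LatentBatch(b, "prior"), 10.0) >= -1e-10


class TestReconstructionCost:
    def test_zero_for_identical(self):
        x = np.random.default_rng(0).random((5, 4))
        assert reconstruction_cost(x, x) == 0.0

    def test_single_cell_value(self):
        assert reconstruction_cost([[1.0, 2.0]], [[0.0, 0.0]]) == pytest.approx(5.0)

    def test_mean_over_cells(self):
        x = np.array([[1.0, 2.0], [1.0, 0.0]])
        xh = np.array([[0.0, 0.0], [0.0, 0.0]])
        assert reconstruction_cost(x, xh) == pytest.approx(3.0)  # mean of (5, 1)


class TestDistributions:
    def test_aggregate_means_then_normalizes(self):
        q = aggregate_to_distribution(np.array([[1.0, 3.0], [3.0, 1.0]]), eps=0)
        np.testing.assert_allclose(q, [0.5, 0.5])

    def test_aggregate_single_simplex_row_identity(self):
        q = aggregate_to_distribution(np.array([[0.2, 0.3, 0.5]]), eps=0)
        np.testing.assert_allclose(q, [0.2, 0.3, 0.5])

    def test_aggregate_all_zero_smooths_to_uniform(self):
        q = aggregate_to_distribution(np.zeros((3, 4)), eps=1e-8)
        np.testing.assert_allclose(q, 0.25)

    def test_kl_zero_iff_equal(self):
        p = np.array([0.1, 0.4, 0.5])
        assert bulk_consistency_kl(p, p) == 0.0
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.dirichlet(np.ones(6))
            b = rng.dirichlet(np.ones(6))
            assert bulk_consistency_kl(a, b) >= 0.0

    def test_kl_hand_values(self):
        assert bulk_consistency_kl([0.5, 0.5], [0.25, 0.75]) == pytest.approx(0.143841, abs=1e-6)
        assert bulk_consistency_kl([1.0, 0.0], [0.5, 0.5]) == pytest.approx(math.log(2), abs=1e-12)


class TestTotalLoss:
    def test_degenerate_weights_reduce_to_reconstruction(self):
        rng = np.random.default_rng(0)
        x, xh = rng.random((6, 5)), rng.random((6, 5))
        z = LatentBatch(rng.normal(size=(6, 3)))
        zp = LatentBatch(rng.normal(size=(6, 3)), "prior")
        cfg = BisConfig(bottleneck_dim=3, lam=0.0, beta=0.0)
        total, comps = total_loss(x, xh, z, zp, np.full(5, 0.2), cfg)
        assert total == pytest.approx(reconstruction_cost(x, xh))
        assert comps["mmd"] >= 0 and comps["kl"] >= 0

    def test_affine_combination(self):
        rng = np.random.default_rng(3)
        x, xh = rng.random((6, 5)), rng.random((6, 5))
        z = LatentBatch(rng.normal(size=(6, 3)))
        zp = LatentBatch(rng.normal(size=(6, 3)), "prior")
        cfg = BisConfig(bottleneck_dim=3, lam=0.01, beta=0.5)
        total, c = total_loss(x, xh, z, zp, np.full(5, 0.2), cfg)
        assert total == pytest.approx(
            c["reconstruction"] + 0.01 * c["mmd"] + 0.5 * c["kl"], abs=1e-12
        )

    def test_perfect_everything_is_zero(self):
        x = np.random.default_rng(0).random((4, 3)) + 0.1
        z = LatentBatch(np.random.default_rng(1).normal(size=(4, 2)))
        cfg = BisConfig(bottleneck_dim=2, eps=0.0)
        p = aggregate_to_distribution(x, 0.0)
        total, _ = total_loss(x, x, z, LatentBatch(z.codes.copy(), "prior"), p, cfg)
        assert total == pytest.approx(0.0, abs=1e-10)


class TestEncodeDecode:
    def test_shapes_and_determinism(self):
        x = _log_dataset()
        model = BisModel(x.n_cols, TINY_CFG)
        z = encode(x, model)
        assert z.codes.shape == (x.n_rows, 8)
        dup = encode(np.vstack([x.values[0], x.values[0]]), model)
        np.testing.assert_array_equal(dup.codes[0], dup.codes[1])

    def test_decode_nonnegative(self):
        model = BisModel(40, TINY_CFG)
        z = LatentBatch(np.random.default_rng(0).normal(size=(7, 8)))
        out = decode(z, model)
        assert out.shape == (7, 40)
        assert out.min() >= 0.0

    def test_dimension_mismatches_error(self):
        model = BisModel(40, TINY_CFG)
        with pytest.raises(ValueError, match="gene dimension"):
            model.encode_array(np.ones((3, 17)))
        with pytest.raises(ValueError, match="code dimension"):
            model.decode_array(np.ones((3, 5)))
        with pytest.raises(ValueError, match="nonempty"):
            model.encode_array(np.ones((0, 40)))


class TestTraining:
    def test_loss_decreases(self):
        x = _log_dataset(200, 50)
        cfg = BisConfig(
            encoder_widths=(32, 16), bottleneck_dim=8, decoder_widths=(16, 32),
            epochs=50, batch_size=64, seed=0,
        )
        model, hist = train(x, None, cfg)
        assert hist.total_loss[-1] < hist.total_loss[0]
        assert model.trained

    def test_same_seed_identical_history(self):
        x = _log_dataset(80, 30)
        cfg = BisConfig(
            encoder_widths=(16,), bottleneck_dim=4, decoder_widths=(16,),
            epochs=8, batch_size=32, seed=3,
        )
        _, h1 = train(x, None, cfg)
        _, h2 = train(x, None, cfg)
        assert h1.total_loss == h2.total_loss
        assert h1.mmd_loss == h2.mmd_loss

    def test_zero_weights_still_report_components(self):
        x = _log_dataset(80, 30)
        counts = x.with_values(np.round(np.expm1(x.values)), layer_tag="raw_counts")
        bulk = bis.synth_bulk(counts, n_samples=2, noise_cv=0.0)
        bulk = bis.log1p_transform(bis.normalize_total(bulk))
        _, bulk = bis.align_genes(x, bulk)
        cfg = BisConfig(
            encoder_widths=(16,), bottleneck_dim=4, decoder_widths=(16,),
            epochs=4, batch_size=32, seed=3, lam=0.0, beta=0.0,
        )
        _, h = train(x, bulk, cfg)
        assert all(m > 0 for m in h.mmd_loss)
        assert all(k > 0 for k in h.kl_loss)
        for r, m, k, t in zip(
            h.reconstruction_loss, h.mmd_loss, h.kl_loss, h.total_loss
        ):
            assert t == pytest.approx(r, abs=1e-9)

    def test_history_decomposition(self):
        x = _log_dataset(100, 30)
        counts = x.with_values(np.round(np.expm1(x.values)), layer_tag="raw_counts")
        bulk = bis.synth_bulk(counts, 2, 0.0)
        bulk = bis.log1p_transform(bis.normalize_total(bulk))
        _, bulk = bis.align_genes(x, bulk)
        cfg = BisConfig(
            encoder_widths=(16,), bottleneck_dim=4, decoder_widths=(16,),
            epochs=6, batch_size=48, seed=1,
        )
        _, h = train(x, bulk, cfg)
        for r, m, k, t in zip(
            h.reconstruction_loss, h.mmd_loss, h.kl_loss, h.total_loss
        ):
            assert t == pytest.approx(r + cfg.lam * m + cfg.beta * k, abs=1e-6)

    def test_misaligned_bulk_rejected(self):
        x = _log_dataset(60, 25)
        bulk = make_matrix(np.ones((2, 10)), row_prefix="s", col_prefix="other")
        with pytest.raises(ValueError, match="align"):
            train(x, bulk, TINY_CFG)

    def test_batch_size_one_rejected(self):
        with pytest.raises(ValueError, match="batch_size"):
            BisConfig(batch_size=1)


@pytest.fixture(scope="module")
def trained():
    x = _log_dataset(150, 40)
    model, _ = train(x, None, TINY_CFG)
    return x, model


class TestImpute:

    def test_fill_zeros_only_preserves_nonzeros(self, trained):
        x, model = trained
        cfg = BisConfig(
            encoder_widths=(32, 16), bottleneck_dim=8, decoder_widths=(16, 32),
            seed=0, fill_zeros_only=True,
        )
        out = impute(model, x, cfg)
        nz = x.values > 0
        np.testing.assert_array_equal(out.values[nz], x.values[nz])
        assert out.layer_tag == "imputed"

    def test_full_mode_is_autoencoder_output(self, trained):
        x, model = trained
        out = impute(model, x)
        expected = model.decode_array(model.encode_array(x.values))
        np.testing.assert_array_equal(out.values, expected)
        assert out.values.min() >= 0.0

    def test_untrained_model_rejected(self):
        model = BisModel(40, TINY_CFG)
        with pytest.raises(ValueError, match="trained"):
            impute(model, _log_dataset(30, 40))

    def test_checkpoint_round_trip(self, trained, tmp_path):
        x, model = trained
        p = tmp_path / "model.npz"
        save_checkpoint(model, str(p))
        back = load_checkpoint(str(p))
        np.testing.assert_array_equal(
            impute(back, x).values, impute(model, x).values
        )
        assert back.gene_ids == model.gene_ids
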