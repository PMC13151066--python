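"""Masked CVAE: tokenization, condition masking, losses, training, sampling."""

import numpy as np
import pytest

from pepmorph import nn
from pepmorph.cvae import (
    BOS,
    EOS,
    PAD,
    V,
    CVAEConfig,
    MaskedCVAE,
    PepMorphModel,
    auxiliary_losses,
    detokenize,
    kl_divergence,
    reconstruction_loss,
    stochastic_mask,
    tokenize,
    tokenize_batch,
    toy_config,
    train_cvae,
    _corpus_arrays,
)
from pepmorph.descriptors import InvalidPeptideError, Peptide, SLOT_NAMES
from pepmorph import make_synthetic_corpus


@pytest.fixture(scope="module")
def random_net():
    """An untrained network: structural contracts don't need training."""
    return MaskedCVAE(toy_config(), np.random.default_rng(0))


@pytest.fixture(scope="module")
def overfit_model():
    """Tiny corpus memorization run shared by the overfit-family tests."""
    corpus = make_synthetic_corpus(50, seed=11)
    cfg = toy_config(epochs=600, beta_max=0.0, batch_size=16,
                     mask_drop_prob=0.0, label_smoothing=0.0, latent_dim=16)
    model, history = train_cvae(corpus, None, cfg, seed=0)
    return corpus, model, history


class TestTokenization:
    def test_framing_example(self):
        ids = tokenize("ACD")
        assert ids[0] == BOS
        assert detokenize(ids) == "ACD"
        assert ids[4] == EOS
        assert all(t == PAD for t in ids[5:])
        assert len(ids) == 12

    def test_round_trip_random(self, rng):
        from pepmorph.descriptors import CANONICAL_RESIDUES

        for _ in range(50):
            L = rng.integers(1, 11)
            seq = "".join(rng.choice(list(CANONICAL_RESIDUES), size=L))
            assert detokenize(tokenize(seq)) == seq

    def test_full_length_has_no_slack_pad(self):
        ids = tokenize("ACDEFGHIKL")
        assert ids[-1] == EOS
        assert PAD not in ids

    def test_too_long_errors(self):
        with pytest.raises(InvalidPeptideError):
            tokenize("ACDEFGHIKLV")


class TestConditionSummary:
    def test_fully_masked_ignores_values(self, random_net):
        m = np.zeros(6)
        s1 = random_net.summarize(np.zeros(6), m).numpy()
        s2 = random_net.summarize(np.ones(6) * 7, m).numpy()
        assert np.array_equal(s1, s2)

    def test_unobserved_slot_is_invisible(self, random_net):
        c = np.array([0.5, 0.2, 1.0, 0.0, 0.7, 0.4])
        m = np.array([1.0, 0, 1, 1, 0, 1])
        s1 = random_net.summarize(c, m).numpy()
        c2 = c.copy()
        c2[1] = 99.0
        c2[4] = -5.0
        s2 = random_net.summarize(c2, m).numpy()
        assert np.array_equal(s1, s2)

    def test_observed_slot_is_visible(self, random_net):
        c = np.array([0.5, 0.2, 1.0, 0.0, 0.7, 0.4])
        m = np.ones(6)
        s1 = random_net.summarize(c, m).numpy()
        c2 = c.copy()
        c2[4] += 0.3
        s2 = random_net.summarize(c2, m).numpy()
        assert not np.array_equal(s1, s2)

    def test_prior_inherits_invisibility(self, random_net):
        c = np.array([0.5, 0.2, 1.0, 0.0, 0.7, 0.4])
        m = np.array([1.0, 0, 1, 1, 0, 1])
        mu1, lv1 = random_net.prior(random_net.summarize(c, m))
        c2 = c.copy()
        c2[1] = 99.0
        mu2, lv2 = random_net.prior(random_net.summarize(c2, m))
        assert np.array_equal(mu1.numpy(), mu2.numpy())
        assert np.array_equal(lv1.numpy(), lv2.numpy())

    def test_dimension_mismatch(self, random_net):
        with pytest.raises(ValueError):
            random_net.summarize(np.zeros(5), np.zeros(6))


class TestEncoder:
    def test_pad_invariance(self, random_net):
        # a short peptide framed at 8 vs 12 positions: same pooled posterior
        base = [BOS] + [5, 6, 7] + [EOS]
        short = np.array([base + [PAD] * 3])
        long = np.array([base + [PAD] * 7])
        mu1, lv1 = random_net.encode(short)
        mu2, lv2 = random_net.encode(long)
        assert np.allclose(mu1.numpy(), mu2.numpy(), atol=1e-10)
        assert np.allclose(lv1.numpy(), lv2.numpy(), atol=1e-10)

    def test_distinct_peptides_distinct_means(self, random_net):
        t = tokenize_batch(["ACDF", "WYKR"])
        mu, _ = random_net.encode(t)
        assert not np.allclose(mu.numpy()[0], mu.numpy()[1])

    def test_batch_vs_single(self, random_net):
        t = tokenize_batch(["ACDF", "WYKR", "GGG"])
        mu_b, _ = random_net.encode(t)
        for i in range(3):
            mu_s, _ = random_net.encode(t[i][None, :])
            assert np.allclose(mu_b.numpy()[i], mu_s.numpy()[0], atol=1e-10)

    def test_all_pad_errors(self, random_net):
        with pytest.raises(ValueError):
            random_net.encode(np.full((1, 12), PAD))


class TestKL:
    def test_identical_is_zero(self):
        mu = np.array([[0.3, -1.2]])
        lv = np.array([[0.1, -0.5]])
        assert kl_divergence(mu, lv, mu, lv) == pytest.approx(0.0, abs=1e-12)

    def test_unit_shift_closed_form(self):
        # K=1, mu_q=1, sigma=1 both, mu_p=0 -> KL = 0.5
        assert kl_divergence([[1.0]], [[0.0]], [[0.0]], [[0.0]]) == pytest.approx(0.5)

    def test_monte_carlo_oracle(self, rng):
        """Closed form agrees with E_q[log q - log p] within 3 SEs at 1e5."""
        mu_q, lv_q = rng.normal(size=(1, 3)), rng.normal(scale=0.5, size=(1, 3))
        mu_p, lv_p = rng.normal(size=(1, 3)), rng.normal(scale=0.5, size=(1, 3))
        analytic = kl_divergence(mu_q, lv_q, mu_p, lv_p)
        sd_q, sd_p = np.exp(lv_q / 2), np.exp(lv_p / 2)
        z = mu_q + sd_q * rng.standard_normal((100_000, 3))
        log_q = (-0.5 * ((z - mu_q) / sd_q) ** 2 - np.log(sd_q)
                 - 0.5 * np.log(2 * np.pi)).sum(axis=1)
        log_p = (-0.5 * ((z - mu_p) / sd_p) ** 2 - np.log(sd_p)
                 - 0.5 * np.log(2 * np.pi)).sum(axis=1)
        diff = log_q - log_p
        se = diff.std(ddof=1) / np.sqrt(len(diff))
        assert abs(diff.mean() - analytic) < 3 * se + 1e-9

    def test_nonnegative_random_pairs(self, rng):
        for _ in range(100):
            args = [rng.normal(size=(1, 4)) for _ in range(4)]
            assert kl_divergence(*args) >= -1e-12

    def test_nonfinite_variance_errors(self):
        with pytest.raises(ValueError):
            kl_divergence([[0.0]], [[np.inf]], [[0.0]], [[0.0]])


class TestReconstructionLoss:
    def test_perfect_logits_no_smoothing(self):
        targets = np.array([[3, 4, EOS, PAD]])
        logits_data = np.full((1, 4, V), -1e3)
        for t, tok in enumerate(targets[0]):
            if tok != PAD:
                logits_data[0, t, tok] = 1e3
        loss = reconstruction_loss(nn.Tensor(logits_data), targets, 0.0)
        assert float(loss.numpy()) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_logits_give_log_v(self):
        targets = np.array([[3, 4, EOS]])
        loss = reconstruction_loss(nn.Tensor(np.zeros((1, 3, V))), targets, 0.0)
        assert float(loss.numpy()) == pytest.approx(np.log(V))

    def test_smoothed_floor_matches_closed_form(self):
        """With smoothing ε the optimal distribution is w (target mass
        1−ε+ε/V, others ε/V) and the floor is its entropy H(w)."""
        eps = 0.1
        w = np.full(V, eps / V)
        target_tok = 5
        w[target_tok] = 1 - eps + eps / V
        logits = nn.Tensor(np.log(w)[None, None, :])
        targets = np.array([[target_tok]])
        floor = float(reconstruction_loss(logits, targets, eps).numpy())
        assert floor == pytest.approx(-(w * np.log(w)).sum(), rel=1e-9)
        # any other distribution does worse
        off = nn.Tensor(np.zeros((1, 1, V)))
        assert float(reconstruction_loss(off, targets, eps).numpy()) > floor

    def test_pad_positions_excluded(self):
        targets = np.array([[3, EOS, PAD, PAD]])
        logits_data = np.zeros((1, 4, V))
        loss = reconstruction_loss(nn.Tensor(logits_data), targets, 0.0)
        assert float(loss.numpy()) == pytest.approx(np.log(V))  # mean over 2 real positions


class TestAuxiliaryLosses:
    def test_perfect_predictions_vanish(self):
        c = np.array([[0.5, 0.2, 1.0, 0.0, 0.7, 0.4]])
        m = np.ones((1, 6))
        big = 1e4
        mask_logits = nn.Tensor(np.full((1, 6), big))
        bin_logits = nn.Tensor(np.array([[big, -big]]))   # targets 1, 0
        cont_preds = nn.Tensor(c[:, [0, 1, 4, 5]])
        l_mask, l_bin, l_cont = auxiliary_losses(c, m, m, mask_logits,
                                                 bin_logits, cont_preds)
        assert float(l_mask.numpy()) == pytest.approx(0.0, abs=1e-6)
        assert float(l_bin.numpy()) == pytest.approx(0.0, abs=1e-6)
        assert float(l_cont.numpy()) == pytest.approx(0.0, abs=1e-12)

    def test_no_observed_continuous_contributes_zero(self):
        c = np.array([[np.nan, np.nan, 1.0, 0.0, np.nan, np.nan]])
        m = np.array([[0.0, 0, 1, 1, 0, 0]])
        _, _, l_cont = auxiliary_losses(
            c, m, m, nn.Tensor(np.zeros((1, 6))), nn.Tensor(np.zeros((1, 2))),
            nn.Tensor(np.ones((1, 4))))
        assert float(l_cont.numpy()) == 0.0

    def test_matches_scalar_arithmetic(self, rng):
        """Vectorized implementation equals a hand-rolled per-element loop."""
        B = 5
        c = rng.uniform(0, 1, size=(B, 6))
        c[:, 2:4] = rng.integers(0, 2, size=(B, 2))
        m = (rng.random((B, 6)) > 0.4).astype(float)
        m[:, 0] = 1.0
        mask_logits = rng.normal(size=(B, 6))
        bin_logits = rng.normal(size=(B, 2))
        cont_preds = rng.normal(size=(B, 4))
        l_mask, l_bin, l_cont = auxiliary_losses(
            c, m, m, nn.Tensor(mask_logits), nn.Tensor(bin_logits),
            nn.Tensor(cont_preds))

        def bce(x, t):
            p = 1 / (1 + np.exp(-x))
            return -t * np.log(p) - (1 - t) * np.log(1 - p)

        exp_mask = np.mean([bce(mask_logits[n, i], m[n, i])
                            for n in range(B) for i in range(6)])
        exp_bin = 0.0
        for n in range(B):
            obs = [j for j, slot in enumerate((2, 3)) if m[n, slot] == 1]
            if obs:
                exp_bin += np.mean([bce(bin_logits[n, j], c[n, (2, 3)[j]])
                                    for j in obs])
        exp_bin /= B
        exp_cont = 0.0
        for n in range(B):
            obs = [j for j, slot in enumerate((0, 1, 4, 5)) if m[n, slot] == 1]
            if obs:
                exp_cont += np.mean([(cont_preds[n, j] - c[n, (0, 1, 4, 5)[j]]) ** 2
                                     for j in obs])
        exp_cont /= B
        assert float(l_mask.numpy()) == pytest.approx(exp_mask, rel=1e-9)
        assert float(l_bin.numpy()) == pytest.approx(exp_bin, rel=1e-9)
        assert float(l_cont.numpy()) == pytest.approx(exp_cont, rel=1e-9)


class TestTotalLoss:
    def test_weighted_sum(self):
        from pepmorph.cvae import LossBreakdown, total_loss

        parts = LossBreakdown(rec=1.0, kl=1.0, mask=1.0, bin=1.0, cont=1.0,
                              beta=1.0, lambda_mask=1.0, lambda_bin=1.0,
                              lambda_cont=1.0)
        assert total_loss(parts) == 5.0
        parts.beta = 0.0
        parts.lambda_mask = parts.lambda_bin = parts.lambda_cont = 0.0
        assert total_loss(parts) == 1.0

    def test_random_weights_match_arithmetic(self, rng):
        from pepmorph.cvae import LossBreakdown, total_loss

        vals = rng.uniform(0, 2, size=9)
        parts = LossBreakdown(*vals)
        expected = (vals[0] + vals[5] * vals[1] + vals[6] * vals[2]
                    + vals[7] * vals[3] + vals[8] * vals[4])
        assert total_loss(parts) == pytest.approx(expected)


class TestStochasticMask:
    def test_single_observed_always_kept(self, rng):
        m = np.array([[0, 0, 1, 0, 0, 0]], dtype=float)
        for _ in range(200):
            out = stochastic_mask(m, rng, drop_prob=0.9)
            assert np.array_equal(out, m)

    def test_zero_drop_is_identity(self, rng):
        m = np.array([[1, 1, 0, 1, 0, 1]], dtype=float)
        assert np.array_equal(stochastic_mask(m, rng, 0.0), m)

    def test_subset_and_nonempty(self, rng):
        m = np.array([[1, 1, 1, 0, 1, 1]], dtype=float)
        for _ in range(300):
            out = stochastic_mask(m, rng, 0.7)
            assert np.all(out <= m)
            assert out.sum() >= 1

    def test_retention_rate_under_keep_one(self, rng):
        """Empirical retention matches the keep-one-corrected expectation."""
        d_obs = 4
        m = np.zeros((1, 6))
        m[0, :d_obs] = 1
        p = 0.5
        draws = np.array([stochastic_mask(m, rng, p)[0, :d_obs]
                          for _ in range(20_000)])
        # P(slot kept) = (1-p) + p^d_obs / d_obs (slot re-added when all drop)
        expected = (1 - p) + p ** d_obs / d_obs
        assert np.allclose(draws.mean(axis=0), expected, atol=0.015)

    def test_empty_mask_errors(self, rng):
        with pytest.raises(ValueError):
            stochastic_mask(np.zeros((1, 6)), rng)


class TestTraining:
    def test_loss_decreases(self, small_splits):
        train_df, val_df, _ = small_splits
        model, hist = train_cvae(train_df, val_df, toy_config(epochs=6), seed=0)
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_empty_corpus_errors(self, small_corpus):
        import pandas as pd

        with pytest.raises(ValueError):
            train_cvae(pd.DataFrame(columns=small_corpus.columns), None,
                       toy_config(epochs=1))

    def test_weighted_sampler_enriches_positives(self, small_corpus):
        """Positive has_beta_strand rows are resampled ≈10x their base rate."""
        from pepmorph.cvae import _sample_weights

        cfg = toy_config()
        w = _sample_weights(small_corpus, cfg)
        beta_pos = np.nan_to_num(small_corpus["has_beta_strand"].to_numpy()) == 1
        assembled_only = (np.nan_to_num(small_corpus["is_assembled"].to_numpy()) == 1) & ~beta_pos
        neither = ~beta_pos & ~assembled_only
        if beta_pos.any() and neither.any():
            ratio = w[beta_pos].mean() / w[neither].mean()
            assert ratio == pytest.approx(10.0, rel=0.25) or ratio > 10


class TestOverfitFamily:
    def test_memorization(self, overfit_model):
        """Teacher-forced CE on the 50 training peptides drops below 0.05
        nats when the model is allowed to memorize them."""
        corpus, model, _ = overfit_model
        tokens, c, m = _corpus_arrays(corpus, model.stats)
        with nn.no_grad():
            mu_q, _ = model.net.encode(tokens)
            s = model.net.summarize(np.nan_to_num(c), m)
            logits = model.net.decode_logits(tokens[:, :-1], mu_q, s)
            ce = reconstruction_loss(logits, tokens[:, 1:], 0.0)
        assert float(ce.numpy()) < 0.05

    def test_no_posterior_collapse(self, overfit_model):
        corpus, model, _ = overfit_model
        tokens, _, _ = _corpus_arrays(corpus, model.stats)
        with nn.no_grad():
            mu_q, _ = model.net.encode(tokens)
        mu = mu_q.numpy()
        dist = np.linalg.norm(mu[:, None] - mu[None, :], axis=-1)
        off_diag = dist[~np.eye(len(mu), dtype=bool)]
        assert off_diag.min() > 0.0

    def test_generation_contract_and_determinism(self, overfit_model):
        corpus, model, _ = overfit_model
        c, m = model.condition_from_targets(length=5)
        a = [p.sequence for p in model.generate(c, m, 20, np.random.default_rng(3))]
        b = [p.sequence for p in model.generate(c, m, 20, np.random.default_rng(3))]
        assert a == b
        for seq in a:
            Peptide(seq)  # valid peptides, length <= 10

    def test_checkpoint_round_trip(self, overfit_model, tmp_path):
        corpus, model, _ = overfit_model
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = PepMorphModel.load(path)
        c, m = model.condition_from_targets(length=6)
        a = [p.sequence for p in model.generate(c, m, 15, np.random.default_rng(9))]
        b = [p.sequence for p in loaded.generate(c, m, 15, np.random.default_rng(9))]
        assert a == b

    def test_generation_masked_slot_invisibility(self, overfit_model):
        """Perturbing an unobserved slot changes nothing at fixed seed."""
        corpus, model, _ = overfit_model
        c, m = model.condition_from_targets(length=6)
        c2 = c.copy()
        for i, name in enumerate(SLOT_NAMES):
            if not m[i]:
                c2[i] = 123.0
        a = [p.sequence for p in model.generate(c, m, 15, np.random.default_rng(4))]
        b = [p.sequence for p in model.generate(c2, m, 15, np.random.default_rng(4))]
        assert a == b
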