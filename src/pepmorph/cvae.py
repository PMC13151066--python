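"""Masked conditional variational autoencoder for peptide generation.

The model conditions on a 6-slot descriptor vector ``c`` together with a
binary observation mask ``m``: a small MLP summarizes ``[c ⊙ m, m]`` into
a condition summary ``s`` that parametrizes both a diagonal-Gaussian
latent prior ``p(z|s)`` and (as a memory token, next to a latent token
from ``z``) the cross-attention of an autoregressive transformer decoder.
Unobserved descriptor slots are marginalized by the conditional prior,
never imputed, so any subset of descriptors can be specified at
generation time.

Training minimizes label-smoothed token cross-entropy plus a cyclic
KL term against the masked conditional prior and three light auxiliary
heads (mask reconstruction; observed-only BCE on the binary slots;
observed-only MSE on the continuous slots), with weighted sampling for
the rare positive binary labels and per-epoch augmentation with random
length-only peptides.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import nn
from .descriptors import (
    BINARY_SLOTS,
    CANONICAL_RESIDUES,
    CONTINUOUS_SLOTS,
    L_MAX,
    SLOT_NAMES,
    Peptide,
    ScalingStats,
)

__all__ = [
    "PAD", "BOS", "EOS", "VOCAB", "CVAEConfig", "MaskedCVAE",
    "PepMorphModel", "tokenize", "detokenize", "stochastic_mask",
    "kl_divergence", "reconstruction_loss", "auxiliary_losses", "total_loss",
    "LossBreakdown", "train_cvae", "toy_config",
]

# Vocabulary: 20 canonical residues plus <pad>, <bos>, <eos>.
PAD, BOS, EOS = 0, 1, 2
VOCAB = ["<pad>", "<bos>", "<eos>"] + list(CANONICAL_RESIDUES)
TOKEN_OF = {t: i for i, t in enumerate(VOCAB)}
V = len(VOCAB)              # 23 symbols
FRAME = L_MAX + 2           # <bos> + residues + <eos>, right-padded


def tokenize(p: Peptide | str) -> np.ndarray:
    """Frame a peptide as [<bos>, residues..., <eos>, <pad>...] of FRAME length."""
    pep = p if isinstance(p, Peptide) else Peptide(str(p))
    ids = [BOS] + [TOKEN_OF[r] for r in pep.sequence] + [EOS]
    ids += [PAD] * (FRAME - len(ids))
    return np.array(ids, dtype=np.int64)


def detokenize(ids: np.ndarray) -> str:
    """Inverse of :func:`tokenize`; residues between <bos> and <eos>."""
    out = []
    for t in np.asarray(ids).tolist():
        if t == BOS:
            continue
        if t in (EOS, PAD):
            break
        out.append(VOCAB[t])
    return "".join(out)


def tokenize_batch(sequences) -> np.ndarray:
    return np.stack([tokenize(s) for s in sequences])


@dataclass(frozen=True)
class CVAEConfig:
    """Hyperparameters. Architecture defaults are the full-scale settings
    (2-layer / 8-head / width-256 encoder and decoder); the unstated knobs
    (latent and summary width, auxiliary weights, smoothing, mask-drop
    probability, cyclic-KL schedule) carry documented defaults.
    """

    d_model: int = 256
    n_heads: int = 8
    n_layers: int = 2
    ff_dim: int = 512
    latent_dim: int = 32
    summary_dim: int = 64
    phi_hidden: int = 128
    label_smoothing: float = 0.1
    mask_drop_prob: float = 0.5
    lambda_mask: float = 1.0
    lambda_bin: float = 1.0
    lambda_cont: float = 1.0
    beta_max: float = 1.0
    beta_period: int = 25
    lr: float = 1e-3
    weight_decay: float = 1e-4
    epochs: int = 250
    batch_size: int = 256
    plateau_patience: int = 30
    augment_per_epoch: int = 5000
    sample_weight_assembled: float = 2.0
    sample_weight_beta: float = 10.0
    temperature: float = 1.0


def toy_config(**overrides) -> CVAEConfig:
    """Desk-scale configuration for tests and worked examples.

    Label smoothing is near zero here: with temperature-1 multinomial
    decoding, smoothing ε caps the per-step probability of the correct
    token (notably <eos>) at ≈1−ε, which directly bounds achievable
    condition compliance on small corpora.
    """
    base = CVAEConfig(d_model=48, n_heads=4, n_layers=2, ff_dim=96,
                      latent_dim=8, summary_dim=16, phi_hidden=32,
                      label_smoothing=0.01, epochs=40, batch_size=128,
                      augment_per_epoch=0, beta_period=10, beta_max=0.2)
    return replace(base, **overrides)


class MaskedCVAE(nn.Module):
    """Encoder, masked conditional prior, auxiliary heads, and decoder."""

    def __init__(self, config: CVAEConfig, rng: np.random.Generator):
        c = config
        self.config = c
        d = c.d_model
        self.token_emb = nn.Embedding(V, d, rng)
        self.pos_table = nn.sinusoidal_positions(FRAME, d)
        self.encoder_layers = [
            nn.TransformerEncoderLayer(d, c.n_heads, c.ff_dim, rng)
            for _ in range(c.n_layers)]
        self.enc_norm = nn.LayerNorm(d)
        self.mu_head = nn.Linear(d, c.latent_dim, rng)
        self.logvar_head = nn.Linear(d, c.latent_dim, rng)
        # condition summary phi([c*m, m]) and prior heads
        n_slots = len(SLOT_NAMES)
        self.phi = nn.MLP([2 * n_slots, c.phi_hidden, c.summary_dim], rng)
        self.prior_mu = nn.Linear(c.summary_dim, c.latent_dim, rng)
        self.prior_logvar = nn.Linear(c.summary_dim, c.latent_dim, rng)
        # auxiliary heads on s
        self.mask_head = nn.Linear(c.summary_dim, n_slots, rng)
        self.bin_head = nn.Linear(c.summary_dim, len(BINARY_SLOTS), rng)
        self.cont_head = nn.Linear(c.summary_dim, len(CONTINUOUS_SLOTS), rng)
        # decoder
        self.z_proj = nn.Linear(c.latent_dim, d, rng)
        self.s_proj = nn.Linear(c.summary_dim, d, rng)
        self.decoder_layers = [
            nn.TransformerDecoderLayer(d, c.n_heads, c.ff_dim, rng)
            for _ in range(c.n_layers)]
        self.dec_norm = nn.LayerNorm(d)
        self.out_head = nn.Linear(d, V, rng)

    # -- condition path -------------------------------------------------------
    def summarize(self, c: np.ndarray, m: np.ndarray) -> nn.Tensor:
        """Condition summary s = phi([c ⊙ m, m]); (B, d) inputs.

        Unobserved slots enter only through m: their c values are replaced
        by 0 before the MLP, so perturbing them cannot change s.
        """
        c = np.atleast_2d(np.asarray(c, dtype=float))
        m = np.atleast_2d(np.asarray(m, dtype=float))
        if c.shape != m.shape or c.shape[1] != len(SLOT_NAMES):
            raise ValueError("c and m must both be (B, 6)")
        masked_c = np.where(m > 0, c, 0.0)
        if not np.all(np.isfinite(masked_c)):
            raise ValueError("observed slots must be finite")
        return self.phi(nn.Tensor(np.concatenate([masked_c, m], axis=1)))

    def prior(self, s: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        return self.prior_mu(s), self.prior_logvar(s)

    def aux_outputs(self, s: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor, nn.Tensor]:
        return self.mask_head(s), self.bin_head(s), self.cont_head(s)

    # -- encoder --------------------------------------------------------------
    def encode(self, tokens: np.ndarray) -> tuple[nn.Tensor, nn.Tensor]:
        """Posterior parameters from mean-pooled non-<pad> encoder states."""
        tokens = np.atleast_2d(tokens)
        pad = tokens == PAD
        if np.any(pad.all(axis=1)):
            raise ValueError("all-<pad> input")
        x = self.token_emb(tokens) + nn.Tensor(self.pos_table[: tokens.shape[1]])
        mask = nn.padding_attn_mask(pad)
        for layer in self.encoder_layers:
            x = layer(x, attn_mask=mask)
        pooled = nn.masked_mean(self.enc_norm(x), ~pad)
        return self.mu_head(pooled), self.logvar_head(pooled)

    # -- decoder --------------------------------------------------------------
    def _memory(self, z: nn.Tensor, s: nn.Tensor) -> nn.Tensor:
        """Two-token cross-attention memory: latent token and condition token."""
        zt = self.z_proj(z).reshape(z.shape[0], 1, self.config.d_model)
        st = self.s_proj(s).reshape(s.shape[0], 1, self.config.d_model)
        return nn.concatenate([zt, st], axis=1)

    def decode_logits(self, tokens_in: np.ndarray, z: nn.Tensor, s: nn.Tensor) -> nn.Tensor:
        """Next-token logits for each input position (teacher forcing)."""
        tokens_in = np.atleast_2d(tokens_in)
        t = tokens_in.shape[1]
        x = self.token_emb(tokens_in) + nn.Tensor(self.pos_table[:t])
        self_mask = nn.causal_mask(t) + nn.padding_attn_mask(tokens_in == PAD)
        memory = self._memory(z, s)
        for layer in self.decoder_layers:
            x = layer(x, memory, self_mask=self_mask)
        return self.out_head(self.dec_norm(x))


# -- losses -------------------------------------------------------------------

@dataclass
class LossBreakdown:
    """Per-term training losses and their weights; total is the weighted sum."""

    rec: float
    kl: float
    mask: float
    bin: float
    cont: float
    beta: float
    lambda_mask: float
    lambda_bin: float
    lambda_cont: float

    @property
    def total(self) -> float:
        return total_loss(self)


def total_loss(parts: LossBreakdown) -> float:
    return (parts.rec + parts.beta * parts.kl + parts.lambda_mask * parts.mask
            + parts.lambda_bin * parts.bin + parts.lambda_cont * parts.cont)


def kl_divergence(mu_q, logvar_q, mu_p, logvar_p) -> float:
    """Closed-form KL(q ‖ p) between diagonal Gaussians, mean over batch.

    0.5 Σ_k [ log(σ²_p/σ²_q) + (σ²_q + (μ_q − μ_p)²)/σ²_p − 1 ] ≥ 0,
    zero iff q == p.
    """
    args = [a.numpy() if isinstance(a, nn.Tensor) else np.asarray(a, dtype=float)
            for a in (mu_q, logvar_q, mu_p, logvar_p)]
    mu_q, logvar_q, mu_p, logvar_p = [np.atleast_2d(a) for a in args]
    if not all(np.all(np.isfinite(a)) for a in (logvar_q, logvar_p)):
        raise ValueError("non-finite log-variance")
    var_q, var_p = np.exp(logvar_q), np.exp(logvar_p)
    kl = 0.5 * (logvar_p - logvar_q + (var_q + (mu_q - mu_p) ** 2) / var_p - 1.0)
    return float(kl.sum(axis=1).mean())


def _kl_tensor(mu_q, logvar_q, mu_p, logvar_p) -> nn.Tensor:
    var_q = logvar_q.exp()
    var_p = logvar_p.exp()
    diff = mu_q - mu_p
    kl = (logvar_p - logvar_q + (var_q + diff * diff) / var_p - 1.0) * 0.5
    return kl.sum(axis=1).mean()


def reconstruction_loss(logits: nn.Tensor, targets: np.ndarray,
                        label_smoothing: float = 0.0) -> nn.Tensor:
    """Label-smoothed cross-entropy, mean over non-<pad> target positions.

    ``logits`` is (B, T, V) for positions predicting ``targets`` (B, T);
    <eos> counts, <pad> does not.
    """
    targets = np.atleast_2d(targets)
    valid = targets != PAD
    logp = logits.log_softmax(axis=-1)
    b_idx, t_idx = np.nonzero(valid)
    picked = logp[b_idx, t_idx, targets[b_idx, t_idx]]
    nll = -picked.mean()
    if label_smoothing > 0:
        smooth = -(logp[b_idx, t_idx].mean())  # uniform over V at valid positions
        nll = nll * (1.0 - label_smoothing) + smooth * label_smoothing
    return nll


def _bce_logits(logits: nn.Tensor, targets: np.ndarray) -> nn.Tensor:
    """Elementwise numerically-stable BCE-with-logits (no reduction)."""
    t = nn.Tensor(np.asarray(targets, dtype=float))
    x = logits
    # |x|/2 - x(t - 1/2) + log(1 + exp(-|x|)), stable for large |x|
    absx = x.abs()
    return absx * 0.5 + x * (0.5 - t) + ((-absx).exp() + 1.0).log()


def auxiliary_losses(c: np.ndarray, m: np.ndarray, train_mask: np.ndarray,
                     mask_logits: nn.Tensor, bin_logits: nn.Tensor,
                     cont_preds: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor, nn.Tensor]:
    """Mask / binary / continuous auxiliary losses.

    - L_mask: mean BCE over all d slots against the training mask.
    - L_bin: BCE on binary slots, averaged per sample over *observed*
      binary slots only; samples with none contribute zero.
    - L_cont: MSE on continuous slots, averaged per sample over observed
      continuous slots only; samples with none contribute zero.
    """
    c = np.atleast_2d(np.asarray(c, dtype=float))
    train_mask = np.atleast_2d(np.asarray(train_mask, dtype=float))
    n = c.shape[0]

    l_mask = _bce_logits(mask_logits, train_mask).mean()

    bin_obs = train_mask[:, list(BINARY_SLOTS)]                     # (B, 2)
    bin_targets = np.nan_to_num(c[:, list(BINARY_SLOTS)])
    per_elem_bin = _bce_logits(bin_logits, bin_targets) * bin_obs
    counts_b = np.maximum(bin_obs.sum(axis=1), 1.0)
    l_bin = (per_elem_bin.sum(axis=1) / counts_b).sum() * (1.0 / n)

    cont_obs = train_mask[:, list(CONTINUOUS_SLOTS)]                # (B, 4)
    cont_targets = np.nan_to_num(c[:, list(CONTINUOUS_SLOTS)])
    diff = cont_preds - cont_targets
    per_elem_cont = diff * diff * cont_obs
    counts_c = np.maximum(cont_obs.sum(axis=1), 1.0)
    l_cont = (per_elem_cont.sum(axis=1) / counts_c).sum() * (1.0 / n)
    return l_mask, l_bin, l_cont


def stochastic_mask(m_observed: np.ndarray, rng: np.random.Generator,
                    drop_prob: float = 0.5) -> np.ndarray:
    """Randomly drop observed slots, always keeping at least one.

    Applied on top of natural missingness during training so the model
    sees arbitrary subsets of available descriptors.
    """
    m_observed = np.atleast_2d(np.asarray(m_observed))
    if np.any(m_observed.sum(axis=1) == 0):
        raise ValueError("each sample must have at least one observed slot")
    keep = (rng.random(m_observed.shape) >= drop_prob) & (m_observed > 0)
    empty = np.nonzero(~keep.any(axis=1))[0]
    for i in empty:
        obs = np.nonzero(m_observed[i] > 0)[0]
        keep[i, obs[rng.integers(len(obs))]] = True
    return keep.astype(np.float64)


# -- training & generation ----------------------------------------------------

def _corpus_arrays(df, stats: ScalingStats):
    """Tokens, normalized descriptor matrix and natural observation mask."""
    tokens = tokenize_batch(df["sequence"].tolist())
    raw = df[list(SLOT_NAMES)].to_numpy(dtype=float)
    m = np.isfinite(raw).astype(np.float64)
    c = stats.normalize(raw)
    return tokens, c, m


def _sample_weights(df, config: CVAEConfig) -> np.ndarray:
    w = np.ones(len(df))
    assembled = df["is_assembled"].to_numpy(dtype=float)
    beta = df["has_beta_strand"].to_numpy(dtype=float)
    w[np.nan_to_num(assembled) == 1.0] *= config.sample_weight_assembled
    w[np.nan_to_num(beta) == 1.0] *= config.sample_weight_beta
    return w / w.sum()


class PepMorphModel:
    """Trained model bundle: network, config, scaling stats, vocabulary."""

    FORMAT_VERSION = 1

    def __init__(self, net: MaskedCVAE, config: CVAEConfig, stats: ScalingStats):
        self.net = net
        self.config = config
        self.stats = stats

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        meta = {"format_version": self.FORMAT_VERSION,
                "config": asdict(self.config),
                "stats": self.stats.to_dict(),
                "vocab": VOCAB}
        arrays = {f"w::{k}": v for k, v in self.net.state_dict().items()}
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "PepMorphModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta.get("format_version") != cls.FORMAT_VERSION:
                raise ValueError("incompatible checkpoint format")
            config = CVAEConfig(**meta["config"])
            stats = ScalingStats.from_dict(meta["stats"])
            if meta["vocab"] != VOCAB:
                raise ValueError("checkpoint vocabulary mismatch")
            net = MaskedCVAE(config, np.random.default_rng(0))
            net.load_state_dict({k[3:]: data[k] for k in data.files if k.startswith("w::")})
        return cls(net, config, stats)

    # -- conditioning helpers -------------------------------------------------
    def condition_from_targets(self, **targets) -> tuple[np.ndarray, np.ndarray]:
        """Build (normalized c, m) from named raw-unit descriptor targets.

        Binary slots are passed as exact 0/1; continuous slots are given in
        raw units and min-max normalized here. Unspecified slots are masked.
        """
        c = np.zeros(len(SLOT_NAMES))
        m = np.zeros(len(SLOT_NAMES))
        raw = np.full(len(SLOT_NAMES), np.nan)
        for name, value in targets.items():
            if name not in SLOT_NAMES:
                raise KeyError(f"unknown descriptor {name!r}")
            raw[SLOT_NAMES.index(name)] = float(value)
            m[SLOT_NAMES.index(name)] = 1.0
        normed = self.stats.normalize(raw)
        for i in range(len(SLOT_NAMES)):
            if m[i]:
                c[i] = normed[i] if i in CONTINUOUS_SLOTS else raw[i]
        return c, m

    # -- generation -----------------------------------------------------------
    def generate(self, c: np.ndarray, m: np.ndarray, n: int,
                 rng: np.random.Generator | int | None = None,
                 temperature: float | None = None,
                 max_retries: int = 20) -> list[Peptide]:
        """Sample n peptides: z ~ p(z|s), decode left-to-right until <eos>.

        Multinomial sampling from the temperature-scaled softmax at each
        step. Degenerate empty decodes are resampled (bounded retries).
        """
        rng = np.random.default_rng(rng)
        temp = self.config.temperature if temperature is None else temperature
        out: list[Peptide] = []
        with nn.no_grad():
            s = self.net.summarize(c, m)
            mu_p, logvar_p = self.net.prior(s)
            mu_p, sd_p = mu_p.numpy()[0], np.exp(0.5 * logvar_p.numpy()[0])
            retries = 0
            while len(out) < n and retries <= max_retries:
                need = n - len(out)
                z = mu_p + sd_p * rng.standard_normal((need, len(mu_p)))
                s_rep = nn.Tensor(np.repeat(s.numpy(), need, axis=0))
                seqs = self._decode(nn.Tensor(z), s_rep, need, rng, temp)
                for seq in seqs:
                    if seq:
                        out.append(Peptide(seq))
                retries += 1
        if len(out) < n:
            raise RuntimeError("generation kept producing empty sequences")
        return out[:n]

    def _decode(self, z: nn.Tensor, s: nn.Tensor, n: int,
                rng: np.random.Generator, temperature: float) -> list[str]:
        tokens = np.full((n, 1), BOS, dtype=np.int64)
        done = np.zeros(n, dtype=bool)
        for _ in range(L_MAX + 1):
            logits = self.net.decode_logits(tokens, z, s).numpy()[:, -1, :]
            logits[:, PAD] = -np.inf
            logits[:, BOS] = -np.inf
            if tokens.shape[1] == 1:
                logits[:, EOS] = -np.inf  # at least one residue
            if tokens.shape[1] == L_MAX + 1:
                logits[:] = -np.inf
                logits[:, EOS] = 0.0      # frame exhausted: force <eos>
            probs = np.exp((logits / max(temperature, 1e-6))
                           - (logits / max(temperature, 1e-6)).max(axis=1, keepdims=True))
            probs /= probs.sum(axis=1, keepdims=True)
            nxt = np.array([rng.choice(V, p=probs[i]) for i in range(n)])
            nxt[done] = PAD
            done |= nxt == EOS
            tokens = np.concatenate([tokens, nxt[:, None]], axis=1)
            if done.all():
                break
        return [detokenize(tokens[i]) for i in range(n)]

    # -- evaluation -----------------------------------------------------------
    def conditional_ce(self, sequence: str, c: np.ndarray, m: np.ndarray,
                       use_prior_mean: bool = True,
                       rng: np.random.Generator | None = None) -> float:
        """Teacher-forced per-token cross-entropy (nats) over non-<pad>
        target positions including <eos>, conditioned on (c, m).

        The latent is the conditional prior mean by default (deterministic
        evaluation); pass ``use_prior_mean=False`` with an rng to sample.
        """
        pep = Peptide(sequence)
        tokens = tokenize(pep)[None, :]
        with nn.no_grad():
            s = self.net.summarize(c, m)
            mu_p, logvar_p = self.net.prior(s)
            if use_prior_mean:
                z = mu_p
            else:
                z = nn.Tensor(mu_p.numpy() + np.exp(0.5 * logvar_p.numpy())
                              * np.random.default_rng(rng).standard_normal(mu_p.shape))
            logits = self.net.decode_logits(tokens[:, :-1], z, s)
            loss = reconstruction_loss(logits, tokens[:, 1:], label_smoothing=0.0)
        return float(loss.numpy())


def train_cvae(train_df, val_df, config: CVAEConfig | None = None,
               seed: int = 0, verbose: bool = False
               ) -> tuple[PepMorphModel, list[dict]]:
    """Train the masked CVAE; returns the model bundle and loss history.

    Optimizer is AdamW with LR halving on validation plateau; each epoch
    resamples the corpus with the class-imbalance weights and appends
    ``augment_per_epoch`` random peptides that observe only the length
    descriptor.
    """
    from .dataset import sample_random_peptides

    config = CVAEConfig() if config is None else config
    if train_df.empty:
        raise ValueError("empty training split")
    rng = np.random.default_rng(seed)
    stats = ScalingStats.fit(train_df)
    net = MaskedCVAE(config, rng)
    tokens_all, c_all, m_all = _corpus_arrays(train_df, stats)
    weights = _sample_weights(train_df, config)
    val_tokens, val_c, val_m = (None, None, None)
    if val_df is not None and len(val_df):
        val_tokens, val_c, val_m = _corpus_arrays(val_df, stats)
    opt = nn.AdamW(net.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    sched = nn.ReduceLROnPlateau(opt, patience=config.plateau_patience)
    history: list[dict] = []
    n = len(train_df)
    length_slot = SLOT_NAMES.index("length")

    for epoch in range(config.epochs):
        beta = nn.cyclic_beta(epoch, config.beta_period, config.beta_max)
        idx = rng.choice(n, size=n, replace=True, p=weights)
        ep_tokens, ep_c, ep_m = tokens_all[idx], c_all[idx], m_all[idx]
        if config.augment_per_epoch > 0:
            aug = sample_random_peptides(config.augment_per_epoch, (3, L_MAX), rng)
            a_tokens = tokenize_batch(aug)
            a_c = np.zeros((len(aug), len(SLOT_NAMES)))
            a_c[:, length_slot] = stats.normalize(
                np.column_stack([[len(p) for p in aug]] + [[np.nan] * len(aug)] * 5)
            )[:, length_slot]
            a_m = np.zeros_like(a_c)
            a_m[:, length_slot] = 1.0
            ep_tokens = np.concatenate([ep_tokens, a_tokens])
            ep_c = np.concatenate([ep_c, a_c])
            ep_m = np.concatenate([ep_m, a_m])
        order = rng.permutation(len(ep_tokens))
        totals = []
        for start in range(0, len(order), config.batch_size):
            sel = order[start:start + config.batch_size]
            parts = _train_step(net, opt, ep_tokens[sel], ep_c[sel], ep_m[sel],
                                beta, config, rng)
            totals.append(parts.total)
        entry = {"epoch": epoch, "beta": beta, "train_loss": float(np.mean(totals)),
                 "lr": opt.param_groups[0]["lr"]}
        if val_tokens is not None:
            entry["val_ce"] = _eval_ce(net, val_tokens, val_c, val_m)
            sched.step(entry["val_ce"])
        history.append(entry)
        if verbose:
            print(f"epoch {epoch}: {entry}")
    return PepMorphModel(net, config, stats), history


def _train_step(net: MaskedCVAE, opt, tokens, c, m, beta, config, rng) -> LossBreakdown:
    m_train = stochastic_mask(np.maximum(m, _ensure_one(m)), rng, config.mask_drop_prob)
    s = net.summarize(np.nan_to_num(c), m_train)
    mu_q, logvar_q = net.encode(tokens)
    mu_p, logvar_p = net.prior(s)
    eps = rng.standard_normal(mu_q.shape)
    z = mu_q + (logvar_q * 0.5).exp() * nn.Tensor(eps)
    logits = net.decode_logits(tokens[:, :-1], z, s)
    l_rec = reconstruction_loss(logits, tokens[:, 1:], config.label_smoothing)
    l_kl = _kl_tensor(mu_q, logvar_q, mu_p, logvar_p)
    mask_logits, bin_logits, cont_preds = net.aux_outputs(s)
    l_mask, l_bin, l_cont = auxiliary_losses(c, m, m_train, mask_logits,
                                             bin_logits, cont_preds)
    loss = (l_rec + beta * l_kl + config.lambda_mask * l_mask
            + config.lambda_bin * l_bin + config.lambda_cont * l_cont)
    opt.zero_grad()
    loss.backward()
    opt.step()
    return LossBreakdown(float(l_rec.numpy()), float(l_kl.numpy()),
                         float(l_mask.numpy()), float(l_bin.numpy()),
                         float(l_cont.numpy()), beta, config.lambda_mask,
                         config.lambda_bin, config.lambda_cont)


def _ensure_one(m: np.ndarray) -> np.ndarray:
    """Guarantee each row has an observed slot (length is always known)."""
    fix = np.zeros_like(m)
    empty = m.sum(axis=1) == 0
    fix[empty, SLOT_NAMES.index("length")] = 1.0
    return fix


def _eval_ce(net: MaskedCVAE, tokens, c, m, batch: int = 256) -> float:
    """Teacher-forced CE with prior-mean latents (validation metric)."""
    ces = []
    counts = []
    with nn.no_grad():
        for start in range(0, len(tokens), batch):
            tk = tokens[start:start + batch]
            s = net.summarize(np.nan_to_num(c[start:start + batch]),
                              np.maximum(m[start:start + batch],
                                         _ensure_one(m[start:start + batch])))
            mu_p, _ = net.prior(s)
            logits = net.decode_logits(tk[:, :-1], mu_p, s)
            ce = reconstruction_loss(logits, tk[:, 1:], label_smoothing=0.0)
            ces.append(float(ce.numpy()))
            counts.append((tk[:, 1:] != PAD).sum())
    return float(np.average(ces, weights=counts))
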