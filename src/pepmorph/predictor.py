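"""Two-head aggregation predictor.

A shared sequence encoder feeds an aggregation-propensity (AP) regression
head and a self-assembly (SA/no-SA) classification head. The encoder is
pluggable: the default is a small self-contained transformer trained from
scratch (an adapter slot exists for an external pretrained protein
language encoder, but none is required). Training is two-stage: heads
only with the encoder frozen, then end-to-end with discriminative
learning rates and exponential decay. Each loss term applies only to rows
where its label exists.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd

from . import nn
from .cvae import PAD, V, VOCAB, tokenize_batch
from .descriptors import Peptide

__all__ = ["PredictorConfig", "PredictorOutput", "SequenceEncoder",
           "AggregationPredictor", "train_two_stage", "toy_predictor_config"]


@dataclass(frozen=True)
class PredictorConfig:
    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 2
    ff_dim: int = 128
    hidden_dim: int = 64
    lr_heads: float = 1e-3
    lr_encoder: float = 1e-5
    stage1_epochs: int = 5
    stage2_epochs: int = 6
    lr_decay_gamma: float = 0.8
    batch_size: int = 256
    bce_weight: float = 1.0
    mse_weight: float = 1.0


def toy_predictor_config(**overrides) -> PredictorConfig:
    """Desk-scale configuration with a from-scratch encoder.

    The full-scale stage-2 settings (encoder LR 1e-5, 6 epochs) assume a
    pretrained encoder being fine-tuned; a randomly initialized encoder
    needs an ordinary learning rate and more end-to-end epochs.
    """
    base = PredictorConfig(d_model=32, n_heads=2, n_layers=1, ff_dim=64,
                           hidden_dim=32, lr_encoder=1e-3, stage2_epochs=30,
                           lr_decay_gamma=0.93)
    return replace(base, **overrides)


class SequenceEncoder(nn.Module):
    """Default trainable encoder: embeddings + transformer + masked mean.

    Any object with ``__call__(tokens) -> Tensor (B, D)`` and an
    ``out_dim`` attribute can stand in (e.g. an adapter around a
    pretrained protein language model).
    """

    def __init__(self, config: PredictorConfig, rng: np.random.Generator):
        self.emb = nn.Embedding(V, config.d_model, rng)
        self.pos_table = nn.sinusoidal_positions(32, config.d_model)
        self.layers = [nn.TransformerEncoderLayer(config.d_model, config.n_heads,
                                                  config.ff_dim, rng)
                       for _ in range(config.n_layers)]
        self.norm = nn.LayerNorm(config.d_model)
        self.out_dim = config.d_model

    def __call__(self, tokens: np.ndarray) -> nn.Tensor:
        tokens = np.atleast_2d(tokens)
        pad = tokens == PAD
        special = pad | (tokens == 1) | (tokens == 2)  # <pad>, <bos>, <eos>
        if np.any((~special).sum(axis=1) == 0):
            raise ValueError("input contains no residue tokens")
        x = self.emb(tokens) + nn.Tensor(self.pos_table[: tokens.shape[1]])
        mask = nn.padding_attn_mask(pad)
        for layer in self.layers:
            x = layer(x, attn_mask=mask)
        # masked mean over residue (non-special, non-pad) positions
        return nn.masked_mean(self.norm(x), ~special)


@dataclass(frozen=True)
class PredictorOutput:
    """Point predictions: AP estimate and assembly probability."""

    ap_hat: float
    p_assemble: float

    def __post_init__(self):
        if not np.isfinite(self.ap_hat):
            raise ValueError("non-finite ap_hat")
        if not 0.0 <= self.p_assemble <= 1.0:
            raise ValueError("p_assemble outside [0, 1]")


class AggregationPredictor(nn.Module):
    """Shared projection plus AP-regression and SA-classification heads."""

    FORMAT_VERSION = 1

    def __init__(self, config: PredictorConfig | None = None,
                 encoder: SequenceEncoder | None = None, seed: int = 0):
        config = PredictorConfig() if config is None else config
        rng = np.random.default_rng(seed)
        self.config = config
        self.encoder = SequenceEncoder(config, rng) if encoder is None else encoder
        self.proj = nn.Linear(self.encoder.out_dim, config.hidden_dim, rng)
        self.ap_head = nn.Linear(config.hidden_dim, 1, rng)
        self.sa_head = nn.Linear(config.hidden_dim, 1, rng)
        self._trained = False

    def forward(self, tokens: np.ndarray) -> tuple[nn.Tensor, nn.Tensor]:
        """(ap_hat, sa_logit) tensors of shape (B,)."""
        rep = self.encoder(tokens)
        h = self.proj(rep).gelu()
        b = tokens.shape[0] if tokens.ndim > 1 else 1
        return (self.ap_head(h).reshape(b), self.sa_head(h).reshape(b))

    def predict(self, peptide: Peptide | str) -> PredictorOutput:
        if not self._trained:
            raise RuntimeError("predictor has not been trained or loaded")
        return self.predict_batch([peptide])[0]

    def predict_batch(self, peptides) -> list[PredictorOutput]:
        if not self._trained:
            raise RuntimeError("predictor has not been trained or loaded")
        tokens = tokenize_batch([p.sequence if isinstance(p, Peptide) else str(p)
                                 for p in peptides])
        with nn.no_grad():
            ap, logit = self.forward(tokens)
        p = 1.0 / (1.0 + np.exp(-logit.numpy()))
        return [PredictorOutput(float(a), float(q))
                for a, q in zip(np.atleast_1d(ap.numpy()), np.atleast_1d(p))]

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        meta = {"format_version": self.FORMAT_VERSION,
                "config": asdict(self.config), "encoder_type": "builtin"}
        arrays = {f"w::{k}": v for k, v in self.state_dict().items()}
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "AggregationPredictor":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta.get("format_version") != cls.FORMAT_VERSION:
                raise ValueError("incompatible checkpoint format")
            model = cls(PredictorConfig(**meta["config"]))
            model.load_state_dict({k[3:]: data[k] for k in data.files
                                   if k.startswith("w::")})
        model._trained = True
        return model


def _head_params(model: AggregationPredictor) -> list[nn.Parameter]:
    return (model.proj.parameters() + model.ap_head.parameters()
            + model.sa_head.parameters())


def _loss(model: AggregationPredictor, tokens, ap, sa, config) -> nn.Tensor:
    """Masked sum of MSE(AP) over AP-labeled rows and BCE(SA) over
    SA-labeled rows; rows missing a label contribute nothing to that term."""
    ap_hat, sa_logit = model.forward(tokens)
    ap_mask = np.isfinite(ap)
    sa_mask = np.isfinite(sa)
    total = None
    if ap_mask.any():
        diff = (ap_hat - np.nan_to_num(ap)) * ap_mask.astype(float)
        mse = (diff * diff).sum() * (1.0 / ap_mask.sum())
        total = mse * config.mse_weight
    if sa_mask.any():
        t = np.nan_to_num(sa)
        x = sa_logit
        bce_el = x.abs() * 0.5 + x * (0.5 - t) + ((-x.abs()).exp() + 1.0).log()
        bce = (bce_el * sa_mask.astype(float)).sum() * (1.0 / sa_mask.sum())
        term = bce * config.bce_weight
        total = term if total is None else total + term
    if total is None:
        raise ValueError("batch has neither AP nor SA labels")
    return total


def train_two_stage(corpus: pd.DataFrame, config: PredictorConfig | None = None,
                    seed: int = 0, verbose: bool = False,
                    model: AggregationPredictor | None = None
                    ) -> tuple[AggregationPredictor, list[dict]]:
    """Stage 1: encoder frozen, heads only (AdamW, lr_heads, 5 epochs).
    Stage 2: end-to-end with discriminative LRs (encoder lr_encoder, heads
    lr_heads) and exponential LR decay (6 epochs).
    """
    config = PredictorConfig() if config is None else config
    labeled = corpus[np.isfinite(corpus["ap"].astype(float))
                     | np.isfinite(corpus["is_assembled"].astype(float))]
    if labeled.empty:
        raise ValueError("corpus has neither AP nor SA labels")
    rng = np.random.default_rng(seed)
    if model is None:
        model = AggregationPredictor(config, seed=seed)
    tokens = tokenize_batch(labeled["sequence"].tolist())
    ap = labeled["ap"].to_numpy(dtype=float)
    sa = labeled["is_assembled"].to_numpy(dtype=float)
    history: list[dict] = []

    def run_epochs(opt, n_epochs, stage, scheduler=None):
        n = len(tokens)
        for epoch in range(n_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, config.batch_size):
                sel = order[start:start + config.batch_size]
                loss = _loss(model, tokens[sel], ap[sel], sa[sel], config)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.numpy()))
            if scheduler is not None:
                scheduler.step()
            entry = {"stage": stage, "epoch": epoch, "loss": float(np.mean(losses))}
            history.append(entry)
            if verbose:
                print(entry)

    # stage 1: heads only — encoder parameters receive no updates
    opt1 = nn.AdamW(_head_params(model), lr=config.lr_heads)
    run_epochs(opt1, config.stage1_epochs, stage=1)
    # stage 2: end-to-end, discriminative LRs, exponential decay
    opt2 = nn.AdamW([
        {"params": model.encoder.parameters(), "lr": config.lr_encoder},
        {"params": _head_params(model), "lr": config.lr_heads},
    ])
    sched = nn.ExponentialDecay(opt2, gamma=config.lr_decay_gamma)
    run_epochs(opt2, config.stage2_epochs, stage=2, scheduler=sched)
    model._trained = True
    return model, history
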