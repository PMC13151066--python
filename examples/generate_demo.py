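"""Train a small masked conditional VAE and sample under partial conditions.

Trains on a synthetic corpus whose only observed descriptor is length,
then asks for peptides of a chosen length while leaving every other
descriptor unconstrained (masked). The fraction of samples that hit the
requested length measures how well generation honors the condition.
"""

import numpy as np

from pepmorph import make_synthetic_corpus, toy_config, train_cvae
from pepmorph.dataset import SplitSpec, stratified_split

corpus = make_synthetic_corpus(2000, seed=42)
for col in ("ap", "is_assembled", "has_beta_strand",
            "hydrophobic_moment", "net_charge"):
    corpus[col] = np.nan  # length-only conditioning study

train_df, val_df, _ = stratified_split(corpus, SplitSpec(seed=0))
print(f"training on {len(train_df)} peptides (desk-scale config) ...")
model, history = train_cvae(train_df, val_df, toy_config(), seed=0)
print(f"final validation cross-entropy: {history[-1]['val_ce']:.3f} nats")
print()

rng = np.random.default_rng(1)
for L in (5, 8):
    c, m = model.condition_from_targets(length=L)
    peps = model.generate(c, m, 50, rng)
    rate = np.mean([len(p) == L for p in peps])
    print(f"conditioned on length {L}: {rate:.0%} of 50 samples comply")
    print("  e.g.", " ".join(p.sequence for p in peps[:6]))
print()
print("Unconditioned slots stay masked, so the model is free to vary")
print("everything except the requested length.")
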