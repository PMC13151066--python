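"""Morphology-targeted screening funnel with cohort statistics.

Uses stub components (a pool-based generator, a lookup predictor, and a
sequence-derived descriptor provider) so the funnel mechanics are visible
without training: budgeted generation over the sphere condition grid,
dedup, the aggregation screen (p >= 0.75 and predicted AP >= 1.8), the
descriptor-compliance screen, and top-k selection, followed by Wilson
intervals, calls-per-hit, and a Fisher comparison of two cohorts.
"""

import numpy as np

from pepmorph import build_grid, calls_per_hit, fisher_or, wilson_ci
from pepmorph.dataset import sample_random_peptides
from pepmorph.descriptors import Peptide
from pepmorph.funnel import run_funnel
from pepmorph.predictor import PredictorOutput


class PoolGenerator:
    """Stands in for a trained generator: emits random length-5 peptides."""

    def __init__(self, seed):
        self.rng = np.random.default_rng(seed)

    def generate(self, c, m, n, rng, temperature=None):
        return sample_random_peptides(n, (5, 5), rng)


class HydrophobicityPredictor:
    """Deterministic stub: AP rises with hydrophobic residue fraction."""

    def predict_batch(self, sequences):
        from pepmorph.dataset import hydrophobic_fraction

        outs = []
        for s in sequences:
            f = hydrophobic_fraction(str(s))
            ap = 1.2 + 1.2 * f
            outs.append(PredictorOutput(ap, 1.0 / (1.0 + np.exp(-8 * (f - 0.5)))))
        return outs


grid = build_grid("sphere")
print(f"sphere grid: {len(grid)} conditions "
      f"(3 lengths x 5 hydrophobic-moment x 4 net-charge targets)")


def provider(sequence):
    # pretend-structure descriptor recomputation in normalized units
    from pepmorph.dataset import hydrophobic_fraction

    vec = np.zeros(6)
    vec[0] = float(len(sequence))
    vec[2] = 1.0
    vec[4] = hydrophobic_fraction(sequence)        # proxy moment
    vec[5] = 0.5                                    # near-neutral charge
    return vec


candidates, report = run_funnel(PoolGenerator(0), HydrophobicityPredictor(),
                                grid, per_condition_n=5, descriptor_provider=provider,
                                top_k=15, seed=0)
print(f"funnel: generated {report.n_generated} -> dedup {report.n_deduplicated}"
      f" -> aggregation {report.n_aggregation_pass}"
      f" -> compliance {report.n_compliance_pass}"
      f" -> selected {report.n_selected}")

hits, n = report.n_compliance_pass, report.n_generated
lo, hi = wilson_ci(hits, n)
print(f"hit rate {hits}/{n} = {hits/n:.1%} (Wilson 95% CI {lo:.1%}-{hi:.1%})")
print(f"calls per hit: {calls_per_hit(n, hits):.0f}")

# compare two hypothetical cohorts (success/failure counts)
oddsratio, p = fisher_or([[12, 3], [8, 5]])
print(f"cohort comparison: odds ratio {oddsratio:.1f}, two-sided p = {p:.3f}")
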