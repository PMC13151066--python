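"""Generation-quality evaluation.

Conditional likelihood (teacher-forced cross-entropy and perplexity under
three mask regimes), novelty and diversity via the normalized edit
distance (Levenshtein distance divided by the longer length), global
Needleman-Wunsch percent identity, condition matching (exact for
binary slots, ±10% relative for continuous), and realistic condition
sampling from per-length Gaussian mixtures fitted on training
descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import BINARY_SLOTS, CONTINUOUS_SLOTS, SLOT_NAMES
from .cvae import PepMorphModel, stochastic_mask

__all__ = [
    "ConditionQuery", "perplexity", "teacher_forced_ce", "ned",
    "novelty_report", "diversity_report", "nw_percent_identity",
    "condition_match", "ConditionSampler",
]

MATCH_REL_TOL = 0.10     # ±10% relative tolerance for continuous targets
MATCH_ABS_TOL = 0.02     # absolute fallback when the target is 0 (normalized units)


@dataclass(frozen=True)
class ConditionQuery:
    """A normalized descriptor target vector with its observation mask."""

    c: np.ndarray
    m: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "c", np.asarray(self.c, dtype=float))
        object.__setattr__(self, "m", np.asarray(self.m, dtype=float))
        if self.c.shape != (len(SLOT_NAMES),) or self.m.shape != self.c.shape:
            raise ValueError("c and m must be 6-vectors")
        if self.k < 1:
            raise ValueError("at least one slot must be observed")

    @property
    def k(self) -> int:
        return int(self.m.sum())


def perplexity(ce_nats: float) -> float:
    """PPL = exp(CE), with CE the mean per-token cross-entropy in nats."""
    return float(np.exp(ce_nats))


def teacher_forced_ce(model: PepMorphModel, records, regime: str = "observed",
                      rng: np.random.Generator | int | None = None,
                      drop_prob: float = 0.5) -> dict:
    """Mean teacher-forced CE (nats) and perplexity over a held-out table.

    Regimes: ``observed`` — each sample's native availability mask;
    ``full`` — complete-case subset with all slots observed;
    ``random-on-top`` — complete-case subset with extra random masking
    (per-slot drop probability ``drop_prob``, keeping at least one slot).
    """
    if regime not in ("observed", "full", "random-on-top"):
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(rng)
    raw = records[list(SLOT_NAMES)].to_numpy(dtype=float)
    m_nat = np.isfinite(raw).astype(float)
    c_norm = model.stats.normalize(raw)
    if regime in ("full", "random-on-top"):
        complete = m_nat.all(axis=1)
        records = records[complete]
        c_norm, m_nat = c_norm[complete], m_nat[complete]
    if not len(records):
        raise ValueError("no records under this regime")
    ces, weights = [], []
    for i, seq in enumerate(records["sequence"].tolist()):
        m = m_nat[i]
        if m.sum() == 0:
            continue
        if regime == "random-on-top":
            m = stochastic_mask(m, rng, drop_prob)[0]
        ce = model.conditional_ce(seq, np.nan_to_num(c_norm[i]), m)
        ces.append(ce)
        weights.append(len(seq) + 1)  # residues + <eos>
    mean_ce = float(np.average(ces, weights=weights))
    return {"regime": regime, "ce_nats": mean_ce, "perplexity": perplexity(mean_ce),
            "n": len(ces)}


def levenshtein(a: str, b: str) -> int:
    import edlib

    return edlib.align(a, b)["editDistance"]


def ned(a: str, b: str) -> float:
    """Normalized edit distance: Levenshtein / longer length, in [0, 1]."""
    if not a or not b:
        raise ValueError("NED is undefined for empty strings")
    return levenshtein(a, b) / max(len(a), len(b))


def novelty_report(generated, training) -> dict:
    """Exact-match fraction vs the training set and the NN-NED distribution."""
    generated = [str(s) for s in generated]
    training = [str(s) for s in training]
    if not generated or not training:
        raise ValueError("both sets must be non-empty")
    train_set = set(training)
    exact = sum(g in train_set for g in generated) / len(generated)
    nn_ned = np.array([min(ned(g, t) for t in training) for g in generated])
    return {"exact_match_fraction": exact,
            "nn_ned": nn_ned,
            "nn_ned_median": float(np.median(nn_ned))}


def diversity_report(generated_by_condition: dict, rng=None,
                     global_pairs: int = 100_000) -> dict:
    """Within-condition exact-match rate and pairwise-NED statistics.

    Pairwise NED is exhaustive within each condition; the global statistic
    uses a seeded random subsample of ``global_pairs`` pairs across the
    pooled generated set.
    """
    rng = np.random.default_rng(rng)
    per_condition = {}
    pooled: list[str] = []
    for cond, seqs in generated_by_condition.items():
        seqs = [str(s) for s in seqs]
        pooled.extend(seqs)
        n = len(seqs)
        entry: dict = {"n": n, "exact_match_rate": None, "pairwise_ned_mean": None,
                       "pairwise_ned_std": None}
        if n >= 2:
            n_unique = len(set(seqs))
            pair_count = n * (n - 1) // 2
            dup_pairs = sum(c * (c - 1) // 2
                            for c in _counts(seqs).values())
            entry["exact_match_rate"] = dup_pairs / pair_count
            neds = [ned(seqs[i], seqs[j]) for i in range(n) for j in range(i + 1, n)]
            entry["pairwise_ned_mean"] = float(np.mean(neds))
            entry["pairwise_ned_std"] = float(np.std(neds))
            entry["n_unique"] = n_unique
        per_condition[cond] = entry
    report = {"per_condition": per_condition}
    if len(pooled) >= 2:
        i = rng.integers(len(pooled), size=global_pairs)
        j = rng.integers(len(pooled), size=global_pairs)
        keep = i != j
        neds = [ned(pooled[a], pooled[b]) for a, b in zip(i[keep], j[keep])]
        report["global_pairwise_ned_mean"] = float(np.mean(neds))
        report["global_pairwise_ned_std"] = float(np.std(neds))
    rates = [e["exact_match_rate"] for e in per_condition.values()
             if e["exact_match_rate"] is not None]
    report["mean_within_condition_exact_match"] = (float(np.mean(rates))
                                                   if rates else None)
    return report


def _counts(items) -> dict:
    out: dict = {}
    for x in items:
        out[x] = out.get(x, 0) + 1
    return out


def nw_percent_identity(a: str, b: str, match: float = 1.0,
                        mismatch: float = 0.0, gap: float = 0.0) -> float:
    """Needleman-Wunsch global alignment percent identity in [0, 100].

    Default scoring (match +1, mismatch 0, gap 0) maximizes the number of
    matched columns; identity = matches / alignment length × 100, over the
    first optimal alignment (deterministic).
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    aln = aligner.align(a, b)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(x == y and x != "-" for x, y in zip(s1, s2))
    return 100.0 * matches / len(s1)


def similarity_summary(generated, reference, rng=None, max_pairs: int = 20_000) -> dict:
    """Mean/median NW percent identity of generated sequences vs a reference
    set (subsampled pairs when the cross product is large)."""
    rng = np.random.default_rng(rng)
    generated = [str(s) for s in generated]
    reference = [str(s) for s in reference]
    pairs = [(g, r) for g in generated for r in reference if g is not r]
    if len(pairs) > max_pairs:
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in idx]
    vals = np.array([nw_percent_identity(a, b) for a, b in pairs])
    return {"mean": float(vals.mean()), "median": float(np.median(vals)),
            "n_pairs": len(pairs)}


def condition_match(predicted: np.ndarray, query: ConditionQuery,
                    rel_tol: float = MATCH_REL_TOL,
                    abs_tol_at_zero: float = MATCH_ABS_TOL) -> dict:
    """Per-slot and aggregate match of predicted descriptors to a query.

    Binary/discrete slots match on exact equality; continuous slots match
    when |pred − target| ≤ rel_tol·|target| (absolute ``abs_tol_at_zero``
    when the target is 0). The aggregate is true iff every observed slot
    matches.
    """
    predicted = np.asarray(predicted, dtype=float)
    per_slot: dict[str, bool] = {}
    for i, name in enumerate(SLOT_NAMES):
        if not query.m[i]:
            continue
        if not np.isfinite(predicted[i]):
            raise ValueError(f"missing prediction for observed slot {name!r}")
        target = query.c[i]
        if i in BINARY_SLOTS:
            per_slot[name] = predicted[i] == target
        elif target == 0:
            per_slot[name] = abs(predicted[i]) <= abs_tol_at_zero
        else:
            per_slot[name] = abs(predicted[i] - target) <= rel_tol * abs(target)
    return {"per_slot": per_slot, "all": all(per_slot.values())}


class ConditionSampler:
    """Per-length Gaussian mixtures over normalized training descriptors.

    Component counts are chosen by BIC in 1..max_components per length.
    Sampled condition vectors respect the observed correlations; masks
    distribute queries evenly across the number of conditioned slots
    k ∈ {1..6} (length always among the observed slots so every query is
    well-posed for generation).
    """

    def __init__(self, training_records, stats, max_components: int = 5,
                 min_count: int = 10, seed: int = 0):
        from sklearn.mixture import GaussianMixture

        self.stats = stats
        self.models: dict[int, object] = {}
        self.medians: dict[int, np.ndarray] = {}
        raw = training_records[list(SLOT_NAMES)].to_numpy(dtype=float)
        normed = stats.normalize(raw)
        lengths = raw[:, SLOT_NAMES.index("length")].astype(int)
        for L in np.unique(lengths):
            rows = normed[lengths == L]
            complete = rows[np.isfinite(rows).all(axis=1)]
            if len(complete) < min_count:
                raise ValueError(
                    f"length {L}: only {len(complete)} complete rows; "
                    f"need at least {min_count} to fit a mixture")
            best, best_bic = None, np.inf
            for k in range(1, max_components + 1):
                gm = GaussianMixture(n_components=k, covariance_type="full",
                                     reg_covar=1e-6, random_state=seed)
                gm.fit(complete)
                bic = gm.bic(complete)
                if bic < best_bic:
                    best, best_bic = gm, bic
            self.models[int(L)] = best
            self.medians[int(L)] = np.median(complete, axis=0)

    def sample_conditions(self, length: int, n: int, seed: int = 0
                          ) -> list[ConditionQuery]:
        """n queries for one length, spread evenly across k ∈ {1..6}."""
        rng = np.random.default_rng(seed)
        gm = self.models[int(length)]
        vecs, _ = gm.sample(n)
        rng_order = rng.permutation(n)
        vecs = vecs[rng_order]
        ks = [(i % 6) + 1 for i in range(n)]
        length_slot = SLOT_NAMES.index("length")
        queries = []
        for vec, k in zip(vecs, ks):
            c = vec.copy()
            c[length_slot] = self.stats.normalize(
                np.array([float(length)] + [np.nan] * 5))[length_slot]
            for b in BINARY_SLOTS:
                c[b] = float(c[b] > 0.5)
            m = np.zeros(len(SLOT_NAMES))
            m[length_slot] = 1.0
            others = [i for i in range(len(SLOT_NAMES)) if i != length_slot]
            extra = rng.choice(others, size=k - 1, replace=False) if k > 1 else []
            for i in extra:
                m[i] = 1.0
            queries.append(ConditionQuery(c, m))
        return queries

    def rare_conditions(self, kind: str, length: int, hm_threshold: float = 0.8
                        ) -> ConditionQuery:
        """A rare-regime query: β-strand positive, or extreme hydrophobic
        moment (> threshold, normalized), others near per-length medians."""
        med = self.medians[int(length)].copy()
        c = med
        m = np.ones(len(SLOT_NAMES))
        for b in BINARY_SLOTS:
            c[b] = float(c[b] > 0.5)
        c[SLOT_NAMES.index("length")] = self.stats.normalize(
            np.array([float(length)] + [np.nan] * 5))[0]
        if kind == "beta":
            c[SLOT_NAMES.index("has_beta_strand")] = 1.0
        elif kind == "hydrophobic_moment":
            c[SLOT_NAMES.index("hydrophobic_moment")] = max(
                hm_threshold, c[SLOT_NAMES.index("hydrophobic_moment")])
        else:
            raise ValueError(f"unknown rare-condition kind {kind!r}")
        return ConditionQuery(c, m)
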