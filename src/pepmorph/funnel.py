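"""Morphology-targeted discovery funnel and cohort statistics.

Targets are expressed as condition grids over morphology-proxy
descriptors (Table-style sweep: length step 1, hydrophobic moment step
0.1, net charge step 0.05 in normalized units, self-assembly flag fixed
to 1). A fixed generation budget is spread over the grid, candidates are
deduplicated and passed through a dual filter — an aggregation screen
(classifier probability ≥ 0.75 AND predicted AP ≥ 1.8) and a
descriptor-compliance screen (every conditioned descriptor recomputed
from a supplied monomer structure must lie within the ±10% matching
rule) — before top-k selection by predicted AP.

Cohort statistics: Wilson score confidence intervals for hit rates,
calls-per-hit, and two-sided Fisher exact tests with odds ratios on
2×2 success/failure tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .descriptors import SLOT_NAMES, Peptide, ScalingStats
from .evalgen import ConditionQuery, condition_match

__all__ = [
    "ConditionGrid", "CandidateRecord", "FunnelReport", "build_grid",
    "run_funnel", "baseline_cohort", "calls_per_hit", "wilson_ci", "fisher_or",
    "AGGREGATION_P_MIN", "AGGREGATION_AP_MIN",
]

AGGREGATION_P_MIN = 0.75   # classifier probability threshold
AGGREGATION_AP_MIN = 1.8   # predicted aggregation-propensity threshold


@dataclass(frozen=True)
class ConditionGrid:
    """An enumerable cross-product of descriptor targets for one morphology."""

    target: str
    queries: tuple[ConditionQuery, ...]

    def __len__(self) -> int:
        return len(self.queries)


def _frange(start: float, stop: float, step: float, inclusive: bool) -> list[float]:
    n = round((stop - start) / step) + (1 if inclusive else 0)
    return [round(start + i * step, 10) for i in range(n)]


def build_grid(target: str,
               sphere_lengths=(5, 6, 7),
               fibril_lengths=(7, 8, 9, 10),
               hm_range=(0.6, 1.0), hm_step: float = 0.1,
               nc_range=(0.4, 0.6), nc_step: float = 0.05,
               hm_inclusive: bool = True, nc_inclusive: bool = False,
               stats: ScalingStats | None = None) -> ConditionGrid:
    """Build the sphere or fibril condition grid.

    Sphere: lengths 5-7 × hydrophobic moment [0.6, 1.0] (step 0.1,
    inclusive: 5 values) × net charge [0.4, 0.6) (step 0.05, half-open:
    4 values) = 60 conditions. Fibril: lengths 7-10 × has_beta_strand = 1
    × the same net-charge sweep = 16 conditions. ``is_assembled`` is fixed
    to 1 everywhere. Hydrophobic moment and net charge are in min-max
    normalized units. Endpoint conventions are configurable; the defaults
    are the only reading consistent with an even 4800-sequence budget at
    80 (sphere) and 300 (fibril) per condition.

    Length is normalized with ``stats`` when given (as the generator
    expects); otherwise left raw in the query vector.
    """
    idx = {name: i for i, name in enumerate(SLOT_NAMES)}
    hms = _frange(*hm_range, hm_step, hm_inclusive)
    ncs = _frange(*nc_range, nc_step, nc_inclusive)
    queries = []

    def norm_length(L: float) -> float:
        if stats is None:
            return float(L)
        return stats.normalize(np.array([float(L)] + [np.nan] * 5))[idx["length"]]

    if target == "sphere":
        for L in sphere_lengths:
            for hm in hms:
                for nc in ncs:
                    c = np.zeros(len(SLOT_NAMES))
                    m = np.zeros(len(SLOT_NAMES))
                    c[idx["length"]], m[idx["length"]] = norm_length(L), 1
                    c[idx["is_assembled"]], m[idx["is_assembled"]] = 1.0, 1
                    c[idx["hydrophobic_moment"]], m[idx["hydrophobic_moment"]] = hm, 1
                    c[idx["net_charge"]], m[idx["net_charge"]] = nc, 1
                    queries.append(ConditionQuery(c, m))
    elif target == "fibril":
        for L in fibril_lengths:
            for nc in ncs:
                c = np.zeros(len(SLOT_NAMES))
                m = np.zeros(len(SLOT_NAMES))
                c[idx["length"]], m[idx["length"]] = norm_length(L), 1
                c[idx["is_assembled"]], m[idx["is_assembled"]] = 1.0, 1
                c[idx["has_beta_strand"]], m[idx["has_beta_strand"]] = 1.0, 1
                c[idx["net_charge"]], m[idx["net_charge"]] = nc, 1
                queries.append(ConditionQuery(c, m))
    else:
        raise ValueError(f"unknown morphology target {target!r}")
    return ConditionGrid(target, tuple(queries))


@dataclass
class CandidateRecord:
    """One candidate's journey through the funnel."""

    sequence: str
    source_condition: ConditionQuery | None
    ap_hat: float = math.nan
    p_assemble: float = math.nan
    recomputed: np.ndarray | None = None
    passed_aggregation: bool = False
    passed_compliance: bool = False
    selected: bool = False
    failure_reason: str | None = None


@dataclass
class FunnelReport:
    """Stage counts along the funnel (monotone non-increasing)."""

    target: str
    n_generated: int
    n_deduplicated: int
    n_aggregation_pass: int
    n_compliance_pass: int
    n_selected: int

    def stages(self) -> list[int]:
        return [self.n_generated, self.n_deduplicated, self.n_aggregation_pass,
                self.n_compliance_pass, self.n_selected]


def _apply_filters(candidates: list[CandidateRecord], predictor,
                   descriptor_provider, top_k: int,
                   p_min: float, ap_min: float) -> FunnelReport | None:
    """Shared aggregation + compliance + top-k stages."""
    outputs = predictor.predict_batch([c.sequence for c in candidates])
    for cand, out in zip(candidates, outputs):
        cand.ap_hat = out.ap_hat
        cand.p_assemble = out.p_assemble
        cand.passed_aggregation = (out.p_assemble >= p_min and out.ap_hat >= ap_min)
        if not cand.passed_aggregation:
            cand.failure_reason = "aggregation"
    for cand in candidates:
        if not cand.passed_aggregation:
            continue
        try:
            cand.recomputed = np.asarray(descriptor_provider(cand.sequence), dtype=float)
        except Exception as exc:  # provider failure drops the candidate
            cand.failure_reason = f"descriptor_provider: {exc}"
            continue
        if cand.source_condition is None:
            cand.passed_compliance = True
            continue
        result = condition_match(cand.recomputed, cand.source_condition)
        cand.passed_compliance = result["all"]
        if not cand.passed_compliance:
            cand.failure_reason = "compliance"
    survivors = [c for c in candidates if c.passed_compliance]
    survivors.sort(key=lambda c: (-c.ap_hat, c.sequence))  # ties: lexicographic
    for c in survivors[:top_k]:
        c.selected = True
    return survivors


def run_funnel(model, predictor, grid: ConditionGrid, per_condition_n: int,
               descriptor_provider, top_k: int = 15, seed: int = 0,
               p_min: float = AGGREGATION_P_MIN, ap_min: float = AGGREGATION_AP_MIN
               ) -> tuple[list[CandidateRecord], FunnelReport]:
    """Generate per_condition_n peptides per grid condition and filter.

    ``descriptor_provider(sequence) -> 6-vector`` recomputes the
    descriptor slots in the same normalized units as the grid queries
    (typically from a predicted monomer structure; a synthetic stub in
    tests). Dedup keeps the first occurrence within the target regime.
    """
    rng = np.random.default_rng(seed)
    candidates: list[CandidateRecord] = []
    seen: set[str] = set()
    n_generated = 0
    for query in grid.queries:
        peptides = model.generate(query.c, query.m, per_condition_n, rng)
        n_generated += len(peptides)
        for p in peptides:
            if p.sequence in seen:
                continue
            seen.add(p.sequence)
            candidates.append(CandidateRecord(p.sequence, query))
    survivors = _apply_filters(candidates, predictor, descriptor_provider,
                               top_k, p_min, ap_min)
    report = FunnelReport(
        target=grid.target,
        n_generated=n_generated,
        n_deduplicated=len(candidates),
        n_aggregation_pass=sum(c.passed_aggregation for c in candidates),
        n_compliance_pass=len(survivors),
        n_selected=sum(c.selected for c in candidates),
    )
    return candidates, report


def baseline_cohort(kind: str, budget: int, grid: ConditionGrid, predictor,
                    descriptor_provider, model=None, top_k: int = 15,
                    seed: int = 0, length_range=(3, 10),
                    p_min: float = AGGREGATION_P_MIN,
                    ap_min: float = AGGREGATION_AP_MIN
                    ) -> tuple[list[CandidateRecord], FunnelReport]:
    """Baselines under the same screening pipeline and budget.

    ``random``: uniformly random sequences. ``length_only``: model
    generation with every morphology-proxy descriptor masked (only length
    and the assembly flag observed). Candidates are judged against the
    grid conditions: a baseline candidate passes compliance if its
    recomputed descriptors match *any* grid condition.
    """
    from .dataset import sample_random_peptides

    rng = np.random.default_rng(seed)
    sequences: list[str] = []
    if kind == "random":
        sequences = [p.sequence for p in
                     sample_random_peptides(budget, length_range, rng)]
    elif kind == "length_only":
        if model is None:
            raise ValueError("length_only baseline requires a generator model")
        idx_len = SLOT_NAMES.index("length")
        idx_sa = SLOT_NAMES.index("is_assembled")
        grid_lengths = sorted({q.c[idx_len] for q in grid.queries})
        per = budget // len(grid_lengths)
        for L in grid_lengths:
            c = np.zeros(len(SLOT_NAMES))
            m = np.zeros(len(SLOT_NAMES))
            c[idx_len], m[idx_len] = L, 1
            c[idx_sa], m[idx_sa] = 1.0, 1
            sequences.extend(p.sequence for p in model.generate(c, m, per, rng))
    else:
        raise ValueError(f"unknown baseline kind {kind!r}")
    candidates = []
    seen: set[str] = set()
    for seq in sequences:
        if seq in seen:
            continue
        seen.add(seq)
        candidates.append(CandidateRecord(seq, None))
    outputs = predictor.predict_batch([c.sequence for c in candidates])
    for cand, out in zip(candidates, outputs):
        cand.ap_hat = out.ap_hat
        cand.p_assemble = out.p_assemble
        cand.passed_aggregation = (out.p_assemble >= p_min and out.ap_hat >= ap_min)
    for cand in candidates:
        if not cand.passed_aggregation:
            cand.failure_reason = "aggregation"
            continue
        try:
            cand.recomputed = np.asarray(descriptor_provider(cand.sequence), dtype=float)
        except Exception as exc:
            cand.failure_reason = f"descriptor_provider: {exc}"
            continue
        cand.passed_compliance = any(
            condition_match(cand.recomputed, q)["all"] for q in grid.queries)
        if not cand.passed_compliance:
            cand.failure_reason = "compliance"
    survivors = sorted((c for c in candidates if c.passed_compliance),
                       key=lambda c: (-c.ap_hat, c.sequence))
    for c in survivors[:top_k]:
        c.selected = True
    report = FunnelReport(grid.target, len(sequences), len(candidates),
                          sum(c.passed_aggregation for c in candidates),
                          len(survivors), sum(c.selected for c in candidates))
    return candidates, report


# -- cohort statistics --------------------------------------------------------

def calls_per_hit(n_calls: int, n_hits: int) -> float:
    """Screening efficiency N/H; infinity when there are no hits."""
    if n_calls < 0 or n_hits < 0 or n_hits > n_calls:
        raise ValueError("need n_calls >= n_hits >= 0")
    if n_hits == 0:
        return math.inf
    return n_calls / n_hits


def wilson_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Two-sided Wilson score confidence interval for a binomial proportion."""
    from statsmodels.stats.proportion import proportion_confint

    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def fisher_or(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2×2 table.

    Returns (odds_ratio, p). The odds ratio is the sample OR a·d/(b·c);
    a zero in b or c yields an infinite sentinel (interpreted
    qualitatively), and an all-zero table is an error. The two-sided p
    sums hypergeometric outcomes no more likely than the observed table.
    """
    from scipy.stats import fisher_exact

    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("table must be 2x2 non-negative integers")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    oddsratio, p = fisher_exact(t.astype(int), alternative="two-sided")
    return float(oddsratio), float(p)
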