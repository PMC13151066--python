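"""Training-corpus assembly and synthetic fixtures.

Merges descriptor sources with a priority-source dedup policy, assigns
self-assembly labels from aggregation-propensity (AP) thresholds, augments
with uniformly random sequences, and builds stratified splits. The
synthetic corpus generator plants a known monotone sequence→AP rule so
every downstream model can be validated by recovery experiments without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import (
    CANONICAL_RESIDUES,
    EISENBERG_SCALE,
    Peptide,
    helical_hydrophobic_moment,
    net_charge,
)

__all__ = [
    "SA_THRESHOLD", "NO_SA_THRESHOLD", "SplitSpec", "PlantedRule",
    "assign_sa_label", "merge_sources", "sample_random_peptides",
    "stratified_split", "make_synthetic_corpus", "hydrophobic_fraction",
]

#: Operational AP separators: AP >= 1.8 -> SA, AP <= 1.65 -> no-SA,
#: intermediates unlabeled. Global across lengths for simplicity.
SA_THRESHOLD = 1.8
NO_SA_THRESHOLD = 1.65

#: Residues counted as hydrophobic for the planted rule (positive on the
#: Eisenberg scale).
HYDROPHOBIC_RESIDUES = frozenset(r for r, h in EISENBERG_SCALE.items() if h > 0)


def assign_sa_label(ap: float, sa_threshold: float = SA_THRESHOLD,
                    no_sa_threshold: float = NO_SA_THRESHOLD) -> str:
    """'SA' iff ap >= 1.8, 'no-SA' iff ap <= 1.65, else 'unlabeled'.

    A missing (NaN) AP yields 'unlabeled' rather than an error.
    """
    if ap is None or not np.isfinite(ap):
        return "unlabeled"
    if ap >= sa_threshold:
        return "SA"
    if ap <= no_sa_threshold:
        return "no-SA"
    return "unlabeled"


def merge_sources(table_a: pd.DataFrame, table_b: pd.DataFrame,
                  priority: str = "a") -> tuple[pd.DataFrame, dict]:
    """Merge two (sequence, ap) sources, priority source winning on overlap.

    Returns the merged table and an overlap report with the per-pair
    |ΔAP| statistics for sequences present in both sources.
    """
    a = table_a.copy()
    b = table_b.copy()
    for t in (a, b):
        t["sequence"] = t["sequence"].str.upper()
    overlap = set(a["sequence"]) & set(b["sequence"])
    report = {"n_overlap": len(overlap)}
    if overlap:
        ap_a = a.set_index("sequence")["ap"]
        ap_b = b.set_index("sequence")["ap"]
        diffs = (ap_a.loc[sorted(overlap)] - ap_b.loc[sorted(overlap)]).abs()
        report["mean_abs_ap_diff"] = float(diffs.mean())
        report["std_abs_ap_diff"] = float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0
    first, second = (a, b) if priority == "a" else (b, a)
    second = second[~second["sequence"].isin(set(first["sequence"]))]
    merged = pd.concat([first, second], ignore_index=True)
    merged = merged.drop_duplicates(subset="sequence", keep="first").reset_index(drop=True)
    return merged, report


def sample_random_peptides(n: int, length_range: tuple[int, int] = (3, 10),
                           rng: np.random.Generator | int | None = None,
                           exclusion_set: set[str] | None = None,
                           max_attempts_factor: int = 200) -> list[Peptide]:
    """Uniform random peptides: length uniform over the range, residues i.i.d.

    No duplicates internally and no member of ``exclusion_set``. Raises if
    the requested count cannot be reached (tiny combinatorial space).
    """
    rng = np.random.default_rng(rng)
    lo, hi = length_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid length range")
    exclusion = exclusion_set or set()
    out: list[Peptide] = []
    seen: set[str] = set()
    alphabet = np.array(list(CANONICAL_RESIDUES))
    attempts = 0
    limit = max(n, 1) * max_attempts_factor
    while len(out) < n:
        if attempts >= limit:
            raise RuntimeError(
                f"could only draw {len(out)}/{n} unique peptides for range {length_range}")
        attempts += 1
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=L))
        if seq in seen or seq in exclusion:
            continue
        seen.add(seq)
        out.append(Peptide(seq))
    return out


@dataclass(frozen=True)
class SplitSpec:
    """Fractions and stratification settings for the train/val/test split."""

    train: float = 0.8
    val: float = 0.1
    test: float = 0.1
    stratify_by: str = "length"
    seed: int = 0

    def __post_init__(self):
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


def stratified_split(records: pd.DataFrame, spec: SplitSpec = SplitSpec()
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Deterministic per-length stratified train/val/test split.

    Per-stratum proportions are preserved within rounding; strata smaller
    than 3 fall back to a non-stratified assignment with a warning.
    """
    import warnings

    if records.empty:
        raise ValueError("cannot split an empty corpus")
    rng = np.random.default_rng(spec.seed)
    key = records[spec.stratify_by]
    train_idx, val_idx, test_idx = [], [], []
    small_strata = []
    for value, group in records.groupby(key, sort=True):
        idx = group.index.to_numpy()
        rng.shuffle(idx)
        if len(idx) < 3:
            small_strata.append(value)
            train_idx.extend(idx)
            continue
        n = len(idx)
        n_test = max(1, round(n * spec.test))
        n_val = max(1, round(n * spec.val))
        test_idx.extend(idx[:n_test])
        val_idx.extend(idx[n_test:n_test + n_val])
        train_idx.extend(idx[n_test + n_val:])
    if small_strata:
        warnings.warn(f"strata {small_strata} too small to stratify; placed in train")
    return (records.loc[sorted(train_idx)].reset_index(drop=True),
            records.loc[sorted(val_idx)].reset_index(drop=True),
            records.loc[sorted(test_idx)].reset_index(drop=True))


def hydrophobic_fraction(sequence: str) -> float:
    """Fraction of residues with positive Eisenberg hydrophobicity."""
    return sum(r in HYDROPHOBIC_RESIDUES for r in sequence) / len(sequence)


@dataclass(frozen=True)
class PlantedRule:
    """Parameters of the synthetic monotone sequence→AP rule.

    ap = intercept + slope · hydrophobic_fraction + N(0, noise_sigma).
    Defaults put AP in ≈[1.2, 2.4], straddling the 1.65/1.8 labeling
    thresholds the way the real AP distribution does.
    """

    intercept: float = 1.2
    slope: float = 1.2
    noise_sigma: float = 0.05

    def apply(self, sequence: str, rng: np.random.Generator) -> float:
        ap = self.intercept + self.slope * hydrophobic_fraction(sequence)
        if self.noise_sigma > 0:
            ap += rng.normal(0.0, self.noise_sigma)
        return float(ap)


def make_synthetic_corpus(n: int, rule: PlantedRule = PlantedRule(),
                          missingness_3d: float = 0.5,
                          missingness_ap: float = 0.2,
                          length_range: tuple[int, int] = (3, 10),
                          beta_min_length: int = 7,
                          beta_rate: float = 0.05,
                          seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Generate a labelled synthetic corpus with planted structure.

    - sequences: uniform random (length uniform over ``length_range``)
    - length / net_charge: exact from the sequence
    - ap: planted monotone function of hydrophobic fraction + noise;
      missing for a ``missingness_ap`` fraction (emulating records with
      no aggregation source, e.g. random-augmentation peptides)
    - is_assembled: thresholded from ap where ap is present
    - hydrophobic_moment: deterministic helical-wheel moment from the
      sequence; missing (with has_beta_strand) for a ``missingness_3d``
      fraction, emulating structures that were never predicted
    - has_beta_strand: rare positive flag for long, β-prone sequences
    """
    rng = np.random.default_rng(seed)
    peptides = sample_random_peptides(n, length_range, rng)
    rows = []
    for p in peptides:
        seq = p.sequence
        ap = rule.apply(seq, rng)
        has_ap = rng.random() >= missingness_ap
        has_3d = rng.random() >= missingness_3d
        label = assign_sa_label(ap) if has_ap else "unlabeled"
        beta = 0.0
        if len(seq) >= beta_min_length and rng.random() < beta_rate:
            beta = 1.0
        rows.append({
            "sequence": seq,
            "length": float(len(seq)),
            "ap": ap if has_ap else np.nan,
            "is_assembled": (1.0 if label == "SA" else 0.0 if label == "no-SA" else np.nan),
            "has_beta_strand": beta if has_3d else np.nan,
            "hydrophobic_moment": helical_hydrophobic_moment(seq) if has_3d else np.nan,
            "net_charge": float(net_charge(p)),
            "provenance": "random" if not has_ap else "source_A",
            "sa_label": label,
            "true_ap": ap,  # planted ground truth, kept for recovery tests
        })
    return pd.DataFrame(rows)
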