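"""Peptide descriptor calculation and min-max conditioning normalization.

Descriptors come in three classes: sequence-derived (length, net charge at
neutral pH), aggregation descriptors (aggregation propensity and the
self-assembly flag, taken from source tables), and monomer-structure
descriptors computed from a predicted 3D conformation (β-strand
assignment from secondary-structure labels, hydrophobic moment along
Cα→Cβ directions on the Eisenberg scale).

The six-slot descriptor vector that conditions the generative model uses
the fixed slot order defined in :data:`SLOT_NAMES`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SLOT_NAMES", "BINARY_SLOTS", "CONTINUOUS_SLOTS", "CANONICAL_RESIDUES",
    "EISENBERG_SCALE", "Peptide", "StructureModel", "ScalingStats",
    "net_charge", "beta_strand_descriptor", "hydrophobic_moment",
    "helical_hydrophobic_moment", "pseudo_cbeta", "compute_descriptor_table",
]

#: Fixed conditioning-slot order of the descriptor vector c (d = 6).
SLOT_NAMES = ("length", "ap", "is_assembled", "has_beta_strand",
              "hydrophobic_moment", "net_charge")
#: Indices of binary slots (exact-match semantics, fixed 0/1 scaling).
BINARY_SLOTS = (2, 3)
#: Indices of continuous slots (min-max scaled, ±10% match tolerance).
CONTINUOUS_SLOTS = (0, 1, 4, 5)

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)

L_MAX = 10

#: Eisenberg consensus hydrophobicity scale (dimensionless, per residue).
EISENBERG_SCALE: dict[str, float] = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

_POSITIVE = frozenset("KR")   # Lys, Arg: +1 at neutral pH
_NEGATIVE = frozenset("DE")   # Asp, Glu: -1; His treated as uncharged

ANGSTROM_TO_NM = 0.1


class InvalidPeptideError(ValueError):
    """Sequence violates the canonical-residue / length contract."""


@dataclass(frozen=True)
class Peptide:
    """A peptide sequence of 1..L_max canonical one-letter residues."""

    sequence: str

    def __post_init__(self):
        seq = self.sequence
        if not seq or len(seq) > L_MAX:
            raise InvalidPeptideError(
                f"length must be in [1, {L_MAX}], got {len(seq)}: {seq!r}")
        bad = set(seq) - _CANONICAL_SET
        if bad:
            raise InvalidPeptideError(f"non-canonical residues {sorted(bad)} in {seq!r}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


@dataclass
class StructureModel:
    """Per-residue backbone geometry plus secondary-structure labels.

    Coordinates are in nanometres (PDB readers convert from Å on read).
    ``cb`` rows may contain NaN where a residue has no Cβ (e.g. Gly).
    """

    sequence: str
    n: np.ndarray          # (L, 3) backbone N
    ca: np.ndarray         # (L, 3) Cα
    c: np.ndarray          # (L, 3) backbone C
    cb: np.ndarray         # (L, 3) Cβ, NaN where absent
    ss_labels: str         # DSSP-style letters, length L

    def __post_init__(self):
        L = len(self.sequence)
        for name in ("n", "ca", "c", "cb"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (L, 3):
                raise ValueError(f"{name} must have shape ({L}, 3), got {arr.shape}")
            setattr(self, name, arr)
        if len(self.ss_labels) != L:
            raise ValueError("ss_labels length must equal sequence length")
        for name in ("n", "ca", "c"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite {name} coordinates")


def net_charge(p: Peptide | str) -> int:
    """Net charge at neutral pH: +1 per Lys/Arg, -1 per Asp/Glu, else 0."""
    seq = Peptide(p).sequence if isinstance(p, str) else p.sequence
    return sum(+1 if r in _POSITIVE else -1 if r in _NEGATIVE else 0 for r in seq)


def beta_strand_descriptor(ss_labels: str) -> tuple[float, int]:
    """Fraction of residues labelled 'E' (extended strand) and its binarization.

    Returns ``(f_beta, has_beta)`` with ``has_beta = 1`` iff any residue is
    labelled 'E'. Only the letter 'E' counts; other sheet-adjacent labels
    (e.g. isolated bridge 'B') do not.
    """
    if not ss_labels:
        raise ValueError("empty secondary-structure label string")
    f_beta = ss_labels.count("E") / len(ss_labels)
    return f_beta, int(f_beta > 0)


def pseudo_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Virtual Cβ position from backbone N, Cα, C.

    Standard tetrahedral construction (ideal side-chain geometry); used for
    Gly and residues with a missing Cβ so the Cα→Cβ direction is always
    defined, deterministic, and rotation-covariant.
    """
    b = ca - n
    c2 = c - ca
    a = np.cross(b, c2)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * c2 + ca


def _ca_cb_units(s: StructureModel) -> np.ndarray:
    """Unit vectors along Cα→Cβ per residue, with the pseudo-Cβ fallback."""
    L = len(s.sequence)
    units = np.empty((L, 3))
    for l in range(L):
        cb = s.cb[l]
        if not np.all(np.isfinite(cb)):
            cb = pseudo_cbeta(s.n[l], s.ca[l], s.c[l])
        v = cb - s.ca[l]
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(f"zero-length Ca->Cb vector at residue {l}")
        units[l] = v / norm
    return units


def hydrophobic_moment(s: StructureModel,
                       scale: dict[str, float] | None = None) -> float:
    """Magnitude of the length-normalized hydrophobic-moment vector.

    M = || (1/L) Σ_l h_l v̂_l || with h_l the (Eisenberg) hydrophobicity of
    residue l and v̂_l the unit vector along Cα→Cβ. Dividing by L makes the
    magnitude length-independent; the construction uses only relative
    geometry, so M is invariant under rigid rotation and translation.
    """
    scale = EISENBERG_SCALE if scale is None else scale
    h = np.array([scale[r] for r in s.sequence])
    units = _ca_cb_units(s)
    vec = (h[:, None] * units).mean(axis=0)
    return float(np.linalg.norm(vec))


def helical_hydrophobic_moment(sequence: str, angle_deg: float = 100.0,
                               scale: dict[str, float] | None = None) -> float:
    """Sequence-only hydrophobic moment on an ideal helical wheel.

    The classic Eisenberg construction: residue l contributes h_l along the
    in-plane direction at l·angle (100° per residue for an α-helix). The
    synthetic corpus uses this when no 3D structure exists.
    """
    scale = EISENBERG_SCALE if scale is None else scale
    h = np.array([scale[r] for r in sequence])
    theta = np.deg2rad(angle_deg) * np.arange(len(sequence))
    mx = (h * np.cos(theta)).sum()
    my = (h * np.sin(theta)).sum()
    return float(np.hypot(mx, my) / len(sequence))


@dataclass
class ScalingStats:
    """Per-slot (min, max) from the training split, for min-max scaling.

    Binary slots are pinned to (0, 1) by convention so they pass through
    unchanged. A constant continuous slot maps to 0 with a warning.
    """

    mins: np.ndarray
    maxs: np.ndarray
    slot_names: tuple[str, ...] = field(default=SLOT_NAMES)

    def __post_init__(self):
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if self.mins.shape != (len(self.slot_names),) or self.maxs.shape != self.mins.shape:
            raise ValueError("mins/maxs must have one entry per slot")
        if np.any(self.maxs < self.mins):
            raise ValueError("max < min in scaling stats")

    @classmethod
    def fit(cls, table, slot_names: tuple[str, ...] = SLOT_NAMES) -> "ScalingStats":
        """Fit per-slot ranges from a descriptor DataFrame (NaN = missing)."""
        mins, maxs = [], []
        for i, name in enumerate(slot_names):
            if i in BINARY_SLOTS:
                mins.append(0.0)
                maxs.append(1.0)
                continue
            col = np.asarray(table[name], dtype=float)
            col = col[np.isfinite(col)]
            if col.size == 0:
                # a never-observed slot cannot be scaled; pin to (0, 1)
                warnings.warn(f"no observed values for slot {name!r}; using (0, 1)")
                mins.append(0.0)
                maxs.append(1.0)
                continue
            mins.append(float(col.min()))
            maxs.append(float(col.max()))
        return cls(np.array(mins), np.array(maxs), slot_names)

    def normalize(self, c: np.ndarray) -> np.ndarray:
        """Map raw slot values to [0, 1] (NaN passes through as NaN)."""
        c = np.asarray(c, dtype=float)
        span = self.maxs - self.mins
        out = np.empty_like(c, dtype=float)
        for i in range(len(self.slot_names)):
            if span[i] == 0:
                if np.any(np.isfinite(np.atleast_1d(c[..., i]))):
                    warnings.warn(f"constant slot {self.slot_names[i]!r}: normalizing to 0")
                out[..., i] = np.where(np.isfinite(c[..., i]), 0.0, np.nan)
            else:
                out[..., i] = (c[..., i] - self.mins[i]) / span[i]
        return out

    def denormalize(self, c: np.ndarray) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        span = self.maxs - self.mins
        return c * span + self.mins

    def to_dict(self) -> dict:
        return {"mins": self.mins.tolist(), "maxs": self.maxs.tolist(),
                "slot_names": list(self.slot_names)}

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingStats":
        return cls(np.array(d["mins"]), np.array(d["maxs"]), tuple(d["slot_names"]))


def compute_descriptor_table(peptides, structures: dict | None = None,
                             source_table=None, dedup: str = "first"):
    """Materialize the descriptor table for a set of peptides.

    ``length`` and ``net_charge`` are always computed from the sequence;
    ``has_beta_strand`` and ``hydrophobic_moment`` are filled only where a
    :class:`StructureModel` is supplied in ``structures``; ``ap`` and
    ``is_assembled`` are passed through from ``source_table`` (indexed by
    sequence) when given. Missing entries are NaN.
    """
    import pandas as pd

    structures = structures or {}
    rows = []
    seen: set[str] = set()
    for p in peptides:
        pep = p if isinstance(p, Peptide) else Peptide(str(p))
        seq = pep.sequence
        if seq in seen:
            if dedup == "first":
                continue
            raise ValueError(f"duplicate sequence {seq!r}")
        seen.add(seq)
        row = {"sequence": seq, "length": pep.length, "ap": np.nan,
               "is_assembled": np.nan, "has_beta_strand": np.nan,
               "hydrophobic_moment": np.nan, "net_charge": net_charge(pep)}
        s = structures.get(seq)
        if s is not None:
            _, has_beta = beta_strand_descriptor(s.ss_labels)
            row["has_beta_strand"] = float(has_beta)
            row["hydrophobic_moment"] = hydrophobic_moment(s)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["sequence", "length", "ap", "is_assembled",
                                     "has_beta_strand", "hydrophobic_moment",
                                     "net_charge"])
    if source_table is not None and len(df):
        src = source_table.set_index("sequence")
        for col in ("ap", "is_assembled"):
            if col in src.columns:
                df[col] = df["sequence"].map(src[col]).astype(float)
    return df
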