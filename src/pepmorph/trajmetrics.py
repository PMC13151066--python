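"""Trajectory-derived aggregation and morphology metrics.

Aggregation propensity (AP) from a per-frame SASA series — the mean of
the first two frames over the mean of the last two (SASA drops as
peptides aggregate, so aggregators give AP well above 1). Aggregate
morphology from a coarse-grained final frame: beads are clustered by
surface-to-surface contact under the minimum-image convention, the
largest cluster is unwrapped across periodic boundaries, and the ratio
of its smallest to largest mass-weighted inertia-tensor eigenvalues
(RMOI ∈ (0, 1]) classifies it as fibrillar (≤ 0.35), spherical
(≥ 0.75), or undefined in between.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np

from .io import BeadFrame

__all__ = [
    "RMOI_FIBRIL_MAX", "RMOI_SPHERE_MIN", "DEFAULT_R_CUT", "MorphologyCall",
    "ap_from_sasa", "cluster_beads", "largest_cluster", "unwrap_cluster",
    "inertia_rmoi", "classify_morphology", "majority_vote",
]

RMOI_FIBRIL_MAX = 0.35
RMOI_SPHERE_MIN = 0.75
DEFAULT_R_CUT = 0.6  # nm, surface-to-surface contact cutoff


def ap_from_sasa(series: np.ndarray) -> float:
    """AP = mean(first two SASA frames) / mean(last two).

    Requires at least four time-ordered, positive SASA values so the early
    and late windows do not overlap.
    """
    s = np.asarray(series, dtype=float)
    if s.ndim != 1 or len(s) < 4:
        raise ValueError("need a 1-D SASA series with at least 4 frames")
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("SASA values must be positive and finite")
    first2 = (s[0] + s[1]) / 2.0
    last2 = (s[-2] + s[-1]) / 2.0
    return float(first2 / last2)


def _min_image_diff(diff: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Displacement vectors mapped to the nearest periodic image."""
    return diff - box * np.round(diff / box)


def _adjacency(frame: BeadFrame, r_cut: float) -> np.ndarray:
    pos = frame.positions
    diff = pos[:, None, :] - pos[None, :, :]
    diff = _min_image_diff(diff, frame.box)
    d = np.linalg.norm(diff, axis=-1)
    contact = (d - (frame.radii[:, None] + frame.radii[None, :])) < r_cut
    np.fill_diagonal(contact, False)
    return contact


def cluster_beads(frame: BeadFrame, r_cut: float = DEFAULT_R_CUT) -> np.ndarray:
    """Connected-component labels under minimum-image surface contact.

    Beads j, k are connected iff d_jk − (r_j + r_k) < r_cut with d_jk the
    minimum-image center distance. Labels are 0-based component indices.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    if r_cut <= 0:
        raise ValueError("r_cut must be positive")
    contact = _adjacency(frame, r_cut)
    _, labels = connected_components(csr_matrix(contact), directed=False)
    return labels


def largest_cluster(frame: BeadFrame, r_cut: float = DEFAULT_R_CUT,
                    by: str = "count") -> np.ndarray:
    """Member indices of the largest cluster, by bead count (default) or
    total mass (``by='mass'``)."""
    labels = cluster_beads(frame, r_cut)
    best_label, best_score = None, -np.inf
    for lab in np.unique(labels):
        members = labels == lab
        score = members.sum() if by == "count" else frame.masses[members].sum()
        if score > best_score:
            best_label, best_score = lab, score
    return np.nonzero(labels == best_label)[0]


def unwrap_cluster(frame: BeadFrame, members: np.ndarray,
                   r_cut: float = DEFAULT_R_CUT) -> np.ndarray:
    """Unwrap member coordinates across periodic boundaries.

    Walks a BFS spanning tree of the contact graph, placing each bead at
    the minimum-image position relative to its already-placed neighbor.
    Correct for clusters that are connected through contacts; a cluster
    percolating more than half the box along an axis cannot be
    represented faithfully by any pairwise minimum-image scheme.
    """
    members = np.asarray(members)
    sub = BeadFrame(frame.positions[members], frame.box,
                    frame.radii[members], frame.masses[members])
    contact = _adjacency(sub, r_cut)
    n = len(members)
    out = sub.positions.copy()
    placed = np.zeros(n, dtype=bool)
    for start in range(n):
        if placed[start]:
            continue
        placed[start] = True
        queue = deque([start])
        while queue:
            i = queue.popleft()
            for j in np.nonzero(contact[i])[0]:
                if placed[j]:
                    continue
                diff = _min_image_diff(sub.positions[j] - out[i], frame.box)
                out[j] = out[i] + diff
                placed[j] = True
                queue.append(j)
    return out


def inertia_rmoi(frame: BeadFrame, members: np.ndarray,
                 r_cut: float = DEFAULT_R_CUT) -> tuple[np.ndarray, float]:
    """Inertia-tensor eigenvalues (ascending) and RMOI = λ1/λ3.

    Member coordinates are unwrapped, translated to the mass-weighted
    center of mass, and the standard mass-weighted second-moment inertia
    tensor I = Σ_j m_j (‖r̃_j‖² 1 − r̃_j r̃_jᵀ) is diagonalized.
    """
    members = np.asarray(members)
    if len(members) < 2:
        raise ValueError("need at least two member beads")
    pos = unwrap_cluster(frame, members, r_cut)
    masses = frame.masses[members]
    com = (masses[:, None] * pos).sum(axis=0) / masses.sum()
    r = pos - com
    if np.allclose(r, 0):
        raise ValueError("degenerate cluster: all beads coincident")
    r2 = (r**2).sum(axis=1)
    inertia = (masses[:, None, None]
               * (r2[:, None, None] * np.eye(3) - r[:, :, None] * r[:, None, :])
               ).sum(axis=0)
    eigvals = np.linalg.eigvalsh(inertia)
    eigvals = np.clip(eigvals, 0.0, None)
    rmoi = float(eigvals[0] / eigvals[2])
    return eigvals, rmoi


@dataclass(frozen=True)
class MorphologyCall:
    """An RMOI value and its threshold classification."""

    rmoi: float
    label: str  # fibrillar | spherical | undefined

    def __post_init__(self):
        if not 0.0 <= self.rmoi <= 1.0:
            raise ValueError("rmoi must lie in (0, 1]")


def classify_morphology(rmoi: float, fibril_max: float = RMOI_FIBRIL_MAX,
                        sphere_min: float = RMOI_SPHERE_MIN) -> MorphologyCall:
    """fibrillar iff RMOI ≤ 0.35, spherical iff RMOI ≥ 0.75, else undefined."""
    if rmoi <= fibril_max:
        label = "fibrillar"
    elif rmoi >= sphere_min:
        label = "spherical"
    else:
        label = "undefined"
    return MorphologyCall(float(rmoi), label)


def majority_vote(calls) -> str:
    """Cohort morphology over replicate runs by strict majority.

    With an even split (possible only for even replicate counts) the
    result is 'undefined' with a warning.
    """
    labels = [c.label if isinstance(c, MorphologyCall) else str(c) for c in calls]
    if not labels:
        raise ValueError("no replicate calls")
    counts = {lab: labels.count(lab) for lab in set(labels)}
    best = max(counts.values())
    winners = [lab for lab, n in counts.items() if n == best]
    if len(winners) > 1:
        warnings.warn("replicate tie: no strict majority")
        return "undefined"
    if best * 2 <= len(labels):
        warnings.warn("plurality without strict majority")
    return winners[0]
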