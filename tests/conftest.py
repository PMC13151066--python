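"""Shared fixtures: synthetic corpora, toy structures, seeded generators."""

from __future__ import annotations

import numpy as np
import pytest

from pepmorph import make_synthetic_corpus
from pepmorph.dataset import SplitSpec, stratified_split
from pepmorph.descriptors import StructureModel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """600-record synthetic corpus with the planted AP rule."""
    return make_synthetic_corpus(600, seed=42)


@pytest.fixture(scope="session")
def small_splits(small_corpus):
    return stratified_split(small_corpus, SplitSpec(seed=0))


def make_toy_structure(sequence: str, seed: int = 0,
                       ss_labels: str | None = None) -> StructureModel:
    """Random but valid backbone geometry for a short peptide (nm units)."""
    rng = np.random.default_rng(seed)
    L = len(sequence)
    ca = np.cumsum(rng.normal(0.0, 0.1, size=(L, 3)), axis=0) + np.array([0.38, 0, 0]) * np.arange(L)[:, None]
    n = ca + rng.normal(0.0, 0.05, size=(L, 3)) + np.array([-0.15, 0.05, 0.0])
    c = ca + rng.normal(0.0, 0.05, size=(L, 3)) + np.array([0.15, 0.05, 0.0])
    cb = ca + _random_units(rng, L) * 0.153
    if ss_labels is None:
        ss_labels = "C" * L
    return StructureModel(sequence, n, ca, c, cb, ss_labels)


def _random_units(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


@pytest.fixture
def toy_structure():
    return make_toy_structure("AKDFG", seed=3)
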