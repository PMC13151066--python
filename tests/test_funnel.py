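"""Condition grids, the screening funnel, and cohort statistics."""

import math

import numpy as np
import pytest

from pepmorph.descriptors import SLOT_NAMES
from pepmorph.evalgen import ConditionQuery
from pepmorph.funnel import (
    CandidateRecord,
    build_grid,
    calls_per_hit,
    fisher_or,
    run_funnel,
    wilson_ci,
)


class StubModel:
    """Deterministic generator cycling through a fixed pool of sequences."""

    def __init__(self, pool):
        self.pool = list(pool)
        self._i = 0

    def generate(self, c, m, n, rng, temperature=None):
        from pepmorph.descriptors import Peptide

        out = []
        for _ in range(n):
            out.append(Peptide(self.pool[self._i % len(self.pool)]))
            self._i += 1
        return out


class StubPredictor:
    def __init__(self, table=None, default=(2.0, 1.0)):
        self.table = table or {}
        self.default = default

    def predict_batch(self, sequences):
        from pepmorph.predictor import PredictorOutput

        outs = []
        for s in sequences:
            ap, p = self.table.get(str(s), self.default)
            outs.append(PredictorOutput(ap, p))
        return outs


class TestGrids:
    def test_sphere_condition_count(self):
        grid = build_grid("sphere")
        assert len(grid) == 60  # 3 lengths x 5 moments x 4 charges

    def test_fibril_condition_count(self):
        grid = build_grid("fibril")
        assert len(grid) == 16  # 4 lengths x 4 charges

    def test_budget_split_consistency(self):
        # equal 4800-sequence budgets: 80/condition (sphere), 300 (fibril)
        assert 4800 // len(build_grid("sphere")) == 80
        assert 4800 // len(build_grid("fibril")) == 300

    def test_sphere_masks_mark_swept_slots(self):
        idx = {n: i for i, n in enumerate(SLOT_NAMES)}
        for q in build_grid("sphere").queries:
            observed = {n for n, i in idx.items() if q.m[i] == 1}
            assert observed == {"length", "is_assembled", "hydrophobic_moment",
                                "net_charge"}
            assert q.c[idx["is_assembled"]] == 1.0

    def test_fibril_masks_and_beta(self):
        idx = {n: i for i, n in enumerate(SLOT_NAMES)}
        for q in build_grid("fibril").queries:
            observed = {n for n, i in idx.items() if q.m[i] == 1}
            assert observed == {"length", "is_assembled", "has_beta_strand",
                                "net_charge"}
            assert q.c[idx["has_beta_strand"]] == 1.0

    def test_unknown_target(self):
        with pytest.raises(ValueError):
            build_grid("sheet")


class TestFunnel:
    def _grid_one_condition(self):
        c = np.zeros(6)
        m = np.zeros(6)
        c[0], m[0] = 5.0, 1     # length 5
        from pepmorph.funnel import ConditionGrid

        return ConditionGrid("sphere", (ConditionQuery(c, m),))

    def test_permissive_predictor_passes_everything(self):
        grid = self._grid_one_condition()
        model = StubModel(["AAAAA", "CCCCC", "DDDDD"])
        predictor = StubPredictor()  # ap 2.0, p 1.0 for everything

        def provider(seq):
            vec = np.zeros(6)
            vec[0] = 5.0
            return vec

        candidates, report = run_funnel(model, predictor, grid, 3, provider)
        assert report.n_generated == 3
        assert report.n_aggregation_pass == 3
        assert report.n_compliance_pass == 3

    def test_hostile_structures_fail_compliance(self):
        grid = self._grid_one_condition()
        model = StubModel(["AAAAA", "CCCCC"])
        predictor = StubPredictor()

        def provider(seq):
            vec = np.zeros(6)
            vec[0] = 9.0  # violates the length-5 target
            return vec

        _, report = run_funnel(model, predictor, grid, 2, provider)
        assert report.n_aggregation_pass == 2
        assert report.n_compliance_pass == 0

    def test_planted_enumeration(self):
        """Ten sequences with planted predictions straddling the
        thresholds: surviving counts equal hand enumeration."""
        pool = [f"{a}AAAA" for a in "ACDEFGHIKL"]
        table = {}
        # first 4: fail aggregation (low p or low ap); next 3: pass both
        # stages; last 3: pass aggregation, fail compliance
        for i, s in enumerate(pool):
            if i < 2:
                table[s] = (2.0, 0.5)       # p below 0.75
            elif i < 4:
                table[s] = (1.5, 1.0)       # ap below 1.8
            else:
                table[s] = (1.9 + 0.01 * i, 0.9)
        compliant = set(pool[4:7])

        def provider(seq):
            vec = np.zeros(6)
            vec[0] = 5.0 if seq in compliant else 7.0
            return vec

        grid = self._grid_one_condition()
        model = StubModel(pool)
        candidates, report = run_funnel(model, StubPredictor(table), grid,
                                        10, provider, top_k=2)
        assert report.n_generated == 10
        assert report.n_deduplicated == 10
        assert report.n_aggregation_pass == 6
        assert report.n_compliance_pass == 3
        assert report.n_selected == 2
        # top-k selects the highest ap_hat among survivors
        selected = sorted(c.sequence for c in candidates if c.selected)
        aps = {s: table[s][0] for s in compliant}
        expected = sorted(sorted(compliant, key=lambda s: -aps[s])[:2])
        assert selected == expected

    def test_stage_counts_monotone(self):
        grid = self._grid_one_condition()
        model = StubModel(["AAAAA", "CCCCC", "DDDDD", "EEEEE"])
        table = {"AAAAA": (2.0, 1.0), "CCCCC": (1.0, 1.0),
                 "DDDDD": (2.0, 0.5), "EEEEE": (2.5, 0.9)}

        def provider(seq):
            vec = np.zeros(6)
            vec[0] = 5.0 if seq == "AAAAA" else 8.0
            return vec

        _, report = run_funnel(model, StubPredictor(table), grid, 4, provider)
        stages = report.stages()
        assert all(a >= b for a, b in zip(stages, stages[1:]))

    def test_dedup_and_budget_accounting(self):
        grid = self._grid_one_condition()
        model = StubModel(["AAAAA", "AAAAA", "CCCCC"])  # duplicate in pool
        predictor = StubPredictor()

        def provider(seq):
            vec = np.zeros(6)
            vec[0] = 5.0
            return vec

        _, report = run_funnel(model, predictor, grid, 6, provider)
        assert report.n_generated == 6 * len(grid.queries)
        assert report.n_deduplicated == 2

    def test_provider_failure_drops_candidate(self):
        grid = self._grid_one_condition()
        model = StubModel(["AAAAA", "CCCCC"])

        def provider(seq):
            if seq == "AAAAA":
                raise RuntimeError("prediction failed")
            vec = np.zeros(6)
            vec[0] = 5.0
            return vec

        candidates, report = run_funnel(model, StubPredictor(), grid, 2, provider)
        assert report.n_compliance_pass == 1
        failed = next(c for c in candidates if c.sequence == "AAAAA")
        assert "descriptor_provider" in failed.failure_reason


class TestCallsPerHit:
    @pytest.mark.parametrize("calls,hits,expected", [
        (4800, 76, pytest.approx(63.2, abs=0.1)),
        (4800, 29, pytest.approx(165.5, abs=0.1)),
        (10, 10, 1.0),
    ])
    def test_values(self, calls, hits, expected):
        assert calls_per_hit(calls, hits) == expected

    def test_zero_hits_is_infinite(self):
        assert math.isinf(calls_per_hit(4800, 0))

    def test_negative_errors(self):
        with pytest.raises(ValueError):
            calls_per_hit(5, 6)


class TestWilson:
    def test_boundaries(self):
        lo, _ = wilson_ci(0, 20)
        _, hi = wilson_ci(20, 20)
        assert lo == 0.0
        assert hi == 1.0

    def test_contains_point_estimate(self):
        lo, hi = wilson_ci(8, 10)
        assert lo <= 0.8 <= hi

    def test_textbook_formula(self):
        """Independent evaluation of the Wilson score formula."""
        from scipy.stats import norm

        s, n = 8, 10
        z = norm.ppf(0.975)
        p = s / n
        denom = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        lo, hi = wilson_ci(s, n)
        assert lo == pytest.approx(center - half, rel=1e-9)
        assert hi == pytest.approx(center + half, rel=1e-9)

    def test_zero_n_errors(self):
        with pytest.raises(ValueError):
            wilson_ci(0, 0)


class TestFisher:
    @pytest.mark.parametrize("table,or_expected,p_expected", [
        ([[12, 3], [8, 5]], 2.5, 0.410),
        ([[13, 2], [6, 7]], 91 / 12, 0.042),
        ([[25, 5], [14, 12]], 300 / 70, 0.022),
    ])
    def test_reported_cohort_comparisons(self, table, or_expected, p_expected):
        oddsratio, p = fisher_or(table)
        assert oddsratio == pytest.approx(or_expected, rel=1e-9)
        assert p == pytest.approx(p_expected, abs=5e-4)

    def test_symmetric_table(self):
        oddsratio, p = fisher_or([[4, 4], [4, 4]])
        assert oddsratio == 1.0
        assert p == 1.0

    def test_zero_cell_infinite_or(self):
        oddsratio, p = fisher_or([[5, 0], [2, 3]])
        assert math.isinf(oddsratio)
        assert 0 < p <= 1

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            fisher_or([[0, 0], [0, 0]])

    def test_exhaustive_hypergeometric_enumeration(self, rng):
        """Two-sided p equals direct enumeration of all tables with the
        observed margins, summing those no more likely than observed."""
        from scipy.stats import hypergeom

        for _ in range(20):
            a, b, c, d = rng.integers(0, 12, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            n = a + b + c + d
            row1, col1 = a + b, a + c
            pmf = lambda x: hypergeom.pmf(x, n, row1, col1)
            p_obs = pmf(a)
            lo = max(0, row1 + col1 - n)
            hi = min(row1, col1)
            p_two = sum(pmf(x) for x in range(lo, hi + 1)
                        if pmf(x) <= p_obs * (1 + 1e-9))
            _, p = fisher_or([[a, b], [c, d]])
            assert p == pytest.approx(min(p_two, 1.0), rel=1e-6)
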