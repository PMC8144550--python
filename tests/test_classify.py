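import math
from fractions import Fraction

import numpy as np
import pytest

from ampedit.align import EventTable
from ampedit.classify import (
    ClassifyParams,
    build_prior_ladder,
    classify_cell,
    estimate_q,
    loglik_edit,
    loglik_no_edit,
    mark_edited_reads,
    prior_for_distance,
)
from ampedit.errors import ConfigError
from ampedit.panel import CutSite

from .oracles import binom_pmf_exact, hg_pmf_exact, map_label_exact


class TestPriorLadder:
    def test_endpoint_values(self):
        p = ClassifyParams()
        assert prior_for_distance(0, 10, p) == 0.5
        assert prior_for_distance(1, 10, p) == pytest.approx(1e-1)
        assert prior_for_distance(10, 10, p) == pytest.approx(1e-4)

    def test_monotone_decay(self):
        p = ClassifyParams()
        vals = [prior_for_distance(d, 10, p) for d in range(11)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert all(0 < v < 1 for v in vals)

    def test_ladder_symmetric_around_cut(self):
        ladder = build_prior_ladder((90, 110), CutSite(100, "+"))
        assert ladder.prior_at(100) == 0.5
        assert ladder.prior_at(99) == ladder.prior_at(101) == pytest.approx(0.1)
        assert ladder.prior_at(90) == ladder.prior_at(110) == pytest.approx(1e-4)

    def test_override_wrong_length_errors(self):
        params = ClassifyParams(prior_override=[0.5] * 5)
        with pytest.raises(ConfigError):
            build_prior_ladder((90, 110), 100, params)

    def test_override_out_of_range_errors(self):
        params = ClassifyParams(prior_override=[0.5] * 20 + [1.0])
        with pytest.raises(ConfigError):
            build_prior_ladder((90, 110), 100, params)

    def test_override_is_used(self):
        params = ClassifyParams(prior_override=[0.25] * 21)
        ladder = build_prior_ladder((90, 110), 100, params)
        assert ladder.prior_at(90) == ladder.prior_at(100) == 0.25


class TestLikelihoods:
    def test_no_edit_empty_draw(self):
        assert loglik_no_edit(0, 0, 100, 100) == 0.0

    def test_no_edit_exact_small_cases(self):
        assert loglik_no_edit(1, 0, 1, 1) == pytest.approx(math.log(0.5))
        assert loglik_no_edit(2, 0, 2, 2) == pytest.approx(math.log(1 / 6))

    def test_no_edit_bounds_error(self):
        with pytest.raises(ValueError):
            loglik_no_edit(5, 0, 4, 10)

    def test_edit_closed_form(self):
        assert loglik_edit(2, 1, 0.9) == pytest.approx(math.log(0.243))
        assert loglik_edit(0, 0, 0.5) == 0.0
        assert loglik_edit(0, 5, 0.5) == pytest.approx(5 * math.log(0.5))

    def test_edit_q_domain_error(self):
        with pytest.raises(ValueError):
            loglik_edit(1, 1, 1.0)

    def test_log_space_matches_exact_rationals(self):
        """Hypergeometric and binomial log-likelihoods agree with exact
        rational arithmetic to 1e-9 relative error (randomized N <= 200)."""
        rng = np.random.default_rng(5)
        for _ in range(300):
            N_tx = int(rng.integers(1, 101))
            N_m = int(rng.integers(1, 101))
            n_tx = int(rng.integers(0, N_tx + 1))
            n_m = int(rng.integers(0, N_m + 1))
            exact = hg_pmf_exact(n_tx, N_tx + N_m, n_tx + n_m, N_tx)
            if exact > 0:
                got = math.exp(loglik_no_edit(n_tx, n_m, N_tx, N_m))
                assert abs(got - float(exact)) <= 1e-9 * float(exact)
            q = Fraction(93, 100)
            exact_b = binom_pmf_exact(n_tx, n_tx + n_m, q)
            got_b = math.exp(loglik_edit(n_tx, n_m, float(q)))
            if exact_b > 0:
                assert abs(got_b - float(exact_b)) <= 1e-9 * float(exact_b)


class TestClassifyCell:
    def test_no_treatment_evidence_short_circuits_to_noise(self):
        d = classify_cell(0, 0, 100, 100, 0.5, 0.95)
        assert d.label == "noise"
        d = classify_cell(0, 40, 1000, 1000, 0.5, 0.95)
        assert d.label == "noise"

    def test_strong_tx_only_signal_is_edit(self):
        d = classify_cell(50, 0, 10000, 10000, 0.5, 0.95)
        assert d.label == "edit"

    def test_masked_signal_cell_matches_exact_oracle(self):
        """A cut-site cell where mock indels outnumber treatment ones
        (17 Tx vs 41 M at 30k/30k depth): label fixed by the exact-rational
        MAP oracle, not assumed."""
        n_tx, n_m, N, q = 17, 41, 30000, Fraction(93, 100)
        expected = map_label_exact(n_tx, n_m, N, N, Fraction(1, 2), q)
        d = classify_cell(n_tx, n_m, N, N, 0.5, float(q))
        assert d.label == expected

    def test_decisions_match_exact_oracle_on_random_grid(self):
        rng = np.random.default_rng(17)
        q = Fraction(95, 100)
        for _ in range(200):
            N_tx = int(rng.integers(10, 200))
            N_m = int(rng.integers(10, 200))
            n_tx = int(rng.integers(0, min(N_tx, 30) + 1))
            n_m = int(rng.integers(0, min(N_m, 30) + 1))
            prior_num = int(rng.integers(1, 10))
            prior = Fraction(prior_num, 20)
            got = classify_cell(n_tx, n_m, N_tx, N_m, float(prior), float(q)).label
            want = map_label_exact(n_tx, n_m, N_tx, N_m, prior, q)
            if n_tx == 0:
                assert got == "noise"
            else:
                assert got == want

    def test_monotone_in_n_tx_and_n_m(self):
        """More treatment evidence never flips edit->noise; more mock
        evidence never flips noise->edit."""
        rng = np.random.default_rng(23)
        for _ in range(60):
            N = int(rng.integers(500, 5000))
            n_m = int(rng.integers(0, 30))
            prior = float(rng.choice([1e-4, 1e-2, 0.1, 0.5]))
            labels = [
                classify_cell(n_tx, n_m, N, N, prior, 0.95).label
                for n_tx in range(0, 40)
            ]
            first_edit = labels.index("edit") if "edit" in labels else len(labels)
            assert all(l == "edit" for l in labels[first_edit:])
            n_tx = int(rng.integers(1, 30))
            labels_m = [
                classify_cell(n_tx, n_m2, N, N, prior, 0.95).label
                for n_m2 in range(0, 40)
            ]
            first_noise = labels_m.index("noise") if "noise" in labels_m else len(labels_m)
            assert all(l == "noise" for l in labels_m[first_noise:])

    def test_balanced_small_counts_are_noise(self):
        # with q at the hypergeometric's mean behavior and an even prior,
        # symmetric evidence must not be called an edit
        for n in (1, 2, 5, 10):
            d = classify_cell(n, n, 20000, 20000, 0.5, 0.5)
            assert d.label == "noise"


def _table(cells, n_tx=10000, n_m=10000, site="on", window=(90, 110)):
    t = EventTable(site_id=site, window=window, n_tx=n_tx, n_m=n_m)
    t.counts = {cell: list(counts) for cell, counts in cells.items()}
    return t


class TestEstimateQ:
    CUT = {"on": CutSite(100, "+")}

    def test_single_qualifying_cell(self):
        t = _table({("deletion", 1, 100): (950, 50)})
        q = estimate_q({"on": t}, self.CUT, ["on"])
        assert q.q == pytest.approx(0.95)
        assert q.source == "estimated"

    def test_clamped_high(self):
        t = _table({("deletion", 1, 100): (10000, 0)}, n_tx=20000)
        q = estimate_q({"on": t}, self.CUT, ["on"])
        assert q.q == 0.999 and q.source == "clamped"

    def test_fallback_without_evidence(self):
        t = _table({("deletion", 1, 100): (10, 2)})
        q = estimate_q({"on": t}, self.CUT, ["on"])
        assert q.q == 0.95 and q.source == "default"

    def test_far_from_cut_cells_ignored(self):
        t = _table({("deletion", 1, 92): (900, 0)})
        q = estimate_q({"on": t}, self.CUT, ["on"])
        assert q.source == "default"


class TestMarkEditedReads:
    def test_any_edit_cell_marks_read(self):
        t = _table({("deletion", 1, 100): (5, 0), ("insertion", 1, 95): (5, 5)})
        t.tx_read_cells = {
            "both": frozenset({("deletion", 1, 100), ("insertion", 1, 95)}),
            "noise_only": frozenset({("insertion", 1, 95)}),
        }
        decisions = [
            classify_cell(5, 0, 10000, 10000, 0.5, 0.95, "deletion", 1, 100),
            classify_cell(5, 5, 10000, 10000, 0.01, 0.95, "insertion", 1, 95),
        ]
        assert decisions[0].label == "edit" and decisions[1].label == "noise"
        edited = mark_edited_reads(t, decisions)
        assert edited == {"both"}

    def test_no_window_events_not_marked(self):
        t = _table({})
        assert mark_edited_reads(t, []) == set()
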