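import math

import numpy as np
import pytest

from ampedit.demux import Assignment
from ampedit.panel import Read, locate_cut_sites, revcomp
from ampedit.translocation import (
    TranslocationParams,
    build_fusion_amplicon,
    fdr_correct,
    hypergeometric_tail,
    type_candidate,
    validate_candidates,
    TranslocationResult,
)
from ampedit.translocation import test_pair as pair_test

from .oracles import hg_tail_exact


def _cand_assignment(prefix, suffix):
    return Assignment("r", None, None, "candidate",
                      prefix_primer=prefix, suffix_primer=suffix)


class TestTypeCandidate:
    def test_fr_is_rule_one(self):
        c = type_candidate(Read("r", "ACGT"), _cand_assignment("a:F", "b:R"), "tx")
        assert (c.rule, c.site_a, c.site_b, c.orientation) == (1, "a", "b", "as-written")

    def test_rf_is_rule_one_reverse_complement(self):
        c = type_candidate(Read("r", "ACGT"), _cand_assignment("a:R", "b:F"), "tx")
        assert c.rule == 1 and c.orientation == "reverse-complement"
        assert (c.site_a, c.site_b) == ("b", "a")

    def test_ff_is_rule_three(self):
        c = type_candidate(Read("r", "ACGT"), _cand_assignment("b:F", "a:F"), "mock")
        assert c.rule == 3 and c.sample == "mock"

    def test_rr_is_rule_four(self):
        c = type_candidate(Read("r", "ACGT"), _cand_assignment("a:R", "b:R"), "tx")
        assert c.rule == 4

    def test_same_site_is_not_a_fusion(self):
        assert type_candidate(Read("r", "ACGT"), _cand_assignment("a:F", "a:F"), "tx") is None


class TestFusionAmplicon:
    def test_rule1_concatenation(self, panel2):
        a, b = panel2
        cuts = locate_cut_sites(panel2)
        ca, cb = cuts[a.site_id], cuts[b.site_id]
        amp = build_fusion_amplicon(a, b, 1, ca, cb)
        assert amp == a.amplicon[: ca.index + 1] + b.amplicon[cb.index + 1:]
        assert amp.startswith(a.fwd_primer)
        assert amp.endswith(revcomp(b.rev_primer))

    def test_rule3_head_to_head_length(self, panel2):
        a, b = panel2
        cuts = locate_cut_sites(panel2)
        ca, cb = cuts[a.site_id], cuts[b.site_id]
        amp = build_fusion_amplicon(a, b, 3, ca, cb)
        assert len(amp) == (ca.index + 1) + (cb.index + 1)
        assert amp == a.amplicon[: ca.index + 1] + revcomp(b.amplicon[: cb.index + 1])

    def test_rule4_tail_to_tail_primers(self, panel2):
        a, b = panel2
        cuts = locate_cut_sites(panel2)
        amp = build_fusion_amplicon(a, b, 4, cuts[a.site_id], cuts[b.site_id])
        assert amp.startswith(a.rev_primer)
        assert amp.endswith(revcomp(b.rev_primer))

    def test_same_site_errors(self, panel2):
        a = panel2[0]
        cuts = locate_cut_sites(panel2)
        with pytest.raises(ValueError):
            build_fusion_amplicon(a, a, 1, cuts[a.site_id], cuts[a.site_id])


class TestValidateCandidates:
    def _setup(self, panel2):
        cuts = locate_cut_sites(panel2)
        pm = {s.site_id: s for s in panel2}
        return cuts, pm

    def test_exact_fusion_read_retained(self, panel2):
        cuts, pm = self._setup(panel2)
        a, b = panel2
        amp = build_fusion_amplicon(a, b, 1, cuts[a.site_id], cuts[b.site_id])
        read = Read("r", amp)
        cand = type_candidate(read, _cand_assignment(f"{a.site_id}:F", f"{b.site_id}:R"), "tx")
        counts = validate_candidates([(read, cand)], pm, cuts)
        pair = tuple(sorted((a.site_id, b.site_id)))
        assert counts[pair]["tx"] == 1

    def test_mostly_random_read_rejected(self, panel2):
        cuts, pm = self._setup(panel2)
        a, b = panel2
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), 120))
        read = Read("r", a.fwd_primer + junk + revcomp(b.rev_primer))
        cand = type_candidate(read, _cand_assignment(f"{a.site_id}:F", f"{b.site_id}:R"), "tx")
        counts = validate_candidates([(read, cand)], pm, cuts)
        assert counts == {}

    def test_zero_candidates(self, panel2):
        cuts, pm = self._setup(panel2)
        assert validate_candidates([], pm, cuts) == {}


class TestHypergeometricTail:
    def test_whole_support(self):
        assert hypergeometric_tail(0, 100, 10, 50) == 1.0

    def test_small_exact_value(self):
        # C(2,2) C(8,3) / C(10,5) = 56/252 = 2/9
        assert hypergeometric_tail(2, 10, 2, 5) == pytest.approx(2 / 9, rel=1e-12)

    def test_balanced_large_population(self):
        # exact product form: all 5 candidates drawn into the Tx half
        exact = math.prod((20000 - i) / (40000 - i) for i in range(5))
        assert hypergeometric_tail(5, 40000, 5, 20000) == pytest.approx(exact, rel=1e-10)
        assert hypergeometric_tail(5, 40000, 5, 20000) == pytest.approx(0.03124, rel=1e-3)

    def test_matches_exact_enumeration_on_grid(self):
        rng = np.random.default_rng(9)
        for _ in range(150):
            N = int(rng.integers(1, 61))
            B = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            b = int(rng.integers(0, B + 1))
            exact = float(hg_tail_exact(b, N, B, n))
            got = hypergeometric_tail(b, N, B, n)
            assert got == pytest.approx(exact, rel=1e-10, abs=1e-300)

    def test_monotone_in_b(self):
        vals = [hypergeometric_tail(b, 60, 20, 30) for b in range(21)]
        assert all(x >= y for x, y in zip(vals, vals[1:]))

    def test_invalid_bounds_error(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(1, 10, 12, 5)


class TestPairTest:
    TX = {"a": 10_000, "b": 40_000}
    M = {"a": 10_000, "b": 40_000}

    def test_geometric_mean_sizes_and_p(self):
        res = pair_test(("a", "b"), 5, 0, self.TX, self.M)
        assert res.n == 20_000 and res.N == 40_000
        assert res.p_value == pytest.approx(0.03124, rel=1e-3)

    def test_no_tx_candidates_gives_p_one(self):
        res = pair_test(("a", "b"), 0, 3, self.TX, self.M)
        assert res.p_value == 1.0

    def test_symmetric_under_site_swap(self):
        r1 = pair_test(("a", "b"), 7, 2, self.TX, self.M)
        r2 = pair_test(("b", "a"), 7, 2,
                       {"b": self.TX["a"], "a": self.TX["b"]},
                       {"b": self.M["a"], "a": self.M["b"]})
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-12)
        assert (r1.n, r1.N) == (r2.n, r2.N)

    def test_zero_depth_site_skipped(self):
        assert pair_test(("a", "b"), 1, 0, {"a": 0, "b": 100}, self.M) is None


class TestFdr:
    @staticmethod
    def _results(ps):
        return [
            TranslocationResult("a", f"b{k}", 1, 0, 10, 20, p)
            for k, p in enumerate(ps)
        ]

    def test_single_p_unchanged(self):
        (r,) = fdr_correct(self._results([0.01]))
        assert r.q_value == pytest.approx(0.01) and r.significant

    def test_step_up_adjustment(self):
        rs = fdr_correct(self._results([0.01, 0.02, 0.03]))
        assert [r.q_value for r in rs] == pytest.approx([0.03, 0.03, 0.03])

    def test_p_of_one(self):
        (r,) = fdr_correct(self._results([1.0]))
        assert r.q_value == 1.0 and not r.significant

    def test_q_at_least_p(self):
        rs = fdr_correct(self._results([0.001, 0.2, 0.04, 0.9]))
        for r in rs:
            assert r.q_value >= r.p_value - 1e-15
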