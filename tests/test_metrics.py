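"""Span matching, P/R/F1 with bootstrap CIs, IAA and KL distinctiveness."""

import math
from functools import lru_cache

import numpy as np
import pytest

from volspan import (
    AnnotatedCorpus,
    Category,
    Report,
    SpanAnnotation,
    boundary_distinctiveness,
    iaa,
    match_spans,
    prf,
    span_distinctiveness,
    tokenize,
)
from volspan.metrics import CorpusMatches, MatchResult, _prf_point

from conftest import random_span_set

GP = Category.GLOBAL_PRESENT
HA = Category.HIPPO_ABSENT


def brute_force_tp(gold, pred, mode):
    """Independent oracle: enumerate one-to-one matchings, maximise TP."""
    gold = sorted(gold)
    pred = sorted(pred)

    def compatible(g, p):
        if g.label != p.label:
            return False
        if mode == "exact":
            return g == p
        return min(g.end_tok, p.end_tok) > max(g.start_tok, p.start_tok)

    @lru_cache(maxsize=None)
    def best(gi, used_mask):
        if gi == len(gold):
            return 0
        # skip gold gi
        score = best(gi + 1, used_mask)
        for pi in range(len(pred)):
            if not used_mask & (1 << pi) and compatible(gold[gi], pred[pi]):
                score = max(score, 1 + best(gi + 1, used_mask | (1 << pi)))
        return score

    result = best(0, 0)
    best.cache_clear()
    return result


def total_counts(m: MatchResult):
    return (
        sum(m.tp.values()),
        sum(m.fp.values()),
        sum(m.fn.values()),
    )


class TestMatchSpans:
    def test_identity_matches_in_both_modes(self):
        spans = {SpanAnnotation(2, 7, HA)}
        for mode in ("exact", "relaxed"):
            m = match_spans(spans, set(spans), mode)
            assert m.tp[HA] == 1 and m.fp[HA] == 0 and m.fn[HA] == 0

    def test_shifted_span_relaxed_only(self):
        gold = {SpanAnnotation(2, 7, HA)}
        pred = {SpanAnnotation(3, 8, HA)}
        exact = match_spans(gold, pred, "exact")
        assert (exact.tp[HA], exact.fp[HA], exact.fn[HA]) == (0, 1, 1)
        relaxed = match_spans(gold, pred, "relaxed")
        assert (relaxed.tp[HA], relaxed.fp[HA], relaxed.fn[HA]) == (1, 0, 0)

    def test_split_prediction_matches_once(self):
        gold = {SpanAnnotation(0, 4, GP)}
        pred = {SpanAnnotation(0, 2, GP), SpanAnnotation(2, 4, GP)}
        m = match_spans(gold, pred, "relaxed")
        assert (m.tp[GP], m.fp[GP], m.fn[GP]) == (1, 1, 0)
        assert brute_force_tp(gold, pred, "relaxed") == 1

    def test_label_mismatch_never_matches(self):
        gold = {SpanAnnotation(0, 4, GP)}
        pred = {SpanAnnotation(0, 4, HA)}
        for mode in ("exact", "relaxed"):
            m = match_spans(gold, pred, mode)
            assert m.tp[GP] == 0 and m.fp[HA] == 1 and m.fn[GP] == 1

    def test_nested_same_label_reaches_maximum(self):
        """The greedy order alone would under-match this nested instance;
        augmentation recovers the maximum one-to-one matching."""
        gold = {SpanAnnotation(2, 4, GP), SpanAnnotation(0, 4, GP)}
        pred = {SpanAnnotation(0, 4, GP), SpanAnnotation(0, 2, GP)}
        m = match_spans(gold, pred, "relaxed")
        assert m.tp[GP] == 2 == brute_force_tp(gold, pred, "relaxed")

    @pytest.mark.parametrize("mode", ["exact", "relaxed"])
    def test_agrees_with_brute_force_oracle(self, mode):
        rng = np.random.default_rng(42)
        for _ in range(1200):
            gold = random_span_set(rng, n_tokens=12, max_spans=8)
            pred = random_span_set(rng, n_tokens=12, max_spans=8)
            m = match_spans(gold, pred, mode)
            assert sum(m.tp.values()) == brute_force_tp(gold, pred, mode)

    def test_relaxed_dominates_exact(self):
        """Exact matches are relaxed matches, so relaxed TP >= exact TP and
        relaxed F1 >= exact F1 on every instance."""
        rng = np.random.default_rng(7)
        for _ in range(500):
            gold = random_span_set(rng, n_tokens=10, max_spans=6)
            pred = random_span_set(rng, n_tokens=10, max_spans=6)
            ex = total_counts(match_spans(gold, pred, "exact"))
            rel = total_counts(match_spans(gold, pred, "relaxed"))
            assert rel[0] >= ex[0]
            assert _prf_point(*rel)[2] >= _prf_point(*ex)[2]

    def test_invalid_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            match_spans(set(), set(), "fuzzy")


def _matches_from_counts(counts_per_report, category=GP, mode="relaxed"):
    """Build CorpusMatches from explicit per-report (tp, fp, fn) triples."""
    by_report = {}
    for i, (tp, fp, fn) in enumerate(counts_per_report):
        by_report[f"r{i}"] = MatchResult(
            mode,
            {c: (tp if c is category else 0) for c in Category},
            {c: (fp if c is category else 0) for c in Category},
            {c: (fn if c is category else 0) for c in Category},
        )
    return CorpusMatches(mode, by_report)


class TestPRF:
    def test_closed_form_point_estimates(self):
        report = prf(_matches_from_counts([(2, 1, 1)]), n_boot=10, seed=0)
        m = report.per_category[GP]
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(2 / 3)

    def test_vacuous_category_scores_one(self):
        report = prf(_matches_from_counts([(1, 0, 0)]), n_boot=10, seed=0)
        m = report.per_category[HA]  # no golds, no predictions
        assert m.precision == m.recall == m.f1 == 1.0

    def test_zero_denominator_with_misses_scores_zero(self):
        report = prf(_matches_from_counts([(0, 0, 3)]), n_boot=10, seed=0)
        m = report.per_category[GP]
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0

    def test_single_report_ci_collapses(self):
        report = prf(_matches_from_counts([(3, 1, 2)]), n_boot=50, seed=0)
        m = report.per_category[GP]
        assert m.precision_ci == (m.precision, m.precision)
        assert m.recall_ci == (m.recall, m.recall)

    def test_bounds_and_tp_iff_positive_f1(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tp, fp, fn = (int(rng.integers(0, 5)) for _ in range(3))
            p, r, f = _prf_point(tp, fp, fn)
            assert 0.0 <= p <= 1.0 and 0.0 <= r <= 1.0 and 0.0 <= f <= 1.0
            assert f <= (p + r) / 2 + 1e-12
            if tp > 0:
                assert f > 0
            elif fp + fn > 0:
                assert f == 0

    def test_ci_brackets_point_estimate(self):
        counts = [(2, 1, 0), (1, 0, 1), (3, 1, 1), (0, 1, 2), (2, 0, 0)]
        report = prf(_matches_from_counts(counts), n_boot=500, seed=1)
        m = report.per_category[GP]
        assert m.precision_ci[0] <= m.precision <= m.precision_ci[1]
        assert m.recall_ci[0] <= m.recall <= m.recall_ci[1]

    def test_n_boot_validation(self):
        with pytest.raises(ValueError, match="n_boot"):
            prf(_matches_from_counts([(1, 0, 0)]), n_boot=0)

    def test_bootstrap_coverage_on_known_truth(self):
        """Percentile-bootstrap 95% CIs for recall cover the true value at
        roughly nominal rate on a benchmark where recall is known by
        construction (each report has one gold span, recovered w.p. 0.85)."""
        rng = np.random.default_rng(12345)
        true_r = 0.85
        n_reports, n_trials = 80, 400
        covered = 0
        for _ in range(n_trials):
            hits = rng.random(n_reports) < true_r
            counts = [(1, 0, 0) if h else (0, 1, 1) for h in hits]
            report = prf(
                _matches_from_counts(counts), n_boot=400, seed=int(rng.integers(2**31))
            )
            lo, hi = report.per_category[GP].recall_ci
            covered += lo <= true_r <= hi
        assert 0.90 <= covered / n_trials <= 0.99


class TestIAA:
    def _annotations(self, rng, n_reports=15):
        a = {f"r{i}": random_span_set(rng, 10, 5) for i in range(n_reports)}
        b = {f"r{i}": random_span_set(rng, 10, 5) for i in range(n_reports)}
        return a, b

    def test_identical_annotators_agree_perfectly(self):
        rng = np.random.default_rng(1)
        a, _ = self._annotations(rng)
        for mode in ("exact", "relaxed"):
            assert iaa(a, {k: set(v) for k, v in a.items()}, mode, n_boot=10).f1 == 1.0

    def test_disjoint_spans_score_zero(self):
        a = {"r0": {SpanAnnotation(0, 2, GP)}}
        b = {"r0": {SpanAnnotation(5, 7, GP)}}
        assert iaa(a, b, "relaxed", n_boot=10).f1 == 0.0

    @pytest.mark.parametrize("mode", ["exact", "relaxed"])
    def test_symmetry(self, mode):
        rng = np.random.default_rng(2)
        for _ in range(60):
            a, b = self._annotations(rng, n_reports=6)
            assert iaa(a, b, mode, n_boot=10).f1 == iaa(b, a, mode, n_boot=10).f1

    def test_mismatched_report_sets_rejected(self):
        a = {"r0": set()}
        b = {"r1": set()}
        with pytest.raises(ValueError, match="different report sets"):
            iaa(a, b)


def _corpus_from_tokens(token_lists, span_sets):
    reports = []
    for i, (toks, spans) in enumerate(zip(token_lists, span_sets)):
        text = " ".join(toks)
        reports.append(Report(f"r{i}", text, tokenize(text), {"gold": spans}))
    return AnnotatedCorpus(reports)


class TestDistinctiveness:
    def test_identical_distributions_give_zero(self):
        # spans cover the whole corpus: P == Q
        corpus = _corpus_from_tokens(
            [["a", "b", "a", "b"]], [{SpanAnnotation(0, 4, GP)}]
        )
        assert span_distinctiveness(corpus, GP) == pytest.approx(0.0, abs=1e-12)

    def test_two_token_closed_form(self):
        # corpus [a, a, b, b], spans exactly the two a's: KL = ln 2
        corpus = _corpus_from_tokens(
            [["a", "a", "b", "b"]],
            [{SpanAnnotation(0, 1, GP), SpanAnnotation(1, 2, GP)}],
        )
        assert span_distinctiveness(corpus, GP) == pytest.approx(math.log(2), abs=1e-12)

    def test_boundary_equals_span_for_length_one_spans(self):
        corpus = _corpus_from_tokens(
            [["x", "y", "z", "y"]],
            [{SpanAnnotation(0, 1, HA), SpanAnnotation(2, 3, HA)}],
        )
        assert boundary_distinctiveness(corpus, HA) == pytest.approx(
            span_distinctiveness(corpus, HA), abs=1e-15
        )

    def test_exclusive_boundary_token_is_positive(self):
        # every span starts with "no" and "no" occurs only there
        corpus = _corpus_from_tokens(
            [["no", "atrophy", "seen", "brain", "normal"]],
            [{SpanAnnotation(0, 2, HA)}],
        )
        assert boundary_distinctiveness(corpus, HA) > 0.0
        assert span_distinctiveness(corpus, HA) > 0.0

    def test_disjoint_distractor_never_decreases_divergence(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(3, 8))
            toks = [str(rng.integers(0, 4)) for _ in range(n)]
            spans = {SpanAnnotation(0, int(rng.integers(1, n)), GP)}
            base = _corpus_from_tokens([toks], [spans])
            d0 = span_distinctiveness(base, GP)
            padded = _corpus_from_tokens(
                [toks, ["zz", "ww", "vv"]], [spans, set()]
            )
            d1 = span_distinctiveness(padded, GP)
            assert d1 >= d0 - 1e-12

    def test_no_spans_is_an_error(self):
        corpus = _corpus_from_tokens([["a", "b"]], [set()])
        with pytest.raises(ValueError, match="no GLOBAL_PRESENT spans"):
            span_distinctiveness(corpus, GP)
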