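"""Span-level evaluation: exact/relaxed matching, P/R/F1 with bootstrap CIs,
pairwise inter-annotator agreement, and KL-divergence span distinctiveness.

Two match definitions are supported.  An *exact* match requires a predicted
span to share label, start token and end token with a gold span.  A *relaxed*
match requires the label plus at least one overlapping token.  Matching is
one-to-one per category: candidate pairs are ranked greedily by overlap
length (descending), then gold and predicted start position, and the greedy
assignment is then improved with deterministic augmenting paths so the
reported TP count is the maximum one-to-one matching cardinality.

Distinctiveness statistics quantify how stereotyped a category's vocabulary
is: the Kullback-Leibler divergence (natural log, nats) between the unigram
token distribution inside the category's gold spans (or of their boundary
tokens) and the whole-corpus token distribution.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .corpus import AnnotatedCorpus, Category, SpanAnnotation

__all__ = [
    "MatchResult",
    "CorpusMatches",
    "CategoryMetrics",
    "PRFReport",
    "match_spans",
    "match_corpus",
    "prf",
    "iaa",
    "span_distinctiveness",
    "boundary_distinctiveness",
    "distinctiveness_report",
]

MODES = ("exact", "relaxed")


def _overlap(a: SpanAnnotation, b: SpanAnnotation) -> int:
    return max(0, min(a.end_tok, b.end_tok) - max(a.start_tok, b.start_tok))


@dataclass
class MatchResult:
    """One-to-one span matching outcome for a single report."""

    mode: str
    tp: dict[Category, int]
    fp: dict[Category, int]
    fn: dict[Category, int]
    pairs: list[tuple[SpanAnnotation, SpanAnnotation]] = field(default_factory=list)

    def counts(self, category: Category) -> tuple[int, int, int]:
        return self.tp[category], self.fp[category], self.fn[category]


def _max_matching(
    golds: list[SpanAnnotation], preds: list[SpanAnnotation]
) -> list[tuple[int, int]]:
    """Maximum one-to-one matching between overlapping gold/pred spans.

    Greedy initialisation in the order (overlap desc, gold start asc, gold
    end asc, pred start asc, pred end asc), then deterministic augmenting
    paths, so the result is a maximum-cardinality matching with greedy
    tie-breaking.
    """
    cand = [
        (gi, pi)
        for gi, g in enumerate(golds)
        for pi, p in enumerate(preds)
        if _overlap(g, p) > 0
    ]
    cand.sort(
        key=lambda gp: (
            -_overlap(golds[gp[0]], preds[gp[1]]),
            golds[gp[0]].start_tok,
            golds[gp[0]].end_tok,
            preds[gp[1]].start_tok,
            preds[gp[1]].end_tok,
        )
    )
    gold_to_pred: dict[int, int] = {}
    pred_to_gold: dict[int, int] = {}
    for gi, pi in cand:
        if gi not in gold_to_pred and pi not in pred_to_gold:
            gold_to_pred[gi] = pi
            pred_to_gold[pi] = gi

    # augmenting paths over the overlap graph (Hungarian-style DFS)
    adj: dict[int, list[int]] = {}
    for gi, pi in cand:
        adj.setdefault(gi, []).append(pi)

    def try_augment(gi: int, visited: set[int]) -> bool:
        for pi in adj.get(gi, ()):
            if pi in visited:
                continue
            visited.add(pi)
            if pi not in pred_to_gold or try_augment(pred_to_gold[pi], visited):
                gold_to_pred[gi] = pi
                pred_to_gold[pi] = gi
                return True
        return False

    for gi in range(len(golds)):
        if gi not in gold_to_pred:
            try_augment(gi, set())
    return sorted(gold_to_pred.items())


def match_spans(
    gold: set[SpanAnnotation], pred: set[SpanAnnotation], mode: str = "relaxed"
) -> MatchResult:
    """Match predicted against gold spans one-to-one within each category.

    ``mode="exact"`` matches identical (start, end, label) triples;
    ``mode="relaxed"`` matches same-label spans overlapping by >= 1 token.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    tp = {c: 0 for c in Category}
    fp = {c: 0 for c in Category}
    fn = {c: 0 for c in Category}
    pairs: list[tuple[SpanAnnotation, SpanAnnotation]] = []
    for cat in Category:
        g = sorted(s for s in gold if s.label == cat)
        p = sorted(s for s in pred if s.label == cat)
        if mode == "exact":
            matched = set(g) & set(p)
            tp[cat] = len(matched)
            pairs.extend((s, s) for s in sorted(matched))
        else:
            matching = _max_matching(g, p)
            tp[cat] = len(matching)
            pairs.extend((g[gi], p[pi]) for gi, pi in matching)
        fp[cat] = len(p) - tp[cat]
        fn[cat] = len(g) - tp[cat]
    return MatchResult(mode, tp, fp, fn, pairs)


@dataclass
class CorpusMatches:
    """Report-indexed match results, retaining per-report counts for resampling."""

    mode: str
    by_report: dict[str, MatchResult]

    def count_array(self) -> np.ndarray:
        """(n_reports, n_categories, 3) array of TP/FP/FN counts."""
        cats = list(Category)
        arr = np.zeros((len(self.by_report), len(cats), 3), dtype=np.int64)
        for i, m in enumerate(self.by_report.values()):
            for j, c in enumerate(cats):
                arr[i, j] = m.counts(c)
        return arr


def match_corpus(
    corpus: AnnotatedCorpus,
    gold_source: str,
    pred_source: str,
    mode: str = "relaxed",
) -> CorpusMatches:
    """Run :func:`match_spans` over every report of a corpus."""
    by_report = {
        r.report_id: match_spans(r.spans(gold_source), r.spans(pred_source), mode)
        for r in corpus
    }
    return CorpusMatches(mode, by_report)


def _prf_point(tp: float, fp: float, fn: float) -> tuple[float, float, float]:
    # 0/0 convention: vacuous success (nothing to find, nothing predicted) is
    # perfect; a zero denominator with errors on the other side is 0.
    if tp + fp == 0:
        p = 1.0 if fn == 0 else 0.0
    else:
        p = tp / (tp + fp)
    if tp + fn == 0:
        r = 1.0 if fp == 0 else 0.0
    else:
        r = tp / (tp + fn)
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f


@dataclass
class CategoryMetrics:
    """Point estimates and 95% bootstrap CIs for one category (or pooled)."""

    precision: float
    recall: float
    f1: float
    precision_ci: tuple[float, float]
    recall_ci: tuple[float, float]
    f1_ci: tuple[float, float]
    n_gold: int
    n_pred: int

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "precision_ci": list(self.precision_ci),
            "recall_ci": list(self.recall_ci),
            "f1_ci": list(self.f1_ci),
            "n_gold": self.n_gold,
            "n_pred": self.n_pred,
        }


@dataclass
class PRFReport:
    """Per-category and pooled precision/recall/F1 with bootstrap CIs."""

    per_category: dict[Category, CategoryMetrics]
    micro: CategoryMetrics
    macro: CategoryMetrics
    mode: str
    n_boot: int

    def to_frame(self):
        import pandas as pd

        rows = {c.value: m.as_dict() for c, m in self.per_category.items()}
        rows["micro_average"] = self.micro.as_dict()
        rows["macro_average"] = self.macro.as_dict()
        return pd.DataFrame.from_dict(rows, orient="index")

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "per_category": {c.value: m.as_dict() for c, m in self.per_category.items()},
            "micro_average": self.micro.as_dict(),
            "macro_average": self.macro.as_dict(),
        }


def _bootstrap_cis(
    counts: np.ndarray, n_boot: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percentile-bootstrap 2.5/97.5 bounds for P, R, F1.

    ``counts`` is (n_reports, n_series, 3); reports are resampled with
    replacement, and P/R/F1 recomputed from pooled counts per resample.
    Returns three (n_series, 2) arrays.
    """
    n = counts.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = counts[idx].sum(axis=1).astype(float)  # (n_boot, n_series, 3)
    tp, fp, fn = boot[..., 0], boot[..., 1], boot[..., 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), np.where(fn == 0, 1.0, 0.0))
        r = np.where(tp + fn > 0, tp / np.maximum(tp + fn, 1), np.where(fp == 0, 1.0, 0.0))
        f = np.where(p + r > 0, 2 * p * r / np.maximum(p + r, 1e-300), 0.0)
    lo, hi = 2.5, 97.5
    return (
        np.percentile(p, [lo, hi], axis=0).T,
        np.percentile(r, [lo, hi], axis=0).T,
        np.percentile(f, [lo, hi], axis=0).T,
    )


def prf(matches: CorpusMatches, n_boot: int = 1000, seed: int = 0) -> PRFReport:
    """Micro point estimates from pooled counts plus percentile-bootstrap CIs.

    The pooled ("micro") score sums TP/FP/FN over all six categories; the
    macro score averages the per-category P, R and F1.  CIs resample reports
    with replacement (``n_boot`` resamples, seeded).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    cats = list(Category)
    counts = matches.count_array()  # (n_reports, 6, 3)
    pooled = counts.sum(axis=0)

    # series = 6 categories + micro pool
    series = np.concatenate([counts, counts.sum(axis=1, keepdims=True)], axis=1)
    p_ci, r_ci, f_ci = _bootstrap_cis(series, n_boot, seed)

    per_category: dict[Category, CategoryMetrics] = {}
    for j, cat in enumerate(cats):
        tp, fp, fn = pooled[j]
        p, r, f = _prf_point(tp, fp, fn)
        per_category[cat] = CategoryMetrics(
            p, r, f, tuple(p_ci[j]), tuple(r_ci[j]), tuple(f_ci[j]),
            n_gold=int(tp + fn), n_pred=int(tp + fp),
        )
    tp, fp, fn = pooled.sum(axis=0)
    p, r, f = _prf_point(tp, fp, fn)
    micro = CategoryMetrics(
        p, r, f, tuple(p_ci[-1]), tuple(r_ci[-1]), tuple(f_ci[-1]),
        n_gold=int(tp + fn), n_pred=int(tp + fp),
    )
    macro_p = float(np.mean([m.precision for m in per_category.values()]))
    macro_r = float(np.mean([m.recall for m in per_category.values()]))
    macro_f = float(np.mean([m.f1 for m in per_category.values()]))
    macro = CategoryMetrics(
        macro_p, macro_r, macro_f, (math.nan, math.nan), (math.nan, math.nan),
        (math.nan, math.nan), n_gold=micro.n_gold, n_pred=micro.n_pred,
    )
    return PRFReport(per_category, micro, macro, matches.mode, n_boot)


def iaa(
    a: dict[str, set[SpanAnnotation]],
    b: dict[str, set[SpanAnnotation]],
    mode: str = "exact",
    n_boot: int = 1000,
    seed: int = 0,
) -> CategoryMetrics:
    """Inter-annotator agreement as pooled F1, treating annotator ``a`` as gold.

    Because F1 is symmetric in precision and recall, ``iaa(a, b)`` equals
    ``iaa(b, a)``.  Both annotators must cover exactly the same reports.
    """
    if set(a) != set(b):
        raise ValueError("annotators cover different report sets")
    if not a:
        raise ValueError("no reports to compare")
    by_report = {rid: match_spans(a[rid], b[rid], mode) for rid in sorted(a)}
    report = prf(CorpusMatches(mode, by_report), n_boot=n_boot, seed=seed)
    return report.micro


def _token_distributions(
    corpus: AnnotatedCorpus, category: Category, source: str, boundary_only: bool
) -> tuple[Counter, Counter]:
    span_counts: Counter = Counter()
    corpus_counts: Counter = Counter()
    n_spans = 0
    for r in corpus:
        texts = [t.text.lower() for t in r.tokens]
        corpus_counts.update(texts)
        for span in r.annotation_sets.get(source, set()):
            if span.label != category:
                continue
            n_spans += 1
            if boundary_only:
                if len(span) == 1:
                    span_counts[texts[span.start_tok]] += 1
                else:
                    span_counts[texts[span.start_tok]] += 1
                    span_counts[texts[span.end_tok - 1]] += 1
            else:
                span_counts.update(texts[span.start_tok : span.end_tok])
    if n_spans == 0:
        raise ValueError(f"no {category.value} spans in annotation set {source!r}")
    return span_counts, corpus_counts


def _kl(span_counts: Counter, corpus_counts: Counter) -> float:
    p_total = sum(span_counts.values())
    q_total = sum(corpus_counts.values())
    d = 0.0
    for tok, c in span_counts.items():
        p = c / p_total
        q = corpus_counts[tok] / q_total  # q > 0: span tokens are corpus tokens
        d += p * math.log(p / q)
    return max(d, 0.0)  # clamp -0.0 from rounding when distributions coincide


def span_distinctiveness(
    corpus: AnnotatedCorpus, category: Category, source: str = "gold"
) -> float:
    """KL divergence (nats) of the category's in-span unigram distribution
    against the whole-corpus distribution.  High values indicate stereotyped
    span vocabulary; 0 iff the distributions coincide."""
    return _kl(*_token_distributions(corpus, category, source, boundary_only=False))


def boundary_distinctiveness(
    corpus: AnnotatedCorpus, category: Category, source: str = "gold"
) -> float:
    """As :func:`span_distinctiveness` but over span boundary tokens only
    (first and last token of each span; a length-1 span counts once)."""
    return _kl(*_token_distributions(corpus, category, source, boundary_only=True))


def distinctiveness_report(corpus: AnnotatedCorpus, source: str = "gold"):
    """Per-category average span length, span and boundary distinctiveness,
    with a span-count-weighted average row."""
    import pandas as pd

    rows = {}
    counts = {}
    for cat in Category:
        lengths = [
            len(s)
            for r in corpus
            for s in r.annotation_sets.get(source, set())
            if s.label == cat
        ]
        if not lengths:
            continue
        counts[cat] = len(lengths)
        rows[cat.value] = {
            "avg_span_length": float(np.mean(lengths)),
            "span_distinctiveness": span_distinctiveness(corpus, cat, source),
            "boundary_distinctiveness": boundary_distinctiveness(corpus, cat, source),
            "n_spans": len(lengths),
        }
    if rows:
        total = sum(counts.values())
        rows["weighted_average"] = {
            key: sum(rows[c.value][key] * n for c, n in counts.items()) / total
            for key in ("avg_span_length", "span_distinctiveness", "boundary_distinctiveness")
        } | {"n_spans": total}
    return pd.DataFrame.from_dict(rows, orient="index")
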