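"""Trainable span categoriser: n-gram candidate suggester plus a
per-candidate multilabel classifier, with corpus splitting and k-fold
cross-validation.

The modelling surface follows the Model / Results convention: a
:class:`SpanCategorizer` is constructed from an annotated corpus, its
:meth:`~SpanCategorizer.fit` returns a :class:`SpanCategorizerResults`
carrying the fitted weights, training diagnostics and a ``summary()`` table,
and prediction, evaluation and serialisation hang off the results object.

The suggester enumerates every contiguous token interval up to
``max_span_len`` tokens (default 25, above the longest annotated span of 22,
so every gold span is a candidate and perfect recall is attainable).  The
labeller scores each candidate independently for each of the six categories
with a regularised logistic model over sparse lexical features — span token
bag, first/last span token, three tokens of context either side, and a span
length bucket — and emits every candidate whose per-category probability
reaches that category's threshold.  Overlapping and nested predictions are
therefore possible by construction, which is the point of span
categorisation as opposed to NER.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression

from .corpus import AnnotatedCorpus, Category, Report, SpanAnnotation, Token
from .metrics import PRFReport, match_corpus, prf

__all__ = [
    "SuggesterConfig",
    "suggest_spans",
    "split_corpus",
    "SpanCategorizer",
    "SpanCategorizerResults",
    "kfold_evaluate",
    "TrainReport",
]

GOLD = "gold"

_LEN_BUCKETS = (1, 2, 3, 4, 5, 6, 7, 10, 15)


@dataclass(frozen=True)
class SuggesterConfig:
    """Candidate suggester settings.  ``max_span_len`` defaults to 25 tokens,
    leaving headroom over the longest observed annotation (22)."""

    max_span_len: int = 25

    def __post_init__(self) -> None:
        if self.max_span_len < 1:
            raise ValueError("max_span_len must be >= 1")


def suggest_spans(
    tokens: list[Token], cfg: SuggesterConfig | None = None
) -> list[tuple[int, int]]:
    """All contiguous intervals of 1..max_span_len tokens, ordered by (start, end)."""
    cfg = cfg or SuggesterConfig()
    n = len(tokens)
    return [
        (start, end)
        for start in range(n)
        for end in range(start + 1, min(start + cfg.max_span_len, n) + 1)
    ]


def split_corpus(
    corpus: AnnotatedCorpus, dev_fraction: float, seed: int = 0
) -> tuple[AnnotatedCorpus, AnnotatedCorpus]:
    """Seeded development/holdout split.

    The development size is ``round(n * dev_fraction)`` (half away from
    zero), so a 4007-report corpus at 0.8 yields 3206 development and 801
    holdout reports.
    """
    if not 0.0 < dev_fraction < 1.0:
        raise ValueError("dev_fraction must lie strictly between 0 and 1")
    n = len(corpus)
    if n < 2:
        raise ValueError("need at least 2 reports to split")
    n_dev = int(np.floor(n * dev_fraction + 0.5))
    order = np.random.default_rng(seed).permutation(n)
    dev_ids = {corpus.reports[i].report_id for i in order[:n_dev]}
    dev = AnnotatedCorpus([r for r in corpus if r.report_id in dev_ids])
    holdout = AnnotatedCorpus([r for r in corpus if r.report_id not in dev_ids])
    return dev, holdout


def _bucket(length: int) -> int:
    for i, b in enumerate(_LEN_BUCKETS):
        if length <= b:
            return i
    return len(_LEN_BUCKETS)


def _candidate_features(
    texts: list[str], start: int, end: int
) -> list[str]:
    """Sparse lexical features of one candidate span."""
    feats = [f"bag={t}" for t in set(texts[start:end])]
    feats.append(f"first={texts[start]}")
    feats.append(f"last={texts[end - 1]}")
    for k in range(1, 4):
        feats.append(f"left{k}={texts[start - k] if start - k >= 0 else '<s>'}")
        feats.append(f"right{k}={texts[end + k - 1] if end + k - 1 < len(texts) else '</s>'}")
    feats.append(f"len={_bucket(end - start)}")
    return feats


class SpanCategorizer:
    """Span-categorisation model over an annotated corpus.

    Parameters
    ----------
    corpus : training corpus with gold spans in annotation set ``source``.
    source : name of the gold annotation set (default ``"gold"``).
    suggester : candidate enumeration settings.
    C : inverse L2 regularisation strength of the per-category logistic
        labeller.
    threshold : per-category decision threshold on the predicted probability
        (scalar applied to all categories, or a per-category mapping).
    class_weight : passed to the logistic fit.  ``None`` keeps the natural
        candidate/positive imbalance so probabilities stay calibrated;
        ``"balanced"`` reweights classes and trades precision for recall.
    tol : optimiser stopping tolerance.  Exhaustive suggestion yields millions
        of overwhelmingly negative candidates, so a loose tolerance stops
        before the rare positives are fitted; the tight default matters.
    """

    def __init__(
        self,
        corpus: AnnotatedCorpus,
        source: str = GOLD,
        suggester: SuggesterConfig | None = None,
        C: float = 1.0,
        threshold: float | dict[Category, float] = 0.5,
        class_weight: str | None = None,
        tol: float = 1e-8,
    ) -> None:
        self.corpus = corpus
        self.source = source
        self.suggester = suggester or SuggesterConfig()
        self.C = C
        self.class_weight = class_weight
        self.tol = tol
        if isinstance(threshold, dict):
            self.thresholds = {c: float(threshold.get(c, 0.5)) for c in Category}
        else:
            self.thresholds = {c: float(threshold) for c in Category}

    @classmethod
    def from_corpus(cls, corpus: AnnotatedCorpus, **kwargs) -> "SpanCategorizer":
        return cls(corpus, **kwargs)

    def _design_matrix(
        self, corpus: AnnotatedCorpus, vocab: dict[str, int], grow: bool
    ) -> tuple[sp.csr_matrix, list[tuple[str, int, int]]]:
        """Feature matrix over all candidates of all reports.

        Returns the matrix and the candidate index (report_id, start, end).
        With ``grow`` the vocabulary is extended; otherwise unseen features
        are dropped.
        """
        indptr = [0]
        indices: list[int] = []
        cand_index: list[tuple[str, int, int]] = []
        for report in corpus:
            texts = [t.text.lower() for t in report.tokens]
            for start, end in suggest_spans(report.tokens, self.suggester):
                cols = set()
                for feat in _candidate_features(texts, start, end):
                    col = vocab.get(feat)
                    if col is None and grow:
                        col = vocab[feat] = len(vocab)
                    if col is not None:
                        cols.add(col)
                indices.extend(sorted(cols))
                indptr.append(len(indices))
                cand_index.append((report.report_id, start, end))
        n_cols = max(len(vocab), 1)
        X = sp.csr_matrix(
            (
                np.ones(len(indices), dtype=np.float64),
                np.asarray(indices, dtype=np.int64),
                np.asarray(indptr, dtype=np.int64),
            ),
            shape=(len(cand_index), n_cols),
        )
        return X, cand_index

    def fit(self, seed: int = 0) -> "SpanCategorizerResults":
        """Fit one logistic labeller per category.

        Candidates exactly matching a gold span are positives for that label;
        every other candidate is a negative.  A category without a single
        positive in the corpus is excluded from the model with a warning and
        recorded in the results.
        """
        vocab: dict[str, int] = {}
        X, cand_index = self._design_matrix(self.corpus, vocab, grow=True)

        gold_lookup: dict[tuple[str, int, int], set[Category]] = {}
        for report in self.corpus:
            for span in report.spans(self.source):
                gold_lookup.setdefault(
                    (report.report_id, span.start_tok, span.end_tok), set()
                ).add(span.label)

        weights: dict[Category, tuple[np.ndarray, float]] = {}
        n_positive: dict[Category, int] = {}
        excluded: list[Category] = []
        for cat in Category:
            y = np.fromiter(
                (cat in gold_lookup.get(key, ()) for key in cand_index),
                dtype=np.int8,
                count=len(cand_index),
            )
            n_pos = int(y.sum())
            n_positive[cat] = n_pos
            if n_pos == 0:
                warnings.warn(
                    f"category {cat.value} has no positive spans; excluded from model",
                    stacklevel=2,
                )
                excluded.append(cat)
                continue
            clf = LogisticRegression(
                C=self.C,
                solver="lbfgs",
                class_weight=self.class_weight,
                random_state=seed,
                max_iter=5000,
                tol=self.tol,
            )
            clf.fit(X, y)
            weights[cat] = (clf.coef_[0].copy(), float(clf.intercept_[0]))
        return SpanCategorizerResults(
            vocab=vocab,
            weights=weights,
            thresholds=dict(self.thresholds),
            suggester=self.suggester,
            n_positive=n_positive,
            excluded=excluded,
            config={
                "C": self.C,
                "class_weight": self.class_weight,
                "tol": self.tol,
                "source": self.source,
                "seed": seed,
                "n_train_reports": len(self.corpus),
            },
        )


@dataclass
class SpanCategorizerResults:
    """Fitted span categoriser: weights, thresholds and diagnostics.

    ``predict`` is a pure function of (results, report); saving and reloading
    reproduces predictions exactly.
    """

    vocab: dict[str, int]
    weights: dict[Category, tuple[np.ndarray, float]]
    thresholds: dict[Category, float]
    suggester: SuggesterConfig
    n_positive: dict[Category, int]
    excluded: list[Category]
    config: dict = field(default_factory=dict)

    FORMAT_VERSION = 1

    def predict_scored(self, report: Report) -> list[tuple[SpanAnnotation, float]]:
        """Score all candidates; return spans whose probability meets the
        category threshold, with their probabilities."""
        if not self.weights:
            raise ValueError("model has no fitted categories")
        texts = [t.text.lower() for t in report.tokens]
        cands = suggest_spans(report.tokens, self.suggester)
        if not cands:
            return []
        indptr = [0]
        indices: list[int] = []
        for start, end in cands:
            cols = {
                self.vocab[f]
                for f in _candidate_features(texts, start, end)
                if f in self.vocab
            }
            indices.extend(sorted(cols))
            indptr.append(len(indices))
        X = sp.csr_matrix(
            (
                np.ones(len(indices), dtype=np.float64),
                np.asarray(indices, dtype=np.int64),
                np.asarray(indptr, dtype=np.int64),
            ),
            shape=(len(cands), len(self.vocab)),
        )
        out: list[tuple[SpanAnnotation, float]] = []
        for cat, (coef, intercept) in self.weights.items():
            z = X @ coef + intercept
            probs = 1.0 / (1.0 + np.exp(-z))
            thr = self.thresholds[cat]
            for k in np.nonzero(probs >= thr)[0]:
                start, end = cands[k]
                out.append((SpanAnnotation(start, end, cat), float(probs[k])))
        out.sort(key=lambda sp_: (sp_[0].start_tok, sp_[0].end_tok, sp_[0].label.value))
        return out

    def predict(self, report: Report) -> set[SpanAnnotation]:
        return {span for span, _ in self.predict_scored(report)}

    def annotate_corpus(
        self, corpus: AnnotatedCorpus, target_source: str = "predicted"
    ) -> AnnotatedCorpus:
        """Return a copy of the corpus with predictions stored as a new
        annotation set."""
        out_reports = []
        for r in corpus:
            sets = dict(r.annotation_sets)
            sets[target_source] = self.predict(r)
            out_reports.append(Report(r.report_id, r.text, r.tokens, sets))
        return AnnotatedCorpus(out_reports)

    def evaluate(
        self,
        corpus: AnnotatedCorpus,
        gold_source: str = GOLD,
        mode: str = "relaxed",
        n_boot: int = 1000,
        seed: int = 0,
    ) -> PRFReport:
        """Predict over a corpus and score against its gold spans."""
        annotated = self.annotate_corpus(corpus)
        matches = match_corpus(annotated, gold_source, "predicted", mode)
        return prf(matches, n_boot=n_boot, seed=seed)

    def summary(self) -> str:
        lines = [
            "Span Categorizer Results",
            "=" * 60,
            f"training reports:    {self.config.get('n_train_reports', '?')}",
            f"features:            {len(self.vocab)}",
            f"max span length:     {self.suggester.max_span_len}",
            f"regularisation C:    {self.config.get('C')}",
            f"class weight:        {self.config.get('class_weight')}",
            "-" * 60,
            f"{'category':<22}{'positives':>10}{'threshold':>11}{'fitted':>8}",
        ]
        for cat in Category:
            fitted = "yes" if cat in self.weights else "no"
            lines.append(
                f"{cat.value:<22}{self.n_positive.get(cat, 0):>10}"
                f"{self.thresholds[cat]:>11.2f}{fitted:>8}"
            )
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        """Serialise to a single versioned JSON file (vocabulary, weights,
        thresholds, config); loading reproduces predictions exactly."""
        payload = {
            "format_version": self.FORMAT_VERSION,
            "vocab": self.vocab,
            "weights": {
                cat.value: {"coef": coef.tolist(), "intercept": intercept}
                for cat, (coef, intercept) in self.weights.items()
            },
            "thresholds": {c.value: t for c, t in self.thresholds.items()},
            "suggester": {"max_span_len": self.suggester.max_span_len},
            "n_positive": {c.value: n for c, n in self.n_positive.items()},
            "excluded": [c.value for c in self.excluded],
            "config": self.config,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | Path) -> "SpanCategorizerResults":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if payload.get("format_version") != cls.FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {payload.get('format_version')!r}"
            )
        return cls(
            vocab=payload["vocab"],
            weights={
                Category(c): (np.asarray(w["coef"], dtype=np.float64), float(w["intercept"]))
                for c, w in payload["weights"].items()
            },
            thresholds={Category(c): float(t) for c, t in payload["thresholds"].items()},
            suggester=SuggesterConfig(**payload["suggester"]),
            n_positive={Category(c): int(n) for c, n in payload["n_positive"].items()},
            excluded=[Category(c) for c in payload["excluded"]],
            config=payload["config"],
        )


@dataclass
class TrainReport:
    """K-fold cross-validation outcome: per-fold metrics plus aggregates."""

    k: int
    seed: int
    mode: str
    fold_reports: list[PRFReport]
    fold_sizes: list[int]
    config: dict

    @property
    def micro_f1_per_fold(self) -> list[float]:
        return [r.micro.f1 for r in self.fold_reports]

    def aggregate(self) -> dict:
        """Mean and sd of P/R/F1 per category and pooled, across folds."""
        out: dict = {}
        for key in [c.value for c in Category] + ["micro_average"]:
            ps, rs, fs = [], [], []
            for rep in self.fold_reports:
                m = rep.micro if key == "micro_average" else rep.per_category[Category(key)]
                ps.append(m.precision)
                rs.append(m.recall)
                fs.append(m.f1)
            out[key] = {
                "precision_mean": float(np.mean(ps)),
                "precision_sd": float(np.std(ps, ddof=1)) if len(ps) > 1 else 0.0,
                "recall_mean": float(np.mean(rs)),
                "recall_sd": float(np.std(rs, ddof=1)) if len(rs) > 1 else 0.0,
                "f1_mean": float(np.mean(fs)),
                "f1_sd": float(np.std(fs, ddof=1)) if len(fs) > 1 else 0.0,
            }
        return out

    def as_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "mode": self.mode,
            "fold_sizes": self.fold_sizes,
            "config": self.config,
            "per_fold": [r.as_dict() for r in self.fold_reports],
            "aggregate": self.aggregate(),
        }


def kfold_evaluate(
    corpus: AnnotatedCorpus,
    k: int = 5,
    seed: int = 0,
    mode: str = "relaxed",
    n_boot: int = 200,
    **model_kwargs,
) -> TrainReport:
    """Seeded k-fold cross-validation of the span categoriser.

    The reports are partitioned into k folds whose sizes differ by at most
    one; each fold is scored by a model trained on the remaining k-1 folds.
    """
    n = len(corpus)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds corpus size {n}")
    order = np.random.default_rng(seed).permutation(n)
    folds = [sorted(order[i::k]) for i in range(k)]
    fold_reports: list[PRFReport] = []
    for fold in folds:
        test_ids = {corpus.reports[i].report_id for i in fold}
        train = AnnotatedCorpus([r for r in corpus if r.report_id not in test_ids])
        test = AnnotatedCorpus([r for r in corpus if r.report_id in test_ids])
        results = SpanCategorizer(train, **model_kwargs).fit(seed=seed)
        fold_reports.append(
            results.evaluate(test, mode=mode, n_boot=n_boot, seed=seed)
        )
    return TrainReport(
        k=k,
        seed=seed,
        mode=mode,
        fold_reports=fold_reports,
        fold_sizes=[len(f) for f in folds],
        config=dict(model_kwargs),
    )
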