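"""Seeded generator of synthetic memory-clinic brain-MRI reports with gold spans.

The generator produces free-text reports statistically shaped like a memory-
clinic radiology corpus: a right-skewed report-length distribution (lognormal,
mean ~68 words, median ~61, clipped to [1, 373]), per-category report
prevalences configurable to the cohort rates, span lengths between 1 and 22
tokens, overlapping/nested negated spans covering several categories in one
sentence ("no lobar, regional, or hippocampal volume loss"), negation distant
from the anatomical term (including in a preceding sentence), and a small
configurable fraction of internally inconsistent reports that carry both a
present and an absent finding for the same base category.

Every report carries a single annotation set named ``"gold"`` whose spans are
defined by the generating template, so the generator doubles as a labelled
training and evaluation corpus.  All randomness flows from one seed; the same
config yields byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import (
    BASE_CATEGORIES,
    PRESENT_ABSENT_PAIRS,
    AnnotatedCorpus,
    Category,
    Report,
    SpanAnnotation,
    tokenize,
)

__all__ = [
    "Template",
    "GeneratorConfig",
    "default_phrase_banks",
    "default_distractor_bank",
    "generate_corpus",
    "inject_inconsistency",
    "corpus_statistics",
    "load_config",
]

GOLD = "gold"

# Default cohort prevalences: fraction of reports containing at least one
# span of each category, set to typical memory-clinic rates.
DEFAULT_PREVALENCE: dict[Category, float] = {
    Category.GLOBAL_PRESENT: 0.462,
    Category.GLOBAL_ABSENT: 0.238,
    Category.REGIONAL_PRESENT: 0.238,
    Category.REGIONAL_ABSENT: 0.401,
    Category.HIPPO_PRESENT: 0.371,
    Category.HIPPO_ABSENT: 0.243,
}


@dataclass(frozen=True)
class Template:
    """A sentence template: token texts (with slot placeholders) plus gold spans.

    Slots (``{severity}``, ``{laterality}``, ``{region}``) are single tokens,
    so span indices are stable under substitution.  ``spans`` are half-open
    token intervals within the template.
    """

    tokens: tuple[str, ...]
    spans: tuple[tuple[int, int, Category], ...]

    def __post_init__(self) -> None:
        for start, end, _ in self.spans:
            if not (0 <= start < end <= len(self.tokens)):
                raise ValueError(f"template span [{start}, {end}) out of range")
            if not 1 <= end - start <= 22:
                raise ValueError("template span length must be within 1..22 tokens")


def _t(text: str, *spans: tuple[int, int, Category]) -> Template:
    return Template(tuple(text.split()), tuple(spans))


_SEVERITIES = ("mild", "moderate", "severe", "marked")
_LATERALITIES = ("left", "right", "bilateral")
_REGIONS = ("frontal", "parietal", "temporal", "occipital", "frontotemporal")

C = Category


def default_phrase_banks() -> dict[Category, tuple[Template, ...]]:
    """Author the per-category sentence templates.

    Gold spans include severity/laterality descriptors but exclude
    age-qualifying language ("... in keeping with the patient's age"),
    mirroring the annotation rule that only the objective phrase is labelled.
    """
    return {
        C.GLOBAL_PRESENT: (
            _t("There is {severity} generalised volume loss .", (2, 6, C.GLOBAL_PRESENT)),
            _t("Global volume loss in keeping with the patient's age .", (0, 3, C.GLOBAL_PRESENT)),
            _t("{severity} diffuse cerebral atrophy is noted .", (0, 4, C.GLOBAL_PRESENT)),
            _t(
                "Generalised widening of the sulci and ventricles in keeping with global volume loss .",
                (0, 13, C.GLOBAL_PRESENT),
            ),
            _t("Appearances suggest {severity} global atrophy .", (2, 5, C.GLOBAL_PRESENT)),
            _t(
                "There is prominence of the sulci consistent with generalised volume loss .",
                (2, 11, C.GLOBAL_PRESENT),
            ),
        ),
        C.GLOBAL_ABSENT: (
            _t("Brain volume is normal .", (0, 4, C.GLOBAL_ABSENT)),
            _t("No generalised volume loss .", (0, 4, C.GLOBAL_ABSENT)),
            _t("Brain volume is normal for the patient's age .", (0, 4, C.GLOBAL_ABSENT)),
            _t("There is no significant global atrophy .", (2, 6, C.GLOBAL_ABSENT)),
            _t("No evidence of generalised cerebral volume loss .", (0, 7, C.GLOBAL_ABSENT)),
            _t("Overall brain volume is preserved .", (0, 5, C.GLOBAL_ABSENT)),
        ),
        C.REGIONAL_PRESENT: (
            _t("There is {severity} {region} volume loss .", (2, 6, C.REGIONAL_PRESENT)),
            _t("{severity} atrophy of the {region} lobes .", (0, 6, C.REGIONAL_PRESENT)),
            _t("Disproportionate {region} volume loss is demonstrated .", (0, 4, C.REGIONAL_PRESENT)),
            _t("There is {laterality} {region} atrophy .", (2, 5, C.REGIONAL_PRESENT)),
            _t("Focal volume loss involving the {region} region .", (0, 7, C.REGIONAL_PRESENT)),
        ),
        C.REGIONAL_ABSENT: (
            _t("No lobar or regional atrophy .", (0, 5, C.REGIONAL_ABSENT)),
            _t("No focal regional volume loss .", (0, 5, C.REGIONAL_ABSENT)),
            _t("There is no lobar volume loss .", (2, 6, C.REGIONAL_ABSENT)),
            _t("No disproportionate regional atrophy is seen .", (0, 4, C.REGIONAL_ABSENT)),
            _t("No significant focal cortical thinning is identified .", (0, 5, C.REGIONAL_ABSENT)),
        ),
        C.HIPPO_PRESENT: (
            _t("There is {severity} {laterality} hippocampal volume loss .", (2, 7, C.HIPPO_PRESENT)),
            _t(
                "{severity} {laterality} hippocampal and medial temporal lobe volume loss .",
                (0, 9, C.HIPPO_PRESENT),
            ),
            _t("The hippocampi appear atrophic .", (1, 4, C.HIPPO_PRESENT)),
            _t("{severity} volume loss of the {laterality} hippocampus .", (0, 7, C.HIPPO_PRESENT)),
            _t("Medial temporal lobe atrophy is evident .", (0, 4, C.HIPPO_PRESENT)),
        ),
        C.HIPPO_ABSENT: (
            _t("The hippocampi are normal in volume .", (1, 6, C.HIPPO_ABSENT)),
            _t("No hippocampal volume loss .", (0, 4, C.HIPPO_ABSENT)),
            _t("No atrophy of the hippocampi or medial temporal lobes .", (0, 9, C.HIPPO_ABSENT)),
            _t("Hippocampal volume is preserved .", (0, 4, C.HIPPO_ABSENT)),
            # negation distant from the anatomical term
            _t(
                "There is no evidence of atrophy involving either hippocampus .",
                (2, 9, C.HIPPO_ABSENT),
            ),
            # negation in the sentence preceding the anatomical mention; the
            # gold span crosses the sentence boundary
            _t(
                "No atrophy is identified . This includes the hippocampi .",
                (0, 9, C.HIPPO_ABSENT),
            ),
        ),
    }


# Sentences realising one negation over several categories at once; spans
# overlap (identical or nested intervals with different labels).
def default_combined_templates() -> tuple[Template, ...]:
    return (
        _t(
            "No lobar , regional , or hippocampal volume loss .",
            (0, 9, C.REGIONAL_ABSENT),
            (0, 9, C.HIPPO_ABSENT),
        ),
        _t(
            "There is no regional or hippocampal atrophy .",
            (2, 7, C.REGIONAL_ABSENT),
            (2, 7, C.HIPPO_ABSENT),
        ),
        _t(
            "No lobar , regional , or hippocampal volume loss is seen .",
            (0, 9, C.REGIONAL_ABSENT),
            (5, 9, C.HIPPO_ABSENT),  # nested within the regional span
        ),
    )


def default_distractor_bank() -> tuple[tuple[str, ...], ...]:
    """Non-volumetric radiology sentences used to pad reports to length."""
    sentences = (
        "No acute infarct or haemorrhage .",
        "The ventricles are of normal calibre .",
        "Scattered foci of white matter signal change , likely small vessel disease .",
        "No mass lesion or extra-axial collection .",
        "The major intracranial vessels demonstrate normal flow voids .",
        "Incidental note is made of a small arachnoid cyst .",
        "No restricted diffusion .",
        "The posterior fossa structures are unremarkable .",
        "Mild mucosal thickening in the paranasal sinuses .",
        "No hydrocephalus or midline shift .",
        "Comparison is made with the previous examination .",
        "The orbits and skull base are unremarkable .",
        "Periventricular white matter hyperintensities of a degree expected for age .",
        "No acute intracranial abnormality .",
        "MRI head performed with standard departmental protocol .",
        "The pituitary gland is normal in appearance .",
        "There is a chronic lacune in the left basal ganglia .",
        "No space occupying lesion is identified .",
        "Unremarkable study .",
        "Normal appearances of the craniocervical junction .",
    )
    return tuple(tuple(s.split()) for s in sentences)


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic corpus generator.

    Parameters
    ----------
    n_reports : number of reports to generate (default cohort size 4007).
    prevalence : per-category probability that a report contains at least one
        span of that category.  Within each base category present + absent
        must not exceed 1; a clean report never carries both polarities.
    inconsistency_rate : target fraction of reports carrying a genuine
        present/absent conflict for at least one base category.
    nested_negation_rate : probability that, when both REGIONAL_ABSENT and
        HIPPO_ABSENT occur in a report, they are realised as one negated
        sentence with overlapping spans rather than two sentences.
    length_target : mean words per report of the clipped lognormal length
        distribution (median scales as 61/68 of the mean; clip [1, 373]).
    seed : root seed; fixed seed implies byte-identical output.
    """

    n_reports: int = 4007
    prevalence: dict[Category, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    phrase_banks: dict[Category, tuple[Template, ...]] = field(
        default_factory=default_phrase_banks
    )
    combined_templates: tuple[Template, ...] = field(
        default_factory=default_combined_templates
    )
    distractor_bank: tuple[tuple[str, ...], ...] = field(
        default_factory=default_distractor_bank
    )
    inconsistency_rate: float = 0.035
    nested_negation_rate: float = 0.4
    length_target: float = 68.0
    length_min: int = 1
    length_max: int = 373
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 0:
            raise ValueError("n_reports must be >= 0")
        for cat in Category:
            p = self.prevalence.get(cat, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for {cat.value} outside [0, 1]")
            if p > 0 and not self.phrase_banks.get(cat):
                raise ValueError(
                    f"phrase bank for {cat.value} is empty but prevalence is {p}"
                )
        for rate in (self.inconsistency_rate, self.nested_negation_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        q = self._per_base_conflict_prob()
        for base in BASE_CATEGORIES:
            pres, absent = PRESENT_ABSENT_PAIRS[base]
            pp = self.prevalence.get(pres, 0.0)
            pa = self.prevalence.get(absent, 0.0)
            if pp + pa > 1.0:
                raise ValueError(
                    f"present + absent prevalence for {base} exceeds 1 ({pp + pa})"
                )
            if q > min(pp, pa) and q > 0:
                raise ValueError(
                    f"inconsistency_rate {self.inconsistency_rate} too high for the "
                    f"{base} prevalences (needs per-base conflict prob <= {min(pp, pa):.4f})"
                )
        if self.length_target <= 0:
            raise ValueError("length_target must be positive")

    def _per_base_conflict_prob(self) -> float:
        # Solve 1 - (1 - q)^3 = inconsistency_rate so that the REPORT-level
        # conflict rate matches the configured value in expectation.
        return 1.0 - (1.0 - self.inconsistency_rate) ** (1.0 / len(BASE_CATEGORIES))


def load_config(path: str | Path) -> GeneratorConfig:
    """Load scalar generator settings from a JSON config file.

    Recognised keys: ``n_reports``, ``prevalence`` (category name -> prob),
    ``inconsistency_rate``, ``nested_negation_rate``, ``length_target``,
    ``seed``.  Phrase banks are the library defaults.
    """
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    cfg = GeneratorConfig()
    scalars = {"n_reports", "inconsistency_rate", "nested_negation_rate", "length_target", "seed"}
    for key, value in raw.items():
        if key in scalars:
            setattr(cfg, key, value)
        elif key == "prevalence":
            try:
                cfg.prevalence = {Category(k): float(v) for k, v in value.items()}
            except ValueError as exc:
                raise ValueError(f"unknown category in prevalence: {exc}") from None
        else:
            raise ValueError(f"unknown config key {key!r}")
    cfg.validate()
    return cfg


def _fill_slots(tokens: tuple[str, ...], rng: np.random.Generator) -> tuple[str, ...]:
    out = []
    for tok in tokens:
        if tok == "{severity}":
            out.append(_SEVERITIES[rng.integers(len(_SEVERITIES))])
        elif tok == "{laterality}":
            out.append(_LATERALITIES[rng.integers(len(_LATERALITIES))])
        elif tok == "{region}":
            out.append(_REGIONS[rng.integers(len(_REGIONS))])
        else:
            out.append(tok)
    return tuple(out)


def _detokenize(tokens: tuple[str, ...]) -> str:
    """Join tokens into prose with no space before closing punctuation."""
    parts: list[str] = []
    for tok in tokens:
        if parts and tok in {".", ",", ";", ":", ")"}:
            parts[-1] += tok
        elif parts and parts[-1].endswith("("):
            parts[-1] += tok
        else:
            parts.append(tok)
    return " ".join(parts)


def _n_words(tokens: tuple[str, ...]) -> int:
    return sum(1 for t in tokens if any(c.isalnum() for c in t))


def _assemble_report(
    report_id: str,
    sentences: list[tuple[tuple[str, ...], tuple[tuple[int, int, Category], ...]]],
) -> Report:
    """Concatenate sentence units into a Report with global gold spans."""
    all_spans: set[SpanAnnotation] = set()
    text_parts: list[str] = []
    tok_offset = 0
    for tokens, spans in sentences:
        text_parts.append(_detokenize(tokens))
        for start, end, label in spans:
            all_spans.add(SpanAnnotation(tok_offset + start, tok_offset + end, label))
        tok_offset += len(tokens)
    text = " ".join(text_parts)
    report = Report(report_id, text, tokenize(text), {GOLD: all_spans})
    return report


def _sample_length(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    # lognormal parameterised so the median sits at 61/68 of the mean,
    # reproducing the right skew of the corpus length distribution
    median = cfg.length_target * 61.0 / 68.0
    mu = math.log(median)
    sigma = math.sqrt(max(2.0 * math.log(cfg.length_target / median), 1e-12))
    draw = rng.lognormal(mu, sigma)
    return int(np.clip(round(draw), cfg.length_min, cfg.length_max))


def _category_sentence(
    cat: Category, cfg: GeneratorConfig, rng: np.random.Generator
) -> tuple[tuple[str, ...], tuple[tuple[int, int, Category], ...]]:
    bank = cfg.phrase_banks[cat]
    tpl = bank[rng.integers(len(bank))]
    return _fill_slots(tpl.tokens, rng), tpl.spans


def _generate_report(
    report_id: str, cfg: GeneratorConfig, rng: np.random.Generator
) -> Report:
    q = cfg._per_base_conflict_prob()
    active: list[Category] = []
    conflict_bases: list[str] = []
    for base in BASE_CATEGORIES:
        pres, absent = PRESENT_ABSENT_PAIRS[base]
        pp = cfg.prevalence.get(pres, 0.0)
        pa = cfg.prevalence.get(absent, 0.0)
        u = rng.random()
        # four-way draw with exact marginals: P(cat in report) = prevalence
        if u < q:
            conflict_bases.append(base)
            active.append(pres if rng.random() < 0.5 else absent)
        elif u < q + (pp - q):
            active.append(pres)
        elif u < pp + (pa - q):
            active.append(absent)

    sentences: list[tuple[tuple[str, ...], tuple[tuple[int, int, Category], ...]]] = []
    remaining = list(active)
    if (
        C.REGIONAL_ABSENT in remaining
        and C.HIPPO_ABSENT in remaining
        and cfg.combined_templates
        and rng.random() < cfg.nested_negation_rate
    ):
        tpl = cfg.combined_templates[rng.integers(len(cfg.combined_templates))]
        sentences.append((_fill_slots(tpl.tokens, rng), tpl.spans))
        remaining.remove(C.REGIONAL_ABSENT)
        remaining.remove(C.HIPPO_ABSENT)
    for cat in remaining:
        sentences.append(_category_sentence(cat, cfg, rng))

    target = _sample_length(cfg, rng)
    words = sum(_n_words(toks) for toks, _ in sentences)
    while words < target or not sentences:
        toks = cfg.distractor_bank[rng.integers(len(cfg.distractor_bank))]
        sentences.append((toks, ()))
        words += _n_words(toks)

    order = rng.permutation(len(sentences))
    sentences = [sentences[i] for i in order]
    report = _assemble_report(report_id, sentences)

    for base in conflict_bases:
        report = inject_inconsistency(report, PRESENT_ABSENT_PAIRS[base], rng, config=cfg)
    return report


def generate_corpus(cfg: GeneratorConfig) -> AnnotatedCorpus:
    """Generate ``cfg.n_reports`` gold-annotated reports, fully seeded.

    With default settings the empirical per-category report prevalence tracks
    ``cfg.prevalence`` (sampling error only) and internal present/absent
    conflicts occur at ``cfg.inconsistency_rate``, injected exclusively via
    :func:`inject_inconsistency`.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(max(cfg.n_reports - 1, 0))))
    reports = [
        _generate_report(f"synth-{i:0{width}d}", cfg, rng)
        for i in range(cfg.n_reports)
    ]
    corpus = AnnotatedCorpus(reports)
    corpus.validate()
    return corpus


def inject_inconsistency(
    report: Report,
    category_pair: tuple[Category, Category],
    rng: np.random.Generator,
    config: GeneratorConfig | None = None,
) -> Report:
    """Make a report internally inconsistent for one base category.

    ``category_pair`` must be the (present, absent) pair of a single base
    category.  Sentences are appended so that the report carries gold spans of
    both polarities.  If the report already conflicts for that base the
    report is returned unchanged (idempotent at report level).
    """
    a, b = category_pair
    if a.base != b.base or a.polarity == b.polarity:
        raise ValueError(
            f"category pair must be the present/absent pair of one base, got "
            f"({a.value}, {b.value})"
        )
    cfg = config if config is not None else GeneratorConfig()
    gold = report.annotation_sets.get(GOLD, set())
    have = {s.label for s in gold}
    missing = [c for c in (a, b) if c not in have]
    if not missing:
        return report

    sentences: list[tuple[tuple[str, ...], tuple[tuple[int, int, Category], ...]]] = []
    for cat in missing:
        sentences.append(_category_sentence(cat, cfg, rng))

    # rebuild: existing text + appended conflicting sentences
    new_spans = set(gold)
    text = report.text
    tok_offset = len(report.tokens)
    for tokens, spans in sentences:
        sent_text = _detokenize(tokens)
        text = f"{text} {sent_text}" if text else sent_text
        for start, end, label in spans:
            new_spans.add(SpanAnnotation(tok_offset + start, tok_offset + end, label))
        tok_offset += len(tokens)
    sets = dict(report.annotation_sets)
    sets[GOLD] = new_spans
    out = Report(report.report_id, text, tokenize(text), sets)
    out.validate()
    return out


def corpus_statistics(corpus: AnnotatedCorpus, source: str = GOLD) -> dict:
    """Summary statistics: words/report and per-category span-length profile.

    Words are tokens containing at least one alphanumeric character, so
    punctuation does not inflate report lengths.  Means/medians are reported
    as ``None`` for an empty corpus.
    """
    word_counts = [r.n_words for r in corpus]
    per_cat_lengths: dict[str, list[int]] = {c.value: [] for c in Category}
    for r in corpus:
        for span in r.annotation_sets.get(source, set()):
            per_cat_lengths[span.label.value].append(len(span))

    def _summary(values: list[int]) -> dict:
        if not values:
            return {"count": 0, "mean": None, "median": None, "min": None, "max": None}
        arr = np.asarray(values)
        return {
            "count": int(arr.size),
            "mean": float(arr.mean()),
            "median": float(np.median(arr)),
            "min": int(arr.min()),
            "max": int(arr.max()),
        }

    return {
        "n_reports": len(corpus),
        "words_per_report": _summary(word_counts),
        "total_spans": sum(len(v) for v in per_cat_lengths.values()),
        "spans_per_category": {k: len(v) for k, v in per_cat_lengths.items()},
        "span_length_per_category": {k: _summary(v) for k, v in per_cat_lengths.items()},
    }
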