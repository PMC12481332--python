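"""Report-level aggregation: per-report category labels, cohort prevalence
tables, and internal-inconsistency detection.

A report is labelled with a category iff it contains at least one span of
that category, so one report can carry any subset of the six labels.  A
report is internally inconsistent for a base category (global, regional,
hippocampal) when it carries both the present and the absent label of that
base — counted purely at the label level, with no linguistic adjudication.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus import BASE_CATEGORIES, PRESENT_ABSENT_PAIRS, AnnotatedCorpus, Category, Report

__all__ = [
    "ReportLabels",
    "PrevalenceTable",
    "InconsistencyFlag",
    "report_labels",
    "prevalence",
    "find_inconsistencies",
]


@dataclass(frozen=True)
class ReportLabels:
    report_id: str
    labels: dict[Category, bool]

    def __getitem__(self, cat: Category) -> bool:
        return self.labels[cat]


@dataclass
class PrevalenceTable:
    """Report counts and cohort percentages per category.

    Categories are not mutually exclusive; percentages need not sum to 100.
    """

    n_reports: int
    counts: dict[Category, int]

    def percentage(self, cat: Category) -> float:
        return 100.0 * self.counts[cat] / self.n_reports

    def as_dict(self) -> dict:
        return {
            "n_reports": self.n_reports,
            "categories": {
                c.value: {"count": self.counts[c], "percentage": self.percentage(c)}
                for c in Category
            },
        }

    def to_text(self) -> str:
        """Aligned plain-text table: category, report count, % of cohort."""
        lines = [f"{'Category':<26}{'Total':>8}{'Prevalence':>12}"]
        for c in Category:
            lines.append(
                f"{c.value:<26}{self.counts[c]:>8}{self.percentage(c):>11.1f}%"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class InconsistencyFlag:
    """A report carrying both present and absent labels of one base category."""

    report_id: str
    base: str  # GLOBAL | REGIONAL | HIPPO


def report_labels(report: Report, source: str) -> ReportLabels:
    """Six boolean labels: true iff >= 1 span of the category in ``source``."""
    spans = report.spans(source)  # raises KeyError if source missing
    present = {s.label for s in spans}
    return ReportLabels(report.report_id, {c: c in present for c in Category})


def prevalence(corpus: AnnotatedCorpus, source: str) -> PrevalenceTable:
    """Cohort prevalence: reports containing at least one span per category."""
    if len(corpus) == 0:
        raise ValueError("prevalence is undefined for an empty corpus")
    counts = {c: 0 for c in Category}
    for report in corpus:
        labels = report_labels(report, source)
        for c in Category:
            counts[c] += labels[c]
    return PrevalenceTable(len(corpus), counts)


def find_inconsistencies(
    corpus: AnnotatedCorpus, source: str
) -> tuple[list[InconsistencyFlag], float]:
    """Flag every (report, base category) with conflicting present/absent
    labels; returns the flags and the fraction of reports flagged at least
    once."""
    flags: list[InconsistencyFlag] = []
    flagged_reports: set[str] = set()
    for report in corpus:
        labels = report_labels(report, source)
        for base in BASE_CATEGORIES:
            pres, absent = PRESENT_ABSENT_PAIRS[base]
            if labels[pres] and labels[absent]:
                flags.append(InconsistencyFlag(report.report_id, base))
                flagged_reports.add(report.report_id)
    rate = len(flagged_reports) / len(corpus) if len(corpus) else 0.0
    return flags, rate
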