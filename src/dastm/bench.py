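"""Per-segment and per-protein evaluation of TM predictions.

A predicted segment counts as a true positive when it overlaps an annotated
helical segment by at least three residues (experimental segment endpoints
are too uncertain for stricter per-residue criteria).  Matching is strict
one-to-one: candidate pairs are accepted greedily in descending overlap
order, so one prediction can never absorb two annotated helices silently —
twin-peak ambiguities surface as FN/FP in the per-record report instead of
being auto-resolved.  Predictions that land on an annotated signal peptide
are discarded from the bookkeeping (neither TP nor FP): signal peptides are
biophysically helix-like and are flagged, not penalized.

Beta-strand labels (B/b) are ignored entirely; the method targets
alpha-helical TM segments only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .caller import CallerParams, predict
from .core import DEFAULT_WINDOW, PairScoreMatrix, default_matrix
from .io import SequenceRecord, TopologyAnnotation, annotation_segments

__all__ = [
    "MatchParams",
    "MatchResult",
    "ConfusionCounts",
    "Metrics",
    "ClassRow",
    "ProteinTable",
    "RecordReport",
    "EvaluationResult",
    "match_segments",
    "compute_metrics",
    "evaluate_dataset",
    "fn_multiplicity",
]

Segment = tuple[int, int]


class ContractViolationError(ValueError):
    """Inputs violate a documented precondition."""


@dataclass(frozen=True)
class MatchParams:
    """Segment-matching rules."""

    min_overlap: int = 3
    exclude_signal_fp: bool = True

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass(frozen=True)
class MatchResult:
    """Outcome of matching one record's predictions to its annotation."""

    tp: tuple[tuple[Segment, Segment], ...]  # (predicted, annotated) pairs
    fp: tuple[Segment, ...]
    fn: tuple[Segment, ...]
    discarded_signal: tuple[Segment, ...]


@dataclass(frozen=True)
class ConfusionCounts:
    """Aggregate per-segment confusion bookkeeping.

    ``n_predicted`` excludes predictions discarded by the signal-peptide
    rule, so tp + fp == n_predicted and tp + fn == n_annotated.
    """

    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ContractViolationError("confusion counts must be >= 0")

    @property
    def n_annotated(self) -> int:
        return self.tp + self.fn

    @property
    def n_predicted(self) -> int:
        return self.tp + self.fp


@dataclass(frozen=True)
class Metrics:
    """Recall and precision; ``None`` when the denominator is zero."""

    recall: float | None
    precision: float | None

    def rounded(self, ndigits: int = 3) -> "Metrics":
        r = None if self.recall is None else round(self.recall, ndigits)
        p = None if self.precision is None else round(self.precision, ndigits)
        return Metrics(r, p)


def _check_sorted_disjoint(segments: Sequence[Segment], what: str) -> None:
    prev_end = 0
    for start, end in segments:
        if start < 1 or end < start:
            raise ContractViolationError(f"{what}: malformed segment ({start},{end})")
        if start <= prev_end:
            raise ContractViolationError(
                f"{what}: segments must be sorted and non-overlapping"
            )
        prev_end = end


def _overlap(a: Segment, b: Segment) -> int:
    return min(a[1], b[1]) - max(a[0], b[0]) + 1


def match_segments(predicted: Sequence[Segment],
                   annotated: Sequence[Segment],
                   signal_regions: Sequence[Segment] = (),
                   params: MatchParams | None = None) -> MatchResult:
    """One-to-one greedy matching by descending overlap.

    Ties break on earlier annotated start, then earlier predicted start.
    Unmatched predictions overlapping a signal region by >= ``min_overlap``
    are discarded (neither TP nor FP) when ``exclude_signal_fp`` is set.
    """
    if params is None:
        params = MatchParams()
    _check_sorted_disjoint(predicted, "predicted")
    _check_sorted_disjoint(annotated, "annotated")
    _check_sorted_disjoint(signal_regions, "signal_regions")

    candidates = []
    for a in annotated:
        for p in predicted:
            ov = _overlap(p, a)
            if ov >= params.min_overlap:
                candidates.append((-ov, a[0], p[0], p, a))
    candidates.sort()

    used_p: set[Segment] = set()
    used_a: set[Segment] = set()
    tp: list[tuple[Segment, Segment]] = []
    for _, _, _, p, a in candidates:
        if p in used_p or a in used_a:
            continue
        used_p.add(p)
        used_a.add(a)
        tp.append((p, a))
    tp.sort(key=lambda pair: pair[0])

    fp: list[Segment] = []
    discarded: list[Segment] = []
    for p in predicted:
        if p in used_p:
            continue
        if params.exclude_signal_fp and any(
                _overlap(p, s) >= params.min_overlap for s in signal_regions):
            discarded.append(p)
        else:
            fp.append(p)
    fn = [a for a in annotated if a not in used_a]
    return MatchResult(tuple(tp), tuple(fp), tuple(fn), tuple(discarded))


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Standard recall = TP/(TP+FN) and precision = TP/(TP+FP)."""
    recall = counts.tp / counts.n_annotated if counts.n_annotated > 0 else None
    precision = counts.tp / counts.n_predicted if counts.n_predicted > 0 else None
    return Metrics(recall, precision)


@dataclass(frozen=True)
class ClassRow:
    """Per-protein identification tallies for one dataset class."""

    total: int
    called_tm: int

    @property
    def called_non_tm(self) -> int:
        return self.total - self.called_tm

    @property
    def pct_tm(self) -> float:
        return round(100.0 * self.called_tm / self.total, 1) if self.total else 0.0

    @property
    def pct_non_tm(self) -> float:
        return round(100.0 * self.called_non_tm / self.total, 1) if self.total else 0.0


@dataclass(frozen=True)
class ProteinTable:
    """Per-protein TM identification table, one row per dataset class."""

    rows: dict[str, ClassRow]

    def to_text(self) -> str:
        lines = ["class\ttotal\tcalled_TM\tpct_TM\tcalled_non-TM\tpct_non-TM"]
        for cls in sorted(self.rows):
            r = self.rows[cls]
            lines.append(f"{cls}\t{r.total}\t{r.called_tm}\t{r.pct_tm:.1f}"
                         f"\t{r.called_non_tm}\t{r.pct_non_tm:.1f}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class RecordReport:
    """Per-record evaluation detail."""

    record_id: str
    true_class: str  # tm | globular | signal
    classification: str  # TM | non-TM
    n_annotated: int
    n_predicted: int
    tp: int
    fp: int
    fn: int
    discarded_signal: int
    twin_peak_segments: int


@dataclass(frozen=True)
class EvaluationResult:
    counts: ConfusionCounts
    metrics: Metrics
    protein_table: ProteinTable
    records: tuple[RecordReport, ...]
    skipped: tuple[str, ...] = ()

    def summary_text(self) -> str:
        m = self.metrics
        rec = "NA" if m.recall is None else f"{m.recall:.3f}"
        pre = "NA" if m.precision is None else f"{m.precision:.3f}"
        hist = fn_multiplicity(self.records)
        lines = [
            "== per-segment performance ==",
            f"annotated TM segments\t{self.counts.n_annotated}",
            f"predicted TM segments\t{self.counts.n_predicted}",
            f"true positives\t{self.counts.tp}",
            f"false positives\t{self.counts.fp}",
            f"false negatives\t{self.counts.fn}",
            f"recall\t{rec}",
            f"precision\t{pre}",
            "== per-protein identification ==",
            self.protein_table.to_text().rstrip("\n"),
            "== missed-segment multiplicity (k FN -> proteins) ==",
        ]
        lines += [f"{k}\t{hist[k]}" for k in sorted(hist)] or ["(none)"]
        return "\n".join(lines) + "\n"


def _true_class(annotation: TopologyAnnotation) -> str:
    labels = set(annotation.labels)
    if labels & {"H", "h"}:
        return "tm"
    if "S" in labels:
        return "signal"
    return "globular"


def evaluate_dataset(pairs: Iterable[tuple[SequenceRecord, TopologyAnnotation]],
                     library: Iterable[SequenceRecord],
                     matrix: PairScoreMatrix | None = None,
                     window: int = DEFAULT_WINDOW,
                     caller_params: CallerParams | None = None,
                     match_params: MatchParams | None = None,
                     ) -> EvaluationResult:
    """Predict every record and score against its annotation.

    Helical ground truth is the H/h label runs, signal regions the S runs;
    B/b (beta) segments are ignored.  Records whose annotation length does
    not match the sequence are skipped and reported, not fatal.  Per-protein
    classification comes from the caller (trusted mode by default).
    """
    if matrix is None:
        matrix = default_matrix()
    if caller_params is None:
        caller_params = CallerParams(mode="trusted")
    if match_params is None:
        match_params = MatchParams()
    library = list(library)

    tp = fp = fn = 0
    reports: list[RecordReport] = []
    skipped: list[str] = []
    class_tallies: dict[str, list[int]] = {}

    for record, annotation in pairs:
        if len(record) != len(annotation):
            skipped.append(record.id)
            continue
        annotated = annotation_segments(annotation, {"H", "h"})
        signal_regions = annotation_segments(annotation, {"S"})
        result = predict(record, library, matrix, window, caller_params)
        predicted = [(s.start, s.end) for s in result.segments]
        match = match_segments(predicted, annotated, signal_regions, match_params)
        tp += len(match.tp)
        fp += len(match.fp)
        fn += len(match.fn)
        cls = _true_class(annotation)
        tally = class_tallies.setdefault(cls, [0, 0])
        tally[0] += 1
        if result.classification == "TM":
            tally[1] += 1
        reports.append(RecordReport(
            record_id=record.id,
            true_class=cls,
            classification=result.classification,
            n_annotated=len(annotated),
            n_predicted=len(predicted) - len(match.discarded_signal),
            tp=len(match.tp),
            fp=len(match.fp),
            fn=len(match.fn),
            discarded_signal=len(match.discarded_signal),
            twin_peak_segments=sum(
                1 for s in result.segments if "twin_peak" in s.warnings),
        ))

    counts = ConfusionCounts(tp, fp, fn)
    table = ProteinTable({cls: ClassRow(total, called)
                          for cls, (total, called) in class_tallies.items()})
    return EvaluationResult(counts, compute_metrics(counts), table,
                            tuple(reports), tuple(skipped))


def fn_multiplicity(records: Iterable[RecordReport]) -> dict[int, int]:
    """Histogram: k missed segments -> number of proteins with exactly k FN.

    Proteins with zero FN are omitted; the weighted total
    ``sum(k * count)`` equals the dataset FN count.
    """
    hist: dict[int, int] = {}
    for rep in records:
        if rep.fn > 0:
            hist[rep.fn] = hist.get(rep.fn, 0) + 1
    return hist
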