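"""Turn a global DAS profile into transmembrane segment calls.

Positions whose profile score reaches the cutoff (default 2.5) form the
predicted segments — maximal runs, no minimum length, no merging, because
even very short hydrophobic hits can be real and experimental segment
endpoints are themselves uncertain.  Advisory warnings (possible signal
peptide near the N-terminus, twin peaks separated by a short linker) never
alter the calls; they flag situations the user should inspect.

A protein is classified TM when it has two or more called segments; with
exactly one segment the decision falls to the quality value (the maximum
profile peak inside a segment) against a quality threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .core import (DEFAULT_WINDOW, PairScoreMatrix, ParameterError,
                   ScoreProfile, das_profile, default_matrix)
from .io import SequenceRecord

__all__ = [
    "CallerParams",
    "PredictedSegment",
    "PredictionResult",
    "call_segments",
    "annotate_warnings",
    "quality_value",
    "classify_protein",
    "predict",
    "render_profile",
    "SIGNAL_WARNING",
    "TWIN_PEAK_WARNING",
]

SIGNAL_WARNING = "possible_signal_peptide"
TWIN_PEAK_WARNING = "twin_peak"


@dataclass(frozen=True)
class CallerParams:
    """Segment-calling and classification parameters.

    cutoff            profile score threshold for TM calling (2.5)
    signal_window     N-terminal span checked for the signal-peptide warning
    twin_gap          max linker length (residues) that triggers twin-peak
    mode              'unconditional' always computes the quality value;
                      'trusted' computes it only when the protein has exactly
                      one called segment (where it decides TM vs non-TM)
    quality_threshold single-segment TM decision threshold
    plot_cap          fixed-scale rendering cap for the y axis
    signal_on_peak    use the peak position instead of the segment start for
                      the signal-peptide rule
    """

    cutoff: float = 2.5
    signal_window: int = 25
    twin_gap: int = 4
    mode: Literal["unconditional", "trusted"] = "trusted"
    quality_threshold: float = 3.0
    plot_cap: float = 5.0
    signal_on_peak: bool = False

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ParameterError(f"cutoff must be > 0, got {self.cutoff}")
        if self.signal_window < 1:
            raise ParameterError("signal_window must be >= 1")
        if self.twin_gap < 0:
            raise ParameterError("twin_gap must be >= 0")
        if self.plot_cap < self.cutoff:
            raise ParameterError("plot_cap must be >= cutoff")
        if self.mode not in ("unconditional", "trusted"):
            raise ParameterError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class PredictedSegment:
    """A called TM segment, 1-based inclusive coordinates."""

    start: int
    end: int
    peak: float
    peak_position: int
    mean_excess: float
    warnings: frozenset[str] = frozenset()

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class PredictionResult:
    """Full prediction for one query."""

    query_id: str
    segments: tuple[PredictedSegment, ...]
    classification: Literal["TM", "non-TM"]
    quality: float | None
    mode: str
    params: CallerParams

    def to_tsv(self) -> str:
        """Short-output TSV: a query line, then one line per segment."""
        q = "NA" if self.quality is None else f"{self.quality:.3f}"
        lines = [f"{self.query_id}\t{self.classification}\t{q}\t{len(self.segments)}"]
        for seg in self.segments:
            warn = ",".join(sorted(seg.warnings)) if seg.warnings else "-"
            lines.append(
                f"{self.query_id}\t{seg.start}\t{seg.end}\t{seg.peak:.3f}\t{warn}"
            )
        return "\n".join(lines) + "\n"


def call_segments(profile: ScoreProfile,
                  params: CallerParams | None = None) -> list[PredictedSegment]:
    """Maximal runs of positions with D >= cutoff (inclusive threshold)."""
    if params is None:
        params = CallerParams()
    d = profile.values
    if len(d) == 0:
        raise ParameterError("profile is empty")
    above = d >= params.cutoff
    segments: list[PredictedSegment] = []
    start: int | None = None
    for pos in range(len(d) + 1):
        inside = pos < len(d) and above[pos]
        if inside and start is None:
            start = pos
        elif not inside and start is not None:
            chunk = d[start:pos]
            peak_off = int(np.argmax(chunk))
            segments.append(PredictedSegment(
                start=start + 1,
                end=pos,
                peak=float(chunk[peak_off]),
                peak_position=start + 1 + peak_off,
                mean_excess=float(np.mean(chunk - params.cutoff)),
            ))
            start = None
    return segments


def annotate_warnings(segments: Sequence[PredictedSegment],
                      params: CallerParams | None = None,
                      ) -> list[PredictedSegment]:
    """Attach advisory warnings; never changes intervals or scores."""
    if params is None:
        params = CallerParams()
    warned: list[set[str]] = [set(s.warnings) for s in segments]
    for i, seg in enumerate(segments):
        anchor = seg.peak_position if params.signal_on_peak else seg.start
        if anchor <= params.signal_window:
            warned[i].add(SIGNAL_WARNING)
        if i + 1 < len(segments):
            gap = segments[i + 1].start - seg.end - 1
            if gap <= params.twin_gap:
                warned[i].add(TWIN_PEAK_WARNING)
                warned[i + 1].add(TWIN_PEAK_WARNING)
    return [replace(s, warnings=frozenset(w))
            for s, w in zip(segments, warned)]


def quality_value(profile: ScoreProfile,
                  segments: Sequence[PredictedSegment],
                  params: CallerParams | None = None) -> float:
    """Prediction-strength scalar: the maximum peak over all segments.

    Matters most for single-segment queries, where it decides TM vs non-TM.
    """
    if not segments:
        raise ParameterError("quality value undefined without segments")
    return max(s.peak for s in segments)


def classify_protein(segments: Sequence[PredictedSegment],
                     quality: float | None,
                     params: CallerParams | None = None,
                     ) -> Literal["TM", "non-TM"]:
    """>= 2 segments: TM; 0: non-TM; exactly 1: TM iff quality >= threshold."""
    if params is None:
        params = CallerParams()
    if len(segments) >= 2:
        return "TM"
    if len(segments) == 0:
        return "non-TM"
    if quality is None:
        raise ParameterError(
            "quality value required to classify a single-segment protein"
        )
    return "TM" if quality >= params.quality_threshold else "non-TM"


def predict(query: SequenceRecord,
            library: Iterable[SequenceRecord],
            matrix: PairScoreMatrix | None = None,
            window: int = DEFAULT_WINDOW,
            params: CallerParams | None = None) -> PredictionResult:
    """Full pipeline: profile -> calls -> warnings -> quality -> class."""
    if params is None:
        params = CallerParams()
    if matrix is None:
        matrix = default_matrix()
    profile = das_profile(query, library, matrix, window)
    segments = annotate_warnings(call_segments(profile, params), params)
    quality: float | None = None
    if segments and (params.mode == "unconditional" or len(segments) == 1):
        quality = quality_value(profile, segments, params)
    classification = classify_protein(segments, quality, params)
    return PredictionResult(query.id, tuple(segments), classification,
                            quality, params.mode, params)


def render_profile(profile: ScoreProfile,
                   segments: Sequence[PredictedSegment] = (),
                   params: CallerParams | None = None,
                   scaling: Literal["free", "fixed"] = "free",
                   out_path=None,
                   title: str = ""):
    """Plot the DAS profile with the cutoff line; return the figure.

    Fixed scaling clamps the y axis to [0, plot_cap] so profiles of different
    proteins are directly comparable; free scaling fits the data.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if params is None:
        params = CallerParams()
    if len(profile) == 0:
        raise ParameterError("profile is empty")
    positions = np.arange(1, len(profile) + 1)
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(positions, profile.values, color="black", lw=1.0)
    ax.axhline(params.cutoff, color="red", ls=":", lw=1.0,
               label=f"cutoff {params.cutoff:g}")
    for seg in segments:
        ax.axvspan(seg.start, seg.end, color="orange", alpha=0.25)
    if scaling == "fixed":
        ax.set_ylim(0.0, params.plot_cap)
    else:
        top = max(float(np.max(profile.values)), params.cutoff) * 1.05
        ax.set_ylim(0.0, top)
    ax.set_xlabel("sequence position")
    ax.set_ylabel("DAS score")
    if title:
        ax.set_title(title)
    ax.legend(loc="upper right", frameon=False, fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path)
        plt.close(fig)
    return fig
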