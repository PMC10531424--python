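"""Synthetic protein generator with ground-truth topology annotations.

Generates three caricatured protein classes so the whole pipeline is
testable without external datasets:

* multi-spanning TM proteins — alternating hydrophilic loops and strongly
  hydrophobic segments of 15-30 residues (the canonical TM-helix span),
  labeled ``H`` over segments and alternating ``1``/``2`` over loops;
* globular proteins — background-composition sequences rejection-sampled so
  no run of 9+ strongly hydrophobic residues appears by chance, labels all
  ``1``;
* signal-peptide proteins — a short N-terminal hydrophobic core (7-15
  residues, starting within the first five positions) labeled ``S``,
  followed by a globular body labeled ``2``.

Composition weights are deliberate caricatures (strong hydrophobic/
hydrophilic contrast), not models of real membrane proteins.  All
randomness flows from the explicit seed in :class:`GeneratorParams`.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field

import numpy as np

from .core import BACKGROUND_FREQUENCIES
from .io import SequenceRecord, TopologyAnnotation, write_labeled_fasta

__all__ = [
    "GeneratorParams",
    "GeneratorError",
    "HYDROPHOBIC_WEIGHTS",
    "HYDROPHILIC_WEIGHTS",
    "synth_tm_protein",
    "synth_globular",
    "synth_signal_protein",
    "synth_dataset",
    "synth_library",
]


class GeneratorError(RuntimeError):
    """Raised when rejection sampling cannot satisfy the composition rules."""


#: TM-segment residue weights: I/L/V/F/A/M-dominated.
HYDROPHOBIC_WEIGHTS: dict[str, float] = {
    "I": 0.27, "L": 0.27, "V": 0.21, "F": 0.10, "A": 0.06,
    "M": 0.04, "W": 0.02, "G": 0.015, "T": 0.01, "S": 0.005,
}

#: Loop residue weights: charged/polar-dominated.
HYDROPHILIC_WEIGHTS: dict[str, float] = {
    "D": 0.12, "E": 0.13, "K": 0.12, "R": 0.10, "N": 0.09,
    "Q": 0.09, "S": 0.10, "T": 0.08, "G": 0.10, "P": 0.07,
}

#: Residues counted as "strongly hydrophobic" by the globular rejection rule.
_STRONG_HYDROPHOBICS = frozenset("ILVFM")
_MAX_STRONG_RUN = 8
_MAX_REJECTION_TRIES = 1000


@dataclass(frozen=True)
class GeneratorParams:
    """Architecture and composition parameters for the generator."""

    n_segments_range: tuple[int, int] = (1, 7)
    segment_len_range: tuple[int, int] = (15, 30)
    loop_len_range: tuple[int, int] = (10, 60)
    globular_len_range: tuple[int, int] = (100, 400)
    hydrophobic_weights: dict[str, float] = field(
        default_factory=lambda: dict(HYDROPHOBIC_WEIGHTS))
    hydrophilic_weights: dict[str, float] = field(
        default_factory=lambda: dict(HYDROPHILIC_WEIGHTS))
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.n_segments_range, self.segment_len_range,
                       self.loop_len_range, self.globular_len_range):
            if lo < 1 or hi < lo:
                raise ValueError(f"invalid range ({lo}, {hi})")
        for name, table in (("hydrophobic", self.hydrophobic_weights),
                            ("hydrophilic", self.hydrophilic_weights)):
            total = sum(table.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} weights sum to {total!r}, expected 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _draw(rng: np.random.Generator, weights: dict[str, float], n: int) -> str:
    letters = list(weights)
    p = np.array([weights[a] for a in letters])
    p = p / p.sum()
    return "".join(rng.choice(letters, size=n, p=p))


def _rand_len(rng: np.random.Generator, lo_hi: tuple[int, int]) -> int:
    return int(rng.integers(lo_hi[0], lo_hi[1] + 1))


def _longest_strong_run(residues: str) -> int:
    best = run = 0
    for ch in residues:
        run = run + 1 if ch in _STRONG_HYDROPHOBICS else 0
        best = max(best, run)
    return best


def _draw_globular_body(rng: np.random.Generator, length: int) -> str:
    """Background-composition sequence with no accidental TM-like run."""
    for _ in range(_MAX_REJECTION_TRIES):
        body = _draw(rng, BACKGROUND_FREQUENCIES, length)
        if _longest_strong_run(body) <= _MAX_STRONG_RUN:
            return body
    raise GeneratorError(
        f"could not draw a {length}-residue globular sequence without a "
        f"strong hydrophobic run in {_MAX_REJECTION_TRIES} tries"
    )


def synth_tm_protein(params: GeneratorParams, n_segments: int,
                     rng: np.random.Generator | None = None,
                     record_id: str = "SYNTM",
                     ) -> tuple[SequenceRecord, TopologyAnnotation]:
    """Alternating loop/segment/.../loop architecture with planted H runs."""
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    if rng is None:
        rng = params.rng()
    seq_parts: list[str] = []
    lab_parts: list[str] = []
    side = "1"
    for i in range(n_segments):
        loop_len = _rand_len(rng, params.loop_len_range)
        seq_parts.append(_draw(rng, params.hydrophilic_weights, loop_len))
        lab_parts.append(side * loop_len)
        seg_len = _rand_len(rng, params.segment_len_range)
        seq_parts.append(_draw(rng, params.hydrophobic_weights, seg_len))
        lab_parts.append("H" * seg_len)
        side = "2" if side == "1" else "1"
    loop_len = _rand_len(rng, params.loop_len_range)
    seq_parts.append(_draw(rng, params.hydrophilic_weights, loop_len))
    lab_parts.append(side * loop_len)
    return (SequenceRecord(record_id, "".join(seq_parts), "synthetic TM protein"),
            TopologyAnnotation("".join(lab_parts)))


def synth_globular(params: GeneratorParams, length: int | None = None,
                   rng: np.random.Generator | None = None,
                   record_id: str = "SYNGLOB",
                   ) -> tuple[SequenceRecord, TopologyAnnotation]:
    """Globular (non-TM, no signal) protein; labels all '1'."""
    if rng is None:
        rng = params.rng()
    if length is None:
        length = _rand_len(rng, params.globular_len_range)
    if length < 1:
        raise ValueError("length must be >= 1")
    body = _draw_globular_body(rng, length)
    return (SequenceRecord(record_id, body, "synthetic globular protein"),
            TopologyAnnotation("1" * length))


def synth_signal_protein(params: GeneratorParams,
                         rng: np.random.Generator | None = None,
                         record_id: str = "SYNSIG",
                         ) -> tuple[SequenceRecord, TopologyAnnotation]:
    """Signal-peptide protein: N-terminal hydrophobic core, globular body."""
    if rng is None:
        rng = params.rng()
    prefix_len = int(rng.integers(1, 5))  # core starts within first 5 positions
    prefix = "M" + _draw(rng, params.hydrophilic_weights, prefix_len - 1)
    core_len = int(rng.integers(7, 16))
    core = _draw(rng, params.hydrophobic_weights, core_len)
    body_len = _rand_len(rng, params.globular_len_range)
    body = _draw_globular_body(rng, body_len)
    residues = prefix + core + body
    labels = "S" * (prefix_len + core_len) + "2" * body_len
    return (SequenceRecord(record_id, residues, "synthetic signal-peptide protein"),
            TopologyAnnotation(labels))


def synth_records(params: GeneratorParams, n_tm: int, n_globular: int,
                  n_signal: int,
                  ) -> list[tuple[SequenceRecord, TopologyAnnotation]]:
    """Seeded, shuffled mixture of the three classes as in-memory pairs."""
    if min(n_tm, n_globular, n_signal) < 0:
        raise ValueError("record counts must be >= 0")
    rng = params.rng()
    pairs: list[tuple[SequenceRecord, TopologyAnnotation]] = []
    for i in range(n_tm):
        n_seg = _rand_len(rng, params.n_segments_range)
        pairs.append(synth_tm_protein(params, n_seg, rng,
                                      record_id=f"TM{i + 1:04d}"))
    for i in range(n_globular):
        pairs.append(synth_globular(params, None, rng,
                                    record_id=f"GLOB{i + 1:04d}"))
    for i in range(n_signal):
        pairs.append(synth_signal_protein(params, rng,
                                          record_id=f"SIG{i + 1:04d}"))
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


def synth_dataset(params: GeneratorParams, n_tm: int, n_globular: int,
                  n_signal: int) -> str:
    """Labeled-FASTA document for a seeded mixed dataset."""
    pairs = synth_records(params, n_tm, n_globular, n_signal)
    buf = _stdio.StringIO()
    write_labeled_fasta(pairs, buf)
    return buf.getvalue()


def synth_library(params: GeneratorParams, size: int):
    """Synthetic reference library: multi-spanning TM proteins (3-7 segments).

    Members are generated sequentially from the seed, so for a fixed seed the
    size-8 library is a prefix of the size-16/24/32 ones.
    """
    from .library import LIBRARY_SIZES, ReferenceLibrary

    if size not in LIBRARY_SIZES:
        raise ValueError(f"library size must be one of {LIBRARY_SIZES}, got {size}")
    rng = params.rng()
    members: list[SequenceRecord] = []
    for i in range(size):
        n_seg = int(rng.integers(3, 8))
        rec, _ = synth_tm_protein(params, n_seg, rng,
                                  record_id=f"SYNLIB{i + 1:02d}")
        members.append(rec)
    return ReferenceLibrary(f"synthetic-{size}-seed{params.seed}", tuple(members))
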