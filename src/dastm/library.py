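"""Reference libraries of transmembrane protein sequences.

Every query is scored against a small library of multi-spanning TM
proteins.  Bundled library sizes are 8, 16, 24 and 32 with a nested-prefix
guarantee (the size-8 members are the first 8 of every larger library), so
size is purely a speed/robustness knob; size 8 is the recommended default.

The bundled file ``data/tm_library_synthetic.fasta`` is a synthetic
stand-in built by :mod:`dastm.synth` with a fixed seed: 32 generated
multi-spanning TM sequences stored as plain FASTA so users can audit it or
substitute a curated library of real sequences via ``load_library(path)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence, Union

from .caller import CallerParams, predict
from .core import (DEFAULT_WINDOW, ConfigurationError, PairScoreMatrix,
                   default_matrix)
from .io import SequenceRecord, read_fasta

__all__ = [
    "LIBRARY_SIZES",
    "ReferenceLibrary",
    "LibraryValidation",
    "load_library",
    "validate_library",
]

LIBRARY_SIZES = (8, 16, 24, 32)

_BUNDLED_FILE = "tm_library_synthetic.fasta"


@dataclass(frozen=True)
class ReferenceLibrary:
    """An ordered, fixed-size set of reference TM sequences."""

    name: str
    members: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ConfigurationError(f"library {self.name!r}: duplicate member ids")

    @property
    def size(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)


def load_library(source: Union[str, Path, None] = None,
                 size: int = 8) -> ReferenceLibrary:
    """Load the first ``size`` members of a FASTA library file.

    With no ``source`` the bundled synthetic library is used.  Requesting
    more members than the file holds, or a file with duplicate ids, is a
    configuration error.
    """
    if size not in LIBRARY_SIZES:
        raise ConfigurationError(
            f"library size must be one of {LIBRARY_SIZES}, got {size}"
        )
    if source is None:
        ref = resources.files("dastm").joinpath("data", _BUNDLED_FILE)
        with resources.as_file(ref) as path:
            records = read_fasta(path)
        name = f"bundled-synthetic-{size}"
    else:
        records = read_fasta(source)
        name = f"{Path(source).stem}-{size}"
    if len(records) < size:
        raise ConfigurationError(
            f"library source holds {len(records)} records, "
            f"fewer than the requested size {size}"
        )
    return ReferenceLibrary(name, tuple(records[:size]))


@dataclass(frozen=True)
class LibraryValidation:
    """Per-member self-consistency report for a reference library."""

    library_name: str
    member_segment_counts: dict[str, int]
    invalid_reason: str | None = None

    @property
    def passes(self) -> bool:
        if self.invalid_reason is not None:
            return False
        return all(n >= 1 for n in self.member_segment_counts.values())

    @property
    def failing_members(self) -> list[str]:
        return [m for m, n in self.member_segment_counts.items() if n < 1]

    def to_text(self) -> str:
        lines = [f"library\t{self.library_name}",
                 f"passes\t{str(self.passes).lower()}"]
        if self.invalid_reason:
            lines.append(f"invalid\t{self.invalid_reason}")
        for member, n in self.member_segment_counts.items():
            status = "ok" if n >= 1 else "FAIL"
            lines.append(f"member\t{member}\t{n}\t{status}")
        return "\n".join(lines) + "\n"


def validate_library(library: ReferenceLibrary,
                     matrix: PairScoreMatrix | None = None,
                     window: int = DEFAULT_WINDOW,
                     params: CallerParams | None = None) -> LibraryValidation:
    """Check every member is itself called TM-like by the rest of the library.

    Each member is predicted against the remaining members (the standard
    self-exclusion); the library passes when every member yields at least
    one called segment.  A single-member library has an empty comparator set
    after self-exclusion and is flagged invalid outright.
    """
    if matrix is None:
        matrix = default_matrix()
    if params is None:
        params = CallerParams()
    if len(library) < 2:
        return LibraryValidation(
            library.name, {},
            invalid_reason="self-exclusion leaves an empty comparator set",
        )
    counts: dict[str, int] = {}
    for member in library:
        result = predict(member, library.members, matrix, window, params)
        counts[member.id] = len(result.segments)
    return LibraryValidation(library.name, counts)
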