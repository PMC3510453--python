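"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package; GFF is
converted to/from 1-based closed at the I/O boundary only.  Replicons are
circular by default because the target organisms carry circular genetic
elements; linear contigs are supported for generality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Replicon",
    "CoverageTrack",
    "SmoothedTrack",
    "Fragment",
    "FragmentSet",
    "NucleosomeCall",
    "Annotation",
    "TranscriptUnit",
]


@dataclass
class Replicon:
    """A named replicon (chromosome or plasmid), optionally with sequence."""

    name: str
    length: int
    circular: bool = True
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"replicon {self.name!r}: length must be positive")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"replicon {self.name!r}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass
class CoverageTrack:
    """Per-base coverage x[i] over one replicon."""

    replicon: Replicon
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) != self.replicon.length:
            raise ValueError(
                f"coverage length {len(self.values)} != replicon length "
                f"{self.replicon.length}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coverage contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("coverage contains negative values")


@dataclass
class SmoothedTrack:
    """Convolution output y[i] plus a description of the kernel that made it."""

    replicon: Replicon
    values: np.ndarray
    kernel_desc: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.replicon.length:
            raise ValueError("smoothed track length != replicon length")


@dataclass(frozen=True)
class Fragment:
    """One protected fragment, 0-based half-open.

    Fragments spanning the circular origin are stored as two records sharing
    a ``wrap_id``; each half obeys 0 <= start < end <= replicon length, which
    keeps emitted BED standard-compliant.
    """

    replicon_name: str
    start: int
    end: int
    strand: str = "."
    wrap_id: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad fragment interval [{self.start}, {self.end})")


@dataclass
class FragmentSet:
    replicon: Replicon
    fragments: list[Fragment] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass
class NucleosomeCall:
    """One called nucleosome midpoint (dyad) with its flanking troughs."""

    replicon_name: str
    midpoint: int
    peak_value: float
    left_trough: int
    right_trough: int
    prominence: float


@dataclass(frozen=True)
class Annotation:
    """A predicted gene annotation (e.g. an ORF call), 0-based half-open."""

    id: str
    replicon_name: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"annotation {self.id}: bad interval")


@dataclass
class TranscriptUnit:
    """A refined transcription unit.

    ``status`` is one of confirmed / merged / novel; merged units absorb at
    least two source annotation ids, novel units none.
    """

    replicon_name: str
    start: int
    end: int
    strand: str
    status: str
    source_ids: tuple[str, ...] = ()
    mean_coverage: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("transcript unit start >= end")
        if self.status == "merged" and len(self.source_ids) < 2:
            raise ValueError("merged unit needs >= 2 source ids")
        if self.status == "novel" and self.source_ids:
            raise ValueError("novel unit must have no source ids")

    @property
    def tss(self) -> int:
        """0-based position of the transcription start (strand-aware)."""
        return self.start if self.strand != "-" else self.end - 1

    @property
    def tts(self) -> int:
        """0-based position of the transcription terminus (strand-aware)."""
        return self.end - 1 if self.strand != "-" else self.start
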