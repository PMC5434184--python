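"""Shared genomic primitives: intervals, sequences, strand arithmetic.

All coordinates are 0-based, half-open. Strand is "+", "-" or "." for
unstranded features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator

import numpy as np

STRANDS = ("+", "-", ".")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# 2-bit encoding used by the aligner and the mappability track
_ENCODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode ACGT into uint8 codes 0..3 (anything else maps to 0)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval with optional strand."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def distance_to(self, pos: int) -> int:
        """Distance from a point to this interval; 0 if the point is inside."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class ReferenceGenome:
    """A set of named contigs restricted to the nucleotide alphabet."""

    contigs: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            if set(seq.upper()) - set("ACGTN"):
                raise ValueError(f"contig {name!r} has non-ACGTN characters")

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def __iter__(self) -> Iterator[str]:
        return iter(self.contigs)

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of an interval, reverse-complemented for "-" strand."""
        seq = self.contigs[interval.contig][interval.start : interval.end]
        return revcomp(seq) if interval.strand == "-" else seq
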