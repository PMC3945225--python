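"""Aligned-tag container.

A *tag* is the 5' genomic position of a uniquely mapped sequencing read; it
is the counting unit of ChIP-seq enrichment. A :class:`TagCollection` holds,
per chromosome, position-sorted tags with their strands, plus the chromosome
lengths and the total depth used for reads-per-million (RPM) scaling.

All coordinates are 0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import MitobookError


@dataclass
class TagCollection:
    chrom_lengths: dict[str, int]
    positions: dict[str, np.ndarray] = field(default_factory=dict)
    strands: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom in list(self.positions):
            if chrom not in self.chrom_lengths:
                raise MitobookError(f"tags on unknown chromosome {chrom!r}")
            pos = np.asarray(self.positions[chrom], dtype=np.int64)
            strand = np.asarray(
                self.strands.get(chrom, np.ones(len(pos), dtype=np.int8)),
                dtype=np.int8,
            )
            if len(pos) != len(strand):
                raise MitobookError(f"position/strand length mismatch on {chrom}")
            order = np.argsort(pos, kind="stable")
            pos, strand = pos[order], strand[order]
            L = self.chrom_lengths[chrom]
            if len(pos) and (pos[0] < 0 or pos[-1] >= L):
                raise MitobookError(
                    f"tag position outside [0, {L}) on chromosome {chrom}"
                )
            self.positions[chrom] = pos
            self.strands[chrom] = strand
        for chrom in self.chrom_lengths:
            self.positions.setdefault(chrom, np.empty(0, dtype=np.int64))
            self.strands.setdefault(chrom, np.empty(0, dtype=np.int8))

    @property
    def total_tags(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))

    @property
    def genome_length(self) -> int:
        return int(sum(self.chrom_lengths.values()))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Tags with position in the half-open interval [start, end)."""
        if chrom not in self.chrom_lengths:
            raise MitobookError(f"unknown chromosome {chrom!r}")
        pos = self.positions[chrom]
        return int(np.searchsorted(pos, end, "left") - np.searchsorted(pos, start, "left"))

    def counts_in_windows(self, chrom: str, starts: np.ndarray, width: int) -> np.ndarray:
        """Vectorized tag counts for same-width windows [s, s+width)."""
        pos = self.positions[chrom]
        starts = np.asarray(starts, dtype=np.int64)
        return (
            np.searchsorted(pos, starts + width, "left")
            - np.searchsorted(pos, starts, "left")
        ).astype(np.int64)

    def positions_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        pos = self.positions[chrom]
        lo = np.searchsorted(pos, start, "left")
        hi = np.searchsorted(pos, end, "left")
        return pos[lo:hi]

    def __eq__(self, other: object) -> bool:  # round-trip tests rely on this
        if not isinstance(other, TagCollection):
            return NotImplemented
        if self.chrom_lengths != other.chrom_lengths:
            return False
        for chrom in self.chrom_lengths:
            if not np.array_equal(self.positions[chrom], other.positions[chrom]):
                return False
            if not np.array_equal(self.strands[chrom], other.strands[chrom]):
                return False
        return True
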