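"""Core domain types for the editing/Alu proximity pipeline.

All genomic coordinates are 0-based, half-open (BED-native). Human-readable
reports convert to 1-based only at the presentation layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STRANDS = ("+", "-", ".")

#: Closed vocabulary of functional-region annotations carried by a site.
REGION_CLASSES = (
    "missense",
    "synonymous",
    "nonsense",
    "utr5",
    "utr3",
    "intron",
    "noncoding",
    "splice",
    "unknown",
)


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class EditingSite:
    """A single genomic adenosine claimed to undergo A-to-I editing."""

    chrom: str
    pos: int
    strand: str = "."
    region: str = "unknown"
    tissue_derived: bool = True
    on_refseq: bool = True
    source: str = ""
    in_alu: bool = False

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.region not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region!r}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.strand)


@dataclass
class AluElement:
    """A repeat element interval, with family label and edited flag."""

    interval: GenomicInterval
    family: str = ""
    edited: bool = False

    @property
    def name(self) -> str:
        return self.interval.name or self.family


@dataclass
class GeneModel:
    """A gene with its ordered, non-overlapping exons on one chromosome."""

    gene_id: str
    strand: str
    exons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        chroms = {e.chrom for e in self.exons}
        if len(chroms) > 1:
            raise ValueError(f"gene {self.gene_id}: exons on multiple chromosomes")
        self.exons.sort(key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    def exonic_positions(self) -> set[int]:
        out: set[int] = set()
        for e in self.exons:
            out.update(range(e.start, e.end))
        return out


class ScoreTrack:
    """Sparse per-base score track (conservation scores and the like).

    Each covered position carries exactly one score; querying an uncovered
    position reports it as undefined. Internally one sorted position array
    and a parallel score array per chromosome.
    """

    def __init__(self) -> None:
        self._pos: dict[str, np.ndarray] = {}
        self._score: dict[str, np.ndarray] = {}

    @classmethod
    def from_positions(cls, per_chrom: dict[str, dict[int, float]]) -> "ScoreTrack":
        track = cls()
        for chrom, mapping in per_chrom.items():
            if not mapping:
                continue
            pos = np.fromiter(mapping.keys(), dtype=np.int64)
            order = np.argsort(pos)
            pos = pos[order]
            score = np.fromiter(mapping.values(), dtype=np.float64)[order]
            track._pos[chrom] = pos
            track._score[chrom] = score
        return track

    def chroms(self) -> list[str]:
        return sorted(self._pos)

    def n_covered(self) -> int:
        return sum(len(p) for p in self._pos.values())

    def get(self, chrom: str, pos: int):
        """Score at a position, or None when undefined."""
        arr = self._pos.get(chrom)
        if arr is None:
            return None
        i = np.searchsorted(arr, pos)
        if i < len(arr) and arr[i] == pos:
            return float(self._score[chrom][i])
        return None

    def get_many(self, chrom: str, positions) -> tuple[np.ndarray, np.ndarray]:
        """Vector lookup: (scores, defined-mask); undefined scores are NaN."""
        positions = np.asarray(positions, dtype=np.int64)
        scores = np.full(len(positions), np.nan)
        arr = self._pos.get(chrom)
        if arr is None or len(arr) == 0:
            return scores, np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(arr, positions)
        idx_clip = np.minimum(idx, len(arr) - 1)
        mask = arr[idx_clip] == positions
        scores[mask] = self._score[chrom][idx_clip[mask]]
        return scores, mask

    def iter_runs(self):
        """Yield (chrom, start, end, score) runs of equal consecutive scores."""
        for chrom in self.chroms():
            pos = self._pos[chrom]
            score = self._score[chrom]
            if len(pos) == 0:
                continue
            run_start = pos[0]
            prev = pos[0]
            val = score[0]
            for p, s in zip(pos[1:], score[1:]):
                if p == prev + 1 and s == val:
                    prev = p
                    continue
                yield chrom, int(run_start), int(prev) + 1, float(val)
                run_start = prev = p
                val = s
            yield chrom, int(run_start), int(prev) + 1, float(val)
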