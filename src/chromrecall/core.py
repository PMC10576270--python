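"""Core genomic value types shared by every pipeline stage.

All coordinates are 0-based, half-open (BED convention). 1-based coordinates
appear only in human-facing reports, never internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "TagLibrary",
    "GenomeLayout",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must be > start, got [{self.start}, {self.end}) on {self.chrom}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two half-open spans share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus its summit, signal and provenance.

    The summit is the single position used to center quantification windows
    and profile plots; it must lie inside the interval.
    """

    interval: GenomicInterval
    summit: int
    signal: float = 0.0
    source: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.signal < 0:
            raise ValueError(f"signal must be >= 0, got {self.signal}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


class TagLibrary:
    """One sequencing library's cut sites plus its depth-normalization factor.

    ``scale = 1e7 / total_unique_reads`` converts raw cut-site counts into
    depth-normalized tag units so that densities are comparable between
    libraries of different sequencing depth. ``total_unique_reads`` is
    alignment metadata (the post-filter unique read count) supplied by the
    caller; it is not inferred from the tag file, which may be a subset.
    """

    def __init__(
        self,
        name: str,
        cut_sites: Mapping[str, Iterable[int]],
        total_unique_reads: int,
    ) -> None:
        if total_unique_reads <= 0:
            raise ValueError(
                f"total_unique_reads must be positive, got {total_unique_reads}"
            )
        self.name = name
        # sorted arrays allow O(log n) window counts via searchsorted
        self._sites: Dict[str, np.ndarray] = {
            chrom: np.sort(np.asarray(list(pos), dtype=np.int64))
            for chrom, pos in cut_sites.items()
        }
        self.total_unique_reads = int(total_unique_reads)
        n_sites = sum(arr.size for arr in self._sites.values())
        if self.total_unique_reads < n_sites:
            raise ValueError(
                f"total_unique_reads ({self.total_unique_reads}) is smaller than "
                f"the number of loaded cut sites ({n_sites})"
            )

    @property
    def scale(self) -> float:
        """Depth-normalization factor, 1e7 / total unique reads."""
        return 1e7 / self.total_unique_reads

    @property
    def chroms(self) -> Iterator[str]:
        return iter(self._sites)

    def n_sites(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(self._sites.get(chrom, np.empty(0)).size)
        return int(sum(arr.size for arr in self._sites.values()))

    def sites(self, chrom: str) -> np.ndarray:
        """Sorted cut-site positions on one chromosome (empty if none)."""
        return self._sites.get(chrom, np.empty(0, dtype=np.int64))

    def count_in(self, chrom: str, start: int, end: int) -> int:
        """Number of cut sites with position in [start, end)."""
        arr = self.sites(chrom)
        return int(np.searchsorted(arr, end) - np.searchsorted(arr, start))

    def __repr__(self) -> str:
        return (
            f"TagLibrary({self.name!r}, {self.n_sites()} sites, "
            f"total_unique_reads={self.total_unique_reads})"
        )


class GenomeLayout:
    """Chromosome name -> length table used for clipping and validation."""

    def __init__(self, lengths: Mapping[str, int]) -> None:
        for chrom, length in lengths.items():
            if length <= 0:
                raise ValueError(f"length of {chrom} must be positive, got {length}")
        self.lengths: Dict[str, int] = dict(lengths)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    def __iter__(self) -> Iterator[str]:
        return iter(self.lengths)

    def contains_interval(self, iv: GenomicInterval) -> bool:
        return iv.chrom in self.lengths and iv.end <= self.lengths[iv.chrom]

    def clip(self, chrom: str, start: int, end: int) -> tuple[int, int]:
        """Clip [start, end) to the chromosome; raises if nothing remains."""
        if chrom not in self.lengths:
            raise KeyError(f"unknown chromosome {chrom!r}")
        s, e = max(0, start), min(self.lengths[chrom], end)
        if e <= s:
            raise ValueError(
                f"window [{start}, {end}) lies entirely off chromosome {chrom}"
            )
        return s, e
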