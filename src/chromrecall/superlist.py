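"""Union "superlist" of peaks across libraries.

Peak callers tuned to be conservative miss weak peaks; re-calling first
builds the union of every peak called in any library, then quantifies tag
density on that shared list. This module builds that union: overlapping
peaks (>= 1 shared base) are merged, bookended peaks are not, and each
merged peak gets a canonical summit taken from its highest-signal
contributor (leftmost summit on ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Mapping, Sequence, Tuple

from .core import GenomicInterval, Peak

__all__ = ["Superlist", "merge_intervals", "build_superlist"]


def merge_intervals(intervals: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    """Merge overlapping intervals into the minimal sorted disjoint cover.

    Half-open semantics: intervals sharing at least one base are merged;
    bookended intervals ([0,100) and [100,200)) stay separate.
    """
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged: List[Tuple[str, int, int]] = []
    cur_chrom, cur_start, cur_end = ordered[0].chrom, ordered[0].start, ordered[0].end
    for iv in ordered[1:]:
        if iv.chrom == cur_chrom and iv.start < cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append((cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    merged.append((cur_chrom, cur_start, cur_end))
    return [GenomicInterval(c, s, e) for c, s, e in merged]


@dataclass
class Superlist:
    """Merged cross-library peak list with per-peak provenance.

    ``peaks`` are sorted by (chrom, start) and pairwise disjoint.
    ``provenance[i]`` lists the (library, original peak name) contributors
    of ``peaks[i]``.
    """

    peaks: List[Peak]
    provenance: List[List[Tuple[str, str]]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def names(self) -> List[str]:
        return [p.name for p in self.peaks]


def build_superlist(peak_sets: Mapping[str, Sequence[Peak]]) -> Superlist:
    """Build the union superlist from per-library peak calls.

    Parameters
    ----------
    peak_sets
        Mapping of library name -> peaks called in that library. At least
        one library is required (it may have zero peaks).

    Returns
    -------
    Superlist
        Disjoint merged peaks named ``sl_<k>`` in genomic order. Each merged
        peak's summit is the summit of its highest-signal contributor, with
        the leftmost summit breaking ties; its signal is that contributor's
        signal.
    """
    if not peak_sets:
        raise ValueError("at least one library of peaks is required")
    tagged: List[Tuple[Peak, str, str]] = []
    for lib, peaks in peak_sets.items():
        for i, p in enumerate(peaks):
            tagged.append((p, lib, p.name or f"{lib}_{i}"))
    tagged.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end, t[1], t[2]))

    merged_peaks: List[Peak] = []
    provenance: List[List[Tuple[str, str]]] = []
    cluster: List[Tuple[Peak, str, str]] = []

    def flush() -> None:
        if not cluster:
            return
        chrom = cluster[0][0].chrom
        start = min(p.start for p, _, _ in cluster)
        end = max(p.end for p, _, _ in cluster)
        # canonical summit: highest signal wins, leftmost summit breaks ties
        best = max(cluster, key=lambda t: (t[0].signal, -t[0].summit))
        merged_peaks.append(
            Peak(
                interval=GenomicInterval(chrom, start, end),
                summit=best[0].summit,
                signal=best[0].signal,
                source="superlist",
                name=f"sl_{len(merged_peaks)}",
            )
        )
        provenance.append(sorted((lib, name) for _, lib, name in cluster))
        cluster.clear()

    cur_end = -1
    cur_chrom = None
    for entry in tagged:
        p = entry[0]
        if cluster and p.chrom == cur_chrom and p.start < cur_end:
            cluster.append(entry)
            cur_end = max(cur_end, p.end)
        else:
            flush()
            cluster.append(entry)
            cur_chrom, cur_end = p.chrom, p.end
    flush()
    return Superlist(peaks=merged_peaks, provenance=provenance)
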