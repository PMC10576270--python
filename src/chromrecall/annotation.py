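"""Peak-to-gene assignment by TSS proximity, and gene-set accounting.

A gene is assigned to a peak when its transcription start site lies within
10 kb of the peak interval (inclusive; distance 0 if the TSS falls inside
the peak). Strand is ignored; if a gene has several annotated TSSs, each is
supplied as its own record and all are used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import Peak
from .state_groups import CGROUPS, STATES, StateGroups

__all__ = [
    "GeneModel",
    "tss_within_window",
    "genes_for_group",
    "gene_set_overlap",
    "read_genes_bed",
    "write_genes_bed",
]

DEFAULT_TSS_WINDOW = 10_000


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")


def read_genes_bed(path: str) -> List[GeneModel]:
    """Read TSS records from BED: chrom, tss, tss+1, gene_id[, score, strand]."""
    genes: List[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 4:
                continue
            strand = fields[5] if len(fields) > 5 else "+"
            genes.append(GeneModel(fields[3], fields[0], int(fields[1]), strand))
    return genes


def write_genes_bed(genes: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.gene_id}\t0\t{g.strand}\n")


def tss_within_window(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    window: int = DEFAULT_TSS_WINDOW,
) -> pd.DataFrame:
    """Assign genes to peaks whose interval lies within ``window`` of the TSS.

    Distance is TSS-to-interval: 0 when the TSS falls inside the peak,
    otherwise the gap to the nearest peak base. The bound is inclusive. A
    peak may map to many genes and a gene to many peaks.

    Returns a DataFrame with columns peak, gene_id, distance (one row per
    assignment).
    """
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    sorted_tss: Dict[str, Tuple[np.ndarray, List[GeneModel]]] = {}
    for chrom, glist in by_chrom.items():
        glist.sort(key=lambda g: g.tss)
        sorted_tss[chrom] = (np.array([g.tss for g in glist]), glist)

    rows = []
    for i, peak in enumerate(peaks):
        if peak.chrom not in sorted_tss:
            continue
        tss_arr, glist = sorted_tss[peak.chrom]
        lo = int(np.searchsorted(tss_arr, peak.start - window))
        hi = int(np.searchsorted(tss_arr, peak.end - 1 + window, side="right"))
        for g in glist[lo:hi]:
            if g.tss < peak.start:
                dist = peak.start - g.tss
            elif g.tss >= peak.end:
                dist = g.tss - (peak.end - 1)
            else:
                dist = 0
            rows.append((peak.name or f"peak_{i}", g.gene_id, dist))
    return pd.DataFrame(rows, columns=["peak", "gene_id", "distance"])


def genes_for_group(
    groups: StateGroups, mapping: pd.DataFrame, group_label: str
) -> Set[str]:
    """Union of genes mapped to peaks carrying a state or C-group label."""
    frame = groups.to_frame()
    if group_label in STATES:
        members = frame.index[frame["state"] == group_label]
    elif group_label in CGROUPS:
        members = frame.index[frame["cgroup"] == group_label]
    else:
        raise ValueError(f"unknown group label {group_label!r}")
    hits = mapping[mapping["peak"].isin(set(members))]
    return set(hits["gene_id"])


def gene_set_overlap(set_a: Set[str], set_b: Set[str]) -> Tuple[int, int, int]:
    """Venn counts: (|A intersect B|, |A only|, |B only|)."""
    a, b = set(set_a), set(set_b)
    inter = len(a & b)
    return (inter, len(a) - inter, len(b) - inter)
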