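"""Cell-state partition of superlist peaks and TF-occupancy C-groups.

From the open/closed calls in the two terminal cell states, every peak gets
a state label: open in both (both_open), open only in the naive state
(naive_specific), open only in the primed state (primed_specific), or open
in neither (both_closed; possible after re-calling, retained but excluded
from state-set sizes). Intersecting the state-specific peaks with TF
ChIP-seq peaks yields the four dynamic groups:

* C1 - primed-specific, TF-bound
* C2 - primed-specific, unbound
* C3 - naive-specific, TF-bound (the closed-in-primed enhancers the TF
  occupies)
* C4 - naive-specific, unbound
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GenomicInterval, Peak

__all__ = [
    "STATES",
    "CGROUPS",
    "StateGroups",
    "partition_by_state",
    "intersect_chip",
    "group_summary",
]

STATES = ("both_open", "naive_specific", "primed_specific", "both_closed")
CGROUPS = ("C1", "C2", "C3", "C4", "none")


@dataclass
class StateGroups:
    """Per-peak state and C-group labels, aligned to the superlist order."""

    peak_names: List[str]
    state: pd.Series  # values in STATES
    cgroup: pd.Series  # values in CGROUPS

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"state": self.state, "cgroup": self.cgroup},
            index=pd.Index(self.peak_names, name="peak"),
        )


def partition_by_state(
    open_naive: Sequence[bool], open_primed: Sequence[bool]
) -> pd.Series:
    """Label each peak by which terminal state it is open in.

    Both inputs are per-peak open/closed calls over the same superlist, in
    the same order (e.g. two columns of the open/closed matrix).
    """
    a = np.asarray(open_naive, dtype=bool)
    b = np.asarray(open_primed, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    labels = np.where(
        a & b, "both_open", np.where(a, "naive_specific", np.where(b, "primed_specific", "both_closed"))
    )
    index = open_naive.index if isinstance(open_naive, pd.Series) else None
    return pd.Series(labels, index=index, name="state")


def intersect_chip(
    states: pd.Series,
    peaks: Sequence[Peak],
    chip_peaks: Sequence[GenomicInterval | Peak],
    min_overlap: int = 1,
) -> pd.Series:
    """Split state-specific peaks into C1-C4 by TF ChIP-peak overlap.

    A peak counts as TF-bound when it shares at least ``min_overlap`` bases
    with any ChIP peak. Peaks open in both or neither state get ``none``.
    """
    if len(states) != len(peaks):
        raise ValueError(f"length mismatch: {len(states)} states vs {len(peaks)} peaks")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: Dict[str, IntervalTree] = {}
    for cp in chip_peaks:
        iv = cp.interval if isinstance(cp, Peak) else cp
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    def bound(peak: Peak) -> bool:
        tree = trees.get(peak.chrom)
        if tree is None:
            return False
        for hit in tree.overlap(peak.start, peak.end):
            if min(peak.end, hit.end) - max(peak.start, hit.begin) >= min_overlap:
                return True
        return False

    labels = []
    for state, peak in zip(states, peaks):
        if state == "primed_specific":
            labels.append("C1" if bound(peak) else "C2")
        elif state == "naive_specific":
            labels.append("C3" if bound(peak) else "C4")
        else:
            labels.append("none")
    return pd.Series(labels, index=states.index, name="cgroup")


def group_summary(groups: StateGroups) -> Dict[str, int]:
    """Counts per state and per C-group, with the partition identities.

    Guaranteed: state counts sum to the superlist size, C1 + C2 equals the
    primed-specific count and C3 + C4 the naive-specific count.
    """
    state_counts = groups.state.value_counts()
    cgroup_counts = groups.cgroup.value_counts()
    out = {label: int(state_counts.get(label, 0)) for label in STATES}
    out.update({label: int(cgroup_counts.get(label, 0)) for label in CGROUPS[:4]})
    assert out["C1"] + out["C2"] == out["primed_specific"]
    assert out["C3"] + out["C4"] == out["naive_specific"]
    assert sum(out[s] for s in STATES) == len(groups.peak_names)
    return out
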