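"""Quantitative comparisons on accessibility and expression data.

Row-wise Z scores for relative dynamics across samples, Mann-Whitney U for
group comparisons, summit-centered pileup profiles, moving-average smoothing
over rank-ordered genes, fold-change screens, and the motif-table
post-filter (P < 0.01 and >= 1.5-fold target/background enrichment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .core import GenomeLayout, Peak, TagLibrary

__all__ = [
    "MannWhitneyResult",
    "MotifRecord",
    "zscore_rows",
    "mann_whitney_u",
    "pileup_profile",
    "moving_average_density",
    "fold_change_screen",
    "motif_filter",
]


def zscore_rows(matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Standardize each row to mean 0, sample SD 1 (ddof=1).

    Rows with zero spread map to all zeros. Arrays and DataFrames round-trip
    in kind. Requires at least two columns.
    """
    values = matrix.values if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("zscore_rows needs a matrix with >= 2 columns")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
    return z


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float  #: U statistic of the first sample: #{x_i > y_j} + 0.5 * ties
    p: float
    n_x: int
    n_y: int
    method: str  #: "exact" or "asymptotic"


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    method: str = "auto",
) -> MannWhitneyResult:
    """Mann-Whitney U test between two independent samples.

    ``method="auto"`` uses the exact null distribution when the combined
    sample size is at most 20 and there are no ties, and the normal
    approximation with tie and continuity corrections otherwise; ``"exact"``
    and ``"asymptotic"`` force either route.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    if method == "auto":
        method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = _sps.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return MannWhitneyResult(
        U=float(res.statistic), p=float(res.pvalue), n_x=x.size, n_y=y.size, method=method
    )


def pileup_profile(
    peaks: Sequence[Peak],
    tag_library: TagLibrary,
    halfwidth: int = 1000,
    bin_size: int = 50,
    genome: GenomeLayout | None = None,
) -> pd.Series:
    """Mean scaled cut-site density per bin across summit-centered windows.

    Bins tile ``[summit - halfwidth, summit + halfwidth)``; each bin value
    is the mean over peaks of scaled cut sites per base in that bin. The
    series index gives each bin's offset (left edge) from the summit.
    """
    if halfwidth % bin_size != 0:
        raise ValueError(f"halfwidth {halfwidth} is not a multiple of bin_size {bin_size}")
    if not peaks:
        raise ValueError("at least one peak is required")
    n_bins = 2 * halfwidth // bin_size
    totals = np.zeros(n_bins)
    for peak in peaks:
        arr = tag_library.sites(peak.chrom)
        edges = peak.summit - halfwidth + bin_size * np.arange(n_bins + 1)
        counts = np.diff(np.searchsorted(arr, edges))
        totals += counts
    profile = totals * tag_library.scale / bin_size / len(peaks)
    offsets = -halfwidth + bin_size * np.arange(n_bins)
    return pd.Series(profile, index=offsets, name=tag_library.name)


def moving_average_density(values: Sequence[float], window: int = 51) -> np.ndarray:
    """Centered moving average over rank-ordered values.

    The window must be odd; at the edges it is clipped to the available
    positions, so the smoothed vector has the input length. Used to smooth
    binding density over genes ranked by expression fold change.
    """
    values = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    if window > values.size:
        raise ValueError(f"window {window} exceeds input length {values.size}")
    return (
        pd.Series(values).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def fold_change_screen(
    expr_a: pd.Series,
    expr_b: pd.Series,
    fc_threshold: float = 1.0,
    pseudocount: float = 1.0,
    log2: bool = False,
) -> List[str]:
    """Genes more expressed in sample a than sample b by fold change.

    Keeps gene g iff ``(a_g + pc) / (b_g + pc) > fc_threshold`` (strict).
    With ``log2=True`` the threshold applies to the log2 ratio instead.
    Both series must share the same gene roster.
    """
    if set(expr_a.index) != set(expr_b.index):
        raise ValueError("expression samples must share the same gene roster")
    if (expr_a < 0).any() or (expr_b < 0).any():
        raise ValueError("expression values must be non-negative")
    b = expr_b.reindex(expr_a.index)
    ratio = (expr_a + pseudocount) / (b + pseudocount)
    stat = np.log2(ratio) if log2 else ratio
    return list(expr_a.index[stat > fc_threshold])


@dataclass(frozen=True)
class MotifRecord:
    """One row of a motif-enrichment table."""

    name: str
    p_value: float
    percent_target: float  # % of target regions carrying the motif
    percent_background: float  # % of background regions carrying the motif

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")
        for pct in (self.percent_target, self.percent_background):
            if not (0 <= pct <= 100):
                raise ValueError(f"percentage out of [0, 100]: {pct}")


def motif_filter(
    records: Iterable[MotifRecord],
    max_p: float = 0.01,
    min_ratio: float = 1.5,
) -> List[MotifRecord]:
    """Keep motifs with P below 0.01 and > 1.5-fold target enrichment.

    A motif absent from the background but present in targets has infinite
    enrichment and is kept (subject to the P cutoff); absent from both, it
    is dropped.
    """

    def enriched(r: MotifRecord) -> bool:
        if r.percent_background == 0:
            return r.percent_target > 0
        return r.percent_target / r.percent_background > min_ratio

    return [r for r in records if r.p_value < max_p and enriched(r)]
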