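"""Depth-normalized tag density per superlist peak and open/closed calls.

The classification statistic is the scaled tag density in a summit-centered
window: (cut sites in window) * (1e7 / total unique reads) / window length,
i.e. depth-normalized tags per base. A peak is annotated *open* in a library
when its density reaches the threshold and *closed* otherwise.

The default threshold, 0.2734 scaled tags per base, is a calibration
inherited from the original study's unit system; it is configuration, not a
constant, and should be re-tuned for data normalized differently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenomeLayout, Peak, TagLibrary
from .superlist import Superlist

__all__ = [
    "DEFAULT_THRESHOLD",
    "DEFAULT_WINDOW_HALFWIDTH",
    "AccessibilityMatrix",
    "peak_density",
    "build_matrix",
    "classify_open_closed",
]

#: Density cutoff (scaled tags per base) separating open from closed.
DEFAULT_THRESHOLD = 0.2734
#: Half-width of the summit-centered measurement window, in bases.
DEFAULT_WINDOW_HALFWIDTH = 150


@dataclass
class AccessibilityMatrix:
    """Peaks x libraries normalized tag densities.

    ``values`` is a DataFrame with peak names as rows and library names as
    columns, in roster order; ``window_halfwidth`` records the measurement
    window used.
    """

    values: pd.DataFrame
    window_halfwidth: int

    @property
    def peak_names(self) -> list:
        return list(self.values.index)

    @property
    def libraries(self) -> list:
        return list(self.values.columns)


def _window(peak: Peak, halfwidth: int, genome: GenomeLayout | None) -> tuple[int, int]:
    start, end = peak.summit - halfwidth, peak.summit + halfwidth
    if genome is not None:
        start, end = genome.clip(peak.chrom, start, end)
    else:
        start = max(0, start)
        if end <= start:
            raise ValueError(
                f"window around summit {peak.summit} on {peak.chrom} is empty"
            )
    return start, end


def peak_density(
    peak: Peak,
    tag_library: TagLibrary,
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
    genome: GenomeLayout | None = None,
) -> float:
    """Scaled tag density in the summit-centered window of one peak.

    The window ``[summit - w, summit + w)`` is clipped to the chromosome;
    density is computed over the clipped length. Raises if the window falls
    entirely off the chromosome.
    """
    if window_halfwidth <= 0:
        raise ValueError("window_halfwidth must be positive")
    start, end = _window(peak, window_halfwidth, genome)
    count = tag_library.count_in(peak.chrom, start, end)
    return count * tag_library.scale / (end - start)


def build_matrix(
    superlist: Superlist,
    tag_libraries: Sequence[TagLibrary],
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH,
    genome: GenomeLayout | None = None,
) -> AccessibilityMatrix:
    """Quantify every superlist peak in every library.

    Column order follows the library roster order.
    """
    if not tag_libraries:
        raise ValueError("at least one tag library is required")
    names = [lib.name for lib in tag_libraries]
    if len(set(names)) != len(names):
        raise ValueError("library names must be unique")
    data = np.empty((len(superlist), len(tag_libraries)))
    for j, lib in enumerate(tag_libraries):
        for i, peak in enumerate(superlist.peaks):
            data[i, j] = peak_density(peak, lib, window_halfwidth, genome)
    values = pd.DataFrame(data, index=superlist.names, columns=names)
    return AccessibilityMatrix(values=values, window_halfwidth=window_halfwidth)


def classify_open_closed(
    matrix: AccessibilityMatrix | pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Annotate each (peak, library) open (True) or closed (False).

    A density exactly at the threshold counts as open.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    values = matrix.values if isinstance(matrix, AccessibilityMatrix) else matrix
    return values >= threshold
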