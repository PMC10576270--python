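"""Synthetic multi-library ATAC/ChIP/expression data with ground truth.

The generator emulates the structure of a naive/primed pluripotency
time-course experiment: two terminal cell states plus intermediate
time-point libraries, regulatory loci open in one state, both, or neither,
a transcription factor bound at a configurable subset of the state-specific
loci, and a gene linked to each locus whose expression tracks the locus's
openness in each sample.

Tag counts per locus window are Poisson with mean set as a multiple of the
open/closed classification threshold, over a uniform genomic background;
time-point libraries interpolate each locus's expected density linearly
between its terminal-state values. Expression counts are negative binomial.
All draws come from one seeded NumPy generator, so outputs are
byte-identical given the same configuration.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as crio
from .accessibility import DEFAULT_THRESHOLD, DEFAULT_WINDOW_HALFWIDTH
from .annotation import GeneModel, write_genes_bed
from .core import GenomeLayout, GenomicInterval, Peak, TagLibrary
from .superlist import Superlist

__all__ = ["SimConfig", "SimulatedDataset", "simulate_dataset", "truth_report", "TruthReport"]

_CLASSES = ("both_open", "naive_specific", "primed_specific")


@dataclass
class SimConfig:
    """Study-condition parameters for the generator.

    Density multiples are expressed relative to the classification
    threshold: open loci default to 5x threshold and closed loci to 0.2x,
    with a uniform background at 0.05x threshold-equivalent density.
    ``timepoints`` are interpolation fractions (0 = naive, 1 = primed) for
    the transition libraries.
    """

    seed: int = 0
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000, "chr3": 2_000_000}
    )
    n_both_open: int = 50
    n_naive_specific: int = 100
    n_primed_specific: int = 100
    tf_bound_fraction: Dict[str, float] = field(
        default_factory=lambda: {"both_open": 0.0, "naive_specific": 0.3, "primed_specific": 0.4}
    )
    reads_per_library: int = 10_000_000
    threshold: float = DEFAULT_THRESHOLD
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH
    open_density_multiple: float = 5.0
    closed_density_multiple: float = 0.2
    background_density_multiple: float = 0.05
    timepoints: Tuple[float, ...] = (0.25, 0.5, 0.75)
    peak_width: int = 400
    chip_halfwidth: int = 100
    expr_high_mean: float = 100.0
    expr_low_mean: float = 5.0
    expr_dispersion: float = 0.1
    tss_offset: int = 2_000

    def __post_init__(self) -> None:
        for name in ("n_both_open", "n_naive_specific", "n_primed_specific"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_both_open + self.n_naive_specific + self.n_primed_specific == 0:
            raise ValueError("at least one locus is required")
        if not (self.open_density_multiple > 1 >= self.closed_density_multiple >= 0):
            raise ValueError("need open_density_multiple > 1 >= closed_density_multiple >= 0")
        for cls, frac in self.tf_bound_fraction.items():
            if not (0 <= frac <= 1):
                raise ValueError(f"tf_bound_fraction[{cls}] must be in [0, 1]")
        for f in self.timepoints:
            if not (0 <= f <= 1):
                raise ValueError("timepoints must be fractions in [0, 1]")

    @property
    def n_loci(self) -> int:
        return self.n_both_open + self.n_naive_specific + self.n_primed_specific

    @property
    def library_names(self) -> List[str]:
        mids = [f"t{int(round(100 * f)):02d}" for f in self.timepoints]
        return ["naive", *mids, "primed"]

    @property
    def scale(self) -> float:
        return 1e7 / self.reads_per_library


@dataclass
class SimulatedDataset:
    """In-memory simulation outputs plus the ground truth table."""

    config: SimConfig
    genome: GenomeLayout
    peak_sets: Dict[str, List[Peak]]
    tag_libraries: Dict[str, TagLibrary]
    tag_records: Dict[str, List[Tuple[str, int, int, str]]]
    chip_peaks: List[GenomicInterval]
    genes: List[GeneModel]
    expression: pd.DataFrame
    truth: pd.DataFrame

    @property
    def library_names(self) -> List[str]:
        return self.config.library_names

    def write(self, outdir: str) -> Dict[str, str]:
        """Serialize every output; returns a name -> path manifest."""
        os.makedirs(outdir, exist_ok=True)
        paths: Dict[str, str] = {}

        def reg(key: str, fname: str) -> str:
            paths[key] = os.path.join(outdir, fname)
            return paths[key]

        crio.write_chrom_sizes(self.genome, reg("chrom_sizes", "genome.chrom.sizes"))
        for lib in self.library_names:
            crio.write_peaks_bed(self.peak_sets[lib], reg(f"peaks_{lib}", f"peaks_{lib}.bed"))
            crio.write_tags_bed(self.tag_records[lib], reg(f"tags_{lib}", f"tags_{lib}.bed"))
        crio.write_peaks_bed(
            [
                Peak(iv, summit=(iv.start + iv.end) // 2, name=f"chip_{i}")
                for i, iv in enumerate(self.chip_peaks)
            ],
            reg("chip", "chip_peaks.bed"),
        )
        write_genes_bed(self.genes, reg("genes", "genes.bed"))
        crio.write_expression_tsv(self.expression, reg("expression", "expression.tsv"))
        self.truth.to_csv(reg("truth", "truth.tsv"), sep="\t", index=False)
        return paths


def _place_loci(cfg: SimConfig, rng: np.random.Generator) -> List[Tuple[str, int, int]]:
    """Lay loci across chromosomes, non-overlapping with wide spacing.

    Spacing between consecutive locus windows is at least twice the
    measurement window, so windows never bleed into each other and merged
    peak lists stay 1:1 with loci.
    """
    window = 2 * cfg.window_halfwidth
    stride = cfg.peak_width + 2 * window + window  # >= 2*window clearance + jitter room
    placements: List[Tuple[str, int, int]] = []
    chroms = list(cfg.chrom_lengths)
    per_chrom_capacity = {
        c: max(0, (cfg.chrom_lengths[c] - window) // stride) for c in chroms
    }
    if sum(per_chrom_capacity.values()) < cfg.n_loci:
        raise ValueError(
            f"{cfg.n_loci} loci do not fit the genome at stride {stride}; "
            "enlarge chromosomes or reduce locus count"
        )
    remaining = cfg.n_loci
    for c in chroms:
        take = min(remaining, per_chrom_capacity[c])
        jitter = rng.integers(0, window, size=take)
        for k in range(take):
            start = window + k * stride + int(jitter[k])
            placements.append((c, start, start + cfg.peak_width))
        remaining -= take
        if remaining == 0:
            break
    return placements


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Draw one complete synthetic dataset under the configured conditions."""
    rng = np.random.default_rng(cfg.seed)
    genome = GenomeLayout(cfg.chrom_lengths)
    window_len = 2 * cfg.window_halfwidth

    placements = _place_loci(cfg, rng)
    states = np.array(
        ["both_open"] * cfg.n_both_open
        + ["naive_specific"] * cfg.n_naive_specific
        + ["primed_specific"] * cfg.n_primed_specific
    )
    rng.shuffle(states)  # decouple state from genomic position

    # exact TF-bound counts per class: round(fraction * class size)
    tf_bound = np.zeros(cfg.n_loci, dtype=bool)
    for cls in _CLASSES:
        idx = np.flatnonzero(states == cls)
        k = int(round(cfg.tf_bound_fraction.get(cls, 0.0) * idx.size))
        if k > 0:
            tf_bound[rng.choice(idx, size=k, replace=False)] = True

    cgroup = np.where(
        states == "primed_specific",
        np.where(tf_bound, "C1", "C2"),
        np.where(states == "naive_specific", np.where(tf_bound, "C3", "C4"), "none"),
    )

    # expected density multiple per locus per library
    naive_mult = np.where(
        np.isin(states, ["both_open", "naive_specific"]),
        cfg.open_density_multiple,
        cfg.closed_density_multiple,
    )
    primed_mult = np.where(
        np.isin(states, ["both_open", "primed_specific"]),
        cfg.open_density_multiple,
        cfg.closed_density_multiple,
    )
    fractions = [0.0, *cfg.timepoints, 1.0]
    lib_mult = {
        lib: (1 - f) * naive_mult + f * primed_mult
        for lib, f in zip(cfg.library_names, fractions)
    }

    loci = [
        {
            "locus": f"locus_{i}",
            "chrom": c,
            "start": s,
            "end": e,
            "summit": (s + e) // 2,
            "state": states[i],
            "tf_bound": bool(tf_bound[i]),
            "cgroup": cgroup[i],
            "gene_id": f"g_{i}",
        }
        for i, (c, s, e) in enumerate(placements)
    ]

    peak_sets: Dict[str, List[Peak]] = {}
    tag_libraries: Dict[str, TagLibrary] = {}
    tag_records: Dict[str, List[Tuple[str, int, int, str]]] = {}
    true_open: Dict[str, np.ndarray] = {}

    for lib in cfg.library_names:
        mults = lib_mult[lib]
        open_here = mults > 1.0  # expected density above threshold
        true_open[lib] = open_here
        peak_sets[lib] = [
            Peak(
                interval=GenomicInterval(L["chrom"], L["start"], L["end"]),
                summit=L["summit"],
                signal=float(mults[i]),
                source=lib,
                name=L["locus"],
            )
            for i, L in enumerate(loci)
            if open_here[i]
        ]
        sites: Dict[str, List[int]] = {c: [] for c in cfg.chrom_lengths}
        # locus tags: Poisson counts uniform within the summit-centered window
        for i, L in enumerate(loci):
            mean = mults[i] * cfg.threshold * window_len / cfg.scale
            count = int(rng.poisson(mean))
            if count:
                lo = L["summit"] - cfg.window_halfwidth
                sites[L["chrom"]].extend(
                    int(p) for p in rng.integers(lo, lo + window_len, size=count)
                )
        # uniform background across each chromosome
        for c, length in cfg.chrom_lengths.items():
            mean = cfg.background_density_multiple * cfg.threshold * length / cfg.scale
            count = int(rng.poisson(mean))
            if count:
                sites[c].extend(int(p) for p in rng.integers(0, length, size=count))
        tag_libraries[lib] = TagLibrary(lib, sites, cfg.reads_per_library)
        tag_records[lib] = [
            (c, p, p + 1, "+") for c in cfg.chrom_lengths for p in sorted(sites[c])
        ]

    chip_peaks = [
        GenomicInterval(
            L["chrom"],
            max(0, L["summit"] - cfg.chip_halfwidth),
            L["summit"] + cfg.chip_halfwidth,
        )
        for L in loci
        if L["tf_bound"]
    ]

    genes: List[GeneModel] = []
    for L in loci:
        tss = L["end"] + cfg.tss_offset
        if tss >= cfg.chrom_lengths[L["chrom"]]:
            tss = max(0, L["start"] - cfg.tss_offset)
        genes.append(GeneModel(L["gene_id"], L["chrom"], tss))

    # expression: NB(mean high when the locus is open in that sample)
    n_disp = 1.0 / cfg.expr_dispersion
    expr = {}
    for lib in cfg.library_names:
        means = np.where(true_open[lib], cfg.expr_high_mean, cfg.expr_low_mean)
        p = n_disp / (n_disp + means)
        expr[lib] = rng.negative_binomial(n_disp, p)
    expression = pd.DataFrame(expr, index=[L["gene_id"] for L in loci])
    expression.index.name = "gene_id"

    truth = pd.DataFrame(loci)
    for lib in cfg.library_names:
        truth[f"open_{lib}"] = true_open[lib]

    return SimulatedDataset(
        config=cfg,
        genome=genome,
        peak_sets=peak_sets,
        tag_libraries=tag_libraries,
        tag_records=tag_records,
        chip_peaks=chip_peaks,
        genes=genes,
        expression=expression,
        truth=truth,
    )


@dataclass
class TruthReport:
    """Stage-by-stage comparison of pipeline output against planted truth."""

    open_closed_confusion: pd.DataFrame
    open_closed_accuracy: float
    state_confusion: Optional[pd.DataFrame] = None
    state_accuracy: Optional[float] = None
    cgroup_confusion: Optional[pd.DataFrame] = None
    cgroup_accuracy: Optional[float] = None
    gene_jaccard: Optional[Dict[str, float]] = None
    n_unmatched_peaks: int = 0

    @property
    def exact(self) -> Dict[str, bool]:
        out = {"open_closed": self.open_closed_accuracy == 1.0}
        if self.state_accuracy is not None:
            out["state"] = self.state_accuracy == 1.0
        if self.cgroup_accuracy is not None:
            out["cgroup"] = self.cgroup_accuracy == 1.0
        return out


def _match_loci(truth: pd.DataFrame, superlist: Superlist) -> List[Optional[str]]:
    """Map each superlist peak to the truth locus it overlaps (or None)."""
    by_chrom: Dict[str, List[Tuple[int, int, str]]] = {}
    for row in truth.itertuples():
        by_chrom.setdefault(row.chrom, []).append((row.start, row.end, row.locus))
    for spans in by_chrom.values():
        spans.sort()
    matches: List[Optional[str]] = []
    for peak in superlist.peaks:
        hit = None
        for s, e, locus in by_chrom.get(peak.chrom, []):
            if peak.start < e and s < peak.end:
                if hit is not None:
                    raise ValueError(f"superlist peak {peak.name} overlaps two loci")
                hit = locus
        matches.append(hit)
    return matches


def truth_report(
    truth: pd.DataFrame,
    superlist: Superlist,
    open_closed: pd.DataFrame,
    state_labels: Optional[pd.Series] = None,
    cgroup_labels: Optional[pd.Series] = None,
    gene_sets: Optional[Dict[str, set]] = None,
) -> TruthReport:
    """Confusion matrices and exact-match flags for a pipeline run.

    Superlist peaks are matched to truth loci by interval overlap; peaks
    overlapping no locus (background false peaks) are excluded from the
    confusion matrices but counted in ``n_unmatched_peaks``.
    """
    matches = _match_loci(truth, superlist)
    matched = [(name, loc) for name, loc in zip(superlist.names, matches) if loc is not None]
    if not matched:
        raise ValueError("no superlist peak matches any truth locus (id mismatch?)")
    peak_names = [m[0] for m in matched]
    locus_ids = [m[1] for m in matched]
    tr = truth.set_index("locus").loc[locus_ids]

    pred_oc, true_oc = [], []
    for lib in open_closed.columns:
        col = f"open_{lib}"
        if col not in tr.columns:
            raise ValueError(f"truth table lacks column {col}")
        pred_oc.append(open_closed.loc[peak_names, lib].to_numpy())
        true_oc.append(tr[col].to_numpy())
    pred_flat = np.concatenate(pred_oc)
    true_flat = np.concatenate(true_oc)
    oc_conf = pd.crosstab(
        pd.Series(true_flat, name="truth"), pd.Series(pred_flat, name="called")
    )
    report = TruthReport(
        open_closed_confusion=oc_conf,
        open_closed_accuracy=float((pred_flat == true_flat).mean()),
        n_unmatched_peaks=sum(loc is None for loc in matches),
    )

    if state_labels is not None:
        pred = state_labels.loc[peak_names].to_numpy()
        true = tr["state"].to_numpy()
        report.state_confusion = pd.crosstab(
            pd.Series(true, name="truth"), pd.Series(pred, name="called")
        )
        report.state_accuracy = float((pred == true).mean())
    if cgroup_labels is not None:
        pred = cgroup_labels.loc[peak_names].to_numpy()
        true = tr["cgroup"].to_numpy()
        report.cgroup_confusion = pd.crosstab(
            pd.Series(true, name="truth"), pd.Series(pred, name="called")
        )
        report.cgroup_accuracy = float((pred == true).mean())
    if gene_sets is not None:
        jac = {}
        for label, predicted in gene_sets.items():
            col = "cgroup" if label.startswith("C") else "state"
            true_genes = set(truth.loc[truth[col] == label, "gene_id"])
            union = predicted | true_genes
            jac[label] = float(len(predicted & true_genes) / len(union)) if union else 1.0
        report.gene_jaccard = jac
    return report
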