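"""End-to-end orchestration: superlist -> densities -> states -> statistics.

`run_pipeline` executes the stages in order, serializes every stage's
output under one run directory, and writes a machine-readable manifest
(parameters, input checksums, per-stage row counts, output checksums).
Deterministic stages are bit-identical across reruns with the same inputs
and configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import pandas as pd
import yaml

from . import io as crio
from .accessibility import (
    DEFAULT_THRESHOLD,
    DEFAULT_WINDOW_HALFWIDTH,
    build_matrix,
    classify_open_closed,
)
from .annotation import DEFAULT_TSS_WINDOW, genes_for_group, read_genes_bed, tss_within_window
from .state_groups import (
    CGROUPS,
    StateGroups,
    group_summary,
    intersect_chip,
    partition_by_state,
)
from .stats import mann_whitney_u, zscore_rows
from .superlist import Superlist, build_superlist

__all__ = ["LibrarySpec", "PipelineConfig", "PipelineError", "run_pipeline", "report"]


@dataclass
class LibrarySpec:
    """Paths and metadata for one ATAC-seq library."""

    name: str
    peaks: str  # BED of called peaks
    tags: str  # BED of cut-site records
    total_unique_reads: int


@dataclass
class PipelineConfig:
    libraries: List[LibrarySpec]
    naive_library: str
    primed_library: str
    chrom_sizes: str
    chip_peaks: Optional[str] = None
    genes: Optional[str] = None
    expression: Optional[str] = None
    outdir: str = "chromrecall_run"
    window_halfwidth: int = DEFAULT_WINDOW_HALFWIDTH
    threshold: float = DEFAULT_THRESHOLD
    min_overlap: int = 1
    tss_window: int = DEFAULT_TSS_WINDOW
    #: Mann-Whitney contrasts as (group_a, group_b, library) label triples
    contrasts: List[Tuple[str, str, str]] = field(default_factory=list)
    exclude_chroms: List[str] = field(default_factory=lambda: ["chrM"])
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["libraries"] = [LibrarySpec(**lib) for lib in raw["libraries"]]
        raw["contrasts"] = [tuple(c) for c in raw.get("contrasts", [])]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["contrasts"] = [list(c) for c in self.contrasts]
        return d


class PipelineError(RuntimeError):
    """A stage failure; carries the name of the failing stage."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> str:
    """Run every stage; returns the run directory path.

    On stage failure a ``FAILED`` marker naming the stage is left in the
    run directory alongside any partial outputs, and a
    :class:`PipelineError` is raised.
    """
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "inputs": {},
        "stages": {},
        "outputs": {},
    }
    stage = "setup"
    try:
        stage = "load"
        genome = crio.read_chrom_sizes(config.chrom_sizes)
        manifest["inputs"][config.chrom_sizes] = _sha256(config.chrom_sizes)
        exclude = set(config.exclude_chroms)
        peak_sets = {}
        tag_libraries = []
        names = [lib.name for lib in config.libraries]
        if config.naive_library not in names or config.primed_library not in names:
            raise ValueError("naive/primed library names must be in the roster")
        for lib in config.libraries:
            peak_sets[lib.name] = crio.filter_chromosomes(
                crio.read_peaks_bed(lib.peaks, lib.name), exclude
            )
            tags = crio.read_tags(lib.tags, lib.total_unique_reads, lib.name)
            tag_libraries.append(tags)
            manifest["inputs"][lib.peaks] = _sha256(lib.peaks)
            manifest["inputs"][lib.tags] = _sha256(lib.tags)

        stage = "superlist"
        sl = build_superlist(peak_sets)
        _write_superlist(sl, outdir)
        manifest["stages"]["superlist"] = {"n_peaks": len(sl)}

        stage = "accessibility"
        matrix = build_matrix(sl, tag_libraries, config.window_halfwidth, genome)
        matrix.values.to_csv(
            os.path.join(outdir, "density.tsv"),
            sep="\t",
            index_label="peak # scaled tags per base, summit +/- %d" % config.window_halfwidth,
        )
        manifest["stages"]["accessibility"] = {
            "n_peaks": len(sl),
            "n_libraries": len(tag_libraries),
        }

        stage = "classify"
        oc = classify_open_closed(matrix, config.threshold)
        oc.astype(int).to_csv(
            os.path.join(outdir, "open_closed.tsv"),
            sep="\t",
            index_label="peak # 1 = open (density >= %r)" % config.threshold,
        )
        manifest["stages"]["classify"] = {"n_open_calls": int(oc.values.sum())}

        stage = "states"
        state = partition_by_state(oc[config.naive_library], oc[config.primed_library])
        stage = "cgroups"
        if config.chip_peaks:
            chip = crio.filter_chromosomes(
                crio.read_peaks_bed(config.chip_peaks, "chip"), exclude
            )
            manifest["inputs"][config.chip_peaks] = _sha256(config.chip_peaks)
            cgroup = intersect_chip(state, sl.peaks, chip, config.min_overlap)
        else:
            cgroup = pd.Series(["none"] * len(sl), index=state.index, name="cgroup")
        groups = StateGroups(peak_names=sl.names, state=state, cgroup=cgroup)
        _write_groups(sl, groups, outdir)
        summary = group_summary(groups)
        with open(os.path.join(outdir, "group_summary.json"), "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        manifest["stages"]["cgroups"] = summary

        stage = "stats"
        zscore_rows(matrix.values).to_csv(
            os.path.join(outdir, "zscores.tsv"),
            sep="\t",
            index_label="peak # row-wise Z score (sample SD)",
        )
        results = []
        frame = groups.to_frame()
        for group_a, group_b, lib_name in config.contrasts:
            xa = matrix.values.loc[_group_members(frame, group_a), lib_name]
            xb = matrix.values.loc[_group_members(frame, group_b), lib_name]
            res = mann_whitney_u(xa, xb)
            results.append(
                {
                    "group_a": group_a,
                    "group_b": group_b,
                    "library": lib_name,
                    "U": res.U,
                    "p": res.p,
                    "n_a": res.n_x,
                    "n_b": res.n_y,
                    "method": res.method,
                }
            )
        with open(os.path.join(outdir, "mann_whitney.json"), "w") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
        manifest["stages"]["stats"] = {"n_contrasts": len(results)}

        stage = "annotation"
        if config.genes:
            genes = read_genes_bed(config.genes)
            manifest["inputs"][config.genes] = _sha256(config.genes)
            mapping = tss_within_window(sl.peaks, genes, config.tss_window)
            mapping.to_csv(os.path.join(outdir, "peak_gene_map.tsv"), sep="\t", index=False)
            for label in CGROUPS[:4]:
                gene_set = genes_for_group(groups, mapping, label)
                with open(os.path.join(outdir, f"genes_{label}.txt"), "w") as fh:
                    fh.write("".join(f"{g}\n" for g in sorted(gene_set)))
            manifest["stages"]["annotation"] = {"n_assignments": len(mapping)}

        stage = "manifest"
        for fname in sorted(os.listdir(outdir)):
            fpath = os.path.join(outdir, fname)
            if fname not in ("manifest.json", "FAILED") and os.path.isfile(fpath):
                manifest["outputs"][fname] = _sha256(fpath)
        with open(os.path.join(outdir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    except Exception as exc:
        with open(os.path.join(outdir, "FAILED"), "w") as fh:
            fh.write(f"{stage}\n{exc}\n")
        raise PipelineError(stage, str(exc)) from exc
    failed = os.path.join(outdir, "FAILED")
    if os.path.exists(failed):
        os.remove(failed)
    return outdir


def _group_members(frame: pd.DataFrame, label: str) -> pd.Index:
    col = "cgroup" if label in CGROUPS else "state"
    members = frame.index[frame[col] == label]
    if members.empty:
        raise ValueError(f"group {label!r} has no peaks")
    return members


def _write_superlist(sl: Superlist, outdir: str) -> None:
    crio.write_peaks_bed(sl.peaks, os.path.join(outdir, "superlist.bed"))
    with open(os.path.join(outdir, "superlist_provenance.tsv"), "w") as fh:
        fh.write("peak\tlibrary\tsource_peak\n")
        for peak, contributors in zip(sl.peaks, sl.provenance):
            for lib, src in contributors:
                fh.write(f"{peak.name}\t{lib}\t{src}\n")


def _write_groups(sl: Superlist, groups: StateGroups, outdir: str) -> None:
    with open(os.path.join(outdir, "state_groups.bed"), "w") as fh:
        for peak, state, cgroup in zip(sl.peaks, groups.state, groups.cgroup):
            fh.write(
                f"{peak.chrom}\t{peak.start}\t{peak.end}\t{peak.name}\t"
                f"{peak.signal!r}\t.\t{state}\t{cgroup}\n"
            )


def report(run_dir: str) -> dict:
    """Summaries of a completed run: counts, density quartiles, test results.

    Reads the serialized stage outputs, so it can run long after the
    pipeline. Raises if the run failed or is incomplete.
    """
    failed = os.path.join(run_dir, "FAILED")
    if os.path.exists(failed):
        with open(failed) as fh:
            raise PipelineError(fh.readline().strip() or "unknown", "run is marked FAILED")
    needed = ["group_summary.json", "density.tsv", "state_groups.bed", "manifest.json"]
    for fname in needed:
        if not os.path.exists(os.path.join(run_dir, fname)):
            raise PipelineError("report", f"missing output {fname}; run incomplete")

    with open(os.path.join(run_dir, "group_summary.json")) as fh:
        counts = json.load(fh)
    density = pd.read_csv(os.path.join(run_dir, "density.tsv"), sep="\t", index_col=0)
    labels = pd.read_csv(
        os.path.join(run_dir, "state_groups.bed"),
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "peak", "signal", "strand", "state", "cgroup"],
    ).set_index("peak")

    quartiles: dict = {}
    for label in CGROUPS[:4]:
        members = labels.index[labels["cgroup"] == label]
        if members.empty:
            continue
        sub = density.loc[members]
        quartiles[label] = {
            lib: [float(q) for q in sub[lib].quantile([0.25, 0.5, 0.75])]
            for lib in density.columns
        }

    out = {"counts": counts, "density_quartiles": quartiles}
    mw_path = os.path.join(run_dir, "mann_whitney.json")
    if os.path.exists(mw_path):
        with open(mw_path) as fh:
            mw = json.load(fh)
        if mw:
            out["mann_whitney"] = mw
    with open(os.path.join(run_dir, "report.json"), "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
    return out
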