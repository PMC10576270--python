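# Methods

## Re-calling model

The unit of analysis is the *superlist peak*: the union of peak calls across
all libraries, merged wherever calls share at least one base. Half-open BED
coordinates are used throughout, so bookended peaks (`[0,100)`, `[100,200)`)
are distinct. Each merged peak's canonical summit is the summit of its
highest-signal contributing call, with the leftmost summit breaking ties —
a deterministic rule chosen because any single-position summit inside the
merged span is defensible and reproducibility matters more than the choice.

Accessibility of a peak in a library is its depth-normalized tag density in
a summit-centered window:

```
density = n_cut_sites([summit - w, summit + w)) * (1e7 / total_unique_reads) / (2w)
```

in scaled tags per base. Defaults and their reasoning:

- **Window half-width `w` = 150 bases** (300-base window). The density is a
  per-peak statistic and heatmap displays of such data are summit-centered;
  300 bases spans the typical nucleosome-free region an ATAC peak reports
  without bleeding into flanking background. Configurable
  (`window_halfwidth`). Windows are clipped at chromosome edges and the
  density computed over the clipped length; a window entirely off its
  chromosome is an error.
- **Threshold = 0.2734 scaled tags per base.** This cutoff separates open
  from closed. It is a calibration inherited from the unit system of the
  analysis the package reimplements and is deliberately exposed as
  configuration, not a constant: data normalized differently needs a
  re-tuned value. A density exactly at the threshold counts as open (the
  open/closed rule is stated as below-vs-above; equality had to be assigned
  to one side and the open side keeps the "recover weak peaks" intent).
- **Cut site = 5' end of each tag record** (`start` on the + strand,
  `end - 1` on the -), with no Tn5 +4/−5 shift: offsets, if wanted, are
  assumed applied upstream. `total_unique_reads` is alignment metadata
  supplied by the caller, not inferred from the tag file, because tag files
  may be filtered subsets of the alignment the depth factor refers to.

State labels come from the two terminal libraries only:
(open, open) → `both_open`, (open, closed) → `naive_specific`,
(closed, open) → `primed_specific`, (closed, closed) → `both_closed`.
`both_closed` peaks — possible after re-calling since the superlist includes
every called peak — are retained in outputs but excluded from state-set
sizes. TF occupancy uses interval overlap of at least `min_overlap` bases
(default 1) between the superlist peak and any ChIP peak; summit containment
was the alternative, but boundary overlap is the weakest reproducible rule
and the parameter makes stricter choices available.

## Statistics

- **Row-wise Z scores** use the sample SD (ddof = 1); rows with zero spread
  map to all zeros rather than NaN.
- **Mann–Whitney U** reports `U = #{x_i > y_j} + 0.5 #ties` for the first
  sample. The exact null distribution is used when the pooled sample size
  is ≤ 20 with no ties, otherwise the normal approximation with tie and
  continuity corrections (both routes can be forced). The computation is
  delegated to scipy; the test suite checks it against an independent
  pair-count and full-enumeration oracle.
- **Pileup profiles** are mean scaled cut sites per base per bin over
  summit-centered windows; bins must tile the window exactly.
- **Moving average** over rank-ordered values uses a centered window
  (odd length, default 51 genes) clipped at the edges, so the output keeps
  the input length. 51 is a smoothing choice for ~10^3-gene rankings; no
  principled value exists and it is a parameter.
- **Fold-change screen** keeps gene g iff
  `(a_g + 1)/(b_g + 1) > threshold` with strict inequality, default
  threshold 1 on the linear scale (any increase passes). The pseudocount
  of 1 avoids division by zero on count-like expression units. A `log2`
  switch applies the threshold to the log2 ratio instead, since "fold
  change > 1" is ambiguous between the two conventions; linear is the
  documented default.
- **Motif filter** keeps records with `p < 0.01` and
  `percent_target / percent_background > 1.5`, both strict; a motif absent
  from the background but present in targets has infinite enrichment and is
  kept, absent from both it is dropped.
- **Peak-to-gene assignment** links a gene to a peak when the TSS-to-interval
  distance is ≤ 10 kb (inclusive, GREAT-style; distance 0 inside the peak).
  Strand is ignored and every supplied TSS of a multi-TSS gene is used.

## Synthetic data

The generator emulates a two-terminal-state (naive/primed) time course:
loci of three classes (`both_open`, `naive_specific`, `primed_specific`)
placed non-overlapping with at least two window-lengths of clearance, a TF
bound at an exact per-class fraction of loci, and one gene per locus with a
TSS 2 kb from the locus.

- **Tag model.** Per locus, per library, the window tag count is Poisson
  with mean `density_multiple × threshold × window_length / scale`;
  positions are uniform within the window. Open loci default to 5× the
  threshold and closed loci to 0.2×, over a uniform genomic background at
  0.05× threshold-equivalent density. Time-point libraries interpolate each
  locus's expected multiple linearly between its terminal values at
  fractions 0.25/0.5/0.75. A locus's *true* open call in a library is
  `multiple > 1` (expected density above threshold).
- **Expression model.** Negative binomial, dispersion 0.1, mean 100 when
  the linked locus is open in that sample and 5 otherwise — count-like
  units with realistic overdispersion.
- **Defaults** (50/100/100 loci, TF fractions 0.3/0.4 on the specific
  classes, 10^7 unique reads per library so the scale factor is 1) are the
  package's fixed study conditions; the planted C-groups are then
  C1:40, C2:60, C3:30, C4:70.
- **Determinism.** One `numpy.random.default_rng(seed)` stream threads
  through all draws; identical configs produce byte-identical files.

What the generator does *not* model: fragment-length structure, Tn5
sequence bias, GC effects, replicate variance, copy-number or mappability
artifacts, and correlated noise between neighboring loci. Passing tests
therefore demonstrate that the pipeline's logic recovers planted structure
under idealized count noise — not that the default threshold or window is
optimal for any particular real dataset.

## Pipeline

`run_pipeline` executes load → superlist → accessibility → classify →
states → cgroups → stats → annotation, serializing each stage (BED/TSV/
JSON, headers naming units) and writing a manifest of parameters, input
SHA-256 checksums, stage row counts and output checksums. Any stage error
aborts with the failing stage named and leaves a `FAILED` marker beside the
partial outputs. All stages are deterministic, so reruns on identical
inputs are bit-identical (the manifest differs only where it embeds paths).

## Problem sizes

Tests and the acceptance script run on desk-scale genomes (2–6 Mb over 2–3
chromosomes, 80–500 loci, ~10^5 tags per library), sizes at which the
brute-force oracles (per-base union masks, all-pairs distance scans,
enumeration of rank assignments) remain exact and fast while every code
path of the full-scale analysis is exercised.

## Known limitations

- The threshold's unit system travels with the 1e7-reads scale convention;
  users normalizing otherwise must re-calibrate.
- Superlist merging can chain overlapping peaks into long spans; no
  sub-peak deconvolution is attempted.
- Mann–Whitney p-values are reported raw; the intended use is single
  planned contrasts, not genome-wide screening with multiplicity control.
- The open/closed call is per-library and thresholded; no uncertainty or
  replicate-variance model is attached to it.
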