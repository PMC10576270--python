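"""Superlist re-calling: union peak list, tag densities, open/closed calls.

Simulates a small naive/primed dataset, merges every library's peak calls
into one superlist, measures depth-normalized tag density per peak per
library and annotates open/closed at the 0.2734 tags-per-base threshold.
"""

from chromrecall import (
    SimConfig,
    build_matrix,
    build_superlist,
    classify_open_closed,
    simulate_dataset,
)

ds = simulate_dataset(SimConfig(seed=1))
sl = build_superlist(ds.peak_sets)
libs = [ds.tag_libraries[name] for name in ds.library_names]
matrix = build_matrix(sl, libs, genome=ds.genome)
open_closed = classify_open_closed(matrix)

print(f"superlist peaks: {len(sl)} (from {sum(len(p) for p in ds.peak_sets.values())} "
      "per-library calls)")
print("open peaks per library (weak peaks recovered on the shared list):")
for lib in ds.library_names:
    called = len(ds.peak_sets[lib])
    recalled = int(open_closed[lib].sum())
    print(f"  {lib:>7}: {called} called -> {recalled} open after re-calling")
print("\nFirst 3 superlist peaks, density per library (scaled tags/base):")
print(matrix.values.head(3).round(3).to_string())
# A density above 0.2734 means the locus is accessible (open chromatin) in
# that library; the re-called open counts track each library's true state.
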