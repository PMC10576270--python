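import filecmp
import os

import numpy as np
import pandas as pd
import pytest

from chromrecall.accessibility import build_matrix, classify_open_closed
from chromrecall.simulate import SimConfig, simulate_dataset, truth_report
from chromrecall.state_groups import intersect_chip, partition_by_state
from chromrecall.superlist import build_superlist


def small_config(**kw):
    defaults = dict(
        seed=3,
        chrom_lengths={"chr1": 400_000, "chr2": 400_000},
        n_both_open=20,
        n_naive_specific=40,
        n_primed_specific=40,
        timepoints=(0.5,),
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def classify_dataset(ds):
    sl = build_superlist(ds.peak_sets)
    libs = [ds.tag_libraries[n] for n in ds.library_names]
    matrix = build_matrix(sl, libs, ds.config.window_halfwidth, ds.genome)
    oc = classify_open_closed(matrix, ds.config.threshold)
    return sl, oc


class TestDeterminism:
    def test_same_seed_reproduces_everything_in_memory(self):
        d1, d2 = simulate_dataset(small_config()), simulate_dataset(small_config())
        pd.testing.assert_frame_equal(d1.truth, d2.truth)
        pd.testing.assert_frame_equal(d1.expression, d2.expression)
        assert d1.tag_records == d2.tag_records
        assert d1.chip_peaks == d2.chip_peaks

    def test_same_seed_writes_byte_identical_files(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        simulate_dataset(small_config()).write(str(a))
        simulate_dataset(small_config()).write(str(b))
        for fname in sorted(os.listdir(a)):
            assert filecmp.cmp(a / fname, b / fname, shallow=False), fname

    def test_different_seeds_differ(self):
        d1 = simulate_dataset(small_config(seed=1))
        d2 = simulate_dataset(small_config(seed=2))
        assert d1.tag_records != d2.tag_records


class TestConfigValidation:
    def test_loci_must_fit_genome(self):
        with pytest.raises(ValueError, match="fit"):
            simulate_dataset(small_config(chrom_lengths={"chr1": 10_000}))

    def test_density_multiple_ordering_enforced(self):
        with pytest.raises(ValueError):
            small_config(open_density_multiple=0.9)
        with pytest.raises(ValueError):
            small_config(closed_density_multiple=1.5)

    def test_fractions_bounded(self):
        with pytest.raises(ValueError):
            small_config(tf_bound_fraction={"naive_specific": 1.2})
        with pytest.raises(ValueError):
            small_config(timepoints=(1.5,))


class TestGeneratorMarginals:
    def test_open_locus_tag_counts_match_poisson_mean(self):
        """Realized mean tag count per open-locus window within 3 SE of target."""
        cfg = SimConfig(seed=5, n_both_open=200, n_naive_specific=1, n_primed_specific=1)
        ds = simulate_dataset(cfg)
        w = cfg.window_halfwidth
        mean_target = cfg.open_density_multiple * cfg.threshold * 2 * w / cfg.scale
        lib = ds.tag_libraries["naive"]
        open_rows = ds.truth[ds.truth["state"] == "both_open"]
        counts = [
            lib.count_in(r.chrom, r.summit - w, r.summit + w)
            for r in open_rows.itertuples()
        ]
        # background adds a small positive extra inside the window
        background = cfg.background_density_multiple * cfg.threshold * 2 * w / cfg.scale
        se = np.sqrt(mean_target / len(counts))
        assert abs(np.mean(counts) - (mean_target + background)) < 3 * se

    def test_truth_state_counts_match_config(self, default_dataset):
        counts = default_dataset.truth["state"].value_counts()
        cfg = default_dataset.config
        assert counts["both_open"] == cfg.n_both_open
        assert counts["naive_specific"] == cfg.n_naive_specific
        assert counts["primed_specific"] == cfg.n_primed_specific

    def test_tf_bound_counts_are_exact(self, default_dataset):
        truth = default_dataset.truth
        assert (truth["cgroup"] == "C1").sum() == 40
        assert (truth["cgroup"] == "C2").sum() == 60
        assert (truth["cgroup"] == "C3").sum() == 30
        assert (truth["cgroup"] == "C4").sum() == 70


class TestRecovery:
    def test_noiseless_classification_is_perfect(self, noiseless_dataset):
        sl, oc = classify_dataset(noiseless_dataset)
        rep = truth_report(noiseless_dataset.truth, sl, oc)
        assert rep.open_closed_accuracy == 1.0

    def test_stochastic_classification_accurate(self, default_dataset):
        """5x/0.2x threshold multiples give >= 95% open/closed accuracy."""
        sl, oc = classify_dataset(default_dataset)
        rep = truth_report(default_dataset.truth, sl, oc)
        assert rep.open_closed_accuracy >= 0.95

    def test_accuracy_monotone_in_snr(self):
        """Raising the open-density multiple never lowers recovery accuracy."""
        accs = []
        for mult in (1.5, 3.0, 6.0):
            cfg = small_config(open_density_multiple=mult)
            ds = simulate_dataset(cfg)
            sl, oc = classify_dataset(ds)
            accs.append(truth_report(ds.truth, sl, oc).open_closed_accuracy)
        assert accs == sorted(accs)

    def test_truth_report_confusion_and_flags(self, noiseless_dataset):
        ds = noiseless_dataset
        sl, oc = classify_dataset(ds)
        state = partition_by_state(oc["naive"], oc["primed"])
        cgroup = intersect_chip(state, sl.peaks, ds.chip_peaks)
        rep = truth_report(ds.truth, sl, oc, state, cgroup)
        assert rep.exact == {"open_closed": True, "state": True, "cgroup": True}
        # identity confusion matrix: off-diagonal mass is zero
        cm = rep.state_confusion
        assert cm.values.sum() == np.trace(cm.reindex(index=cm.columns).fillna(0).values)

    def test_single_flipped_call_shows_in_confusion(self, noiseless_dataset):
        ds = noiseless_dataset
        sl, oc = classify_dataset(ds)
        flipped = oc.copy()
        col = flipped.columns[0]
        flipped.iloc[0, 0] = not flipped.iloc[0, 0]
        rep = truth_report(ds.truth, sl, flipped)
        total = flipped.size
        assert rep.open_closed_accuracy == pytest.approx((total - 1) / total)

    def test_expression_tracks_openness(self, default_dataset):
        """Genes at open loci express high, closed loci low, in each state."""
        ds = default_dataset
        truth = ds.truth.set_index("gene_id")
        expr = ds.expression
        for lib in ("naive", "primed"):
            open_mask = truth[f"open_{lib}"]
            assert expr.loc[open_mask, lib].mean() > 5 * expr.loc[~open_mask, lib].mean()
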