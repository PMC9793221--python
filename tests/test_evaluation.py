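"""Experimental designs: splits, reproducibility, audit consistency."""

import numpy as np
import pytest

from soygs import evaluation, rrblup
from soygs.datatypes import PopulationPartition
from soygs.errors import ConfigurationError, DataError

from .conftest import toy_phenotype


class TestQuartilePartition:
    def test_1007_sample_group_sizes(self):
        rng = np.random.default_rng(0)
        y = toy_phenotype(rng.normal(434, 30, 1007))
        part = evaluation.quartile_partition(y)
        sizes = [part.group_sizes()[f"Ppop{i}"] for i in (1, 2, 3, 4)]
        assert sizes == [252, 252, 252, 251]

    def test_eight_distinct_values_split_at_sorted_order(self):
        y = toy_phenotype([8, 1, 5, 3, 7, 2, 6, 4])
        part = evaluation.quartile_partition(y)
        by_label = {
            lab: sorted(y.values[part.members(lab)]) for lab in part.group_names()
        }
        assert by_label["Ppop1"] == [1, 2]
        assert by_label["Ppop4"] == [7, 8]

    def test_all_tied_values_split_by_id_order(self):
        y = toy_phenotype(np.ones(8), ids=[f"s{i}" for i in range(8)])
        p1 = evaluation.quartile_partition(y)
        p2 = evaluation.quartile_partition(y)
        assert np.array_equal(p1.labels, p2.labels)
        assert list(p1.labels[:2]) == ["Ppop1", "Ppop1"]

    def test_group_ordering_matches_trait(self):
        rng = np.random.default_rng(3)
        y = toy_phenotype(rng.normal(0, 1, 40))
        part = evaluation.quartile_partition(y)
        means = [y.values[part.members(f"Ppop{i}")].mean() for i in (1, 2, 3, 4)]
        assert means == sorted(means)


class TestSizeSweep:
    def test_reproducible_and_repeat_stable(self, small_panel):
        G, y = small_panel[0], small_panel[1]
        t1 = evaluation.training_size_sweep(G, y, sizes=(50, 120), n_repeats=3,
                                            seed=9)
        t2 = evaluation.training_size_sweep(G, y, sizes=(50, 120), n_repeats=3,
                                            seed=9)
        assert t1.rows.equals(t2.rows)
        # reducing the repeat count must not change earlier repeats
        t3 = evaluation.training_size_sweep(G, y, sizes=(50, 120), n_repeats=2,
                                            seed=9)
        merged = t1.rows[t1.rows.repeat_index < 2].reset_index(drop=True)
        assert merged.equals(t3.rows.reset_index(drop=True))

    def test_training_size_bounds(self, small_panel):
        G, y = small_panel[0], small_panel[1]
        with pytest.raises(ConfigurationError):
            evaluation.training_size_sweep(G, y, sizes=(G.n_samples,), n_repeats=1)

    def test_audit_rows_reconcile_with_accuracy(self, small_panel):
        G, y = small_panel[0], small_panel[1]
        table = evaluation.training_size_sweep(
            G, y, sizes=(60,), n_repeats=3, seed=4, keep_predictions=True
        )
        assert len(table.audit) == 3
        for (train, test, pred, obs, acc), row_acc in zip(
            table.audit, table.rows["accuracy"]
        ):
            assert len(np.intersect1d(train, test)) == 0
            assert np.isclose(rrblup.prediction_accuracy(pred, obs), acc)
            assert np.isclose(acc, row_acc)

    def test_summary_means_equal_row_means(self, small_panel):
        G, y = small_panel[0], small_panel[1]
        table = evaluation.training_size_sweep(G, y, sizes=(50, 100),
                                               n_repeats=4, seed=1)
        for _, s in table.summary.iterrows():
            rows = table.rows[table.rows.n_train == s.n_train]
            assert abs(rows.accuracy.mean() - s["mean"]) < 1e-12


class TestCrossGroup:
    def test_two_group_offdiagonals_equal_leave_one_group_out(self, small_panel):
        G, y, _, part, _ = small_panel
        cgm = evaluation.cross_group_matrix(G, y, part, seed=3)
        logo = evaluation.leave_one_group_out(G, y, part, seed=3)
        for lab_train, lab_test in (("pop1", "pop2"), ("pop2", "pop1")):
            cell = cgm.rows[
                (cgm.rows.training_spec == lab_train)
                & (cgm.rows.prediction_spec == lab_test)
            ].accuracy.iloc[0]
            row = logo.rows[logo.rows.prediction_spec == lab_test].accuracy.iloc[0]
            assert np.isclose(cell, row)

    def test_diagonal_uses_requested_folds(self, small_panel):
        G, y, _, part, _ = small_panel
        cgm = evaluation.cross_group_matrix(G, y, part, n_folds=5, seed=0)
        diag = cgm.rows[
            (cgm.rows.training_spec == "pop1") & (cgm.rows.prediction_spec == "pop1")
        ]
        assert len(diag) == 5
        assert (diag.n_train + diag.n_test == part.group_sizes()["pop1"]).all()

    def test_undersized_group_flagged_missing(self, small_panel):
        G, y = small_panel[0], small_panel[1]
        half = (G.n_samples - 1) // 2
        labels = np.array(
            ["A"] * half + ["B"] * (G.n_samples - 1 - half) + ["single"]
        )
        part = PopulationPartition(G.sample_ids, labels, "phenotypic")
        logo = evaluation.leave_one_group_out(G, y, part)
        acc = logo.rows.set_index("prediction_spec")["accuracy"]
        assert np.isnan(acc["single"])
        assert not np.isnan(acc["A"]) and not np.isnan(acc["B"])

    def test_needs_two_groups(self, small_panel):
        G, y = small_panel[0], small_panel[1]
        part = PopulationPartition(G.sample_ids, ["all"] * G.n_samples, "genetic")
        with pytest.raises(DataError):
            evaluation.cross_group_matrix(G, y, part)


class TestMarkerSubsets:
    def test_rows_complete_and_random_sets_size_matched(self, small_panel):
        G, y = small_panel[0], small_panel[1]
        table = evaluation.marker_subset_eval(
            G, y, thresholds=(0, 1, 2), n_folds=3, n_random_repeats=2, seed=5,
            paper_mode=True,
        )
        rows = table.rows
        assert set(rows.threshold) == {0, 1, 2}
        for t in (1, 2):
            assoc = rows[(rows.threshold == t) & (rows.selection == "associated")]
            rand = rows[(rows.threshold == t) & (rows.selection == "random")]
            assert len(assoc) == 3
            assert len(rand) == 6  # 2 repeats x 3 folds
            assert set(rand.n_markers) <= set(assoc.n_markers)

    def test_full_marker_set_random_equals_associated(self, small_panel):
        G, y = small_panel[0], small_panel[1]
        table = evaluation.marker_subset_eval(
            G, y, thresholds=(0,), n_folds=3, seed=5, paper_mode=True
        )
        piv = table.rows.pivot_table(
            index="fold_index", columns="selection", values="accuracy"
        )
        assert np.allclose(piv["associated"], piv["random"])

    def test_per_fold_selection_deterministic(self, small_panel):
        G, y = small_panel[0], small_panel[1]
        t1 = evaluation.marker_subset_eval(G, y, thresholds=(1,), n_folds=3,
                                           seed=2, paper_mode=False)
        t2 = evaluation.marker_subset_eval(G, y, thresholds=(1,), n_folds=3,
                                           seed=2, paper_mode=False)
        assert t1.rows.equals(t2.rows)

    def test_disjoint_folds_cover_panel(self, small_panel):
        G, y = small_panel[0], small_panel[1]
        table = evaluation.marker_subset_eval(G, y, thresholds=(0,), n_folds=4,
                                              seed=7, paper_mode=True)
        assoc = table.rows[table.rows.selection == "associated"]
        assert int(assoc.n_test.sum()) == G.n_samples
        assert (assoc.n_train + assoc.n_test == G.n_samples).all()
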