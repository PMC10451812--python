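import numpy as np
import pytest

from a1scape import (
    SubcompartmentLabeling,
    persistent_bins,
    region_sets,
    repositioning_proportion,
    transition_counts,
    TransitionTable,
)
from a1scape.labels import LABELS, MERGE_4CLASS
from conftest import random_labeling


def lab_of(genome, labels, ct):
    return SubcompartmentLabeling(genome, ct, np.array(labels))


class TestTransitionCounts:
    def test_identical_labelings_are_diagonal(self, genome_multi):
        rng = np.random.default_rng(0)
        a = random_labeling(genome_multi, rng, "a")
        b = SubcompartmentLabeling(genome_multi, "b", a.labels.copy())
        t = transition_counts(a, b)
        assert t.total == genome_multi.n_bins
        assert np.trace(t.counts) == t.total
        assert t.repositioning == 0.0

    def test_hand_counted_toy(self, genome10):
        src = lab_of(genome10, ["A1"] * 5 + ["B4"] * 5, "s")
        dst = lab_of(
            genome10,
            ["A1", "A1", "A2", "A2", "A2", "B4", "B4", "B4", "B4", "B3"],
            "d",
        )
        t = transition_counts(src, dst)
        # 4 of 10 bins changed
        assert t.repositioning == pytest.approx(0.4)
        f = t.transfer_fractions
        assert f.loc["A1", "A1"] == pytest.approx(2 / 5)
        assert f.loc["A1", "A2"] == pytest.approx(3 / 5)
        assert f.loc["B4", "B3"] == pytest.approx(1 / 5)
        # row fractions of non-empty rows sum to 1
        nonzero = t.counts.sum(axis=1) > 0
        assert np.allclose(f.to_numpy()[nonzero].sum(axis=1), 1.0)

    def test_na_bins_dropped_from_both_sides(self, genome10):
        src = lab_of(genome10, ["A1"] * 8 + ["NA", "A1"], "s")
        dst = lab_of(genome10, ["A1"] * 9 + ["NA"], "d")
        t = transition_counts(src, dst)
        assert t.total == 8
        assert t.n_dropped == 2

    def test_transpose_symmetry(self, genome_multi):
        rng = np.random.default_rng(3)
        a, b = random_labeling(genome_multi, rng, "a"), random_labeling(
            genome_multi, rng, "b"
        )
        t, u = transition_counts(a, b), transition_counts(b, a)
        assert np.array_equal(t.counts.T, u.counts)
        assert t.repositioning == pytest.approx(u.repositioning)

    def test_mismatched_genomes_rejected(self, genome10, genome_multi):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            transition_counts(
                random_labeling(genome10, rng), random_labeling(genome_multi, rng)
            )


class TestRepositioningProportion:
    def test_toy_table(self):
        counts = np.zeros((8, 8), dtype=int)
        counts[0, 0], counts[0, 1] = 3, 1
        counts[1, 0], counts[1, 1] = 2, 4
        t = TransitionTable("s", "d", counts, 0)
        assert repositioning_proportion(t) == pytest.approx(0.3)

    def test_subset_restriction(self):
        counts = np.zeros((8, 8), dtype=int)
        counts[0, 0], counts[0, 1] = 3, 1
        counts[1, 0], counts[1, 1] = 2, 4
        t = TransitionTable("s", "d", counts, 0)
        assert repositioning_proportion(t, subset=["A1"]) == pytest.approx(0.25)
        with pytest.raises(ValueError):
            repositioning_proportion(t, subset=["B4"])

    def test_merging_never_increases_repositioning(self, genome_multi):
        # moves inside one merged class stop counting as repositioning
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = random_labeling(genome_multi, rng, "a")
            b = random_labeling(genome_multi, rng, "b")
            t = transition_counts(a, b)
            assert (
                repositioning_proportion(t, merge_scheme=MERGE_4CLASS)
                <= repositioning_proportion(t) + 1e-12
            )


class TestPersistence:
    def test_two_identical_labelings_fully_persistent(self, genome_multi):
        rng = np.random.default_rng(5)
        a = random_labeling(genome_multi, rng, "a")
        b = SubcompartmentLabeling(genome_multi, "b", a.labels.copy())
        for lab in set(a.labels) - {"NA"}:
            assert persistent_bins([a, b], lab, "a").proportion == 1.0

    def test_monotone_in_panel_size(self, genome_multi):
        rng = np.random.default_rng(7)
        panel = [random_labeling(genome_multi, rng, f"c{i}") for i in range(5)]
        # grow panel while some A1 bins remain in the reference
        if not (panel[0].labels == "A1").any():
            pytest.skip("no A1 in reference draw")
        props = []
        for k in range(2, 6):
            props.append(persistent_bins(panel[:k], "A1", "c0").proportion)
        assert all(x >= y - 1e-12 for x, y in zip(props, props[1:]))

    def test_a1_unchanged_under_4class_merge(self, dataset):
        p8 = persistent_bins(dataset.labelings, "A1", "ES")
        p4 = persistent_bins(
            dataset.labelings, "A1", "ES", merge_scheme=MERGE_4CLASS
        )
        assert np.array_equal(p8.persistent_bins, p4.persistent_bins)

    def test_unknown_reference_rejected(self, genome_multi):
        rng = np.random.default_rng(0)
        panel = [random_labeling(genome_multi, rng, f"c{i}") for i in range(2)]
        with pytest.raises(ValueError):
            persistent_bins(panel, "A1", "nope")


class TestRegionSets:
    def test_identical_panel_has_empty_variable(self, genome_multi):
        rng = np.random.default_rng(2)
        a = random_labeling(genome_multi, rng, "a")
        panel = [
            SubcompartmentLabeling(genome_multi, f"c{i}", a.labels.copy())
            for i in range(5)
        ]
        rs = region_sets(panel)
        for i in range(5):
            assert rs[f"variable_A1.c{i}"].bins.size == 0

    def test_partition_law(self, dataset):
        rs = region_sets(dataset.labelings)
        common = set(rs["common_A1"].bins.tolist())
        for lab in dataset.labelings:
            own = set(np.flatnonzero(lab.labels == "A1").tolist())
            var = set(rs[f"variable_A1.{lab.cell_type}"].bins.tolist())
            assert common & var == set()
            assert common | var == own

    def test_planted_common_a1_recovered_exactly(self, dataset):
        rs = region_sets(dataset.labelings)
        assert np.array_equal(rs["common_A1"].bins, dataset.truth["common_a1"])
        assert np.array_equal(rs["common_B4"].bins, dataset.truth["common_b4"])

    def test_interval_merge_idempotent(self, dataset):
        rs = region_sets(dataset.labelings)["common_A1"]
        iv = rs.intervals
        # re-deriving intervals from the bins of the intervals is stable
        bins2 = []
        g = dataset.genome
        for chrom, s, e in iv:
            b0 = g.bin_index(chrom, s)
            b1 = g.bin_index(chrom, e - 1)
            bins2.extend(range(b0, b1 + 1))
        assert g.bins_to_intervals(bins2) == iv
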