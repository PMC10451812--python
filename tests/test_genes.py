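"""Gene classification, density/gap statistics and enrichment tests."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from a1scape import (
    ExpressionMatrix,
    GeneTable,
    RegionSet,
    SubcompartmentLabeling,
    classify_genes,
    density_by_subcompartment,
    enrichment_odds_ratio,
    expression_by_subcompartment,
    expression_change_by_transition,
    gap_lengths,
    gene_density,
)
from a1scape.genes import adjust_bh


def gene_table(rows):
    return GeneTable(
        pd.DataFrame(
            rows, columns=["gene_id", "chrom", "tss", "strand", "housekeeping"]
        )
    )


def expr_of(data, cts=("c1", "c2", "c3", "c4", "c5")):
    return ExpressionMatrix(
        pd.DataFrame(data, columns=list(cts)).rename_axis("gene_id")
    )


CLASSIFY_CASES = [
    # (fpkm row, expected active cts, expected high cts, expected specific ct)
    ((1.5, 0.2, 0.2, 0.1, 0.0), {0}, set(), 0),       # folds 7.5..150 all >= 5
    ((0.5, 0.5, 0.5, 0.5, 0.5), set(), set(), None),  # below active threshold
    ((12.0,) * 5, {0, 1, 2, 3, 4}, {0, 1, 2, 3, 4}, None),  # fold 1 < 5
    ((4.9, 1.2, 0.0, 0.0, 0.0), {0, 1}, set(), None),  # fold 4.08 < 5
    ((10.0, 2.0, 0.0, 0.0, 0.0), {0, 1}, set(), 0),    # fold exactly 5
]


@pytest.mark.parametrize("fpkm,act,high,spec", CLASSIFY_CASES)
def test_classify_rule(fpkm, act, high, spec):
    genes = gene_table([("g0", "chr1", 0, "+", False)])
    em = expr_of([list(fpkm)])
    em.fpkm.index = ["g0"]
    cls = classify_genes(em, genes)
    assert set(np.flatnonzero(cls.active.loc["g0"])) == act
    assert set(np.flatnonzero(cls.high.loc["g0"])) == high
    got = np.flatnonzero(cls.specific.loc["g0"])
    assert (set(got) == {spec}) if spec is not None else got.size == 0


def test_high_implies_active_and_specific_unique():
    rng = np.random.default_rng(0)
    vals = rng.lognormal(0, 2, size=(300, 5))
    em = expr_of(vals)
    em.fpkm.index = [f"g{i}" for i in range(300)]
    genes = gene_table([(f"g{i}", "chr1", 0, "+", False) for i in range(300)])
    cls = classify_genes(em, genes)
    assert (cls.high.to_numpy() <= cls.active.to_numpy()).all()
    assert (cls.specific.sum(axis=1) <= 1).all()


def test_specificity_scale_invariance_of_fold_only():
    # scaling one gene's FPKM by a shared constant preserves the fold-based
    # specificity pattern but not the threshold-based active flag
    genes = gene_table([("g0", "chr1", 0, "+", False)])
    lo = expr_of([[2.0, 0.2, 0.2, 0.2, 0.2]])
    lo.fpkm.index = ["g0"]
    hi = expr_of([[200.0, 20.0, 20.0, 20.0, 20.0]])
    hi.fpkm.index = ["g0"]
    c_lo, c_hi = classify_genes(lo, genes), classify_genes(hi, genes)
    assert bool(c_lo.specific.loc["g0", "c1"])
    assert bool(c_hi.specific.loc["g0", "c1"])  # fold unchanged
    tiny = expr_of([[0.02, 0.002, 0.002, 0.002, 0.002]])
    tiny.fpkm.index = ["g0"]
    c_tiny = classify_genes(tiny, genes)
    assert not c_tiny.active.loc["g0"].any()      # active is scale-dependent
    assert not c_tiny.specific.loc["g0"].any()    # needs FPKM above threshold


def test_negative_fpkm_rejected():
    with pytest.raises(ValueError):
        expr_of([[-1.0, 0, 0, 0, 0]])


class TestDensityAndGaps:
    def test_three_tss_per_megabase(self, genome_multi):
        genes = gene_table(
            [(f"g{i}", "chr1", p, "+", False)
             for i, p in enumerate([10_000, 200_000, 400_000])]
        )
        rs = RegionSet("r", genome_multi, np.arange(10))  # 500 kb chr1
        assert gene_density(genes, rs) == pytest.approx(3 / 0.5)

    def test_zero_length_region_rejected(self, genome_multi):
        genes = gene_table([("g0", "chr1", 0, "+", False)])
        rs = RegionSet("r", genome_multi, np.array([], dtype=int))
        with pytest.raises(ValueError):
            gene_density(genes, rs)

    def test_density_additivity_over_disjoint_classes(self, genome_multi):
        rng = np.random.default_rng(1)
        genes = gene_table(
            [(f"g{i}", "chr1", int(p), "+", False)
             for i, p in enumerate(rng.integers(0, 500_000, 40))]
        )
        r1 = RegionSet("r1", genome_multi, np.arange(0, 4))
        r2 = RegionSet("r2", genome_multi, np.arange(4, 10))
        ru = RegionSet("u", genome_multi, np.arange(0, 10))
        d1, d2, du = (gene_density(genes, r) for r in (r1, r2, ru))
        w1 = r1.total_bp / ru.total_bp
        assert du == pytest.approx(w1 * d1 + (1 - w1) * d2)

    def test_gaps_within_intervals_only(self, genome_multi):
        genes = gene_table(
            [("g0", "chr1", 10_000, "+", False),
             ("g1", "chr1", 60_000, "+", False),
             ("g2", "chr1", 200_000, "+", False),
             ("g3", "chr2", 10_000, "+", False)]
        )
        rs = RegionSet("r", genome_multi, np.concatenate(
            [np.arange(0, 5), np.arange(10, 12)]  # chr1 0-250k, chr2 0-100k
        ))
        out = gap_lengths(genes, rs)
        assert sorted(out["gaps"].tolist()) == [50_000, 140_000]

    def test_single_tss_intervals_yield_no_gaps(self, genome_multi):
        genes = gene_table(
            [("g0", "chr1", 10_000, "+", False),
             ("g1", "chr2", 10_000, "+", False)]
        )
        rs = RegionSet("r", genome_multi, np.array([0, 10]))
        with pytest.warns(UserWarning):
            out = gap_lengths(genes, rs)
        assert out["n"] == 0


class TestEnrichment:
    def test_null_table(self):
        r = enrichment_odds_ratio(10, 10, 10, 10)
        assert r.odds_ratio == 1.0
        assert r.p_value == pytest.approx(1.0)

    def test_cross_product(self):
        r = enrichment_odds_ratio(20, 5, 10, 10)
        assert r.odds_ratio == pytest.approx(4.0)

    def test_zero_margin_flagged_nan(self):
        r = enrichment_odds_ratio(5, 0, 3, 4)
        assert np.isnan(r.odds_ratio)
        assert np.isfinite(r.p_value)

    @pytest.mark.parametrize(
        "table", [(3, 7, 9, 2), (0, 10, 10, 0), (6, 6, 6, 6), (1, 2, 3, 4)]
    )
    def test_p_matches_hypergeometric_enumeration(self, table):
        # two-sided Fisher p by exhaustive enumeration over tables with the
        # same margins (n <= 60)
        a, b, c, d = table
        r = enrichment_odds_ratio(a, b, c, d)
        n, r1, c1 = a + b + c + d, a + b, a + c
        probs = {
            k: st.hypergeom.pmf(k, n, r1, c1)
            for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1)
        }
        p0 = probs[a]
        p = sum(v for v in probs.values() if v <= p0 * (1 + 1e-9))
        assert r.p_value == pytest.approx(p, rel=1e-8)

    def test_bh_adjustment(self):
        rs = [enrichment_odds_ratio(*t) for t in
              [(20, 5, 10, 10), (10, 10, 10, 10), (30, 2, 5, 20)]]
        adjust_bh(rs)
        assert all(r.p_adjusted is not None and r.p_adjusted >= r.p_value - 1e-12
                   for r in rs)


class TestExpressionBySubcompartment:
    def test_constant_expression_is_null(self, genome10):
        labs = ["A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4", "A1", "B4"]
        lab = SubcompartmentLabeling(genome10, "c1", np.array(labs))
        genes = gene_table(
            [(f"g{i}", "chr1", i * 50_000 + 100, "+", False) for i in range(10)]
        )
        em = expr_of([[5.0] * 5 for _ in range(10)])
        em.fpkm.index = [f"g{i}" for i in range(10)]
        out = expression_by_subcompartment(em, lab, genes)
        assert out["h_statistic"] == 0.0
        assert out["p_value"] == 1.0

    def test_two_group_rank_oracle(self, genome10):
        # groups {2,4,6} vs {1,3,5} on the FPKM -> log2 scale; compare the
        # H statistic with a direct rank computation
        labs = ["A1"] * 3 + ["B4"] * 3 + ["NA"] * 4
        lab = SubcompartmentLabeling(genome10, "c1", np.array(labs))
        genes = gene_table(
            [(f"g{i}", "chr1", i * 50_000 + 100, "+", False) for i in range(6)]
        )
        fpkm = [[2.0] * 5, [4.0] * 5, [6.0] * 5, [1.0] * 5, [3.0] * 5, [5.0] * 5]
        em = expr_of(fpkm)
        em.fpkm.index = [f"g{i}" for i in range(6)]
        out = expression_by_subcompartment(em, lab, genes)
        g1 = np.log2(np.array([2, 4, 6]) + 1.0)
        g2 = np.log2(np.array([1, 3, 5]) + 1.0)
        h_ref, p_ref = st.kruskal(g1, g2)
        assert out["h_statistic"] == pytest.approx(h_ref, rel=1e-12)
        assert out["p_value"] == pytest.approx(p_ref, rel=1e-12)

    def test_planted_gradient_recovered(self, dataset):
        ref = dataset.labelings[0]
        out = expression_by_subcompartment(dataset.expression, ref, dataset.genes)
        meds = [np.median(out["groups"][l]) for l in
                ("A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4")]
        assert all(np.diff(meds) < 0)
        assert out["p_value"] < 1e-6


class TestExpressionChangeByTransition:
    def _setup(self, genome_multi, seed=0):
        rng = np.random.default_rng(seed)
        from conftest import random_labeling

        src = random_labeling(genome_multi, rng, "s")
        dst = random_labeling(genome_multi, rng, "d")
        n = 600
        rows = []
        for i in range(n):
            chrom = genome_multi.chroms[int(rng.integers(3))]
            pos = int(rng.integers(0, genome_multi.chrom_length(chrom)))
            rows.append((f"g{i}", chrom, pos, "+", False))
        return src, dst, gene_table(rows), rng

    def test_identical_expression_has_no_calls(self, genome_multi):
        src, dst, genes, rng = self._setup(genome_multi)
        f = pd.Series(rng.lognormal(0, 1, len(genes)),
                      index=genes.df["gene_id"])
        grid = expression_change_by_transition(f, f, src, dst, genes)
        nonempty = grid["n"] > 0
        assert (grid.loc[nonempty, "n_up"] == 0).all()
        assert (grid.loc[nonempty, "n_down"] == 0).all()

    def test_planted_downregulation_detected(self, genome_multi):
        src, dst, genes, rng = self._setup(genome_multi, seed=3)
        ids = genes.df["gene_id"]
        f_src = pd.Series(rng.lognormal(1, 0.3, len(ids)), index=ids)
        # symmetric background changes, so up and down calls both occur
        f_dst = f_src * np.power(2.0, rng.normal(0, 1.2, len(ids)))
        bins = genes.tss_bins(src.genome)
        moved = (src.labels[bins.to_numpy()] == "A1") & (
            dst.labels[bins.to_numpy()] == "B4"
        )
        # 4-fold decrease for genes moving A1 -> B4
        f_dst[moved] = f_src[moved] / 4.0
        grid = expression_change_by_transition(f_src, f_dst, src, dst, genes)
        cell = grid[(grid.src == "A1") & (grid.dst == "B4")].iloc[0]
        if cell.n >= 3:
            assert cell.n_down > cell.n_up
            assert cell.p_value < 0.05
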