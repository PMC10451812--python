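"""Interchromosomal A/B ratio: hand oracles, symmetries, brute force."""

import numpy as np
import pytest

from a1scape import (
    BinnedGenome,
    ContactMap,
    SubcompartmentLabeling,
    ab_ratio_by_subcompartment,
    derive_compartment_mask,
    interchromosomal_ab_scores,
)
from a1scape.labels import LABELS


def build_inter(genome, triples):
    r, c, v = zip(*triples)
    return ContactMap(genome, "inter", np.array(r), np.array(c), np.array(v, float))


def labeling(genome, labels):
    return SubcompartmentLabeling(genome, "ct", np.array(labels))


def test_hand_summed_scores(genome_multi):
    g = genome_multi
    # chr1 bin 0 contacts: two A bins on chr2 (2 + 4), one B bin on chr3 (3)
    labs = ["A1"] * 10 + ["A1", "A2"] + ["NA"] * 6 + ["B4"] + ["NA"] * 5
    lab = labeling(g, labs)
    mask = derive_compartment_mask(lab)
    m = build_inter(g, [(0, 10, 2.0), (0, 11, 4.0), (0, 18, 3.0)])
    s = interchromosomal_ab_scores(m, mask)
    assert s.a[0] == pytest.approx(6.0)
    assert s.b[0] == pytest.approx(3.0)
    # a bin with no interchromosomal entries scores zero
    assert s.a[5] == 0.0 and s.b[5] == 0.0


def test_closed_form_on_complete_uniform_map(genome_multi):
    g = genome_multi
    rng = np.random.default_rng(0)
    labs = np.array(["A1", "A2", "B1", "B4"])[rng.integers(0, 4, g.n_bins)]
    lab = labeling(g, labs)
    mask = derive_compartment_mask(lab)
    c = 1.7
    triples = [
        (i, j, c)
        for i in range(g.n_bins)
        for j in range(i + 1, g.n_bins)
        if g.bin_chrom_codes[i] != g.bin_chrom_codes[j]
    ]
    s = interchromosomal_ab_scores(build_inter(g, triples), mask)
    codes = g.bin_chrom_codes
    for i in range(g.n_bins):
        n_a_other = int(((mask.mask == 1) & (codes != codes[i])).sum())
        n_b_other = int(((mask.mask == -1) & (codes != codes[i])).sum())
        assert s.a[i] == pytest.approx(c * n_a_other)
        assert s.b[i] == pytest.approx(c * n_b_other)


def test_eq1_toy_evaluation():
    g = BinnedGenome(("chr1", "chr2"), (100_000, 150_000), 50_000)
    # chr1: [A1, B1]; chr2: [A2, A3, B4]; SC=A1 is bin 0 only
    lab = labeling(g, ["A1", "B1", "A2", "A3", "B4"])
    mask = derive_compartment_mask(lab)
    # bin 0: contacts 2 and 4 with chr2's A bins, 3 with chr2's B bin
    m = build_inter(g, [(0, 2, 2.0), (0, 3, 4.0), (0, 4, 3.0)])
    s = interchromosomal_ab_scores(m, mask)
    res = {r.subcompartment: r for r in ab_ratio_by_subcompartment(s, lab)}
    # A1 = {bin 0}: sum A_i = 6, sum B_i = 3; N_A = 3, N_B = 2
    assert res["A1"].c_a == pytest.approx(6 / 3)
    assert res["A1"].c_b == pytest.approx(3 / 2)
    assert res["A1"].ratio == pytest.approx((6 / 3) / (3 / 2))


def test_uniform_map_equal_territories_gives_unit_ratios():
    g = BinnedGenome(("chr1", "chr2", "chr3"), (200_000,) * 3, 50_000)
    labs = (["A1", "A2", "B1", "B4"]) * 3
    lab = labeling(g, labs)
    mask = derive_compartment_mask(lab)
    triples = [
        (i, j, 2.0)
        for i in range(g.n_bins)
        for j in range(i + 1, g.n_bins)
        if g.bin_chrom_codes[i] != g.bin_chrom_codes[j]
    ]
    s = interchromosomal_ab_scores(build_inter(g, triples), mask)
    for r in ab_ratio_by_subcompartment(s, lab):
        if r.n_bins:
            assert r.ratio == pytest.approx(1.0)


def _random_instance(seed, n_per_chrom=6):
    rng = np.random.default_rng(seed)
    g = BinnedGenome(
        ("chr1", "chr2", "chr3"), (50_000 * n_per_chrom,) * 3, 50_000
    )
    labs = np.array(LABELS + ("NA",))[rng.integers(0, 9, g.n_bins)]
    lab = labeling(g, labs)
    triples = [
        (i, j, float(rng.integers(0, 6)))
        for i in range(g.n_bins)
        for j in range(i + 1, g.n_bins)
        if g.bin_chrom_codes[i] != g.bin_chrom_codes[j]
        if rng.random() < 0.7
    ]
    return g, lab, triples


@pytest.mark.parametrize("seed", range(5))
def test_matches_brute_force_triple_loop(seed):
    g, lab, triples = _random_instance(seed)
    if not (lab.labels[:6] != "NA").any():
        pytest.skip("degenerate draw")
    mask = derive_compartment_mask(lab)
    if mask.n_a == 0 or mask.n_b == 0:
        pytest.skip("degenerate draw")
    m = build_inter(g, triples)
    s = interchromosomal_ab_scores(m, mask)
    res = {r.subcompartment: r for r in ab_ratio_by_subcompartment(s, lab)}

    # brute force directly over the triple list, symmetrized
    full = {}
    for i, j, v in triples:
        full[(i, j)] = full.get((i, j), 0.0) + v
        full[(j, i)] = full.get((j, i), 0.0) + v
    for sc in LABELS:
        sum_a = sum_b = 0.0
        for i in range(g.n_bins):
            if lab.labels[i] != sc:
                continue
            for j in range(g.n_bins):
                if g.bin_chrom_codes[i] == g.bin_chrom_codes[j]:
                    continue
                v = full.get((i, j), 0.0)
                if mask.mask[j] == 1:
                    sum_a += v
                elif mask.mask[j] == -1:
                    sum_b += v
        c_a = sum_a / mask.n_a
        c_b = sum_b / mask.n_b
        r = res[sc]
        assert r.c_a == pytest.approx(c_a, rel=1e-12, abs=1e-15)
        assert r.c_b == pytest.approx(c_b, rel=1e-12, abs=1e-15)
        if c_b > 0:
            assert r.ratio == pytest.approx(c_a / c_b, rel=1e-12)
        else:
            assert np.isnan(r.ratio)


def test_scale_invariance(genome_multi):
    g, lab, triples = _random_instance(42)
    mask = derive_compartment_mask(lab)
    m = build_inter(g, triples)
    r1 = ab_ratio_by_subcompartment(interchromosomal_ab_scores(m, mask), lab)
    r2 = ab_ratio_by_subcompartment(
        interchromosomal_ab_scores(m.scaled(7.3), mask), lab
    )
    for a, b in zip(r1, r2):
        if np.isnan(a.ratio):
            assert np.isnan(b.ratio)
        else:
            assert b.ratio == pytest.approx(a.ratio, rel=1e-12)


def test_ab_relabel_inverts_ratios():
    g, lab, triples = _random_instance(9)
    mask = derive_compartment_mask(lab)
    m = build_inter(g, triples)
    r1 = {x.subcompartment: x for x in
          ab_ratio_by_subcompartment(interchromosomal_ab_scores(m, mask), lab)}
    r2 = {x.subcompartment: x for x in
          ab_ratio_by_subcompartment(
              interchromosomal_ab_scores(m, mask.flipped()), lab)}
    for sc in r1:
        a, b = r1[sc].ratio, r2[sc].ratio
        if np.isfinite(a) and a > 0 and np.isfinite(b):
            assert b == pytest.approx(1 / a, rel=1e-12)


def test_intra_map_rejected(genome10):
    m = ContactMap(genome10, "intra", [0], [1], [1.0])
    lab = labeling(genome10, ["A1"] * 5 + ["B4"] * 5)
    with pytest.raises(ValueError, match="inter"):
        interchromosomal_ab_scores(m, derive_compartment_mask(lab))
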