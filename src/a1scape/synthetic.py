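"""Self-consistent multi-cell-type synthetic datasets with known ground truth.

The generator emulates the statistical structure the downstream statistics
assume: five cell types with block-structured eight-state labelings and
controlled cross-cell-type persistence, power-law distance-decay intra maps
with per-state affinities graded A1 > ... > B4, planted contact domains with
a known uniform enrichment over the B-compartment background,
inter-chromosomal maps whose state-similarity kernel produces the graded A/B
ratio, and gene/FPKM tables containing housekeeping and single-cell-type-
specific genes with configurable placement odds.

Everything is driven by one :class:`numpy.random.Generator`; a fixed seed
makes the whole dataset and every downstream statistic reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .boundaries import SignalTrack
from .contacts import ContactMap, write_contact_dump
from .domains import Domain, DomainSet
from .genes import ExpressionMatrix, GeneTable
from .genome import BinnedGenome
from .labels import LABELS, NA_LABEL, SubcompartmentLabeling, derive_compartment_mask

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_labelings",
    "generate_contact_maps",
    "generate_expression",
    "generate_dataset",
]

_RANKS = np.arange(8)


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults model the study conditions: five cell types, 50 kb bins,
    common-A1 and common-B4 fractions at the observed persistence levels
    (32.53% and 28.95% of the reference cell type's A1/B4), a ~60% per-pair
    repositioning rate, graded affinities with a 4x A1/B4 span, and a
    3 x 20 Mb desk-scale genome (1200 bins) so the full pipeline runs in
    minutes.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 20_000_000, "chr2": 20_000_000, "chr3": 20_000_000
        }
    )
    bin_size: int = 50_000
    cell_types: tuple[str, ...] = (
        "ES", "thymocyte", "macrophage", "NP", "neuron"
    )
    label_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "A1": 0.15, "A2": 0.12, "A3": 0.12, "A4": 0.11,
            "B1": 0.11, "B2": 0.12, "B3": 0.12, "B4": 0.15,
        }
    )
    mean_block_bins: float = 6.0
    common_a1_fraction: float = 0.3253
    common_b4_fraction: float = 0.2895
    move_probability: float = 0.6
    transition_tau: float = 1.0
    na_fraction: float = 0.02

    decay_exponent: float = 1.0          # alpha in (1+d)^-alpha
    depth_intra: float = 100.0
    depth_inter: float = 5.0
    affinity_span: float = 4.0           # a(A1)/a(B4)
    inter_tau: float = 3.0               # rank-similarity kernel width

    n_domains: int = 100
    domain_size_bins: tuple[int, int] = (3, 8)
    domain_enrichment: float = 10.0      # e, balanced-contact units over background

    # active genes per Mbp by genomic context (reference cell type labels)
    gene_density_per_mb: dict[str, float] = field(
        default_factory=lambda: {
            "common_A1": 18.0, "variable_A1": 9.0, "A2": 8.0, "A3": 6.0,
            "A4": 5.0, "B1": 4.0, "B2": 3.0, "B3": 2.0, "B4": 1.0,
        }
    )
    n_housekeeping: int = 60
    n_specific_per_cell_type: int = 25
    placement_odds: float = 3.0          # specific genes: variable-vs-common A1
    # median FPKM of gradient genes by subcompartment rank of their bin
    fpkm_medians: tuple[float, ...] = (8.0, 5.0, 3.0, 2.0, 1.2, 0.8, 0.5, 0.3)
    fpkm_sigma: float = 0.5
    signal_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if abs(sum(self.label_fractions.values())) > 1 + 1e-9:
            raise ValueError("label fractions must sum to <= 1")
        if not 0 <= self.common_a1_fraction <= 1:
            raise ValueError("common_a1_fraction must be in [0, 1]")
        if self.affinity_span <= 1:
            raise ValueError("affinities must be strictly ordered (span > 1)")
        if self.domain_size_bins[0] < 1 or (
            self.domain_size_bins[0] > self.domain_size_bins[1]
        ):
            raise ValueError("invalid domain size range")

    @property
    def affinities(self) -> np.ndarray:
        """Strictly decreasing per-rank affinity, geometric, centred at 1."""
        half = np.sqrt(self.affinity_span)
        return half * (1.0 / self.affinity_span) ** (_RANKS / 7.0) * 1.0

    def genome(self, *, exclude_sex_chroms: bool = True) -> BinnedGenome:
        return BinnedGenome.from_chromsizes(
            self.chrom_lengths, self.bin_size,
            exclude_sex_chroms=exclude_sex_chroms,
        )


@dataclass
class SyntheticDataset:
    """Bundle of generated inputs plus the planted ground truth."""

    config: SyntheticConfig
    genome: BinnedGenome
    labelings: list[SubcompartmentLabeling]
    intra: ContactMap
    inter: ContactMap
    domains: DomainSet
    genes: GeneTable
    expression: ExpressionMatrix
    housekeeping: list[str]
    tracks: dict[str, SignalTrack]
    truth: dict[str, object]

    def write(self, outdir: str | Path) -> dict[str, list[str]]:
        """Emit all inputs as text files (Juicer dumps, BED, bedpe, TSV)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        written: dict[str, list[str]] = {
            "intra": [], "inter": [], "labels": [], "domains": [],
            "tads": [], "genes": [], "expression": [], "signal": [],
        }
        from .io import write_subcompartment_bed

        g = self.genome
        for chrom in g.chroms:
            p = out / f"intra.{chrom}.txt"
            write_contact_dump(self.intra, p, chrom)
            written["intra"].append(str(p))
        for i, c1 in enumerate(g.chroms):
            for c2 in g.chroms[i + 1:]:
                p = out / f"inter.{c1}.{c2}.txt"
                write_contact_dump(self.inter, p, c1, c2)
                written["inter"].append(str(p))
        for lab in self.labelings:
            p = out / f"subcompartments.{lab.cell_type}.bed"
            write_subcompartment_bed(lab, p)
            written["labels"].append(str(p))
        # planted domains split into the two-resolution call files: the
        # 5 kb file is the truth; the 10 kb file duplicates half of the
        # calls and pads the rest by one bin so the keep-smaller merge
        # reconstructs the truth exactly
        doms = list(self.domains)
        p5 = out / "domains.5kb.bedpe"
        p10 = out / "domains.10kb.bedpe"
        with open(p5, "w") as fh:
            for d in doms:
                fh.write(
                    f"{d.chrom}\t{d.start}\t{d.end}"
                    f"\t{d.chrom}\t{d.start}\t{d.end}\n"
                )
        with open(p10, "w") as fh:
            for k, d in enumerate(doms):
                pad = 0 if k % 2 == 0 else self.genome.bin_size
                s = max(0, d.start - pad)
                e = min(self.genome.chrom_length(d.chrom), d.end + pad)
                # a padded decoy must not clip a neighbouring true domain
                clips = any(
                    o is not d and o.chrom == d.chrom
                    and s < o.end and o.start < e
                    for o in doms
                )
                if clips:
                    s, e = d.start, d.end
                fh.write(f"{d.chrom}\t{s}\t{e}\t{d.chrom}\t{s}\t{e}\n")
        written["domains"] = [str(p5), str(p10)]
        ptad = out / "tads.bed"
        with open(ptad, "w") as fh:
            for d in doms:
                fh.write(f"{d.chrom}\t{d.start}\t{d.end}\n")
        written["tads"].append(str(ptad))
        pg = out / "genes.bed"
        with open(pg, "w") as fh:
            for r in self.genes.df.itertuples(index=False):
                start = r.tss if r.strand == "+" else r.tss - 999
                end = r.tss + 1000 if r.strand == "+" else r.tss + 1
                start = max(0, start)
                fh.write(
                    f"{r.chrom}\t{start}\t{end}\t{r.gene_id}\t0\t{r.strand}\n"
                )
        written["genes"].append(str(pg))
        pf = out / "fpkm.tsv"
        self.expression.fpkm.to_csv(pf, sep="\t")
        ph = out / "housekeeping.tsv"
        with open(ph, "w") as fh:
            fh.write("gene_id\n")
            for gid in self.housekeeping:
                fh.write(gid + "\n")
        written["expression"] = [str(pf), str(ph)]
        for mark, tr in self.tracks.items():
            pm = out / f"signal.{mark}.bedgraph"
            with open(pm, "w") as fh:
                for b in range(g.n_bins):
                    if tr.no_data[b]:
                        continue
                    chrom, s, e = g.bin_location(b)
                    fh.write(f"{chrom}\t{s}\t{e}\t{tr.values[b]:.5g}\n")
            written["signal"].append(str(pm))
        return written


# ---------------------------------------------------------------------------
# labelings
# ---------------------------------------------------------------------------


def _block_labels(
    cfg: SyntheticConfig, genome: BinnedGenome, rng: np.random.Generator
) -> np.ndarray:
    """Reference labeling: geometric blocks with labels drawn by fraction."""
    labels = np.empty(genome.n_bins, dtype="<U2")
    fracs = np.array([cfg.label_fractions[l] for l in LABELS])
    fracs = fracs / fracs.sum()
    for chrom in genome.chroms:
        sl = genome.chrom_slice(chrom)
        i = sl.start
        while i < sl.stop:
            n = int(rng.geometric(1.0 / cfg.mean_block_bins))
            n = min(n, sl.stop - i)
            labels[i: i + n] = LABELS[int(rng.choice(8, p=fracs))]
            i += n
    return labels


def generate_labelings(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    genome: BinnedGenome | None = None,
) -> tuple[list[SubcompartmentLabeling], dict[str, np.ndarray]]:
    """Five block-structured labelings with exact planted persistence.

    A designated subset of the reference cell type's A1 bins (the configured
    fraction, rounded) stays A1 in every cell type; likewise for B4. Every
    other bin keeps its reference label with probability
    ``1 - move_probability`` per non-reference cell type, else moves to a
    rank-neighbouring state (kernel ``exp(-|rank diff|/tau)``). Non-pinned
    reference A1/B4 bins that happen to persist everywhere are nudged in one
    random cell type so the recovered common fraction is exact.

    Returns the labelings and a truth dict with ``common_a1`` / ``common_b4``
    bin arrays.
    """
    g = genome or cfg.genome()
    ref = _block_labels(cfg, g, rng)
    ref_a1 = np.flatnonzero(ref == "A1")
    ref_b4 = np.flatnonzero(ref == "B4")
    n_pin_a1 = int(round(cfg.common_a1_fraction * ref_a1.size))
    n_pin_b4 = int(round(cfg.common_b4_fraction * ref_b4.size))
    if ref_a1.size == 0 or ref_b4.size == 0:
        raise ValueError("infeasible fractions: reference has no A1/B4 bins")
    pin_a1 = rng.choice(ref_a1, size=n_pin_a1, replace=False)
    pin_b4 = rng.choice(ref_b4, size=n_pin_b4, replace=False)
    pinned = np.zeros(g.n_bins, dtype=bool)
    pinned[pin_a1] = True
    pinned[pin_b4] = True

    kernel = np.exp(-np.abs(_RANKS[:, None] - _RANKS[None, :]) / cfg.transition_tau)
    np.fill_diagonal(kernel, 0.0)
    kernel /= kernel.sum(axis=1, keepdims=True)

    all_labels = [ref.copy()]
    code_of = {l: k for k, l in enumerate(LABELS)}
    ref_codes = np.array([code_of.get(l, -1) for l in ref])
    for _ in cfg.cell_types[1:]:
        lab = ref.copy()
        movable = ~pinned
        move = movable & (rng.random(g.n_bins) < cfg.move_probability)
        for b in np.flatnonzero(move):
            lab[b] = LABELS[int(rng.choice(8, p=kernel[ref_codes[b]]))]
        if cfg.na_fraction > 0:
            na = movable & (rng.random(g.n_bins) < cfg.na_fraction)
            lab[na] = NA_LABEL
        all_labels.append(lab)

    # exactness: break accidental persistence of non-pinned A1/B4 bins
    for target, pin_set, nudge in (("A1", pin_a1, "A2"), ("B4", pin_b4, "B3")):
        everywhere = np.logical_and.reduce(
            [l == target for l in all_labels]
        )
        accidental = np.flatnonzero(everywhere)
        accidental = np.setdiff1d(accidental, pin_set)
        for b in accidental:
            ct = int(rng.integers(1, len(cfg.cell_types)))
            all_labels[ct][b] = nudge

    labelings = [
        SubcompartmentLabeling(g, ct, lab, provenance="synthetic")
        for ct, lab in zip(cfg.cell_types, all_labels)
    ]
    truth = {
        "common_a1": np.sort(pin_a1),
        "common_b4": np.sort(pin_b4),
        "n_reference_a1": ref_a1.size,
        "n_reference_b4": ref_b4.size,
    }
    return labelings, truth


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------


def _bin_affinity(cfg: SyntheticConfig, labeling: SubcompartmentLabeling) -> np.ndarray:
    aff = cfg.affinities
    codes = labeling.codes
    out = np.where(codes >= 0, aff[np.clip(codes, 0, 7)], 1.0)
    return out


def _plant_domains(
    cfg: SyntheticConfig,
    labeling: SubcompartmentLabeling,
    rng: np.random.Generator,
    max_span_bins: int,
) -> list[tuple[int, int]]:
    """Non-overlapping domain spans (global bins) inside compartment-A runs."""
    g = labeling.genome
    codes = labeling.codes
    is_a = (codes >= 0) & (codes < 4)
    chrom_codes = g.bin_chrom_codes
    lo, hi = cfg.domain_size_bins
    hi = min(hi, max_span_bins)
    lo = min(lo, hi)
    # candidate A runs
    runs = []
    i = 0
    n = g.n_bins
    while i < n:
        if is_a[i]:
            j = i + 1
            while j < n and is_a[j] and chrom_codes[j] == chrom_codes[i]:
                j += 1
            if j - i >= lo:
                runs.append((i, j))
            i = j
        else:
            i += 1
    taken = np.zeros(n, dtype=bool)
    spans: list[tuple[int, int]] = []
    attempts = 0
    while len(spans) < cfg.n_domains and attempts < cfg.n_domains * 50:
        attempts += 1
        s, e = runs[int(rng.integers(len(runs)))]
        size = int(rng.integers(lo, hi + 1))
        if e - s < size:
            continue
        x = int(rng.integers(s, e - size + 1))
        if taken[x: x + size].any():
            continue
        taken[x: x + size] = True
        spans.append((x, x + size))
    return sorted(spans)


def generate_contact_maps(
    cfg: SyntheticConfig,
    labelings: Sequence[SubcompartmentLabeling],
    rng: np.random.Generator,
) -> tuple[ContactMap, ContactMap, DomainSet, dict[str, object]]:
    """Poisson-sampled intra and inter maps plus planted domains.

    Intra intensity: ``depth * (1+d)^-alpha * a_i * a_j`` with per-rank
    affinities a; pairs inside a planted domain instead get the exact
    expected B-compartment background at their distance plus the enrichment
    ``e``, so the recovered strength of a planted domain is ``e`` in
    expectation. Inter intensity: ``depth_inter * exp(-|rank_i-rank_j|/tau)``
    — a state-similarity kernel under which the interchromosomal A/B ratio
    decreases strictly from A1 to B4. Intensities are treated as balanced
    contact values and Poisson-sampled.
    """
    ref = labelings[0]
    g = ref.genome
    aff = _bin_affinity(cfg, ref)
    mask = derive_compartment_mask(ref)
    blocks = mask.b_blocks
    max_block = max(e - s for s, e in blocks) if blocks else 1
    spans = _plant_domains(cfg, ref, rng, max_span_bins=max_block - 1)
    in_domain = np.full(g.n_bins, -1, dtype=np.int64)
    for k, (s, e) in enumerate(spans):
        in_domain[s:e] = k

    # exact expected background per distance from the base intensity
    alpha = cfg.decay_exponent
    lmax = max_block - 1
    bg_num = np.zeros(lmax + 1)
    bg_cnt = np.zeros(lmax + 1, dtype=np.int64)
    for s, e in blocks:
        a = aff[s:e]
        n = e - s
        bg_num[0] += float((a * a).sum())
        bg_cnt[0] += n
        for l in range(1, min(n, lmax + 1)):
            bg_num[l] += float((a[:-l] * a[l:]).sum())
            bg_cnt[l] += n - l
    b_expected = np.full(lmax + 1, np.nan)
    nz = bg_cnt > 0
    b_expected[nz] = (
        cfg.depth_intra * (1.0 + np.arange(lmax + 1)[nz]) ** (-alpha)
        * bg_num[nz] / bg_cnt[nz]
    )

    rows_all, cols_all, vals_all = [], [], []
    chrom_codes = g.bin_chrom_codes
    for chrom in g.chroms:
        sl = g.chrom_slice(chrom)
        idx = np.arange(sl.start, sl.stop)
        nloc = idx.size
        ii, jj = np.triu_indices(nloc)
        gi, gj = idx[ii], idx[jj]
        d = jj - ii
        lam = (
            cfg.depth_intra * (1.0 + d) ** (-alpha) * aff[gi] * aff[gj]
        )
        dom = (in_domain[gi] >= 0) & (in_domain[gi] == in_domain[gj])
        if dom.any():
            lam[dom] = b_expected[d[dom]] + cfg.domain_enrichment
        counts = rng.poisson(lam)
        keep = counts > 0
        rows_all.append(gi[keep])
        cols_all.append(gj[keep])
        vals_all.append(counts[keep].astype(float))
    intra = ContactMap(
        g, "intra",
        np.concatenate(rows_all), np.concatenate(cols_all),
        np.concatenate(vals_all),
    )

    ranks = np.where(ref.codes >= 0, ref.codes, 3.5).astype(float)
    rows_all, cols_all, vals_all = [], [], []
    for ci in range(len(g.chroms)):
        for cj in range(ci + 1, len(g.chroms)):
            i_idx = np.flatnonzero(chrom_codes == ci)
            j_idx = np.flatnonzero(chrom_codes == cj)
            gi = np.repeat(i_idx, j_idx.size)
            gj = np.tile(j_idx, i_idx.size)
            lam = cfg.depth_inter * np.exp(
                -np.abs(ranks[gi] - ranks[gj]) / cfg.inter_tau
            )
            counts = rng.poisson(lam)
            keep = counts > 0
            rows_all.append(gi[keep])
            cols_all.append(gj[keep])
            vals_all.append(counts[keep].astype(float))
    inter = ContactMap(
        g, "inter",
        np.concatenate(rows_all), np.concatenate(cols_all),
        np.concatenate(vals_all),
    )

    domains = DomainSet(
        [
            Domain(*_span_to_interval(g, s, e), resolution=g.bin_size,
                   id=f"dom{k:04d}")
            for k, (s, e) in enumerate(spans)
        ]
    )
    truth = {
        "domain_enrichment": cfg.domain_enrichment,
        "domain_spans": spans,
        "expected_background": b_expected,
        "affinities": cfg.affinities,
    }
    return intra, inter, domains, truth


def _span_to_interval(g: BinnedGenome, s: int, e: int) -> tuple[str, int, int]:
    chrom, bs, _ = g.bin_location(s)
    _, _, be = g.bin_location(e - 1)
    return chrom, bs, be


# ---------------------------------------------------------------------------
# genes, expression, signal
# ---------------------------------------------------------------------------


def generate_expression(
    cfg: SyntheticConfig,
    labelings: Sequence[SubcompartmentLabeling],
    truth: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[GeneTable, ExpressionMatrix, list[str], dict[str, SignalTrack]]:
    """Genes, FPKM matrix, housekeeping list and per-mark signal tracks.

    Gradient genes are placed per bin with a Poisson rate set by the bin's
    genomic context (common A1 densest, then variable A1, then A2..B4 of the
    reference labeling) and get log-normal FPKM whose median follows the
    bin's state in each cell type. Housekeeping genes are high in every cell
    type and split between common/variable A1 by territory length; each
    cell-type-specific gene is high in exactly one cell type and placed in
    variable-vs-common A1 with the configured odds multiplier.
    """
    ref = labelings[0]
    g = ref.genome
    common_a1 = np.asarray(truth["common_a1"])
    ref_a1 = ref.bins_with("A1")
    variable_a1 = np.setdiff1d(ref_a1, common_a1)
    mb_per_bin = g.bin_size / 1e6

    context = ref.labels.astype("<U12").copy()
    context[ref_a1] = "variable_A1"
    context[common_a1] = "common_A1"

    genes_rows: list[tuple[str, str, int, str, bool]] = []
    fpkm_rows: dict[str, np.ndarray] = {}
    counter = 0

    def new_gene(bin_idx: int, hk: bool) -> str:
        nonlocal counter
        chrom, s, e = g.bin_location(int(bin_idx))
        tss = int(rng.integers(s, e))
        strand = "+" if rng.random() < 0.5 else "-"
        gid = f"g{counter:05d}"
        counter += 1
        genes_rows.append((gid, chrom, tss, strand, hk))
        return gid

    medians = np.asarray(cfg.fpkm_medians)

    def gradient_fpkm(bin_idx: int) -> np.ndarray:
        out = np.empty(len(cfg.cell_types))
        for k, lab in enumerate(labelings):
            code = lab.codes[bin_idx]
            med = medians[code] if code >= 0 else medians.mean()
            out[k] = rng.lognormal(np.log(med), cfg.fpkm_sigma)
        return out

    # gradient genes by per-context density
    for b in range(g.n_bins):
        ctx = context[b]
        rate = cfg.gene_density_per_mb.get(ctx, 0.5) * mb_per_bin
        for _ in range(int(rng.poisson(rate))):
            gid = new_gene(b, hk=False)
            fpkm_rows[gid] = gradient_fpkm(b)

    # housekeeping: split across common/variable A1 by territory length
    len_c, len_v = common_a1.size, variable_a1.size
    p_var_hk = len_v / (len_v + len_c)
    for _ in range(cfg.n_housekeeping):
        pool = variable_a1 if rng.random() < p_var_hk else common_a1
        b = int(pool[rng.integers(pool.size)])
        gid = new_gene(b, hk=True)
        fpkm_rows[gid] = rng.lognormal(
            np.log(30.0), cfg.fpkm_sigma, size=len(cfg.cell_types)
        )

    # cell-type-specific: variable-vs-common odds multiplied by the knob
    odds_var = cfg.placement_odds * (len_v / max(len_c, 1))
    p_var_sp = odds_var / (1.0 + odds_var)
    for ct_i, ct in enumerate(cfg.cell_types):
        for _ in range(cfg.n_specific_per_cell_type):
            pool = variable_a1 if rng.random() < p_var_sp else common_a1
            b = int(pool[rng.integers(pool.size)])
            gid = new_gene(b, hk=False)
            f = rng.lognormal(
                np.log(0.3), cfg.fpkm_sigma, size=len(cfg.cell_types)
            )
            f[ct_i] = rng.lognormal(np.log(20.0), cfg.fpkm_sigma)
            fpkm_rows[gid] = f

    gdf = pd.DataFrame(
        genes_rows, columns=["gene_id", "chrom", "tss", "strand", "housekeeping"]
    )
    genes = GeneTable(gdf)
    fpkm = pd.DataFrame.from_dict(
        fpkm_rows, orient="index", columns=list(cfg.cell_types)
    )
    fpkm.index.name = "gene_id"
    expr = ExpressionMatrix(fpkm)
    hk_list = gdf.loc[gdf["housekeeping"], "gene_id"].tolist()

    # per-mark tracks with monotone per-rank means (reference cell type)
    mark_means = {
        "H3K27ac": np.linspace(8, 1, 8),
        "Nipbl": np.linspace(6, 1, 8),
        "H3K9me3": np.linspace(1, 8, 8),
    }
    tracks: dict[str, SignalTrack] = {}
    codes = ref.codes
    for mark, mus in mark_means.items():
        vals = np.where(
            codes >= 0,
            mus[np.clip(codes, 0, 7)],
            np.nan,
        ) + rng.normal(0, cfg.signal_noise_sd, g.n_bins)
        tracks[mark] = SignalTrack(g, vals, mark=mark)
    return genes, expr, hk_list, tracks


def generate_dataset(
    cfg: SyntheticConfig | None = None, seed: int = 0
) -> SyntheticDataset:
    """Generate the full bundle from one seed (end-to-end deterministic)."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(seed)
    g = cfg.genome()
    labelings, truth = generate_labelings(cfg, rng, g)
    intra, inter, domains, ctruth = generate_contact_maps(cfg, labelings, rng)
    genes, expr, hk, tracks = generate_expression(cfg, labelings, truth, rng)
    truth = {**truth, **ctruth, "placement_odds": cfg.placement_odds}
    return SyntheticDataset(
        config=cfg, genome=g, labelings=labelings, intra=intra, inter=inter,
        domains=domains, genes=genes, expression=expr, housekeeping=hk,
        tracks=tracks, truth=truth,
    )
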