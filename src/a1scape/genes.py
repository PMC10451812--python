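"""Gene classes from FPKM and their positioning across subcompartments.

Gene classes follow the standard thresholds: active FPKM > 1, highly
expressed FPKM > 10, cell type-specific = active in one cell type with at
least five-fold higher FPKM than every other cell type. Genes are located
by TSS (the annotated start for + strand records, the annotated end for -
strand). Density, gap-length, Fisher-enrichment and expression-by-state
statistics all consume these classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st

from .genome import BinnedGenome, normalize_chrom_name
from .labels import LABELS, SubcompartmentLabeling
from .transitions import RegionSet, TransitionTable

logger = logging.getLogger(__name__)

__all__ = [
    "GeneTable",
    "ExpressionMatrix",
    "GeneClassification",
    "classify_genes",
    "gene_density",
    "density_by_subcompartment",
    "gap_lengths",
    "EnrichmentResult",
    "enrichment_odds_ratio",
    "adjust_bh",
    "expression_by_subcompartment",
    "expression_change_by_transition",
]


@dataclass
class GeneTable:
    """Gene id / chrom / TSS / strand / housekeeping flag table.

    ``df`` columns: gene_id (unique), chrom, tss (bp), strand, housekeeping
    (bool).
    """

    df: pd.DataFrame

    REQUIRED = ("gene_id", "chrom", "tss", "strand", "housekeeping")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.df.columns)
        if missing:
            raise ValueError(f"gene table missing columns {sorted(missing)}")
        if self.df["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, gene_ids: Iterable[str]) -> "GeneTable":
        ids = set(gene_ids)
        return GeneTable(self.df[self.df["gene_id"].isin(ids)].copy())

    def tss_bins(self, genome: BinnedGenome) -> pd.Series:
        """Global bin index of each TSS (NaN for off-genome genes)."""
        out = np.full(len(self.df), -1, dtype=np.int64)
        for k, (chrom, tss) in enumerate(
            zip(self.df["chrom"], self.df["tss"])
        ):
            try:
                out[k] = genome.bin_index(str(chrom), int(tss))
            except (KeyError, ValueError):
                out[k] = -1
        return pd.Series(out, index=self.df["gene_id"].to_numpy())


@dataclass
class ExpressionMatrix:
    """Per-gene FPKM across cell types, with the class thresholds attached."""

    fpkm: pd.DataFrame          # index gene_id, columns cell types
    active_threshold: float = 1.0
    high_threshold: float = 10.0
    specificity_fold: float = 5.0

    def __post_init__(self) -> None:
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def cell_types(self) -> list[str]:
        return list(self.fpkm.columns)


@dataclass
class GeneClassification:
    """Boolean class flags per gene and cell type."""

    active: pd.DataFrame         # genes x cell types
    high: pd.DataFrame
    specific: pd.DataFrame       # at most one True per gene row
    housekeeping: pd.Series      # cell-type independent

    def genes_of(self, klass: str, cell_type: str | None = None) -> pd.Index:
        if klass == "housekeeping":
            return self.housekeeping.index[self.housekeeping]
        table = {"active": self.active, "high": self.high,
                 "specific": self.specific}[klass]
        if cell_type is None:
            return table.index[table.any(axis=1)]
        return table.index[table[cell_type]]


def classify_genes(
    expr: ExpressionMatrix,
    genes: GeneTable,
    *,
    specificity_mode: str = "each",
    eps: float = 0.01,
) -> GeneClassification:
    """Assign active / highly-expressed / cell type-specific flags.

    A gene is specific to cell type c iff FPKM_c exceeds the active
    threshold and FPKM_c / max(FPKM_other, eps) >= fold for every other
    cell type (``specificity_mode="each"``; ``"max"`` tests only against
    the largest other value — mathematically the same — and ``"mean"``
    against their mean). ``eps`` guards division by zero.
    """
    f = expr.fpkm
    if f.shape[1] < 2:
        raise ValueError("specificity needs at least two cell types")
    active = f > expr.active_threshold
    high = f > expr.high_threshold
    vals = f.to_numpy(dtype=float)
    n_ct = vals.shape[1]
    spec = np.zeros_like(vals, dtype=bool)
    for c in range(n_ct):
        others = np.delete(vals, c, axis=1)
        if specificity_mode in ("each", "max"):
            ref = others.max(axis=1)
        elif specificity_mode == "mean":
            ref = others.mean(axis=1)
        else:
            raise ValueError(f"unknown specificity_mode {specificity_mode!r}")
        fold = vals[:, c] / np.maximum(ref, eps)
        spec[:, c] = (vals[:, c] > expr.active_threshold) & (
            fold >= expr.specificity_fold
        )
    specific = pd.DataFrame(spec, index=f.index, columns=f.columns)
    hk = (
        genes.df.set_index("gene_id")["housekeeping"]
        .reindex(f.index)
        .fillna(False)
        .astype(bool)
    )
    return GeneClassification(
        active=active, high=high, specific=specific, housekeeping=hk
    )


# ---------------------------------------------------------------------------
# positioning statistics
# ---------------------------------------------------------------------------


def _tss_in_intervals(
    genes: GeneTable, intervals: Sequence[tuple[str, int, int]]
) -> np.ndarray:
    """Boolean: TSS of each gene falls inside any half-open interval."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    starts = {c: np.array(sorted(s for s, _ in iv)) for c, iv in by_chrom.items()}
    ends = {c: np.array(sorted(e for _, e in iv)) for c, iv in by_chrom.items()}
    out = np.zeros(len(genes.df), dtype=bool)
    for k, (chrom, tss) in enumerate(zip(genes.df["chrom"], genes.df["tss"])):
        chrom = normalize_chrom_name(str(chrom))
        if chrom not in starts:
            continue
        idx = np.searchsorted(starts[chrom], tss, side="right") - 1
        if idx >= 0 and tss < ends[chrom][idx]:
            out[k] = True
    return out


def gene_density(
    genes: GeneTable, regions: RegionSet | Sequence[tuple[str, int, int]]
) -> float:
    """TSS count per Mbp of region territory."""
    intervals = regions.intervals if isinstance(regions, RegionSet) else list(regions)
    total_bp = sum(e - s for _, s, e in intervals)
    if total_bp == 0:
        raise ValueError("region has zero length")
    n = int(_tss_in_intervals(genes, intervals).sum())
    return n / (total_bp / 1e6)


def density_by_subcompartment(
    genes: GeneTable, labeling: SubcompartmentLabeling
) -> pd.Series:
    """Gene density (per Mbp) in each of the eight subcompartments."""
    g = labeling.genome
    out = {}
    for lab in LABELS:
        bins = labeling.bins_with(lab)
        if bins.size == 0:
            out[lab] = np.nan
            continue
        out[lab] = gene_density(genes, g.bins_to_intervals(bins))
    return pd.Series(out)


def gap_lengths(
    genes: GeneTable, regions: RegionSet
) -> dict[str, object]:
    """Gaps between consecutive TSS inside each merged region interval.

    Gaps never span interval breaks. Returns the pooled gap array plus
    median and quartiles; an empty distribution (fewer than two TSS in every
    interval) is returned with a warning rather than raised.
    """
    tss_by_chrom: dict[str, np.ndarray] = {
        c: np.sort(sub["tss"].to_numpy())
        for c, sub in genes.df.groupby(genes.df["chrom"].map(normalize_chrom_name))
    }
    gaps: list[np.ndarray] = []
    for chrom, s, e in regions.intervals:
        pos = tss_by_chrom.get(chrom)
        if pos is None:
            continue
        inside = pos[(pos >= s) & (pos < e)]
        if inside.size >= 2:
            gaps.append(np.diff(inside))
    allg = np.concatenate(gaps) if gaps else np.array([], dtype=np.int64)
    if allg.size == 0:
        warnings.warn(f"no gaps measurable in {regions.name}")
        return dict(gaps=allg, median=np.nan, q1=np.nan, q3=np.nan, n=0)
    return dict(
        gaps=allg,
        median=float(np.median(allg)),
        q1=float(np.percentile(allg, 25)),
        q3=float(np.percentile(allg, 75)),
        n=int(allg.size),
    )


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    """2x2 Fisher exact test with the cross-product odds ratio.

    ``table`` rows are the two gene sets, columns the two region classes:
    [[set1_in_A, set1_in_B], [set2_in_A, set2_in_B]]. The OR is computed on
    raw counts with no continuity correction and flagged NaN when a cell of
    the off-diagonal product is zero.
    """

    table: np.ndarray
    odds_ratio: float
    p_value: float
    description: str = ""
    p_adjusted: float | None = None


def enrichment_odds_ratio(
    set1_in_a: int, set1_in_b: int, set2_in_a: int, set2_in_b: int,
    description: str = "",
) -> EnrichmentResult:
    """Fisher exact test on a 2x2 gene-set x region contingency table."""
    table = np.array(
        [[set1_in_a, set1_in_b], [set2_in_a, set2_in_b]], dtype=np.int64
    )
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if table.sum() == 0:
        raise ValueError("empty contingency table")
    a, b, c, d = table.ravel()
    odds = (a * d) / (b * c) if b * c > 0 else float("nan")
    _, p = st.fisher_exact(table, alternative="two-sided")
    return EnrichmentResult(
        table=table, odds_ratio=float(odds), p_value=float(p),
        description=description,
    )


def region_enrichment(
    genes1: GeneTable,
    genes2: GeneTable,
    region_a: RegionSet,
    region_b: RegionSet,
    description: str = "",
) -> EnrichmentResult:
    """Contrast two gene sets' TSS membership across two region classes."""
    a1 = int(_tss_in_intervals(genes1, region_a.intervals).sum())
    b1 = int(_tss_in_intervals(genes1, region_b.intervals).sum())
    a2 = int(_tss_in_intervals(genes2, region_a.intervals).sum())
    b2 = int(_tss_in_intervals(genes2, region_b.intervals).sum())
    desc = description or (
        f"{region_a.name} vs {region_b.name}"
    )
    return enrichment_odds_ratio(a1, b1, a2, b2, desc)


def adjust_bh(results: Sequence[EnrichmentResult]) -> None:
    """Benjamini-Hochberg adjust a batch of enrichment results in place."""
    ps = np.array([r.p_value for r in results])
    qs = st.false_discovery_control(ps, method="bh")
    for r, q in zip(results, qs):
        r.p_adjusted = float(q)


# ---------------------------------------------------------------------------
# expression vs positioning
# ---------------------------------------------------------------------------


def expression_by_subcompartment(
    expr: ExpressionMatrix,
    labeling: SubcompartmentLabeling,
    genes: GeneTable,
    cell_type: str | None = None,
) -> dict[str, object]:
    """log2(FPKM+1) distributions grouped by the TSS bin's subcompartment.

    Returns the per-label value arrays and the omnibus Kruskal-Wallis
    statistic across groups with at least one gene (empty labels are dropped
    with a warning).
    """
    ct = cell_type or labeling.cell_type
    if ct not in expr.fpkm.columns:
        raise KeyError(f"no FPKM column for cell type {ct!r}")
    bins = genes.tss_bins(labeling.genome)
    vals = np.log2(expr.fpkm[ct].reindex(bins.index).to_numpy() + 1.0)
    groups: dict[str, np.ndarray] = {}
    for lab in LABELS:
        member = np.isin(bins.to_numpy(), labeling.bins_with(lab))
        member &= np.isfinite(vals)
        if member.sum() == 0:
            warnings.warn(f"label {lab} has zero genes; dropped")
            continue
        groups[lab] = vals[member]
    if len(groups) < 2:
        raise ValueError("fewer than two non-empty label groups")
    samples = list(groups.values())
    if all(np.allclose(s, samples[0][0]) for s in samples):
        h, p = 0.0, 1.0
    else:
        h, p = st.kruskal(*samples)
    return dict(groups=groups, h_statistic=float(h), p_value=float(p))


def expression_change_by_transition(
    expr_src: pd.Series,
    expr_dst: pd.Series,
    src_labeling: SubcompartmentLabeling,
    dst_labeling: SubcompartmentLabeling,
    genes: GeneTable,
    *,
    fold_threshold: float = 1.0,
) -> pd.DataFrame:
    """Up/down-regulation composition of every subcompartment move.

    Genes are assigned a move (s, t) from the labels of their TSS bin in
    the source and destination cell types, and called up/down when
    |log2((FPKM_dst+1)/(FPKM_src+1))| >= ``fold_threshold``. Each cell's
    up-vs-down split is Fisher-tested against the pooled split of all
    genes; BH-adjusted q-values and significance tiers are attached.
    Cells with zero genes are NA.
    """
    bins = genes.tss_bins(src_labeling.genome)
    ids = bins.index
    delta = np.log2(expr_dst.reindex(ids).to_numpy() + 1.0) - np.log2(
        expr_src.reindex(ids).to_numpy() + 1.0
    )
    up = delta >= fold_threshold
    down = delta <= -fold_threshold
    src_lab = src_labeling.labels[bins.to_numpy()]
    dst_lab = dst_labeling.labels[bins.to_numpy()]
    ok = (bins.to_numpy() >= 0) & (src_lab != "NA") & (dst_lab != "NA")
    ok &= np.isfinite(delta)
    bg_up = int(up[ok].sum())
    bg_down = int(down[ok].sum())
    rows = []
    for s in LABELS:
        for t in LABELS:
            member = ok & (src_lab == s) & (dst_lab == t)
            n = int(member.sum())
            if n == 0:
                rows.append(dict(src=s, dst=t, n=0, n_up=np.nan,
                                 n_down=np.nan, odds_ratio=np.nan,
                                 p_value=np.nan))
                continue
            cu, cd = int(up[member].sum()), int(down[member].sum())
            table = [[cu, cd], [bg_up, bg_down]]
            if (cu + cd) == 0 or (bg_up + bg_down) == 0:
                odds, p = np.nan, np.nan
            else:
                odds = (
                    (cu * bg_down) / (cd * bg_up)
                    if cd * bg_up > 0 else np.nan
                )
                _, p = st.fisher_exact(table)
            rows.append(dict(src=s, dst=t, n=n, n_up=cu, n_down=cd,
                             odds_ratio=odds, p_value=p))
    grid = pd.DataFrame(rows)
    ps = grid["p_value"].to_numpy()
    finite = np.isfinite(ps)
    q = np.full_like(ps, np.nan)
    if finite.any():
        q[finite] = st.false_discovery_control(ps[finite], method="bh")
    grid["q_value"] = q
    grid["tier"] = np.select(
        [grid["p_value"] < 0.01, grid["p_value"] < 0.05],
        ["**", "*"], default="",
    )
    return grid
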