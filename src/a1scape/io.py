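"""Readers and writers for the text formats the pipeline consumes.

Covers subcompartment BED (raw Calder ``A.1.1`` labels or renamed
``A1..B4``), Arrowhead-style bedpe/TSV domain calls, TAD BED, gene BED6 and
(gene-feature) GTF, FPKM and housekeeping TSVs, and bedGraph / bigWig signal.
Contact dumps live in :mod:`a1scape.contacts`.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .boundaries import SignalTrack
from .domains import Domain, DomainSet
from .genes import ExpressionMatrix, GeneTable
from .genome import BinnedGenome, normalize_chrom_name
from .labels import (
    LABELS,
    NA_LABEL,
    RAW_LABEL_MAP,
    SubcompartmentLabeling,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_subcompartment_bed",
    "write_subcompartment_bed",
    "read_domain_bedpe",
    "read_tad_bed",
    "read_gene_bed",
    "read_gene_gtf",
    "read_fpkm_tsv",
    "read_housekeeping_tsv",
    "read_bedgraph",
    "read_bigwig",
]


class LabelFormatError(ValueError):
    pass


def _normalize_label(raw: str) -> str:
    raw = raw.strip()
    if raw in RAW_LABEL_MAP:
        return RAW_LABEL_MAP[raw]
    if raw in LABELS or raw == NA_LABEL:
        return raw
    raise LabelFormatError(f"unknown subcompartment label {raw!r}")


def read_subcompartment_bed(
    path: str | Path,
    genome: BinnedGenome,
    cell_type: str = "",
) -> SubcompartmentLabeling:
    """Load a labeling from BED4, assigning each bin by maximal overlap.

    Intervals may carry raw Calder labels (renamed through the fixed
    A.1.1->A1 ... B.2.2->B4 map) or already-renamed names. Each bin takes
    the label of the interval overlapping it most; exact ties go to the
    interval earlier in sorted genomic order (logged). Uncovered bins are
    NA; chromosomes absent from the genome (e.g. excluded sex chromosomes)
    are skipped.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "label"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "label": str},
    )
    if len(df) == 0:
        raise ValueError(f"{path}: empty annotation")
    df["chrom"] = df["chrom"].map(normalize_chrom_name)
    df["label"] = df["label"].map(_normalize_label)
    chrom_order = {c: k for k, c in enumerate(genome.chroms)}
    df = df[df["chrom"].isin(chrom_order)]
    df = df.sort_values(
        ["chrom", "start", "end"],
        key=lambda col: col.map(chrom_order) if col.name == "chrom" else col,
    )
    # per-(bin, label) overlap accumulation: assignment is then invariant
    # under splitting an interval into adjacent same-label pieces
    acc = np.zeros((genome.n_bins, len(LABELS)), dtype=np.int64)
    first_seen = np.full((genome.n_bins, len(LABELS)), np.iinfo(np.int64).max,
                         dtype=np.int64)
    bs = genome.bin_size
    for order, (chrom, start, end, label) in enumerate(df.itertuples(index=False)):
        if label == NA_LABEL:
            continue
        clen = genome.chrom_length(chrom)
        start, end = max(0, int(start)), min(int(end), clen)
        if start >= end:
            continue
        off = genome.chrom_offset(chrom)
        b0 = off + start // bs
        b1 = off + (end - 1) // bs
        idx = np.arange(b0, b1 + 1)
        bin_lo = (idx - off) * bs
        bin_hi = np.minimum(bin_lo + bs, clen)
        ov = np.minimum(bin_hi, end) - np.maximum(bin_lo, start)
        li = LABELS.index(label)
        acc[idx, li] += ov
        first_seen[idx, li] = np.minimum(first_seen[idx, li], order)
    labels = np.full(genome.n_bins, NA_LABEL, dtype="<U2")
    covered = np.flatnonzero(acc.sum(axis=1) > 0)
    best = acc.max(axis=1)
    ties = 0
    for b in covered:
        cand = np.flatnonzero(acc[b] == best[b])
        if cand.size > 1:
            ties += 1
            # exact tie: the label whose interval appears first in sorted order
            cand = cand[np.argsort(first_seen[b, cand], kind="stable")][:1]
        labels[b] = LABELS[int(cand[0])]
    if ties:
        logger.info(
            "%s: %d exact overlap ties resolved to the earlier interval",
            path, ties,
        )
    return SubcompartmentLabeling(
        genome=genome, cell_type=cell_type, labels=labels,
        provenance=str(path),
    )


def write_subcompartment_bed(
    labeling: SubcompartmentLabeling, path: str | Path
) -> None:
    """Write merged same-label runs as BED4 (NA bins omitted)."""
    g = labeling.genome
    with open(path, "w") as fh:
        run_start = None
        prev = None
        for i in range(g.n_bins + 1):
            cur = None
            if i < g.n_bins:
                chrom, s, e = g.bin_location(i)
                lab = labeling.labels[i]
                cur = (chrom, lab) if lab != NA_LABEL else None
            if cur != prev:
                if prev is not None:
                    pc, pl = prev
                    fh.write(f"{pc}\t{run_start}\t{run_end}\t{pl}\n")
                if cur is not None:
                    run_start = s
                prev = cur
            if cur is not None:
                run_end = e


def read_domain_bedpe(path: str | Path, resolution: int | None = None) -> DomainSet:
    """Parse Arrowhead-style bedpe/TSV domain calls.

    Uses the first six columns (chrom1 x1 x2 chrom2 y1 y2); Arrowhead emits
    on-diagonal squares, so the domain interval is (chrom1, min(x1, y1),
    max(x2, y2)). Header lines starting with 'chr1'/'#' are skipped.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 6:
                raise ValueError(f"{path}: expected >= 6 bedpe columns")
            try:
                int(parts[1])
            except ValueError:  # header row ("chr1 x1 x2 chr2 y1 y2 ...")
                continue
            c1 = normalize_chrom_name(parts[0])
            c2 = normalize_chrom_name(parts[3])
            if c1 != c2:
                raise ValueError(f"{path}: interchromosomal domain record")
            x1, x2 = int(parts[1]), int(parts[2])
            y1, y2 = int(parts[4]), int(parts[5])
            rows.append(Domain(c1, min(x1, y1), max(x2, y2), resolution))
    return DomainSet(rows).sorted()


def read_tad_bed(path: str | Path, resolution: int | None = None) -> DomainSet:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    doms = [
        Domain(normalize_chrom_name(c), int(s), int(e), resolution)
        for c, s, e in df.itertuples(index=False)
    ]
    return DomainSet(doms).sorted()


# ---------------------------------------------------------------------------
# genes & expression
# ---------------------------------------------------------------------------


def _finish_gene_table(
    df: pd.DataFrame, housekeeping: Iterable[str] | None
) -> GeneTable:
    hk = set(housekeeping) if housekeeping is not None else set()
    df = df.copy()
    df["housekeeping"] = df["gene_id"].isin(hk)
    return GeneTable(df)


def read_gene_bed(
    path: str | Path, housekeeping: Iterable[str] | None = None
) -> GeneTable:
    """BED6 genes; the TSS is the start for '+' records, the end-1 for '-'."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3, 5], names=["chrom", "start", "end", "gene_id", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "gene_id": str, "strand": str},
    )
    df["chrom"] = df["chrom"].map(normalize_chrom_name)
    df["tss"] = np.where(df["strand"] == "-", df["end"] - 1, df["start"])
    return _finish_gene_table(
        df[["gene_id", "chrom", "tss", "strand"]], housekeeping
    )


def read_gene_gtf(
    path: str | Path,
    housekeeping: Iterable[str] | None = None,
    feature: str = "gene",
) -> GeneTable:
    """Minimal GTF reader: keeps ``feature`` records, extracts gene_id."""
    import re

    pat = re.compile(r'gene_id "([^"]+)"')
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != feature:
                continue
            m = pat.search(parts[8])
            if not m:
                continue
            chrom = normalize_chrom_name(parts[0])
            start, end = int(parts[3]) - 1, int(parts[4])  # GTF is 1-based
            strand = parts[6]
            tss = end - 1 if strand == "-" else start
            rows.append((m.group(1), chrom, tss, strand))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    df = df.drop_duplicates(subset="gene_id")
    return _finish_gene_table(df, housekeeping)


def read_fpkm_tsv(path: str | Path, **thresholds) -> ExpressionMatrix:
    """TSV with a gene_id column and one FPKM column per cell type."""
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "gene_id"
    return ExpressionMatrix(df.astype(float), **thresholds)


def read_housekeeping_tsv(path: str | Path) -> list[str]:
    """One gene id per line (first tab-separated field; header 'gene_id' ok)."""
    out = []
    with open(path) as fh:
        for line in fh:
            tok = line.split("\t")[0].strip()
            if tok and tok.lower() not in ("gene_id", "gene"):
                out.append(tok)
    return out


# ---------------------------------------------------------------------------
# signal
# ---------------------------------------------------------------------------


def read_bedgraph(
    path: str | Path, genome: BinnedGenome, mark: str = ""
) -> SignalTrack:
    """Average a bedGraph into per-bin means (coverage-weighted).

    Bins with no overlapping record are flagged no-data rather than
    zero-filled.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "value": np.float64},
    )
    df["chrom"] = df["chrom"].map(normalize_chrom_name)
    num = np.zeros(genome.n_bins)
    cov = np.zeros(genome.n_bins)
    bs = genome.bin_size
    for chrom, start, end, value in df.itertuples(index=False):
        if chrom not in genome.chrom_index:
            continue
        clen = genome.chrom_length(chrom)
        start, end = max(0, start), min(end, clen)
        if start >= end or not np.isfinite(value):
            continue
        off = genome.chrom_offset(chrom)
        b0, b1 = off + start // bs, off + (end - 1) // bs
        idx = np.arange(b0, b1 + 1)
        lo = (idx - off) * bs
        hi = np.minimum(lo + bs, clen)
        ov = np.minimum(hi, end) - np.maximum(lo, start)
        num[idx] += ov * value
        cov[idx] += ov
    values = np.full(genome.n_bins, np.nan)
    has = cov > 0
    values[has] = num[has] / cov[has]
    return SignalTrack(genome, values, mark=mark, no_data=~has)


def read_bigwig(
    path: str | Path, genome: BinnedGenome, mark: str = ""
) -> SignalTrack:
    """Per-bin mean from a bigWig (requires pyBigWig)."""
    import pyBigWig  # optional dependency

    bw = pyBigWig.open(str(path))
    values = np.full(genome.n_bins, np.nan)
    try:
        names = {normalize_chrom_name(c): c for c in bw.chroms()}
        for chrom in genome.chroms:
            if chrom not in names:
                continue
            sl = genome.chrom_slice(chrom)
            n = sl.stop - sl.start
            clen = min(genome.chrom_length(chrom), bw.chroms()[names[chrom]])
            stats = bw.stats(
                names[chrom], 0, clen, nBins=n, type="mean", exact=True
            )
            vals = np.array(
                [np.nan if s is None else float(s) for s in stats]
            )
            values[sl] = vals
    finally:
        bw.close()
    return SignalTrack(genome, values, mark=mark)
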