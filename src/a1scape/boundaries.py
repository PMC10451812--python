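"""Boundary metagene profiles, inside/outside-domain counts, signal by state.

TSS profiles around TAD / contact-domain boundaries are orientation-agnostic
metagenes: each boundary contributes its window of offset bins, edges near
chromosome ends contribute only their valid offsets, and the profile is the
mean TSS count per offset bin per contributing boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .domains import DomainSet
from .genes import GeneTable, _tss_in_intervals
from .genome import BinnedGenome, normalize_chrom_name
from .labels import LABELS, SubcompartmentLabeling
from .transitions import RegionSet

logger = logging.getLogger(__name__)

__all__ = [
    "BoundaryProfile",
    "boundary_gene_profile",
    "InsideOutsideCounts",
    "inside_outside_domain_counts",
    "SignalTrack",
    "signal_by_subcompartment",
]


@dataclass
class BoundaryProfile:
    half_width: int
    bin_width: int
    offsets: np.ndarray            # bp offset of each profile bin's left edge
    counts: np.ndarray             # total TSS per offset bin
    boundaries_per_offset: np.ndarray
    n_boundaries: int
    gene_class: str = ""

    @property
    def normalized(self) -> np.ndarray:
        """Mean TSS per profile bin per boundary (NaN where no boundary)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.boundaries_per_offset > 0,
                self.counts / self.boundaries_per_offset,
                np.nan,
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                offset=self.offsets,
                count=self.counts,
                n_boundaries=self.boundaries_per_offset,
                mean_tss=self.normalized,
            )
        )


def boundary_gene_profile(
    boundaries: Sequence[tuple[str, int]],
    genes: GeneTable,
    chrom_lengths: dict[str, int],
    *,
    half_width: int = 500_000,
    bin_width: int = 50_000,
    gene_class: str = "",
) -> BoundaryProfile:
    """Average TSS counts in offset bins centered on each boundary.

    Offset bin k (k = -W..W-1 in units of ``bin_width``) covers
    [boundary + k*bin_width, boundary + (k+1)*bin_width). Offset bins
    extending beyond the boundary's chromosome are excluded from that
    boundary's average (per-offset denominators track how many boundaries
    contributed).
    """
    if half_width % bin_width != 0:
        raise ValueError("window must fit the profile bin width evenly")
    if len(boundaries) == 0:
        raise ValueError("need at least one boundary")
    w = half_width // bin_width
    offsets = (np.arange(-w, w)) * bin_width
    counts = np.zeros(2 * w)
    denom = np.zeros(2 * w, dtype=np.int64)
    if len(genes) == 0:
        warnings.warn("empty gene set; profile is all zero")
    tss_by_chrom = {
        c: np.sort(sub["tss"].to_numpy())
        for c, sub in genes.df.groupby(
            genes.df["chrom"].map(normalize_chrom_name)
        )
    }
    lengths = {normalize_chrom_name(c): l for c, l in chrom_lengths.items()}
    for chrom, pos in boundaries:
        chrom = normalize_chrom_name(chrom)
        clen = lengths[chrom]
        tss = tss_by_chrom.get(chrom, np.array([]))
        for k in range(2 * w):
            lo = pos + offsets[k]
            hi = lo + bin_width
            if lo < 0 or hi > clen:
                continue
            denom[k] += 1
            if tss.size:
                counts[k] += int(
                    np.searchsorted(tss, hi, side="left")
                    - np.searchsorted(tss, lo, side="left")
                )
    return BoundaryProfile(
        half_width=half_width,
        bin_width=bin_width,
        offsets=offsets,
        counts=counts,
        boundaries_per_offset=denom,
        n_boundaries=len(boundaries),
        gene_class=gene_class,
    )


@dataclass
class InsideOutsideCounts:
    region_class: str
    gene_class: str
    inside: int
    outside: int
    inside_bp: int
    outside_bp: int


def inside_outside_domain_counts(
    genes: GeneTable,
    domains: DomainSet,
    regions: RegionSet,
    gene_class: str = "",
) -> InsideOutsideCounts:
    """Count TSS inside vs outside contact domains within a region class.

    A gene counts as inside iff its TSS lies within any domain interval
    (domains are unioned first, so splitting a domain into adjacent pieces
    covering the same territory changes nothing). Only genes whose TSS falls
    in the region class are considered.
    """
    in_region = _tss_in_intervals(genes, regions.intervals)
    dom_iv = _merge_intervals(
        [(normalize_chrom_name(d.chrom), d.start, d.end) for d in domains]
    )
    in_domain = _tss_in_intervals(genes, dom_iv)
    inside = int((in_region & in_domain).sum())
    outside = int((in_region & ~in_domain).sum())
    region_bp = regions.total_bp
    inside_bp = _overlap_bp(regions.intervals, dom_iv)
    return InsideOutsideCounts(
        region_class=regions.name,
        gene_class=gene_class,
        inside=inside,
        outside=outside,
        inside_bp=inside_bp,
        outside_bp=region_bp - inside_bp,
    )


def _merge_intervals(
    intervals: Iterable[tuple[str, int, int]]
) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for chrom, s, e in sorted(intervals):
        if out and out[-1][0] == chrom and s <= out[-1][2]:
            out[-1] = (chrom, out[-1][1], max(out[-1][2], e))
        else:
            out.append((chrom, s, e))
    return out


def _overlap_bp(
    a: Sequence[tuple[str, int, int]], b: Sequence[tuple[str, int, int]]
) -> int:
    total = 0
    for chrom, s, e in a:
        for c2, s2, e2 in b:
            if c2 == chrom:
                total += max(0, min(e, e2) - max(s, s2))
    return total


# ---------------------------------------------------------------------------
# per-bin signal
# ---------------------------------------------------------------------------


@dataclass
class SignalTrack:
    """Per-bin mean signal for one mark; bins with no data are flagged."""

    genome: BinnedGenome
    values: np.ndarray
    mark: str = ""
    no_data: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.genome.n_bins,):
            raise ValueError("track length != bin count")
        if self.no_data is None:
            self.no_data = ~np.isfinite(self.values)
        else:
            self.no_data = np.asarray(self.no_data, dtype=bool)
        if np.any(~np.isfinite(self.values[~self.no_data])):
            raise ValueError("non-finite values outside the no-data flag")


def signal_by_subcompartment(
    track: SignalTrack, labeling: SubcompartmentLabeling
) -> pd.DataFrame:
    """Mean and IQR of per-bin signal for each subcompartment.

    No-data bins are ignored; a label with zero data bins yields an NA row.
    """
    rows = []
    for lab in LABELS:
        member = (labeling.labels == lab) & ~track.no_data
        vals = track.values[member]
        if vals.size == 0:
            rows.append(dict(label=lab, n=0, mean=np.nan, median=np.nan,
                             q1=np.nan, q3=np.nan))
            continue
        rows.append(
            dict(
                label=lab, n=int(vals.size), mean=float(vals.mean()),
                median=float(np.median(vals)),
                q1=float(np.percentile(vals, 25)),
                q3=float(np.percentile(vals, 75)),
            )
        )
    return pd.DataFrame(rows).set_index("label")
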