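"""Subcompartment repositioning between cell types.

Counts how 50 kb bins move between the eight subcompartment states across a
pair of cell types (transition matrices, per-state transfer fractions, the
overall repositioning proportion), and across a panel of cell types
(persistence). Bins that are NA in any involved labeling are excluded from
both numerator and denominator of every proportion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import BinnedGenome
from .labels import LABELS, MERGE_4CLASS, SubcompartmentLabeling

__all__ = [
    "TransitionTable",
    "transition_counts",
    "repositioning_proportion",
    "PersistenceResult",
    "persistent_bins",
    "RegionSet",
    "region_sets",
]


@dataclass
class TransitionTable:
    """8x8 bin-count matrix of subcompartment moves src -> dst."""

    src_cell_type: str
    dst_cell_type: str
    counts: np.ndarray          # (8, 8) int
    n_dropped: int              # bins NA in either labeling

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (8, 8):
            raise ValueError("counts must be 8x8")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def transfer_fractions(self) -> pd.DataFrame:
        """Row-normalized fractions; empty rows stay all-zero."""
        rows = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(rows > 0, self.counts / rows, 0.0)
        return pd.DataFrame(frac, index=list(LABELS), columns=list(LABELS))

    @property
    def repositioning(self) -> float:
        """Overall repositioning proportion: 1 - trace/total."""
        return repositioning_proportion(self)

    def transposed(self) -> "TransitionTable":
        return TransitionTable(
            self.dst_cell_type, self.src_cell_type, self.counts.T,
            self.n_dropped,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(LABELS), columns=list(LABELS)
        )

    def to_long(self) -> pd.DataFrame:
        """Chord-plot-ready long format (src, dst, count, fraction)."""
        frac = self.transfer_fractions
        recs = [
            (s, d, int(self.counts[i, j]), float(frac.iloc[i, j]))
            for i, s in enumerate(LABELS)
            for j, d in enumerate(LABELS)
        ]
        return pd.DataFrame(recs, columns=["src", "dst", "count", "fraction"])


def transition_counts(
    src: SubcompartmentLabeling, dst: SubcompartmentLabeling
) -> TransitionTable:
    """Tabulate per-bin subcompartment moves between two cell types."""
    if src.genome is not dst.genome and (
        src.genome.chroms != dst.genome.chroms
        or src.genome.bin_size != dst.genome.bin_size
    ):
        raise ValueError("labelings are on different binned genomes")
    sc, dc = src.codes, dst.codes
    both = (sc >= 0) & (dc >= 0)
    if not both.any():
        raise ValueError("no bins annotated in both cell types")
    flat = sc[both].astype(np.int64) * 8 + dc[both]
    counts = np.bincount(flat, minlength=64).reshape(8, 8)
    return TransitionTable(
        src.cell_type, dst.cell_type, counts, int((~both).sum())
    )


def repositioning_proportion(
    table: TransitionTable,
    subset: Sequence[str] | None = None,
    merge_scheme: Mapping[str, str] | None = None,
) -> float:
    """Fraction of bins whose state changed, optionally per source subset.

    With ``merge_scheme`` the 8x8 matrix is first collapsed to merged
    classes (moves within one class no longer count as repositioning).
    ``subset`` restricts to source rows (given in the label vocabulary of
    the *merged* matrix when a scheme is supplied).
    """
    counts = table.counts
    names: list[str] = list(LABELS)
    if merge_scheme is not None:
        classes = sorted({merge_scheme[l] for l in LABELS},
                         key=lambda c: min(LABELS.index(l)
                                           for l in LABELS if merge_scheme[l] == c))
        idx = np.array([classes.index(merge_scheme[l]) for l in LABELS])
        merged = np.zeros((len(classes), len(classes)), dtype=np.int64)
        np.add.at(merged, (idx[:, None], idx[None, :]), counts)
        counts, names = merged, classes
    if subset is not None:
        rows = [names.index(s) for s in subset]
        counts = counts[rows, :]
        diag = sum(
            counts[k, names.index(s)] for k, s in enumerate(subset)
        )
    else:
        diag = np.trace(counts)
    total = counts.sum()
    if total == 0:
        raise ValueError("subset has zero source bins")
    return float((total - diag) / total)


@dataclass
class PersistenceResult:
    """Bins that keep a target state across every cell type in a panel."""

    target: str
    reference_cell_type: str
    persistent_bins: np.ndarray
    n_reference: int
    merged_scheme: bool = False

    @property
    def proportion(self) -> float:
        if self.n_reference == 0:
            raise ValueError(
                f"reference cell type has no {self.target} bins"
            )
        return self.persistent_bins.size / self.n_reference


def persistent_bins(
    labelings: Sequence[SubcompartmentLabeling],
    target: str,
    reference: str,
    merge_scheme: Mapping[str, str] | None = None,
) -> PersistenceResult:
    """Find bins labeled ``target`` in every cell type of the panel.

    The persistence proportion is reported against the bins carrying the
    target state in the named reference cell type. Under a merge scheme the
    target is a merged class name (e.g. ``"A2-A4"``); note the merged {A1}
    class is a singleton, so A1 persistence is identical under the 8-state
    and 4-class schemes.
    """
    if len(labelings) < 2:
        raise ValueError("need at least two labelings")
    names = [lab.cell_type for lab in labelings]
    if reference not in names:
        raise ValueError(f"reference {reference!r} not among {names}")
    if merge_scheme is None:
        per_ct = [lab.labels == target for lab in labelings]
    else:
        if target not in set(merge_scheme.values()):
            raise ValueError(f"{target!r} is not a class of the merge scheme")
        per_ct = [lab.merged(dict(merge_scheme)) == target for lab in labelings]
    persistent = np.flatnonzero(np.logical_and.reduce(per_ct))
    ref_mask = per_ct[names.index(reference)]
    return PersistenceResult(
        target=target,
        reference_cell_type=reference,
        persistent_bins=persistent,
        n_reference=int(ref_mask.sum()),
        merged_scheme=merge_scheme is not None,
    )


@dataclass
class RegionSet:
    """A named genomic region class as a set of bins plus merged intervals."""

    name: str
    genome: BinnedGenome
    bins: np.ndarray

    def __post_init__(self) -> None:
        self.bins = np.unique(np.asarray(self.bins, dtype=np.int64))

    @property
    def intervals(self) -> list[tuple[str, int, int]]:
        return self.genome.bins_to_intervals(self.bins)

    @property
    def total_bp(self) -> int:
        return sum(e - s for _, s, e in self.intervals)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, s, e in self.intervals:
                fh.write(f"{chrom}\t{s}\t{e}\t{self.name}\n")


def region_sets(
    labelings: Sequence[SubcompartmentLabeling],
) -> dict[str, RegionSet]:
    """Partition A1 into common and variable subsets; extract common B4.

    Returns ``common_A1`` (bins labeled A1 in every cell type),
    ``variable_A1.<cell_type>`` for each cell type (its A1 bins not in the
    common set) and ``common_B4``. For every cell type,
    common_A1 and variable_A1 are disjoint and their union is exactly that
    cell type's A1 bins.
    """
    g = labelings[0].genome
    a1_masks = [lab.labels == "A1" for lab in labelings]
    b4_masks = [lab.labels == "B4" for lab in labelings]
    common_a1 = np.flatnonzero(np.logical_and.reduce(a1_masks))
    common_b4 = np.flatnonzero(np.logical_and.reduce(b4_masks))
    out = {
        "common_A1": RegionSet("common_A1", g, common_a1),
        "common_B4": RegionSet("common_B4", g, common_b4),
    }
    for lab, mask in zip(labelings, a1_masks):
        own = np.flatnonzero(mask)
        variable = np.setdiff1d(own, common_a1)
        out[f"variable_A1.{lab.cell_type}"] = RegionSet(
            f"variable_A1.{lab.cell_type}", g, variable
        )
    return out
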