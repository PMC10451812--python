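"""KR-balanced contact matrices as sparse, mask-aware bin-pair maps.

A :class:`ContactMap` stores balanced (dimensionless) contact values on the
global bins of a :class:`~a1scape.genome.BinnedGenome`. Intra maps hold only
same-chromosome pairs, inter maps only cross-chromosome pairs; both store the
canonical (min, max) key once and answer symmetric queries. Bins whose
balancing failed (NaN rows in the dump) are masked and excluded from every
numerator and denominator downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import BinnedGenome, normalize_chrom_name

logger = logging.getLogger(__name__)

__all__ = ["ContactMap", "read_contact_dump", "write_contact_dump"]


class ContactParseError(ValueError):
    pass


class CoordinateError(ValueError):
    pass


@dataclass
class ContactMap:
    """Sparse symmetric contact map on global bins.

    Parameters
    ----------
    genome
        The binned genome indexing rows/columns.
    kind
        ``"intra"`` (same-chromosome pairs only) or ``"inter"``
        (cross-chromosome pairs only).
    rows, cols, vals
        Canonical upper-triangle entries (``rows <= cols`` enforced by
        swapping); duplicate keys are summed.
    bad_bins
        Boolean mask of bins invalidated by balancing failure.
    """

    genome: BinnedGenome
    kind: str
    rows: np.ndarray
    cols: np.ndarray
    vals: np.ndarray
    bad_bins: np.ndarray = None  # type: ignore[assignment]
    resolution: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("intra", "inter"):
            raise ValueError("kind must be 'intra' or 'inter'")
        r = np.asarray(self.rows, dtype=np.int64)
        c = np.asarray(self.cols, dtype=np.int64)
        v = np.asarray(self.vals, dtype=np.float64)
        if not (r.shape == c.shape == v.shape):
            raise ValueError("rows/cols/vals must be parallel")
        swap = r > c
        r2 = np.where(swap, c, r)
        c2 = np.where(swap, r, c)
        same = self.genome.same_chrom(r2, c2) if r2.size else np.zeros(0, bool)
        if self.kind == "intra" and not same.all():
            raise ValueError("intra map contains cross-chromosome pairs")
        if self.kind == "inter" and same.any():
            raise ValueError("inter map contains same-chromosome pairs")
        if np.any(~np.isfinite(v)) or np.any(v < 0):
            raise ValueError("stored contact values must be finite and >= 0")
        n = self.genome.n_bins
        m = sp.coo_matrix((v, (r2, c2)), shape=(n, n)).tocsr()
        m.sum_duplicates()
        if self.bad_bins is None:
            self.bad_bins = np.zeros(n, dtype=bool)
        else:
            self.bad_bins = np.asarray(self.bad_bins, dtype=bool).copy()
        if self.bad_bins.any():
            keep = sp.diags((~self.bad_bins).astype(float))
            m = keep @ m @ keep
            m.eliminate_zeros()
        self._upper = m
        if self.resolution is None:
            self.resolution = self.genome.bin_size
        coo = m.tocoo()
        self.rows, self.cols, self.vals = coo.row, coo.col, coo.data

    # -- queries ----------------------------------------------------------

    @property
    def nnz(self) -> int:
        return int(self._upper.nnz)

    def value(self, i: int, j: int) -> float:
        """Balanced contact value for bin pair (i, j); symmetric."""
        if i > j:
            i, j = j, i
        return float(self._upper[i, j])

    def symmetric(self) -> sp.csr_matrix:
        """Full symmetric CSR matrix (diagonal counted once)."""
        u = self._upper
        d = sp.diags(u.diagonal())
        return (u + u.T - d).tocsr()

    def scaled(self, k: float) -> "ContactMap":
        return ContactMap(
            self.genome, self.kind, self.rows, self.cols, self.vals * k,
            bad_bins=self.bad_bins, resolution=self.resolution,
        )

    def chrom_entries(
        self, chrom: str
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Upper-triangle entries of one chromosome in local bin indices."""
        if self.kind != "intra":
            raise ValueError("chrom_entries requires an intra map")
        sl = self.genome.chrom_slice(chrom)
        sel = (self.rows >= sl.start) & (self.rows < sl.stop)
        return (
            self.rows[sel] - sl.start,
            self.cols[sel] - sl.start,
            self.vals[sel],
        )

    # -- construction -----------------------------------------------------

    @classmethod
    def combine(cls, maps: Iterable["ContactMap"]) -> "ContactMap":
        """Merge per-chromosome(-pair) maps of the same kind and genome."""
        maps = list(maps)
        if not maps:
            raise ValueError("no maps to combine")
        g, kind = maps[0].genome, maps[0].kind
        if any(m.kind != kind or m.genome is not g for m in maps[1:]):
            raise ValueError("maps differ in kind or genome")
        bad = np.zeros(g.n_bins, dtype=bool)
        for m in maps:
            bad |= m.bad_bins
        return cls(
            g, kind,
            np.concatenate([m.rows for m in maps]),
            np.concatenate([m.cols for m in maps]),
            np.concatenate([m.vals for m in maps]),
            bad_bins=bad, resolution=maps[0].resolution,
        )

    @classmethod
    def from_cooler(cls, uri: str, genome: BinnedGenome, kind: str) -> "ContactMap":
        """Adapter loading balanced pixels from a .cool file (optional).

        Requires the ``cooler`` package.
        """
        import cooler  # optional dependency

        clr = cooler.Cooler(uri)
        pix = clr.pixels(join=True)[:]
        bal = clr.bins()[:]["weight"].to_numpy()
        w1 = bal[pix["bin1_id"]] if "bin1_id" in pix else None
        val = pix["count"].to_numpy(dtype=float)
        if w1 is not None:
            val = val * bal[pix["bin1_id"]] * bal[pix["bin2_id"]]
        rows, cols, vals, bad = [], [], [], np.zeros(genome.n_bins, bool)
        for c1, s1, c2, s2, v in zip(
            pix["chrom1"], pix["start1"], pix["chrom2"], pix["start2"], val
        ):
            try:
                i = genome.bin_index(str(c1), int(s1))
                j = genome.bin_index(str(c2), int(s2))
            except KeyError:
                continue
            same = genome.same_chrom(np.array([i]), np.array([j]))[0]
            if (kind == "intra") != bool(same):
                continue
            if not np.isfinite(v):
                bad[i] = bad[j] = True
                continue
            rows.append(i); cols.append(j); vals.append(v)
        return cls(genome, kind, np.array(rows), np.array(cols),
                   np.array(vals), bad_bins=bad)


def read_contact_dump(
    path: str | Path,
    genome: BinnedGenome,
    kind: str,
    chrom1: str,
    chrom2: str | None = None,
) -> ContactMap:
    """Parse a Juicer text dump ('observed KR BP <res>') for one chromosome pair.

    Rows are whitespace-separated triples ``pos1 pos2 value`` with positions
    being bin start coordinates (bp, chromosome-local, multiples of the bin
    size). NaN or negative values are dropped; a bin with only dropped entries
    is routed to the invalid mask.

    Parameters
    ----------
    chrom1, chrom2
        The chromosome(s) the dump's columns refer to. ``chrom2`` defaults to
        ``chrom1`` (intra dump).
    """
    path = Path(path)
    chrom1 = normalize_chrom_name(chrom1)
    chrom2 = normalize_chrom_name(chrom2) if chrom2 else chrom1
    if kind == "intra" and chrom1 != chrom2:
        raise ValueError("intra dump requires chrom1 == chrom2")
    if kind == "inter" and chrom1 == chrom2:
        raise ValueError("inter dump requires distinct chromosomes")
    try:
        df = pd.read_csv(
            path, sep=r"\s+", header=None, comment="#",
            names=["pos1", "pos2", "value"],
            dtype={"pos1": np.int64, "pos2": np.int64, "value": np.float64},
        )
    except (ValueError, TypeError) as exc:
        # re-read leniently to locate the offending line
        lineno = _find_bad_line(path)
        raise ContactParseError(
            f"{path}: malformed row at line {lineno}: {exc}"
        ) from exc
    if df.shape[1] != 3:
        raise ContactParseError(f"{path}: expected 3 columns")
    res = genome.bin_size
    for col, chrom in (("pos1", chrom1), ("pos2", chrom2)):
        pos = df[col].to_numpy()
        off = pos % res != 0
        if off.any():
            ln = int(np.flatnonzero(off)[0]) + 1
            raise CoordinateError(
                f"{path} line {ln}: position {pos[off][0]} is not a multiple "
                f"of the {res} bp resolution"
            )
        if (pos < 0).any() or (pos >= genome.chrom_length(chrom)).any():
            bad = (pos < 0) | (pos >= genome.chrom_length(chrom))
            ln = int(np.flatnonzero(bad)[0]) + 1
            raise CoordinateError(
                f"{path} line {ln}: position {pos[bad][0]} outside {chrom}"
            )
    off1 = genome.chrom_offset(chrom1)
    off2 = genome.chrom_offset(chrom2)
    i = off1 + df["pos1"].to_numpy() // res
    j = off2 + df["pos2"].to_numpy() // res
    v = df["value"].to_numpy()
    drop = ~np.isfinite(v) | (v < 0)
    bad = np.zeros(genome.n_bins, dtype=bool)
    if drop.any():
        touched = np.unique(np.concatenate([i[drop], j[drop]]))
        kept = np.unique(np.concatenate([i[~drop], j[~drop]]))
        bad[np.setdiff1d(touched, kept)] = True
        logger.warning(
            "%s: dropped %d NaN/negative entries; %d bins masked",
            path, int(drop.sum()), int(bad.sum()),
        )
    return ContactMap(
        genome, kind, i[~drop], j[~drop], v[~drop], bad_bins=bad
    )


def _find_bad_line(path: Path) -> int:
    with open(path) as fh:
        for n, line in enumerate(fh, 1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) != 3:
                return n
            try:
                int(parts[0]); int(parts[1]); float(parts[2])
            except ValueError:
                return n
    return 0


def write_contact_dump(
    cmap: ContactMap, path: str | Path, chrom1: str, chrom2: str | None = None
) -> None:
    """Write one chromosome(-pair) block of a map in Juicer dump text form."""
    chrom1 = normalize_chrom_name(chrom1)
    chrom2 = normalize_chrom_name(chrom2) if chrom2 else chrom1
    g = cmap.genome
    sl1, sl2 = g.chrom_slice(chrom1), g.chrom_slice(chrom2)
    sel = (
        (cmap.rows >= sl1.start) & (cmap.rows < sl1.stop)
        & (cmap.cols >= sl2.start) & (cmap.cols < sl2.stop)
    )
    if chrom1 != chrom2:
        # canonical storage may hold the pair with roles swapped
        sel2 = (
            (cmap.rows >= sl2.start) & (cmap.rows < sl2.stop)
            & (cmap.cols >= sl1.start) & (cmap.cols < sl1.stop)
        )
    res = g.bin_size
    with open(path, "w") as fh:
        p1 = (cmap.rows[sel] - sl1.start) * res
        p2 = (cmap.cols[sel] - sl2.start) * res
        for a, b, v in zip(p1, p2, cmap.vals[sel]):
            fh.write(f"{a}\t{b}\t{v:.6g}\n")
        if chrom1 != chrom2 and sel2.any():
            p1 = (cmap.cols[sel2] - sl1.start) * res
            p2 = (cmap.rows[sel2] - sl2.start) * res
            for a, b, v in zip(p1, p2, cmap.vals[sel2]):
                fh.write(f"{a}\t{b}\t{v:.6g}\n")
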