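"""Fixed-width genomic binning shared by every matrix and annotation.

All coordinates in the package are 0-based, half-open. A :class:`BinnedGenome`
tiles each chromosome with ``bin_size`` bp bins (the last bin of a chromosome
may be short) and provides the global-bin-index <-> (chrom, start) mapping that
contact maps, labelings and signal tracks are indexed by.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = ["BinnedGenome", "normalize_chrom_name"]

_SEX_CHROMS = {"chrX", "chrY"}


def normalize_chrom_name(name: str) -> str:
    """Normalize 'chr1' / '1' dialects to the 'chr'-prefixed form."""
    name = name.strip()
    if not name.lower().startswith("chr"):
        return "chr" + name
    return "chr" + name[3:]


def _is_primary(name: str) -> bool:
    # mitochondrial and unplaced/random scaffolds are always excluded
    base = name[3:]
    if base.upper() in {"M", "MT"}:
        return False
    if "_" in base or base.lower().startswith(("un", "gl", "ki", "scaffold")):
        return False
    return True


@dataclass(frozen=True)
class BinnedGenome:
    """Non-overlapping, sorted, half-open bins tiling a chromosome set.

    Parameters
    ----------
    chroms
        Chromosome names, 'chr'-prefixed, in the order bins are laid out.
    lengths
        Chromosome lengths in bp, parallel to ``chroms``.
    bin_size
        Bin width in bp (default 50 kb).
    """

    chroms: tuple[str, ...]
    lengths: tuple[int, ...]
    bin_size: int = 50_000

    _offsets: np.ndarray = field(init=False, repr=False, compare=False)
    _nbins_per_chrom: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.chroms) != len(self.lengths):
            raise ValueError("chroms and lengths must be parallel")
        if len(set(self.chroms)) != len(self.chroms):
            raise ValueError("duplicate chromosome names")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        nb = np.array(
            [-(-l // self.bin_size) for l in self.lengths], dtype=np.int64
        )
        object.__setattr__(self, "_nbins_per_chrom", nb)
        object.__setattr__(
            self, "_offsets", np.concatenate([[0], np.cumsum(nb)])
        )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_chromsizes(
        cls,
        chromsizes: Mapping[str, int],
        bin_size: int = 50_000,
        *,
        exclude_sex_chroms: bool = True,
    ) -> "BinnedGenome":
        """Build from a name->length mapping, normalizing naming dialects.

        Mitochondrial and unplaced contigs are always dropped; chrX/chrY are
        dropped unless ``exclude_sex_chroms=False``.
        """
        chroms: list[str] = []
        lengths: list[int] = []
        for name, length in chromsizes.items():
            norm = normalize_chrom_name(name)
            if not _is_primary(norm):
                continue
            if exclude_sex_chroms and norm in _SEX_CHROMS:
                continue
            chroms.append(norm)
            lengths.append(int(length))
        if not chroms:
            raise ValueError("no chromosomes left after filtering")
        return cls(tuple(chroms), tuple(lengths), bin_size)

    # -- bookkeeping ------------------------------------------------------

    @property
    def n_bins(self) -> int:
        return int(self._offsets[-1])

    @property
    def chrom_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.chroms)}

    def chrom_length(self, chrom: str) -> int:
        return self.lengths[self.chrom_index[chrom]]

    def chrom_nbins(self, chrom: str) -> int:
        return int(self._nbins_per_chrom[self.chrom_index[chrom]])

    def chrom_offset(self, chrom: str) -> int:
        return int(self._offsets[self.chrom_index[chrom]])

    def chrom_slice(self, chrom: str) -> slice:
        ci = self.chrom_index[chrom]
        return slice(int(self._offsets[ci]), int(self._offsets[ci + 1]))

    @property
    def bin_chrom_codes(self) -> np.ndarray:
        """Per-bin integer chromosome code (len == n_bins)."""
        return np.repeat(
            np.arange(len(self.chroms)), self._nbins_per_chrom
        )

    @property
    def bin_starts(self) -> np.ndarray:
        """Per-bin start coordinate in bp (chromosome-local)."""
        return np.concatenate(
            [
                np.arange(n, dtype=np.int64) * self.bin_size
                for n in self._nbins_per_chrom
            ]
        )

    # -- coordinate mapping -----------------------------------------------

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing bp position ``pos``."""
        chrom = normalize_chrom_name(chrom)
        ci = self.chrom_index.get(chrom)
        if ci is None:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not 0 <= pos < self.lengths[ci]:
            raise ValueError(
                f"position {pos} outside {chrom} (length {self.lengths[ci]})"
            )
        return int(self._offsets[ci]) + pos // self.bin_size

    def bin_location(self, index: int) -> tuple[str, int, int]:
        """(chrom, start, end) in bp of the bin with the given global index."""
        if not 0 <= index < self.n_bins:
            raise IndexError(f"bin index {index} out of range")
        ci = int(np.searchsorted(self._offsets, index, side="right")) - 1
        local = index - int(self._offsets[ci])
        start = local * self.bin_size
        end = min(start + self.bin_size, self.lengths[ci])
        return self.chroms[ci], start, end

    def bins_to_intervals(
        self, bins: Iterable[int]
    ) -> list[tuple[str, int, int]]:
        """Merge a set of global bin indices into maximal (chrom,start,end) runs."""
        idx = np.unique(np.fromiter(bins, dtype=np.int64))
        if idx.size == 0:
            return []
        codes = self.bin_chrom_codes[idx]
        # break runs at non-consecutive indices or chromosome changes
        breaks = np.where((np.diff(idx) != 1) | (np.diff(codes) != 0))[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [idx.size - 1]])
        out = []
        for s, e in zip(starts, ends):
            c0, b0, _ = self.bin_location(int(idx[s]))
            _, _, b1 = self.bin_location(int(idx[e]))
            out.append((c0, b0, b1))
        return out

    def same_chrom(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        codes = self.bin_chrom_codes
        return codes[i] == codes[j]
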