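"""Eight-state subcompartment labelings and the A/B compartment mask.

Subcompartments are the eight ranked chromatin states A1 > A2 > A3 > A4 >
B1 > B2 > B3 > B4 produced by renaming hierarchical Calder annotations
(A.1.1 ... B.2.2). A1-A4 belong to the active compartment A, B1-B4 to the
inactive compartment B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .genome import BinnedGenome

logger = logging.getLogger(__name__)

__all__ = [
    "LABELS",
    "NA_LABEL",
    "RAW_LABEL_MAP",
    "MERGE_4CLASS",
    "SubcompartmentLabeling",
    "CompartmentMask",
    "derive_compartment_mask",
]

#: The eight subcompartment labels in rank order, most active first.
LABELS: tuple[str, ...] = ("A1", "A2", "A3", "A4", "B1", "B2", "B3", "B4")
NA_LABEL = "NA"

#: Fixed renaming of hierarchical Calder labels to the rank names.
RAW_LABEL_MAP: dict[str, str] = {
    "A.1.1": "A1",
    "A.1.2": "A2",
    "A.2.1": "A3",
    "A.2.2": "A4",
    "B.1.1": "B1",
    "B.1.2": "B2",
    "B.2.1": "B3",
    "B.2.2": "B4",
}

#: Four-class merge used when comparing persistence across labels of very
#: different genomic footprint: {A1}, {A2,A3,A4}, {B1,B2,B3}, {B4}.
MERGE_4CLASS: dict[str, str] = {
    "A1": "A1",
    "A2": "A2-A4",
    "A3": "A2-A4",
    "A4": "A2-A4",
    "B1": "B1-B3",
    "B2": "B1-B3",
    "B3": "B1-B3",
    "B4": "B4",
}

_LABEL_TO_CODE = {lab: i for i, lab in enumerate(LABELS)}


@dataclass
class SubcompartmentLabeling:
    """Per-bin subcompartment label for one cell type.

    ``labels`` holds one of the eight rank names or ``"NA"`` per bin of
    ``genome``.
    """

    genome: BinnedGenome
    cell_type: str
    labels: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="<U2")
        if self.labels.shape != (self.genome.n_bins,):
            raise ValueError(
                f"labeling length {self.labels.size} != "
                f"{self.genome.n_bins} bins"
            )
        allowed = set(LABELS) | {NA_LABEL}
        bad = set(np.unique(self.labels)) - allowed
        if bad:
            raise ValueError(f"invalid labels {sorted(bad)}")

    @property
    def codes(self) -> np.ndarray:
        """Integer codes 0..7 in rank order; -1 for NA."""
        out = np.full(self.labels.size, -1, dtype=np.int8)
        for lab, code in _LABEL_TO_CODE.items():
            out[self.labels == lab] = code
        return out

    def bins_with(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def merged(self, scheme: dict[str, str]) -> np.ndarray:
        """Class name per bin under a label-merge scheme (NA preserved)."""
        out = self.labels.astype("<U8").copy()
        for lab, cls in scheme.items():
            out[self.labels == lab] = cls
        return out


@dataclass
class CompartmentMask:
    """Per-bin {A, B, NA} mask plus the contiguous B blocks.

    ``mask`` holds 1 for compartment A, -1 for B, 0 for NA.  ``b_blocks``
    are maximal runs of adjacent B bins within one chromosome, half-open in
    global bin indices — the background territory of the domain-strength
    score.
    """

    genome: BinnedGenome
    mask: np.ndarray
    b_blocks: list[tuple[int, int]] = field(default_factory=list)

    @property
    def a_bins(self) -> np.ndarray:
        return np.flatnonzero(self.mask == 1)

    @property
    def b_bins(self) -> np.ndarray:
        return np.flatnonzero(self.mask == -1)

    @property
    def n_a(self) -> int:
        return int((self.mask == 1).sum())

    @property
    def n_b(self) -> int:
        return int((self.mask == -1).sum())

    def flipped(self) -> "CompartmentMask":
        """Mask with the A and B roles exchanged (B blocks recomputed)."""
        return _mask_from_codes(self.genome, -self.mask)


def _mask_from_codes(genome: BinnedGenome, codes: np.ndarray) -> CompartmentMask:
    blocks: list[tuple[int, int]] = []
    is_b = codes == -1
    chrom_codes = genome.bin_chrom_codes
    n = codes.size
    i = 0
    while i < n:
        if is_b[i]:
            j = i + 1
            while j < n and is_b[j] and chrom_codes[j] == chrom_codes[i]:
                j += 1
            blocks.append((i, j))
            i = j
        else:
            i += 1
    return CompartmentMask(genome, codes, blocks)


def derive_compartment_mask(labeling: SubcompartmentLabeling) -> CompartmentMask:
    """Collapse the eight subcompartments to the A/B compartment bipartition.

    A1-A4 map to A, B1-B4 to B; NA bins stay NA. Also extracts the maximal
    contiguous B blocks (never spanning a chromosome break) used as the
    distance-decay background territory, and the totals N_A and N_B.
    """
    codes = np.zeros(labeling.labels.size, dtype=np.int8)
    for lab in LABELS[:4]:
        codes[labeling.labels == lab] = 1
    for lab in LABELS[4:]:
        codes[labeling.labels == lab] = -1
    return _mask_from_codes(labeling.genome, codes)
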