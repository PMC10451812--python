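"""Interchromosomal A/B contact ratio per subcompartment.

For each bin i, A_i sums its interchromosomal balanced contacts with bins in
compartment A (on other chromosomes) and B_i those with compartment B. For a
subcompartment SC the ratio is

    ABRatio(SC) = ( sum_{i in SC} A_i / N_A ) / ( sum_{i in SC} B_i / N_B )

with N_A, N_B the genome-wide A/B territory sizes (bins; equivalently
length, since bins are fixed width). A compartment-A-attracted state scores
above 1; the ratio is invariant to the overall sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contacts import ContactMap
from .labels import LABELS, CompartmentMask, SubcompartmentLabeling

__all__ = [
    "ABScores",
    "interchromosomal_ab_scores",
    "ABRatioResult",
    "ab_ratio_by_subcompartment",
]


@dataclass
class ABScores:
    """Per-bin interchromosomal contact sums with the A and B territories."""

    a: np.ndarray
    b: np.ndarray
    valid: np.ndarray          # False where the map's bin mask applies
    n_a: int
    n_b: int


def interchromosomal_ab_scores(
    inter: ContactMap, mask: CompartmentMask
) -> ABScores:
    """Sum each bin's cross-chromosome contacts into A and B partner totals.

    NA-mask partners and masked bins are skipped. The restriction to other
    chromosomes is structural: an inter map stores no same-chromosome pair.
    """
    if inter.kind != "inter":
        raise ValueError("interchromosomal scores require an inter map")
    if mask.genome.n_bins != inter.genome.n_bins:
        raise ValueError("mask and map are on different genomes")
    if mask.n_a == 0 or mask.n_b == 0:
        raise ValueError("need at least one A and one B bin")
    good = ~inter.bad_bins
    a_vec = ((mask.mask == 1) & good).astype(float)
    b_vec = ((mask.mask == -1) & good).astype(float)
    sym = inter.symmetric()
    a = np.asarray(sym @ a_vec)
    b = np.asarray(sym @ b_vec)
    a[~good] = np.nan
    b[~good] = np.nan
    return ABScores(a=a, b=b, valid=good, n_a=mask.n_a, n_b=mask.n_b)


@dataclass
class ABRatioResult:
    subcompartment: str
    n_bins: int
    sum_a: float
    sum_b: float
    c_a: float
    c_b: float
    ratio: float               # NaN when C_B == 0 (flagged, never inf)
    per_bin_ratio: np.ndarray | None = None


def ab_ratio_by_subcompartment(
    scores: ABScores,
    labeling: SubcompartmentLabeling,
    *,
    per_bin: bool = False,
) -> list[ABRatioResult]:
    """Evaluate the A/B ratio for each of the eight subcompartments.

    With ``per_bin=True`` each result also carries the per-bin ratios
    (A_i/N_A)/(B_i/N_B) of its member bins (bins with B_i = 0 dropped) —
    the distribution a violin plot shows next to the aggregate value.
    """
    if scores.n_a == 0 or scores.n_b == 0:
        raise ValueError("no compartment background (N_A or N_B is zero)")
    out = []
    for sc in LABELS:
        member = (labeling.labels == sc) & scores.valid
        sum_a = float(np.nansum(scores.a[member]))
        sum_b = float(np.nansum(scores.b[member]))
        c_a = sum_a / scores.n_a
        c_b = sum_b / scores.n_b
        ratio = c_a / c_b if c_b > 0 else float("nan")
        pb = None
        if per_bin:
            ai = scores.a[member] / scores.n_a
            bi = scores.b[member] / scores.n_b
            keep = bi > 0
            pb = ai[keep] / bi[keep]
        out.append(
            ABRatioResult(
                subcompartment=sc,
                n_bins=int(member.sum()),
                sum_a=sum_a,
                sum_b=sum_b,
                c_a=c_a,
                c_b=c_b,
                ratio=ratio,
                per_bin_ratio=pb,
            )
        )
    return out


def ab_ratio_frame(results: list[ABRatioResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                subcompartment=r.subcompartment, n_bins=r.n_bins,
                sum_a=r.sum_a, sum_b=r.sum_b, c_a=r.c_a, c_b=r.c_b,
                ratio=r.ratio,
            )
            for r in results
        ]
    )
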