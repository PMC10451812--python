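"""Minimal static figure helpers for the main result types."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .abratio import ABRatioResult
from .boundaries import BoundaryProfile
from .labels import LABELS

__all__ = [
    "plot_ab_ratio",
    "plot_strength_by_label",
    "plot_boundary_profile",
]


def _axes(ax=None):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots(figsize=(5, 3.2))
    return ax


def plot_ab_ratio(results: Sequence[ABRatioResult], ax=None):
    """Violin of per-bin A/B ratios (when present) with the aggregate value."""
    ax = _axes(ax)
    pos = np.arange(len(results))
    per_bin = [r.per_bin_ratio for r in results]
    if all(p is not None and p.size for p in per_bin):
        ax.violinplot([np.log2(p) for p in per_bin], positions=pos,
                      showmedians=True)
        ax.set_ylabel("log2 per-bin A/B ratio")
    ax.plot(pos, [np.log2(r.ratio) if r.ratio > 0 else np.nan
                  for r in results], "ko-", ms=4, label="aggregate")
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xticks(pos, [r.subcompartment for r in results])
    ax.set_title("interchromosomal A/B ratio by subcompartment")
    return ax


def plot_strength_by_label(scored, ax=None):
    """Boxplots of domain strength per assigned subcompartment.

    ``scored`` is the tidy frame from :func:`a1scape.score_domains`.
    """
    ax = _axes(ax)
    groups = [
        scored.loc[scored["label"] == l, "strength"].to_numpy()
        for l in LABELS
    ]
    present = [(l, g) for l, g in zip(LABELS, groups) if g.size]
    ax.boxplot([g for _, g in present],
               tick_labels=[l for l, _ in present], showmeans=True)
    ax.axhline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_ylabel("domain strength S")
    return ax


def plot_boundary_profile(profiles: Sequence[BoundaryProfile], ax=None):
    """Metagene TSS curves around boundaries, one line per gene class."""
    ax = _axes(ax)
    for p in profiles:
        x = (p.offsets + p.bin_width / 2) / 1e3
        ax.plot(x, p.normalized, label=p.gene_class or "genes")
    ax.axvline(0.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("offset from boundary (kb)")
    ax.set_ylabel("mean TSS per bin per boundary")
    ax.legend(frameon=False)
    return ax
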