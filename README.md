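# a1scape

Statistics for subcompartment-resolved Hi-C analysis across cell types.

Hi-C maps partition chromatin into the active A and inactive B compartment,
and — at finer resolution — into eight ranked subcompartment states
A1 > A2 > A3 > A4 > B1 > B2 > B3 > B4 (renamed hierarchical Calder labels:
A.1.1 → A1, …, B.2.2 → B4). `a1scape` implements the bespoke statistics used
to study how these states behave across a panel of cell types, for
computational biologists working with binned (default 50 kb), KR-balanced
contact matrices, subcompartment BED annotations, Arrowhead-style contact
domains and per-gene FPKM tables:

- **Interchromosomal A/B ratio** per subcompartment SC:

  `ABRatio(SC) = (Σ_{i∈SC} A_i / N_A) / (Σ_{i∈SC} B_i / N_B)`

  where `A_i` (resp. `B_i`) sums bin *i*'s cross-chromosome balanced
  contacts with compartment-A (resp. B) territory and `N_A`, `N_B` are the
  genome-wide territory sizes. A-attracted states score above 1; the
  hallmark pattern is a strict decrease from A1 to B4.

- **Contact-domain strength** against the B-compartment distance-decay
  background. From contiguous B blocks `[X_b, Y_b)`:

  `B_l = Σ_b Σ_i I_{i,i+l} / Σ_b (len_b − l)` — the mean balanced contact
  of same-block B pairs at bin distance `l` — then for a domain spanning
  bins X..Y:

  `N_{X,Y} = Σ_{i=X..Y} Σ_{j=i..Y} (I_{i,j} − B_{j−i})`, `S = N_{X,Y} / T`

  with `T` the number of locus pairs. `S` is the mean excess contact per
  pair over quiet chromatin at matched distance (it can be negative).
  Domain calls at 5 kb and 10 kb are merged with the keep-smaller rule.

- **Transitions and persistence**: 8×8 repositioning matrices between cell
  types, the repositioning proportion (1 − trace/total), bins persisting in
  A1 (or B4) across the whole panel, and the resulting region classes —
  *common A1* (A1 in every cell type), *variable A1* (A1 here but not
  everywhere), *common B4*.

- **Gene positioning**: active (FPKM > 1), highly expressed (FPKM > 10),
  housekeeping and cell type-specific (≥ 5-fold vs every other cell type)
  gene classes; densities and TSS gap lengths per state and per region
  class; Fisher exact enrichment (specific vs housekeeping × variable vs
  common A1); expression by state (Kruskal–Wallis) and up/down-regulation
  grids over state transitions; TSS metagene profiles at domain/TAD
  boundaries; per-state signal levels (H3K27ac, Nipbl, H3K9me3, …).

A fully self-consistent **synthetic-data generator** produces five-cell-type
datasets — block labelings with controlled persistence, power-law decay
contact maps with graded state affinities, planted domains with known
enrichment, gene/FPKM tables with known placement odds — so every statistic
can be validated against planted ground truth at desk scale.

## Worked example

```python
from a1scape import (generate_dataset, transition_counts, persistent_bins,
                     derive_compartment_mask, interchromosomal_ab_scores,
                     ab_ratio_by_subcompartment)

ds = generate_dataset(seed=7)                     # 3 x 20 Mb, 1200 bins
t = transition_counts(ds.labelings[0], ds.labelings[1])
print(f"{100 * t.repositioning:.1f}% of bins repositioned")

pr = persistent_bins(ds.labelings, "A1", "ES")
print(f"{100 * pr.proportion:.2f}% of A1 persists in all five cell types")

mask = derive_compartment_mask(ds.labelings[0])
scores = interchromosomal_ab_scores(ds.inter, mask)
for r in ab_ratio_by_subcompartment(scores, ds.labelings[0]):
    print(r.subcompartment, round(r.ratio, 3))
```

prints

```
55.7% of bins repositioned
32.20% of A1 persists in all five cell types
A1 4.201
A2 3.43
A3 2.358
A4 1.355
B1 0.733
B2 0.446
B3 0.321
B4 0.237
```

Over half the genome changes state between two cell types while the
planted common-A1 fraction (38 of 118 reference A1 bins = 32.20%) is
recovered exactly, and the A/B ratio falls strictly from A1 to B4 — the
graded compartment affinity the generator plants. The `examples/` directory
has one narrative script per capability (simulation, transitions, A/B
ratio, domain strength, gene positioning, boundaries/signal, the full
pipeline), and the `a1scape` CLI exposes `simulate` and `run` for
shell-driven use of the same machinery on real files.

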