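"""Subcompartment repositioning between cell types and A1/B4 persistence.

Counts how 50 kb bins move between the eight chromatin states when going
from the reference cell type to each differentiated one, then measures
which A1/B4 bins persist across the whole panel.
"""

from a1scape import generate_dataset, persistent_bins, region_sets, transition_counts
from a1scape.labels import MERGE_4CLASS

ds = generate_dataset(seed=7)
ref = ds.labelings[0]

for other in ds.labelings[1:]:
    t = transition_counts(ref, other)
    print(f"{ref.cell_type} -> {other.cell_type}: "
          f"{100 * t.repositioning:.1f}% of bins repositioned "
          f"({t.total} jointly annotated bins)")

# A1 row of one transition: where does A1 go?
t = transition_counts(ref, ds.labelings[1])
row = t.transfer_fractions.loc["A1"]
print("\nA1 transfer fractions:",
      ", ".join(f"{d}={100 * f:.1f}%" for d, f in row.items() if f > 0))

pa1 = persistent_bins(ds.labelings, "A1", ref.cell_type)
pb4 = persistent_bins(ds.labelings, "B4", ref.cell_type)
print(f"\nA1 persistent in all five cell types: {100 * pa1.proportion:.2f}%")
print(f"B4 persistent in all five cell types: {100 * pb4.proportion:.2f}%")
# under the 4-class merge {A1},{A2-A4},{B1-B3},{B4} the A1 number is identical
pa1m = persistent_bins(ds.labelings, "A1", ref.cell_type,
                       merge_scheme=MERGE_4CLASS)
print(f"A1 persistence under the 4-class merge: {100 * pa1m.proportion:.2f}%")

rs = region_sets(ds.labelings)
print(f"\ncommon A1: {rs['common_A1'].total_bp / 1e6:.2f} Mb in "
      f"{len(rs['common_A1'].intervals)} intervals; "
      f"variable A1 ({ref.cell_type}): "
      f"{rs[f'variable_A1.{ref.cell_type}'].total_bp / 1e6:.2f} Mb")
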