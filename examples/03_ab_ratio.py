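"""Interchromosomal A/B contact ratio per subcompartment.

For each of the eight states, sums every member bin's cross-chromosome
contacts with compartment-A vs compartment-B territory (length-normalized).
A ratio above 1 means the state sits in A-attracted nuclear space; the
hallmark pattern is a strict decrease from A1 to B4.
"""

from a1scape import (
    ab_ratio_by_subcompartment,
    derive_compartment_mask,
    generate_dataset,
    interchromosomal_ab_scores,
)

ds = generate_dataset(seed=7)
ref = ds.labelings[0]
mask = derive_compartment_mask(ref)
scores = interchromosomal_ab_scores(ds.inter, mask)

print(f"A territory: {mask.n_a} bins, B territory: {mask.n_b} bins")
print(f"{'state':>6} {'bins':>5} {'C_A':>8} {'C_B':>8} {'A/B ratio':>10}")
for r in ab_ratio_by_subcompartment(scores, ref):
    print(f"{r.subcompartment:>6} {r.n_bins:>5} "
          f"{r.c_a:>8.2f} {r.c_b:>8.2f} {r.ratio:>10.3f}")
print("\nA strictly decreasing column confirms the graded A1->B4 "
      "compartment affinity planted in the inter-chromosomal maps.")
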