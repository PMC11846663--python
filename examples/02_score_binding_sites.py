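"""Score mismatched binding sites with the CFD-style penalty model.

The score of a site is the product, over mismatched spacer positions, of a
position- and base-pair-specific penalty: 1.0 for a perfect match, and
progressively smaller as mismatches are added — especially PAM-proximal
ones (position 20, next to the PAM).
"""

from guideset.scoring import load_default_table, site_score

table = load_default_table()
spacer = "GATTACAGATTACAGATTAC"


def mutate(seq, pos, base):
    s = list(seq)
    s[pos] = base
    return "".join(s)


print(f"guide spacer: {spacer}")
print(f"perfect match                 -> {site_score(spacer, spacer, table):.4f}")

distal = mutate(spacer, 0, "C")
proximal = mutate(spacer, 19, "T")
both = mutate(distal, 19, "T")
print(f"1 mismatch at position 1      -> {site_score(spacer, distal, table):.4f}"
      "  (PAM-distal, well tolerated)")
print(f"1 mismatch at position 20     -> {site_score(spacer, proximal, table):.4f}"
      "  (PAM-proximal, heavily penalized)")
print(f"both mismatches               -> {site_score(spacer, both, table):.4f}"
      "  (product of the two single-mismatch scores)")
print("\nA set's on-target activity is the sum of its counted sites' scores:")
print("e.g. 6 perfect sites + the two singly-mismatched sites above sum to "
      f"{6 + site_score(spacer, distal, table) + site_score(spacer, proximal, table):.3f} "
      "expected bound probes.")
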