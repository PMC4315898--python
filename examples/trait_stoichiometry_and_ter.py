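"""Whole-cell C:N from macromolecular composition, and TER theory.

Builds the three archetypal trait bundles, derives their cell C:N from the
fixed component stoichiometry (solubles C:N 15, C-rich compounds 150,
N-rich compounds 5), and evaluates the classical threshold-element-ratio
band they imply.
"""

from microstoich import COMPOSITIONS, TheoryParams, derive_cell_cn, ter_cn, ter_cn_recycled

for name, fracs in COMPOSITIONS.items():
    cn = derive_cell_cn(*fracs)
    print(f"{name:13s} composition {fracs} -> cell C:N = {cn:.2f}")

print()
for b_cn in (8.0, 15.0):
    p = TheoryParams(b_cn=b_cn, cue=0.5, nue=1.0)
    print(f"biomass C:N {b_cn:4.1f}, CUE 0.5, NUE 1 -> TER = {ter_cn(p):.0f}")
p = TheoryParams(b_cn=12.22, cue=0.32, nue=1.0, r=2.0)
print(f"\nwith N reused r=2 times faster than C at CUE 0.32: "
      f"TER rises from {ter_cn(p):.0f} to {ter_cn_recycled(p):.0f}")
print("(litter below the threshold is decomposed under C limitation; "
      "above it, under N limitation)")
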