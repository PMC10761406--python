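"""MS2 evidence: diagnostic fragments, mass-difference gaps, propagation.

Builds a toy fragmentation spectrum of a perfluoroalkyl ion and shows the
three MS2 evidence channels: matching against a diagnostic-fragment
list, finding characteristic mass gaps (CF2, HF) between product ions,
and propagating chemical formulas from annotated fragments to their
neighbours across those gaps.
"""

import numpy as np

from fluoroscreen import chem, prioritize as pri
from fluoroscreen.msio import Spectrum

c2f5 = chem.monoisotopic_mass("C2F5") + chem.ELECTRON_MASS
cf2 = chem.CF2.exact_mass
hf = chem.monoisotopic_mass("HF")

c2f4o = chem.monoisotopic_mass("C2F4O")

peaks = sorted([
    (c2f5, 5e4),             # C2F5-  (in the diagnostic list)
    (c2f5 + cf2, 3e4),       # C3F7-  (in the list, and a CF2 gap)
    (c2f5 + c2f4o, 1e4),     # C4F9O- (NOT in the list: propagation target)
    (168.9894 - hf, 8e3),    # an HF gap partner of C3F7-
])
spec = Spectrum(ms_level=2, rt=5.0,
                mz=np.array([p[0] for p in peaks]),
                intensity=np.array([p[1] for p in peaks]),
                polarity="negative", precursor_mz=420.0,
                precursor_intensity=2e5)

dfs = pri.builtin_diagnostic_fragments("negative")
hits, flagged = pri.match_diagnostic_fragments(spec, dfs)
print("diagnostic-fragment hits:")
for mz, d in hits:
    print(f"  {mz:9.4f} -> {d.label}")
print(f"spectrum flagged as PFAS candidate: {flagged}")

diffs = pri.builtin_mass_differences()
print("\ncharacteristic mass gaps:")
for lo, hi, d in pri.match_fragment_differences(spec, diffs):
    print(f"  {lo:9.4f} .. {hi:9.4f}  = {d.label} ({d.delta:.5f} Da)")

seeds = [pri.MS2Annotation(fragment_mz=mz, label=d.label, formula=d.formula,
                           source="df_list") for mz, d in hits]
anns = pri.propagate_formulas(spec, seeds, diffs)
print("\nformula propagation:")
for a in anns:
    if a.source == "propagated":
        print(f"  {a.fragment_mz:9.4f} annotated {a.label} "
              f"(from partner {a.partner_mz:.4f})")
print("Propagation assigns formulas to peaks absent from the fragment")
print("list by adding/subtracting the gap composition element-wise.")
print("Note: the HF partner of C3F7- stays unannotated — subtracting HF")
print("from C3F7 would need a hydrogen it does not have, so the")
print("propagation is (correctly) rejected.")
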