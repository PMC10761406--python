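"""Mass-defect arithmetic: why m/C separates PFAS from hydrocarbons.

Computes the mass defect (MD), carbon-normalized MD (MD/C) and
mass-per-carbon (m/C) for a few reference compounds.  Fluorine-dominated
molecules sit at high m/C (~40-55) because fluorine (19 Da per atom)
carries most of their mass, while CH2-based matrix compounds sit near 14.
"""

from fluoroscreen import chem

compounds = {
    "PFOA (C8HF15O2)": "C8HF15O2",
    "6:2 diPAP (C16H9F26O4P)": "C16H9F26O4P",
    "6:2 FTAB (C15H19F13N2O4S)": "C15H19F13N2O4S",
    "fluoxetine (C17H18F3NO)": "C17H18F3NO",
    "hexadecane (C16H34)": "C16H34",
}

print(f"{'compound':<28} {'mass (Da)':>10} {'MD':>8} {'MD/C':>9} {'m/C':>6}")
for name, formula in compounds.items():
    counts = chem.parse_formula(formula)
    m = chem.monoisotopic_mass(counts)
    md = chem.mass_defect(m)
    c = counts["C"]
    print(f"{name:<28} {m:>10.4f} {md:>+8.4f} {md / c:>+9.5f} {m / c:>6.1f}")

print()
print("A cutoff at m/C > 30 keeps the fluorine-dominated species and")
print("rejects the hydrocarbons; MD/C < +0.003 sharpens the split.")
print()

# Kendrick mass defect: homologues differing by CF2 share a KMD
pfoa_ion = chem.adduct_mz(chem.monoisotopic_mass("C8HF15O2"), "[M-H]-")
for k, label in enumerate(["PFOA [M-H]-", "PFNA [M-H]-", "PFDA [M-H]-"]):
    mz = pfoa_ion + k * chem.CF2.exact_mass
    print(f"{label:<14} m/z {mz:.5f}  CF2-KMD {chem.kendrick_mass_defect(mz, chem.CF2):+.5f}")
print("Equal KMD values mark members of one CF2 homologous series.")
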