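# fluoroscreen

Prioritization of PFAS candidate features in non-target LC/GC-HRMS data.

Per- and polyfluoroalkyl substances (PFAS) number in the thousands, and
most of what sits in a contaminated environmental sample has no reference
standard. Non-target screening therefore starts from thousands of
detected features and has to reduce them — fast and reproducibly — to the
few dozen that deserve manual inspection. `fluoroscreen` implements that
reduction for anyone screening centroided high-resolution MS data
(environmental chemists, exposure scientists) as a Python library with a
thin command-line front end.

## The screening model

Every MS¹ feature gets a carbon-number estimate from its M+1
isotopologue abundance (natural ¹³C),

C ≈ (I<sub>M+1</sub> / I<sub>M</sub>) / 0.011145,

and is placed in the two-dimensional space of carbon-normalized mass
defect versus mass per carbon:

- **MD** = m − round(m), the mass defect under the nearest-integer
  convention (so values wrap into (−0.5, +0.5]);
- **MD/C** = MD / C and **m/C** = m / C.

Hydrocarbon matrix clusters near m/C ≈ 14 with clearly positive MD/C;
fluorine-dominated molecules are pushed to m/C ≈ 40–55 with MD/C near or
below zero (fluorine weighs 19 Da and contributes −0.0016 Da of mass
defect per atom, hydrogen +0.0078 Da). Cutoffs at **m/C > 30** and
**MD/C < +0.003** remove the bulk of non-PFAS features before any
list-based matching, which keeps false positives in the later stages
manageable.

On the reduced feature set the package then accumulates independent
evidence per feature:

- **Homologous series** by Kendrick mass defect: with a repeating unit R
  (CF₂, CF₂O, …), KM = m · nominal(R)/exact(R) and KMD = round(KM) − KM;
  features whose m/z differ by integer multiples of R (±2 mDa, ≥3
  members by default) are assigned a series id.
- **MS² diagnostic fragments** (C₂F₅⁻, C₃F₇⁻, SO₃⁻, …) matched at
  ±2 mDa above a 2000-count noise threshold, **fragment mass
  differences** (ΔCF₂, ΔHF, ΔC₂F₄, …) over all peak pairs, and formula
  **propagation** from annotated fragments across those gaps.
- **Suspect screening** by accurate mass (±4 mDa) for [M−H]⁻, [M+H]⁺ or
  [M]⁺ adducts.
- **EIC coelution correlation**: in-source fragments and adducts share
  their parent's elution profile, so EICs within ±25 s of a seed apex
  with Pearson r² ≥ 0.95 are grouped into one ion family.

Nothing is deleted along the way: every feature row in the results CSV
carries its evidence flags, so cutoffs can be re-tuned iteratively.

## Worked example

`examples/run_full_pipeline.py` generates a ground-truthed synthetic
run (60 hydrocarbon matrix features, a 7-member perfluorocarboxylic-acid
and a 5-member perfluorosulfonic-acid CF₂ ladder, a 4-ion in-source
family, 30 decoys, and a paired blank sharing 18 contaminants), writes
it as mzML and runs the pipeline:

```
stage                      count   % of detected
features_detected            106    100.0%
after_blank_correction        88     83.0%
after_mdc_mc                  16     15.1%
homologous_series              2
df_flagged_spectra            13
diff_flagged_spectra          13
suspect_hits                   2

16 features pass the MD/C-m/C filter; 2 have a suspect hit (PFBS, PFOA).
```

All 106 planted species are found; blank correction removes exactly the
18 shared contaminants; the MD/C–m/C cutoffs keep exactly the 16
fluorinated ions (12 series members + 4 family ions); both planted CF₂
ladders are recovered as series; and the two suspects in the toy list
are matched through their [M−H]⁻ ions. The other examples demonstrate
the individual capabilities: `mass_defect_basics.py` (MD/KMD
arithmetic), `ms2_fragment_annotation.py` (fragment evidence),
`coelution_correlation.py` (ion-family grouping).

The same workflow from a shell:

```bash
fluoroscreen synth --preset full --seed 11 --noise-free --out demo/
fluoroscreen run --sample demo/full.mzML --blank demo/full_blank.mzML --out results.csv
fluoroscreen correlate --mzml demo/full.mzML --results results.csv --seed-mz 788.9751
```

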