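# Methods

## Scope and model

`fluoroscreen` prioritizes candidate per- and polyfluoroalkyl substances
(PFAS) among features detected in centroided single-polarity HRMS
acquisitions. It does not identify compounds; it accumulates orthogonal
evidence (mass-defect position, homologue membership, MS² fragments,
suspect-list matches, coelution families) and leaves the final call to
the analyst. The pipeline is single-sample with an optional paired
blank; batch processing is a loop over samples, not a consensus model.

## Exact-mass arithmetic

Atomic masses are IUPAC 2021 monoisotopic values to ≥6 decimals, stored
in one table in `chem` that every module uses. Adduct masses are
electron-correct: [M−H]⁻ subtracts a proton (1.0072765 Da), [M+H]⁺ adds
one, [M]⁺ subtracts an electron (0.00054858 Da).

The mass defect uses the nearest-integer convention MD = m − round(m),
with values in (−0.5, +0.5]. This is deliberate: saturated hydrocarbons
above roughly C₄₅ accumulate a conventional MD beyond +0.5 Da, which
wraps to negative values and would masquerade as PFAS in a plain MD
filter. The mass-per-carbon axis (m/C) resolves the ambiguity, since
those molecules stay near m/C ≈ 14 while fluorine-dominated species sit
at m/C ≈ 40–55.

Kendrick mass defects are computed as KMD = round(KM) − KM with
KM = m · nominal(R)/exact(R) for a repeating unit R. Under this sign
convention CH₂-type series get small positive KMD; all grouping logic
depends only on within-series equality, never on sign. Exact arithmetic
keeps KMD constant to <1e-9 across ≥20 homologue steps, so the grouping
tolerance is governed entirely by measurement error.

Theoretical isotope patterns are aggregated per nominal-mass offset
(convolution of per-element isotope distributions, exponentiation by
squaring). Fine structure is out of scope: the pattern serves the M+1
carbon estimate and visual checks, for which the ¹³C spacing
(1.0033548 Da) is an adequate stand-in for the aggregated isotopologue
centroid.

## Carbon estimation

C ≈ (I_{M+1}/I_M)/0.011145, using apex intensities of the monoisotopic
and M+1 traces. The 1.1145 %-per-carbon factor is the conventional
screening constant; the pure binomial ¹³C expectation
(0.0107/0.9893 ≈ 1.082 % per carbon) differs by ~3 %, which is
immaterial against the ≥30 % isotope-ratio uncertainty of real
low-abundance features. Features without an M+1 intensity get no
estimate, are flagged, and are excluded from carbon-normalized
filtering rather than guessed at. With multiplicative noise of relative
SD s on the isotope ratio, the estimate is unbiased with relative SD ≈ s
(≈ √2·s when both traces carry independent noise s).

## Feature finding

The MS¹ feature finder is a transparent greedy EIC tracer, not a port
of any metabolomics feature finder — external feature tables are
accepted as an equivalent entry point, so parity with a specific
algorithm is not a goal. Constraints, with defaults chosen for QTOF
screening data: mass error 10 ppm, MS¹ intensity threshold 2000 counts,
chromatographic FWHM between 1 s and 1 min (linear interpolation at
half max), and at least two isotopologue traces (an M+1 trace at
+1.0033548 Da found in ≥3 scans with a nonzero apex intensity). Seeds
are processed in descending intensity; traced centroids are claimed so
each centroid contributes to one feature, which also prevents an intense
feature's M+1 trace from seeding a phantom feature. Apex m/z is the
intensity-weighted mean over the trace, area is trapezoidal over RT.

An isotope-envelope plausibility check stands in for model-based
isotope filtering: the M+1/M ratio must lie within ±50 % of the
expectation for the rounded carbon estimate, the estimate must be ≥0.5,
and it must not exceed m/z / 12 (more carbons than the mass allows).
This rejects grossly implausible envelopes while remaining a pure
ratio test.

MS² alignment: each MS² scan is matched to the nearest-m/z feature
within 5 mDa / 0.2 min; per feature, the matched scan with the highest
precursor intensity wins (ties: earlier scan). Blank correction removes
a sample feature when a blank feature matches within 2 mDa / 0.1 min
and the sample's integrated area is below 5× the blank's. Area (not
apex intensity) is compared, as it is the more robust abundance measure
for tailing background peaks; removed features are retained with a
`blank_removed` flag for audit.

## Evidence channels

**MD/C–m/C filter.** Keep m/C > 30 and MD/C < +0.003 (each cutoff
individually optional). Non-passing features are flagged, not deleted.

**Homologous series.** Features are linked when their m/z difference is
within ±2 mDa of a nonzero integer multiple of the repeating unit's
exact mass; connected components with ≥3 members become series. Allowing
multiples k > 1 means a missing homologue does not split a ladder, at
the cost that a bridging feature can merge two series — accepted, since
series membership is a prioritization hint, not an identification.
Retention time is deliberately not used; RT-shift verification is a
downstream visual check via the ladder EIC extractor.

**MS² matching.** Peaks below the 2000-count MS² noise threshold are
ignored. Diagnostic fragments are matched at ±2 mDa; the shipped starter
list (~40 ions: the CₙF₂ₙ₊₁⁻ series, SO₃⁻/FSO₃⁻/PO₃⁻-type head-group
ions, positive-mode CₙF₂ₙ₋₁⁺ ions) is generated from formulas at import
time — no hard-coded masses — and users can supply larger lists as CSV.
Fragment mass differences (ΔCF₂, ΔC₂F₄, ΔHF, ΔCF₂O, ΔC₂F₄O, ΔHF+CO₂,
ΔC₁₀H₃F₁₇) are matched over all C(n,2) peak gaps. Formula propagation
iterates to a fixed point, adding/subtracting gap compositions
element-wise and rejecting any step that would need a negative element
count; each propagated annotation records its partner peak.

**Suspect screening.** Accurate-mass match at ±4 mDa for the chosen
adducts, restricted to adducts consistent with the run polarity. All
matches are reported (no deduplication); suspect lists are validated on
load by recomputing each exact mass from its formula and warning above
1 mDa of disagreement.

**Coelution correlation.** EIC extraction sums centroids within
mz ± width, with width = 5 mDa by default — the stated width is the
half-window each side, following common usage. Candidates are features
whose apex RT lies within ±25 s of the seed apex; both EICs are
extracted on the shared MS¹ scan grid over that window and compared by
squared Pearson correlation against a 0.95 threshold. Pairs with fewer
than five jointly nonzero grid points are reported as undefined and
excluded rather than given a meaningless r².

## Synthetic data

The generator plants species as explicit molecular formulas so that
every ground-truth quantity (m/z, isotope ratio, carbon count, m/C,
MD/C, series spacing) is recomputable through `chem`. Default study
conditions: a 10-min run at 0.02-min MS¹ scan spacing; Gaussian elution
with σ = 0.03 min (FWHM ≈ 4.2 s); hydrocarbon matrix as random CcHhOo
compositions with m/C in [12.5, 25] and amplitudes log-uniform over
10⁴–10⁶ counts; CF₂-spaced homologous series (perfluorocarboxylic and
perfluorosulfonic acids as [M−H]⁻) with a fixed RT increment per
homologue; an in-source family (parent, −HF, +Cl−H, +Ac−H) sharing one
profile; a blank run containing 30 % of the matrix at sample abundance;
ddMS² scans for fluorinated species carrying planted diagnostic
fragments and CF₂/HF ladders, plus CH₂-ladder MS² decoys on matrix
features. Realistic noise defaults are 1 ppm m/z jitter and 2 %
multiplicative intensity noise; `noise_free()` variants define the
recovery benchmarks.

Two modelling conventions worth knowing: planted M+1/M ratios use the
same 0.011145-per-carbon factor the estimator inverts, so carbon
recovery is exact on noise-free data (the ~3 % binomial offset is a
separate, documented fact about the estimator, not hidden in the
generator); and planted ions are kept ≥50 mDa away from all existing M
and M+1 positions, so noise-free recovery tests measure the pipeline,
not accidental coincidences. Consequently the synthetic benchmarks say
nothing about overlapping isotope envelopes, tailing peaks, profile
data, or real electrospray response — passing them demonstrates correct
bookkeeping and algorithmic behaviour under the stated model, not
instrument-grade robustness.

## Numerical and engineering choices

- RT is minutes everywhere; mzML files in seconds are converted on read.
- mzML I/O is a minimal self-contained implementation (the PSI 1.1
  subset needed here: centroided spectrum list, scan times, polarity,
  64-bit uncompressed arrays, one selected ion per MS² scan); written
  files are verified against an independent third-party mzML reader in
  the test suite. Profile spectra and mixed-polarity files are rejected
  with actionable errors.
- The pipeline is deterministic end to end: identical inputs and
  configuration give byte-identical results CSVs (fixed column order,
  stable sorts, no hash iteration anywhere in output paths).
- Ties in MS² assignment break toward the earlier scan; features are
  reported sorted by descending area.
- Degenerate inputs: empty blank lists pass through with a warning;
  features lacking M+1 keep empty carbon-dependent columns; EIC
  requests outside the run's RT range raise.

## Known limitations

No retention-time alignment across runs, no multi-sample consensus, no
charge states beyond ±1, no fine isotope structure, no structure
elucidation or identification-confidence scoring. The feature finder
assumes well-separated centroids and will merge species closer than the
ppm tolerance. The shipped fragment list is a starter set, not a
comprehensive literature compilation.
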