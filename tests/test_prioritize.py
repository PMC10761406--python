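"""MD/C-m/C filtering, homologue detection, MS2 matching, suspect screening."""

import itertools

import numpy as np
import pytest

from fluoroscreen import chem, prioritize as pri
from fluoroscreen.chem import adduct_mz, monoisotopic_mass, parse_formula
from fluoroscreen.features import Feature
from fluoroscreen.msio import Spectrum
from fluoroscreen.synthdata import SynthConfig, generate_feature_csv


def _feature_for(formula, mz=None):
    """Feature with exact carbon count and the formula's neutral mass as
    a stand-in m/z (for worked m/C examples)."""
    counts = parse_formula(formula)
    m = mz if mz is not None else monoisotopic_mass(counts)
    f = Feature(mz=m, rt=1.0, area=1.0, intensity_M=1e5)
    f.carbon_est = float(counts["C"])
    return f


class TestMdcMc:
    @pytest.mark.parametrize("formula,expected_mc", [
        ("C16H9F26O4P", 49),   # 6:2 diPAP
        ("C8HF15O2", 51),      # PFOA
        ("C15H19F13N2O4S", 38),  # 6:2 FTAB
        ("C17H18F3NO", 18),    # fluoxetine
        ("CH2", 14),           # pure methylene composition
    ])
    def test_worked_mc_examples(self, formula, expected_mc):
        f = _feature_for(formula)
        pri.compute_mdc_mc([f])
        assert int(f.m_over_c) == expected_mc

    def test_columns_empty_without_carbon(self):
        f = Feature(mz=400.0, rt=1.0, area=1.0, intensity_M=1e5)
        pri.compute_mdc_mc([f])
        assert f.mdc is None and f.m_over_c is None
        assert "no_carbon_estimate" in f.flags

    def test_filter_rules(self):
        ok = _feature_for("C8HF15O2")       # m/C ~ 51, MD/C < 0
        bad_mc = _feature_for("C17H18F3NO")  # m/C ~ 18
        bad_mdc = Feature(mz=400.16, rt=1.0, area=1.0, intensity_M=1e5)
        bad_mdc.carbon_est = 10.0            # m/C 40 but MD/C = +0.016
        feats = pri.compute_mdc_mc([ok, bad_mc, bad_mdc])
        passed = pri.filter_mdc_mc(feats)
        assert passed == [ok]
        assert "mdc_mc_pass" in ok.flags and "mdc_mc_pass" not in bad_mdc.flags

    def test_empty_input(self):
        assert pri.filter_mdc_mc([]) == []

    def test_synthetic_table_exact_separation(self):
        """90 hydrocarbons + 10 fluorinated homologues: the cutoffs keep
        exactly the fluorinated rows (noise-free carbon estimates)."""
        from fluoroscreen.synthdata import SeriesSpec

        cfg = SynthConfig(
            seed=9, n_matrix_features=90,
            series=(SeriesSpec(label="PFCA", base_formula="C4HF7O2",
                               n_members=10, rt_start=0.9, rt_step=0.85),),
            rt_max=12.0,
        ).noise_free()
        table, truth = generate_feature_csv(cfg)
        feats = [Feature(mz=r.mz, rt=r.rt, area=r.intensity_M,
                         intensity_M=r.intensity_M,
                         intensity_M1=r.intensity_M1)
                 for r in table.itertuples()]
        from fluoroscreen.features import estimate_carbon
        for f in feats:
            estimate_carbon(f)
        pri.compute_mdc_mc(feats)
        passed = pri.filter_mdc_mc(feats)
        passed_mz = {round(f.mz, 4) for f in passed}
        pfas_mz = {round(m, 4) for m in truth[truth.kind == "pfas"].mz}
        assert passed_mz == pfas_mz


class TestHomologousSeries:
    def _ladder(self, n=7, base="C4HF7O2"):
        f = parse_formula(base)
        out = []
        for k in range(n):
            out.append(adduct_mz(monoisotopic_mass(f), "[M-H]-"))
            f = chem.combine(f, parse_formula("CF2"))
        return out

    def test_planted_ladder_recovered(self):
        feats = [Feature(mz=m, rt=1.0 + i, area=1.0, intensity_M=1e5)
                 for i, m in enumerate(self._ladder(7))]
        series = pri.detect_homologous_series(feats)
        assert len(series) == 1
        assert series[0].member_feature_indices == list(range(7))
        assert all(f.hs_ids == [1] for f in feats)

    def test_perturbed_member_excluded(self):
        mzs = self._ladder(7)
        mzs[3] += 0.005  # 5 mDa off, outside the 2 mDa tolerance
        feats = [Feature(mz=m, rt=1.0, area=1.0, intensity_M=1e5) for m in mzs]
        series = pri.detect_homologous_series(feats)
        assert len(series) == 1
        assert len(series[0].member_feature_indices) == 6
        assert 3 not in series[0].member_feature_indices

    def test_min_members(self):
        feats = [Feature(mz=m, rt=1.0, area=1.0, intensity_M=1e5)
                 for m in self._ladder(2)]
        assert pri.detect_homologous_series(feats, min_members=3) == []

    def test_gap_in_ladder_still_one_series(self):
        # missing homologue: spacing 2 x CF2 still links the neighbours
        mzs = self._ladder(5)
        del mzs[2]
        feats = [Feature(mz=m, rt=1.0, area=1.0, intensity_M=1e5) for m in mzs]
        series = pri.detect_homologous_series(feats)
        assert len(series) == 1 and len(series[0].member_feature_indices) == 4

    def test_pairwise_spacing_invariant(self):
        """Recovered series members are pairwise integer multiples of the
        unit within an accumulated tolerance."""
        feats = [Feature(mz=m, rt=1.0, area=1.0, intensity_M=1e5)
                 for m in self._ladder(7)]
        series = pri.detect_homologous_series(feats)[0]
        ru = series.repeating_unit
        for i, j in itertools.combinations(series.member_feature_indices, 2):
            d = abs(feats[i].mz - feats[j].mz)
            k = round(d / ru.exact_mass)
            assert k >= 1 and abs(d - k * ru.exact_mass) <= 0.002 * (
                len(series.member_feature_indices) - 1)


def _spec(peaks, polarity="negative"):
    peaks = sorted(peaks)
    return Spectrum(
        ms_level=2, rt=1.0,
        mz=np.array([p[0] for p in peaks]),
        intensity=np.array([p[1] for p in peaks]),
        polarity=polarity, precursor_mz=500.0, precursor_intensity=1e5)


C2F5_MZ = monoisotopic_mass("C2F5") + chem.ELECTRON_MASS  # 118.99256
C3F7_MZ = monoisotopic_mass("C3F7") + chem.ELECTRON_MASS  # 168.98937


class TestDiagnosticFragments:
    def test_planted_fragments_hit(self):
        spec = _spec([(C2F5_MZ, 1e4), (C3F7_MZ, 2e4)])
        dfs = pri.builtin_diagnostic_fragments("negative")
        hits, flagged = pri.match_diagnostic_fragments(spec, dfs)
        assert len(hits) == 2 and flagged

    def test_noise_threshold(self):
        spec = _spec([(C2F5_MZ, 500), (C3F7_MZ, 1500)])
        dfs = pri.builtin_diagnostic_fragments("negative")
        hits, flagged = pri.match_diagnostic_fragments(spec, dfs, noise=2000)
        assert hits == [] and not flagged

    def test_mass_tolerance(self):
        spec = _spec([(C2F5_MZ + 0.003, 1e4)])
        dfs = pri.builtin_diagnostic_fragments("negative")
        hits, _ = pri.match_diagnostic_fragments(spec, dfs, tol=0.002)
        assert hits == []

    def test_polarity_mismatch_raises(self):
        spec = _spec([(C2F5_MZ, 1e4)], polarity="positive")
        dfs = pri.builtin_diagnostic_fragments("negative")
        with pytest.raises(ValueError, match="polarity"):
            pri.match_diagnostic_fragments(spec, dfs)

    def test_min_hits_flagging(self):
        spec = _spec([(C2F5_MZ, 1e4)])
        dfs = pri.builtin_diagnostic_fragments("negative")
        _, flagged = pri.match_diagnostic_fragments(spec, dfs, min_hits=2)
        assert not flagged


class TestFragmentDifferences:
    def test_cf2_gap(self):
        spec = _spec([(C2F5_MZ, 1e4), (C3F7_MZ, 1e4)])
        hits = pri.match_fragment_differences(spec, pri.builtin_mass_differences())
        labels = {h[2].label for h in hits}
        assert labels == {"CF2"}

    def test_hf_gap(self):
        hf = monoisotopic_mass("HF")
        spec = _spec([(100.0, 1e4), (100.0 + hf, 1e4)])
        hits = pri.match_fragment_differences(spec, pri.builtin_mass_differences())
        assert {h[2].label for h in hits} == {"HF"}

    def test_single_peak_no_hits(self):
        spec = _spec([(100.0, 1e4)])
        assert pri.match_fragment_differences(
            spec, pri.builtin_mass_differences()) == []

    def test_matches_brute_force_oracle(self):
        """Vectorized matcher agrees with a double-loop oracle on random
        spectra (set equality of hits)."""
        rng = np.random.default_rng(7)
        diffs = pri.builtin_mass_differences()
        for _ in range(20):
            n = int(rng.integers(2, 200))
            mz = np.sort(rng.uniform(50, 900, n))
            inten = rng.uniform(0, 1e5, n)
            spec = _spec(list(zip(mz, inten)))
            got = {(round(a, 6), round(b, 6), d.label)
                   for a, b, d in pri.match_fragment_differences(spec, diffs)}
            peaks = sorted(m for m, i in zip(spec.mz, spec.intensity)
                           if i >= 2000)
            want = set()
            for i in range(len(peaks)):
                for j in range(i + 1, len(peaks)):
                    for d in diffs:
                        if abs((peaks[j] - peaks[i]) - d.delta) <= 0.002:
                            want.add((round(peaks[i], 6), round(peaks[j], 6),
                                      d.label))
            assert got == want


class TestPropagation:
    def test_addition_propagates(self):
        c2f4 = monoisotopic_mass("C2F4")
        spec = _spec([(C2F5_MZ, 1e4), (C2F5_MZ + c2f4, 1e4)])
        seed = pri.MS2Annotation(fragment_mz=C2F5_MZ, label="C2F5-",
                                 formula=parse_formula("C2F5"),
                                 source="df_list")
        anns = pri.propagate_formulas(spec, [seed],
                                      pri.builtin_mass_differences())
        new = [a for a in anns if a.source == "propagated"]
        assert len(new) == 1
        assert new[0].formula == {"C": 4, "F": 9}
        assert new[0].partner_mz == pytest.approx(C2F5_MZ)
        # propagated mass stays consistent with the peak it annotates
        assert abs(monoisotopic_mass(new[0].formula) + chem.ELECTRON_MASS
                   - new[0].fragment_mz) < 0.0025

    def test_elementwise_subtraction(self):
        c2f4 = monoisotopic_mass("C2F4")
        spec = _spec([(C2F5_MZ, 1e4), (C2F5_MZ - c2f4, 1e4)])
        seed = pri.MS2Annotation(fragment_mz=C2F5_MZ, label="C2F5-",
                                 formula=parse_formula("C2F5"),
                                 source="df_list")
        anns = pri.propagate_formulas(spec, [seed],
                                      pri.builtin_mass_differences())
        new = [a for a in anns if a.source == "propagated"]
        # C2F5 - C2F4 = F: valid element-wise subtraction
        assert any(a.formula == {"F": 1} for a in new)

    def test_invalid_subtraction_rejected(self):
        hf = monoisotopic_mass("HF")
        spec = _spec([(C2F5_MZ, 1e4), (C2F5_MZ - hf, 1e4)])
        seed = pri.MS2Annotation(fragment_mz=C2F5_MZ, label="C2F5-",
                                 formula=parse_formula("C2F5"),
                                 source="df_list")
        anns = pri.propagate_formulas(
            spec, [seed], [pri.MassDifference.from_formula("HF")])
        # C2F5 has no H: subtracting HF is impossible, adding misses peaks
        assert [a for a in anns if a.source == "propagated"] == []

    def test_no_seed_no_propagation(self):
        spec = _spec([(C2F5_MZ, 1e4)])
        assert pri.propagate_formulas(
            spec, [], pri.builtin_mass_differences()) == []

    def test_chained_propagation_reaches_fixed_point(self):
        cf2 = monoisotopic_mass("CF2")
        peaks = [(C2F5_MZ + k * cf2, 1e4) for k in range(4)]
        spec = _spec(peaks)
        seed = pri.MS2Annotation(fragment_mz=C2F5_MZ, label="C2F5-",
                                 formula=parse_formula("C2F5"),
                                 source="df_list")
        anns = pri.propagate_formulas(spec, [seed],
                                      [pri.MassDifference.from_formula("CF2")])
        assert len([a for a in anns if a.source == "propagated"]) == 3
        assert any(a.formula == {"C": 5, "F": 11} for a in anns)


class TestSuspectScreen:
    def _pfoa_suspect(self):
        return pri.SuspectEntry(
            name="PFOA", formula=parse_formula("C8HF15O2"),
            exact_mass=monoisotopic_mass("C8HF15O2"))

    def test_negative_mode_hit(self):
        f = Feature(mz=412.9664, rt=1.0, area=1.0, intensity_M=1e5)
        hits = pri.suspect_screen([f], [self._pfoa_suspect()])
        assert len(hits) == 1
        assert hits[0].adduct_label == "[M-H]-"
        assert "suspect_hit" in f.flags
        assert f.extras["suspect_names"] == ["PFOA"]

    def test_tolerance_respected(self):
        f = Feature(mz=412.9664 + 0.010, rt=1.0, area=1.0, intensity_M=1e5)
        assert pri.suspect_screen([f], [self._pfoa_suspect()]) == []

    def test_radical_cation_adduct(self):
        neutral = 300.0
        f = Feature(mz=neutral - chem.ELECTRON_MASS, rt=1.0, area=1.0,
                    intensity_M=1e5)
        s = pri.SuspectEntry(name="X", formula=None, exact_mass=neutral)
        hits = pri.suspect_screen([f], [s], adducts=("[M]+",),
                                  polarity="positive")
        assert len(hits) == 1 and abs(hits[0].error_mda) < 1e-6

    def test_polarity_consistency_enforced(self):
        f = Feature(mz=412.9664, rt=1.0, area=1.0, intensity_M=1e5)
        with pytest.raises(ValueError, match="polarity"):
            pri.suspect_screen([f], [self._pfoa_suspect()],
                               adducts=("[M+H]+",), polarity="negative")


class TestListIO:
    def test_suspect_csv_mismatch_warns(self, tmp_path):
        p = tmp_path / "suspects.csv"
        p.write_text("name,smiles,formula,exact_mass\n"
                     "PFOA,C(=O)(O)C(F)(F)...,C8HF15O2,413.9737\n"
                     "Corrupt,,C8HF15O2,413.9800\n")
        with pytest.warns(UserWarning, match="Corrupt"):
            suspects = pri.read_suspect_csv(p)
        assert len(suspects) == 2
        assert suspects[0].name == "PFOA"

    def test_fragment_csv_formula_and_mz(self, tmp_path):
        p = tmp_path / "frags.csv"
        p.write_text("label,formula_or_mz,polarity\n"
                     "C2F5-,C2F5,negative\n"
                     "custom,329.9999,negative\n")
        frags = pri.read_fragment_csv(p)
        assert frags[0].mz == pytest.approx(C2F5_MZ, abs=1e-5)
        assert frags[1].mz == pytest.approx(329.9999)

    def test_difference_csv(self, tmp_path):
        p = tmp_path / "diffs.csv"
        p.write_text("label,formula\ndCF2,CF2\n")
        diffs = pri.read_difference_csv(p)
        assert diffs[0].delta == pytest.approx(49.99681, abs=1e-5)

    def test_builtin_fragment_masses_are_consistent(self):
        """Every built-in fragment with a formula has an m/z within
        0.5 mDa of its electron-corrected formula mass."""
        for pol in ("negative", "positive"):
            for d in pri.builtin_diagnostic_fragments(pol):
                assert d.formula is not None
                sign = +1 if pol == "negative" else -1
                calc = monoisotopic_mass(d.formula) + sign * chem.ELECTRON_MASS
                assert abs(calc - d.mz) < 0.0005
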