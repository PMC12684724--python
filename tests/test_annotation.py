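"""Formula/adduct arithmetic and the three annotation routes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import isocontext as ic
from isocontext.annotation import DEFAULT_ADDUCTS, PROTON_MASS
from isocontext.errors import ConfigurationError, ParseError, ValidationError

MH = next(a for a in DEFAULT_ADDUCTS if a.name == "[M+H]+")
MmH = next(a for a in DEFAULT_ADDUCTS if a.name == "[M-H]-")

# hand-computed from IUPAC monoisotopic masses
WATER_MASS = 2 * 1.0078250319 + 15.9949146221
GLUCOSE_MASS = 6 * 12.0 + 12 * 1.0078250319 + 6 * 15.9949146221


class TestFormula:
    @pytest.mark.parametrize("text,expected", [
        ("C6H12O6", {"C": 6, "H": 12, "O": 6}),
        ("H2O", {"H": 2, "O": 1}),
        ("C10H16N5O13P3", {"C": 10, "H": 16, "N": 5, "O": 13, "P": 3}),
        ("NaCl", {"Na": 1, "Cl": 1}),
    ])
    def test_parse(self, text, expected):
        assert ic.parse_formula(text) == expected

    def test_unknown_element_position(self):
        with pytest.raises(ParseError, match="X"):
            ic.parse_formula("C6H12O6X")

    def test_empty_rejected(self):
        with pytest.raises(ParseError):
            ic.parse_formula("")

    def test_water_mass(self):
        assert ic.monoisotopic_mass({"H": 2, "O": 1}) == pytest.approx(
            WATER_MASS, abs=1e-5)

    def test_glucose_mass(self):
        assert ic.monoisotopic_mass(ic.parse_formula("C6H12O6")) == \
            pytest.approx(GLUCOSE_MASS, abs=1e-4)

    def test_empty_composition_rejected(self):
        with pytest.raises(ValidationError):
            ic.monoisotopic_mass({})

    @given(st.dictionaries(st.sampled_from(["C", "H", "N", "O", "P", "S"]),
                           st.integers(1, 40), min_size=1),
           st.dictionaries(st.sampled_from(["C", "H", "N", "O", "P", "S"]),
                           st.integers(1, 40), min_size=1))
    @settings(max_examples=50, deadline=None)
    def test_mass_additive(self, a, b):
        merged = dict(a)
        for k, v in b.items():
            merged[k] = merged.get(k, 0) + v
        assert ic.monoisotopic_mass(merged) == pytest.approx(
            ic.monoisotopic_mass(a) + ic.monoisotopic_mass(b), rel=1e-12)


class TestAdductPpm:
    def test_protonated_glucose(self):
        assert ic.adduct_mz(180.063388, MH) == pytest.approx(181.070664,
                                                             abs=1e-4)

    def test_deprotonated_glucose(self):
        assert ic.adduct_mz(180.063388, MmH) == pytest.approx(179.056112,
                                                              abs=1e-4)

    def test_dimer(self):
        dimer = ic.AdductDef("[2M+H]+", PROTON_MASS, 1, multimer=2)
        assert ic.adduct_mz(100.0, dimer) == pytest.approx(201.00727646,
                                                           abs=1e-8)

    def test_ppm_identity(self):
        assert ic.ppm_error(181.070664, 181.070664) == 0.0

    def test_ppm_five(self):
        assert ic.ppm_error(181.071569, 181.070664) == pytest.approx(5.0,
                                                                     abs=0.01)

    def test_ppm_extreme(self):
        assert ic.ppm_error(0.0, 181.07) == pytest.approx(-1e6)

    @given(st.floats(50, 2000), st.floats(50, 2000))
    @settings(max_examples=50, deadline=None)
    def test_ppm_antisymmetric_first_order(self, a, b):
        # algebraic identity: e(a,b) + e(b,a) = -e(a,b)*e(b,a)/1e6,
        # i.e. antisymmetric to first order in the error
        e1, e2 = ic.ppm_error(a, b), ic.ppm_error(b, a)
        assert e1 + e2 == pytest.approx(-e1 * e2 / 1e6, rel=1e-9, abs=1e-9)


class TestAnnotateMs1:
    COMPOUNDS = pd.DataFrame({"name": ["glucose"], "formula": ["C6H12O6"]})

    def _features(self, mzs, rts=None):
        rts = rts or [100.0] * len(mzs)
        df = pd.DataFrame({"mz": mzs, "rt": rts},
                          index=pd.Index([f"F{i}" for i in range(len(mzs))],
                                         name="feature_id"))
        df["S1"] = 1.0
        return ic.FeatureTable(df)

    def test_glucose_hit(self):
        feats = self._features([181.0707])
        out = ic.annotate_ms1(feats, self.COMPOUNDS, [MH], ppm_tol=5.0)
        assert len(out) == 1
        assert out.iloc[0]["compound_name"] == "glucose"
        assert abs(out.iloc[0]["ppm_error"]) < 5.0

    def test_no_hit_empty(self):
        out = ic.annotate_ms1(self._features([500.0]), self.COMPOUNDS,
                              [MH], ppm_tol=5.0)
        assert len(out) == 0

    def test_isobaric_hits_sorted_by_ppm(self):
        # two compounds within tolerance of one feature; brute-force order
        compounds = pd.DataFrame({
            "name": ["fructose", "glucose"],
            "formula": ["C6H12O6", "C6H12O6"],
        })
        feats = self._features([181.0707])
        out = ic.annotate_ms1(feats, compounds, [MH], ppm_tol=5.0)
        assert len(out) == 2
        errs = out["ppm_error"].abs().to_numpy()
        assert (np.diff(errs) >= 0).all()

    def test_bad_formula_skipped_and_counted(self):
        compounds = pd.DataFrame({"name": ["good", "bad"],
                                  "formula": ["C6H12O6", "Xx9"]})
        out = ic.annotate_ms1(self._features([181.0707]), compounds, [MH])
        assert out.attrs["skipped_compounds"] == 1
        assert set(out["compound_name"]) == {"good"}

    def test_permutation_invariance(self):
        compounds = pd.DataFrame({"name": ["a", "b"],
                                  "formula": ["C6H12O6", "C5H10O5"]})
        feats1 = self._features([181.0707, 151.0601])
        feats2 = self._features([151.0601, 181.0707])
        o1 = ic.annotate_ms1(feats1, compounds, [MH])
        o2 = ic.annotate_ms1(feats2, compounds.iloc[::-1], [MH])
        key = ["compound_name", "adduct"]
        s1 = o1.sort_values(key + ["ppm_error"]).reset_index(drop=True)
        s2 = o2.sort_values(key + ["ppm_error"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(s1[key + ["ppm_error"]],
                                      s2[key + ["ppm_error"]])


class TestStandards:
    def _feat(self, mz, rt):
        df = pd.DataFrame({"mz": [mz], "rt": [rt], "S1": [1.0]},
                          index=pd.Index(["F0"], name="feature_id"))
        return ic.FeatureTable(df)

    def test_both_windows_match(self):
        std = ic.ReferenceStandard("glucose", "C6H12O6", rt=120.0, mz=181.0707)
        out = ic.match_reference_standards(self._feat(181.0706, 118.0), [std],
                                           ppm_tol=5.0, rt_tol=10.0)
        assert len(out) == 1
        assert out.iloc[0]["source"] == "standard"

    def test_rt_outside_window(self):
        std = ic.ReferenceStandard("glucose", "C6H12O6", rt=120.0, mz=181.0707)
        out = ic.match_reference_standards(self._feat(181.0706, 140.0), [std],
                                           ppm_tol=5.0, rt_tol=10.0)
        assert len(out) == 0

    def test_tie_broken_by_combined_distance(self):
        # equal ppm distance, rt decides (brute-force over both candidates)
        mz = 181.0707
        s_far = ic.ReferenceStandard("far", "C6H12O6", rt=128.0, mz=mz)
        s_near = ic.ReferenceStandard("near", "C6H12O6", rt=122.0, mz=mz)
        out = ic.match_reference_standards(self._feat(mz, 120.0),
                                           [s_far, s_near],
                                           ppm_tol=5.0, rt_tol=10.0)
        assert out.iloc[0]["compound_name"] == "near"


class TestMs2:
    def _feat_table(self, mzs, rts):
        df = pd.DataFrame({"mz": mzs, "rt": rts, "S1": 1.0},
                          index=pd.Index([f"F{i}" for i in range(len(mzs))],
                                         name="feature_id"))
        return ic.FeatureTable(df)

    def test_alignment(self):
        spec = ic.Ms2Spectrum(181.0708, 121.0, [(85.0, 100.0)])
        feats = self._feat_table([181.0707], [120.0])
        assigned, unassigned = ic.align_ms2_to_features([spec], feats,
                                                        ppm_tol=10, rt_tol=15)
        assert "F0" in assigned and not unassigned

    def test_unassigned_reported(self):
        spec = ic.Ms2Spectrum(500.0, 121.0, [(85.0, 100.0)])
        feats = self._feat_table([181.0707], [120.0])
        assigned, unassigned = ic.align_ms2_to_features([spec], feats)
        assert not assigned and unassigned == [spec]

    def test_two_features_nearest_ppm_wins(self):
        spec = ic.Ms2Spectrum(181.07080, 120.0, [(85.0, 100.0)])
        feats = self._feat_table([181.07078, 181.07090], [120.0, 120.0])
        assigned, _ = ic.align_ms2_to_features([spec], feats,
                                               ppm_tol=10, rt_tol=15)
        assert list(assigned) == ["F0"]

    def test_similarity_identity(self):
        a = ic.Ms2Spectrum(100.0, 0.0, [(50.0, 10.0), (60.0, 5.0)])
        assert ic.spectral_similarity(a, a) == pytest.approx(1.0)

    def test_similarity_disjoint(self):
        a = ic.Ms2Spectrum(100.0, 0.0, [(50.0, 10.0)])
        b = ic.Ms2Spectrum(100.0, 0.0, [(70.0, 10.0)])
        assert ic.spectral_similarity(a, b) == 0.0

    def test_similarity_half_overlap(self):
        # sqrt intensities both 1 -> cosine of (1,1) with (1,0) = 1/sqrt(2)
        a = ic.Ms2Spectrum(100.0, 0.0, [(100.0, 1.0), (200.0, 1.0)])
        b = ic.Ms2Spectrum(100.0, 0.0, [(100.0, 1.0)])
        assert ic.spectral_similarity(a, b) == pytest.approx(0.70710678,
                                                             abs=1e-6)

    def test_similarity_symmetric(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = ic.Ms2Spectrum(100.0, 0.0, [(float(m), float(i)) for m, i in
                                            zip(rng.uniform(50, 500, 5),
                                                rng.uniform(1, 100, 5))])
            b = ic.Ms2Spectrum(100.0, 0.0, [(float(m), float(i)) for m, i in
                                            zip(rng.uniform(50, 500, 5),
                                                rng.uniform(1, 100, 5))])
            assert ic.spectral_similarity(a, b) == pytest.approx(
                ic.spectral_similarity(b, a), abs=1e-12)

    def test_similarity_matches_matchms_on_unambiguous_spectra(self):
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        # well-separated peaks: greedy pairing order cannot differ
        peaks_a = [(100.0, 4.0), (200.0, 9.0), (300.0, 16.0)]
        peaks_b = [(100.005, 1.0), (200.0, 25.0), (400.0, 9.0)]
        a = ic.Ms2Spectrum(500.0, 0.0, peaks_a)
        b = ic.Ms2Spectrum(500.0, 0.0, peaks_b)
        ours = ic.spectral_similarity(a, b, mz_tol=0.01)
        sa = matchms.Spectrum(mz=np.array([p[0] for p in peaks_a]),
                              intensities=np.array([p[1] for p in peaks_a]),
                              metadata={"precursor_mz": 500.0})
        sb = matchms.Spectrum(mz=np.array([p[0] for p in peaks_b]),
                              intensities=np.array([p[1] for p in peaks_b]),
                              metadata={"precursor_mz": 500.0})
        ref = CosineGreedy(tolerance=0.01, intensity_power=0.5).pair(sa, sb)
        assert ours == pytest.approx(float(ref["score"]), abs=1e-9)

    def test_empty_spectrum_rejected(self):
        a = ic.Ms2Spectrum(100.0, 0.0, [(50.0, 1.0)])
        b = ic.Ms2Spectrum(100.0, 0.0, [])
        with pytest.raises(ValidationError):
            ic.spectral_similarity(a, b)

    def test_annotate_ms2_exact_match(self):
        spec = ic.Ms2Spectrum(181.0707, 120.0, [(85.0, 100.0), (71.0, 40.0)])
        lib = [ic.Ms2Spectrum(181.0707, 0.0, [(85.0, 100.0), (71.0, 40.0)],
                              name="glucose")]
        out = ic.annotate_ms2({"F0": [spec]}, lib, min_score=0.8)
        assert len(out) == 1
        assert out.iloc[0]["score"] == pytest.approx(1.0)

    def test_min_score_out_of_range(self):
        with pytest.raises(ConfigurationError):
            ic.annotate_ms2({}, [ic.Ms2Spectrum(1.0, 0.0, [(1.0, 1.0)])],
                            min_score=1.01)

    def test_min_score_threshold_filters(self):
        spec = ic.Ms2Spectrum(181.0707, 120.0,
                              [(85.0, 100.0), (71.0, 40.0), (59.0, 20.0)])
        close = ic.Ms2Spectrum(181.0707, 0.0,
                               [(85.0, 100.0), (71.0, 40.0), (59.0, 20.0)],
                               name="hit")
        partial = ic.Ms2Spectrum(181.0707, 0.0, [(85.0, 100.0)], name="weak")
        s_hit = ic.spectral_similarity(spec, close)
        s_weak = ic.spectral_similarity(spec, partial)
        assert s_hit >= 0.9 > s_weak  # oracle per entry
        out = ic.annotate_ms2({"F0": [spec]}, [close, partial], min_score=0.9)
        assert list(out["compound_name"]) == ["hit"]
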