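"""Annotation logic: candidate ranking, B/C discrimination, reporting."""

import numpy as np
import pytest

from crambederep.dereplicate import (
    annotate_crambescidin,
    annotate_feature,
    annotate_run,
    build_report,
    discriminate_B_vs_C,
    fragment_matches,
    label_isomer_pairs,
)
from crambederep.library import SeriesParams
from crambederep.spectra import Feature, Ms2Spectrum


def feat(mz, z, rt=11.0, peaks=None, fid="F0001"):
    ms2 = None
    if peaks:
        mzs, ints = zip(*peaks)
        ms2 = Ms2Spectrum(mz, rt, np.array(mzs), np.array(ints), precursor_z=z)
    return Feature(mz=mz, rt=rt, z=z, intensity=1e6, ms2=ms2, feature_id=fid)


def test_most_abundant_metabolite_identified():
    """The dominant doubly charged ion at 225.1835 is crambescin A2 448."""
    f = feat(
        225.1835,
        2,
        rt=11.70,
        peaks=[(127.0863, 60.0), (204.1721, 80.0), (132.1130, 90.0), (276.2321, 25.0)],
    )
    anns = annotate_feature(f)
    assert anns[0].name == "crambescin A2 448"
    assert anns[0].params == SeriesParams("A", 2, 8)
    roles = {m.role for m in anns[0].matched}
    assert {"alkyl_loss", "ch2n2_loss", "guanidinoalkyl", "ester_core"} <= roles
    assert all(abs(m.delta_ppm) <= 5 or m.mz_theor < 400 for m in anns[0].matched)


def test_new_homologue_m5_n4_ranks_first():
    f = feat(
        218.1757,
        2,
        rt=10.87,
        peaks=[(197.1646, 70.0), (174.1600, 80.0), (148.1095, 50.0), (220.1689, 20.0)],
    )
    anns = annotate_feature(f)
    assert anns[0].params == SeriesParams("A", 5, 4)
    assert anns[0].name == "crambescin A 434 homologue (m = 5, n = 4)"
    # the classical A2 434 assignment shares the formula but loses on fragments
    a2 = next(a for a in anns if a.params == SeriesParams("A", 2, 7))
    assert a2.score < anns[0].score


def test_no_candidate_within_tolerance_yields_empty():
    assert annotate_feature(feat(600.0, 1)) == []


def test_undetermined_charge_yields_empty():
    assert annotate_feature(feat(225.1835, None)) == []


def test_fragment_tolerance_floor_below_mz_400():
    # printed 242.1484 vs theoretical 242.1500 is -6.6 ppm but 1.6 mDa
    assert fragment_matches(242.1484, 242.1500, 1)
    assert not fragment_matches(242.1400, 242.1500, 1)
    # above m/z 400 the 5 ppm rule is strict
    assert not fragment_matches(522.3766, 522.3797, 1)


class TestBCDiscrimination:
    B = SeriesParams("B", 5, 6)
    C = SeriesParams("C", 5, 6)

    def _spectrum(self, peaks):
        mzs, ints = zip(*peaks)
        return Ms2Spectrum(241.1961, 11.5, np.array(mzs), np.array(ints), precursor_z=2)

    def test_dominant_c_diagnostic_chooses_c(self):
        spec = self._spectrum(
            [(148.6021, 100.0), (174.1600, 60.0), (198.1965, 10.0), (284.1957, 8.0)]
        )
        choice, ratio, ev = discriminate_B_vs_C(spec, self.B, self.C)
        assert choice == "C" and ratio > 0.5

    def test_dominant_rda_pair_chooses_b(self):
        spec = self._spectrum(
            [(198.1965, 100.0), (284.1957, 70.0), (156.1749, 40.0), (111.0443, 30.0)]
        )
        choice, ratio, ev = discriminate_B_vs_C(spec, self.B, self.C)
        assert choice == "B" and ratio < 0.5

    def test_neither_diagnostic_is_undetermined(self):
        spec = self._spectrum([(400.0, 10.0)])
        choice, ratio, ev = discriminate_B_vs_C(spec, self.B, self.C)
        assert choice is None and ratio is None

    def test_feature_level_annotation_picks_c1_480(self):
        f = feat(
            241.1961,
            2,
            rt=11.24,
            peaks=[(174.1600, 70.0), (148.6021, 100.0)],
        )
        top = annotate_feature(f)[0]
        assert top.name == "crambescin C1 480"

    def test_feature_level_annotation_picks_b1_480(self):
        f = feat(
            241.1961,
            2,
            rt=11.68,
            peaks=[(156.1749, 40.0), (111.0443, 30.0), (174.1600, 60.0), (284.1957, 70.0), (198.1965, 90.0)],
        )
        top = annotate_feature(f)[0]
        assert top.name == "crambescin B1 480"

    def test_isobars_never_silently_merged(self):
        f = feat(241.1961, 2, peaks=[(500.0, 5.0)])
        top = annotate_feature(f)[0]
        assert ("B1 480" in top.name and "C1 480" in top.name) or "bc_undetermined" in top.flags


def test_crambescidin_with_markers():
    f = feat(
        273.2094,
        3,
        rt=11.84,
        peaks=[(264.1707, 80.0), (246.1587, 60.0), (139.0751, 30.0), (70.0657, 90.0)],
    )
    ann = annotate_crambescidin(f)
    assert ann.name == "crambescidin 816"
    assert not ann.formula_only
    assert len(ann.matched) >= 2


def test_crambescidin_without_markers_falls_back_to_formula():
    f = feat(273.2094, 3, peaks=[(500.0, 10.0)])
    ann = annotate_crambescidin(f)
    assert ann.formula_only
    assert ann.name == "guanidine-related compound (C45H80N6O7)"


def test_guanidine_related_small_ion():
    f = feat(282.1806, 1, rt=8.16)
    ann = annotate_crambescidin(f)
    assert ann.name == "guanidine-related compound (C14H23N3O3)"
    assert ann.formula_only


class TestIsomerLabelling:
    def _a3(self, rt, fid):
        f = feat(263.1990, 2, rt=rt, fid=fid,
                 peaks=[(142.1334, 30.0), (384.2649, 40.0), (160.1440, 60.0), (242.1875, 50.0)])
        return annotate_feature(f)[0]

    def test_pair_labelled_cis_then_trans(self):
        early, late = self._a3(11.79, "F1"), self._a3(12.03, "F2")
        out = label_isomer_pairs([late, early])
        by_rt = sorted(out, key=lambda a: a.feature.rt)
        assert by_rt[0].name.endswith("(cis)") and "isomer_cis" in by_rt[0].flags
        assert by_rt[1].name.endswith("(trans)") and "isomer_trans" in by_rt[1].flags

    def test_single_feature_unlabelled(self):
        out = label_isomer_pairs([self._a3(11.79, "F1")])
        assert "(cis)" not in out[0].name and "(trans)" not in out[0].name

    def test_three_coformula_features_warn_and_stay_unlabelled(self):
        anns = [self._a3(rt, f"F{i}") for i, rt in enumerate((11.5, 11.8, 12.1))]
        with pytest.warns(UserWarning, match="co-formula"):
            out = label_isomer_pairs(anns)
        assert all("(cis)" not in a.name and "(trans)" not in a.name for a in out)


def test_report_row_for_compound_12():
    f = feat(
        225.1835,
        2,
        rt=11.16,
        peaks=[(204.1722, 80.0), (188.1756, 90.0), (155.1178, 40.0), (220.1689, 20.0)],
        fid="F0012",
    )
    report = build_report(annotate_feature(f)[:1])
    row = report.iloc[0]
    assert row["mw_exp"] == "448.3514"
    assert row["delta_ppm"] == "-0.45"
    assert row["identification"] == "crambescin A 448 homologue (m = 6, n = 4)"
    assert row["z"] == 2


def test_report_empty_is_header_only():
    report = build_report([])
    assert len(report) == 0
    assert list(report.columns)[:4] == ["index", "mz", "rt", "z"]


def test_report_is_deterministic():
    feats = [
        feat(225.1835, 2, rt=11.70, fid="F1",
             peaks=[(127.0863, 60.0), (204.1721, 80.0), (132.1130, 90.0)]),
        feat(273.2094, 3, rt=11.84, fid="F2",
             peaks=[(264.1707, 80.0), (246.1587, 60.0), (70.0657, 90.0)]),
    ]
    t1 = build_report(annotate_run(feats)).to_csv(sep="\t", index=False)
    t2 = build_report(annotate_run(feats)).to_csv(sep="\t", index=False)
    assert t1 == t2
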