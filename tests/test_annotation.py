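"""Isotope/adduct annotation, reference matching and main-peak selection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lcmspipe.annotation import (
    AnnotationParams,
    annotate_adducts,
    annotate_isotopes,
    main_peak,
    match_reference,
)
from lcmspipe.constants import ISOTOPE_SPACING, PROTON_MASS, SODIUM_CATION_MASS
from lcmspipe.io import AdductRule, ReferenceEntry
from lcmspipe.model import (
    Annotation,
    AnnotationKind,
    Feature,
    FeatureSet,
    IonMode,
)

from conftest import make_feature

M_H = AdductRule("M+H", PROTON_MASS, 1, 1)
M_NA = AdductRule("M+Na", SODIUM_CATION_MASS, 1, 1)
M_MINUS_H = AdductRule("M-H", -PROTON_MASS, -1, 1)
RULES = [M_H, M_NA, M_MINUS_H]

GLUCOSE = 180.06339


def coeluting_set(mz_ratio_pairs, rt=120.0):
    feats = []
    base = make_feature(0, 100.0, rt)
    for i, (mz, ratio) in enumerate(mz_ratio_pairs):
        feats.append(Feature(id=i, mz=mz, times=base.times,
                             intensities=ratio * base.intensities, rt=rt,
                             ion_mode=IonMode.POSITIVE))
    return FeatureSet(id=0, features=tuple(feats), rt=rt)


class TestAnnotateIsotopes:
    def test_singly_charged_m1(self):
        fs = coeluting_set([(181.07066, 1.0), (181.07066 + ISOTOPE_SPACING, 0.3)])
        out = annotate_isotopes(fs)
        iso = out.features[1].annotations[0]
        assert iso.kind is AnnotationKind.ISOTOPE
        assert iso.label == "M+1"
        assert iso.partner_id == 0
        assert iso.score == pytest.approx(1.0)
        assert out.features[0].annotations == ()

    def test_doubly_charged_spacing(self):
        fs = coeluting_set([(300.0, 1.0), (300.0 + ISOTOPE_SPACING / 2, 0.4)])
        out = annotate_isotopes(fs)
        assert out.features[1].annotations[0].label == "M+1"

    def test_ratio_gate_blocks_wrong_order(self):
        fs = coeluting_set([(181.07066, 1.0), (181.07066 + ISOTOPE_SPACING, 5.0)])
        out = annotate_isotopes(fs)
        assert out.features[1].annotations == ()

    def test_chain_anchors_to_monoisotopic(self):
        fs = coeluting_set([
            (181.07066, 1.0),
            (181.07066 + ISOTOPE_SPACING, 0.3),
            (181.07066 + 2 * ISOTOPE_SPACING, 0.05),
        ])
        out = annotate_isotopes(fs)
        assert [a.label for f in out.features[1:] for a in f.annotations] == \
            ["M+1", "M+2"]
        assert all(a.partner_id == 0 for f in out.features[1:]
                   for a in f.annotations)


class TestAnnotateAdducts:
    def test_proton_sodium_pair_yields_consensus_mass(self):
        mh = M_H.mz_for_neutral(GLUCOSE)
        mna = M_NA.mz_for_neutral(GLUCOSE)
        assert mh == pytest.approx(181.07066, abs=2e-5)
        assert mna == pytest.approx(203.05261, abs=2e-5)
        fs = coeluting_set([(mh, 1.0), (mna, 0.4)])
        out = annotate_adducts(fs, RULES, IonMode.POSITIVE)
        labels = {f.id: [a.label for a in f.annotations] for f in out.features}
        assert labels == {0: ["M+H"], 1: ["M+Na"]}
        assert abs(out.neutral_mass - GLUCOSE) / GLUCOSE * 1e6 <= 5.0

    def test_single_feature_gets_nothing(self):
        fs = coeluting_set([(181.07066, 1.0)])
        out = annotate_adducts(fs, RULES, IonMode.POSITIVE)
        assert out.features[0].annotations == ()
        assert out.neutral_mass is None

    def test_disagreeing_masses_not_annotated(self):
        mh = M_H.mz_for_neutral(GLUCOSE)
        mna = M_NA.mz_for_neutral(GLUCOSE * (1 + 300e-6))  # 300 ppm off
        fs = coeluting_set([(mh, 1.0), (mna, 0.4)])
        out = annotate_adducts(fs, RULES, IonMode.POSITIVE,
                               AnnotationParams(tol_ppm=10.0))
        assert all(f.annotations == () for f in out.features)

    def test_no_applicable_rule_warns_and_passes_through(self, caplog):
        fs = coeluting_set([(181.07066, 1.0)])
        with caplog.at_level("WARNING"):
            out = annotate_adducts(fs, [M_MINUS_H], IonMode.POSITIVE)
        assert out is fs

    def test_annotation_preserves_feature_order_and_count(self):
        mh = M_H.mz_for_neutral(GLUCOSE)
        mna = M_NA.mz_for_neutral(GLUCOSE)
        fs = coeluting_set([(mh, 1.0), (mna, 0.4), (555.0, 0.2)])
        out = annotate_adducts(fs, RULES, IonMode.POSITIVE)
        assert [f.id for f in out.features] == [f.id for f in fs.features]
        assert [f.mz for f in out.features] == [f.mz for f in fs.features]


class TestNeutralMassRoundTrip:
    @given(
        mass=st.floats(min_value=50.0, max_value=2000.0),
        rule=st.sampled_from([
            M_H, M_NA, M_MINUS_H,
            AdductRule("M+2H", 2 * PROTON_MASS, 2, 1),
            AdductRule("2M+H", PROTON_MASS, 1, 2),
            AdductRule("M-H2O+H", PROTON_MASS - 18.010565, 1, 1),
        ]),
    )
    def test_mz_neutral_inversion(self, mass, rule):
        assert rule.neutral_for_mz(rule.mz_for_neutral(mass)) == pytest.approx(
            mass, rel=1e-9)


class TestMatchReference:
    @pytest.fixture
    def glucose_set(self):
        return coeluting_set([(M_H.mz_for_neutral(GLUCOSE), 1.0)], rt=124.0)

    def test_match_via_proton_adduct(self, glucose_set):
        lib = [ReferenceEntry("glucose", GLUCOSE, expected_rt=124.0,
                              ion_modes=frozenset({IonMode.POSITIVE}))]
        matches = match_reference([glucose_set], lib, RULES, IonMode.POSITIVE)
        assert len(matches) == 1
        m = matches[0]
        assert m.entry.name == "glucose"
        assert m.rule.name == "M+H"
        assert m.mz_error_ppm <= 1e-6
        member = m.feature_set.features[0]
        assert any(a.kind is AnnotationKind.IDENTITY and a.label == "glucose"
                   for a in member.annotations)

    def test_rt_gate_blocks_match(self, glucose_set):
        lib = [ReferenceEntry("glucose", GLUCOSE, expected_rt=124.0 + 30.0)]
        assert match_reference([glucose_set], lib, RULES, IonMode.POSITIVE,
                               rt_tol=10.0) == []

    def test_missing_expected_rt_matches_on_mass(self, glucose_set):
        lib = [ReferenceEntry("glucose", GLUCOSE, expected_rt=None)]
        matches = match_reference([glucose_set], lib, RULES, IonMode.POSITIVE)
        assert len(matches) == 1
        assert matches[0].rt_error_s is None

    def test_empty_input(self):
        lib = [ReferenceEntry("x", 100.0)]
        assert match_reference([], lib, RULES, IonMode.POSITIVE) == []


class TestMainPeak:
    def test_annotated_proton_adduct_wins(self):
        fs = coeluting_set([(203.05261, 1.0), (181.07066, 0.6)])
        annotated = annotate_adducts(fs, RULES, IonMode.POSITIVE)
        assert main_peak(annotated, IonMode.POSITIVE).mz == pytest.approx(181.07066)

    def test_intensity_argmax_without_annotations(self):
        fs = coeluting_set([(150.0, 0.5), (250.0, 1.0)])
        assert main_peak(fs, IonMode.POSITIVE).mz == 250.0

    def test_tie_breaks_to_lower_mz(self):
        fs = coeluting_set([(150.0, 1.0), (250.0, 1.0)])
        assert main_peak(fs, IonMode.POSITIVE).mz == 150.0

    def test_isotopes_not_eligible(self):
        fs = coeluting_set([(181.07066, 0.4),
                            (181.07066 + ISOTOPE_SPACING, 0.39)])
        out = annotate_isotopes(fs)
        assert main_peak(out, IonMode.POSITIVE).mz == pytest.approx(181.07066)
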