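"""Key-identifier evaluation: windows, scopes and the special rules."""

import datetime

import pytest

from claimstroke.identifiers import (
    FLAG_NAMES,
    IdentifierVector,
    evaluate_anticoagulants,
    evaluate_code_window,
    evaluate_image_followup,
    evaluate_new_antithrombotics,
    evaluate_transfer_to_rehab,
    extract_identifier_vector,
)
from claimstroke.model import CodeKind, Department, Setting

from conftest import make_episode, make_line


class TestCodeWindow:
    def test_ct_code_inside_window(self, catalog):
        ep = make_episode([make_line("HA471", off=-3)])
        assert evaluate_code_window(ep, catalog.identifiers["brain_ct"])

    def test_empty_episode_is_false(self, catalog):
        ep = make_episode([])
        assert not evaluate_code_window(ep, catalog.identifiers["brain_ct"])

    @pytest.mark.parametrize("off, expected", [(0, True), (30, True), (31, False), (-1, False)])
    def test_holter_window_boundaries(self, catalog, off, expected):
        ep = make_episode([make_line("E6545", off=off)])
        assert evaluate_code_window(ep, catalog.identifiers["holter"]) is expected

    def test_in_hospital_only_scope_excludes_outpatient(self, catalog):
        ep = make_episode([make_line("E6545", off=5, setting=Setting.OUTPATIENT)])
        assert not evaluate_code_window(ep, catalog.identifiers["holter"])

    def test_special_logic_identifier_rejected(self, catalog):
        with pytest.raises(ValueError, match="special logic"):
            evaluate_code_window(make_episode([]), catalog.identifiers["image_fu"])


class TestImageFollowup:
    def test_ct_then_mri_counts_two_events(self, catalog):
        ep = make_episode([make_line("HA451", off=-1), make_line("HE101", off=3)])
        assert evaluate_image_followup(ep, catalog)

    def test_single_event_is_false(self, catalog):
        ep = make_episode([make_line("HE101", off=0)])
        assert not evaluate_image_followup(ep, catalog)

    def test_same_code_on_two_dates_counts(self, catalog):
        # events are distinct (code, service date) pairs
        ep = make_episode([make_line("HA451", off=0), make_line("HA451", off=2)])
        assert evaluate_image_followup(ep, catalog)

    def test_same_code_same_date_is_one_event(self, catalog):
        ep = make_episode([make_line("HA451", off=0), make_line("HA451", off=0)])
        assert not evaluate_image_followup(ep, catalog)

    def test_event_outside_seven_day_window_ignored(self, catalog):
        ep = make_episode([make_line("HA451", off=0), make_line("HE101", off=8)])
        assert not evaluate_image_followup(ep, catalog)


ASPIRIN = "110701ATB"
CLOPIDOGREL = "136901ATB"
WARFARIN = "249103ATB"
RIVAROXABAN = "511401ATB"
HEPARIN = "168601BIJ"


def _drug(code, off, **kw):
    return make_line(code, off=off, kind=CodeKind.DRUG, **kw)


class TestNewAntithrombotics:
    def test_first_ever_use(self, catalog):
        ep = make_episode([_drug(ASPIRIN, 1)])
        assert evaluate_new_antithrombotics(ep, 3, catalog=catalog)

    def test_unchanged_regimen_is_false(self, catalog):
        ep = make_episode([_drug(ASPIRIN, -90, setting=Setting.OUTPATIENT), _drug(ASPIRIN, 1)])
        assert not evaluate_new_antithrombotics(ep, 3, catalog=catalog)

    def test_added_ingredient(self, catalog):
        ep = make_episode(
            [
                _drug(ASPIRIN, -90, setting=Setting.OUTPATIENT),
                _drug(ASPIRIN, 1),
                _drug(CLOPIDOGREL, 2),
            ]
        )
        assert evaluate_new_antithrombotics(ep, 3, catalog=catalog)

    def test_switched_composition(self, catalog):
        ep = make_episode([_drug(WARFARIN, -90, setting=Setting.OUTPATIENT), _drug(RIVAROXABAN, 1)])
        assert evaluate_new_antithrombotics(ep, 3, catalog=catalog)

    def test_pure_discontinuation_is_false(self, catalog):
        ep = make_episode([_drug(ASPIRIN, -90, setting=Setting.OUTPATIENT)])
        assert not evaluate_new_antithrombotics(ep, 3, catalog=catalog)

    def test_exposure_older_than_180_days_does_not_mask(self, catalog):
        ep = make_episode([_drug(ASPIRIN, -200, setting=Setting.OUTPATIENT), _drug(ASPIRIN, 1)])
        assert evaluate_new_antithrombotics(ep, 3, catalog=catalog)

    @pytest.mark.parametrize("off, expected", [(3, True), (4, False)])
    def test_three_day_window_boundary(self, catalog, off, expected):
        ep = make_episode([_drug(ASPIRIN, off)])
        assert evaluate_new_antithrombotics(ep, 3, catalog=catalog) is expected

    def test_90d_counts_nr_ns_outpatient_only(self, catalog):
        dept_filter = catalog.identifiers["new_antithrombotics_90d_nrns_opd"].department_filter
        neuro = make_episode(
            [_drug(ASPIRIN, 45, setting=Setting.OUTPATIENT, department=Department.NEUROLOGY)]
        )
        other = make_episode(
            [_drug(ASPIRIN, 45, setting=Setting.OUTPATIENT, department=Department.OTHER)]
        )
        assert evaluate_new_antithrombotics(neuro, 90, dept_filter, catalog)
        assert not evaluate_new_antithrombotics(other, 90, dept_filter, catalog)

    def test_90d_in_hospital_lines_count_regardless_of_department(self, catalog):
        dept_filter = catalog.identifiers["new_antithrombotics_90d_nrns_opd"].department_filter
        ep = make_episode([_drug(ASPIRIN, 45, department=Department.OTHER)])
        assert evaluate_new_antithrombotics(ep, 90, dept_filter, catalog)

    def test_monotone_3d_implies_7d(self, catalog):
        ep = make_episode([_drug(CLOPIDOGREL, 2)])
        assert evaluate_new_antithrombotics(ep, 3, catalog=catalog)
        assert evaluate_new_antithrombotics(ep, 7, catalog=catalog)


class TestAnticoagulants:
    def test_heparin_at_day_zero(self, catalog):
        assert evaluate_anticoagulants(make_episode([_drug(HEPARIN, 0)]), catalog)

    def test_presence_not_novelty(self, catalog):
        # same anticoagulant in the lookback: still true (unlike new-user rule)
        ep = make_episode([_drug(HEPARIN, -60, setting=Setting.OUTPATIENT), _drug(HEPARIN, 2)])
        assert evaluate_anticoagulants(ep, catalog)
        assert not evaluate_new_antithrombotics(ep, 7, catalog=catalog)

    def test_antiplatelet_only_is_false(self, catalog):
        assert not evaluate_anticoagulants(make_episode([_drug(ASPIRIN, 1)]), catalog)

    @pytest.mark.parametrize("off, expected", [(7, True), (8, False)])
    def test_window_boundary(self, catalog, off, expected):
        ep = make_episode([_drug(WARFARIN, off)])
        assert evaluate_anticoagulants(ep, catalog) is expected


class TestTransferToRehab:
    def test_neurology_plus_rehabilitation(self):
        ep = make_episode(
            [
                make_line("ZZ01", off=1, department=Department.NEUROLOGY),
                make_line("ZZ02", off=12, department=Department.REHABILITATION),
            ]
        )
        assert evaluate_transfer_to_rehab(ep)

    def test_neurology_only_is_false(self):
        ep = make_episode([make_line("ZZ01", off=1, department=Department.NEUROLOGY)])
        assert not evaluate_transfer_to_rehab(ep)

    def test_rehabilitation_outside_window_is_false(self):
        ep = make_episode(
            [
                make_line("ZZ01", off=1, department=Department.NEUROLOGY),
                make_line("ZZ02", off=31, department=Department.REHABILITATION),
            ]
        )
        assert not evaluate_transfer_to_rehab(ep)

    def test_outpatient_lines_do_not_count(self):
        ep = make_episode(
            [
                make_line("ZZ01", off=1, department=Department.NEUROLOGY),
                make_line(
                    "ZZ02",
                    off=5,
                    department=Department.REHABILITATION,
                    setting=Setting.OUTPATIENT,
                ),
            ]
        )
        assert not evaluate_transfer_to_rehab(ep)


class TestExtractVector:
    def test_empty_episode_all_false(self, catalog):
        vec = extract_identifier_vector(make_episode([]), catalog)
        assert vec == IdentifierVector()

    def test_single_cta_line_sets_ct_and_cta_only(self, catalog):
        vec = extract_identifier_vector(make_episode([make_line("HA471", off=0)]), catalog)
        assert vec.brain_ct and vec.cta
        assert not vec.image_fu
        others = {k: v for k, v in vec.as_dict().items() if k not in ("brain_ct", "cta")}
        assert not any(others.values())

    def test_subset_implication_cta_implies_ct(self, catalog):
        # over assorted single-imaging-line episodes, cta=true forces ct=true
        for code in sorted(catalog.code_set("image_fu").codes):
            vec = extract_identifier_vector(make_episode([make_line(code, off=0)]), catalog)
            assert not vec.cta or vec.brain_ct

    def test_vector_has_exactly_17_flags(self):
        assert len(FLAG_NAMES) == 17
        assert len(IdentifierVector().as_dict()) == 17


def test_extraction_invariant_to_line_order(catalog):
    lines = [
        make_line("HA471", off=0),
        make_line("HE101", off=1),
        _drug(CLOPIDOGREL, 2),
        _drug(HEPARIN, 3),
        make_line("E6545", off=10),
        make_line("ZZ99", off=20, department=Department.NEUROLOGY),
        make_line("ZZ98", off=21, department=Department.REHABILITATION),
    ]
    expected = extract_identifier_vector(make_episode(lines), catalog)
    assert extract_identifier_vector(make_episode(lines[::-1]), catalog) == expected
    assert expected.image_fu and expected.transfer_to_rehab
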