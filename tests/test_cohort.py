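import random

import pandas as pd
import pytest

from conftest import make_patient
from irskit.cohort import (
    CHEMO,
    COMBO,
    DAYS_PER_MONTH,
    MONO,
    MONOTHERAPY_SPEC,
    OTHER,
    RACE_SPEC,
    CohortSpec,
    TherapyLine,
    assign_tumor_type_covariate,
    classify_therapy_line,
    derive_os,
    derive_rwpfs,
    group_race,
    load_patients,
    select_cohort,
)


class TestClassifyTherapyLine:
    @pytest.mark.parametrize(
        "agents, expected_class, pembro",
        [
            ({"pembrolizumab"}, MONO, True),
            ({"nivolumab"}, MONO, False),
            ({"carboplatin", "pemetrexed", "pembrolizumab"}, COMBO, True),
            ({"carboplatin", "bevacizumab"}, CHEMO, False),
            ({"carboplatin", "pemetrexed"}, CHEMO, False),
            ({"ipilimumab", "nivolumab"}, OTHER, False),
            ({"mystery-agent"}, OTHER, False),
            ({"pembrolizumab", "mystery-agent"}, OTHER, True),
        ],
    )
    def test_mapping(self, agents, expected_class, pembro):
        assert classify_therapy_line(agents) == (expected_class, pembro)

    def test_empty_agents_rejected(self):
        with pytest.raises(ValueError):
            classify_therapy_line(set())


class TestEndpointDerivation:
    def test_event_at_next_line_start(self):
        p = make_patient(
            lines=[(0, None, frozenset({"pembrolizumab"})),
                   (120, None, frozenset({"docetaxel"}))],
            death_day=300, last_followup_day=400,
        )
        rec = derive_rwpfs(p, p.lines[0])
        assert rec.event and rec.duration_months == pytest.approx(120 / DAYS_PER_MONTH)
        assert rec.duration_months == pytest.approx(3.9425, abs=1e-3)

    def test_censored_at_last_followup(self):
        p = make_patient(lines=[(0, None, frozenset({"pembrolizumab"}))],
                         last_followup_day=400)
        rec = derive_rwpfs(p, p.lines[0])
        assert not rec.event
        assert rec.duration_months == pytest.approx(400 / DAYS_PER_MONTH)

    def test_death_is_progression_event(self):
        p = make_patient(lines=[(0, None, frozenset({"pembrolizumab"}))],
                         death_day=250, last_followup_day=250)
        rec = derive_rwpfs(p, p.lines[0])
        assert rec.event and rec.duration_months == pytest.approx(250 / DAYS_PER_MONTH)

    def test_os_event_and_censoring(self):
        p = make_patient(lines=[(0, None, frozenset({"pembrolizumab"}))],
                         death_day=300, last_followup_day=300)
        assert derive_os(p, p.lines[0]).duration_months == pytest.approx(
            300 / DAYS_PER_MONTH
        )
        q = make_patient(lines=[(0, None, frozenset({"pembrolizumab"}))],
                         last_followup_day=400)
        rec = derive_os(q, q.lines[0])
        assert not rec.event and rec.duration_months == pytest.approx(
            400 / DAYS_PER_MONTH
        )

    def test_rwpfs_never_exceeds_os(self):
        for death, fu, nxt in [(300, 300, 120), (None, 400, 50), (250, 250, None)]:
            lines = [(0, None, frozenset({"pembrolizumab"}))]
            if nxt is not None:
                lines.append((nxt, None, frozenset({"docetaxel"})))
            p = make_patient(lines=lines, death_day=death, last_followup_day=fu)
            assert (
                derive_rwpfs(p, p.lines[0]).duration_months
                <= derive_os(p, p.lines[0]).duration_months
            )

    def test_same_day_event_gets_half_day_floor(self):
        # death on the line's start day: zero-length interval floored at 0.5d
        p = make_patient(
            lines=[(10, None, frozenset({"pembrolizumab"}))],
            death_day=10, last_followup_day=10,
        )
        rec = derive_rwpfs(p, p.lines[0])
        assert rec.event
        assert rec.duration_months == pytest.approx(0.5 / DAYS_PER_MONTH)

    def test_foreign_line_rejected(self):
        p = make_patient(lines=[(0, None, frozenset({"pembrolizumab"}))])
        stray = TherapyLine("someone-else", 1, 0, None, frozenset({"pembrolizumab"}))
        with pytest.raises(ValueError):
            derive_rwpfs(p, stray)


def _eligibility_fixture():
    """Hand-enumerable fixture: patients with one disqualifying feature each."""
    mono = frozenset({"pembrolizumab"})
    chemo = frozenset({"carboplatin"})
    ctla4 = frozenset({"ipilimumab"})
    pts = [
        make_patient("OK1", [(30, None, mono)]),
        make_patient("OK2", [(30, 120, chemo), (120, None, mono)]),
        make_patient("NO-MOLECULAR", [(30, None, mono)], covariates=False),
        make_patient("LATE-SPECIMEN", [(30, None, mono)], collection_day=60),
        make_patient("PRIOR-IO", [(30, 120, ctla4), (120, None, mono)]),
        make_patient("WRONG-CLASS", [(30, None, chemo)]),
        make_patient("MSI-H", [(30, None, mono)], msi_high=True),
        make_patient("DISCOVERY", [(30, None, mono)], in_discovery=True),
        make_patient("PRIOR-VAL", [(30, None, mono)], in_prior_validation=True),
    ]
    return pts


class TestSelectCohort:
    def test_membership_matches_hand_enumeration(self):
        cohort = select_cohort(_eligibility_fixture(), MONOTHERAPY_SPEC)
        # MSI-H is NOT excluded from the monotherapy cohort
        assert set(cohort.table["patient_id"]) == {"OK1", "OK2", "MSI-H"}
        audit = cohort.audit
        assert audit["molecular_data"] == 1
        assert audit["specimen_before_start"] == 1
        assert audit["no_prior_io"] == 1
        assert audit["discovery_excluded"] == 1
        assert audit["prior_validation_excluded"] == 1

    def test_race_spec_excludes_msi_high_keeps_prior_validation(self):
        cohort = select_cohort(_eligibility_fixture(), RACE_SPEC)
        assert set(cohort.table["patient_id"]) == {"OK1", "OK2", "PRIOR-VAL"}

    def test_audit_counts_sum_to_exclusions(self):
        cohort = select_cohort(_eligibility_fixture(), MONOTHERAPY_SPEC)
        n_candidate_lines = sum(len(p.lines) for p in _eligibility_fixture())
        excluded = sum(v for k, v in cohort.audit.items() if k != "selected")
        assert cohort.audit["selected"] + excluded == n_candidate_lines

    def test_order_independent(self):
        pts = _eligibility_fixture()
        a = select_cohort(pts, MONOTHERAPY_SPEC).table
        shuffled = pts[:]
        random.Random(4).shuffle(shuffled)
        b = select_cohort(shuffled, MONOTHERAPY_SPEC).table
        pd.testing.assert_frame_equal(a, b)

    def test_empty_result_allowed(self):
        spec = CohortSpec(name="none", tumor_whitelist=("PANCREAS",))
        cohort = select_cohort(_eligibility_fixture(), spec)
        assert cohort.table.empty and cohort.audit["selected"] == 0

    def test_one_line_per_patient(self):
        mono = frozenset({"pembrolizumab"})
        # two eligible mono lines; only the earliest is taken
        p = make_patient("P2", [(30, 90, mono), (200, None, mono)])
        spec = CohortSpec(name="mono", require_no_prior_io=False)
        table = select_cohort([p], spec).table
        assert list(table["start_day"]) == [30]


class TestTumorTypeRecode:
    def test_strict_threshold(self):
        s = pd.Series(["A"] * 20 + ["B"] * 16 + ["C"] * 15 + ["D"] * 2)
        recoded, ref = assign_tumor_type_covariate(s)
        assert set(recoded.unique()) == {"A", "B", "other"}
        assert ref == "A"

    def test_exactly_sixteen_kept(self):
        recoded, ref = assign_tumor_type_covariate(pd.Series(["A"] * 16))
        assert set(recoded.unique()) == {"A"} and ref == "A"

    def test_single_rare_type_pools(self):
        recoded, ref = assign_tumor_type_covariate(pd.Series(["A"] * 3))
        assert set(recoded.unique()) == {"other"} and ref == "other"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assign_tumor_type_covariate(pd.Series([], dtype=object))


class TestRaceGrouping:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            ("White or Caucasian", "European"),
            ("Black or African American", "non-European"),
            ("Asian", "non-European"),
            ("Other", "non-European"),
            ("American Indian or Alaskan Native", "non-European"),
            ("Native Hawaiian or Other Pacific Islander", "non-European"),
            ("", "unknown"),
            (None, "unknown"),
            ("declined", "unknown"),
        ],
    )
    def test_mapping(self, raw, expected):
        assert group_race(raw) == expected


class TestLoadPatients:
    def test_flat_file_roundtrip(self, tmp_path):
        (tmp_path / "patients.csv").write_text(
            "patient_id,age,sex,tumor_type,race,collection_day,death_day,"
            "last_followup_day,msi_high,mtc,panel_mb,in_discovery,in_prior_validation\n"
            "P1,64,F,NSCLC,White or Caucasian,5,300,300,False,0.6,1.2,False,False\n"
            "P2,70,M,EGC,Asian,5,,400,False,0.5,1.2,False,False\n"
        )
        (tmp_path / "lines.csv").write_text(
            "patient_id,line_number,start_day,stop_day,agents\n"
            "P1,1,30,100,carboplatin;pemetrexed\n"
            "P1,2,100,,pembrolizumab\n"
            "P2,1,30,,nivolumab\n"
        )
        (tmp_path / "covariates.tsv").write_text(
            "sample_id\ttmb\tpd1\tpdl1\ttop2a\tadam12\n"
            "P1\t12.0\t4.0\t4.0\t4.0\t4.0\n"
            "P2\t1.0\t0.0\t0.0\t0.0\t0.0\n"
        )
        pats = load_patients(
            tmp_path / "patients.csv", tmp_path / "lines.csv",
            tmp_path / "covariates.tsv",
        )
        assert len(pats) == 2
        p1 = next(p for p in pats if p.patient_id == "P1")
        assert p1.lines[0].therapy_class == CHEMO
        assert p1.lines[1].therapy_class == MONO
        assert p1.irs.group2 == "H"  # TMB 12 dominates the score
        assert p1.death_day == 300
        p2 = next(p for p in pats if p.patient_id == "P2")
        assert p2.death_day is None and p2.irs.group2 == "L"
        cohort = select_cohort(pats, MONOTHERAPY_SPEC)
        assert set(cohort.table["patient_id"]) == {"P1", "P2"}
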