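"""Repeat-group classification, POF definition, censoring rules, summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fxpoi.cohort import (
    CessationCause,
    Participant,
    RecordRejected,
    RepeatGroup,
    build_survival_records,
    classify_repeat_group,
    is_pof,
    menopause_summary,
    to_survival_record,
)


def woman(
    id="w1",
    repeat=30,
    interview=50.0,
    menopause_age=None,
    cause=CessationCause.NONE,
    last_menses=None,
    **kw,
):
    return Participant(
        id=id,
        repeat_length=repeat,
        age_at_interview=interview,
        menopause_reported=cause == CessationCause.NATURAL_MENOPAUSE,
        age_at_menopause=menopause_age,
        cessation_cause=cause,
        age_at_last_menses=last_menses,
        bmi=kw.pop("bmi", 25.0),
        **kw,
    )


class TestClassification:
    @pytest.mark.parametrize(
        "repeat,expected",
        [
            (30, RepeatGroup.NORMAL),
            (54, RepeatGroup.NORMAL),
            (55, RepeatGroup.LOW_PM),
            (79, RepeatGroup.LOW_PM),
            (80, RepeatGroup.MID_PM),
            (91, RepeatGroup.MID_PM),  # observed mid-PM sample repeat length
            (100, RepeatGroup.MID_PM),  # overlap boundary goes to mid
            (101, RepeatGroup.HIGH_PM),
            (200, RepeatGroup.HIGH_PM),
        ],
    )
    def test_group_assignment(self, repeat, expected):
        assert classify_repeat_group(repeat) == expected

    def test_partition_is_total_and_exclusive(self):
        """Every repeat count in [1, 200] belongs to exactly one group and
        the group ranges tile the interval."""
        seen = {g: 0 for g in RepeatGroup}
        for n in range(1, 201):
            seen[classify_repeat_group(n)] += 1
        assert sum(seen.values()) == 200
        assert seen == {
            RepeatGroup.NORMAL: 54,
            RepeatGroup.LOW_PM: 25,
            RepeatGroup.MID_PM: 21,
            RepeatGroup.HIGH_PM: 100,
        }

    def test_configurable_mid_high_boundary(self):
        assert classify_repeat_group(100, mid_high_boundary=99) == RepeatGroup.HIGH_PM

    @pytest.mark.parametrize("bad", [0, -5, 201, 500])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            classify_repeat_group(bad)

    @given(st.integers(min_value=1, max_value=200))
    def test_bounds_match_assignment(self, n):
        g = classify_repeat_group(n)
        lo, hi = g.bounds
        assert lo <= n <= hi


class TestPof:
    @pytest.mark.parametrize(
        "age,expected", [(21.0, True), (39.9, True), (40.0, False), (49.0, False)]
    )
    def test_threshold_is_strict(self, age, expected):
        p = woman(menopause_age=age, cause=CessationCause.NATURAL_MENOPAUSE)
        assert is_pof(p) is expected

    def test_undefined_without_menopause(self):
        with pytest.raises(ValueError):
            is_pof(woman())


class TestCensoring:
    def test_natural_menopause_is_an_event(self):
        rec = to_survival_record(
            woman(menopause_age=49.0, cause=CessationCause.NATURAL_MENOPAUSE)
        )
        assert (rec.time, rec.event) == (49.0, True)

    def test_no_cessation_censors_at_interview(self):
        rec = to_survival_record(woman(interview=43.0))
        assert (rec.time, rec.event) == (43.0, False)

    def test_hysterectomy_censors_at_last_menses(self):
        rec = to_survival_record(
            woman(interview=50.0, cause=CessationCause.HYSTERECTOMY, last_menses=38.0)
        )
        assert (rec.time, rec.event) == (38.0, False)

    def test_time_never_exceeds_interview_age(self):
        for p in [
            woman(menopause_age=44.0, interview=44.0, cause=CessationCause.NATURAL_MENOPAUSE),
            woman(interview=61.0),
            woman(cause=CessationCause.OTHER_MEDICAL, last_menses=30.0, interview=55.0),
        ]:
            rec = to_survival_record(p)
            assert rec.time <= p.age_at_interview
            assert rec.event == (p.cessation_cause == CessationCause.NATURAL_MENOPAUSE)

    def test_missing_branch_age_rejected(self):
        with pytest.raises(RecordRejected):
            to_survival_record(woman(cause=CessationCause.HYSTERECTOMY))

    def test_missing_bmi_dropped_with_logging(self, caplog):
        cohort = [woman(id="a", bmi=None), woman(id="b")]
        recs = build_survival_records(cohort)
        assert [r.id for r in recs] == ["b"]
        assert "missing BMI" in caplog.text

    def test_race_indicator_against_reference(self):
        rec = to_survival_record(woman(race_ethnicity="Other"))
        assert rec.covariates["race_nonwhite"] == 1.0
        rec = to_survival_record(woman(race_ethnicity="White"))
        assert rec.covariates["race_nonwhite"] == 0.0


class TestParticipantInvariants:
    def test_menopause_after_interview_rejected(self):
        with pytest.raises(ValueError):
            woman(menopause_age=60.0, interview=50.0, cause=CessationCause.NATURAL_MENOPAUSE)

    def test_cause_must_match_reported_flag(self):
        with pytest.raises(ValueError):
            Participant(
                id="x",
                repeat_length=30,
                age_at_interview=50,
                menopause_reported=True,
                cessation_cause=CessationCause.NONE,
            )

    def test_bad_genotype_count_rejected(self):
        with pytest.raises(ValueError):
            woman(genotypes={"rs365132": 3})


class TestSummary:
    def test_group_mean_is_plain_average(self):
        cohort = [
            woman(id=f"w{i}", repeat=60, menopause_age=a, interview=60.0,
                  cause=CessationCause.NATURAL_MENOPAUSE)
            for i, a in enumerate([44.0, 46.0, 48.0])
        ]
        tab = menopause_summary(cohort)
        assert tab.loc["LowPM", "mean_age_menopause"] == pytest.approx(46.0)
        assert tab.loc["LowPM", "n_menopause"] == 3

    def test_excluding_pof_raises_group_means(self):
        cohort = [
            woman(id="a", repeat=85, menopause_age=30.0, interview=50.0,
                  cause=CessationCause.NATURAL_MENOPAUSE),
            woman(id="b", repeat=85, menopause_age=46.0, interview=50.0,
                  cause=CessationCause.NATURAL_MENOPAUSE),
            woman(id="c", repeat=85, interview=40.0),
        ]
        incl = menopause_summary(cohort, exclude_pof=False)
        excl = menopause_summary(cohort, exclude_pof=True)
        assert (
            excl.loc["MidPM", "mean_age_menopause"]
            > incl.loc["MidPM", "mean_age_menopause"]
        )
        # counts reported on the full group either way
        assert excl.loc["MidPM", "n_total"] == 3
        assert excl.loc["MidPM", "n_pof"] == 1

    def test_empty_group_mean_is_absent_not_zero(self):
        tab = menopause_summary([woman()])
        assert np.isnan(tab.loc["MidPM", "mean_age_menopause"])
        assert tab.loc["MidPM", "n_total"] == 0

    def test_count_ordering_invariant(self):
        from fxpoi.simulate import CohortGeneratorConfig, generate_cohort

        cohort, _ = generate_cohort(CohortGeneratorConfig.full_study(n=400), seed=9)
        tab = menopause_summary(cohort)
        assert (tab["n_pof"] <= tab["n_menopause"]).all()
        assert (tab["n_menopause"] <= tab["n_total"]).all()

    def test_default_cohort_group_ordering(self):
        """Mid-PM carriers have the earliest mean menopause; noncarriers the
        latest — the signature non-linear repeat effect."""
        from fxpoi.simulate import CohortGeneratorConfig, generate_cohort

        cohort, _ = generate_cohort(CohortGeneratorConfig.full_study(), seed=1)
        m = menopause_summary(cohort)["mean_age_menopause"]
        assert m["MidPM"] == min(m)
        assert m["Normal"] == max(m)
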