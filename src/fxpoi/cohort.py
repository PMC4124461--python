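"""Participant data model, FMR1 repeat-group classification, and censoring rules.

The cohort is a set of women characterized by the CGG repeat length of their
largest FMR1 allele, their reproductive history (age at natural menopause,
or the age and cause of any other cessation of menses), and covariates used
in the downstream survival and burden analyses.

Repeat groups follow the standard premutation (PM) stratification:

=========  ==================
Normal     < 55 repeats
Low PM     55-79 repeats
Mid PM     80-100 repeats
High PM    101-200 repeats
=========  ==================

The printed mid/high ranges overlap at 100; 100 repeats is assigned to the
mid group (the mid range is "approximately 80-100"), and the boundary is
configurable via :func:`classify_repeat_group`.

Premature ovarian failure (POF) is cessation of menses strictly before age
40.  Censoring for the survival analysis: women who have not experienced
menopause are censored at age at interview; women whose menses stopped for
another reason (hysterectomy, other medical) are censored at age at last
menses.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CessationCause",
    "RepeatGroup",
    "Participant",
    "SurvivalRecord",
    "classify_repeat_group",
    "is_pof",
    "to_survival_record",
    "build_survival_records",
    "menopause_summary",
    "POF_AGE_THRESHOLD",
    "MAX_PM_REPEATS",
]

#: POF = cessation of menses strictly before this age (years).
POF_AGE_THRESHOLD = 40.0

#: Largest repeat length handled; above this the allele is a full mutation.
MAX_PM_REPEATS = 200


class CessationCause(str, enum.Enum):
    """Why menses stopped (or ``NONE`` if they have not)."""

    NATURAL_MENOPAUSE = "natural_menopause"
    HYSTERECTOMY = "hysterectomy"
    OTHER_MEDICAL = "other_medical"
    NONE = "none"


class RepeatGroup(str, enum.Enum):
    """FMR1 repeat-length stratum of the largest allele."""

    NORMAL = "Normal"
    LOW_PM = "LowPM"
    MID_PM = "MidPM"
    HIGH_PM = "HighPM"

    @property
    def bounds(self) -> tuple[int, int]:
        """Inclusive repeat-count range of this group (default boundaries)."""
        return _DEFAULT_BOUNDS[self]


_DEFAULT_BOUNDS: dict[RepeatGroup, tuple[int, int]] = {
    RepeatGroup.NORMAL: (1, 54),
    RepeatGroup.LOW_PM: (55, 79),
    RepeatGroup.MID_PM: (80, 100),
    RepeatGroup.HIGH_PM: (101, MAX_PM_REPEATS),
}

#: PM groups in display order (excludes noncarriers).
PM_GROUPS = (RepeatGroup.LOW_PM, RepeatGroup.MID_PM, RepeatGroup.HIGH_PM)


def classify_repeat_group(
    repeat_length: int, *, mid_high_boundary: int = 100
) -> RepeatGroup:
    """Assign a repeat length to its group.

    Parameters
    ----------
    repeat_length
        CGG repeat count of the largest FMR1 allele, ``1 <= n <= 200``.
    mid_high_boundary
        Largest repeat count still counted as mid-PM.  The published ranges
        overlap at 100; the default assigns 100 to the mid group.

    Raises
    ------
    ValueError
        If ``repeat_length`` is below 1 or above 200 (a full-mutation
        allele, outside the scope of the premutation analyses).
    """
    n = int(repeat_length)
    if n < 1:
        raise ValueError(f"repeat_length must be >= 1, got {repeat_length}")
    if n > MAX_PM_REPEATS:
        raise ValueError(
            f"repeat_length {repeat_length} exceeds {MAX_PM_REPEATS}: "
            "full-mutation allele, outside the premutation analyses"
        )
    if n < 55:
        return RepeatGroup.NORMAL
    if n < 80:
        return RepeatGroup.LOW_PM
    if n <= mid_high_boundary:
        return RepeatGroup.MID_PM
    return RepeatGroup.HIGH_PM


@dataclass
class Participant:
    """One woman's reproductive history, repeat length, covariates, genotypes.

    ``genotypes`` maps SNP rsid -> effect-allele count in {0, 1, 2}; a SNP
    absent from the map is an uncalled genotype.
    """

    id: str
    repeat_length: int
    age_at_interview: float
    menopause_reported: bool
    age_at_menopause: Optional[float] = None
    cessation_cause: CessationCause = CessationCause.NONE
    age_at_last_menses: Optional[float] = None
    ever_smoked: bool = False
    current_hormone_use: bool = False
    bmi: Optional[float] = None
    race_ethnicity: str = "White"
    genotypes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.repeat_length < 1:
            raise ValueError(f"{self.id}: repeat_length must be >= 1")
        if (
            self.age_at_menopause is not None
            and self.age_at_menopause > self.age_at_interview
        ):
            raise ValueError(
                f"{self.id}: age_at_menopause ({self.age_at_menopause}) "
                f"exceeds age_at_interview ({self.age_at_interview})"
            )
        if (
            self.age_at_last_menses is not None
            and self.age_at_last_menses > self.age_at_interview
        ):
            raise ValueError(
                f"{self.id}: age_at_last_menses exceeds age_at_interview"
            )
        # menopause_reported and natural-menopause cause must agree
        natural = self.cessation_cause == CessationCause.NATURAL_MENOPAUSE
        if natural != bool(self.menopause_reported):
            raise ValueError(
                f"{self.id}: cessation_cause={self.cessation_cause.value!r} "
                f"inconsistent with menopause_reported={self.menopause_reported}"
            )
        for rsid, count in self.genotypes.items():
            if count not in (0, 1, 2):
                raise ValueError(
                    f"{self.id}: genotype at {rsid} must be in {{0,1,2}}, got {count}"
                )

    @property
    def repeat_group(self) -> RepeatGroup:
        return classify_repeat_group(self.repeat_length)


@dataclass
class SurvivalRecord:
    """A censored time-to-menopause observation on the age scale."""

    id: str
    time: float
    event: bool
    covariates: dict[str, float]
    group: RepeatGroup

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.id}: survival time must be > 0")
        for name, value in self.covariates.items():
            if value is None or (isinstance(value, float) and np.isnan(value)):
                raise ValueError(f"{self.id}: covariate {name!r} is absent")


class RecordRejected(ValueError):
    """A participant could not be converted to a survival record."""


def is_pof(participant: Participant) -> bool:
    """True iff the participant reached natural menopause before age 40.

    Raises ``ValueError`` when menopause was not reported: POF status is
    undefined for women still cycling or censored for another reason.
    """
    if not participant.menopause_reported:
        raise ValueError(
            f"{participant.id}: POF is undefined without reported menopause"
        )
    if participant.age_at_menopause is None:
        raise ValueError(f"{participant.id}: menopause reported without an age")
    return participant.age_at_menopause < POF_AGE_THRESHOLD


#: Covariates required (non-absent) for a survival record, by default.
DEFAULT_COVARIATES = ("age_at_interview", "race_nonwhite", "ever_smoked", "bmi")


def _covariate_map(p: Participant, race_reference: str) -> dict[str, float]:
    if p.bmi is None or (isinstance(p.bmi, float) and np.isnan(p.bmi)):
        raise RecordRejected(f"{p.id}: missing BMI")
    return {
        "age_at_interview": float(p.age_at_interview),
        "race_nonwhite": float(p.race_ethnicity != race_reference),
        "ever_smoked": float(bool(p.ever_smoked)),
        "bmi": float(p.bmi),
    }


def to_survival_record(
    participant: Participant, *, race_reference: str = "White"
) -> SurvivalRecord:
    """Apply the censoring rules to one participant.

    Natural menopause -> (age at menopause, event).  No cessation of menses
    -> censored at age at interview.  Hysterectomy / other medical cause ->
    censored at age at last menses.  Race/ethnicity is encoded as a single
    indicator against ``race_reference``.

    Raises
    ------
    RecordRejected
        If an age field required by the branch taken is absent.
    """
    p = participant
    cause = p.cessation_cause
    if cause == CessationCause.NATURAL_MENOPAUSE:
        if p.age_at_menopause is None:
            raise RecordRejected(f"{p.id}: natural menopause without an age")
        time, event = float(p.age_at_menopause), True
    elif cause == CessationCause.NONE:
        time, event = float(p.age_at_interview), False
    else:  # hysterectomy or other medical cause
        if p.age_at_last_menses is None:
            raise RecordRejected(
                f"{p.id}: cessation cause {cause.value!r} without age at last menses"
            )
        time, event = float(p.age_at_last_menses), False
    return SurvivalRecord(
        id=p.id,
        time=time,
        event=event,
        covariates=_covariate_map(p, race_reference),
        group=p.repeat_group,
    )


def build_survival_records(
    cohort: Iterable[Participant],
    *,
    exclude_pof: bool = False,
    race_reference: str = "White",
) -> list[SurvivalRecord]:
    """Convert a cohort, dropping unusable participants with a logged reason.

    With ``exclude_pof`` the women who reported POF are removed entirely
    before fitting (not re-censored).
    """
    records: list[SurvivalRecord] = []
    n_rejected = 0
    for p in cohort:
        if exclude_pof and p.menopause_reported and is_pof(p):
            continue
        try:
            records.append(to_survival_record(p, race_reference=race_reference))
        except RecordRejected as exc:
            n_rejected += 1
            logger.warning("survival record rejected: %s", exc)
    if n_rejected:
        logger.info("rejected %d of %d participants", n_rejected, n_rejected + len(records))
    return records


def menopause_summary(
    cohort: list[Participant], *, exclude_pof: bool = False
) -> pd.DataFrame:
    """Per-repeat-group descriptive table of age at menopause.

    Columns: total N, N reporting menopause, N with POF, mean +- SD of age
    at interview, and the unadjusted mean +- SD of age at natural menopause
    over the women who reported it.  With ``exclude_pof`` the POF women are
    dropped from the interview-age and menopause-age statistics (counts stay
    on the full group).  Groups with no menopause reporters get NaN means,
    never zero.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    rows = []
    for group in RepeatGroup:
        members = [p for p in cohort if p.repeat_group == group]
        reporters = [p for p in members if p.menopause_reported]
        pof = [p for p in reporters if is_pof(p)]
        stat_members = members
        stat_reporters = reporters
        if exclude_pof:
            pof_ids = {p.id for p in pof}
            stat_members = [p for p in members if p.id not in pof_ids]
            stat_reporters = [p for p in reporters if p.id not in pof_ids]
        interview = np.array([p.age_at_interview for p in stat_members], dtype=float)
        meno = np.array(
            [p.age_at_menopause for p in stat_reporters], dtype=float
        )
        rows.append(
            {
                "repeat_group": group.value,
                "n_total": len(members),
                "n_menopause": len(reporters),
                "n_pof": len(pof),
                "mean_age_interview": interview.mean() if len(interview) else np.nan,
                "sd_age_interview": interview.std(ddof=1) if len(interview) > 1 else np.nan,
                "mean_age_menopause": meno.mean() if len(meno) else np.nan,
                "sd_age_menopause": meno.std(ddof=1) if len(meno) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("repeat_group")
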