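"""Per-visit glycemic classification and longitudinal progression grouping.

Classification follows the ADA three-state scheme on fasting plasma glucose
(FPG), 2-hour post-load glucose, HbA1c, and antidiabetic-medication use:

* diabetes:     FPG >= 126 mg/dL, or 2h-PG >= 200 mg/dL, or HbA1c >= 6.5 %,
                or current antidiabetic medication;
* prediabetes:  FPG in [100, 126), or 2h-PG in [140, 200), or HbA1c in [5.7, 6.5);
* NGT:          every *present* criterion below the prediabetes cutoff.

A participant eligible for longitudinal analysis is NGT (off medication) at
baseline with a fully evaluable OGTT and has an OGTT at the year-10 visit.
Progression over follow-up is summarised either by the worst status ever
attained after baseline (default) or by the status at the final visit.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .cohort_data import Cohort, Participant, Visit

# ADA cutoffs (mg/dL for glucose, percent for HbA1c)
FPG_PREDM, FPG_DM = 100.0, 126.0
PG2H_PREDM, PG2H_DM = 140.0, 200.0
HBA1C_PREDM, HBA1C_DM = 5.7, 6.5


class GlycemicStatus(enum.IntEnum):
    """Three-state glycemic status; integer value encodes severity order."""

    UNKNOWN = -1
    NGT = 0
    PREDM = 1
    DM = 2


class ProgressionGroup(enum.IntEnum):
    NON_P = 0     # maintained NGT throughout follow-up
    PREDM_P = 1   # progressed to prediabetes
    T2D_P = 2     # progressed to type 2 diabetes


class ProgressionRule(enum.Enum):
    EVER_WORST = "ever-worst"     # worst status at any post-baseline visit
    FINAL_VISIT = "final-visit"   # status at the last evaluable visit


def classify_visit(fpg: float | None = None, pg2h: float | None = None,
                   hba1c: float | None = None, on_medication: bool = False) -> GlycemicStatus:
    """Classify one visit from whichever criteria are available.

    Absent criteria are simply not consulted; a visit with only FPG = 95 is
    NGT.  Returns UNKNOWN when no criterion is evaluable and the medication
    flag is false.
    """
    for name, v in (("fpg", fpg), ("pg2h", pg2h), ("hba1c", hba1c)):
        if v is not None and v < 0:
            raise ValueError(f"negative {name}: {v}")
    if on_medication:
        return GlycemicStatus.DM
    if fpg is None and pg2h is None and hba1c is None:
        return GlycemicStatus.UNKNOWN
    if (fpg is not None and fpg >= FPG_DM) or \
       (pg2h is not None and pg2h >= PG2H_DM) or \
       (hba1c is not None and hba1c >= HBA1C_DM):
        return GlycemicStatus.DM
    if (fpg is not None and fpg >= FPG_PREDM) or \
       (pg2h is not None and pg2h >= PG2H_PREDM) or \
       (hba1c is not None and hba1c >= HBA1C_PREDM):
        return GlycemicStatus.PREDM
    return GlycemicStatus.NGT


def classify_visit_record(visit: Visit) -> GlycemicStatus:
    """Classify a :class:`Visit` from its OGTT and medication flag."""
    return classify_visit(
        fpg=visit.ogtt.g0, pg2h=visit.ogtt.g120, hba1c=visit.ogtt.hba1c,
        on_medication=bool(visit.on_antidiabetic_medication))


@dataclass(frozen=True)
class Exclusion:
    participant_id: str
    reason: str


#: ordered eligibility rules; the first failing rule is the recorded reason
REASON_NOT_NGT = "baseline not NGT"
REASON_MEDICATION = "baseline antidiabetic medication"
REASON_INCOMPLETE_BASELINE = "baseline OGTT incomplete"
REASON_NO_YEAR10 = "no year-10 OGTT"


def filter_eligible(cohort: Cohort) -> tuple[Cohort, list[Exclusion]]:
    """Apply the study's eligibility rules and log one reason per exclusion.

    Retains participants who (a) classify NGT on baseline labs, (b) are off
    antidiabetic medication at baseline, (c) have g0, g120 and HbA1c all
    present at baseline, and (d) have an evaluable OGTT at visit 5.
    """
    kept, excluded = [], []
    for p in cohort.participants:
        base = p.visit(0)
        if base is None:
            excluded.append(Exclusion(p.id, REASON_NOT_NGT))
            continue
        labs_status = classify_visit(fpg=base.ogtt.g0, pg2h=base.ogtt.g120,
                                     hba1c=base.ogtt.hba1c, on_medication=False)
        if labs_status != GlycemicStatus.NGT:
            excluded.append(Exclusion(p.id, REASON_NOT_NGT))
            continue
        if base.on_antidiabetic_medication:
            excluded.append(Exclusion(p.id, REASON_MEDICATION))
            continue
        if base.ogtt.g0 is None or base.ogtt.g120 is None or base.ogtt.hba1c is None:
            excluded.append(Exclusion(p.id, REASON_INCOMPLETE_BASELINE))
            continue
        v5 = p.visit(5)
        if v5 is None or (v5.ogtt.g0 is None and v5.ogtt.g120 is None
                          and v5.ogtt.hba1c is None):
            excluded.append(Exclusion(p.id, REASON_NO_YEAR10))
            continue
        kept.append(p)
    out = Cohort(participants=tuple(kept),
                 provenance=cohort.provenance + " [eligible]",
                 metadata=dict(cohort.metadata))
    return out, excluded


def progression_from_statuses(statuses: list[GlycemicStatus],
                              rule: ProgressionRule = ProgressionRule.EVER_WORST,
                              ) -> ProgressionGroup:
    """Collapse an ordered sequence of post-baseline statuses to a group label.

    UNKNOWN visits are skipped, never imputed.
    """
    known = [s for s in statuses if s != GlycemicStatus.UNKNOWN]
    if not known:
        raise ValueError("no evaluable post-baseline visit")
    if rule == ProgressionRule.EVER_WORST:
        worst = max(known)
    elif rule == ProgressionRule.FINAL_VISIT:
        worst = known[-1]
    else:  # pragma: no cover
        raise ValueError(f"unknown rule {rule}")
    return {GlycemicStatus.NGT: ProgressionGroup.NON_P,
            GlycemicStatus.PREDM: ProgressionGroup.PREDM_P,
            GlycemicStatus.DM: ProgressionGroup.T2D_P}[worst]


def assign_progression(participant: Participant,
                       rule: ProgressionRule = ProgressionRule.EVER_WORST,
                       ) -> ProgressionGroup:
    """Label a participant by their post-baseline glycemic trajectory."""
    post = [v for v in sorted(participant.visits, key=lambda v: v.visit_index)
            if v.visit_index >= 1]
    statuses = [classify_visit_record(v) for v in post]
    return progression_from_statuses(statuses, rule=rule)
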