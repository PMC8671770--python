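"""Eligibility and completeness filtering of an intake stream.

The analytic sample is produced by applying, in order, with each record
excluded exactly once by the first matching rule:

1. duplicate respondent id (the first occurrence is kept);
2. incomplete survey (any missing scored item);
3. age outside the 18–25 eligibility window (tallied as the age rule);
4. did not attend a US high school;
5. graduate student.

First-match attribution keeps the tally well defined even for records that
fail several rules, and makes the counts conserve: every input record is
either kept or lands in exactly one exclusion bucket.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

from edmood.instruments import SurveyRecord

AGE_MIN = 18
AGE_MAX = 25


@dataclass
class ExclusionTally:
    n_started: int = 0
    n_duplicates: int = 0
    n_incomplete: int = 0
    n_over_age: int = 0  # outside the 18-25 window (both bounds enforced)
    n_foreign_high_school: int = 0
    n_graduate: int = 0
    n_final: int = 0

    def as_dict(self) -> dict[str, int]:
        return asdict(self)

    def check_conservation(self) -> bool:
        return self.n_final == self.n_started - (
            self.n_duplicates
            + self.n_incomplete
            + self.n_over_age
            + self.n_foreign_high_school
            + self.n_graduate
        )


def apply_eligibility(
    records: Sequence[SurveyRecord],
) -> tuple[list[SurveyRecord], ExclusionTally]:
    """Filter an intake stream into the analytic sample.

    Returns the kept records (input order preserved) and the exclusion tally.
    Records without an id raise ``ValueError`` — deduplication is impossible.
    """
    tally = ExclusionTally(n_started=len(records))
    seen: set[str] = set()
    kept: list[SurveyRecord] = []
    for rec in records:
        if not rec.respondent_id:
            raise ValueError("record without respondent id cannot be deduplicated")
        if rec.respondent_id in seen:
            tally.n_duplicates += 1
            continue
        seen.add(rec.respondent_id)
        if not rec.is_complete:
            tally.n_incomplete += 1
        elif rec.age is None or not AGE_MIN <= rec.age <= AGE_MAX:
            tally.n_over_age += 1
        elif not rec.attended_us_high_school:
            tally.n_foreign_high_school += 1
        elif rec.student_level == "graduate":
            tally.n_graduate += 1
        else:
            kept.append(rec)
    tally.n_final = len(kept)
    assert tally.check_conservation()
    return kept, tally
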