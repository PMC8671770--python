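"""Questionnaire scoring: GAD-7, PHQ-2 and the EDE-Q subscales.

Scoring conventions
-------------------
* GAD-7: seven items on a 0–3 Likert scale, summed; total 0–21, diagnostic
  cutoff 10.
* PHQ-2: two items on a 0–3 Likert scale, summed; total 0–6, diagnostic
  cutoff 3.
* EDE-Q concern/restraint subscales: day-frequency items on a 0–6 scale
  (restraint 5 items, eating concern 4, shape concern 8, weight concern 5),
  averaged; each subscale score lies in [0, 6].
* Binge eating: a single 28-day episode count, 0–41, used as-is.
* Purging behaviors (vomiting, laxative use, excessive exercise): 28-day
  counts recoded onto clinically weighted 0–6 bins — a recoded score of 4 or
  more marks the frequency at which the behavior is considered clinically
  significant — and summed into a 0–18 purging score.

Missing items are never imputed or prorated: any missing scored item raises
:class:`~edmood.errors.ScoringError` from the scoring functions, and marks
the record incomplete for cohort filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from edmood.errors import ScoringError, UndefinedStatisticError

#: items per averaged EDE-Q subscale, in canonical order
SUBSCALE_SIZES: dict[str, int] = {
    "restraint": 5,
    "eating_concern": 4,
    "shape_concern": 8,
    "weight_concern": 5,
}

#: CSV column stem per subscale
_SUBSCALE_STEM = {
    "restraint": "restraint",
    "eating_concern": "eatconcern",
    "shape_concern": "shapeconcern",
    "weight_concern": "weightconcern",
}

MAX_COUNT = 41  # administered response ceiling for 28-day behavior counts


@dataclass
class SurveyRecord:
    """One respondent's raw survey responses plus eligibility attributes.

    Any field may be ``None`` (missing); completeness is checked by
    :meth:`missing_items`.
    """

    respondent_id: str
    age: Optional[int] = None
    attended_us_high_school: Optional[bool] = None
    student_level: Optional[str] = None  # "undergraduate" | "graduate"
    gad_items: list[Optional[int]] = field(default_factory=lambda: [None] * 7)
    phq_items: list[Optional[int]] = field(default_factory=lambda: [None] * 2)
    edeq_items: dict[str, list[Optional[int]]] = field(
        default_factory=lambda: {k: [None] * n for k, n in SUBSCALE_SIZES.items()}
    )
    binge_count: Optional[int] = None
    vomit_count: Optional[int] = None
    laxative_count: Optional[int] = None
    exercise_count: Optional[int] = None
    latent_group: Optional[int] = None  # set by the synthetic generator only

    def missing_items(self) -> list[str]:
        """Names of all scored items that are missing."""
        out = [f"gad_{i + 1}" for i, v in enumerate(self.gad_items) if v is None]
        out += [f"phq_{i + 1}" for i, v in enumerate(self.phq_items) if v is None]
        for sub, items in self.edeq_items.items():
            stem = _SUBSCALE_STEM[sub]
            out += [f"{stem}_{i + 1}" for i, v in enumerate(items) if v is None]
        for name in ("binge_count", "vomit_count", "laxative_count", "exercise_count"):
            if getattr(self, name) is None:
                out.append(name)
        return out

    @property
    def is_complete(self) -> bool:
        return not self.missing_items()


@dataclass
class ScaleScores:
    """Scored scales for one respondent."""

    respondent_id: str
    gad7_total: int
    phq2_total: int
    restraint: float
    eating_concern: float
    shape_concern: float
    weight_concern: float
    binge: int
    purging: int
    vomit_recode: int
    laxative_recode: int
    exercise_recode: int


def _check_items(items: Sequence, n: int, lo: int, hi: int, scale: str) -> list[int]:
    if len(items) != n:
        raise ScoringError(f"{scale}: expected {n} items, got {len(items)}")
    out = []
    for i, v in enumerate(items):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ScoringError(f"{scale}: item {i + 1} is missing")
        iv = int(v)
        if iv != v or not lo <= iv <= hi:
            raise ScoringError(f"{scale}: item {i + 1} value {v!r} outside {lo}..{hi}")
        out.append(iv)
    return out


def score_gad7(gad_items: Sequence[int]) -> int:
    """Sum the seven 0–3 anxiety items; total 0–21."""
    return sum(_check_items(gad_items, 7, 0, 3, "GAD-7"))


def score_phq2(phq_items: Sequence[int]) -> int:
    """Sum the two 0–3 depression items; total 0–6."""
    return sum(_check_items(phq_items, 2, 0, 3, "PHQ-2"))


def score_frequency_subscale(items: Sequence[int], subscale: str) -> float:
    """Average the 0–6 day-frequency items of one EDE-Q subscale."""
    if subscale not in SUBSCALE_SIZES:
        raise ScoringError(f"unknown subscale {subscale!r}")
    vals = _check_items(items, SUBSCALE_SIZES[subscale], 0, 6, subscale)
    return sum(vals) / len(vals)


def _check_count(count, name: str) -> int:
    if count is None or (isinstance(count, float) and math.isnan(count)):
        raise ScoringError(f"{name}: count is missing")
    c = int(count)
    if c != count or not 0 <= c <= MAX_COUNT:
        raise ScoringError(f"{name}: count {count!r} outside 0..{MAX_COUNT}")
    return c


def recode_vomit_or_laxative(count: int) -> int:
    """Clinically weighted recode of a 28-day vomiting/laxative count.

    0 = no use; 1–5 = used that many times; 6 = used six or more times.
    Equivalent to ``min(count, 6)``; a recode of 4+ is clinically significant.
    """
    return min(_check_count(count, "vomit/laxative"), 6)


def recode_exercise(count: int) -> int:
    """Clinically weighted recode of a 28-day excessive-exercise count.

    Bins: 0; 1–5 -> 1; 6–10 -> 2; 11–15 -> 3; 16–20 -> 4; 21–25 -> 5;
    more than 25 -> 6.  Exercising 20+ times in 28 days (recode 4+) is the
    clinically significant level.
    """
    c = _check_count(count, "exercise")
    if c == 0:
        return 0
    if c > 25:
        return 6
    return (c - 1) // 5 + 1


def score_purging(vomit_count: int, laxative_count: int, exercise_count: int) -> int:
    """Sum of the three recoded purging items; range 0–18."""
    return (
        recode_vomit_or_laxative(vomit_count)
        + recode_vomit_or_laxative(laxative_count)
        + recode_exercise(exercise_count)
    )


def cronbach_alpha(item_matrix) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    Parameters
    ----------
    item_matrix : array-like, shape (n_respondents, n_items)
        Complete item responses; no missing entries (listwise deletion is the
        caller's responsibility).

    Notes
    -----
    alpha = k/(k-1) * (1 - sum of item variances / variance of row totals),
    with the population (ddof=0) variance convention used consistently in
    numerator and denominator; the ratio — hence alpha — is identical under
    the sample convention.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ScoringError("alpha requires a 2-D matrix with at least 2 items")
    if x.shape[0] < 3:
        raise ScoringError("alpha requires at least 3 respondents")
    if np.isnan(x).any():
        raise ScoringError("alpha input contains missing values")
    k = x.shape[1]
    total_var = np.var(x.sum(axis=1), ddof=0)
    if total_var == 0:
        raise UndefinedStatisticError("total-score variance is zero; alpha undefined")
    item_var = np.var(x, axis=0, ddof=0).sum()
    return k / (k - 1) * (1.0 - item_var / total_var)


def score_record(record: SurveyRecord) -> ScaleScores:
    """Score all scales for one complete respondent record."""
    return ScaleScores(
        respondent_id=record.respondent_id,
        gad7_total=score_gad7(record.gad_items),
        phq2_total=score_phq2(record.phq_items),
        restraint=score_frequency_subscale(record.edeq_items["restraint"], "restraint"),
        eating_concern=score_frequency_subscale(
            record.edeq_items["eating_concern"], "eating_concern"
        ),
        shape_concern=score_frequency_subscale(
            record.edeq_items["shape_concern"], "shape_concern"
        ),
        weight_concern=score_frequency_subscale(
            record.edeq_items["weight_concern"], "weight_concern"
        ),
        binge=_check_count(record.binge_count, "binge"),
        purging=score_purging(
            record.vomit_count, record.laxative_count, record.exercise_count
        ),
        vomit_recode=recode_vomit_or_laxative(record.vomit_count),
        laxative_recode=recode_vomit_or_laxative(record.laxative_count),
        exercise_recode=recode_exercise(record.exercise_count),
    )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def survey_columns() -> list[str]:
    """Column order of the survey CSV dialect."""
    cols = ["id", "age", "us_high_school", "student_level"]
    cols += [f"gad_{i}" for i in range(1, 8)]
    cols += [f"phq_{i}" for i in range(1, 3)]
    for sub, n in SUBSCALE_SIZES.items():
        cols += [f"{_SUBSCALE_STEM[sub]}_{i}" for i in range(1, n + 1)]
    cols += ["binge_n", "vomit_n", "laxative_n", "exercise_n"]
    return cols


def _cell(v):
    return "" if v is None else v


def records_to_frame(records: Sequence[SurveyRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {
            "id": r.respondent_id,
            "age": _cell(r.age),
            "us_high_school": "" if r.attended_us_high_school is None
            else int(r.attended_us_high_school),
            "student_level": _cell(r.student_level),
        }
        for i, v in enumerate(r.gad_items):
            row[f"gad_{i + 1}"] = _cell(v)
        for i, v in enumerate(r.phq_items):
            row[f"phq_{i + 1}"] = _cell(v)
        for sub in SUBSCALE_SIZES:
            for i, v in enumerate(r.edeq_items[sub]):
                row[f"{_SUBSCALE_STEM[sub]}_{i + 1}"] = _cell(v)
        row["binge_n"] = _cell(r.binge_count)
        row["vomit_n"] = _cell(r.vomit_count)
        row["laxative_n"] = _cell(r.laxative_count)
        row["exercise_n"] = _cell(r.exercise_count)
        rows.append(row)
    return pd.DataFrame(rows, columns=survey_columns())


def write_survey_csv(records: Sequence[SurveyRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def _opt_int(v):
    if pd.isna(v) or v == "":
        return None
    return int(v)


def read_survey_csv(path) -> list[SurveyRecord]:
    """Read the survey CSV dialect; empty cells become missing values."""
    df = pd.read_csv(path, dtype={"id": str, "student_level": str})
    records = []
    for _, row in df.iterrows():
        level = row.get("student_level")
        hs = _opt_int(row.get("us_high_school"))
        records.append(
            SurveyRecord(
                respondent_id=str(row["id"]),
                age=_opt_int(row.get("age")),
                attended_us_high_school=None if hs is None else bool(hs),
                student_level=None if pd.isna(level) or level == "" else str(level),
                gad_items=[_opt_int(row.get(f"gad_{i}")) for i in range(1, 8)],
                phq_items=[_opt_int(row.get(f"phq_{i}")) for i in range(1, 3)],
                edeq_items={
                    sub: [
                        _opt_int(row.get(f"{_SUBSCALE_STEM[sub]}_{i}"))
                        for i in range(1, n + 1)
                    ]
                    for sub, n in SUBSCALE_SIZES.items()
                },
                binge_count=_opt_int(row.get("binge_n")),
                vomit_count=_opt_int(row.get("vomit_n")),
                laxative_count=_opt_int(row.get("laxative_n")),
                exercise_count=_opt_int(row.get("exercise_n")),
            )
        )
    return records


def scores_to_frame(scores: Sequence[ScaleScores]) -> pd.DataFrame:
    """One row per respondent, mirroring the ScaleScores fields."""
    cols = [f.name for f in fields(ScaleScores)]
    return pd.DataFrame([{c: getattr(s, c) for c in cols} for s in scores], columns=cols)
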