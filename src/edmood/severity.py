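"""Sample-relative eating-disorder severity composite.

Each of six EDE-Q subscales (restraint, eating concern, shape concern,
weight concern, binge eating, purging) is recoded against the 75th and 90th
percentiles of the *analytic sample itself*: below the 75th percentile -> 0,
between the 75th and 90th percentile (inclusive at both cutoffs) -> 1, above
the 90th percentile -> 2.  The six category scores sum to a 0–12 composite.
Because the cutoffs are within-sample percentiles the composite is
sample-relative by construction; cutoffs are always recomputed from the
supplied sample, never taken from norm tables.

Percentiles use linear interpolation between order statistics (the common
spreadsheet/statistical default; ``numpy.percentile`` ``method="linear"``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from edmood.errors import InsufficientSampleError

#: the six severity subscales, in reporting order
SEVERITY_SUBSCALES = [
    "restraint",
    "eating_concern",
    "shape_concern",
    "weight_concern",
    "binge",
    "purging",
]

QUANTILE_METHOD = "linear"  # fixed so cutoffs are bit-reproducible
MIN_SAMPLE = 10


@dataclass
class SeverityCutoffs:
    """Within-sample 75th/90th percentile table for the six subscales."""

    p75: dict[str, float]
    p90: dict[str, float]
    sample_n: int

    def to_json(self, path) -> None:
        payload = {
            sub: {"p75": self.p75[sub], "p90": self.p90[sub], "n": self.sample_n}
            for sub in SEVERITY_SUBSCALES
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SeverityCutoffs":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            p75={s: payload[s]["p75"] for s in SEVERITY_SUBSCALES},
            p90={s: payload[s]["p90"] for s in SEVERITY_SUBSCALES},
            sample_n=payload[SEVERITY_SUBSCALES[0]]["n"],
        )


@dataclass
class SeverityResult:
    """Per-subscale 0/1/2 categories and their 0–12 total for one respondent."""

    categories: dict[str, int]
    total: int


def compute_cutoffs(subscale_scores: dict[str, np.ndarray] | pd.DataFrame) -> SeverityCutoffs:
    """75th/90th percentile cutoffs for each severity subscale.

    Parameters
    ----------
    subscale_scores
        Mapping (or DataFrame) with one equal-length, complete vector of
        scores per subscale in :data:`SEVERITY_SUBSCALES`; at least
        ``MIN_SAMPLE`` respondents.
    """
    vecs = {s: np.asarray(subscale_scores[s], dtype=float) for s in SEVERITY_SUBSCALES}
    lengths = {len(v) for v in vecs.values()}
    if len(lengths) != 1:
        raise ValueError("subscale vectors must have equal length")
    n = lengths.pop()
    if n < MIN_SAMPLE:
        raise InsufficientSampleError(
            f"severity cutoffs require at least {MIN_SAMPLE} respondents, got {n}"
        )
    for s, v in vecs.items():
        if np.isnan(v).any():
            raise ValueError(f"missing values in subscale {s!r}")
    p75 = {s: float(np.percentile(v, 75, method=QUANTILE_METHOD)) for s, v in vecs.items()}
    p90 = {s: float(np.percentile(v, 90, method=QUANTILE_METHOD)) for s, v in vecs.items()}
    return SeverityCutoffs(p75=p75, p90=p90, sample_n=int(n))


def categorize(score: float, p75: float, p90: float) -> int:
    """0 below p75, 1 in [p75, p90], 2 above p90 (both cutoffs inclusive -> 1)."""
    if score < p75:
        return 0
    if score <= p90:
        return 1
    return 2


def severity_score(scores, cutoffs: SeverityCutoffs) -> SeverityResult:
    """Severity categories and 0–12 total for one respondent.

    ``scores`` is any object with the six subscale values as attributes or
    mapping keys (a :class:`~edmood.instruments.ScaleScores`, a dict, a
    pandas row).
    """
    def get(sub):
        if hasattr(scores, sub):
            return getattr(scores, sub)
        return scores[sub]

    cats = {
        sub: categorize(float(get(sub)), cutoffs.p75[sub], cutoffs.p90[sub])
        for sub in SEVERITY_SUBSCALES
    }
    return SeverityResult(categories=cats, total=sum(cats.values()))


def severity_table(scored: pd.DataFrame, cutoffs: SeverityCutoffs) -> pd.DataFrame:
    """Vectorized severity columns for a scored-respondents frame.

    Returns a copy of ``scored`` with ``sev_<subscale>`` columns and
    ``sev_total`` appended.
    """
    out = scored.copy()
    total = np.zeros(len(out), dtype=int)
    for sub in SEVERITY_SUBSCALES:
        v = out[sub].to_numpy(dtype=float)
        cat = np.where(v < cutoffs.p75[sub], 0, np.where(v <= cutoffs.p90[sub], 1, 2))
        out[f"sev_{sub}"] = cat
        total += cat
    out["sev_total"] = total
    return out
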