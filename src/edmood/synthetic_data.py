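"""Synthetic survey-cohort generator.

Emulates a college-age screening cohort with a four-latent-group structure:
per group, GAD-7 and PHQ-2 totals are drawn from truncated normals on their
scale ranges, the four averaged EDE-Q subscales from truncated normals on
[0, 6], binge counts from a moment-matched negative binomial (published
per-cluster SDs exceed the means), vomiting/laxative counts from
zero-inflated geometric counts, and excessive exercise by inverting the
clinical 0–6 recode bins.  Totals are decomposed into item responses by
random unit allocation under the per-item caps, so item sums reproduce each
drawn total exactly and every scored value stays in range.

Because the published targets are *cluster-level moments*, the parent
location of every truncated normal is solved so the truncated distribution's
mean equals the target (otherwise truncation biases the high-anxiety group's
mean visibly).  The SD shrinkage that truncation induces is not hidden: the
run manifest reports target versus realized moments.  Within a group the
anxiety, depression, eating and count draws are independent — a documented
simplification, since no within-cluster correlation structure is published.

:func:`generate_intake` wraps the cohort with configured numbers of
duplicate, incomplete, over-age, foreign-high-school and graduate records
(each engineered to trip exactly one exclusion rule), deterministically
shuffled, so the eligibility filter's tally arithmetic is testable
end-to-end.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import brentq

from edmood.errors import ConfigError
from edmood.instruments import SUBSCALE_SIZES, SurveyRecord, score_record

#: recode bin -> raw 28-day count range for excessive exercise
EXERCISE_BINS = [(0, 0), (1, 5), (6, 10), (11, 15), (16, 20), (21, 25), (26, 41)]

#: mean of the positive part of the zero-inflated vomit/laxative counts
_ZIG_POSITIVE_MEAN = 1.5


@dataclass
class GroupSpec:
    """Target moments for one latent group (published per-cluster scales)."""

    n: int
    gad: tuple[float, float]  # mean, sd on the 0-21 total scale
    phq: tuple[float, float]  # mean, sd on the 0-6 total scale
    edeq: dict[str, tuple[float, float]]  # subscale -> (mean, sd) on [0, 6]
    binge: tuple[float, float]  # mean, sd of the 28-day count
    vomit_mean: float
    laxative_mean: float
    exercise: tuple[float, float]  # mean, sd on the recoded 0-6 scale


@dataclass
class IntakeSpec:
    n_duplicates: int = 0
    n_incomplete: int = 0
    n_over_age: int = 0
    n_foreign_hs: int = 0
    n_graduate: int = 0


@dataclass
class GeneratorConfig:
    seed: int
    groups: list[GroupSpec]
    intake: IntakeSpec = field(default_factory=IntakeSpec)

    def validate(self) -> None:
        if not self.groups:
            raise ConfigError("at least one group is required")
        for gi, g in enumerate(self.groups, start=1):
            if g.n < 0:
                raise ConfigError(f"group {gi}: n must be >= 0")
            _check_target(f"group {gi} gad mean", g.gad, 0, 21)
            _check_target(f"group {gi} phq mean", g.phq, 0, 6)
            for sub, ms in g.edeq.items():
                if sub not in SUBSCALE_SIZES:
                    raise ConfigError(f"group {gi}: unknown subscale {sub!r}")
                _check_target(f"group {gi} {sub} mean", ms, 0, 6)
            if g.binge[0] < 0 or g.binge[1] < 0:
                raise ConfigError(f"group {gi}: binge moments must be >= 0")
            if g.vomit_mean < 0 or g.laxative_mean < 0:
                raise ConfigError(f"group {gi}: purge-count means must be >= 0")
            _check_target(f"group {gi} exercise mean", g.exercise, 0, 6)
        for name, v in asdict(self.intake).items():
            if v < 0:
                raise ConfigError(f"intake {name} must be >= 0")

    # -- JSON round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "groups": [
                {
                    "n": g.n,
                    "gad": list(g.gad),
                    "phq": list(g.phq),
                    "edeq": {k: list(v) for k, v in g.edeq.items()},
                    "binge": list(g.binge),
                    "vomit_mean": g.vomit_mean,
                    "laxative_mean": g.laxative_mean,
                    "exercise": list(g.exercise),
                }
                for g in self.groups
            ],
            "intake": asdict(self.intake),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        cfg = cls(
            seed=int(d["seed"]),
            groups=[
                GroupSpec(
                    n=int(g["n"]),
                    gad=tuple(g["gad"]),
                    phq=tuple(g["phq"]),
                    edeq={k: tuple(v) for k, v in g["edeq"].items()},
                    binge=tuple(g["binge"]),
                    vomit_mean=float(g["vomit_mean"]),
                    laxative_mean=float(g["laxative_mean"]),
                    exercise=tuple(g["exercise"]),
                )
                for g in d["groups"]
            ],
            intake=IntakeSpec(**d.get("intake", {})),
        )
        cfg.validate()
        return cfg

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def default(cls, seed: Optional[int] = None) -> "GeneratorConfig":
        """Packaged defaults: the four published anxiety/depression clusters."""
        ref = importlib.resources.files("edmood.data") / "default_cohort.json"
        cfg = cls.from_dict(json.loads(ref.read_text()))
        if seed is not None:
            cfg.seed = int(seed)
        return cfg


def _check_target(name: str, ms: Sequence[float], lo: float, hi: float) -> None:
    mean, sd = ms
    if sd < 0:
        raise ConfigError(f"{name}: sd must be >= 0")
    if sd == 0:
        if not lo <= mean <= hi:
            raise ConfigError(f"{name}: degenerate mean {mean} outside [{lo}, {hi}]")
    elif not lo < mean < hi:
        raise ConfigError(f"{name}: mean {mean} not strictly inside ({lo}, {hi})")


# ---------------------------------------------------------------------------
# primitive draws
# ---------------------------------------------------------------------------

def _matched_parent_mean(target: float, sd: float, lo: float, hi: float) -> float:
    """Parent normal location whose [lo, hi]-truncation has mean ``target``."""

    def trunc_mean(mu: float) -> float:
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return float(stats.truncnorm.mean(a, b, loc=mu, scale=sd))

    span = 20.0 * sd + (hi - lo)
    try:
        return brentq(lambda mu: trunc_mean(mu) - target, lo - span, hi + span, xtol=1e-8)
    except ValueError as exc:  # pragma: no cover - guarded by _check_target
        raise ConfigError(f"cannot match truncated mean {target} on [{lo}, {hi}]") from exc


def _truncnorm_draws(rng, target: float, sd: float, lo: float, hi: float, size: int):
    if sd == 0:
        return np.full(size, float(np.clip(target, lo, hi)))
    mu = _matched_parent_mean(target, sd, lo, hi)
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def _allocate_items(rng, total: int, n_items: int, cap: int) -> list[int]:
    """Spread ``total`` unit increments over ``n_items`` items capped at ``cap``."""
    vals = np.zeros(n_items, dtype=int)
    for _ in range(int(min(total, n_items * cap))):
        open_idx = np.flatnonzero(vals < cap)
        vals[open_idx[rng.integers(open_idx.size)]] += 1
    return [int(v) for v in vals]


def _binge_draws(rng, mean: float, sd: float, size: int) -> np.ndarray:
    if mean == 0:
        return np.zeros(size, dtype=int)
    var = sd**2
    if var > mean:  # negative binomial, moment-matched
        r = mean**2 / (var - mean)
        p = r / (r + mean)
        draws = rng.negative_binomial(r, p, size=size)
    else:
        draws = rng.poisson(mean, size=size)
    return np.minimum(draws, 41).astype(int)


def _zig_draws(rng, mean: float, size: int) -> np.ndarray:
    """Zero-inflated geometric counts with the given (small) mean."""
    if mean == 0:
        return np.zeros(size, dtype=int)
    pi = min(mean / _ZIG_POSITIVE_MEAN, 1.0)
    positive = rng.random(size) < pi
    draws = rng.geometric(1.0 / _ZIG_POSITIVE_MEAN, size=size) * positive
    return np.minimum(draws, 41).astype(int)


def _exercise_draws(rng, mean: float, sd: float, size: int) -> np.ndarray:
    """Raw 28-day counts whose clinical recode matches the target moments."""
    recoded = np.clip(np.rint(_truncnorm_draws(rng, mean, sd, 0, 6, size)), 0, 6)
    raw = np.empty(size, dtype=int)
    for i, r in enumerate(recoded.astype(int)):
        lo, hi = EXERCISE_BINS[r]
        raw[i] = lo if lo == hi else rng.integers(lo, hi + 1)
    return raw


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def generate_cohort(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> list[SurveyRecord]:
    """Draw one eligible respondent list with the configured group structure.

    Deterministic for a fixed config (the seed drives every draw); re-running
    reproduces byte-identical records.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records: list[SurveyRecord] = []
    idx = 0
    for gi, g in enumerate(config.groups, start=1):
        gad_totals = np.clip(np.rint(_truncnorm_draws(rng, *g.gad, 0, 21, g.n)), 0, 21)
        phq_totals = np.clip(np.rint(_truncnorm_draws(rng, *g.phq, 0, 6, g.n)), 0, 6)
        sub_means = {
            sub: _truncnorm_draws(rng, *g.edeq[sub], 0, 6, g.n) for sub in SUBSCALE_SIZES
        }
        binge = _binge_draws(rng, *g.binge, g.n)
        vomit = _zig_draws(rng, g.vomit_mean, g.n)
        laxative = _zig_draws(rng, g.laxative_mean, g.n)
        exercise = _exercise_draws(rng, *g.exercise, g.n)
        ages = rng.integers(18, 26, size=g.n)
        for j in range(g.n):
            idx += 1
            edeq_items = {}
            for sub, n_items in SUBSCALE_SIZES.items():
                total = int(np.clip(np.rint(sub_means[sub][j] * n_items), 0, 6 * n_items))
                edeq_items[sub] = _allocate_items(rng, total, n_items, 6)
            records.append(
                SurveyRecord(
                    respondent_id=f"R{idx:06d}",
                    age=int(ages[j]),
                    attended_us_high_school=True,
                    student_level="undergraduate",
                    gad_items=_allocate_items(rng, int(gad_totals[j]), 7, 3),
                    phq_items=_allocate_items(rng, int(phq_totals[j]), 2, 3),
                    edeq_items=edeq_items,
                    binge_count=int(binge[j]),
                    vomit_count=int(vomit[j]),
                    laxative_count=int(laxative[j]),
                    exercise_count=int(exercise[j]),
                    latent_group=gi,
                )
            )
    return records


def _clone(rec: SurveyRecord, new_id: Optional[str] = None, **changes) -> SurveyRecord:
    out = SurveyRecord(
        respondent_id=new_id if new_id is not None else rec.respondent_id,
        age=rec.age,
        attended_us_high_school=rec.attended_us_high_school,
        student_level=rec.student_level,
        gad_items=list(rec.gad_items),
        phq_items=list(rec.phq_items),
        edeq_items={k: list(v) for k, v in rec.edeq_items.items()},
        binge_count=rec.binge_count,
        vomit_count=rec.vomit_count,
        laxative_count=rec.laxative_count,
        exercise_count=rec.exercise_count,
        latent_group=rec.latent_group,
    )
    for k, v in changes.items():
        setattr(out, k, v)
    return out


def generate_intake(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> list[SurveyRecord]:
    """Cohort plus the configured ineligible/duplicate/incomplete records.

    Each added record trips exactly one exclusion rule, so the eligibility
    tally of the output equals the intake spec and the kept sample is the
    underlying cohort.  The stream is shuffled deterministically.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cohort = generate_cohort(config, rng)
    if not cohort and any(v > 0 for v in asdict(config.intake).values()):
        raise ConfigError("intake extras require a non-empty cohort to clone from")
    spec = config.intake
    extras: list[SurveyRecord] = []

    def pick() -> SurveyRecord:
        return cohort[int(rng.integers(len(cohort)))]

    for _ in range(spec.n_duplicates):
        extras.append(_clone(pick()))  # same id -> duplicate rule
    xid = 0
    for _ in range(spec.n_incomplete):
        xid += 1
        rec = _clone(pick(), new_id=f"X{xid:06d}")
        rec.gad_items[int(rng.integers(7))] = None
        extras.append(rec)
    for _ in range(spec.n_over_age):
        xid += 1
        extras.append(_clone(pick(), new_id=f"X{xid:06d}", age=int(rng.integers(26, 31))))
    for _ in range(spec.n_foreign_hs):
        xid += 1
        extras.append(_clone(pick(), new_id=f"X{xid:06d}", attended_us_high_school=False))
    for _ in range(spec.n_graduate):
        xid += 1
        extras.append(_clone(pick(), new_id=f"X{xid:06d}", student_level="graduate"))
    stream = cohort + extras
    order = rng.permutation(len(stream))
    return [stream[i] for i in order]


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def realized_moments(records: Sequence[SurveyRecord]) -> dict:
    """Per-latent-group realized means/SDs of the scored scales."""
    by_group: dict[int, list] = {}
    for rec in records:
        if rec.is_complete:
            by_group.setdefault(rec.latent_group or 0, []).append(score_record(rec))
    out = {}
    for gi in sorted(by_group):
        scores = by_group[gi]
        cols = {
            "gad7_total": [s.gad7_total for s in scores],
            "phq2_total": [s.phq2_total for s in scores],
            "restraint": [s.restraint for s in scores],
            "eating_concern": [s.eating_concern for s in scores],
            "shape_concern": [s.shape_concern for s in scores],
            "weight_concern": [s.weight_concern for s in scores],
            "binge": [s.binge for s in scores],
            "purging": [s.purging for s in scores],
        }
        out[gi] = {
            name: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1))}
            for name, v in cols.items()
        }
        out[gi]["n"] = len(scores)
    return out


def generator_manifest(config: GeneratorConfig, records: Sequence[SurveyRecord]) -> dict:
    """Seed, targets and realized moments — truncation shrinkage made visible."""
    targets = {
        gi: {
            "n": g.n,
            "gad7_total": {"mean": g.gad[0], "sd": g.gad[1]},
            "phq2_total": {"mean": g.phq[0], "sd": g.phq[1]},
            **{sub: {"mean": m, "sd": s} for sub, (m, s) in g.edeq.items()},
            "binge": {"mean": g.binge[0], "sd": g.binge[1]},
        }
        for gi, g in enumerate(config.groups, start=1)
    }
    return {
        "seed": config.seed,
        "targets": targets,
        "realized": realized_moments(records),
    }
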