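"""End-to-end pipeline: simulate -> filter -> score -> severity -> cluster -> analyze.

Each stage reads and writes plain CSV/JSON files, so any stage can be
re-run from the previous stage's outputs; :func:`run_pipeline` chains them
and emits a run manifest (config hash, seed, file digests, exclusion tally,
chosen k, labels, warnings) sufficient to reproduce the run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from edmood import __version__
from edmood.cohort import ExclusionTally, apply_eligibility
from edmood.clustering import (
    ClusterSolution,
    cluster_frame,
    detect_elbow,
    kmeans_partition,
    label_clusters,
    ward_schedule,
)
from edmood.group_stats import (
    anova_from_raw,
    pair_letters,
    summarize_groups,
    tukey_pattern,
)
from edmood.instruments import (
    SUBSCALE_SIZES,
    cronbach_alpha,
    read_survey_csv,
    score_record,
    scores_to_frame,
    write_survey_csv,
)
from edmood.severity import SeverityCutoffs, compute_cutoffs, severity_table
from edmood.synthetic_data import GeneratorConfig, generate_intake

#: report rows: column in the merged frame -> display name
REPORT_VARIABLES = [
    ("phq2_total", "depression_phq2"),
    ("gad7_total", "anxiety_gad7"),
    ("restraint", "restraint_eating"),
    ("shape_concern", "shape_concern"),
    ("weight_concern", "weight_concern"),
    ("eating_concern", "eating_concern"),
    ("binge", "binge_eating"),
    ("purging", "purging"),
    ("vomit_recode", "vomiting"),
    ("laxative_recode", "laxatives"),
    ("exercise_recode", "excessive_exercise"),
    ("sev_total", "eating_disorder_severity"),
]


@dataclass
class RunManifest:
    package_version: str
    seed: int
    config_sha256: str
    kmeans_restarts: int
    kmeans_init: str
    exclusion_tally: dict
    chosen_k: int
    cluster_labels: list[str]
    cluster_centroids: list[list[float]]
    warnings: list[str] = field(default_factory=list)
    file_digests: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: GeneratorConfig, intake_csv: Path) -> None:
    write_survey_csv(generate_intake(config), intake_csv)


def stage_filter(intake_csv: Path, cohort_csv: Path, tally_json: Path) -> ExclusionTally:
    kept, tally = apply_eligibility(read_survey_csv(intake_csv))
    write_survey_csv(kept, cohort_csv)
    with open(tally_json, "w") as fh:
        json.dump(tally.as_dict(), fh, indent=2)
    return tally


def stage_score(cohort_csv: Path, scored_csv: Path) -> pd.DataFrame:
    scored = scores_to_frame([score_record(r) for r in read_survey_csv(cohort_csv)])
    scored.to_csv(scored_csv, index=False)
    return scored


def stage_severity(
    scored_csv: Path, cutoffs_json: Path, severity_csv: Path
) -> SeverityCutoffs:
    scored = pd.read_csv(scored_csv)
    cutoffs = compute_cutoffs(scored)
    cutoffs.to_json(cutoffs_json)
    severity_table(scored, cutoffs).to_csv(severity_csv, index=False)
    return cutoffs


def stage_cluster(
    severity_csv: Path,
    clusters_csv: Path,
    schedule_csv: Path,
    seed: int,
    restarts: int = 10,
    init: str = "plusplus",
    k: Optional[int] = None,
) -> ClusterSolution:
    scored = pd.read_csv(severity_csv)
    points = scored[["gad7_total", "phq2_total"]].to_numpy(dtype=float)
    schedule = ward_schedule(points)
    schedule.to_frame().to_csv(schedule_csv, index=False)
    if k is None:
        k = detect_elbow(schedule)
    solution = label_clusters(
        kmeans_partition(points, k, seed=seed, restarts=restarts, init=init)
    )
    cluster_frame(scored["respondent_id"].astype(str), solution).to_csv(
        clusters_csv, index=False
    )
    return solution


def _scale_alphas(cohort_csv: Path) -> dict[str, float]:
    """Cronbach's alpha for the multi-item scales on the analytic sample."""
    records = read_survey_csv(cohort_csv)
    mats = {
        "anxiety_gad7": np.array([r.gad_items for r in records], dtype=float),
        "depression_phq2": np.array([r.phq_items for r in records], dtype=float),
    }
    for sub in SUBSCALE_SIZES:
        mats[sub] = np.array([r.edeq_items[sub] for r in records], dtype=float)
    return {name: float(cronbach_alpha(m)) for name, m in mats.items()}


def stage_analyze(
    severity_csv: Path,
    clusters_csv: Path,
    report_tsv: Path,
    report_json: Path,
    cohort_csv: Optional[Path] = None,
) -> list[dict]:
    """Per-variable cluster contrasts shaped like the published summary tables."""
    scored = pd.read_csv(severity_csv)
    clusters = pd.read_csv(clusters_csv, dtype={"id": str})
    merged = scored.merge(
        clusters, left_on=scored["respondent_id"].astype(str), right_on="id"
    )
    alphas = _scale_alphas(cohort_csv) if cohort_csv else {}
    k = int(merged["cluster_index"].max())
    letters = pair_letters(k)
    rows = []
    for column, display in REPORT_VARIABLES:
        groups = [
            merged.loc[merged["cluster_index"] == c, column].to_numpy(dtype=float)
            for c in range(1, k + 1)
        ]
        summaries = summarize_groups(groups)
        anova = anova_from_raw(groups)
        tukey = tukey_pattern([(s.n, s.mean, s.sd) for s in summaries])
        display_alpha = {"restraint": "restraint_eating"}.get(display, display)
        rows.append(
            {
                "variable": display,
                "cronbach_alpha": alphas.get(column, alphas.get(display_alpha)),
                "groups": [
                    {
                        "cluster": c + 1,
                        "label": merged.loc[
                            merged["cluster_index"] == c + 1, "cluster_label"
                        ].iloc[0],
                        "n": s.n,
                        "mean": s.mean,
                        "sd": s.sd,
                        "ci95_low": s.ci95[0],
                        "ci95_high": s.ci95[1],
                    }
                    for c, s in enumerate(summaries)
                ],
                "f_stat": anova.f_stat,
                "df_between": anova.df_between,
                "df_within": anova.df_within,
                "p_value": anova.p_value,
                "partial_eta_sq": anova.partial_eta_sq,
                "effect_class": anova.effect_class,
                "tukey_letters": tukey.significant_pairs,
                "letter_map": {L: list(p) for L, p in letters.items()},
            }
        )
    # TSV shaped like the published tables: one row per variable
    tsv_rows = []
    for row in rows:
        r = {"variable": row["variable"],
             "cronbach_alpha": "" if row["cronbach_alpha"] is None
             else f"{row['cronbach_alpha']:.2f}"}
        for g in row["groups"]:
            r[f"cluster{g['cluster']}_{g['label']}"] = (
                f"{g['mean']:.2f}±{g['sd']:.2f} "
                f"({g['ci95_low']:.2f}–{g['ci95_high']:.2f})"
            )
        r["F"] = f"{row['f_stat']:.2f}"
        r["df"] = f"{row['df_between']}, {row['df_within']}"
        r["p"] = f"{row['p_value']:.4g}"
        r["tukey"] = row["tukey_letters"]
        r["partial_eta_sq"] = f"{row['partial_eta_sq']:.3f}"
        r["effect"] = row["effect_class"]
        tsv_rows.append(r)
    pd.DataFrame(tsv_rows).to_csv(report_tsv, sep="\t", index=False)
    with open(report_json, "w") as fh:
        json.dump(rows, fh, indent=2)
    return rows


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(
    config: GeneratorConfig | str | Path,
    outdir: str | Path,
    seed: Optional[int] = None,
    restarts: int = 10,
    init: str = "plusplus",
) -> RunManifest:
    """Run every stage in order under ``outdir`` and write ``manifest.json``."""
    if not isinstance(config, GeneratorConfig):
        config = GeneratorConfig.from_json(config)
    if seed is not None:
        config.seed = int(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    paths = {
        "intake": outdir / "intake.csv",
        "cohort": outdir / "cohort.csv",
        "tally": outdir / "exclusion_tally.json",
        "scored": outdir / "scored.csv",
        "cutoffs": outdir / "severity_cutoffs.json",
        "severity": outdir / "severity.csv",
        "clusters": outdir / "clusters.csv",
        "schedule": outdir / "schedule.csv",
        "report_tsv": outdir / "report.tsv",
        "report_json": outdir / "report.json",
    }

    stage_simulate(config, paths["intake"])
    tally = stage_filter(paths["intake"], paths["cohort"], paths["tally"])
    stage_score(paths["cohort"], paths["scored"])
    stage_severity(paths["scored"], paths["cutoffs"], paths["severity"])
    solution = stage_cluster(
        paths["severity"], paths["clusters"], paths["schedule"],
        seed=config.seed, restarts=restarts, init=init,
    )
    stage_analyze(
        paths["severity"], paths["clusters"], paths["report_tsv"],
        paths["report_json"], cohort_csv=paths["cohort"],
    )

    manifest = RunManifest(
        package_version=__version__,
        seed=config.seed,
        config_sha256=hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        kmeans_restarts=restarts,
        kmeans_init=init,
        exclusion_tally=tally.as_dict(),
        chosen_k=solution.k,
        cluster_labels=solution.labels or [],
        cluster_centroids=[[float(v) for v in c] for c in solution.centroids],
        warnings=solution.warnings,
        file_digests={name: _sha256(p) for name, p in paths.items()},
    )
    manifest.to_json(outdir / "manifest.json")
    return manifest
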