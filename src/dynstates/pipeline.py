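"""End-to-end orchestration: simulate -> LEiDA -> cluster -> metrics ->
factors -> GLMs, with TSV artifacts and a reproducibility manifest.

Every stage writes its outputs as tab-separated tables under the run
directory; ``manifest.json`` echoes the fully resolved configuration
and seed, which suffices to reproduce the run bit for bit.  Subjects
are pooled in lexicographic subject-id order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .factor_reduction import dti_pc1, superordinate_scores
from .phase_dynamics import AcquisitionSpec, leida_transform
from .state_clustering import (
    ClusteringConfig,
    select_num_states,
    state_communities,
)
from .state_metrics import (
    StateSequence,
    cohort_state_summary,
    transition_probabilities,
)
from .stats_models import ModelSpec, fit_glm, interaction_scan
from .synthetic_cohort import CohortData, SimulationConfig, simulate_cohort

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "read_table",
    "write_table",
]


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    output_dir: str | Path = "dynstates_run"
    seed: int = 0
    acquisition: AcquisitionSpec = field(default_factory=AcquisitionSpec)
    clustering: ClusteringConfig | None = None
    simulation: SimulationConfig | None = None
    retained_volumes: int | None = None
    run_stats: bool = True

    def resolved_clustering(self) -> ClusteringConfig:
        return self.clustering or ClusteringConfig(seed=self.seed)

    def resolved_simulation(self) -> SimulationConfig:
        return self.simulation or SimulationConfig(seed=self.seed)


@dataclass
class RunManifest:
    config: dict
    artifacts: dict[str, str]
    k_star: int | None = None
    pooled_occupancy: dict[int, float] | None = None

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=_json_default))


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a TSV with header; floats use shortest-round-trip repr so
    write-then-read reproduces values exactly."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path, required_columns: list[str] | None = None) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, checking the schema."""
    df = pd.read_csv(path, sep="\t")
    if required_columns is not None:
        missing = [c for c in required_columns if c not in df.columns]
        extra = [c for c in df.columns if c not in required_columns]
        if missing or extra:
            raise ValueError(
                f"schema mismatch for {path}: missing columns {missing}, "
                f"unexpected columns {extra}"
            )
    return df


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig, cohort_data: CohortData | None = None) -> RunManifest:
    """Execute the full analysis and write all artifacts.

    When ``cohort_data`` is None a synthetic cohort is generated from
    ``config.simulation`` (ground truth is serialised alongside the
    data).  Stages: LEiDA per subject, pooling, state-number selection
    and clustering, per-subject state metrics and transition matrices,
    factor reduction (emotional instability, diffusion PC1), and the
    GLM scans.  Returns the manifest listing every artifact.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    spec = config.acquisition

    with _stage("simulate"):
        if cohort_data is None:
            cohort_data = simulate_cohort(config.resolved_simulation())
            truth_path = outdir / "truth.json"
            truth_path.write_text(
                json.dumps(cohort_data.truth.to_jsonable(), indent=2)
            )
            artifacts["truth"] = str(truth_path)
        cohort = cohort_data.cohort
        artifacts["cohort"] = str(write_table(cohort, outdir / "cohort.tsv"))
        for sid in sorted(cohort_data.timecourses):
            p = write_table(
                cohort_data.timecourses[sid], outdir / "timecourses" / f"{sid}.tsv"
            )
            artifacts[f"timecourses/{sid}"] = str(p)
        for metric, table in cohort_data.dti.items():
            artifacts[f"dti_{metric}"] = str(
                write_table(table, outdir / f"dti_{metric}.tsv")
            )

    with _stage("leida"):
        eigen: dict[str, pd.DataFrame] = {}
        for sid in sorted(cohort_data.timecourses):
            eigen[sid] = leida_transform(
                cohort_data.timecourses[sid],
                spec,
                retained_volumes=config.retained_volumes,
            )
            artifacts[f"eigenvectors/{sid}"] = str(
                write_table(eigen[sid], outdir / "eigenvectors" / f"{sid}.tsv")
            )
        order = sorted(eigen)
        pooled = np.vstack([eigen[sid].to_numpy() for sid in order])
        rows_per_subject = {sid: len(eigen[sid]) for sid in order}

    with _stage("cluster"):
        selection = select_num_states(pooled, config.resolved_clustering())
        k = selection.k_star
        artifacts["db_table"] = str(
            write_table(selection.db_table, outdir / "davies_bouldin.tsv")
        )
        centroids = pd.DataFrame(
            selection.state_set.centroids,
            columns=list(eigen[order[0]].columns),
        )
        centroids.insert(0, "state", np.arange(1, k + 1))
        artifacts["centroids"] = str(write_table(centroids, outdir / "centroids.tsv"))
        labels_by_subject: dict[str, np.ndarray] = {}
        start = 0
        for sid in order:
            n_rows = rows_per_subject[sid]
            labels_by_subject[sid] = selection.labels[start : start + n_rows]
            start += n_rows
        label_frame = pd.DataFrame(
            [
                {"subject_id": sid, "timepoint": t, "state": int(s)}
                for sid in order
                for t, s in enumerate(labels_by_subject[sid])
            ]
        )
        artifacts["state_labels"] = str(
            write_table(label_frame, outdir / "state_labels.tsv")
        )

    with _stage("metrics"):
        sequences = [
            StateSequence(sid, labels_by_subject[sid], spec.tr_seconds)
            for sid in order
        ]
        pooled_frac, metric_table, all_visited = cohort_state_summary(sequences, k)
        artifacts["state_metrics"] = str(
            write_table(metric_table, outdir / "state_metrics.tsv")
        )
        transition_frames = [
            transition_probabilities(s, k).to_frame() for s in sequences
        ]
        transitions = pd.concat(transition_frames, ignore_index=True)
        artifacts["transitions"] = str(
            write_table(transitions, outdir / "transition_probabilities.tsv")
        )

    with _stage("factors"):
        ei_scores, ei_loadings = superordinate_scores(
            cohort.set_index("subject_id")[
                ["neuroticism", "extraversion", "openness", "agreeableness",
                 "conscientiousness"]
            ]
        )
        factors = cohort[["subject_id"]].copy()
        factors["emotional_instability"] = ei_scores.loc[
            factors["subject_id"]
        ].to_numpy()
        dti_scores = {}
        for metric, table in cohort_data.dti.items():
            scores, coefs = dti_pc1(
                table.drop(columns=["subject_id", "group"], errors="ignore")
            )
            dti_scores[metric] = pd.Series(
                scores.to_numpy(), index=table["subject_id"]
            )
            artifacts[f"dti_{metric}_coefficients"] = str(
                write_table(
                    coefs.rename_axis("roi").reset_index(),
                    outdir / f"dti_{metric}_pc1_coefficients.tsv",
                )
            )
            factors[f"dti_{metric}_pc1"] = (
                dti_scores[metric].reindex(factors["subject_id"]).to_numpy()
            )
        artifacts["factors"] = str(write_table(factors, outdir / "factors.tsv"))
        artifacts["ei_loadings"] = str(
            write_table(
                ei_loadings.rename_axis("dimension").reset_index(),
                outdir / "emotional_instability_loadings.tsv",
            )
        )

    results = pd.DataFrame()
    if config.run_stats:
        with _stage("glm"):
            full = cohort.merge(factors, on="subject_id")
            patients = full[full["group"] == "mtbi"]
            scan = interaction_scan(
                patients,
                metric_table[metric_table["subject_id"].isin(patients["subject_id"])],
                k=k,
                transitions=transitions[
                    transitions["subject_id"].isin(patients["subject_id"])
                ],
            )
            scan.insert(0, "analysis", "ei_by_metric")
            group_rows = _group_difference_models(full, metric_table, k)
            group_rows.insert(0, "analysis", "group_difference")
            results = pd.concat([scan, group_rows], ignore_index=True)
            artifacts["glm_results"] = str(
                write_table(results, outdir / "glm_results.tsv")
            )

    manifest = RunManifest(
        config={
            "seed": config.seed,
            "output_dir": str(outdir),
            "retained_volumes": config.retained_volumes,
            "acquisition": dataclasses.asdict(spec),
            "clustering": dataclasses.asdict(config.resolved_clustering()),
            "simulation": dataclasses.asdict(config.resolved_simulation())
            if config.simulation is not None or cohort_data is None
            else None,
            "subject_order": order,
            "rows_per_subject": rows_per_subject,
            "all_states_visited": bool(all_visited),
            "ei_loadings": {k_: float(v) for k_, v in ei_loadings.items()},
        },
        artifacts=artifacts,
        k_star=k,
        pooled_occupancy={int(s): float(f) for s, f in pooled_frac.items()},
    )
    manifest.write(outdir / "manifest.json")
    return manifest


def _group_difference_models(
    full: pd.DataFrame, metric_table: pd.DataFrame, k: int
) -> pd.DataFrame:
    """`metric ~ group + age + sex + education` per state-specific measure."""
    rows = []
    data_base = full.set_index("subject_id")
    data_base["group_mtbi"] = (data_base["group"] == "mtbi").astype(float)
    for metric_class in ("mean_dwell_seconds", "fraction_of_time", "n_visits"):
        for state in range(1, k + 1):
            sub = metric_table[metric_table["state"] == state].set_index(
                "subject_id"
            )
            data = data_base.loc[sub.index].copy()
            data["metric"] = sub[metric_class].to_numpy(dtype=float)
            data = data.dropna(subset=["metric"])
            spec = ModelSpec(
                response="metric",
                predictors=["group_mtbi"],
                bonferroni_m=k,
            )
            try:
                res = fit_glm(spec, data)
            except ValueError as exc:
                rows.append(
                    {
                        "metric_class": metric_class,
                        "metric": f"state{state}",
                        "error": str(exc),
                    }
                )
                continue
            coef = res.coefficients.set_index("term")
            rows.append(
                {
                    "metric_class": metric_class,
                    "metric": f"state{state}",
                    "family": res.family,
                    "transform": res.transform,
                    "bonferroni_m": k,
                    "n_obs": res.n_obs,
                    "overall_stat": res.overall_stat,
                    "overall_p": res.overall_p,
                    "overall_p_corrected": res.overall_p_corrected,
                    "group_estimate": float(coef.loc["group_mtbi", "estimate"]),
                    "group_p": float(coef.loc["group_mtbi", "p"]),
                    "vif_max": float(res.vif.max()),
                    "accepted": res.accepted,
                }
            )
    return pd.DataFrame(rows)
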