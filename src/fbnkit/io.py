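"""Cohort readers/writers, run configuration, and pipeline orchestration."""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortSpec, SubjectTimeSeries, generate_cohort, write_cohort
from .evaluate import ClassifierSpec, EvaluationReport, loocv_evaluate, selection_reports
from .graph import feature_table

__all__ = ["RunConfig", "read_cohort", "run_pipeline"]


def read_cohort(manifest_path: str | Path) -> tuple[list[SubjectTimeSeries], np.ndarray]:
    """Load a cohort from a manifest TSV (subject_id, path, group).

    Paths are resolved relative to the manifest's directory.  All subjects
    must share an identical region header; shape or parsing problems raise
    with the offending subject named.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, sep="\t")
    required = {"subject_id", "path", "group"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    subjects: list[SubjectTimeSeries] = []
    labels: list[int] = []
    header: tuple[str, ...] | None = None
    for row in manifest.itertuples(index=False):
        path = Path(row.path)
        if not path.is_absolute():
            path = manifest_path.parent / path
        if not path.exists():
            raise FileNotFoundError(f"subject {row.subject_id}: missing file {path}")
        try:
            df = pd.read_csv(path, sep="\t", float_precision="round_trip")
            data = df.to_numpy(dtype=float)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"subject {row.subject_id}: non-numeric data in {path}") from exc
        labels_here = tuple(map(str, df.columns))
        if header is None:
            header = labels_here
        elif labels_here != header:
            raise ValueError(
                f"subject {row.subject_id}: region header mismatch "
                f"({len(labels_here)} regions vs {len(header)} expected)"
            )
        subjects.append(
            SubjectTimeSeries(
                data=data,
                region_labels=labels_here,
                subject_id=str(row.subject_id),
                group=int(row.group),
            )
        )
        labels.append(int(row.group))
    return subjects, np.asarray(labels, dtype=int)


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run."""

    manifest: str | None = None
    synthetic: CohortSpec | None = None
    model: str = "sparse_lowrank"
    lam1: float = 1.0
    lam2: float = 1.0
    lam: float = 1.0
    binarize_method: str | None = None
    pearson_density: float = 0.2
    candidate_counts: tuple[int, ...] = tuple(range(1, 151))
    classifier_C: float = 1.0
    out_dir: str = "fbnkit_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(raw.get("synthetic"), dict):
            raw["synthetic"] = CohortSpec(**raw["synthetic"])
        if "candidate_counts" in raw:
            raw["candidate_counts"] = tuple(raw["candidate_counts"])
        return cls(**raw)

    def params(self) -> dict:
        if self.model == "sparse":
            return {"lam": self.lam}
        if self.model in ("slr", "sparse_lowrank"):
            return {"lam1": self.lam1, "lam2": self.lam2}
        return {}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = dataclasses.asdict(self.synthetic)
        d["candidate_counts"] = list(self.candidate_counts)
        return d


def run_pipeline(config: RunConfig) -> EvaluationReport:
    """Construct -> extract -> select -> classify, with artifacts on disk.

    Writes per-subject feature table, the evaluation report, selection
    reports, and a provenance record (config + seed + versions) to
    ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.manifest is not None:
        subjects, labels = read_cohort(config.manifest)
    elif config.synthetic is not None:
        spec = dataclasses.replace(config.synthetic, seed=config.seed)
        subjects, labels = generate_cohort(spec)
        write_cohort(subjects, labels, out / "cohort")
    else:
        raise ValueError("config needs either a manifest or a synthetic cohort spec")

    from .evaluate import cohort_features
    from .graph import FeatureVector

    features = cohort_features(
        subjects,
        model=config.model,
        params=config.params(),
        binarize_method=config.binarize_method,
        density=config.pearson_density,
    )
    m = subjects[0].n_regions
    fvs = [
        FeatureVector(values=row, m=m, subject_id=s.subject_id)
        for row, s in zip(features, subjects)
    ]
    feature_table(fvs, list(subjects[0].region_labels)).to_csv(
        out / "features.tsv", sep="\t"
    )

    report = loocv_evaluate(
        subjects,
        labels,
        model=config.model,
        params=config.params(),
        classifier=ClassifierSpec(C=config.classifier_C),
        candidate_counts=config.candidate_counts,
        binarize_method=config.binarize_method,
        density=config.pearson_density,
        features=features,
    )
    report.to_json(out / "report.json")
    pd.DataFrame([{**vars(report.confusion), **report.metrics}]).to_csv(
        out / "metrics.tsv", sep="\t", index=False
    )
    props, counts = selection_reports(report, m, list(subjects[0].region_labels))
    props.to_csv(out / "selected_kind_proportions.tsv", sep="\t")
    counts.to_csv(out / "region_selection_counts.tsv", sep="\t")

    provenance = {
        "config": config.to_dict(),
        "seed": config.seed,
        "versions": {
            "fbnkit": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
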