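"""End-to-end orchestration: per-subject segmentation -> volumetry -> cohort
assembly -> optional statistics, driven by one declarative run config."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as aio
from .errors import AdiposegError, ConfigurationError
from .segmentation import SegmentationParams, segment_stack
from .stats import derive_measures, run_table2_analysis
from .volumetry import DEFAULT_WINDOW, compute_volumes

__all__ = ["SubjectSpec", "RunConfig", "PipelineSummary", "run_pipeline", "load_run_config"]


@dataclass
class SubjectSpec:
    subject_id: str
    image: Path
    edits: Path | None = None


@dataclass
class StatsOptions:
    predictors: list[str]
    outcomes: list[str]
    covariates: list[str] = field(default_factory=list)
    q: float = 0.05
    correct: bool = True
    stratify_by: str | None = None
    method: str = "spearman_partial"


@dataclass
class RunConfig:
    subjects: list[SubjectSpec]
    out_dir: Path
    params: SegmentationParams = field(default_factory=SegmentationParams)
    slice_window: tuple[int, int] = DEFAULT_WINDOW
    extra_table: Path | None = None
    id_column: str = "subject_id"
    glucose_unit: str = "mg/dL"
    stats: StatsOptions | None = None
    seed: int = 0
    fail_fast: bool = False

    def __post_init__(self) -> None:
        first, last = self.slice_window
        if first < 1 or last < first:
            raise ConfigurationError(f"slice_window: invalid window ({first}, {last})")
        if self.stats is not None and not (0 < self.stats.q < 1):
            raise ConfigurationError("stats.q: must lie in (0, 1)")
        for s in self.subjects:
            if not Path(s.image).exists():
                raise ConfigurationError(f"subjects[{s.subject_id}].image: {s.image} not found")
            if s.edits is not None and not Path(s.edits).exists():
                raise ConfigurationError(f"subjects[{s.subject_id}].edits: {s.edits} not found")
        if self.extra_table is not None and not Path(self.extra_table).exists():
            raise ConfigurationError(f"extra_table: {self.extra_table} not found")


@dataclass
class PipelineSummary:
    n_succeeded: int
    n_failed: int
    failures: list[tuple[str, str, str]]  # (subject, stage, message)
    cohort_path: Path | None
    stats_path: Path | None

    @property
    def exit_status(self) -> int:
        return 0 if self.n_failed == 0 else 2


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (paths relative to the file)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    base = path.parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    try:
        subjects = [
            SubjectSpec(
                subject_id=str(rec["id"]),
                image=resolve(rec["image"]),
                edits=resolve(rec["edits"]) if rec.get("edits") else None,
            )
            for rec in raw["subjects"]
        ]
        out_dir = resolve(raw["out_dir"])
    except KeyError as exc:
        raise ConfigurationError(f"{path}: missing required config key {exc}") from None
    params = SegmentationParams(**raw.get("segmentation", {}))
    stats = None
    if "stats" in raw:
        stats = StatsOptions(**raw["stats"])
    window = tuple(raw.get("slice_window", DEFAULT_WINDOW))
    return RunConfig(
        subjects=subjects,
        out_dir=out_dir,
        params=params,
        slice_window=window,  # type: ignore[arg-type]
        extra_table=resolve(raw["extra_table"]) if raw.get("extra_table") else None,
        id_column=raw.get("id_column", "subject_id"),
        glucose_unit=raw.get("glucose_unit", "mg/dL"),
        stats=stats,
        seed=int(raw.get("seed", 0)),
        fail_fast=bool(raw.get("fail_fast", False)),
    )


def run_pipeline(config: RunConfig) -> PipelineSummary:
    """Read -> normalize -> torso -> fat -> split -> edits -> volumes per
    subject, then assemble the cohort table and (optionally) run statistics.

    A failing subject is quarantined (recorded, skipped) unless
    ``fail_fast``; the summary reports succeeded/failed counts, and the exit
    status is non-zero when any subject failed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    failures: list[tuple[str, str, str]] = []

    for subject in config.subjects:
        stage = "read"
        try:
            stack = aio.read_image(subject.image)
            stage = "segment"
            edits = aio.read_edit_script(subject.edits) if subject.edits else None
            result = segment_stack(stack, config.params, edits=edits)
            stage = "volumes"
            report = compute_volumes(result, stack, window=config.slice_window)
            stage = "write"
            aio.write_masks(result, stack, out_dir / "subjects" / subject.subject_id,
                            seed=config.seed)
            rows.append(
                {
                    config.id_column: subject.subject_id,
                    "sat_cm3": report.sat_cm3,
                    "vat_cm3": report.vat_cm3,
                    "vat_sat_ratio": report.vat_sat_ratio,
                }
            )
        except (AdiposegError, OSError) as exc:
            failures.append((subject.subject_id, stage, str(exc)))
            if config.fail_fast:
                break

    cohort_path = None
    stats_path = None
    if rows:
        cohort = pd.DataFrame(rows)
        if config.extra_table is not None:
            extra = aio.read_cohort(config.extra_table)
            extra[config.id_column] = extra[config.id_column].astype(str)
            cohort = cohort.merge(extra, on=config.id_column, how="left")
        cohort = derive_measures(cohort, glucose_unit=config.glucose_unit)
        cohort_path = aio.write_cohort(cohort, out_dir / "cohort.csv")
        if config.stats is not None:
            so = config.stats
            table = run_table2_analysis(
                cohort,
                predictors=so.predictors,
                outcomes=so.outcomes,
                covariates=so.covariates,
                q=so.q,
                correct=so.correct,
                stratify_by=so.stratify_by,
                method=so.method,
            )
            stats_path = out_dir / "stats.csv"
            table.to_csv(stats_path, index=False)

    return PipelineSummary(
        n_succeeded=len(rows),
        n_failed=len(failures),
        failures=failures,
        cohort_path=cohort_path,
        stats_path=stats_path,
    )
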