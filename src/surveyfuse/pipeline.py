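"""End-to-end pipeline: simulate -> anchors -> fuse -> analyze -> report.

Every stage draws its seed deterministically from one master seed (by
stable hashing of the stage name, so adding a stage never perturbs the
others' streams), and a run manifest records the configuration hash,
per-stage seeds and artifact checksums, which together determine
re-runnability of the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .analysis import format_report, make_report, run_pair_analysis
from .partial_correlation import anchor_estimates
from .scales import apply_outcome_coding, codings_from_codebook
from .survey import CodebookError, SurveyFrame, check_shared_covariates
from .synthetic import (
    EXPOSURES,
    OUTCOMES,
    N_FILE_A,
    N_TOTAL,
    PopulationConfig,
    SplitSpec,
    generate_population,
    split_surveys,
    write_fixture,
)

logger = logging.getLogger("surveyfuse")


class PipelineError(RuntimeError):
    pass


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed derived by stable hashing of the stage name."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (mirrors the YAML schema)."""

    n_population: int = N_TOTAL
    measurement: str = "likert"
    frac_A: float = N_FILE_A / N_TOTAL
    composition_drift: dict = field(default_factory=dict)
    pairs: list = field(default_factory=lambda: [
        [e, o] for e in EXPOSURES for o in OUTCOMES
    ])
    rho_mode: str = "relative"
    weight_scheme: str = "equal-share"
    stochastic: bool = False
    covariate_set: str = "full"
    master_seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    stage_seeds: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _log_stage(log_path: Path | None, stage: str, **info):
    logger.info("stage %s: %s", stage, info)
    if log_path is not None:
        with log_path.open("a") as fh:
            fh.write(json.dumps({"stage": stage, "time": time.time(), **info}) + "\n")


def coded_outcomes(frame: SurveyFrame) -> SurveyFrame:
    """Apply the codebook's outcome codings, turning any labelled outcome
    columns numeric (numeric codes pass through)."""
    codings = codings_from_codebook(frame.codebook)
    if not codings:
        return frame
    data = apply_outcome_coding(frame.data, codings)
    return SurveyFrame(data=data, codebook=frame.codebook, name=frame.name)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute the full pipeline and write all artifacts under out_dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run_log.jsonl"
    log_path.write_text("")
    manifest = RunManifest(config_hash=config.config_hash(), master_seed=config.master_seed)

    def finish_stage(stage, **info):
        manifest.timestamps[stage] = time.time()
        _log_stage(log_path, stage, **info)

    try:
        # simulate
        seed = stage_seed(config.master_seed, "simulate")
        manifest.stage_seeds["simulate"] = seed
        pop_config = PopulationConfig(
            n_population=config.n_population,
            measurement=config.measurement,
            seed=seed,
        )
        population, truth = generate_population(pop_config)
        manifest.stage_seeds["split"] = stage_seed(config.master_seed, "split")
        A, B = split_surveys(
            population,
            SplitSpec(
                frac_A=config.frac_A,
                composition_drift=dict(config.composition_drift),
                seed=manifest.stage_seeds["split"],
            ),
        )
        paths = write_fixture({"file_A": A, "file_B": B}, out_dir / "fixtures")
        finish_stage("simulate", n_A=len(A), n_B=len(B))

        # anchors
        proxies = {
            (e, o): f"proxy_{o}" for e, o in (tuple(p) for p in config.pairs)
        }
        anchors = anchor_estimates(B, proxies)
        anchor_rows = [
            {"exposure": e, "outcome": o, "anchor": r}
            for (e, o), r in anchors.items()
        ]
        pd.DataFrame(anchor_rows).to_csv(out_dir / "anchors.csv", index=False)
        finish_stage("anchors", n_pairs=len(anchors))

        # fuse + analyze per pair
        A = coded_outcomes(A)
        pooled = []
        fuse_seed = stage_seed(config.master_seed, "fuse")
        for e, o in (tuple(p) for p in config.pairs):
            est = run_pair_analysis(
                A, B, e, o, anchors[(e, o)],
                covariate_set=config.covariate_set,
                rho_mode=config.rho_mode,
                scheme=config.weight_scheme,
                stochastic=config.stochastic,
                seed=fuse_seed,
            )
            pooled.append(est)
        finish_stage("analyze", n_estimates=len(pooled))

        # report
        report = make_report(pooled)
        report.to_csv(out_dir / "report.csv", index=False)
        (out_dir / "report.txt").write_text(format_report(report))
        finish_stage("report", rows=len(report))
    except Exception as exc:  # halt with stage context
        raise PipelineError(f"pipeline failed: {exc}") from exc

    for p in sorted(out_dir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest.artifacts[str(p.relative_to(out_dir))] = _checksum(p)
    manifest.save(out_dir / "manifest.json")
    return manifest


def validate_inputs(
    file_a: str | Path, file_b: str | Path
) -> list[str]:
    """Validate a two-file fixture: role tags, level sets, and
    demographic-codebook equality across files.  Returns the issue list
    (empty when well formed)."""
    issues: list[str] = []
    frames = {}
    for label, path in (("file_A", file_a), ("file_B", file_b)):
        try:
            frames[label] = SurveyFrame.load(path, name=label)
        except (CodebookError, FileNotFoundError, KeyError) as exc:
            issues.append(f"{label}: {exc}")
    if len(frames) == 2:
        try:
            check_shared_covariates(frames["file_A"], frames["file_B"])
        except CodebookError as exc:
            issues.append(str(exc))
        if not frames["file_A"].columns_by_role("outcome"):
            issues.append("file_A declares no outcome variables")
        if not frames["file_B"].columns_by_role("exposure_score", "exposure_item"):
            issues.append("file_B declares no exposure variables")
    return issues
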