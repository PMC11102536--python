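"""End-to-end orchestration: simulate -> align/measure -> metrics -> analyze.

A run is reproducible from (config, seed): the global seed fans out to
per-case subseeds through ``numpy.random.SeedSequence`` keyed by stable
(seed, stage, case-index) tuples, so adding cases never reshuffles existing
ones.  Every stage writes its artifacts under the run directory and a
manifest of content digests is emitted at the end.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, StageError
from .outcome_metrics import DEFAULT_CUTOFF_DEG, build_records, records_to_frame
from .rotation_measure import (
    RegistrationSettings,
    fit_case,
    measure_case,
    measurements_from_frame,
    measurements_to_frame,
)
from .stats_report import build_report, digest_of
from .synthetic_arch import GeneratorConfig, emit_case, generate_arch, load_case

log = logging.getLogger("rotometry")

_SIM_STAGE, _MEASURE_STAGE = 1, 2


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "run"
    n_cases: int = 5
    arches: tuple = ("mandibular", "maxillary")
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides
    registration: dict = field(default_factory=dict)  # RegistrationSettings overrides
    cutoff_deg: float = DEFAULT_CUTOFF_DEG
    alpha: float = 0.05

    def validate(self) -> None:
        if self.n_cases < 1:
            raise InvalidInputError("n_cases must be >= 1")
        if not 0 < self.alpha < 1:
            raise InvalidInputError("alpha must lie in (0, 1)")
        if self.cutoff_deg < 0:
            raise InvalidInputError("cutoff_deg must be >= 0")
        for arch in self.arches:
            if arch not in ("mandibular", "maxillary"):
                raise InvalidInputError(f"unknown arch {arch!r}")
        # Fail fast on bad stage settings before any stage runs.
        self.registration_settings()
        bad = set(self.generator) - {
            f.name for f in dataclasses.fields(GeneratorConfig)
        }
        if bad:
            raise InvalidInputError(f"unknown generator settings: {sorted(bad)}")

    def registration_settings(self) -> RegistrationSettings:
        return RegistrationSettings(**self.registration)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        if "arches" in data:
            data["arches"] = tuple(data["arches"])
        return cls(**data)


def _case_seed(seed: int, stage: int, index: int) -> int:
    return int(np.random.SeedSequence((seed, stage, index)).generate_state(1)[0])


def _case_specs(config: RunConfig):
    i = 0
    for arch in config.arches:
        for k in range(config.n_cases):
            yield i, arch, f"{arch[:4]}-{k:03d}"
            i += 1


def simulate(config: RunConfig, out_dir: Path) -> list[Path]:
    """Generate and emit all synthetic cases; returns case directories."""
    dirs = []
    for i, arch, case_id in _case_specs(config):
        overrides = dict(config.generator)
        gen = GeneratorConfig(
            seed=_case_seed(config.seed, _SIM_STAGE, i),
            arch=arch,
            case_id=case_id,
            **overrides,
        )
        case, truth = generate_arch(gen)
        case_dir = out_dir / "cases" / case_id
        emit_case(case, truth, case_dir)
        dirs.append(case_dir)
        log.info("simulate: wrote %s", case_dir)
    return dirs


def measure_stage(config: RunConfig, out_dir: Path) -> Path:
    """Superimpose and measure every emitted case -> measurements.csv."""
    cases_root = out_dir / "cases"
    if not cases_root.is_dir():
        raise StageError("measure", f"no cases directory at {cases_root}")
    settings = config.registration_settings()
    frames, quarantine = [], []
    for case_dir in sorted(cases_root.iterdir()):
        if not (case_dir / "case.json").exists():
            continue
        case, _ = load_case(case_dir)
        fits = fit_case(case, settings)
        for frame in ("T1", "T2"):
            g = fits.global_fit[frame]
            (case_dir / f"global_fit_{frame}.json").write_text(
                json.dumps(
                    {
                        **g.transform.to_json_dict(),
                        "rms_mm": g.rms_mm,
                        "iterations": g.iterations,
                    }
                )
            )
        measurements, problems = measure_case(case, fits)
        frames.append(measurements_to_frame(measurements))
        for frame, fdi, err in problems:
            quarantine.append(
                {"case_id": case.case_id, "frame": frame, "fdi": fdi, "error": err}
            )
            log.warning("measure: quarantined %s/%s tooth %s: %s",
                        case.case_id, frame, fdi, err)
    if not frames:
        raise StageError("measure", "no cases could be measured")
    df = pd.concat(frames, ignore_index=True)
    path = out_dir / "measurements.csv"
    df.to_csv(path, index=False)
    (out_dir / "quarantine.json").write_text(json.dumps(quarantine, indent=2))
    return path


def metrics_stage(config: RunConfig, out_dir: Path) -> Path:
    """Derive per-tooth outcome records -> records.csv."""
    m_path = out_dir / "measurements.csv"
    if not m_path.exists():
        raise StageError("metrics", f"missing measurements file {m_path}")
    measurements = measurements_from_frame(pd.read_csv(m_path))
    records = build_records(measurements, cutoff_deg=config.cutoff_deg)
    path = out_dir / "records.csv"
    records_to_frame(records).to_csv(path, index=False)
    return path


def analyze_stage(config: RunConfig, out_dir: Path) -> dict:
    """Statistical report -> report/ CSVs + metadata."""
    r_path = out_dir / "records.csv"
    if not r_path.exists():
        raise StageError("analyze", f"missing records file {r_path}")
    from .outcome_metrics import records_from_frame

    records = records_from_frame(pd.read_csv(r_path))
    return build_report(
        records,
        out_dir / "report",
        alpha=config.alpha,
        seed=config.seed,
        config_digest=digest_of(dataclasses.asdict(config)),
    )


def _digest_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in order; returns the run directory.

    Per-tooth failures are quarantined without aborting; a missing upstream
    artifact aborts with a :class:`StageError` naming the stage.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    completed = []
    manifest = {"config_digest": digest_of(dataclasses.asdict(config)), "stages": {}}
    try:
        simulate(config, out_dir)
        completed.append("simulate")
        measure_stage(config, out_dir)
        completed.append("measure")
        metrics_stage(config, out_dir)
        completed.append("metrics")
        analyze_stage(config, out_dir)
        completed.append("analyze")
    finally:
        artifacts = {}
        for pattern in ("measurements.csv", "records.csv", "report/*.csv"):
            for p in sorted(out_dir.glob(pattern)):
                artifacts[str(p.relative_to(out_dir))] = _digest_file(p)
        manifest["stages"] = {"completed": completed}
        manifest["artifacts"] = artifacts
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out_dir
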