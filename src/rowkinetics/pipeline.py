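"""End-to-end workflows: simulate -> preprocess -> targets -> features ->
train -> evaluate, plus the default synthetic benchmarks.

The default ergometer benchmark is 12 subjects x 80 cycles at 20 strokes/min.
Sessions are generated at 50 Hz for network training and evaluation (the
stroke signal lives well below 10 Hz, so this preserves the waveform content
while keeping desk-scale training times); the generator's native rates
(150 Hz ergometer, 100 Hz boat) remain the defaults elsewhere.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import synthetic
from .datamodel import ERGO_CONDITION, write_session
from .model import (
    CycleDataset,
    KineticsEstimationResults,
    LoovResults,
    NetworkConfig,
    RowingKineticsModel,
    TrainConfig,
    dataset_from_sessions,
)

logger = logging.getLogger("rowkinetics")

BENCHMARK_SUBJECTS = 12
BENCHMARK_CYCLES = 80
BENCHMARK_SAMPLE_RATE_HZ = 50.0
BENCHMARK_UNITS = 64
BENCHMARK_SPLIT_EPOCHS = 120
BENCHMARK_LOOV_EPOCHS = 25


def subject_seed(base_seed: int, index: int) -> int:
    """Deterministic per-subject seed derived from one base seed."""
    return (base_seed * 1009 + index * 101) % (2**31 - 1)


def make_sessions(
    condition: str = ERGO_CONDITION,
    n_subjects: int = BENCHMARK_SUBJECTS,
    n_cycles: int = BENCHMARK_CYCLES,
    seed: int = 1,
    sample_rate_hz: float = BENCHMARK_SAMPLE_RATE_HZ,
    noise_sd: float = 1.0,
    arm_fault_prob: float = 0.0,
) -> list[synthetic.SimulatedSession]:
    """Simulate one session per subject under the benchmark conditions."""
    sessions = []
    for i in range(n_subjects):
        profile, params = synthetic.sample_subject(
            condition, subject_seed(seed, i), arm_fault_prob=arm_fault_prob,
            noise_sd=noise_sd,
        )
        sessions.append(
            synthetic.simulate_session(
                profile, params, n_cycles, sample_rate_hz=sample_rate_hz
            )
        )
        logger.info("simulated %s: %d cycles", profile.subject_id, n_cycles)
    return sessions


def benchmark_dataset(seed: int = 1, **kwargs) -> CycleDataset:
    """The default synthetic ergometer benchmark as a ready CycleDataset."""
    return dataset_from_sessions(make_sessions(seed=seed, **kwargs))


@dataclass
class BenchmarkResult:
    """Outcome of the split + leave-one-out benchmark run."""

    split: KineticsEstimationResults
    loov: LoovResults | None

    @property
    def split_mae_norm_pct(self) -> float:
        return self.split.evaluate().mean_mae_norm_pct

    @property
    def loov_mae_norm_pct(self) -> float | None:
        return None if self.loov is None else self.loov.mean_mae_norm_pct

    def to_dict(self) -> dict:
        out = {"split": self.split.evaluate().to_dict()}
        if self.loov is not None:
            out["loov"] = {
                "per_target": self.loov.aggregate.round(6).to_dict(orient="index"),
                "mean_MAE_norm_pct": round(self.loov.mean_mae_norm_pct, 6),
            }
        return out


def run_benchmark(
    dataset: CycleDataset,
    seed: int = 1,
    units: int = BENCHMARK_UNITS,
    dropout: float = 0.0,
    split_epochs: int = BENCHMARK_SPLIT_EPOCHS,
    loov_epochs: int | None = BENCHMARK_LOOV_EPOCHS,
) -> BenchmarkResult:
    """Train the 80/20-split model and (optionally) the leave-one-out folds.

    The LOOV folds use a reduced epoch cap: the held-out-subject error is
    dominated by the generalization gap, not by late-epoch refinement.
    """
    net_cfg = NetworkConfig(n_inputs=dataset.n_inputs, lstm_units=units,
                            dropout=dropout, seed=seed)
    split_cfg = TrainConfig(max_epochs=split_epochs, seed=seed,
                            patience_epochs=min(20, split_epochs - 1))
    model = RowingKineticsModel(dataset, net_cfg, split_cfg)
    logger.info("training 80/20 split model (%d cycles)", len(dataset))
    split_res = model.fit()
    loov_res = None
    if loov_epochs is not None:
        loov_cfg = TrainConfig(max_epochs=loov_epochs,
                               patience_epochs=min(20, loov_epochs - 1), seed=seed)
        logger.info("running leave-one-out over %d subjects", len(dataset.subjects))
        loov_res = model.fit_loov(loov_cfg)
    return BenchmarkResult(split=split_res, loov=loov_res)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (CLI-facing)."""

    condition: str = ERGO_CONDITION
    n_subjects: int = BENCHMARK_SUBJECTS
    n_cycles: int = BENCHMARK_CYCLES
    sample_rate_hz: float = BENCHMARK_SAMPLE_RATE_HZ
    seed: int = 1
    units: int = BENCHMARK_UNITS
    dropout: float = 0.0
    split_epochs: int = BENCHMARK_SPLIT_EPOCHS
    loov_epochs: int | None = BENCHMARK_LOOV_EPOCHS
    run_loov: bool = True
    noise_sd: float = 1.0
    out_dir: str = "rowkinetics_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate, train and evaluate; write the artifact tree and report.

    Artifacts: ``sessions/`` (CSV streams + truth), ``reports/report.json``.
    Returns the report dictionary.
    """
    out = Path(config.out_dir)
    sessions_dir = out / "sessions"
    reports_dir = out / "reports"
    reports_dir.mkdir(parents=True, exist_ok=True)
    sessions = make_sessions(
        condition=config.condition,
        n_subjects=config.n_subjects,
        n_cycles=config.n_cycles,
        seed=config.seed,
        sample_rate_hz=config.sample_rate_hz,
        noise_sd=config.noise_sd,
    )
    for sess in sessions:
        write_session(
            sessions_dir / sess.profile.subject_id,
            sess.streams, sess.profile, sess.true_targets, sess.cycles,
        )
    dataset = dataset_from_sessions(sessions)
    logger.info("dataset: %d cycles from %d subjects", len(dataset), config.n_subjects)
    result = run_benchmark(
        dataset,
        seed=config.seed,
        units=config.units,
        dropout=config.dropout,
        split_epochs=config.split_epochs,
        loov_epochs=config.loov_epochs if config.run_loov else None,
    )
    report = {
        "config": asdict(config),
        "n_cycles": len(dataset),
        **result.to_dict(),
    }
    (reports_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("report written to %s", reports_dir / "report.json")
    return report
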