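"""Loading sessions previously written to the CSV artifact layout."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .datamodel import (
    KineticTargets,
    RowingCycle,
    SensorStream,
    SubjectProfile,
    read_session,
    validate_session,
)


@dataclass
class LoadedSession:
    """A session read back from disk; duck-compatible with SimulatedSession."""

    profile: SubjectProfile
    streams: dict[str, SensorStream]
    cycles: list[RowingCycle]
    true_targets: list[KineticTargets]

    @property
    def condition(self) -> str:
        return self.profile.condition


def load_session(directory: str | Path) -> LoadedSession:
    directory = Path(directory)
    streams, profile = read_session(directory)
    issues = validate_session(streams, profile)
    if issues:
        raise ValueError(f"invalid session {directory.name}: {issues}")
    cycles_path = directory / "cycles.csv"
    cycles: list[RowingCycle] = []
    if cycles_path.exists():
        for row in pd.read_csv(cycles_path).itertuples():
            cycles.append(
                RowingCycle(
                    subject_id=str(row.subject_id),
                    start_idx=int(row.start_idx),
                    end_idx=int(row.end_idx),
                    catch_idx=int(row.catch_idx),
                    stroke_rate_spm=float(row.stroke_rate_spm),
                )
            )
    truth = [
        KineticTargets.from_matrix(
            pd.read_csv(p).drop(columns=["time_s"]).to_numpy(float)
        )
        for p in sorted((directory / "truth").glob("cycle_*.csv"))
    ] if (directory / "truth").is_dir() else []
    return LoadedSession(profile=profile, streams=streams, cycles=cycles, true_targets=truth)


def load_sessions(root: str | Path) -> list[LoadedSession]:
    root = Path(root)
    dirs = sorted(p for p in root.iterdir() if (p / "subject.json").exists())
    if not dirs:
        raise ValueError(f"no sessions found under {root}")
    return [load_session(p) for p in dirs]
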