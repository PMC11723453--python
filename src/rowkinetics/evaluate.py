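"""Performance metrics and technique determinants.

Errors are computed over the effective drive phase, interpolated to a
50-frame grid per cycle::

    MAE  = (1 / C T) * sum_c sum_t |y_tc - yhat_tc|
    cMAE = (1 / C T) * sum_t |sum_c (y_tc - yhat_tc)|

``cMAE`` is the error of the cycle-averaged curve on the same scale as MAE
(so cMAE <= MAE always).  Both are also expressed as a percentage of the
mean measured curve value over the drive grid.

Technique determinants are computed over the *entire* drive phase (catch to
finish), not the threshold-based effective drive window:

* T2P — peak instant as % of the phase,
* M2P — 100 x mean / max,
* WR  — 100 x (area under the curve before the peak) / (total area).

Whether estimated sequences preserve a rower's technique is quantified with
two-sample t-tests (pooled variance, alpha = 0.05) on the determinants:
intra-subject accuracy As (fraction of subjects where measured vs estimated
means are statistically indistinguishable) and inter-subject accuracy Ap
(fraction of subject pairs where the measured-vs-measured and
estimated-vs-estimated test decisions agree).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import TARGET_NAMES

DRIVE_GRID_FRAMES = 50
ALPHA = 0.05

DETERMINANT_NAMES = ["T2P", "M2P", "WR"]


class EvaluationError(ValueError):
    pass


def interp_drive_grid(seq: np.ndarray, n_frames: int = DRIVE_GRID_FRAMES) -> np.ndarray:
    """Linearly interpolate a drive-phase slice onto ``n_frames`` even frames."""
    seq = np.asarray(seq, float)
    if len(seq) < 2:
        raise EvaluationError("drive window must contain at least 2 samples")
    x_new = np.linspace(0.0, len(seq) - 1.0, n_frames)
    return np.interp(x_new, np.arange(len(seq)), seq)


def mae_cmae(measured: np.ndarray, estimated: np.ndarray) -> tuple[float, float]:
    """MAE and cMAE over a (C cycles, T frames) pair of curve stacks."""
    measured = np.atleast_2d(np.asarray(measured, float))
    estimated = np.atleast_2d(np.asarray(estimated, float))
    if measured.shape != estimated.shape:
        raise EvaluationError("measured and estimated stacks must have equal shape")
    C, T = measured.shape
    if C == 0:
        raise EvaluationError("need at least one cycle")
    resid = measured - estimated
    mae = float(np.abs(resid).sum() / (C * T))
    cmae = float(np.abs(resid.sum(axis=0)).sum() / (C * T))
    return mae, cmae


def normalize_error(err: float, measured: np.ndarray, eps: float = 1e-9) -> float:
    """Express an error as a percentage of the mean measured curve value."""
    mean_v = float(np.mean(measured))
    if abs(mean_v) < eps:
        raise EvaluationError("degenerate_normalizer")
    return 100.0 * err / mean_v


@dataclass(frozen=True)
class Determinants:
    """Technique determinants of one curve, all in percent."""

    T2P: float
    M2P: float
    WR: float

    def as_array(self) -> np.ndarray:
        return np.array([self.T2P, self.M2P, self.WR])


def determinants(seq: np.ndarray) -> Determinants:
    """T2P / M2P / WR of a catch-to-finish curve.

    Plateau peaks resolve to the first index of the maximum.  Raises on
    curves with no positive peak ("no_peak").
    """
    seq = np.asarray(seq, float)
    if len(seq) < 2:
        raise EvaluationError("curve too short")
    peak = float(seq.max())
    if peak <= 0:
        raise EvaluationError("no_peak")
    k = int(np.argmax(seq))
    t2p = 100.0 * k / (len(seq) - 1)
    # clamp away float rounding overshoot (e.g. mean/max of a flat curve)
    m2p = min(100.0 * float(seq.mean()) / peak, 100.0)
    total_area = float(np.trapezoid(seq))
    if total_area <= 0:
        raise EvaluationError("no_peak")
    area_before = float(np.trapezoid(seq[: k + 1])) if k > 0 else 0.0
    wr = min(100.0 * area_before / total_area, 100.0)
    return Determinants(T2P=t2p, M2P=m2p, WR=wr)


def _ttest(a: np.ndarray, b: np.ndarray, welch: bool = False) -> float:
    return float(stats.ttest_ind(a, b, equal_var=not welch).pvalue)


def intra_subject_accuracy(
    measured: dict[str, np.ndarray],
    estimated: dict[str, np.ndarray],
    alpha: float = ALPHA,
    welch: bool = False,
) -> tuple[float, dict[str, bool]]:
    """Intra-subject accuracy As.

    For each subject, test whether the determinant means from measured and
    estimated sequences differ; HA = subjects where the null (equal means)
    is NOT rejected.  As = 100 * HA / (HA + HR).  Returns (As, per-subject
    acceptance).  Subjects with fewer than 2 cycles are excluded.
    """
    decisions: dict[str, bool] = {}
    for subject, m in measured.items():
        e = estimated[subject]
        if len(m) < 2 or len(e) < 2:
            warnings.warn(f"subject {subject} has < 2 cycles; excluded", stacklevel=2)
            continue
        if np.array_equal(m, e):
            decisions[subject] = True  # identical samples: trivially accepted
            continue
        decisions[subject] = _ttest(m, e, welch) > alpha
    if not decisions:
        raise EvaluationError("no subjects with enough cycles")
    ha = sum(decisions.values())
    return 100.0 * ha / len(decisions), decisions


def inter_subject_accuracy(
    measured: dict[str, np.ndarray],
    estimated: dict[str, np.ndarray],
    alpha: float = ALPHA,
    welch: bool = False,
) -> tuple[float, dict[tuple[str, str], bool]]:
    """Inter-subject accuracy Ap.

    For every unordered subject pair, compare the reject/accept decision of
    the measured-vs-measured t-test with that of the estimated-vs-estimated
    test; CH = pairs with matching decisions.  Ap = 100 * CH / (CH + DH).
    """
    subjects = [s for s in measured if len(measured[s]) >= 2 and len(estimated[s]) >= 2]
    if len(subjects) < 2:
        raise EvaluationError("need >= 2 subjects with >= 2 cycles")
    agreement: dict[tuple[str, str], bool] = {}
    for s1, s2 in combinations(subjects, 2):
        rej_m = _ttest(measured[s1], measured[s2], welch) <= alpha
        rej_e = _ttest(estimated[s1], estimated[s2], welch) <= alpha
        agreement[(s1, s2)] = rej_m == rej_e
    ap = 100.0 * sum(agreement.values()) / len(agreement)
    return ap, agreement


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    """Per-target error metrics plus determinant and accuracy summaries.

    ``per_target`` is a DataFrame indexed by target name with columns
    MAE, cMAE, MAE_norm_pct, cMAE_norm_pct; ``determinant_mae`` holds the
    mean absolute determinant errors (percentage points) per target;
    accuracies are filled when subject-level analysis was run.
    """

    per_target: pd.DataFrame
    determinant_mae: pd.DataFrame | None = None
    intra_accuracy: dict[str, float] = field(default_factory=dict)
    inter_accuracy: dict[str, float] = field(default_factory=dict)
    n_cycles: int = 0

    @property
    def mean_mae_norm_pct(self) -> float:
        return float(self.per_target["MAE_norm_pct"].mean())

    @property
    def mean_cmae_norm_pct(self) -> float:
        return float(self.per_target["cMAE_norm_pct"].mean())

    def to_dict(self) -> dict:
        out = {
            "n_cycles": self.n_cycles,
            "per_target": self.per_target.round(6).to_dict(orient="index"),
            "mean_MAE_norm_pct": round(self.mean_mae_norm_pct, 6),
            "mean_cMAE_norm_pct": round(self.mean_cmae_norm_pct, 6),
            "intra_accuracy_pct": self.intra_accuracy,
            "inter_accuracy_pct": self.inter_accuracy,
        }
        if self.determinant_mae is not None:
            out["determinant_mae_pct"] = self.determinant_mae.round(6).to_dict(orient="index")
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def summary(self) -> str:
        lines = [
            "Reconstruction error over the effective drive phase "
            f"({self.n_cycles} cycles, 50-frame grid)",
            self.per_target.round(3).to_string(),
            f"mean MAE_norm  = {self.mean_mae_norm_pct:.2f}%",
            f"mean cMAE_norm = {self.mean_cmae_norm_pct:.2f}%",
        ]
        if self.determinant_mae is not None:
            lines += ["", "Determinant MAE (percentage points):",
                      self.determinant_mae.round(3).to_string()]
        if self.inter_accuracy:
            mean_ap = float(np.mean(list(self.inter_accuracy.values())))
            lines.append(f"inter-subject technique accuracy Ap = {mean_ap:.1f}%")
        if self.intra_accuracy:
            mean_as = float(np.mean(list(self.intra_accuracy.values())))
            lines.append(f"intra-subject technique accuracy As = {mean_as:.1f}%")
        return "\n".join(lines)


def evaluate_cycles(
    measured_grids: dict[str, np.ndarray],
    estimated_grids: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Per-target MAE/cMAE (raw and normalized) from (C, 50) grid stacks."""
    rows = {}
    for name in TARGET_NAMES:
        m, e = measured_grids[name], estimated_grids[name]
        mae, cmae = mae_cmae(m, e)
        rows[name] = {
            "MAE": mae,
            "cMAE": cmae,
            "MAE_norm_pct": normalize_error(mae, m),
            "cMAE_norm_pct": normalize_error(cmae, m),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
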