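"""The sequence-to-sequence LSTM estimator: configuration, training,
hyperparameter search, leave-one-subject-out validation, and a
Model/Results front-end.

The intended entry point mirrors the statsmodels idiom::

    model = RowingKineticsModel.from_sessions(sessions)
    res = model.fit()            # 80/20 split, early stopping
    print(res.summary())
    report = res.evaluate()      # drive-phase MAE/cMAE, determinants, Ap/As

Cycles are variable-length sequences in absolute time (never
time-normalized); features and targets are z-normalized with statistics
fitted on the training cycles only, and predictions are de-normalized
before any metric is computed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evaluate as ev
from . import kinetics, nn
from .datamodel import TARGET_NAMES, RowingCycle
from .features import NormStats, build_session_features, fit_norm
from .synthetic import SimulatedSession

SEARCH_UNITS_MIN = 10
SEARCH_UNITS_MAX = 500
SEARCH_DROPOUTS = (0.0, 0.05, 0.10)


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------

@dataclass
class CycleRecord:
    """One rowing cycle ready for the network.

    ``X`` raw features (T, n_inputs); ``Y`` measured targets (T, 6);
    ``drive_rel`` the effective drive window and ``catch_rel`` the catch
    index, both relative to the cycle start.
    """

    subject_id: str
    X: np.ndarray
    Y: np.ndarray
    drive_rel: tuple[int, int]
    catch_rel: int
    sample_rate_hz: float

    def __len__(self) -> int:
        return self.X.shape[0]


@dataclass
class CycleDataset:
    records: list[CycleRecord]
    feature_names: list[str]
    condition: str

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_inputs(self) -> int:
        return len(self.feature_names)

    @property
    def subjects(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.subject_id, None)
        return list(seen)

    def by_subject(self) -> dict[str, list[int]]:
        groups: dict[str, list[int]] = {}
        for i, r in enumerate(self.records):
            groups.setdefault(r.subject_id, []).append(i)
        return groups


def dataset_from_sessions(
    sessions: list[SimulatedSession],
    smooth_cutoff_hz: float | None = 8.0,
) -> CycleDataset:
    """Build a CycleDataset from simulated (or loaded) sessions.

    Measured targets are recomputed from the emitted streams through the
    kinetics pipeline (with optional velocity pre-smoothing against
    measurement noise); features are the condition's kinematic channel set.
    The first cycle of each session is dropped (previous-stroke scalars are
    undefined there).
    """
    if not sessions:
        raise ModelError("no sessions given")
    condition = sessions[0].condition
    records: list[CycleRecord] = []
    feature_names: list[str] | None = None
    for sess in sessions:
        channels = kinetics.session_target_channels(
            sess.streams, condition, smooth_cutoff_hz=smooth_cutoff_hz
        )
        force = channels["Fh_x"]
        cycles = [replace_drive(c) for c in sess.cycles]
        kept, feats = build_session_features(
            sess.streams, cycles, sess.profile, force, smooth_cutoff_hz
        )
        fs = (sess.streams["ergo"] if condition == "ergometer" else sess.streams["boat"]).sample_rate_hz
        for cyc, feat in zip(kept, feats):
            if feature_names is None:
                feature_names = feat.channels
            Y = np.column_stack(
                [channels[name][cyc.start_idx : cyc.end_idx] for name in TARGET_NAMES]
            )
            records.append(
                CycleRecord(
                    subject_id=sess.profile.subject_id,
                    X=feat.values,
                    Y=Y,
                    drive_rel=(cyc.drive_start_idx - cyc.start_idx,
                               cyc.drive_end_idx - cyc.start_idx),
                    catch_rel=cyc.catch_idx - cyc.start_idx,
                    sample_rate_hz=fs,
                )
            )
    if feature_names is None:
        raise ModelError("sessions produced no usable cycles")
    return CycleDataset(records=records, feature_names=feature_names, condition=condition)


def replace_drive(c: RowingCycle) -> RowingCycle:
    """Copy a cycle with the drive window cleared (it is re-detected)."""
    return RowingCycle(
        subject_id=c.subject_id, start_idx=c.start_idx, end_idx=c.end_idx,
        catch_idx=c.catch_idx, stroke_rate_spm=c.stroke_rate_spm,
        scalars=dict(c.scalars),
    )


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters of the dense-LSTM-dense stack."""

    n_inputs: int
    lstm_units: int = 64
    dropout: float = 0.0
    n_outputs: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_outputs != 6:
            raise ModelError("the estimator reconstructs exactly 6 target sequences")
        if not (SEARCH_UNITS_MIN <= self.lstm_units <= SEARCH_UNITS_MAX):
            raise ModelError(
                f"lstm_units must lie in [{SEARCH_UNITS_MIN}, {SEARCH_UNITS_MAX}]"
            )


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings: Adam, lr 1e-3, minibatch 32, patience 20."""

    max_epochs: int = 10_000
    learning_rate: float = 1e-3
    minibatch: int = 32
    patience_epochs: int = 20
    seed: int = 0
    split_fraction: float = 0.2
    stratify_by_subject: bool = True

    def __post_init__(self) -> None:
        if self.patience_epochs >= self.max_epochs:
            raise ModelError("patience must be smaller than max_epochs")


def build_network(cfg: NetworkConfig) -> nn.LSTMRegressor:
    """Instantiate the untrained dense -> LSTM -> dropout -> dense stack."""
    if cfg.n_inputs not in (16, 18):
        warnings.warn(
            f"n_inputs={cfg.n_inputs} is neither the 16-channel ergometer nor "
            "the 18-channel boat feature set", stacklevel=2,
        )
    return nn.LSTMRegressor(
        n_in=cfg.n_inputs, units=cfg.lstm_units, n_out=cfg.n_outputs,
        dropout=cfg.dropout, seed=cfg.seed,
    )


def lstm_param_count(n_inputs: int, units: int) -> int:
    """Closed-form parameter count of a single LSTM layer (fused biases)."""
    return 4 * ((n_inputs + units) * units + units)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """Weights from the best validation epoch plus the training history."""

    weights: dict[str, np.ndarray]
    network_config: NetworkConfig
    norm: NormStats
    history: pd.DataFrame  # columns: train_loss, val_rmse
    best_epoch: int

    def network(self) -> nn.LSTMRegressor:
        net = build_network(self.network_config)
        net.set_weights(self.weights)
        return net


def _length_sorted_batches(
    lengths: np.ndarray, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Batch indices sorted by length (jittered ties), batch order shuffled."""
    order = np.argsort(lengths + rng.uniform(0, 0.5, len(lengths)), kind="stable")
    batches = [order[i : i + batch_size] for i in range(0, len(order), batch_size)]
    rng.shuffle(batches)
    return batches


def _forward_rmse(net: nn.LSTMRegressor, data: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Full-cycle RMSE (normalized units) over a list of (X, Y) cycles."""
    sq_sum, n = 0.0, 0
    for i in range(0, len(data), 64):
        chunk = data[i : i + 64]
        X, Y, mask = nn.pad_batch([c[0] for c in chunk], [c[1] for c in chunk])
        pred = net.forward(X)
        diff = (pred - Y) * mask[..., None]
        sq_sum += float((diff ** 2).sum())
        n += int(mask.sum()) * Y.shape[-1]
    return math.sqrt(sq_sum / n)


def train(
    net: nn.LSTMRegressor,
    train_data: list[tuple[np.ndarray, np.ndarray]],
    val_data: list[tuple[np.ndarray, np.ndarray]],
    cfg: TrainConfig,
    norm: NormStats,
    network_config: NetworkConfig,
) -> TrainedModel:
    """Adam training with early stopping on validation full-cycle RMSE.

    ``train_data`` / ``val_data`` are z-normalized (X, Y) pairs of
    variable length.  Any decrease of the validation RMSE counts as
    improvement; training stops once ``patience_epochs`` epochs pass without
    one, and the best-epoch weights are returned.
    """
    if not val_data:
        raise ModelError("validation set is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(lr=cfg.learning_rate)
    lengths = np.array([len(x) for x, _ in train_data], float)
    history = []
    best_rmse = math.inf
    best_weights = net.get_weights()
    best_epoch = -1
    since_improve = 0
    for epoch in range(cfg.max_epochs):
        epoch_loss, n_batches = 0.0, 0
        for batch_idx in _length_sorted_batches(lengths, cfg.minibatch, rng):
            X, Y, mask = nn.pad_batch(
                [train_data[i][0] for i in batch_idx],
                [train_data[i][1] for i in batch_idx],
            )
            pred, cache = net.forward(X, train=True, rng=rng, want_cache=True)
            loss, dY = nn.masked_mse_and_grad(pred, Y, mask)
            grads = net.backward(cache, dY)
            opt.step(net.params, grads)
            epoch_loss += loss
            n_batches += 1
        val_rmse = _forward_rmse(net, val_data)
        history.append({"train_loss": epoch_loss / n_batches, "val_rmse": val_rmse})
        if val_rmse < best_rmse:
            best_rmse = val_rmse
            best_weights = net.get_weights()
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if since_improve >= cfg.patience_epochs:
                break
    net.set_weights(best_weights)
    return TrainedModel(
        weights=best_weights,
        network_config=network_config,
        norm=norm,
        history=pd.DataFrame(history),
        best_epoch=best_epoch,
    )


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def split_indices(
    dataset: CycleDataset, cfg: TrainConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Random train/validation split by cycle, stratified by subject."""
    rng = np.random.default_rng(cfg.seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    if cfg.stratify_by_subject:
        groups = dataset.by_subject().values()
    else:
        groups = [list(range(len(dataset)))]
    for idxs in groups:
        idxs = np.array(idxs)
        rng.shuffle(idxs)
        n_val = max(1, int(round(cfg.split_fraction * len(idxs))))
        val_idx.extend(idxs[:n_val])
        train_idx.extend(idxs[n_val:])
    return np.array(sorted(train_idx)), np.array(sorted(val_idx))


# ---------------------------------------------------------------------------
# Model / Results front-end
# ---------------------------------------------------------------------------

class RowingKineticsModel:
    """Sequence-to-sequence LSTM estimator of rowing forces and powers.

    Parameters
    ----------
    dataset : CycleDataset
        Per-cycle feature/target sequences (see :func:`dataset_from_sessions`).
    network_config, train_config : optional
        Architecture and optimization settings; defaults are a 64-unit LSTM
        without dropout and the standard Adam/early-stopping recipe.
    """

    def __init__(
        self,
        dataset: CycleDataset,
        network_config: NetworkConfig | None = None,
        train_config: TrainConfig | None = None,
    ):
        self.dataset = dataset
        self.network_config = network_config or NetworkConfig(n_inputs=dataset.n_inputs)
        if self.network_config.n_inputs != dataset.n_inputs:
            raise ModelError("network n_inputs does not match the dataset")
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_sessions(
        cls,
        sessions: list[SimulatedSession],
        network_config: NetworkConfig | None = None,
        train_config: TrainConfig | None = None,
        smooth_cutoff_hz: float | None = 8.0,
    ) -> "RowingKineticsModel":
        dataset = dataset_from_sessions(sessions, smooth_cutoff_hz)
        return cls(dataset, network_config, train_config)

    # -- fitting --------------------------------------------------------------

    def _normalized(self, idx: np.ndarray, norm: NormStats):
        recs = [self.dataset.records[i] for i in idx]
        return [
            (
                norm.transform_features(r.X).astype(np.float32),
                norm.transform_targets(r.Y).astype(np.float32),
            )
            for r in recs
        ]

    def fit(
        self,
        train_idx: np.ndarray | None = None,
        val_idx: np.ndarray | None = None,
    ) -> "KineticsEstimationResults":
        """Train on an 80/20 cycle split (or explicit index sets)."""
        if train_idx is None or val_idx is None:
            train_idx, val_idx = split_indices(self.dataset, self.train_config)
        recs = self.dataset.records
        norm = fit_norm(
            [recs[i].X for i in train_idx],
            [recs[i].Y for i in train_idx],
            self.dataset.feature_names,
            list(TARGET_NAMES),
        )
        net = build_network(self.network_config)
        trained = train(
            net,
            self._normalized(train_idx, norm),
            self._normalized(val_idx, norm),
            self.train_config,
            norm,
            self.network_config,
        )
        return KineticsEstimationResults(self, trained, train_idx, val_idx)

    def fit_loov(self, train_config: TrainConfig | None = None) -> "LoovResults":
        """Leave-one-subject-out validation (see :func:`leave_one_out`)."""
        return leave_one_out(self.dataset, self.network_config,
                             train_config or self.train_config)


class KineticsEstimationResults:
    """Fitted estimator: weights, history, predictions and evaluation."""

    def __init__(
        self,
        model: RowingKineticsModel,
        trained: TrainedModel,
        train_idx: np.ndarray,
        val_idx: np.ndarray,
    ):
        self.model = model
        self.trained = trained
        self.train_idx = train_idx
        self.val_idx = val_idx
        self._net = trained.network()
        self._report: ev.EvalReport | None = None

    @property
    def history(self) -> pd.DataFrame:
        return self.trained.history

    @property
    def norm(self) -> NormStats:
        return self.trained.norm

    def predict(self, records: list[CycleRecord]) -> list[np.ndarray]:
        """De-normalized (T, 6) predictions for a list of cycles."""
        norm = self.norm
        out: list[np.ndarray] = []
        for i in range(0, len(records), 64):
            chunk = records[i : i + 64]
            X, _, mask = nn.pad_batch(
                [norm.transform_features(r.X).astype(np.float32) for r in chunk],
                [np.zeros((len(r), 6), np.float32) for r in chunk],
            )
            pred = self._net.forward(X)
            for j, r in enumerate(chunk):
                out.append(norm.inverse_targets(pred[j, : len(r)].astype(float)))
        return out

    def _val_records(self) -> list[CycleRecord]:
        return [self.model.dataset.records[i] for i in self.val_idx]

    def evaluate(self, subject_level: bool = True) -> ev.EvalReport:
        """Drive-phase error metrics and technique-determinant recovery.

        Metrics use the *measured* effective drive window for both measured
        and estimated sequences; determinants use the full catch-to-finish
        phase.  With ``subject_level`` and >= 2 subjects in validation, the
        intra-/inter-subject t-test accuracies are included.
        """
        if self._report is not None:
            return self._report
        records = self._val_records()
        preds = self.predict(records)
        self._report = evaluation_report(records, preds, subject_level=subject_level)
        return self._report

    def plot_cycle(self, index: int = 0, ax=None):
        """Plot measured vs estimated target curves for one validation cycle.

        Requires matplotlib (the ``plot`` extra).  Returns the axes array.
        """
        import matplotlib.pyplot as plt

        rec = self._val_records()[index]
        pred = self.predict([rec])[0]
        t = np.arange(len(rec)) / rec.sample_rate_hz
        if ax is None:
            _, ax = plt.subplots(2, 3, figsize=(11, 6), sharex=True)
        axes = np.asarray(ax).ravel()
        units = ["N", "N", "W", "W", "W", "W"]
        for j, (name, unit) in enumerate(zip(TARGET_NAMES, units)):
            axes[j].plot(t, rec.Y[:, j], label="measured", lw=1.2)
            axes[j].plot(t, pred[:, j], label="estimated", lw=1.2, ls="--")
            axes[j].axvline(rec.catch_rel / rec.sample_rate_hz, color="k",
                            lw=0.6, alpha=0.5)
            axes[j].set_title(f"{name} [{unit}]")
        axes[0].legend(frameon=False, fontsize=8)
        for a in axes[3:]:
            a.set_xlabel("time since finish [s]")
        return axes

    def summary(self) -> str:
        cfg, tc = self.model.network_config, self.model.train_config
        n_epochs = len(self.history)
        lines = [
            "Rowing kinetics LSTM estimation results",
            "=" * 48,
            f"condition:        {self.model.dataset.condition}",
            f"cycles:           {len(self.model.dataset)} "
            f"(train {len(self.train_idx)}, val {len(self.val_idx)})",
            f"architecture:     dense({cfg.n_inputs}) -> LSTM({cfg.lstm_units}) "
            f"-> dropout({cfg.dropout:.0%}) -> dense(6)",
            f"parameters:       {self._net.n_params()} "
            f"(LSTM layer: {self._net.n_lstm_params()})",
            f"optimizer:        Adam lr={tc.learning_rate}, minibatch={tc.minibatch}, "
            f"patience={tc.patience_epochs}",
            f"epochs run:       {n_epochs} (best epoch {self.trained.best_epoch})",
            f"best val RMSE:    {self.history['val_rmse'].min():.4f} (normalized units)",
            "",
        ]
        return "\n".join(lines) + self.evaluate().summary()


def evaluation_report(
    records: list[CycleRecord],
    preds: list[np.ndarray],
    subject_level: bool = True,
) -> ev.EvalReport:
    """Build an EvalReport from cycles and their de-normalized predictions."""
    grids_m: dict[str, list[np.ndarray]] = {n: [] for n in TARGET_NAMES}
    grids_e: dict[str, list[np.ndarray]] = {n: [] for n in TARGET_NAMES}
    dets_m: dict[str, dict[str, list[np.ndarray]]] = {}
    dets_e: dict[str, dict[str, list[np.ndarray]]] = {}
    det_err: dict[str, list[np.ndarray]] = {n: [] for n in TARGET_NAMES}
    for rec, pred in zip(records, preds):
        ds, de = rec.drive_rel
        for j, name in enumerate(TARGET_NAMES):
            grids_m[name].append(ev.interp_drive_grid(rec.Y[ds:de, j]))
            grids_e[name].append(ev.interp_drive_grid(pred[ds:de, j]))
            try:
                dm = ev.determinants(rec.Y[rec.catch_rel :, j])
                de_ = ev.determinants(pred[rec.catch_rel :, j])
            except ev.EvaluationError:
                continue
            det_err[name].append(np.abs(dm.as_array() - de_.as_array()))
            dets_m.setdefault(name, {}).setdefault(rec.subject_id, []).append(dm.as_array())
            dets_e.setdefault(name, {}).setdefault(rec.subject_id, []).append(de_.as_array())
    per_target = ev.evaluate_cycles(
        {n: np.vstack(g) for n, g in grids_m.items()},
        {n: np.vstack(g) for n, g in grids_e.items()},
    )
    det_mae = pd.DataFrame(
        {n: np.mean(det_err[n], axis=0) if det_err[n] else [np.nan] * 3
         for n in TARGET_NAMES},
        index=ev.DETERMINANT_NAMES,
    ).T
    report = ev.EvalReport(per_target=per_target, determinant_mae=det_mae,
                           n_cycles=len(records))
    subjects = {r.subject_id for r in records}
    if subject_level and len(subjects) >= 2:
        for name in TARGET_NAMES:
            if name not in dets_m:
                continue
            for k, det in enumerate(ev.DETERMINANT_NAMES):
                m = {s: np.array(v)[:, k] for s, v in dets_m[name].items()}
                e = {s: np.array(v)[:, k] for s, v in dets_e[name].items()}
                try:
                    ap, _ = ev.inter_subject_accuracy(m, e)
                    as_, _ = ev.intra_subject_accuracy(m, e)
                except ev.EvaluationError:
                    continue
                report.inter_accuracy[f"{name}:{det}"] = ap
                report.intra_accuracy[f"{name}:{det}"] = as_
    return report


# ---------------------------------------------------------------------------
# random search and leave-one-out
# ---------------------------------------------------------------------------

def sample_search_space(n_trials: int, seed: int) -> list[tuple[int, float]]:
    """Draw (units, dropout) pairs: log-uniform units in [10, 500], dropout
    uniform over {0, 0.05, 0.10}."""
    if n_trials < 1:
        raise ModelError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    units = np.round(
        np.exp(rng.uniform(math.log(SEARCH_UNITS_MIN), math.log(SEARCH_UNITS_MAX), n_trials))
    ).astype(int)
    units = np.clip(units, SEARCH_UNITS_MIN, SEARCH_UNITS_MAX)
    dropouts = rng.choice(SEARCH_DROPOUTS, n_trials)
    return [(int(u), float(d)) for u, d in zip(units, dropouts)]


def drive_phase_mae(records: list[CycleRecord], preds: list[np.ndarray]) -> float:
    """Mean (over the six targets) absolute drive-phase error in raw units."""
    grids_m = {n: [] for n in TARGET_NAMES}
    grids_e = {n: [] for n in TARGET_NAMES}
    for rec, pred in zip(records, preds):
        ds, de = rec.drive_rel
        for j, name in enumerate(TARGET_NAMES):
            grids_m[name].append(ev.interp_drive_grid(rec.Y[ds:de, j]))
            grids_e[name].append(ev.interp_drive_grid(pred[ds:de, j]))
    maes = [ev.mae_cmae(np.vstack(grids_m[n]), np.vstack(grids_e[n]))[0] for n in TARGET_NAMES]
    return float(np.mean(maes))


def random_search(
    dataset: CycleDataset,
    n_trials: int,
    seed: int,
    train_config: TrainConfig | None = None,
) -> tuple[NetworkConfig, pd.DataFrame]:
    """Random hyperparameter search over LSTM units and dropout.

    Each trial trains on the same 80/20 split and is scored by the mean
    drive-phase MAE over the six de-normalized targets on validation; the
    best configuration is returned together with the trial table.
    """
    tc = train_config or TrainConfig(seed=seed)
    trials = sample_search_space(n_trials, seed)
    rows = []
    best: tuple[float, NetworkConfig] | None = None
    for t, (units, dropout) in enumerate(trials):
        cfg = NetworkConfig(
            n_inputs=dataset.n_inputs, lstm_units=units, dropout=dropout, seed=seed + t
        )
        res = RowingKineticsModel(dataset, cfg, tc).fit()
        mae = drive_phase_mae(res._val_records(), res.predict(res._val_records()))
        rows.append({"trial": t, "units": units, "dropout": dropout,
                     "drive_mae": mae, "epochs": len(res.history)})
        if best is None or mae < best[0]:
            best = (mae, cfg)
    assert best is not None
    return best[1], pd.DataFrame(rows)


@dataclass
class LoovResults:
    """Per-subject leave-one-out folds and their aggregate errors."""

    folds: dict[str, KineticsEstimationResults]
    reports: dict[str, ev.EvalReport] = field(default_factory=dict)

    def _ensure_reports(self) -> None:
        for subject, res in self.folds.items():
            if subject not in self.reports:
                self.reports[subject] = res.evaluate(subject_level=False)

    @property
    def aggregate(self) -> pd.DataFrame:
        """Mean per-target metrics over subjects (each validated once)."""
        self._ensure_reports()
        return sum(r.per_target for r in self.reports.values()) / len(self.reports)

    @property
    def mean_mae_norm_pct(self) -> float:
        self._ensure_reports()
        return float(np.mean([r.mean_mae_norm_pct for r in self.reports.values()]))

    def summary(self) -> str:
        self._ensure_reports()
        lines = [
            f"Leave-one-subject-out validation over {len(self.folds)} folds",
            self.aggregate.round(3).to_string(),
            f"mean MAE_norm over subjects = {self.mean_mae_norm_pct:.2f}%",
        ]
        return "\n".join(lines)


def leave_one_out(
    dataset: CycleDataset,
    network_config: NetworkConfig,
    train_config: TrainConfig,
) -> LoovResults:
    """Leave-one-subject-out cross-validation.

    Each fold trains on all other subjects' cycles and validates (including
    the early-stopping criterion) on the held-out subject.  Per-fold metrics
    aggregate as the arithmetic mean over subjects.
    """
    groups = dataset.by_subject()
    if len(groups) < 3:
        raise ModelError("leave-one-out needs at least 3 subjects")
    folds: dict[str, KineticsEstimationResults] = {}
    for subject, val_idx in groups.items():
        if not val_idx:
            warnings.warn(f"subject {subject} has no cycles; fold skipped", stacklevel=2)
            continue
        train_idx = np.array(
            [i for s, idxs in groups.items() if s != subject for i in idxs]
        )
        model = RowingKineticsModel(dataset, network_config, train_config)
        folds[subject] = model.fit(train_idx=np.sort(train_idx), val_idx=np.array(val_idx))
    return LoovResults(folds=folds)
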