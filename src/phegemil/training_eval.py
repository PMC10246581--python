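"""Splitting, training, hyperparameter search, metrics and the
cross-environment / genotype-only protocols.

Evaluation splits are grouped by entry (a genetically unique line never
appears in two partitions) and stratified by trial, at 80/10/10
train/validation/test fractions, repeated 5 times by default.  Training
minimises MSE with Adam, tracks validation Pearson per epoch, supports
plateau and cyclic-cosine learning-rate schedules and early stopping, and is
fully seeded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_core import GenotypeMatrix, PlotSample
from .mil_model import ModelConfig, PheGeMIL, mse_loss, predict_yield
from .nn import Adam, CosineAnnealing, ReduceLROnPlateau, Tensor

__all__ = [
    "SplitPlan",
    "MetricsReport",
    "SearchSpace",
    "TrainConfig",
    "make_splits",
    "train_model",
    "random_search",
    "evaluate",
    "predictions_for",
    "ensemble_predict",
    "harmonize_markers",
    "finetune_genotype_only",
    "entry_level_aggregate",
    "pearson",
]


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Per-repeat assignment of plots to train/val/test, grouped by entry."""

    assignments: pd.DataFrame  # columns: plot_id, repeat, partition
    repeats: int
    fractions: tuple[float, float, float]

    def partition(self, samples: list[PlotSample], repeat: int, part: str) -> list[PlotSample]:
        sel = self.assignments[
            (self.assignments["repeat"] == repeat)
            & (self.assignments["partition"] == part)
        ]["plot_id"]
        wanted = set(sel)
        return [s for s in samples if s.plot_id in wanted]

    def to_csv(self, path) -> None:
        self.assignments.to_csv(path, index=False)


def make_splits(
    samples: list[PlotSample],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    repeats: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Entry-grouped, trial-stratified repeated random splits.

    All replicate plots of an entry travel together; within each trial the
    entries are shuffled and allocated to partitions at the requested
    fractions.  An entry whose replicates span several trials is stratified
    by its majority trial (with a warning).
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    entry_plots: dict[str, list[str]] = {}
    entry_trials: dict[str, list[str]] = {}
    for s in samples:
        entry_plots.setdefault(s.entry_id, []).append(s.plot_id)
        entry_trials.setdefault(s.entry_id, []).append(s.trial_id)
    entry_trial: dict[str, str] = {}
    for entry, trials in entry_trials.items():
        uniq, counts = np.unique(trials, return_counts=True)
        if len(uniq) > 1:
            warnings.warn(
                f"entry {entry} spans trials {list(uniq)}; stratifying by majority",
                stacklevel=2,
            )
        entry_trial[entry] = str(uniq[np.argmax(counts)])

    by_trial: dict[str, list[str]] = {}
    for entry in sorted(entry_plots):
        by_trial.setdefault(entry_trial[entry], []).append(entry)

    rng = np.random.default_rng(seed)
    f_train, f_val, _f_test = fractions
    rows = []
    for rep in range(repeats):
        for trial in sorted(by_trial):
            entries = list(by_trial[trial])
            rng.shuffle(entries)
            n = len(entries)
            n_train = int(round(f_train * n))
            n_val = int(round(f_val * n))
            n_train = min(n_train, n)
            n_val = min(n_val, n - n_train)
            parts = (
                [(e, "train") for e in entries[:n_train]]
                + [(e, "val") for e in entries[n_train : n_train + n_val]]
                + [(e, "test") for e in entries[n_train + n_val :]]
            )
            for entry, part in parts:
                for plot_id in entry_plots[entry]:
                    rows.append({"plot_id": plot_id, "repeat": rep, "partition": part})
    return SplitPlan(
        assignments=pd.DataFrame(rows), repeats=repeats, fractions=fractions
    )


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class MetricsReport:
    mae: float
    mse: float
    pearson: float
    r2: float
    level: str = "plot"
    pearson_defined: bool = True


def evaluate(
    predictions: np.ndarray,
    observations: np.ndarray,
    level: str = "plot",
    entry_map: list[str] | None = None,
) -> MetricsReport:
    """MAE, MSE, Pearson r and R^2 = 1 - SS_res/SS_tot.

    With level="entry", replicate plots of each entry are averaged first
    (entry_map gives the entry id per plot).
    """
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {obs.shape}")
    if level == "entry":
        if entry_map is None:
            raise ValueError("entry-level evaluation requires entry_map")
        _, pred, obs = entry_level_aggregate(pred, obs, entry_map)
    r = pearson(pred, obs)
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return MetricsReport(
        mae=float(np.mean(np.abs(pred - obs))),
        mse=float(np.mean((pred - obs) ** 2)),
        pearson=r,
        r2=r2,
        level=level,
        pearson_defined=not math.isnan(r),
    )


def entry_level_aggregate(
    plot_predictions, plot_observations, entry_map: list[str]
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Average predictions and observations over the replicate plots of each
    entry; returns (entry ids, mean predictions, mean observations)."""
    pred = np.asarray(plot_predictions, dtype=float)
    obs = np.asarray(plot_observations, dtype=float)
    if len(entry_map) != len(pred):
        raise ValueError("entry_map length does not match predictions")
    for i, e in enumerate(entry_map):
        if e is None or e == "":
            raise ValueError(f"plot at position {i} has no entry mapping")
    df = pd.DataFrame({"entry": entry_map, "pred": pred, "obs": obs})
    agg = df.groupby("entry", sort=True).mean()
    return list(agg.index), agg["pred"].to_numpy(), agg["obs"].to_numpy()


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-3
    schedule: str = "none"  # none | plateau | cosine
    batch_size: int = 8
    epochs: int = 20
    patience: int = 5
    seed: int = 0
    genotype_only: bool = False


def predictions_for(
    model: PheGeMIL, samples: list[PlotSample], genotype_only: bool = False
) -> np.ndarray:
    return np.array(
        [predict_yield(s, model, genotype_only=genotype_only) for s in samples]
    )


def train_model(
    train: list[PlotSample],
    val: list[PlotSample],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig = TrainConfig(),
    model: PheGeMIL | None = None,
    trainable_params: list | None = None,
) -> tuple[PheGeMIL, list[dict]]:
    """Train (or continue training) the MIL model by minimising MSE.

    Validation Pearson is tracked per epoch; early stopping keeps the
    best-epoch weights.  All randomness (init, batching, bag subsampling)
    derives from `train_cfg.seed`.
    """
    if train_cfg.schedule not in ("none", "plateau", "cosine"):
        raise ValueError(f"unknown schedule {train_cfg.schedule!r}")
    rng = np.random.default_rng(train_cfg.seed)
    if model is None:
        model = PheGeMIL(model_cfg, rng)
        # start the output bias at the mean training yield so the regressor
        # learns deviations rather than the overall scale
        if train:
            model.reg2.bias.data[:] = np.mean([s.yield_t_ha for s in train])
    params = trainable_params if trainable_params is not None else model.parameters()
    optimizer = Adam(params, lr=train_cfg.lr)
    scheduler = None
    if train_cfg.schedule == "plateau":
        scheduler = ReduceLROnPlateau(optimizer, mode="max", patience=2)
    elif train_cfg.schedule == "cosine":
        scheduler = CosineAnnealing(optimizer, period=max(2, train_cfg.epochs // 2))

    best_state = model.state_dict()
    best_val = -math.inf
    bad_epochs = 0
    history: list[dict] = []
    order = np.arange(len(train))
    for epoch in range(train_cfg.epochs):
        rng.shuffle(order)
        epoch_losses = []
        for start in range(0, len(order), train_cfg.batch_size):
            batch = [train[i] for i in order[start : start + train_cfg.batch_size]]
            optimizer.zero_grad()
            preds = []
            for s in batch:
                yhat, _ = model.forward(
                    s, train=True, rng=rng, genotype_only=train_cfg.genotype_only
                )
                preds.append(yhat.reshape(1))
            from .nn import concatenate

            pred_vec = concatenate(preds, axis=0)
            target = Tensor(np.array([s.yield_t_ha for s in batch]))
            loss = mse_loss(pred_vec, target)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {start // train_cfg.batch_size} "
                    f"(lr={optimizer.lr:g})"
                )
            loss.backward()
            optimizer.step()
            epoch_losses.append(float(loss.data))

        val_pearson = float("nan")
        if val:
            val_pred = predictions_for(model, val, train_cfg.genotype_only)
            val_obs = np.array([s.yield_t_ha for s in val])
            val_pearson = pearson(val_pred, val_obs)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(epoch_losses)) if epoch_losses else float("nan"),
                "val_pearson": val_pearson,
                "lr": optimizer.lr,
            }
        )
        if scheduler is not None:
            scheduler.step(val_pearson if val else 0.0)
        if val and not math.isnan(val_pearson) and val_pearson > best_val:
            best_val = val_pearson
            best_state = model.state_dict()
            bad_epochs = 0
        else:
            bad_epochs += 1
            if val and bad_epochs > train_cfg.patience:
                break
    if val and train_cfg.epochs > 0:
        model.load_state_dict(best_state)
    return model, history


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchSpace:
    """The random-search grid for model/training hyperparameters."""

    learning_rates: tuple[float, ...] = (1e-5, 1e-4, 1e-3)
    schedules: tuple[str, ...] = ("none", "plateau", "cosine")
    batch_sizes: tuple[int, ...] = (8, 16)
    bag_sizes: tuple[int, ...] = (8, 16, 32)
    heads: tuple[int, ...] = (1, 4, 8)
    temporal: tuple[bool, ...] = (True, False)
    channel: tuple[bool, ...] = (True, False)

    def sample(self, rng: np.random.Generator) -> dict:
        return {
            "lr": float(rng.choice(self.learning_rates)),
            "schedule": str(rng.choice(self.schedules)),
            "batch_size": int(rng.choice(self.batch_sizes)),
            "bag_size": int(rng.choice(self.bag_sizes)),
            "n_heads": int(rng.choice(self.heads)),
            "temporal_encoding": bool(rng.choice(self.temporal)),
            "channel_encoding": bool(rng.choice(self.channel)),
        }


def random_search(
    train: list[PlotSample],
    val: list[PlotSample],
    space: SearchSpace = SearchSpace(),
    n_runs: int = 20,
    seed: int = 0,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig = TrainConfig(),
    evaluator=None,
) -> tuple[dict, pd.DataFrame]:
    """Random search over the grid; select by validation Pearson.

    `evaluator(draw) -> score` may be injected (e.g. for testing); the
    default trains a model per draw and scores it on the validation set.
    """
    rng = np.random.default_rng(seed)
    draws = [space.sample(rng) for _ in range(n_runs)]
    if evaluator is None:
        if model_cfg is None:
            raise ValueError("model_cfg required with the default evaluator")

        def evaluator(draw: dict) -> float:
            mc = replace(
                model_cfg,
                n_heads=draw["n_heads"],
                bag_size=draw["bag_size"],
                temporal_encoding=draw["temporal_encoding"],
                channel_encoding=draw["channel_encoding"],
            )
            tc = replace(
                train_cfg,
                lr=draw["lr"],
                schedule=draw["schedule"],
                batch_size=draw["batch_size"],
            )
            model, history = train_model(train, val, mc, tc)
            scores = [h["val_pearson"] for h in history if not math.isnan(h["val_pearson"])]
            return max(scores) if scores else float("-inf")

    records = []
    failures = []
    for i, draw in enumerate(draws):
        try:
            score = evaluator(draw)
        except Exception as exc:  # noqa: BLE001 - aggregated below
            failures.append((i, draw, repr(exc)))
            score = float("-inf")
        records.append({**draw, "run": i, "val_pearson": score})
    leaderboard = pd.DataFrame(records).sort_values(
        "val_pearson", ascending=False, kind="stable"
    )
    if len(failures) == n_runs:
        raise RuntimeError(f"all {n_runs} search runs failed: {failures[:3]}...")
    best = leaderboard.iloc[0]
    best_cfg = {k: best[k] for k in draws[0]}
    return best_cfg, leaderboard


# ---------------------------------------------------------------------------
# ensembling, marker harmonization, genotype-only fine-tuning
# ---------------------------------------------------------------------------

def ensemble_predict(
    models: list[PheGeMIL], samples: list[PlotSample], genotype_only: bool = False
) -> np.ndarray:
    """Arithmetic mean of member predictions per sample."""
    if not models:
        raise ValueError("need at least one model to ensemble")
    n_markers = {m.config.n_markers for m in models}
    if len(n_markers) > 1:
        raise ValueError(f"incompatible marker sets across members: {n_markers}")
    preds = np.stack([predictions_for(m, samples, genotype_only) for m in models])
    return preds.mean(axis=0)


def harmonize_markers(
    train_marker_ids: list[str],
    new_genotypes: GenotypeMatrix,
    fill_values: np.ndarray | None = None,
    min_overlap: float = 0.5,
) -> tuple[np.ndarray, dict]:
    """Align a new environment's genotypes to the trained marker list.

    Markers absent from the new set are filled with the training-set mean
    dosage (`fill_values`, aligned with `train_marker_ids`; defaults to 1.0,
    the mid-dosage).  Fails when the marker overlap drops below
    `min_overlap`.
    """
    new_pos = {m: j for j, m in enumerate(new_genotypes.marker_ids)}
    shared = [m for m in train_marker_ids if m in new_pos]
    overlap = len(shared) / len(train_marker_ids) if train_marker_ids else 0.0
    if overlap < min_overlap:
        raise ValueError(
            f"marker overlap {overlap:.1%} below the {min_overlap:.0%} floor"
        )
    if fill_values is None:
        fill_values = np.full(len(train_marker_ids), 1.0)
    from .io_core import impute_dosage

    imputed_new = impute_dosage(new_genotypes)
    n_lines = len(new_genotypes.line_ids)
    out = np.empty((n_lines, len(train_marker_ids)))
    filled = 0
    for j, m in enumerate(train_marker_ids):
        if m in new_pos:
            out[:, j] = imputed_new[:, new_pos[m]]
        else:
            out[:, j] = fill_values[j]
            filled += 1
    report = {
        "n_train_markers": len(train_marker_ids),
        "n_shared": len(shared),
        "n_filled": filled,
        "n_dropped_from_new": len(new_genotypes.marker_ids) - len(shared),
        "overlap": overlap,
    }
    return out, report


def finetune_genotype_only(
    model: PheGeMIL,
    train_samples: list[PlotSample],
    val_samples: list[PlotSample] | None = None,
    lr: float | None = None,
    base_lr: float = 1e-3,
    epochs: int = 5,
    batch_size: int = 8,
    seed: int = 0,
) -> tuple[PheGeMIL, list[dict]]:
    """Continue MSE training presenting genotype-only bags.

    Image encoders are frozen (their weights are not touched); the learning
    rate defaults to 0.1x the original.  Intended for cross-environment
    genotype-only prediction after multi-modal training.  The input model is
    left untouched; the fine-tuned copy is returned.
    """
    import copy

    if model.genotype_encoder is None:
        raise ValueError("model has no genotype encoder; cannot fine-tune")
    if lr is None:
        lr = 0.1 * base_lr
    model = copy.deepcopy(model)
    frozen = set()
    for enc in model.image_encoders.values():
        frozen.update(id(p) for p in enc.parameters())
    trainable = [p for p in model.parameters() if id(p) not in frozen]
    cfg = TrainConfig(
        lr=lr,
        epochs=epochs,
        batch_size=batch_size,
        seed=seed,
        genotype_only=True,
        patience=max(2, epochs),
    )
    return train_model(
        train_samples,
        val_samples or [],
        model.config,
        cfg,
        model=model,
        trainable_params=trainable,
    )
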