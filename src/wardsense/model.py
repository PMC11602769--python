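"""Symptom-prediction sequence models.

The four model families share one conv-GRU backbone and differ only in
their output heads:

* ``mode="single"`` — one head for one rating scale;
* ``mode="multi"`` — four heads (one per scale) trained jointly by
  multitask learning, sharing every backbone parameter;
* ``task="deterioration"`` — sigmoid heads classifying whether the
  scale total increased versus the participant's previous assessment
  (binary cross-entropy loss, undefined first-assessment labels
  masked);
* ``task="score"`` — linear heads regressing the absolute total (mean
  squared error on min-max-scaled scores so the four losses are
  commensurate).

Usage follows the model/results convention of the mainstream
statistical stacks::

    model = SymptomSequenceModel(train_examples, mode="multi", task="score")
    res = model.fit()
    preds = res.predict(test_examples)
    print(res.summary())
"""

from __future__ import annotations

import dataclasses
import io
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .examples import Example, ExampleDataset, FeatureScaler
from .features import INPUT_REGISTRY
from .scales import DEFAULT_SCALE_RANGES, SCALE_NAMES

MODES = ("single", "multi")
TASKS = ("deterioration", "score")


class ModelConfigError(ValueError):
    """Invalid mode/task/head combination or dimensions."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture + task configuration of one model."""

    mode: str = "multi"
    task: str = "score"
    scale: str | None = None          # required iff mode == "single"
    conv_channels: tuple[int, ...] = (32, 64)
    kernel_size: int = 5
    pool: int = 4
    gru_hidden: int = 64
    gru_layers: int = 1
    dropout: float = 0.2
    head_width: int = 32

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ModelConfigError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.task not in TASKS:
            raise ModelConfigError(f"task must be one of {TASKS}, got {self.task!r}")
        if self.mode == "single":
            if self.scale not in SCALE_NAMES:
                raise ModelConfigError(
                    f"single mode requires scale in {SCALE_NAMES}, got {self.scale!r}")
        elif self.scale is not None:
            raise ModelConfigError("multi mode must leave scale unset")
        if self.gru_layers != 1:
            raise ModelConfigError("only 1 GRU layer is supported")
        if min(self.conv_channels) <= 0 or self.kernel_size <= 0 or \
                self.gru_hidden <= 0 or self.head_width <= 0 or self.pool <= 0:
            raise ModelConfigError("all dimensions must be positive")

    @property
    def heads(self) -> tuple[str, ...]:
        return (self.scale,) if self.mode == "single" else SCALE_NAMES


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings."""

    learning_rate: float = 1e-3
    batch_size: int = 16
    max_epochs: int = 80
    min_epochs: int = 30               # epochs before early stopping may trigger
    patience: int = 12                 # early-stop patience on validation loss
    val_fraction: float = 0.15         # participant-grouped validation share
    loss_weights: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ModelConfigError("hyperparameters must be positive")


def build_model(config: ModelConfig, seed: int = 0) -> nn.SeqNet:
    """Instantiate the untrained network for a configuration: temporal
    1D convolutions over the 672-hour axis (features as channels), a
    GRU whose last hidden state feeds a fully connected layer, then one
    scalar head per target scale."""
    return nn.SeqNet(n_features=len(INPUT_REGISTRY),
                     head_names=list(config.heads),
                     conv_channels=config.conv_channels,
                     kernel=config.kernel_size, pool=config.pool,
                     gru_hidden=config.gru_hidden, dropout=config.dropout,
                     head_width=config.head_width, seed=seed)


def _targets(examples: list[Example], config: ModelConfig,
             scale_ranges: dict[str, tuple[int, int]]
             ) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-head target vectors and validity masks."""
    y, m = {}, {}
    for s in config.heads:
        if config.task == "score":
            lo, hi = scale_ranges[s]
            y[s] = np.array([(e.score_labels[s] - lo) / (hi - lo) for e in examples])
            m[s] = np.ones(len(examples))
        else:
            lab = [e.deterioration_labels[s] for e in examples]
            y[s] = np.array([float(v) if v is not None else 0.0 for v in lab])
            m[s] = np.array([v is not None for v in lab], dtype=float)
    return y, m


class SymptomSequenceModel:
    """A symptom-prediction model specification bound to training data.

    Parameters
    ----------
    examples : list of Example or ExampleDataset
        The training instances (typically the cross-validation split).
    mode, task, scale :
        Shorthand for the corresponding :class:`ModelConfig` fields,
        ignored when ``config`` is given.
    """

    def __init__(self, examples, mode: str = "multi", task: str = "score",
                 scale: str | None = None, config: ModelConfig | None = None,
                 scale_ranges: dict[str, tuple[int, int]] | None = None) -> None:
        if isinstance(examples, ExampleDataset):
            examples = examples.examples
        self.examples: list[Example] = list(examples)
        self.config = config or ModelConfig(mode=mode, task=task, scale=scale)
        self.scale_ranges = dict(scale_ranges or DEFAULT_SCALE_RANGES)

    @classmethod
    def from_dataset(cls, dataset: ExampleDataset, split: str = "cv",
                     **kwargs) -> "SymptomSequenceModel":
        return cls(dataset.split(split), **kwargs)

    # ------------------------------------------------------------------
    def fit(self, train_config: TrainConfig | None = None
            ) -> "SymptomSequenceResults":
        """Train with Adam, early-stopping on a participant-grouped
        validation split; returns the fitted results object."""
        tc = train_config or TrainConfig()
        cfg = self.config
        if not self.examples:
            raise ValueError("empty training set")
        rng = np.random.default_rng(tc.seed)

        scaler = FeatureScaler().fit(self.examples)
        X = scaler.transform_batch(self.examples)
        y, mask = _targets(self.examples, cfg, self.scale_ranges)

        if cfg.task == "deterioration":
            for s in cfg.heads:
                vals = y[s][mask[s] > 0]
                if vals.size and (vals.min() == vals.max()):
                    warnings.warn(f"head {s}: single-class deterioration labels "
                                  "in the training set", stacklevel=2)

        # participant-grouped validation split
        pids = sorted({e.participant_id for e in self.examples})
        rng.shuffle(pids)
        n_val = int(round(tc.val_fraction * len(pids)))
        n_val = min(max(n_val, 1 if len(pids) > 1 else 0), len(pids) - 1)
        val_pids = set(pids[:n_val])
        idx_all = np.arange(len(self.examples))
        val_idx = np.array([i for i in idx_all
                            if self.examples[i].participant_id in val_pids], dtype=int)
        tr_idx = np.array([i for i in idx_all if i not in set(val_idx)], dtype=int)

        weights = {s: 1.0 for s in cfg.heads}
        if tc.loss_weights:
            weights.update(tc.loss_weights)

        net = build_model(cfg, seed=tc.seed)
        opt = nn.Adam(net.param_layers, lr=tc.learning_rate)

        def batch_loss(indices: np.ndarray, train: bool) -> float:
            out = net.forward(X[indices], train=train, rng=rng)
            total = 0.0
            dheads = {}
            for s in cfg.heads:
                fn = nn.bce_with_logits if cfg.task == "deterioration" else nn.mse
                loss, dz = fn(out[s], y[s][indices], mask[s][indices])
                total += weights[s] * loss
                dheads[s] = weights[s] * dz
            if train:
                net.backward(dheads)
            return total

        log_rows = []
        best_val = np.inf
        best_state = net.state_dict()
        best_epoch = 0
        bad = 0
        for epoch in range(tc.max_epochs):
            order = tr_idx.copy()
            rng.shuffle(order)
            ep_loss, nb = 0.0, 0
            for start in range(0, len(order), tc.batch_size):
                b = order[start:start + tc.batch_size]
                opt.zero_grad()
                ep_loss += batch_loss(b, train=True)
                nb += 1
                opt.step()
            train_loss = ep_loss / max(nb, 1)
            if len(val_idx):
                val_loss = batch_loss(val_idx, train=False)
            else:
                val_loss = train_loss
            log_rows.append({"epoch": epoch, "train_loss": train_loss,
                             "val_loss": val_loss})
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = net.state_dict()
                best_epoch = epoch
                bad = 0
            else:
                bad += 1
                if epoch >= tc.min_epochs and bad > tc.patience:
                    break
        net.load_state_dict(best_state)
        return SymptomSequenceResults(
            model=self, net=net, scaler=scaler, train_config=tc,
            training_log=pd.DataFrame(log_rows), best_epoch=best_epoch,
            registry=tuple(INPUT_REGISTRY))


@dataclass
class SymptomSequenceResults:
    """Fitted model: learned parameters, scaler statistics, registry
    snapshot and training log, with prediction and persistence."""

    model: SymptomSequenceModel
    net: nn.SeqNet
    scaler: FeatureScaler
    train_config: TrainConfig
    training_log: pd.DataFrame
    best_epoch: int
    registry: tuple[str, ...] = tuple(INPUT_REGISTRY)

    @property
    def config(self) -> ModelConfig:
        return self.model.config

    def _check_registry(self) -> None:
        current = tuple(INPUT_REGISTRY)
        if current != tuple(self.registry):
            diff = sorted(set(current).symmetric_difference(self.registry))
            raise ValueError(f"feature registry mismatch; differing columns: {diff}")

    def predict(self, examples) -> pd.DataFrame:
        """Per-scale predictions: probabilities in [0,1] for
        deterioration heads, native-range (clipped) totals for score
        heads. Index follows the input order."""
        self._check_registry()
        if isinstance(examples, ExampleDataset):
            examples = examples.examples
        X = self.scaler.transform_batch(list(examples))
        out = self.net.forward(X, train=False)
        cols = {}
        for s in self.config.heads:
            if self.config.task == "deterioration":
                cols[s] = nn._sigmoid(out[s])
            else:
                lo, hi = self.model.scale_ranges[s]
                cols[s] = np.clip(out[s] * (hi - lo) + lo, lo, hi)
        return pd.DataFrame(cols)

    # ------------------------------------------------------------------
    def summary(self) -> str:
        cfg = self.config
        buf = io.StringIO()
        title = f"Symptom sequence model — {cfg.mode.capitalize()}-{cfg.task.capitalize()}"
        if cfg.mode == "single":
            title += f" ({cfg.scale})"
        buf.write(title + "\n" + "=" * len(title) + "\n")
        rows = [
            ("heads", ", ".join(cfg.heads)),
            ("parameters", f"{self.net.n_parameters():,}"),
            ("training examples", str(len(self.model.examples))),
            ("epochs run", str(len(self.training_log))),
            ("best epoch", str(self.best_epoch)),
            ("final train loss", f"{self.training_log['train_loss'].iloc[-1]:.4f}"),
            ("best val loss", f"{self.training_log['val_loss'].min():.4f}"),
            ("learning rate", f"{self.train_config.learning_rate:g}"),
            ("batch size", str(self.train_config.batch_size)),
            ("architecture",
             f"conv{list(cfg.conv_channels)} k{cfg.kernel_size} pool{cfg.pool} "
             f"-> GRU({cfg.gru_hidden}) -> FC({cfg.head_width})"),
        ]
        w = max(len(k) for k, _ in rows)
        for k, v in rows:
            buf.write(f"{k.ljust(w)} : {v}\n")
        return buf.getvalue()

    # ------------------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = {
            "config": dataclasses.asdict(self.config),
            "train_config": dataclasses.asdict(self.train_config),
            "scale_ranges": {k: list(v) for k, v in self.model.scale_ranges.items()},
            "registry": list(self.registry),
            "best_epoch": self.best_epoch,
            "training_log": self.training_log.to_dict(orient="list"),
        }
        arrays = {f"param::{k}": v for k, v in self.net.state_dict().items()}
        arrays["scaler_mean"] = self.scaler.mean_
        arrays["scaler_scale"] = self.scaler.scale_
        np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)
        return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "SymptomSequenceResults":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            state = {k.split("::", 1)[1]: z[k] for k in z.files if k.startswith("param::")}
            mean, scale = z["scaler_mean"], z["scaler_scale"]
        cfgd = dict(meta["config"])
        cfgd["conv_channels"] = tuple(cfgd["conv_channels"])
        config = ModelConfig(**cfgd)
        tcd = dict(meta["train_config"])
        tc = TrainConfig(**tcd)
        model = SymptomSequenceModel([], config=config,
                                     scale_ranges={k: tuple(v) for k, v in
                                                   meta["scale_ranges"].items()})
        net = build_model(config, seed=tc.seed)
        net.load_state_dict(state)
        scaler = FeatureScaler()
        scaler.mean_, scaler.scale_ = mean, scale
        return cls(model=model, net=net, scaler=scaler, train_config=tc,
                   training_log=pd.DataFrame(meta["training_log"]),
                   best_epoch=int(meta["best_epoch"]),
                   registry=tuple(meta["registry"]))


# ---------------------------------------------------------------------------
# random search
# ---------------------------------------------------------------------------

DEFAULT_SEARCH_SPACE: dict = {
    "learning_rate": ("log_uniform", 1e-4, 1e-2),
    "gru_hidden": ("choice", (32, 64, 128)),
    "kernel_size": ("choice", (3, 5, 7)),
    "dropout": ("uniform", 0.0, 0.5),
    "batch_size": ("choice", (16, 32)),
}


def _sample_space(space: dict, rng: np.random.Generator) -> dict:
    out = {}
    for key, spec in space.items():
        kind = spec[0]
        if kind == "choice":
            out[key] = spec[1][rng.integers(len(spec[1]))]
        elif kind == "uniform":
            out[key] = float(rng.uniform(spec[1], spec[2]))
        elif kind == "log_uniform":
            out[key] = float(np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2]))))
        else:
            raise ValueError(f"unknown sampling kind {kind!r}")
    return out


@dataclass
class RandomSearchResult:
    best_model_config: ModelConfig
    best_train_config: TrainConfig
    trials: pd.DataFrame    # one row per sampled configuration


def random_search(examples: list[Example], base_config: ModelConfig,
                  space: dict | None = None, k: int = 3, budget: int = 20,
                  seed: int = 0, max_epochs: int = 30,
                  scale_ranges: dict | None = None) -> RandomSearchResult:
    """Uniform random search over the hyperparameter space, scored by
    participant-grouped k-fold cross-validation (mean AUC for
    deterioration models, mean R² for score models). Returns the best
    configuration and the full trial table."""
    from .evaluation import evaluate_fold_metric, make_folds  # lazy: avoids cycle

    if budget < 1:
        raise ValueError("budget must be >= 1")
    space = space if space is not None else DEFAULT_SEARCH_SPACE
    if not space:
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    pids = sorted({e.participant_id for e in examples})
    k_eff = min(k, len(pids))
    plan = make_folds(pids, k_eff, seed=seed)

    rows = []
    arch_keys = {f.name for f in dataclasses.fields(ModelConfig)}
    for trial in range(budget):
        draw = _sample_space(space, rng)
        mc = dataclasses.replace(base_config,
                                 **{k_: v for k_, v in draw.items() if k_ in arch_keys})
        tc_kwargs = {k_: v for k_, v in draw.items() if k_ in
                     ("learning_rate", "batch_size")}
        tc = TrainConfig(max_epochs=max_epochs, seed=seed, **tc_kwargs)
        fold_scores = []
        for fold in range(k_eff):
            tr = [e for e in examples if plan.assignment[e.participant_id] != fold]
            te = [e for e in examples if plan.assignment[e.participant_id] == fold]
            if not tr or not te:
                continue
            res = SymptomSequenceModel(tr, config=mc,
                                       scale_ranges=scale_ranges).fit(tc)
            fold_scores.append(evaluate_fold_metric(res, te))
        score = float(np.mean(fold_scores)) if fold_scores else np.nan
        rows.append({"trial": trial, **draw, "cv_metric": score})
    trials = pd.DataFrame(rows)
    best_i = int(trials["cv_metric"].idxmax())
    best = trials.loc[best_i]
    best_mc = dataclasses.replace(
        base_config, **{k_: (int(best[k_]) if k_ in ("gru_hidden", "kernel_size")
                             else float(best[k_]))
                        for k_ in space if k_ in arch_keys})
    best_tc = TrainConfig(
        learning_rate=float(best.get("learning_rate", 1e-3)),
        batch_size=int(best.get("batch_size", 32)),
        max_epochs=max_epochs, seed=seed)
    return RandomSearchResult(best_model_config=best_mc,
                              best_train_config=best_tc, trials=trials)
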