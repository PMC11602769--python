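"""Validation design and metrics.

Implements the study's evaluation protocol: participant-grouped 5-fold
cross-validation on the pre-cutoff recruits, temporal external
validation on the rest, accuracy and tie-corrected AUC with vertically
pooled ROC curves for the Deterioration task, R² and NRMSE (RMSE over
the instrument's theoretical score range) for the Score task,
permutation feature importance on the external set, and the t-SNE
ward-distribution visualization.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .cohort import CohortBundle, load_cohort
from .examples import DEFAULT_CUTOFF, Example, ExampleDataset, build_dataset
from .features import INPUT_REGISTRY, FeatureConfig, featurize_cohort
from .model import (ModelConfig, RandomSearchResult, SymptomSequenceModel,
                    SymptomSequenceResults, TrainConfig, random_search)
from .scales import SCALE_NAMES, scale_span

FPR_GRID = np.linspace(0.0, 1.0, 101)


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """Random participant-level partition into k folds (sizes differ by
    at most one participant)."""

    k: int
    assignment: dict[str, int]
    seed: int


def make_folds(cv_participants: list[str], k: int, seed: int = 0) -> FoldPlan:
    pids = list(cv_participants)
    if k > len(pids):
        raise ValueError(f"k={k} exceeds {len(pids)} participants")
    rng = np.random.default_rng(seed)
    order = list(pids)
    rng.shuffle(order)
    assignment = {pid: i % k for i, pid in enumerate(order)}
    return FoldPlan(k=k, assignment=assignment, seed=seed)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def classification_metrics(probabilities, labels, threshold: float = 0.5
                           ) -> dict[str, float]:
    """Accuracy at ``threshold`` and AUC by the rank (Mann-Whitney)
    statistic with tie correction. Single-class labels leave the AUC
    undefined (NaN, flagged)."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    acc = float(np.mean((p >= threshold) == (y > 0.5)))
    n_pos = int((y > 0.5).sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return {"accuracy": acc, "auc": float("nan"), "auc_defined": False}
    ranks = rankdata(p)
    auc = (ranks[y > 0.5].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return {"accuracy": acc, "auc": float(auc), "auc_defined": True}


def regression_metrics(predictions, scores, scale_range: float
                       ) -> dict[str, float]:
    """R² = 1 − SS_res/SS_tot and NRMSE = RMSE / score range. A
    zero-variance truth vector leaves R² undefined (NaN, flagged)."""
    if scale_range <= 0:
        raise ValueError("scale_range must be positive")
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(scores, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 examples")
    rmse = float(np.sqrt(np.mean((p - y) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return {"r2": float("nan"), "nrmse": rmse / scale_range,
                "r2_defined": False}
    r2 = 1.0 - float(np.sum((p - y) ** 2)) / ss_tot
    return {"r2": r2, "nrmse": rmse / scale_range, "r2_defined": True}


def pooled_roc(fold_curves: list[tuple[np.ndarray, np.ndarray]],
               fpr_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Vertically pool per-fold ROC curves: at each grid FPR the pooled
    TPR is the mean of the folds' linearly interpolated TPRs, with a
    ±1 SD band."""
    if not fold_curves:
        raise ValueError("no fold curves supplied")
    grid = FPR_GRID if fpr_grid is None else np.asarray(fpr_grid, dtype=float)
    tprs = np.stack([np.interp(grid, np.asarray(fpr), np.asarray(tpr))
                     for fpr, tpr in fold_curves])
    return pd.DataFrame({"fpr": grid, "tpr_mean": tprs.mean(axis=0),
                         "tpr_sd": tprs.std(axis=0, ddof=0)})


def pooled_score_metrics(results: SymptomSequenceResults,
                         examples: list[Example]) -> dict[str, float]:
    """Overall Score-model performance: (prediction, truth) pairs of
    every head, min-max normalized per scale so the four instruments
    are commensurate, pooled into one R²/NRMSE computation."""
    preds = results.predict(examples)
    ps, ys = [], []
    for s in results.config.heads:
        lo, hi = results.model.scale_ranges[s]
        ps.append((preds[s].to_numpy() - lo) / (hi - lo))
        ys.append((np.array([e.score_labels[s] for e in examples]) - lo) / (hi - lo))
    return regression_metrics(np.concatenate(ps), np.concatenate(ys), 1.0)


def pooled_deterioration_metrics(results: SymptomSequenceResults,
                                 examples: list[Example]) -> dict[str, float]:
    """Overall Deterioration-model performance: labelled
    (probability, label) pairs of every head pooled into one
    accuracy/AUC computation."""
    preds = results.predict(examples)
    ps, ys = [], []
    for s in results.config.heads:
        lab = [e.deterioration_labels[s] for e in examples]
        keep = [i for i, v in enumerate(lab) if v is not None]
        ps.append(preds[s].to_numpy()[keep])
        ys.append(np.array([float(lab[i]) for i in keep]))
    return classification_metrics(np.concatenate(ps), np.concatenate(ys))


def evaluate_fold_metric(results: SymptomSequenceResults,
                         examples: list[Example]) -> float:
    """Scalar model-selection metric on held-out examples: mean AUC
    over heads for deterioration models, mean R² for score models."""
    preds = results.predict(examples)
    cfg = results.config
    vals = []
    for s in cfg.heads:
        if cfg.task == "deterioration":
            lab = [e.deterioration_labels[s] for e in examples]
            keep = [i for i, v in enumerate(lab) if v is not None]
            if not keep:
                continue
            m = classification_metrics(preds[s].to_numpy()[keep],
                                       [float(lab[i]) for i in keep])
            if m["auc_defined"]:
                vals.append(m["auc"])
        else:
            y = [e.score_labels[s] for e in examples]
            m = regression_metrics(preds[s].to_numpy(), y,
                                   scale_span(s, results.model.scale_ranges))
            if m["r2_defined"]:
                vals.append(m["r2"])
    return float(np.mean(vals)) if vals else float("nan")


# ---------------------------------------------------------------------------
# permutation importance
# ---------------------------------------------------------------------------

def permutation_importance(results: SymptomSequenceResults,
                           examples: list[Example], scale: str | None = None,
                           n_repeats: int = 5, seed: int = 0) -> pd.DataFrame:
    """Mean metric drop (AUC for deterioration, R² for score) when one
    feature's 672-row column block is permuted across examples.

    ``scale`` picks the head to score (defaults to the model's only
    head for single mode, the mean over heads for multi). Returns a
    frame with columns feature, importance, rank (1 = most important).
    """
    if not examples:
        raise ValueError("external example set is empty")
    cfg = results.config
    rng = np.random.default_rng(seed)
    X = results.scaler.transform_batch(list(examples))

    def metric_of(Xmat: np.ndarray) -> float:
        out = results.net.forward(Xmat, train=False)
        vals = []
        heads = [scale] if scale is not None else list(cfg.heads)
        for s in heads:
            z = out[s]
            if cfg.task == "deterioration":
                from .nn import _sigmoid
                p = _sigmoid(z)
                lab = [e.deterioration_labels[s] for e in examples]
                keep = [i for i, v in enumerate(lab) if v is not None]
                m = classification_metrics(p[keep], [float(lab[i]) for i in keep])
                if m["auc_defined"]:
                    vals.append(m["auc"])
            else:
                lo, hi = results.model.scale_ranges[s]
                p = np.clip(z * (hi - lo) + lo, lo, hi)
                y = [e.score_labels[s] for e in examples]
                m = regression_metrics(p, y, hi - lo)
                if m["r2_defined"]:
                    vals.append(m["r2"])
        return float(np.mean(vals)) if vals else float("nan")

    base = metric_of(X)
    n = len(examples)
    importances = np.zeros(len(INPUT_REGISTRY))
    for j in range(len(INPUT_REGISTRY)):
        drops = []
        for _ in range(n_repeats):
            perm = rng.permutation(n)
            Xp = X.copy()
            Xp[:, :, j] = X[perm, :, j]
            drops.append(base - metric_of(Xp))
        importances[j] = float(np.mean(drops))
    order = np.argsort(-importances, kind="stable")
    ranks = np.empty(len(order), dtype=int)
    ranks[order] = np.arange(1, len(order) + 1)
    return pd.DataFrame({"feature": list(INPUT_REGISTRY),
                         "importance": importances, "rank": ranks,
                         "top5": ranks <= 5})


# ---------------------------------------------------------------------------
# t-SNE ward visualization
# ---------------------------------------------------------------------------

def tsne_ward_plot(feature_rows: pd.DataFrame, ward_labels, seed: int = 0,
                   perplexity: float = 30.0, max_iter: int = 1000,
                   out_path: str | Path | None = None):
    """2-D t-SNE embedding of hourly 31-feature rows, colored by ward.

    Requires at least two wards and ``3 × perplexity`` rows. Returns
    ``(embedding, figure)``.
    """
    from sklearn.manifold import TSNE

    X = np.asarray(feature_rows, dtype=float)
    labels = np.asarray(ward_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need rows from at least 2 wards")
    if len(X) < 3 * perplexity:
        raise ValueError(
            f"{len(X)} rows is too few for perplexity {perplexity}; "
            f"supply at least {int(3 * perplexity)} rows or lower the perplexity")
    emb = TSNE(n_components=2, perplexity=perplexity, init="pca",
               max_iter=max_iter, random_state=seed).fit_transform(X)

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 5))
    for w in np.unique(labels):
        m = labels == w
        ax.scatter(emb[m, 0], emb[m, 1], s=6, alpha=0.6, label=str(w))
    ax.legend(title="ward", fontsize=8)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.set_title("Hourly sensor features by ward")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
    return emb, fig


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentConfig:
    """Settings of one full run of the validation design."""

    cutoff_date: date = DEFAULT_CUTOFF
    k_folds: int = 5
    search_budget: int = 0              # 0 = use default hyperparameters
    max_epochs: int = 60
    seed: int = 0
    scales: tuple[str, ...] = SCALE_NAMES
    tasks: tuple[str, ...] = ("deterioration", "score")
    run_importance: bool = True
    run_tsne: bool = True
    importance_repeats: int = 5
    tsne_rows: int = 1200
    tsne_perplexity: float = 30.0


@dataclass
class MetricsReport:
    """Per-configuration, per-scale, per-split results with fold
    structure, pooled ROC curves, importance tables and trial logs."""

    deterioration: pd.DataFrame = field(default_factory=pd.DataFrame)
    score: pd.DataFrame = field(default_factory=pd.DataFrame)
    pooled_rocs: dict = field(default_factory=dict)    # (config, scale) -> DataFrame
    importance: pd.DataFrame = field(default_factory=pd.DataFrame)
    trials: dict = field(default_factory=dict)
    exclusions: pd.DataFrame = field(default_factory=pd.DataFrame)
    config: ExperimentConfig | None = None

    def to_json(self) -> str:
        def _clean(df: pd.DataFrame) -> list[dict]:
            return json.loads(df.to_json(orient="records"))
        payload = {
            "deterioration": _clean(self.deterioration),
            "score": _clean(self.score),
            "importance": _clean(self.importance) if len(self.importance) else [],
        }
        return json.dumps(payload, indent=2)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "metrics.json").write_text(self.to_json())
        if len(self.deterioration):
            self.deterioration.to_csv(out / "deterioration_metrics.csv", index=False)
        if len(self.score):
            self.score.to_csv(out / "score_metrics.csv", index=False)
        if len(self.importance):
            self.importance.to_csv(out / "importance.csv", index=False)
        for (cfg_name, s), df in self.pooled_rocs.items():
            df.to_csv(out / f"roc_{cfg_name}_{s}.csv", index=False)
        for name, df in self.trials.items():
            df.to_csv(out / f"trials_{name}.csv", index=False)


def _det_eval(preds: pd.DataFrame, examples: list[Example], s: str):
    lab = [e.deterioration_labels[s] for e in examples]
    keep = [i for i, v in enumerate(lab) if v is not None]
    if not keep:
        return None, None, None
    p = preds[s].to_numpy()[keep]
    y = np.array([float(lab[i]) for i in keep])
    m = classification_metrics(p, y)
    curve = None
    if m["auc_defined"]:
        fpr, tpr, _ = roc_curve(y, p)
        curve = (fpr, tpr)
    return m, curve, (p, y)


def _fit_eval_config(cfg: ModelConfig, dataset: ExampleDataset, plan: FoldPlan,
                     exp: ExperimentConfig,
                     scale_ranges: dict) -> dict:
    """Cross-validate, refit on all cv data, externally validate."""
    cv_ex = dataset.split("cv")
    ext_ex = dataset.split("external")
    tc = TrainConfig(max_epochs=exp.max_epochs, seed=exp.seed)
    label = f"{cfg.mode}_{cfg.task}" + (f"_{cfg.scale}" if cfg.scale else "")

    trials = None
    if exp.search_budget > 0:
        sr = random_search(cv_ex, cfg, budget=exp.search_budget,
                           k=min(3, plan.k), seed=exp.seed,
                           max_epochs=max(5, exp.max_epochs // 2),
                           scale_ranges=scale_ranges)
        cfg = sr.best_model_config
        tc = dataclasses.replace(sr.best_train_config, max_epochs=exp.max_epochs)
        trials = sr.trials

    fold_rows = []
    fold_curves: dict[str, list] = {s: [] for s in cfg.heads}
    pooled_pairs: dict[str, list] = {s: [] for s in cfg.heads}
    for fold in range(plan.k):
        tr = [e for e in cv_ex if plan.assignment[e.participant_id] != fold]
        te = [e for e in cv_ex if plan.assignment[e.participant_id] == fold]
        if not tr or not te:
            continue
        res = SymptomSequenceModel(tr, config=cfg, scale_ranges=scale_ranges).fit(tc)
        preds = res.predict(te)
        for s in cfg.heads:
            if cfg.task == "deterioration":
                m, curve, pair = _det_eval(preds, te, s)
                if m is None:
                    continue
                fold_rows.append({"fold": fold, "scale": s, **m})
                if curve is not None:
                    fold_curves[s].append(curve)
                pooled_pairs[s].append(pair)
            else:
                y = [e.score_labels[s] for e in te]
                m = regression_metrics(preds[s], y, scale_span(s, scale_ranges))
                fold_rows.append({"fold": fold, "scale": s, **m})
                pooled_pairs[s].append((preds[s].to_numpy(), np.asarray(y, float)))

    final = SymptomSequenceModel(cv_ex, config=cfg, scale_ranges=scale_ranges).fit(tc)
    ext_rows = []
    if ext_ex:
        preds = final.predict(ext_ex)
        for s in cfg.heads:
            if cfg.task == "deterioration":
                m, _, pair = _det_eval(preds, ext_ex, s)
                if m is not None:
                    ext_rows.append({"scale": s, **m, "pair": pair})
            else:
                y = [e.score_labels[s] for e in ext_ex]
                m = regression_metrics(preds[s], y, scale_span(s, scale_ranges))
                ext_rows.append({"scale": s, **m,
                                 "pair": (preds[s].to_numpy(), np.asarray(y, float))})
    return {"label": label, "config": cfg, "results": final,
            "fold_rows": pd.DataFrame(fold_rows), "ext_rows": ext_rows,
            "fold_curves": fold_curves, "trials": trials}


def _norm_pairs(pairs, scale_ranges, scale):
    lo, hi = scale_ranges[scale]
    return [((p - lo) / (hi - lo), (y - lo) / (hi - lo)) for p, y in pairs]


def run_experiment(cohort, out_dir: str | Path | None = None,
                   exp: ExperimentConfig | None = None,
                   feature_config: FeatureConfig | None = None) -> MetricsReport:
    """Run the full validation design on a cohort (a directory written
    by the simulator or a loaded bundle): featurize → build examples →
    for each of the four configurations (Single/Multi × Deterioration/
    Score) cross-validate, refit and externally validate; compute
    pooled ROC curves, permutation importance and the t-SNE figure."""
    exp = exp or ExperimentConfig()
    bundle = load_cohort(cohort) if not isinstance(cohort, CohortBundle) else cohort
    scale_ranges = bundle.config.scale_ranges

    series, exclusions = featurize_cohort(bundle, feature_config)
    dataset = build_dataset(bundle, series, exp.cutoff_date)
    cv_pids = dataset.participants("cv")
    k = min(exp.k_folds, len(cv_pids))
    if k < 2:
        raise ValueError(f"need >= 2 cross-validation participants, have {len(cv_pids)}")
    plan = make_folds(cv_pids, k, seed=exp.seed)

    configs: list[ModelConfig] = []
    for task in exp.tasks:
        for s in exp.scales:
            configs.append(ModelConfig(mode="single", task=task, scale=s))
        configs.append(ModelConfig(mode="multi", task=task))

    det_rows, score_rows = [], []
    pooled_rocs, trials, imp_rows = {}, {}, []
    for cfg in configs:
        out = _fit_eval_config(cfg, dataset, plan, exp, scale_ranges)
        fr = out["fold_rows"]
        name = f"{cfg.mode}" + (f"({cfg.scale})" if cfg.scale else "")
        if out["trials"] is not None:
            trials[out["label"]] = out["trials"]
        scales_here = list(cfg.heads)
        # per-scale cv mean (SD) + external point values
        for s in scales_here:
            sub = fr[fr["scale"] == s] if len(fr) else fr
            ext = next((r for r in out["ext_rows"] if r["scale"] == s), None)
            if cfg.task == "deterioration":
                row = {"configuration": name, "mode": cfg.mode, "scale": s,
                       "cv_accuracy_mean": sub["accuracy"].mean() if len(sub) else np.nan,
                       "cv_accuracy_sd": sub["accuracy"].std(ddof=1) if len(sub) > 1 else np.nan,
                       "cv_auc_mean": sub["auc"].mean() if len(sub) else np.nan,
                       "cv_auc_sd": sub["auc"].std(ddof=1) if len(sub) > 1 else np.nan,
                       "ext_accuracy": ext["accuracy"] if ext else np.nan,
                       "ext_auc": ext["auc"] if ext else np.nan}
                det_rows.append(row)
                if out["fold_curves"][s]:
                    pooled_rocs[(out["label"], s)] = pooled_roc(out["fold_curves"][s])
            else:
                row = {"configuration": name, "mode": cfg.mode, "scale": s,
                       "cv_r2_mean": sub["r2"].mean() if len(sub) else np.nan,
                       "cv_r2_sd": sub["r2"].std(ddof=1) if len(sub) > 1 else np.nan,
                       "cv_nrmse_mean": sub["nrmse"].mean() if len(sub) else np.nan,
                       "cv_nrmse_sd": sub["nrmse"].std(ddof=1) if len(sub) > 1 else np.nan,
                       "ext_r2": ext["r2"] if ext else np.nan,
                       "ext_nrmse": ext["nrmse"] if ext else np.nan}
                score_rows.append(row)
        # pooled "overall" row for multi configurations (and for the
        # single family, pooled across its per-scale models at the end)
        if exp.run_importance and dataset.split("external"):
            for s in scales_here:
                imp = permutation_importance(out["results"], dataset.split("external"),
                                             scale=s, n_repeats=exp.importance_repeats,
                                             seed=exp.seed)
                imp["model"] = f"{name}-{cfg.task}-{s}"
                imp_rows.append(imp)

    report = MetricsReport(
        deterioration=pd.DataFrame(det_rows), score=pd.DataFrame(score_rows),
        pooled_rocs=pooled_rocs,
        importance=pd.concat(imp_rows, ignore_index=True) if imp_rows else pd.DataFrame(),
        trials=trials, exclusions=exclusions, config=exp)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.save(out)
        if exp.run_tsne:
            rows, labels = sample_feature_rows(bundle, series, n_rows=exp.tsne_rows,
                                               seed=exp.seed)
            perp = min(exp.tsne_perplexity, max(5.0, len(rows) / 4))
            try:
                tsne_ward_plot(rows, labels, seed=exp.seed, perplexity=perp,
                               out_path=out / "tsne_wards.png")
            except ValueError as err:
                warnings.warn(f"t-SNE skipped: {err}", stacklevel=2)
    return report


def sample_feature_rows(bundle: CohortBundle, series: dict, n_rows: int = 1200,
                        seed: int = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample hourly 31-feature rows (sensor features + age/100 + sex)
    across participants, with their ward labels, for the t-SNE view."""
    rng = np.random.default_rng(seed)
    meta = bundle.metadata.set_index("participant_id")
    frames, labels = [], []
    per = max(1, n_rows // max(len(series), 1))
    for pid, fs in series.items():
        f = fs.features
        take = min(per, len(f))
        idx = rng.choice(len(f), size=take, replace=False)
        sub = f.iloc[np.sort(idx)].copy()
        m = meta.loc[pid]
        sub["age"] = float(m["age"]) / 100.0
        sub["sex"] = 1.0 if m["sex"] == "F" else 0.0
        frames.append(sub[list(INPUT_REGISTRY)])
        labels.extend([str(m["ward"])] * take)
    rows = pd.concat(frames, ignore_index=True)
    return rows, np.asarray(labels)
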