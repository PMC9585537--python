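"""End-to-end orchestration and evaluation metrics.

Stage order: impute -> stratified split -> standardize (fit on train) ->
K-means noise filter (train rows only) -> discriminant feature extraction
-> patient-similarity kNN graph over all retained nodes -> transductive
GCN training with epoch checkpoints -> confusion/ROC metrics on the test
nodes.  Every stage draws randomness from the single configured seed, so a
fixed config yields byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy.stats import rankdata

from cardiodx import cluster_denoise, datakit, graphnet, lqda
from cardiodx.datakit import FeatureTable

__all__ = [
    "Metrics",
    "confusion_metrics",
    "roc_auc",
    "dataset_summary",
    "run_pipeline",
    "config_hash",
    "DEFAULT_CONFIG",
]

logger = logging.getLogger(__name__)


@dataclass
class Metrics:
    """Binary confusion counts and the derived rates."""

    TP: int
    FP: int
    TN: int
    FN: int
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_score: float
    auc: float | None = None
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return asdict(self)


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """Confusion counts and rates; undefined ratios return 0 with a warning flag."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    warnings: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.append(f"{name} undefined (zero denominator); reported as 0")
            return 0.0
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    if prec + sens == 0:
        f_score = 0.0
    else:
        f_score = 2.0 * prec * sens / (prec + sens)
    return Metrics(
        TP=tp, FP=fp, TN=tn, FN=fn,
        accuracy=(tp + tn) / y_true.size,
        sensitivity=sens, specificity=spec, precision=prec, f_score=f_score,
        warnings=warnings,
    )


def roc_auc(scores: np.ndarray, y_true: np.ndarray) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic (ties half)."""
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    if scores.shape != y_true.shape:
        raise ValueError("length mismatch")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    rank_sum_pos = ranks[y_true == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def dataset_summary(table: FeatureTable) -> dict:
    """Per-class counts and percentages (2 decimals, round-half-even)."""
    y = np.asarray(table.y)
    total = y.size
    classes = sorted(int(c) for c in np.unique(y))
    summary = {"total": total, "classes": {}}
    for cls in classes:
        count = int((y == cls).sum())
        summary["classes"][cls] = {
            "count": count,
            "percent": round(100.0 * count / total, 2),
        }
    return summary


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "data": {
        "kind": "synthetic",
        "path": None,
        "dialect": "processed_14",
        "n_per_class": [200, 200],
        "n_features": 13,
        "separation": 4.0,
        "outlier_fraction": 0.0,
        "missing_fraction": 0.0,
    },
    "split": {"test_fraction": 0.3},
    "cluster": {"k": None, "quantile": 0.95, "restarts": 5},
    "features": {
        "kernel": "rbf",
        "sigma": None,
        "degree": 2,
        "alpha": 0.5,
        "gamma": 0.1,
        "class_scheme": "raw",
    },
    "graph": {"k_nn": 10, "sigma": "auto"},
    "train": {
        "hidden": [16, 16],
        "K": 3,
        "lambda_cut": 0.1,
        "g_c": 2,
        "epochs": 500,
        "lr": 0.05,
        "momentum": 0.9,
        "checkpoints": [100, 200, 300, 400, 500],
    },
    "classifier": "gcn",
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _load_table(cfg: dict, seed: int) -> FeatureTable:
    data = cfg["data"]
    if data["kind"] == "uci":
        if not data.get("path"):
            raise ValueError("stage load: uci data requires a path")
        return datakit.read_uci_heart(data["path"], dialect=data.get("dialect", "processed_14"))
    if data["kind"] == "synthetic":
        j = int(data["n_features"])
        sep = float(data["separation"])
        mu1 = np.full(j, sep / np.sqrt(j))  # ||mu1 - mu0|| = sep, unit covariance
        spec = datakit.SyntheticSpec(
            n_per_class=tuple(int(n) for n in data["n_per_class"]),
            means=(np.zeros(j), mu1),
            covariances=(np.eye(j), np.eye(j)),
            outlier_fraction=float(data["outlier_fraction"]),
            missing_fraction=float(data["missing_fraction"]),
            seed=seed,
        )
        return datakit.generate_synthetic(spec)
    raise ValueError(f"stage load: unknown data kind {data['kind']!r}")


def run_pipeline(config: dict | None = None) -> dict:
    """Execute all stages and return the run report.

    The report carries the config hash, per-stage row counts, a dataset
    summary, and an epoch-checkpoint metrics table (one row per checkpoint
    for the GCN classifier; a single row for the Mahalanobis classifier).
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    seed = int(cfg["seed"])
    report: dict = {"config_hash": config_hash(cfg), "seed": seed, "stages": {}}

    # --- load & clean -----------------------------------------------------
    table = _load_table(cfg, seed)
    report["stages"]["loaded_rows"] = table.n_samples
    y_raw = table.y.copy()
    y_bin = datakit.binarize_target(np.clip(y_raw, 0, 4))
    table = datakit.impute_missing(table)
    report["dataset_summary"] = dataset_summary(
        FeatureTable(table.X, y_bin, table.missing, table.names)
    )

    # --- split & standardize ---------------------------------------------
    train_idx, test_idx = datakit.stratified_split(
        y_bin, float(cfg["split"]["test_fraction"]), seed
    )
    X_train_raw = table.X[train_idx]
    Xs_train, mean, std = datakit.standardize(X_train_raw)
    Xs_test, _, _ = datakit.standardize(table.X[test_idx], mean, std)
    report["stages"]["train_rows"] = int(train_idx.size)
    report["stages"]["test_rows"] = int(test_idx.size)

    # --- cluster-based noise filter (train only) ---------------------------
    ccfg = cfg["cluster"]
    model_km = cluster_denoise.kmeans_fit(
        Xs_train,
        k=ccfg["k"],
        seed=seed,
        n_restarts=int(ccfg["restarts"]),
    )
    train_table = FeatureTable(
        Xs_train,
        y_raw[train_idx],
        np.zeros_like(Xs_train, dtype=bool),
        table.names,
        outlier_flags=None if table.outlier_flags is None else table.outlier_flags[train_idx],
    )
    filtered, removed = cluster_denoise.filter_noise(
        train_table, model_km, quantile=float(ccfg["quantile"])
    )
    kept_mask = np.ones(train_idx.size, dtype=bool)
    kept_mask[removed] = False
    report["stages"]["filtered_train_rows"] = filtered.n_samples
    report["stages"]["removed_rows"] = int(removed.size)

    # --- discriminant features --------------------------------------------
    fcfg = cfg["features"]
    kernel = lqda.KernelSpec(
        kind=fcfg["kernel"],
        sigma=fcfg["sigma"],
        degree=int(fcfg["degree"]),
    )
    y_train_bin = y_bin[train_idx][kept_mask]
    if fcfg["class_scheme"] == "raw":
        y_fit = filtered.y  # raw 0-4 codes where available
    elif fcfg["class_scheme"] == "binary":
        y_fit = y_train_bin
    else:
        raise ValueError(f"stage features: unknown class_scheme {fcfg['class_scheme']!r}")
    kda = lqda.fit_kda(
        filtered.X, y_fit, kernel=kernel,
        alpha=float(fcfg["alpha"]), gamma=float(fcfg["gamma"]),
    )
    F_train = lqda.project(filtered.X, kda)
    F_test = lqda.project(Xs_test, kda)
    report["stages"]["feature_dim"] = kda.M

    y_test = y_bin[test_idx]
    metrics_rows: list[dict] = []

    if cfg["classifier"] == "lqda":
        # Mahalanobis classifier needs a model fitted on binary labels
        kda_bin = lqda.fit_kda(
            filtered.X, y_train_bin, kernel=kernel,
            alpha=float(fcfg["alpha"]), gamma=float(fcfg["gamma"]),
        )
        pred, d = lqda.mahalanobis_classify(lqda.project(Xs_test, kda_bin), kda_bin)
        m = confusion_metrics(y_test, pred)
        m.auc = roc_auc(d[:, 0] - d[:, 1], y_test)
        row = {"epoch": None, **m.as_dict()}
        metrics_rows.append(row)
    elif cfg["classifier"] == "gcn":
        # --- graph over filtered-train + test nodes (transductive) --------
        gcfg, tcfg = cfg["graph"], cfg["train"]
        F_all = np.vstack([F_train, F_test])
        y_all = np.concatenate([y_train_bin, y_test])
        mask = np.zeros(F_all.shape[0], dtype=bool)
        mask[: F_train.shape[0]] = True
        graph = graphnet.build_knn_graph(
            F_all, k_nn=int(gcfg["k_nn"]), sigma=gcfg["sigma"]
        )
        report["stages"]["graph_nodes"] = graph.n_nodes

        def eval_fn(epoch: int, probs: np.ndarray) -> dict:
            p_test = probs[~mask]
            m = confusion_metrics(y_test, (p_test[:, 1] >= 0.5).astype(int))
            m.auc = roc_auc(p_test[:, 1], y_test)
            return {"epoch": epoch, **m.as_dict()}

        gcn = graphnet.train_gcn(
            graph, F_all, y_all, mask,
            hidden=tuple(int(h) for h in tcfg["hidden"]),
            K=int(tcfg["K"]),
            lambda_cut=float(tcfg["lambda_cut"]),
            g_c=int(tcfg["g_c"]),
            epochs=int(tcfg["epochs"]),
            lr=float(tcfg["lr"]),
            momentum=float(tcfg["momentum"]),
            seed=seed,
            checkpoints=tuple(int(e) for e in tcfg["checkpoints"]),
            eval_fn=eval_fn,
        )
        metrics_rows = gcn.history
    else:
        raise ValueError(f"stage classify: unknown classifier {cfg['classifier']!r}")

    report["metrics_table"] = metrics_rows
    report["final_metrics"] = metrics_rows[-1] if metrics_rows else None
    return report
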