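"""Connectome-based classification with NBS feature selection.

Subjects are classified (patient vs control) from their vectorized Fisher-z
connectivity inside a nested, stratified cross-validation loop.  In each
outer fold, edge-wise group statistics and suprathreshold connected
components are computed on the *training subjects only*; the Fisher-z values
of the largest component's edges are the features (falling back to the top-k
edges by |t| when no edge survives the selection threshold, as happens under
the null).  The inner loop picks the regularization strength of a
linear-kernel support-vector classifier; accuracy, sensitivity and
specificity are aggregated over outer folds, along with per-edge selection
frequencies and mean SVM weights for interpretability.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._utils import rng_from
from .nbs import edgewise_stats, suprathreshold_components

__all__ = ["ClassifierConfig", "ClassificationResult", "NBSPredict", "nested_cv_classify", "contribution_map"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassifierConfig:
    """Nested-CV settings for the connectome classifier."""

    outer_folds: int = 10
    inner_folds: int = 5
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0)
    t0_selection: float = 3.5
    fallback_k: int = 10
    repeats: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must be >= 2")
        if not self.c_grid:
            raise ValueError("regularization grid must be nonempty")
        if any(c <= 0 for c in self.c_grid):
            raise ValueError("regularization values must be positive")


@dataclass
class ClassificationResult:
    """Aggregated nested-CV performance and edge-level interpretability."""

    accuracy: float
    sensitivity: float
    specificity: float
    fold_metrics: pd.DataFrame
    edge_selection_frequency: np.ndarray = field(repr=False)
    mean_edge_weight: np.ndarray = field(repr=False)
    config: ClassifierConfig | None = None

    def summary(self) -> str:
        n_sel = int(np.count_nonzero(self.edge_selection_frequency))
        lines = [
            "NBS-feature-selected SVM (nested cross-validation)",
            f"  accuracy:    {self.accuracy:.3f}",
            f"  sensitivity: {self.sensitivity:.3f}",
            f"  specificity: {self.specificity:.3f}",
            f"  folds: {len(self.fold_metrics)}   edges ever selected: {n_sel}",
        ]
        return "\n".join(lines)


def _confound_residualize(
    train_X: np.ndarray, test_X: np.ndarray, train_C: np.ndarray, test_C: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Remove covariate effects from features, fitting on the training fold only."""
    beta = np.linalg.lstsq(train_C, train_X, rcond=None)[0]
    return train_X - train_C @ beta, test_X - test_C @ beta


def nested_cv_classify(
    fc_stack: np.ndarray,
    labels: np.ndarray,
    edge_pairs: np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
    design: pd.DataFrame | None = None,
    remove_confounds: bool = False,
) -> ClassificationResult:
    """Nested-CV linear SVM with fold-wise NBS feature selection.

    Parameters
    ----------
    labels : array of {0, 1}
        1 = patient (positive class for sensitivity).
    design : DataFrame, optional
        Design matrix for the fold-wise edge statistics (its rows are
        subset per fold).  When omitted, an intercept + group design built
        from the training labels is used.
    remove_confounds : bool
        If True (and a design is given), nuisance columns are regressed out
        of the features, with coefficients estimated on the training fold.
    """
    X = np.asarray(fc_stack, dtype=float)
    y = np.asarray(labels).astype(int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("labels contain a single class; classification undefined")
    if not set(classes) <= {0, 1}:
        raise ValueError("labels must be coded 0 (control) / 1 (patient)")
    n, n_edges = X.shape

    rng = rng_from(config.seed, 11)
    freq = np.zeros(n_edges)
    wsum = np.zeros(n_edges)
    rows = []
    n_folds_total = 0
    for rep in range(config.repeats):
        outer = StratifiedKFold(
            n_splits=config.outer_folds, shuffle=True, random_state=int(rng.integers(2**31))
        )
        for fold, (tr, te) in enumerate(outer.split(X, y)):
            feats, weights = _fit_outer_fold(X, y, edge_pairs, tr, te, config, design, remove_confounds, rows, fold, rep, rng)
            freq[feats] += 1
            wsum[feats] += np.abs(weights)
            n_folds_total += 1

    fold_df = pd.DataFrame(
        rows, columns=["repeat", "fold", "n_features", "fallback", "best_c", "accuracy", "sensitivity", "specificity"]
    )
    sel_freq = freq / n_folds_total
    with np.errstate(invalid="ignore"):
        mean_w = np.where(freq > 0, wsum / np.maximum(freq, 1), 0.0)
    return ClassificationResult(
        accuracy=float(fold_df["accuracy"].mean()),
        sensitivity=float(fold_df["sensitivity"].mean()),
        specificity=float(fold_df["specificity"].mean()),
        fold_metrics=fold_df,
        edge_selection_frequency=sel_freq,
        mean_edge_weight=mean_w,
        config=config,
    )


def _fit_outer_fold(
    X, y, edge_pairs, tr, te, config, design, remove_confounds, rows, fold, rep, rng
):
    y_tr, y_te = y[tr], y[te]
    if np.unique(y_tr).size < 2:
        raise ValueError("an outer training fold contains a single class")

    # --- feature selection on training subjects only ---
    if design is not None:
        fold_design = design.iloc[tr]
        stats = edgewise_stats(X[tr], fold_design, contrast="patient_lt_control")
    else:
        Xd = np.column_stack([np.ones(len(tr)), y_tr.astype(float)])
        stats = edgewise_stats(X[tr], Xd, contrast="patient_lt_control")
    comps = suprathreshold_components(stats, edge_pairs, config.t0_selection)
    fallback = not comps
    if comps:
        pair_pos = {tuple(p): k for k, p in enumerate(np.asarray(edge_pairs).tolist())}
        feats = np.array(sorted(pair_pos[e] for e in comps[0].edges))
    else:
        k = min(config.fallback_k, X.shape[1])
        feats = np.sort(np.argsort(-np.abs(stats))[:k])
        logger.info("no suprathreshold edge in fold %d; falling back to top-%d by |t|", fold, k)

    X_tr, X_te = X[tr][:, feats], X[te][:, feats]
    if remove_confounds and design is not None:
        nuis_cols = [c for c in design.columns if c != "group"]
        C = design[nuis_cols].to_numpy(dtype=float)
        X_tr, X_te = _confound_residualize(X_tr, X_te, C[tr], C[te])

    # --- inner CV over the regularization grid (ties -> smaller C) ---
    inner = StratifiedKFold(
        n_splits=config.inner_folds, shuffle=True, random_state=int(rng.integers(2**31))
    )
    inner_scores = []
    for c in config.c_grid:
        accs = []
        for itr, ite in inner.split(X_tr, y_tr):
            scaler = StandardScaler().fit(X_tr[itr])
            clf = SVC(kernel="linear", C=c).fit(scaler.transform(X_tr[itr]), y_tr[itr])
            accs.append(clf.score(scaler.transform(X_tr[ite]), y_tr[ite]))
        inner_scores.append(np.mean(accs))
    best_c = config.c_grid[int(np.argmax(inner_scores))]

    scaler = StandardScaler().fit(X_tr)
    clf = SVC(kernel="linear", C=best_c).fit(scaler.transform(X_tr), y_tr)
    pred = clf.predict(scaler.transform(X_te))
    acc = float((pred == y_te).mean())
    pos, neg = y_te == 1, y_te == 0
    sens = float((pred[pos] == 1).mean()) if pos.any() else np.nan
    spec = float((pred[neg] == 0).mean()) if neg.any() else np.nan
    rows.append((rep, fold, len(feats), fallback, best_c, acc, sens, spec))
    return feats, clf.coef_.ravel()


def contribution_map(
    result: ClassificationResult, edge_index: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Edges ranked by selection frequency (ties by |mean weight|).

    Edges never selected are omitted; an empty table (with a warning) results
    when no edge was ever selected.
    """
    if len(result.fold_metrics) < 2:
        raise ValueError("contribution map needs results from >= 2 folds")
    sel = np.flatnonzero(result.edge_selection_frequency > 0)
    df = pd.DataFrame(
        {
            "edge": sel,
            "selection_frequency": result.edge_selection_frequency[sel],
            "mean_abs_weight": result.mean_edge_weight[sel],
        }
    )
    if df.empty:
        logger.warning("no edge was ever selected; contribution map is empty")
        return df
    df = df.sort_values(
        ["selection_frequency", "mean_abs_weight", "edge"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    if edge_index is not None:
        df = df.merge(edge_index[["edge", "region_i", "region_j"]], on="edge", how="left")
    return df


class NBSPredict:
    """Model wrapper: nested-CV SVM with NBS feature selection.

    ``NBSPredict(fc_stack, labels, edge_pairs, config).fit()`` returns a
    :class:`ClassificationResult`.
    """

    def __init__(
        self,
        fc_stack: np.ndarray,
        labels: np.ndarray,
        edge_pairs: np.ndarray,
        config: ClassifierConfig = ClassifierConfig(),
        design: pd.DataFrame | None = None,
    ):
        self.fc_stack = fc_stack
        self.labels = labels
        self.edge_pairs = edge_pairs
        self.config = config
        self.design = design

    def fit(self, remove_confounds: bool = False) -> ClassificationResult:
        return nested_cv_classify(
            self.fc_stack,
            self.labels,
            self.edge_pairs,
            config=self.config,
            design=self.design,
            remove_confounds=remove_confounds,
        )
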