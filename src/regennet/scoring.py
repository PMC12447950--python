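"""Per-trajectory TF→target edge scoring and held-out evaluation.

The built-in scorer is a pluggable stand-in for CNN-based predictors with
the same contract: one score in [0, 1] per directed TF→target pair from
pseudotime-ordered expression. Cells are averaged into equal-occupancy
pseudotime bins and the score is the maximum absolute Spearman rank
correlation between the TF's bins and the target's bins shifted forward by
1..max_lag, which rewards the regulator-precedes-target timing signature.
Externally computed score tables (e.g., from a trained network) can be
loaded from TSV and flow through the identical downstream path.

Held-out evaluation ranks each validation TF's candidate targets by score
and reports AUPRC (step integration, i.e. average precision) and
precision at k; training-split TFs are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy.stats import rankdata
from sklearn.metrics import average_precision_score

from .preprocess import LOGNORM_LAYER, Trajectory

__all__ = [
    "EdgeScoreTable",
    "GroundTruth",
    "score_pairs",
    "load_external_scores",
    "evaluate_holdout",
]


@dataclass
class EdgeScoreTable:
    """TF→target scores for one trajectory.

    ``df`` has columns ``tf, target, score`` (plus optional ``lag`` and
    ``sign`` from the built-in scorer); (tf, target) pairs are unique and
    scores lie in [0, 1].
    """

    df: pd.DataFrame
    trajectory: str
    provenance: str  # external | builtin

    def __post_init__(self) -> None:
        need = {"tf", "target", "score"}
        missing = need - set(self.df.columns)
        if missing:
            raise ValueError(f"missing column(s): {sorted(missing)}")
        dup = self.df.duplicated(subset=["tf", "target"])
        if dup.any():
            pair = self.df.loc[dup.idxmax(), ["tf", "target"]]
            raise ValueError(
                f"duplicate (tf, target) pair: ({pair['tf']}, {pair['target']})")
        s = self.df["score"].to_numpy(dtype=float)
        if not np.all(np.isfinite(s)) or s.min() < 0.0 or s.max() > 1.0:
            raise ValueError("scores must be finite and in [0, 1]")

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


@dataclass
class GroundTruth:
    """TF → true target set, with a train/validation split label per TF."""

    targets: dict[str, set[str]]
    split: dict[str, str]

    def __post_init__(self) -> None:
        for tf in self.targets:
            if self.split.get(tf) not in ("train", "validation", None):
                raise ValueError(f"bad split label for {tf}: {self.split[tf]}")

    def validation_tfs(self) -> list[str]:
        return sorted(tf for tf, s in self.split.items() if s == "validation")


def _equal_occupancy_bins(values: np.ndarray, order: np.ndarray,
                          n_bins: int) -> np.ndarray:
    """Mean expression per equal-occupancy pseudotime bin (genes stay cols)."""
    chunks = np.array_split(order, n_bins)
    return np.vstack([values[idx].mean(axis=0) for idx in chunks])


def _standardized_ranks(mat: np.ndarray) -> np.ndarray:
    """Rank each row and standardize; all-constant rows become zero."""
    r = rankdata(mat, axis=1).astype(float)
    r -= r.mean(axis=1, keepdims=True)
    norm = np.sqrt((r ** 2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm > 0, r / np.maximum(norm, 1e-300), 0.0)
    return out


def score_pairs(trajectory: Trajectory, adata: AnnData, tf_ids: list[str],
                n_bins: int = 60, max_lag: int = 5) -> EdgeScoreTable:
    """Score every TF→gene pair by maximal lagged rank correlation.

    Requires assigned pseudotime. Scores are |Spearman| between the TF's
    binned series at bins t and the candidate target's at t+lag, maximized
    over lag in 1..max_lag; the best lag and the correlation's sign are
    kept as auxiliary columns. Constant series score 0. Self-pairs are not
    emitted.
    """
    if trajectory.pseudotime is None:
        raise ValueError("trajectory has no pseudotime; run assign_pseudotime")
    if n_bins < max_lag + 2:
        raise ValueError("need n_bins >= max_lag + 2")
    missing = [t for t in tf_ids if t not in adata.var_names]
    if missing:
        raise ValueError(f"TF id(s) absent from matrix: {missing}")
    if LOGNORM_LAYER not in adata.layers:
        raise ValueError("normalized layer missing; run normalize() first")

    cells = trajectory.ordered_cells()
    sub = adata[cells]
    X = np.asarray(sub.layers[LOGNORM_LAYER])
    binned = _equal_occupancy_bins(X, np.arange(len(cells)), n_bins)  # bins x genes

    genes = list(adata.var_names)
    gidx = {g: i for i, g in enumerate(genes)}
    tf_rows = np.array([gidx[t] for t in tf_ids])

    best = np.full((len(tf_ids), len(genes)), 0.0)
    best_lag = np.zeros_like(best, dtype=int)
    best_sign = np.zeros_like(best, dtype=int)
    series = binned.T  # genes x bins
    for lag in range(1, max_lag + 1):
        tf_part = _standardized_ranks(series[tf_rows, : n_bins - lag])
        tg_part = _standardized_ranks(series[:, lag:])
        corr = tf_part @ tg_part.T  # tfs x genes
        improve = np.abs(corr) > np.abs(best)
        best = np.where(improve, corr, best)
        best_lag = np.where(improve, lag, best_lag)
    best_sign = np.sign(best).astype(int)

    rows = []
    for i, tf in enumerate(tf_ids):
        for j, g in enumerate(genes):
            if g == tf:
                continue
            rows.append((tf, g, min(1.0, abs(float(best[i, j]))),
                         int(best_lag[i, j]), int(best_sign[i, j])))
    df = pd.DataFrame(rows, columns=["tf", "target", "score", "lag", "sign"])
    return EdgeScoreTable(df=df, trajectory=trajectory.name,
                          provenance="builtin")


def load_external_scores(path, trajectory: str) -> EdgeScoreTable:
    """Load and validate a TSV of externally computed tf/target/score rows."""
    df = pd.read_csv(path, sep="\t")
    return EdgeScoreTable(df=df, trajectory=trajectory, provenance="external")


def precision_at_k(ranked_is_true: np.ndarray, k: int) -> float:
    k = min(k, len(ranked_is_true))
    return float(ranked_is_true[:k].mean()) if k else float("nan")


def auprc_step(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Average precision = step-function integral of the PR curve."""
    return float(average_precision_score(y_true, scores))


def evaluate_holdout(scores: EdgeScoreTable, truth: GroundTruth,
                     ks: tuple[int, ...] = (10,)) -> pd.DataFrame:
    """Per-validation-TF AUPRC and precision at k.

    Each validation TF's scored targets are ranked by score (ties broken
    by target id for determinism); its true target set defines the
    positives. Raises if a validation TF has no scored true target.
    """
    val_tfs = truth.validation_tfs()
    if not val_tfs:
        raise ValueError("empty validation split")
    rows = []
    for tf in val_tfs:
        sub = scores.df[scores.df["tf"] == tf].sort_values(
            ["score", "target"], ascending=[False, True], kind="mergesort")
        if sub.empty:
            raise ValueError(f"validation TF has no scored pairs: {tf}")
        true_set = truth.targets.get(tf, set())
        y = sub["target"].isin(true_set).to_numpy()
        if not y.any():
            raise ValueError(f"validation TF has no scored true targets: {tf}")
        row = {"tf": tf, "n_candidates": len(sub), "n_true": int(y.sum()),
               "auprc": auprc_step(y, sub["score"].to_numpy())}
        for k in ks:
            row[f"precision_at_{k}"] = precision_at_k(y, k)
        rows.append(row)
    return pd.DataFrame(rows)
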