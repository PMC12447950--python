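"""Single-cell QC, normalization, trajectory subsetting and pseudotime.

Expression matrices are carried as :class:`anndata.AnnData` (cells as
``obs``, genes as ``var``), the standard single-cell container. Required
``obs`` columns:

``timepoint``
    hours post ablation (hpa); one of {0, 0.5, 1, 3, 5, 10} or the string
    ``"control"`` for undamaged samples.
``cell_type``
    one of the eight neuromast cell types (see :data:`CELL_TYPES`).

``mito_fraction`` and ``n_genes_expressed`` are recomputed from the raw
counts whenever QC runs, with mitochondrial genes identified by a
configurable name-prefix list (default ``("mt-",)``).

Pseudotime is a documented stand-in for third-party principal-curve
fitting: cells are projected onto the first principal axis of the
normalized data restricted to the trajectory, the axis is oriented so the
mean projection does not decrease from the earliest to the latest
timepoint, and projections are min-max scaled to [0, 1]. Downstream edge
scoring only needs a monotone cell ordering, which this preserves on
trajectories with a dominant temporal axis of variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "CELL_TYPES",
    "TRAJECTORY_SPECS",
    "Trajectory",
    "qc_filter",
    "normalize",
    "subset_trajectory",
    "assign_pseudotime",
    "read_expression_tsv",
]

CELL_TYPES = (
    "HC progenitor", "young HC", "mature HC", "central SC",
    "DV SC", "AP SC", "amplifying SC", "mantle cell",
)

#: cell-type -> inclusive hpa interval, per trajectory
TRAJECTORY_SPECS: dict[str, dict[str, tuple[float, float]]] = {
    "SC": {"central SC": (0.0, 10.0)},
    "HC": {
        "central SC": (0.0, 3.0),
        "HC progenitor": (1.0, 5.0),
        "young HC": (3.0, 10.0),
        "mature HC": (3.0, 10.0),
    },
}

LOGNORM_LAYER = "lognorm"


@dataclass
class Trajectory:
    """An ordered cell subset with optional pseudotime in [0, 1]."""

    name: str
    cell_ids: list[str]
    spec: dict[str, tuple[float, float]]
    pseudotime: pd.Series | None = field(default=None)

    def ordered_cells(self) -> list[str]:
        if self.pseudotime is None:
            return list(self.cell_ids)
        # tie-break on cell id keeps the ordering deterministic
        df = pd.DataFrame({"pt": self.pseudotime,
                           "cid": self.pseudotime.index.astype(str)})
        return list(df.sort_values(["pt", "cid"], kind="mergesort").index)


def _counts(adata: AnnData) -> np.ndarray:
    X = adata.X
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


def compute_qc_metrics(adata: AnnData,
                       mito_prefixes: tuple[str, ...] = ("mt-",)) -> None:
    """Recompute ``n_genes_expressed`` and ``mito_fraction`` in place."""
    X = _counts(adata)
    adata.obs["n_genes_expressed"] = (X > 0).sum(axis=1)
    is_mito = np.array([g.startswith(mito_prefixes) for g in adata.var_names])
    totals = X.sum(axis=1)
    mito = X[:, is_mito].sum(axis=1) if is_mito.any() else np.zeros(X.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1e-300), 0.0)
    adata.obs["mito_fraction"] = frac


def qc_filter(adata: AnnData, lower: int = 300, upper: int = 6000,
              mito_max: float = 0.05,
              mito_prefixes: tuple[str, ...] = ("mt-",)) -> AnnData:
    """Retain cells with lower < genes expressed < upper and mito < mito_max.

    Both count inequalities are strict, as are the printed thresholds they
    default to; the gene set is unchanged. Idempotent.
    """
    if adata.n_obs == 0:
        logger.warning("qc_filter: empty matrix")
        return adata.copy()
    compute_qc_metrics(adata, mito_prefixes)
    keep = ((adata.obs["n_genes_expressed"] > lower)
            & (adata.obs["n_genes_expressed"] < upper)
            & (adata.obs["mito_fraction"] < mito_max))
    n_genes_fail = int((~((adata.obs["n_genes_expressed"] > lower)
                          & (adata.obs["n_genes_expressed"] < upper))).sum())
    n_mito_fail = int((adata.obs["mito_fraction"] >= mito_max).sum())
    logger.info("qc_filter: kept %d/%d cells (%d failed gene-count bounds, "
                "%d failed mito)", int(keep.sum()), adata.n_obs,
                n_genes_fail, n_mito_fail)
    return adata[keep.values].copy()


def normalize(adata: AnnData, scale: float = 1e4) -> AnnData:
    """Count-normalize each cell to ``scale`` total, then log1p.

    Stored in ``layers["lognorm"]``; raw counts stay in ``X``. Cells with
    zero total get an all-zero normalized vector (with a warning).
    """
    X = _counts(adata).astype(float)
    totals = X.sum(axis=1, keepdims=True)
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.warning("normalize: %d cells with zero total counts", n_zero)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(totals > 0, X / np.maximum(totals, 1e-300) * scale, 0.0)
    adata.layers[LOGNORM_LAYER] = np.log1p(norm)
    return adata


def _hpa(adata: AnnData) -> pd.Series:
    tp = adata.obs["timepoint"]
    return pd.to_numeric(tp, errors="coerce")  # "control" -> NaN


def subset_trajectory(adata: AnnData, spec: str) -> Trajectory:
    """Select the cells of the SC or HC regeneration trajectory.

    SC: central SCs across 0–10 hpa. HC: central SCs 0–3 hpa, HC
    progenitors 1–5 hpa, young and mature HCs 3–10 hpa. Interval endpoints
    are inclusive; "control" cells are never included.
    """
    if spec not in TRAJECTORY_SPECS:
        raise ValueError(f"unknown trajectory spec: {spec!r}")
    unknown = set(adata.obs["cell_type"]) - set(CELL_TYPES)
    if unknown:
        raise ValueError(f"unknown cell_type label(s): {sorted(unknown)}")
    rules = TRAJECTORY_SPECS[spec]
    hpa = _hpa(adata)
    keep = np.zeros(adata.n_obs, dtype=bool)
    for ctype, (lo, hi) in rules.items():
        keep |= ((adata.obs["cell_type"] == ctype).values
                 & (hpa >= lo).values & (hpa <= hi).values)
    return Trajectory(name=spec, cell_ids=list(adata.obs_names[keep]), spec=rules)


def assign_pseudotime(adata: AnnData, trajectory: Trajectory) -> Trajectory:
    """Assign PC1-projection pseudotime to a trajectory's cells.

    The first principal axis of the log-normalized data (trajectory cells
    only) is oriented so that the mean projection of the earliest-hpa cells
    does not exceed that of the latest-hpa cells, then min-max scaled to
    [0, 1]. A single cell gets pseudotime 0.
    """
    if not trajectory.cell_ids:
        raise ValueError("trajectory has no cells")
    if LOGNORM_LAYER not in adata.layers:
        raise ValueError("normalized layer missing; run normalize() first")
    sub = adata[trajectory.cell_ids]
    X = np.asarray(sub.layers[LOGNORM_LAYER])
    if len(trajectory.cell_ids) == 1:
        pt = pd.Series([0.0], index=trajectory.cell_ids)
        return Trajectory(trajectory.name, trajectory.cell_ids, trajectory.spec, pt)
    if np.allclose(X.var(axis=0), 0.0):
        raise ValueError("degenerate trajectory: expression constant across cells")
    proj = PCA(n_components=1, svd_solver="full", random_state=0) \
        .fit_transform(X)[:, 0]
    hpa = _hpa(sub).to_numpy(dtype=float)
    finite = np.isfinite(hpa)
    if finite.any() and len(np.unique(hpa[finite])) > 1:
        lo, hi = np.nanmin(hpa), np.nanmax(hpa)
        if proj[hpa == lo].mean() > proj[hpa == hi].mean():
            proj = -proj
    lo, hi = proj.min(), proj.max()
    pt = (proj - lo) / (hi - lo) if hi > lo else np.zeros_like(proj)
    series = pd.Series(pt, index=trajectory.cell_ids)
    return Trajectory(trajectory.name, trajectory.cell_ids, trajectory.spec, series)


def read_expression_tsv(counts_path, meta_path) -> AnnData:
    """Load a genes × cells TSV count matrix plus per-cell metadata TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    meta = meta.loc[counts.columns]
    adata = AnnData(X=counts.T.to_numpy(), obs=meta,
                    var=pd.DataFrame(index=counts.index))
    adata.obs_names = list(counts.columns)
    return adata


def write_expression_tsv(adata: AnnData, counts_path, meta_path) -> None:
    X = _counts(adata)
    pd.DataFrame(X.T, index=adata.var_names, columns=adata.obs_names) \
        .to_csv(counts_path, sep="\t")
    adata.obs.to_csv(meta_path, sep="\t")
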