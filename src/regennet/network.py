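"""Combined GRN construction, hub ranking and the scale-free diagnostic.

Per-trajectory score tables are merged by taking, for every (TF, target)
pair, the maximum score across the tables that contain it — a pair absent
from a table simply contributes nothing (absence means unscored, not
zero). Each gene then keeps only its top-k highest-scoring regulators
(k = 20 by default), which caps indegrees while leaving the outdegree
distribution free to be approximately scale-free. Hubs are ranked by
outdegree, and a maximum-likelihood fit of a discrete power law with a
bootstrap Kolmogorov–Smirnov goodness-of-fit test provides a descriptive
"approximately scale-free" flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps
from scipy.optimize import minimize_scalar

from .scoring import EdgeScoreTable

__all__ = [
    "CombinedNetwork",
    "combine_max",
    "top_k_regulators",
    "hub_ranking",
    "scale_free_diagnostic",
]


@dataclass
class CombinedNetwork:
    """Directed TF→target network with per-gene indegree capped at k."""

    edges: pd.DataFrame  # tf, target, score
    k: int

    def outdegrees(self) -> pd.Series:
        return self.edges.groupby("tf").size().sort_values(ascending=False)

    def indegrees(self) -> pd.Series:
        return self.edges.groupby("target").size()

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.tf, row.target, score=float(row.score))
        return g

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False)


def combine_max(tables: list[EdgeScoreTable]) -> EdgeScoreTable:
    """Per-pair maximum across score tables (commutative/associative/idempotent)."""
    if not tables:
        raise ValueError("need at least one score table")
    frames = [t.df[["tf", "target", "score"]] for t in tables]
    cat = pd.concat(frames, ignore_index=True)
    out = (cat.groupby(["tf", "target"], as_index=False)["score"].max()
           .sort_values(["tf", "target"], kind="mergesort")
           .reset_index(drop=True))
    name = "+".join(dict.fromkeys(t.trajectory for t in tables))
    prov = "+".join(dict.fromkeys(t.provenance for t in tables))
    return EdgeScoreTable(df=out, trajectory=name, provenance=prov)


def top_k_regulators(table: EdgeScoreTable, k: int = 20,
                     allow_self_edges: bool = False) -> CombinedNetwork:
    """Keep each target's k highest-scoring incoming TFs.

    Ties at the boundary are broken by lexicographic TF id (smaller id
    kept). Self-edges are removed before selection unless re-enabled.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = table.df[["tf", "target", "score"]]
    if not allow_self_edges:
        df = df[df["tf"] != df["target"]]
    df = df.sort_values(["target", "score", "tf"],
                        ascending=[True, False, True], kind="mergesort")
    kept = df.groupby("target", as_index=False, sort=False).head(k)
    kept = kept.sort_values(["tf", "target"], kind="mergesort") \
               .reset_index(drop=True)
    return CombinedNetwork(edges=kept, k=k)


def hub_ranking(network: CombinedNetwork) -> pd.DataFrame:
    """All TFs ordered by outdegree (descending), ties by TF id."""
    if network.edges.empty:
        return pd.DataFrame(columns=["tf", "outdegree", "rank"])
    deg = network.edges.groupby("tf").size().reset_index(name="outdegree")
    deg = deg.sort_values(["outdegree", "tf"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    deg["rank"] = np.arange(1, len(deg) + 1)
    return deg


def _zipf_negloglik(alpha: float, n: int, sum_log: float) -> float:
    return n * np.log(special.zeta(alpha, 1.0)) + alpha * sum_log


def _fit_zipf(x: np.ndarray) -> float:
    n, sum_log = len(x), float(np.log(x).sum())
    res = minimize_scalar(_zipf_negloglik, bounds=(1.01, 10.0),
                          method="bounded", args=(n, sum_log),
                          options={"xatol": 1e-6})
    return float(res.x)


def _zipf_cdf(vals: np.ndarray, alpha: float) -> np.ndarray:
    # closed form via the Hurwitz zeta: F(k) = 1 - zeta(a, k+1)/zeta(a)
    return 1.0 - special.zeta(alpha, vals.astype(float) + 1.0) \
        / special.zeta(alpha, 1.0)


def _ks_distance(x: np.ndarray, alpha: float) -> float:
    vals, counts = np.unique(x, return_counts=True)
    ecdf = np.cumsum(counts) / len(x)
    cdf = _zipf_cdf(vals, alpha)
    ecdf_prev = np.concatenate([[0.0], ecdf[:-1]])
    return float(np.max(np.maximum(np.abs(ecdf - cdf), np.abs(ecdf_prev - cdf))))


def scale_free_diagnostic(outdegrees, n_bootstrap: int = 100,
                          level: float = 0.1,
                          seed: int = 0) -> dict:
    """Fit a discrete power law (x_min = 1) and test goodness of fit.

    ``outdegrees`` may be a CombinedNetwork or an array of positive
    integers. The exponent is the zeta-distribution MLE; the
    goodness-of-fit p-value is the bootstrap fraction of synthetic samples
    from the fitted law whose (refitted) KS distance reaches the observed
    one. The flag is descriptive: True iff p > ``level``.
    """
    if isinstance(outdegrees, CombinedNetwork):
        x = outdegrees.outdegrees().to_numpy()
    else:
        x = np.asarray(outdegrees)
    x = x[x >= 1].astype(int)
    if len(x) < 10:
        raise ValueError("need >= 10 TFs with outdegree >= 1")
    if np.all(x == x[0]):
        raise ValueError("degenerate distribution: all outdegrees equal")
    alpha = _fit_zipf(x)
    d_obs = _ks_distance(x, alpha)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_bootstrap):
        xb = sps.zipf.rvs(alpha, size=len(x), random_state=rng)
        ab = _fit_zipf(xb)
        if _ks_distance(xb, ab) >= d_obs:
            exceed += 1
    p = exceed / n_bootstrap
    return {"exponent": alpha, "ks": d_obs, "p_value": p,
            "approximately_scale_free": bool(p > level)}
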