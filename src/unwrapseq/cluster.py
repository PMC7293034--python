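"""Unwrapping-state classification of +1 nucleosomes.

Per-nucleosome five-group fragment ratios are robust-scaled (median-centered,
MAD-scaled per group), hierarchically clustered, cut into k = 5 classes, and
the classes labelled A–E by which fragment group each over-represents:
A <- G80 (30-80 bp), B <- G100, C <- G120, D <- G140, E <- G168. Ratios are
also rank-correlated with gene expression (Spearman).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats

from .groups import GroupRatioTable

__all__ = [
    "ScaledRatioMatrix",
    "ClusterResult",
    "MAD_NORMAL_CONSISTENCY",
    "CLUSTER_LABELS",
    "scale_ratios",
    "hcluster",
    "label_clusters",
    "correlate_ratios_expression",
]

logger = logging.getLogger(__name__)

#: multiplier making the MAD a consistent estimator of sigma under normality
MAD_NORMAL_CONSISTENCY = 1.4826

CLUSTER_LABELS = ("A", "B", "C", "D", "E")


@dataclass
class ScaledRatioMatrix:
    """Robust-scaled ratio matrix: rows = nucleosomes, cols = fragment groups."""

    values: np.ndarray
    row_ids: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_ids = np.asarray(self.row_ids)
        if self.values.shape != (len(self.row_ids), len(self.columns)):
            raise ValueError("values shape inconsistent with row_ids/columns")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=list(self.columns))


@dataclass
class ClusterResult:
    """Flat cut of an agglomerative clustering, optionally A-E labelled."""

    assignment: np.ndarray  # cluster id (0..k-1) per row
    linkage: np.ndarray  # scipy linkage matrix
    k: int
    row_ids: np.ndarray
    labels: dict[int, str] | None = None  # cluster id -> A..E

    @property
    def row_labels(self) -> np.ndarray:
        """Per-row A-E labels (requires :func:`label_clusters` first)."""
        if self.labels is None:
            raise ValueError("clusters have not been labelled yet")
        return np.array([self.labels[int(c)] for c in self.assignment])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"row_id": self.row_ids, "cluster": self.assignment})
        if self.labels is not None:
            df["label"] = self.row_labels
        return df


def scale_ratios(
    table: GroupRatioTable | pd.DataFrame, c: float = MAD_NORMAL_CONSISTENCY
) -> ScaledRatioMatrix:
    """Center by median and scale by MAD within each fragment group.

    ``scaled = (x - median(x)) / (MAD(x) * c)`` column-wise, with
    ``MAD(x) = median(|x - median(x)|)``. A zero-MAD (constant) column passes
    through as all zeros with a warning rather than aborting, so the
    remaining groups keep their information.
    """
    ratios = table.ratios if isinstance(table, GroupRatioTable) else table
    if len(ratios) < 2:
        raise ValueError("need at least 2 rows to scale")
    x = ratios.to_numpy(dtype=float)
    med = np.median(x, axis=0)
    mad = np.median(np.abs(x - med), axis=0)
    scaled = np.zeros_like(x)
    for j in range(x.shape[1]):
        if mad[j] == 0:
            logger.warning(
                "scale_ratios: column %r has zero MAD; passing through as zeros",
                ratios.columns[j],
            )
            continue
        scaled[:, j] = (x[:, j] - med[j]) / (mad[j] * c)
    return ScaledRatioMatrix(
        scaled, ratios.index.to_numpy(), tuple(map(str, ratios.columns))
    )


def hcluster(
    m: ScaledRatioMatrix,
    k: int = 5,
    linkage: str = "ward",
    metric: str = "euclidean",
) -> ClusterResult:
    """Agglomerative clustering of the scaled ratio matrix, cut into k clusters.

    Ward linkage on Euclidean distances is the default: it recovers compact
    ratio classes far more reliably than complete linkage, which tends to
    chain intermediate nucleosomes into one over-grown cluster (complete and
    average linkage remain available via ``linkage``). Cluster ids are
    renumbered 0..k-1 by first row occurrence so the partition is invariant
    to scipy's internal numbering. Deterministic given the input (scipy
    breaks merge ties by lower index).
    """
    n = len(m.row_ids)
    if n < k:
        raise ValueError(f"cannot cut {n} rows into {k} clusters")
    Z = sch.linkage(m.values, method=linkage, metric=metric)
    flat = sch.fcluster(Z, t=k, criterion="maxclust")
    # renumber by first occurrence for stable ids
    remap: dict[int, int] = {}
    assignment = np.empty(n, dtype=int)
    for i, c in enumerate(flat):
        if c not in remap:
            remap[c] = len(remap)
        assignment[i] = remap[c]
    return ClusterResult(assignment, Z, k, m.row_ids)


def label_clusters(r: ClusterResult, m: ScaledRatioMatrix) -> ClusterResult:
    """Assign A-E labels by maximum-weight bipartite matching.

    The weight of (cluster, group column) is the cluster's median scaled value
    in that column; the matching maximizing total weight gives each cluster a
    unique label (A for the G80 column through E for G168). With k = 5 the
    120 permutations are enumerated outright, which also detects degeneracy:
    a tie between distinct optimal matchings raises an error naming the
    clusters involved.
    """
    if r.k != len(CLUSTER_LABELS):
        raise ValueError(f"labelling requires k = {len(CLUSTER_LABELS)}, got {r.k}")
    if m.values.shape[1] != len(CLUSTER_LABELS):
        raise ValueError("scaled matrix must have exactly five group columns")
    k = r.k
    weight = np.empty((k, k))
    for c in range(k):
        rows = m.values[r.assignment == c]
        if len(rows) == 0:
            raise ValueError(f"cluster {c} is empty")
        weight[c] = np.median(rows, axis=0)

    best_score = -math.inf
    best_perm: tuple[int, ...] | None = None
    tied: list[tuple[int, ...]] = []
    for perm in itertools.permutations(range(k)):
        score = sum(weight[c, perm[c]] for c in range(k))
        if score > best_score + 1e-12:
            best_score, best_perm, tied = score, perm, []
        elif abs(score - best_score) <= 1e-12 and perm != best_perm:
            tied.append(perm)
    assert best_perm is not None
    if tied:
        pairs = sorted(
            {
                (c, best_perm[c], alt[c])
                for alt in tied
                for c in range(k)
                if alt[c] != best_perm[c]
            }
        )
        raise ValueError(
            "degenerate cluster labelling; tied cluster/column pairs: "
            + ", ".join(
                f"cluster {c}: {CLUSTER_LABELS[a]}~{CLUSTER_LABELS[b]}"
                for c, a, b in pairs
            )
        )
    labels = {c: CLUSTER_LABELS[best_perm[c]] for c in range(k)}
    return ClusterResult(r.assignment, r.linkage, r.k, r.row_ids, labels)


def _spearman_perm_pvalue(x: np.ndarray, y: np.ndarray, rho: float) -> float:
    """Permutation p-value for Spearman rho (exact for n <= 8, else sampled)."""
    n = len(x)
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)

    def rho_of(perm_ry: np.ndarray) -> float:
        return float(np.corrcoef(rx, perm_ry)[0, 1])

    obs = abs(rho)
    if n <= 8:
        perms = itertools.permutations(ry)
        count = sum(1 for p in perms if abs(rho_of(np.array(p))) >= obs - 1e-12)
        return count / math.factorial(n)
    rng = np.random.default_rng(0)
    n_resamples = 9999
    count = 1  # include the observed arrangement
    for _ in range(n_resamples):
        if abs(rho_of(rng.permutation(ry))) >= obs - 1e-12:
            count += 1
    return count / (n_resamples + 1)


def correlate_ratios_expression(
    table: GroupRatioTable, expression: pd.Series | pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlation of each group's ratio with gene expression.

    ``expression`` is indexed by window/gene id (a Series, or a DataFrame with
    ``gene_id`` and ``expression`` columns). Only windows present in both and
    included in the ratio table are used; at least 10 matched pairs are
    required. Ties get average ranks; p-values use the t-approximation for
    n > 30 and a permutation test for small n. A constant input yields
    rho = NaN with a warning.
    """
    if isinstance(expression, pd.DataFrame):
        expression = expression.set_index("gene_id")["expression"]
    ratios = table.ratios
    common = ratios.index.intersection(expression.index)
    if len(common) < 10:
        raise ValueError(
            f"need >= 10 matched nucleosome-expression pairs, got {len(common)}"
        )
    y = expression.loc[common].to_numpy(dtype=float)
    rows = []
    for g in ratios.columns:
        x = ratios.loc[common, g].to_numpy(dtype=float)
        n = len(x)
        if np.all(x == x[0]) or np.all(y == y[0]):
            logger.warning(
                "correlate_ratios_expression: %s is constant; rho undefined", g
            )
            rows.append({"group": g, "rho": np.nan, "pvalue": np.nan, "n": n})
            continue
        if n > 30:
            rho, p = scipy.stats.spearmanr(x, y)
        else:
            rho, _ = scipy.stats.spearmanr(x, y)
            p = _spearman_perm_pvalue(x, y, rho)
        rows.append({"group": g, "rho": float(rho), "pvalue": float(p), "n": n})
    return pd.DataFrame(rows).set_index("group")
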