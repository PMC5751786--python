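"""Signed weighted co-expression network, module detection, and the
module-normalized connectivity statistic.

The network follows the WGCNA construction: a signed adjacency
``a_ij = ((1 + cor(x_i, x_j)) / 2) ** beta`` so anticorrelated genes get
near-zero weight, the topological overlap measure (TOM) as edge similarity,
average-linkage hierarchical clustering on ``1 - TOM`` with a static cut,
and a minimum module size. Connectivity of a node is its thresholded-TOM
degree divided by the total degree in its module, so connectivities sum to
one within each module that has at least one edge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass
class NetworkConfig:
    beta: int | None = None  # None: choose by scale-free fit, fall back to 12
    min_module_size: int = 30
    tom_edge_cutoff: float = 0.2
    cut_height: float = 0.9
    correlation_kind: str = "pearson"

    def __post_init__(self) -> None:
        if self.beta is not None and self.beta < 1:
            raise ValueError("beta must be >= 1")
        for name in ("tom_edge_cutoff", "cut_height"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.correlation_kind not in ("pearson", "spearman"):
            raise ValueError("correlation_kind must be pearson or spearman")


@dataclass
class AdjacencyMatrix:
    node_ids: list[str]
    values: np.ndarray  # symmetric, in [0, 1], zero diagonal

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.node_ids), len(self.node_ids)):
            raise ValueError("adjacency shape does not match node ids")
        if not np.allclose(v, v.T):
            raise ValueError("adjacency must be symmetric")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("adjacency values must lie in [0, 1]")
        if v.size and np.abs(np.diag(v)).max() > 1e-12:
            raise ValueError("adjacency diagonal must be zero")


@dataclass
class ModulePartition:
    assignment: dict[str, str]  # node -> module label (UNASSIGNED allowed)

    @property
    def modules(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for node, label in self.assignment.items():
            if label != UNASSIGNED:
                out.setdefault(label, []).append(node)
        return out

    @property
    def n_modules(self) -> int:
        return len(self.modules)


@dataclass
class ConnectivityTable:
    frame: pd.DataFrame  # columns: node, module, degree, connectivity, node_type

    def by_type(self, node_type: str) -> np.ndarray:
        f = self.frame
        return f.loc[f["node_type"] == node_type, "connectivity"].to_numpy()


def _correlation(values: np.ndarray, kind: str) -> np.ndarray:
    if kind == "spearman":
        values = np.apply_along_axis(stats.rankdata, 1, values)
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(values)
    cor = np.where(np.isfinite(cor), cor, 0.0)
    return np.clip(cor, -1.0, 1.0)


def signed_adjacency(
    expr_values: pd.DataFrame | np.ndarray,
    config: NetworkConfig,
    node_ids: Sequence[str] | None = None,
) -> AdjacencyMatrix:
    """Signed adjacency a_ij = ((1 + cor) / 2) ** beta with zero diagonal.

    *expr_values* is features x samples. Constant features (undefined
    correlation) are dropped with a warning. When ``config.beta`` is None
    the soft threshold is chosen by scale-free fit (``pick_soft_threshold``).
    """
    if isinstance(expr_values, pd.DataFrame):
        node_ids = list(expr_values.index)
        values = expr_values.to_numpy(dtype=float)
    else:
        values = np.asarray(expr_values, dtype=float)
        node_ids = list(node_ids) if node_ids is not None else [
            f"n{i}" for i in range(values.shape[0])
        ]
    if values.shape[1] < 3:
        raise ValueError("need >= 3 samples to estimate correlations")
    keep = np.ptp(values, axis=1) > 0  # exact constant-row test
    if not keep.all():
        dropped = [node_ids[i] for i in np.flatnonzero(~keep)]
        logger.warning("dropping %d constant features: %s...", len(dropped), dropped[:5])
        values = values[keep]
        node_ids = [n for n, k in zip(node_ids, keep) if k]
    cor = _correlation(values, config.correlation_kind)
    beta = config.beta
    if beta is None:
        beta = pick_soft_threshold(cor)
    adj = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(adj, 0.0)
    return AdjacencyMatrix(node_ids=node_ids, values=adj)


def pick_soft_threshold(
    cor: np.ndarray, r2_target: float = 0.8, betas: range = range(1, 21)
) -> int:
    """Smallest power giving an approximately scale-free degree distribution
    (signed R^2 of the log-log degree fit >= *r2_target*); falls back to 12,
    the WGCNA convention for signed networks."""
    for beta in betas:
        adj = ((1.0 + cor) / 2.0) ** beta
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=1)
        r2 = _scale_free_fit(k)
        if r2 >= r2_target:
            return beta
    return 12


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    k = k[k > 0]
    if k.size < n_bins:
        return -1.0
    edges = np.linspace(k.min(), k.max() + 1e-9, n_bins + 1)
    counts, _ = np.histogram(k, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    mask = counts > 0
    if mask.sum() < 3:
        return -1.0
    x = np.log10(centers[mask])
    y = np.log10(counts[mask] / counts.sum())
    slope, _, r, _, _ = stats.linregress(x, y)
    return -np.sign(slope) * r**2


def topological_overlap(adjacency: AdjacencyMatrix) -> pd.DataFrame:
    """Topological overlap matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j (the sum excludes u in {i, j}, which is automatic with a zero
    diagonal), and TOM_ii = 1. With no shared neighbours TOM reduces to the
    adjacency itself.
    """
    a = adjacency.values
    k = a.sum(axis=1)
    shared = a @ a  # zero diagonal makes this the u∉{i,j} sum off-diagonal
    numerator = shared + a
    denominator = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denominator > 0, numerator / denominator, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.node_ids, columns=adjacency.node_ids)


def detect_modules(tom: pd.DataFrame, config: NetworkConfig) -> ModulePartition:
    """Average-linkage hierarchical clustering on 1 - TOM, cut at
    ``config.cut_height``; clusters below ``min_module_size`` become
    unassigned. Labels are deterministic: modules are numbered by
    decreasing size, ties broken by the lexicographically smallest member.
    """
    nodes = list(tom.index)
    if len(nodes) < 2:
        return ModulePartition({n: UNASSIGNED for n in nodes})
    dist = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(z, t=config.cut_height, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for node, label in zip(nodes, raw):
        clusters.setdefault(int(label), []).append(node)
    keep = [
        members
        for members in clusters.values()
        if len(members) >= config.min_module_size
    ]
    keep.sort(key=lambda members: (-len(members), min(members)))
    assignment = {n: UNASSIGNED for n in nodes}
    for i, members in enumerate(keep, start=1):
        for n in members:
            assignment[n] = f"M{i}"
    if not keep:
        logger.warning("no module reached min size %d; all nodes unassigned",
                       config.min_module_size)
    return ModulePartition(assignment)


def module_connectivity(
    tom: pd.DataFrame,
    partition: ModulePartition,
    config: NetworkConfig,
    node_types: Mapping[str, str],
) -> ConnectivityTable:
    """Per-node degree and module-normalized connectivity.

    An edge joins two nodes of the same module when their TOM exceeds
    ``tom_edge_cutoff``; degree is the edge count, and connectivity is the
    degree divided by the summed degree in that module (0 when the module
    has no edges). Unassigned nodes get degree and connectivity 0.
    """
    rows = []
    values = tom.to_numpy(dtype=float)
    index = {n: i for i, n in enumerate(tom.index)}
    for module, members in sorted(partition.modules.items()):
        idx = np.array([index[m] for m in members])
        sub = values[np.ix_(idx, idx)]
        edges = sub > config.tom_edge_cutoff
        np.fill_diagonal(edges, False)
        degrees = edges.sum(axis=1)
        total = degrees.sum()
        for m, d in zip(members, degrees):
            c = d / total if total > 0 else 0.0
            rows.append(
                {
                    "node": m,
                    "module": module,
                    "degree": int(d),
                    "connectivity": float(c),
                    "node_type": node_types.get(m, "PCG"),
                }
            )
    for node, label in partition.assignment.items():
        if label == UNASSIGNED:
            rows.append(
                {
                    "node": node,
                    "module": UNASSIGNED,
                    "degree": 0,
                    "connectivity": 0.0,
                    "node_type": node_types.get(node, "PCG"),
                }
            )
    frame = pd.DataFrame(
        rows, columns=["node", "module", "degree", "connectivity", "node_type"]
    )
    return ConnectivityTable(frame=frame)


def compare_connectivity(
    table: ConnectivityTable,
    lnc_type: str = "lncRNA",
    pcg_type: str = "PCG",
    assigned_only: bool = True,
) -> tuple[float, float, dict[str, float]]:
    """One-sided Wilcoxon rank-sum test of lncRNA connectivity exceeding
    protein-coding connectivity, pooled across modules.

    Returns (U statistic, p-value, per-type medians).
    """
    f = table.frame
    if assigned_only:
        f = f[f["module"] != UNASSIGNED]
    lnc = f.loc[f["node_type"] == lnc_type, "connectivity"].to_numpy()
    pcg = f.loc[f["node_type"] == pcg_type, "connectivity"].to_numpy()
    if len(lnc) < 3 or len(pcg) < 3:
        raise ValueError(
            f"need >= 3 nodes of each type, got {len(lnc)} {lnc_type} "
            f"and {len(pcg)} {pcg_type}"
        )
    res = stats.mannwhitneyu(lnc, pcg, alternative="greater")
    medians = {lnc_type: float(np.median(lnc)), pcg_type: float(np.median(pcg))}
    return float(res.statistic), float(res.pvalue), medians
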