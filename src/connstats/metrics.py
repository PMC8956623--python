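"""Weighted graph-theory metrics for FA-weighted structural connectomes.

All measures operate on symmetric non-negative weight matrices where a
weight of zero means "no connection". Path lengths use the reciprocal
transform: the length of an edge is 1/w, so strong (high-FA) connections
are short, and shortest path lengths d_ij are sums of reciprocals along
the best path (Dijkstra). Disconnected pairs have d_ij = +inf and are
ignored in the characteristic path length and contribute 0 to
efficiency-type measures.

Nodal measures: degree K_i, strength S_i, triangle intensity t_i,
clustering C_i = 2 t_i / (K_i (K_i - 1)), local efficiency over the
neighbor subgraph (the subgraph on the neighbors of i, excluding i), and
regional efficiency (mean inverse distance from i to all other nodes).

Global measures: total strength (sum of nodal strengths, so each
undirected edge counts twice), mean clustering over all nodes, the
characteristic path length L (mean over finite off-diagonal d_ij), mean
local efficiency, and global efficiency (mean inverse distance over all
ordered pairs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .io import CohortDataset, WeightedNetwork

__all__ = [
    "MetricSet",
    "GLOBAL_MEASURES",
    "NODAL_MEASURES",
    "degree_and_strength",
    "clustering",
    "shortest_paths",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "regional_efficiency",
    "compute_all",
    "global_metrics_table",
    "nodal_metrics_arrays",
]

GLOBAL_MEASURES = (
    "total_strength",
    "clustering_coefficient",
    "characteristic_path_length",
    "local_efficiency",
    "global_efficiency",
)

NODAL_MEASURES = (
    "degree",
    "strength",
    "clustering",
    "local_efficiency",
    "regional_efficiency",
)


@dataclass(frozen=True)
class MetricSet:
    """Nodal and global topological measures for one network."""

    labels: tuple[str, ...]
    nodal: pd.DataFrame        # one row per node, columns = NODAL_MEASURES
    global_: dict[str, float]  # keys = GLOBAL_MEASURES


def degree_and_strength(net: WeightedNetwork):
    """Nodal degree (count of w>0 neighbors), nodal strength (row sum of
    weights) and total strength (sum of nodal strengths)."""
    w = net.weights
    degree = (w > 0).sum(axis=1).astype(int)
    strength = w.sum(axis=1)
    return degree, strength, float(strength.sum())


def clustering(net: WeightedNetwork):
    """Weighted clustering coefficient.

    Triangle intensity t_i sums the geometric mean of the three weights,
    (w_ij w_jk w_ki)^(1/3), over each distinct triangle through i;
    C_i = 2 t_i / (K_i (K_i - 1)), zero by convention when K_i < 2.
    The global value averages C_i over all nodes, zeros included.
    """
    w = net.weights
    cw = np.cbrt(w)
    # (cw^3 diag) trick: sum over ordered (j,k) of cw_ij cw_jk cw_ki is
    # diag(cw @ cw @ cw); each triangle is counted twice (j,k)/(k,j).
    t = np.diag(cw @ cw @ cw) / 2.0
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, 2.0 * t / denom, 0.0)
    return c, float(c.mean())


def shortest_paths(net: WeightedNetwork) -> np.ndarray:
    """All-pairs shortest path lengths with edge length 1/w (Dijkstra);
    +inf for disconnected pairs, zero diagonal."""
    w = net.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / w, 0.0)
    d = dijkstra(csr_array(lengths), directed=False)
    return d


def characteristic_path_length(d: np.ndarray) -> float:
    """Mean of finite off-diagonal shortest path lengths; pairs with
    infinite distance are ignored. Errors if no pair is connected."""
    off = ~np.eye(d.shape[0], dtype=bool)
    finite = off & np.isfinite(d)
    count = int(finite.sum())
    if count == 0:
        raise ValueError("fully disconnected network: no finite path lengths")
    return float(d[finite].sum() / count)


def global_efficiency(d: np.ndarray) -> float:
    """Mean inverse shortest path length over ordered pairs; infinite
    distances contribute zero."""
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return float(inv.sum() / (n * (n - 1)))


def regional_efficiency(d: np.ndarray) -> np.ndarray:
    """Per-node mean inverse distance to every other node (E_reg)."""
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return inv.sum(axis=1) / (n - 1)


def local_efficiency(net: WeightedNetwork):
    """Weighted local efficiency over neighbor subgraphs.

    For node i with degree K_i >= 2, take the subgraph induced on the
    neighbors of i (i itself excluded), compute shortest path lengths
    d_jk within that subgraph (reciprocal-weight lengths, 1/d = 0 when
    disconnected), and average (w_ij w_ik / d_jk)^(1/3) over ordered
    neighbor pairs j != k, dividing by K_i (K_i - 1). Nodes with fewer
    than two neighbors score 0. The global value is the mean over all
    nodes.
    """
    w = net.weights
    n = net.n
    eloc = np.zeros(n)
    neighbor_lists = [np.flatnonzero(w[i] > 0) for i in range(n)]
    for i in range(n):
        nb = neighbor_lists[i]
        k = nb.size
        if k < 2:
            continue
        sub = w[np.ix_(nb, nb)]
        with np.errstate(divide="ignore"):
            lengths = np.where(sub > 0, 1.0 / sub, 0.0)
        dsub = dijkstra(csr_array(lengths), directed=False)
        with np.errstate(divide="ignore"):
            inv_d = np.where(np.isfinite(dsub), 1.0 / np.where(dsub > 0, dsub, np.inf), 0.0)
        np.fill_diagonal(inv_d, 0.0)
        wi = w[i, nb]
        terms = np.cbrt(np.outer(wi, wi) * inv_d)
        eloc[i] = terms.sum() / (k * (k - 1))
    return eloc, float(eloc.mean())


def compute_all(net: WeightedNetwork) -> MetricSet:
    """One pass producing the full nodal + global metric set."""
    degree, strength, total_strength = degree_and_strength(net)
    c_nodal, c_global = clustering(net)
    d = shortest_paths(net)
    cpl = characteristic_path_length(d)
    eglob = global_efficiency(d)
    ereg = regional_efficiency(d)
    eloc_nodal, eloc_global = local_efficiency(net)

    nodal = pd.DataFrame(
        {
            "degree": degree,
            "strength": strength,
            "clustering": c_nodal,
            "local_efficiency": eloc_nodal,
            "regional_efficiency": ereg,
        },
        index=list(net.labels),
    )
    global_ = {
        "total_strength": total_strength,
        "clustering_coefficient": c_global,
        "characteristic_path_length": cpl,
        "local_efficiency": eloc_global,
        "global_efficiency": eglob,
    }
    return MetricSet(net.labels, nodal, global_)


def global_metrics_table(cohort: CohortDataset) -> pd.DataFrame:
    """Per-subject global measures: one row per subject, columns
    subject_id, group + GLOBAL_MEASURES."""
    rows = []
    for s in cohort.subjects:
        m = compute_all(s.network)
        rows.append({"subject_id": s.subject_id, "group": s.group, **m.global_})
    return pd.DataFrame(rows)


def nodal_metrics_arrays(cohort: CohortDataset,
                         measure_names=NODAL_MEASURES) -> dict[str, np.ndarray]:
    """Per-subject nodal measures as {measure: (n_subjects, n_nodes)}."""
    per_subject = [compute_all(s.network).nodal for s in cohort.subjects]
    return {
        name: np.stack([nod[name].to_numpy(dtype=float) for nod in per_subject])
        for name in measure_names
    }
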