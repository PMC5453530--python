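"""Degree and attribute assortativity, plus the tie-formation
preference index (TFPI).

All degree-assortativity quantities use the excess-degree convention
(degree minus one at each edge end); because Pearson correlation is
shift-invariant, raw degrees give the identical global coefficient.
The universal (group-pair) decomposition assigns each edge the
contribution

    rho_e = (j_e - mu_q)(k_e - mu_q) / (|E| * sigma_q^2)

with mu_q and sigma_q^2 the mean and variance of excess degree over all
2|E| edge ends, so that the contributions of all group pairs sum exactly
to the global coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ParameterError, UndefinedCoefficientError
from .event_io import AttributeTable

__all__ = [
    "GroupingScheme", "TfpiMatrix", "degree_assortativity_global",
    "universal_assortativity_matrix", "attribute_assortativity_scalar",
    "attribute_assortativity_categorical", "tfpi_matrix",
]


@dataclass
class GroupingScheme:
    """Partition of the node set by one categorical attribute."""

    attribute: str
    labels: list  # ordered group labels
    membership: dict  # node -> label
    sizes: np.ndarray  # N_i per label, same order as labels
    fractions: np.ndarray  # w_i = N_i / N

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    @classmethod
    def from_membership(cls, membership: dict, attribute: str = "group",
                        labels=None) -> "GroupingScheme":
        if labels is None:
            labels = sorted(set(membership.values()), key=str)
        labels = list(labels)
        index = {lab: k for k, lab in enumerate(labels)}
        sizes = np.zeros(len(labels), dtype=np.int64)
        for node, lab in membership.items():
            if lab not in index:
                raise ParameterError(f"node {node!r} has unknown label {lab!r}")
            sizes[index[lab]] += 1
        n = sizes.sum()
        if n == 0:
            raise ParameterError("empty grouping")
        return cls(attribute=attribute, labels=labels, membership=dict(membership),
                   sizes=sizes, fractions=sizes / n)

    @classmethod
    def from_attributes(cls, table: AttributeTable, attribute: str,
                        nodes) -> "GroupingScheme":
        values = table.column(attribute)
        membership = {}
        for node in nodes:
            if node not in values:
                raise ParameterError(f"node {node!r} missing from attribute table")
            membership[node] = values[node]
        return cls.from_membership(membership, attribute=attribute)


@dataclass
class TfpiMatrix:
    """Edge-end mixing rates and tie-formation preference per group pair.

    s[i, j] is the mean number of edge ends of group i whose opposite
    endpoint lies in group j (so s[i].sum() is the mean degree of group
    i, and intra-group edges contribute both of their ends to s[i, i]).
    q[i, j] = (p[i, j] - w_j) / (1 - w_j) is zero under proportional
    mixing; rows of groups with zero total degree are undefined (NaN)
    and flagged rather than reported as zero.
    """

    labels: list
    fractions: np.ndarray
    s: np.ndarray
    p: np.ndarray
    q: np.ndarray
    undefined_rows: np.ndarray  # boolean mask over labels


def _edge_end_arrays(g: nx.Graph, values: dict) -> tuple[np.ndarray, np.ndarray]:
    """Per-edge endpoint values, one row per edge (unordered)."""
    left, right = [], []
    for u, v in g.edges:
        left.append(values[u])
        right.append(values[v])
    return np.asarray(left, dtype=np.float64), np.asarray(right, dtype=np.float64)


def _edge_end_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation over the 2|E| ordered edge-end pairs."""
    if x.size < 2:
        raise UndefinedCoefficientError("need at least 2 edges")
    ends = np.concatenate([x, y])
    mu = ends.mean()
    var = ends.var()
    if var <= 0:
        raise UndefinedCoefficientError("zero variance over edge ends")
    cov = ((x - mu) * (y - mu)).mean()
    return float(cov / var)


def degree_assortativity_global(g: nx.Graph) -> float:
    """Pearson correlation of endpoint degrees over all edges."""
    if g.number_of_edges() < 2:
        raise UndefinedCoefficientError("need at least 2 edges")
    deg = dict(g.degree())
    excess = {v: d - 1 for v, d in deg.items()}
    x, y = _edge_end_arrays(g, excess)
    return _edge_end_pearson(x, y)


def universal_assortativity_matrix(g: nx.Graph, grouping: GroupingScheme) -> np.ndarray:
    """Group-pair decomposition of the global degree assortativity.

    Entry (a, b) sums the per-edge contributions of edges whose endpoint
    groups are {label_a, label_b}. The matrix is symmetric (an unordered
    pair's total appears in both of its off-diagonal cells), and the
    upper triangle including the diagonal sums to the global coefficient.
    """
    deg = dict(g.degree())
    excess = {v: d - 1 for v, d in deg.items()}
    x, y = _edge_end_arrays(g, excess)
    if x.size < 2:
        raise UndefinedCoefficientError("need at least 2 edges")
    ends = np.concatenate([x, y])
    mu, var = ends.mean(), ends.var()
    if var <= 0:
        raise UndefinedCoefficientError("zero variance over edge ends")
    m = g.number_of_edges()
    k = grouping.n_groups
    index = {lab: i for i, lab in enumerate(grouping.labels)}
    out = np.zeros((k, k))
    for (u, v), ju, kv in zip(g.edges, x, y):
        rho = (ju - mu) * (kv - mu) / (m * var)
        a, b = index[grouping.membership[u]], index[grouping.membership[v]]
        if a == b:
            out[a, a] += rho
        else:
            out[a, b] += rho
            out[b, a] += rho
    return out


def attribute_assortativity_scalar(g: nx.Graph, values: dict) -> float:
    """Edge-end Pearson correlation of a scalar node attribute."""
    if g.number_of_edges() < 1:
        raise UndefinedCoefficientError("graph has no edges")
    missing = [v for v in g.nodes if v not in values and g.degree(v) > 0]
    if missing:
        raise ParameterError(f"missing attribute value for node(s): {missing[:5]}")
    x, y = _edge_end_arrays(g, values)
    if x.size == 1:
        raise UndefinedCoefficientError("need at least 2 edges")
    return _edge_end_pearson(x, y)


def attribute_assortativity_categorical(g: nx.Graph, labels: dict) -> float:
    """Categorical assortativity from the normalized mixing matrix:
    r = (sum_c e_cc - sum_c a_c b_c) / (1 - sum_c a_c b_c)."""
    if g.number_of_edges() < 1:
        raise UndefinedCoefficientError("graph has no edges")
    cats = sorted({labels[v] for v in g.nodes if g.degree(v) > 0}, key=str)
    index = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    e = np.zeros((k, k))
    for u, v in g.edges:
        a, b = index[labels[u]], index[labels[v]]
        e[a, b] += 1
        e[b, a] += 1
    e /= 2 * g.number_of_edges()
    a_marg = e.sum(axis=1)
    b_marg = e.sum(axis=0)
    denom = 1.0 - float(a_marg @ b_marg)
    if denom <= 0:
        raise UndefinedCoefficientError(
            "single label among edge endpoints: coefficient undefined")
    return float((np.trace(e) - a_marg @ b_marg) / denom)


def tfpi_matrix(g: nx.Graph, grouping: GroupingScheme) -> TfpiMatrix:
    """Edge-end mixing and tie-formation preference index per group pair."""
    k = grouping.n_groups
    index = {lab: i for i, lab in enumerate(grouping.labels)}
    missing = [v for v in g.nodes if v not in grouping.membership]
    if missing:
        raise ParameterError(f"node(s) missing from grouping: {missing[:5]}")
    end_counts = np.zeros((k, k))
    for u, v in g.edges:
        a, b = index[grouping.membership[u]], index[grouping.membership[v]]
        end_counts[a, b] += 1  # end at u, opposite in b
        end_counts[b, a] += 1  # end at v, opposite in a
    sizes = grouping.sizes.astype(np.float64)
    if (sizes <= 0).any():
        raise ParameterError("every group must have at least one member")
    s = end_counts / sizes[:, None]
    s_i = s.sum(axis=1)
    undefined = s_i <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        p = s / s_i[:, None]
    w = grouping.fractions
    with np.errstate(invalid="ignore", divide="ignore"):
        q = (p - w[None, :]) / (1.0 - w[None, :])
    p[undefined, :] = np.nan
    q[undefined, :] = np.nan
    return TfpiMatrix(labels=list(grouping.labels), fractions=w.copy(),
                      s=s, p=p, q=q, undefined_rows=undefined)
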