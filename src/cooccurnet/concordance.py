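"""Agreement between an inferred network and a reference tie network:
dyad-level confusion rates and QAP matrix correlation."""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .errors import ParameterError, UndefinedCoefficientError

__all__ = ["DyadComparison", "QapResult", "confusion_rates", "qap_correlation"]


@dataclass
class DyadComparison:
    """Complete unordered-dyad census of two graphs on a shared node set."""

    nodes: list
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_dyads(self) -> int:
        n = len(self.nodes)
        return n * (n - 1) // 2

    @property
    def tpr(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else math.nan

    @property
    def tnr(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else math.nan

    @property
    def fpr(self) -> float:
        d = self.tn + self.fp
        return self.fp / d if d else math.nan

    @property
    def fnr(self) -> float:
        d = self.tp + self.fn
        return self.fn / d if d else math.nan


@dataclass
class QapResult:
    r: float
    p: float
    n_perm: int


def confusion_rates(inferred: nx.Graph, reference: nx.Graph,
                    node_policy: str = "intersection") -> DyadComparison:
    """Classify every unordered dyad of the shared node set.

    Reference edges are "positives"; TPR = TP/(TP+FN), TNR = TN/(TN+FP).
    """
    if node_policy == "intersection":
        nodes = sorted(set(inferred.nodes) & set(reference.nodes))
    elif node_policy == "union":
        nodes = sorted(set(inferred.nodes) | set(reference.nodes))
    else:
        raise ParameterError(f"unknown node policy {node_policy!r}")
    if not nodes:
        raise ParameterError("shared node set is empty")
    node_set = set(nodes)
    inf_edges = {frozenset(e) for e in inferred.edges
                 if e[0] in node_set and e[1] in node_set and e[0] != e[1]}
    ref_edges = {frozenset(e) for e in reference.edges
                 if e[0] in node_set and e[1] in node_set and e[0] != e[1]}
    tp = len(inf_edges & ref_edges)
    fp = len(inf_edges - ref_edges)
    fn = len(ref_edges - inf_edges)
    n = len(nodes)
    tn = n * (n - 1) // 2 - tp - fp - fn
    return DyadComparison(nodes=nodes, tp=tp, fp=fp, tn=tn, fn=fn)


def qap_correlation(a: nx.Graph, b: nx.Graph, n_perm: int = 999,
                    seed: int = 0) -> QapResult:
    """QAP correlation between two graphs on the same node set.

    r is the Pearson correlation of the off-diagonal adjacency entries;
    the null distribution simultaneously permutes rows and columns of
    one matrix. One-sided p with add-one correction:
    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1).
    """
    if set(a.nodes) != set(b.nodes):
        raise ParameterError("QAP requires identical node sets")
    if n_perm < 1:
        raise ParameterError(f"n_perm must be >= 1, got {n_perm}")
    nodes = sorted(a.nodes)
    n = len(nodes)
    if n < 3:
        raise ParameterError("QAP needs at least 3 nodes")
    ma = nx.to_numpy_array(a, nodelist=nodes, weight=None)
    mb = nx.to_numpy_array(b, nodelist=nodes, weight=None)
    off = ~np.eye(n, dtype=bool)

    def corr(x: np.ndarray, y: np.ndarray) -> float:
        xv, yv = x[off], y[off]
        sx, sy = xv.std(), yv.std()
        if sx == 0 or sy == 0:
            raise UndefinedCoefficientError("zero variance in adjacency matrix")
        return float(((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy))

    r_obs = corr(ma, mb)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(ma, mb[np.ix_(perm, perm)]) >= r_obs:
            exceed += 1
    return QapResult(r=r_obs, p=(1 + exceed) / (n_perm + 1), n_perm=n_perm)
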