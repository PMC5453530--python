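"""Co-occurrence counting and statistical validation of candidate ties.

The event stream is discretized into segments — one segment per
(location, timeslot) pair, holding the distinct subjects seen there.
For every pair of subjects the observed number of shared segments is
tested against a null in which each appearance lands in a segment with
probability proportional to segment size. Under that null the pair
count is approximately Poisson with mean

    E(X_ij) = n_i * n_j / (M (M - 1)) * sum_k L_k (L_k - 1)

where n_i is the number of segments containing subject i, L_k the size
of segment k and M the sum of all segment sizes. Upper-tail p-values
are compared against a Bonferroni-corrected threshold alpha0 / N_T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammainc, gammaln

from .errors import ParameterError
from .event_io import EventStream

__all__ = [
    "Segmentation", "PairStat", "SvcnResult", "segment_events",
    "count_cooccurrences", "expected_cooccurrence", "poisson_upper_tail",
    "corrected_threshold", "build_svcn", "mc_null_pvalue",
]


@dataclass
class Segmentation:
    """Discretized event stream: (location, timeslot) bins of subjects."""

    tau: float
    t0: int
    table: pd.DataFrame  # columns subject_id, location_id, slot, seg_id (deduped)

    _sizes: np.ndarray | None = field(default=None, repr=False)
    _n_by_subject: pd.Series | None = field(default=None, repr=False)

    @property
    def segments(self) -> dict[tuple[str, int], frozenset]:
        """Mapping (location_id, slot_index) -> set of distinct subjects."""
        out: dict[tuple[str, int], set] = {}
        for row in self.table.itertuples(index=False):
            out.setdefault((row.location_id, int(row.slot)), set()).add(row.subject_id)
        return {k: frozenset(v) for k, v in out.items()}

    @property
    def sizes(self) -> np.ndarray:
        """Segment sizes L_k, indexed by seg_id."""
        if self._sizes is None:
            self._sizes = np.bincount(self.table["seg_id"].to_numpy())
        return self._sizes

    @property
    def K(self) -> int:
        """Number of non-empty segments."""
        return len(self.sizes)

    @property
    def M(self) -> int:
        """Total occurrence count, sum of L_k (= sum of n_i)."""
        return int(self.sizes.sum())

    @property
    def n_by_subject(self) -> pd.Series:
        """n_i: number of segments each subject occurs in."""
        if self._n_by_subject is None:
            self._n_by_subject = self.table.groupby("subject_id").size()
        return self._n_by_subject

    def n_occurrences(self, subject: str) -> int:
        return int(self.n_by_subject.get(subject, 0))

    @property
    def sum_pairs(self) -> int:
        """sum_k L_k (L_k - 1), twice the number of within-segment pairs."""
        sizes = self.sizes.astype(np.int64)
        return int((sizes * (sizes - 1)).sum())


@dataclass(frozen=True)
class PairStat:
    """Observed/expected co-occurrence and p-value for one subject pair."""

    i: str
    j: str
    x_obs: int
    x_exp: float
    p_value: float
    significant: bool = False


@dataclass
class SvcnResult:
    """Validated network: all observed subjects plus surviving edges."""

    nodes: list[str]
    edges: list[PairStat]
    alpha0: float
    n_tests: int
    corrected_threshold: float
    correction: str = "bonferroni"
    tau: float = 300.0
    n_candidates: int = 0

    def to_graph(self, attributes=None):
        from .event_io import network_to_graph
        return network_to_graph(self, attributes)


def segment_events(events: EventStream, tau: float,
                   t0_policy: str = "midnight_of_first_day",
                   t0: int | None = None) -> Segmentation:
    """Bin events into (location, timeslot) segments.

    A subject occurring several times in the same segment counts once.
    Slot index is floor((t - t0) / tau). Empty segments never appear.
    """
    if tau <= 0:
        raise ParameterError(f"tau must be positive, got {tau}")
    if len(events) == 0:
        raise ParameterError("cannot segment an empty event stream")
    frame = events.frame
    if t0_policy == "explicit":
        if t0 is None:
            raise ParameterError("explicit t0 policy requires t0")
        origin = int(t0)
    elif t0_policy == "stream_min":
        origin = int(frame["timestamp"].min())
    elif t0_policy == "midnight_of_first_day":
        first = int(frame["timestamp"].min())
        origin = first - first % 86400
    else:
        raise ParameterError(f"unknown t0 policy {t0_policy!r}")
    slots = (frame["timestamp"].to_numpy(np.int64) - origin) // int(tau) \
        if float(tau).is_integer() else np.floor(
            (frame["timestamp"].to_numpy(np.int64) - origin) / tau).astype(np.int64)
    table = pd.DataFrame({
        "subject_id": frame["subject_id"].to_numpy(),
        "location_id": frame["location_id"].to_numpy(),
        "slot": slots,
    }).drop_duplicates(ignore_index=True)
    table["seg_id"] = pd.factorize(
        pd.MultiIndex.from_arrays([table["location_id"], table["slot"]]))[0]
    return Segmentation(tau=float(tau), t0=origin, table=table)


def count_cooccurrences(seg: Segmentation) -> dict[tuple[str, str], int]:
    """Count shared segments X_ij for every pair with X_ij >= 1.

    Keys are (i, j) with i < j lexicographically.
    """
    table = seg.table
    merged = table.merge(table, on="seg_id", suffixes=("_a", "_b"))
    merged = merged[merged["subject_id_a"] < merged["subject_id_b"]]
    if len(merged) == 0:
        return {}
    counts = merged.groupby(["subject_id_a", "subject_id_b"]).size()
    return {(a, b): int(c) for (a, b), c in counts.items()}


def expected_cooccurrence(seg: Segmentation, i: str, j: str) -> float:
    """Null-model expected number of shared segments for subjects i and j."""
    if seg.M < 2:
        raise ParameterError("expected co-occurrence undefined for M < 2")
    n_i, n_j = seg.n_occurrences(i), seg.n_occurrences(j)
    if n_i < 1 or n_j < 1:
        raise ParameterError(f"subjects {i!r}/{j!r} must occur at least once")
    return n_i * n_j / (seg.M * (seg.M - 1)) * seg.sum_pairs


def poisson_upper_tail(x_obs: int, mu: float) -> float:
    """P(Poisson(mu) >= x_obs), accurate in relative terms into deep tails.

    Uses the regularized lower incomplete gamma identity
    P(X >= x) = P_gamma(x, mu), which keeps full relative accuracy far
    below the magnitudes where direct summation would underflow. For
    x > mu with an underflowed gamma value, a log-space series fallback
    extends the range to the smallest positive double.
    """
    if mu <= 0:
        raise ParameterError(f"mu must be positive, got {mu}")
    if x_obs < 0 or x_obs != int(x_obs):
        raise ParameterError(f"x_obs must be a non-negative integer, got {x_obs}")
    x = int(x_obs)
    if x == 0:
        return 1.0
    p = float(gammainc(x, mu))
    if p == 0.0 and x > mu:
        # log-space leading term times a convergent series
        log_lead = x * math.log(mu) - mu - float(gammaln(x + 1))
        s, term = 1.0, 1.0
        n = x
        while True:
            n += 1
            term *= mu / n
            s += term
            if term < 1e-17 * s:
                break
        p = math.exp(log_lead + math.log(s)) if log_lead + math.log(s) > -745 else 0.0
    return min(p, 1.0)


def _poisson_upper_tail_vec(x: np.ndarray, mu: np.ndarray) -> np.ndarray:
    p = gammainc(x.astype(float), mu)
    p = np.minimum(p, 1.0)
    p[x == 0] = 1.0
    zero = (p == 0.0) & (x > mu)
    for idx in np.flatnonzero(zero):
        p[idx] = poisson_upper_tail(int(x[idx]), float(mu[idx]))
    return p


def corrected_threshold(alpha0: float, n_tests: int,
                        method: str = "bonferroni") -> float:
    """Multiple-testing corrected significance threshold p_b."""
    if method != "bonferroni":
        raise ParameterError(f"unsupported correction method {method!r}")
    if not 0 < alpha0 <= 1:
        raise ParameterError(f"alpha0 must be in (0, 1], got {alpha0}")
    if n_tests < 1 or n_tests != int(n_tests):
        raise ParameterError(f"n_tests must be a positive integer, got {n_tests}")
    return alpha0 / int(n_tests)


def pair_stats(seg: Segmentation, alpha0: float = 0.01,
               n_t_policy: str = "candidate_pairs",
               explicit_n_tests: int | None = None) -> tuple[list[PairStat], int, float]:
    """Score all candidate pairs; returns (stats, n_tests, threshold)."""
    counts = count_cooccurrences(seg)
    n_candidates = len(counts)
    n_subjects = seg.n_by_subject.size
    if n_t_policy == "candidate_pairs":
        n_tests = max(n_candidates, 1)
    elif n_t_policy == "all_pairs":
        n_tests = max(n_subjects * (n_subjects - 1) // 2, 1)
    elif n_t_policy == "explicit":
        if explicit_n_tests is None:
            raise ParameterError("explicit n_t policy requires explicit_n_tests")
        n_tests = int(explicit_n_tests)
    else:
        raise ParameterError(f"unknown n_t policy {n_t_policy!r}")
    p_b = corrected_threshold(alpha0, n_tests)
    if not counts:
        return [], n_tests, p_b
    pairs = list(counts.keys())
    x = np.array([counts[p] for p in pairs], dtype=np.int64)
    n = seg.n_by_subject
    n_a = n.loc[[p[0] for p in pairs]].to_numpy(np.float64)
    n_b = n.loc[[p[1] for p in pairs]].to_numpy(np.float64)
    mu = n_a * n_b / (seg.M * (seg.M - 1)) * seg.sum_pairs
    pvals = _poisson_upper_tail_vec(x, mu)
    stats = [PairStat(i=a, j=b, x_obs=int(xo), x_exp=float(m),
                      p_value=float(pv), significant=bool(pv < p_b))
             for (a, b), xo, m, pv in zip(pairs, x, mu, pvals)]
    return stats, n_tests, p_b


def build_svcn(events: EventStream, attributes=None, tau: float = 300.0,
               alpha0: float = 0.01, n_t_policy: str = "candidate_pairs",
               explicit_n_tests: int | None = None,
               t0_policy: str = "midnight_of_first_day",
               t0: int | None = None) -> SvcnResult:
    """Run the full validation pipeline on an event stream.

    Every subject observed in the stream becomes a node; edges are the
    pairs whose co-occurrence count is significant after correction.
    An empty stream yields an empty, error-free result.
    """
    if len(events) == 0:
        return SvcnResult(nodes=[], edges=[], alpha0=alpha0, n_tests=0,
                          corrected_threshold=float("nan"), tau=tau)
    seg = segment_events(events, tau, t0_policy=t0_policy, t0=t0)
    stats, n_tests, p_b = pair_stats(seg, alpha0=alpha0, n_t_policy=n_t_policy,
                                     explicit_n_tests=explicit_n_tests)
    edges = [ps for ps in stats if ps.significant]
    return SvcnResult(nodes=events.subjects(), edges=edges, alpha0=alpha0,
                      n_tests=n_tests, corrected_threshold=p_b, tau=tau,
                      n_candidates=len(stats))


def mc_null_pvalue(seg: Segmentation, i: str, j: str, n_rep: int,
                   seed: int) -> tuple[float, float]:
    """Monte-Carlo p-value for the pair (i, j) under the occupancy null.

    Both subjects are re-placed: their n_i + n_j occurrences are drawn
    jointly without replacement from the M occurrence slots (segment k
    offering L_k slots), reproducing the L_k/M and (L_k-1)/(M-1)
    occupancy probabilities of the analytic null. Returns (p_hat, se)
    where p_hat is the fraction of replicates whose shared-segment count
    reaches the observed one and se its binomial standard error.
    """
    if n_rep < 1:
        raise ParameterError(f"n_rep must be >= 1, got {n_rep}")
    n_i, n_j = seg.n_occurrences(i), seg.n_occurrences(j)
    if n_i > seg.K or n_j > seg.K:
        raise ParameterError("subject occurs in more segments than exist")
    counts = count_cooccurrences(seg)
    key = (i, j) if i < j else (j, i)
    x_obs = counts.get(key, 0)
    if x_obs == 0:
        return 1.0, 0.0
    rng = np.random.default_rng(seed)
    slot_seg = np.repeat(np.arange(seg.K), seg.sizes)
    m = len(slot_seg)
    hits = 0
    draw = n_i + n_j
    for _ in range(n_rep):
        slots = rng.choice(m, size=draw, replace=False)
        segs_i = np.unique(slot_seg[slots[:n_i]])
        segs_j = np.unique(slot_seg[slots[n_i:]])
        if len(np.intersect1d(segs_i, segs_j, assume_unique=True)) >= x_obs:
            hits += 1
    p_hat = hits / n_rep
    se = math.sqrt(p_hat * (1 - p_hat) / n_rep)
    return p_hat, se
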