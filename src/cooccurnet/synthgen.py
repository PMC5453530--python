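"""Synthetic check-in data with planted social structure.

Generates an attributed population, a latent tie graph biased toward
within-group ties, and a time-stamped multi-location check-in stream
whose visit times cluster around daily peak hours. Tied pairs
synchronize a visit (same location, same timeslot) with a configurable
daily probability; the synchronization overwrites one of the pair's
independently drawn visits, so per-subject activity rates do not depend
on the co-visit probability. Setting that probability to zero gives an
exchangeable, tie-free null stream.

All randomness flows from one master seed through per-stage substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError
from .event_io import AttributeTable, EventStream

__all__ = [
    "AttributeSpec", "PopulationSpec", "TieModel", "CheckinModel",
    "gen_population", "gen_tie_graph", "gen_events", "simulate_dataset",
    "default_population_spec", "compose_component_graph",
]

_DAY = 86400
# 2015-09-01T00:00:00Z, midnight-aligned
_DEFAULT_START = 1441065600


@dataclass
class AttributeSpec:
    name: str
    labels: list[str]
    fractions: list[float]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.fractions):
            raise ParameterError(f"{self.name}: labels/fractions length mismatch")
        if any(f < 0 for f in self.fractions):
            raise ParameterError(f"{self.name}: negative fraction")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ParameterError(f"{self.name}: fractions must sum to 1")


@dataclass
class PopulationSpec:
    n: int
    attributes: list[AttributeSpec] = field(default_factory=list)


@dataclass
class TieModel:
    """Dyad-independent tie probabilities with within-group boosts."""

    base_p: float = 0.01
    intra_multipliers: dict[str, float] = field(default_factory=dict)
    target_mean_degree: float | None = None


@dataclass
class CheckinModel:
    n_locations: int = 10
    n_days: int = 30
    visits_per_day_mean: float = 2.5
    visits_rate_shape: float = 4.0  # gamma shape for per-subject rates
    peak_times: tuple[int, ...] = (27000, 43200, 64800)  # 7:30, 12:00, 18:00
    peak_weights: tuple[float, ...] = (0.3, 0.4, 0.3)
    peak_sd: float = 1800.0
    location_concentration: float = 5.0  # Dirichlet over locations
    covisit_rho: float = 0.0
    tau: float = 300.0
    start_epoch: int = _DEFAULT_START

    def __post_init__(self) -> None:
        if not 0.0 <= self.covisit_rho <= 1.0:
            raise ParameterError(f"covisit_rho must be in [0, 1], got {self.covisit_rho}")
        for name in ("n_locations", "n_days", "visits_per_day_mean",
                     "visits_rate_shape", "peak_sd", "location_concentration", "tau"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if len(self.peak_times) != len(self.peak_weights):
            raise ParameterError("peak_times/peak_weights length mismatch")


def default_population_spec(n: int = 200) -> PopulationSpec:
    """Cohort analogue: gender, grade, school, age and region attributes."""
    return PopulationSpec(n=n, attributes=[
        AttributeSpec("gender", ["M", "F"], [0.5, 0.5]),
        AttributeSpec("grade", ["g1", "g2", "g3", "g4"], [0.25, 0.25, 0.25, 0.25]),
        AttributeSpec("school", [f"sch{i}" for i in range(6)], [1 / 6] * 6),
        AttributeSpec("region", ["east", "central", "west", "other"],
                      [0.3, 0.4, 0.25, 0.05]),
    ])


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_population(spec: PopulationSpec, seed: int) -> tuple[list[str], AttributeTable]:
    """Sample subject ids and categorical attributes from the spec."""
    if spec.n < 1:
        raise ParameterError(f"population size must be >= 1, got {spec.n}")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    ids = [f"s{k:05d}" for k in range(spec.n)]
    data = {}
    kinds = {}
    for attr in spec.attributes:
        data[attr.name] = rng.choice(attr.labels, size=spec.n, p=attr.fractions)
        kinds[attr.name] = "categorical"
    frame = pd.DataFrame(data, index=pd.Index(ids, name="subject_id"))
    return ids, AttributeTable(frame=frame, kinds=kinds)


def _tie_probability_matrix(ids: list[str], attributes: AttributeTable,
                            model: TieModel) -> np.ndarray:
    n = len(ids)
    p = np.full((n, n), model.base_p, dtype=np.float64)
    for name, beta in model.intra_multipliers.items():
        if beta < 0:
            raise ParameterError(f"multiplier for {name!r} must be >= 0")
        values = attributes.column(name)
        labels = np.array([values[i] for i in ids])
        same = labels[:, None] == labels[None, :]
        p = np.where(same, p * beta, p)
    if model.target_mean_degree is not None:
        iu = np.triu_indices(n, k=1)
        expected_mean_degree = 2 * p[iu].sum() / n
        if expected_mean_degree > 0:
            p *= model.target_mean_degree / expected_mean_degree
    return p


def gen_tie_graph(ids: list[str], attributes: AttributeTable, model: TieModel,
                  seed: int) -> nx.Graph:
    """Draw the ground-truth tie graph with independent dyad Bernoullis."""
    p = _tie_probability_matrix(ids, attributes, model)
    iu = np.triu_indices(len(ids), k=1)
    probs = p[iu]
    if (probs > 1.0 + 1e-12).any():
        raise ParameterError(
            f"tie probability exceeds 1 (max {probs.max():.4g}); lower base_p or multipliers")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    draws = rng.random(len(probs)) < probs
    g = nx.Graph()
    g.add_nodes_from(ids)
    idx_a, idx_b = iu
    for a, b in zip(idx_a[draws], idx_b[draws]):
        g.add_edge(ids[a], ids[b])
    return g


def gen_events(ids: list[str], ties: nx.Graph, model: CheckinModel,
               seed: int) -> EventStream:
    """Draw the check-in stream; tied pairs co-visit with probability rho/day."""
    rng_rates, rng_visits, rng_sync = _substreams(seed, 3)
    n = len(ids)
    days = model.n_days
    shape = model.visits_rate_shape
    rates = rng_rates.gamma(shape, model.visits_per_day_mean / shape, size=n)
    counts = rng_visits.poisson(rates[:, None], size=(n, days))  # visits per subject-day
    total = int(counts.sum())
    flat = counts.ravel()  # subject-major, day-minor
    subj_idx = np.repeat(np.arange(n * days) // days, flat)
    day_idx = np.repeat(np.arange(n * days) % days, flat)
    # times: peak-hour mixture, truncated to the day
    comp = rng_visits.choice(len(model.peak_times), size=total,
                             p=np.asarray(model.peak_weights, float))
    tod = rng_visits.normal(np.asarray(model.peak_times, float)[comp], model.peak_sd)
    tod = np.clip(tod, 0, _DAY - 1).astype(np.int64)
    # locations: per-subject preferences via the Gumbel-max trick
    prefs = rng_visits.dirichlet([model.location_concentration] * model.n_locations,
                                 size=n)
    gumbel = rng_visits.gumbel(size=(total, model.n_locations))
    loc_idx = np.argmax(np.log(prefs[subj_idx]) + gumbel, axis=1)

    base_times = model.start_epoch + day_idx * _DAY + tod
    base_locs = loc_idx
    times = base_times.copy()
    locs = base_locs.copy()

    if model.covisit_rho > 0 and ties.number_of_edges() > 0:
        _synchronize_covisits(ids, ties, model, rng_sync, counts,
                              day_idx, base_times, base_locs, times, locs)

    location_names = np.array([f"L{k:02d}" for k in range(model.n_locations)])
    frame = pd.DataFrame({
        "subject_id": np.array(ids)[subj_idx],
        "timestamp": times,
        "location_id": location_names[locs],
    })
    frame = frame.sort_values(["timestamp", "subject_id", "location_id"],
                              kind="stable", ignore_index=True)
    return EventStream(frame)


def _synchronize_covisits(ids, ties, model, rng, counts, day_idx,
                          base_times, base_locs, times, locs) -> None:
    """Overwrite one visit per syncing pair-day with a shared slot/location.

    Sources always read the *base* (independent) visit of the source
    subject, and every visit takes part in at most one synchronization
    per study (as source or as target); otherwise chains of ties would
    transitively align third parties into the same slot and plant
    spurious co-occurrences between untied pairs.
    """
    n, days = counts.shape
    tau = int(model.tau)
    pos = {ids[k]: k for k in range(n)}
    # visit index ranges per (subject, day): visits were laid out
    # subject-major/day-minor, so offsets come straight from cumsum
    offsets = np.concatenate(([0], np.cumsum(counts.ravel())))
    FREE, USED = 0, 1  # a visit is spent once it is a source or a target
    state = np.zeros(len(day_idx), dtype=np.int8)

    def day_slice(s: int, d: int) -> slice:
        cell = s * days + d
        return slice(int(offsets[cell]), int(offsets[cell + 1]))

    def pick_free(sl: slice) -> int | None:
        free = np.flatnonzero(state[sl] == FREE)
        if len(free) == 0:
            return None
        return sl.start + int(free[rng.integers(len(free))])

    edges = sorted((min(u, v), max(u, v)) for u, v in ties.edges)
    for u, v in edges:
        su, sv = pos[u], pos[v]
        for d in range(days):
            if rng.random() >= model.covisit_rho:
                continue
            sl_u, sl_v = day_slice(su, d), day_slice(sv, d)
            if sl_u.stop == sl_u.start or sl_v.stop == sl_v.start:
                continue  # one of the pair is inactive that day
            if rng.random() < 0.5:
                src_sl, dst_sl = sl_u, sl_v
            else:
                src_sl, dst_sl = sl_v, sl_u
            src = pick_free(src_sl)
            dst = pick_free(dst_sl)
            if src is None or dst is None:
                continue
            slot_start = base_times[src] - (base_times[src] % tau)
            times[dst] = slot_start + int(rng.integers(tau))
            locs[dst] = base_locs[src]
            state[src] = USED
            state[dst] = USED


def compose_component_graph(components: list[tuple[int, int]], n_isolates: int,
                            seed: int) -> nx.Graph:
    """Random graph with a prescribed component decomposition.

    Each (n_nodes, n_edges) entry becomes one connected component: a
    uniform random recursive tree plus extra random edges up to the
    requested count. Isolated nodes are appended afterwards.
    """
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    offset = 0
    for n_nodes, n_edges in components:
        if n_nodes < 1 or n_edges < n_nodes - 1:
            raise ParameterError(f"component ({n_nodes}, {n_edges}) cannot be connected")
        if n_edges > n_nodes * (n_nodes - 1) // 2:
            raise ParameterError(f"component ({n_nodes}, {n_edges}) has too many edges")
        edges = set()
        for v in range(1, n_nodes):  # spanning tree
            edges.add((int(rng.integers(v)), v))
        while len(edges) < n_edges:
            need = n_edges - len(edges)
            a = rng.integers(0, n_nodes, size=2 * need + 8)
            b = rng.integers(0, n_nodes, size=2 * need + 8)
            for u, v in zip(a, b):
                if u == v:
                    continue
                e = (int(min(u, v)), int(max(u, v)))
                if e not in edges:
                    edges.add(e)
                    if len(edges) == n_edges:
                        break
        g.add_nodes_from(range(offset, offset + n_nodes))
        g.add_edges_from((u + offset, v + offset) for u, v in edges)
        offset += n_nodes
    g.add_nodes_from(range(offset, offset + n_isolates))
    return g


def simulate_dataset(n: int, seed: int,
                     population_spec: PopulationSpec | None = None,
                     tie_model: TieModel | None = None,
                     checkin_model: CheckinModel | None = None):
    """Convenience end-to-end draw: population, ties, events.

    Returns (ids, attribute table, tie graph, event stream).
    """
    spec = population_spec or default_population_spec(n)
    if spec.n != n:
        raise ParameterError("population spec size disagrees with n")
    tie_model = tie_model or TieModel(base_p=0.002,
                                      intra_multipliers={"grade": 6.0, "school": 3.0},
                                      target_mean_degree=4.0)
    checkin_model = checkin_model or CheckinModel()
    # independent per-stage seeds derived from the master seed
    rngs = [int(s.generate_state(1)[0])
            for s in np.random.SeedSequence(seed).spawn(3)]
    ids, attrs = gen_population(spec, seed=rngs[0])
    ties = gen_tie_graph(ids, attrs, tie_model, seed=rngs[1])
    events = gen_events(ids, ties, checkin_model, seed=rngs[2])
    return ids, attrs, ties, events
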