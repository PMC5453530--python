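"""Reading and writing of the tabular formats used across the pipeline.

The canonical event format is a UTF-8 CSV with a mandatory header
``subject_id,timestamp,location_id``. Timestamps are either integer epoch
seconds or ISO-8601 strings; the dialect can be forced or auto-detected
(all-digit strings are treated as epoch seconds). Subject and location
identifiers are opaque strings and never interpreted.

Networks are exported as GraphML (with node attributes) or as a plain
edge-list CSV; reference tie networks are accepted as 2-column edge lists.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterator

import networkx as nx
import numpy as np
import pandas as pd

from .errors import IntegrityError, ParameterError, ParseError, SchemaError

if TYPE_CHECKING:  # pragma: no cover
    from .svcn_core import PairStat, SvcnResult

EVENT_COLUMNS = ("subject_id", "timestamp", "location_id")


@dataclass(frozen=True)
class EventRecord:
    """One check-in: subject seen at a location at a point in time."""

    subject_id: str
    timestamp: int  # epoch seconds
    location_id: str


@dataclass
class EventStream:
    """An ordered collection of check-in events.

    Internally a DataFrame with columns ``subject_id`` (str),
    ``timestamp`` (int64 epoch seconds) and ``location_id`` (str),
    kept in input order.
    """

    frame: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        {c: pd.Series(dtype="int64" if c == "timestamp" else "object")
         for c in EVENT_COLUMNS}))

    def __post_init__(self) -> None:
        missing = [c for c in EVENT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"event frame missing columns: {missing}")
        self.frame = self.frame.loc[:, list(EVENT_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self) -> Iterator[EventRecord]:
        for row in self.frame.itertuples(index=False):
            yield EventRecord(row.subject_id, int(row.timestamp), row.location_id)

    @property
    def n_records(self) -> int:
        """Total record count Z."""
        return len(self.frame)

    def subjects(self) -> list[str]:
        return sorted(self.frame["subject_id"].unique())

    @classmethod
    def from_records(cls, records) -> "EventStream":
        rows = [(r.subject_id, int(r.timestamp), r.location_id) if isinstance(r, EventRecord)
                else (str(r[0]), int(r[1]), str(r[2])) for r in records]
        frame = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
        frame["timestamp"] = frame["timestamp"].astype("int64")
        return cls(frame)


@dataclass
class AttributeTable:
    """Per-subject attributes, each column tagged categorical or scalar."""

    frame: pd.DataFrame  # indexed by subject_id
    kinds: dict[str, str]  # column -> "categorical" | "scalar"

    @property
    def attributes(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def subjects(self) -> list[str]:
        return list(self.frame.index)

    def column(self, name: str) -> dict[str, object]:
        if name not in self.frame.columns:
            raise SchemaError(f"unknown attribute {name!r}")
        return self.frame[name].to_dict()


def _parse_timestamps(raw: pd.Series, dialect: str) -> pd.Series:
    """Convert a string series into int64 epoch seconds."""
    stripped = raw.astype(str).str.strip()
    if dialect == "auto":
        all_digits = stripped.str.fullmatch(r"-?\d+").all()
        dialect = "epoch_seconds" if all_digits else "iso8601"
    if dialect == "epoch_seconds":
        parsed = pd.to_numeric(stripped, errors="coerce")
        bad = parsed.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ParseError(f"timestamp {raw.iloc[int(np.flatnonzero(bad.to_numpy())[0])]!r} "
                             "is not epoch seconds", line=line)
        return parsed.astype("int64")
    if dialect == "iso8601":
        parsed = pd.to_datetime(stripped, errors="coerce", format="ISO8601", utc=True)
        bad = parsed.isna()
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(f"timestamp {raw.iloc[idx]!r} is not ISO-8601", line=idx + 2)
        return (parsed.astype("int64") // 10**9).astype("int64")
    raise ParameterError(f"unknown timestamp dialect {dialect!r}")


def read_events(path, timestamp_dialect: str = "auto") -> EventStream:
    """Read an events CSV into an :class:`EventStream`.

    Rows are returned in file order. Malformed timestamps and empty
    identifier fields raise :class:`ParseError` naming the 1-based line.
    """
    if timestamp_dialect not in ("auto", "iso8601", "epoch_seconds"):
        raise ParameterError(f"unknown timestamp dialect {timestamp_dialect!r}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    frame = frame.loc[:, list(EVENT_COLUMNS)]
    if len(frame) == 0:
        return EventStream()
    for col in ("subject_id", "location_id"):
        empty = frame[col].astype(str).str.strip() == ""
        if empty.any():
            line = int(np.flatnonzero(empty.to_numpy())[0]) + 2
            raise ParseError(f"empty {col}", line=line)
    frame["timestamp"] = _parse_timestamps(frame["timestamp"], timestamp_dialect)
    return EventStream(frame)


def write_events(stream: EventStream, path) -> None:
    """Write an events CSV with epoch-second timestamps (round-trips exactly)."""
    stream.frame.to_csv(path, index=False, lineterminator="\n")


def read_attributes(path) -> AttributeTable:
    """Read a subject-attribute CSV keyed by ``subject_id``.

    Columns that parse fully as numbers are tagged ``scalar``; everything
    else is ``categorical``. Duplicate subject rows are rejected.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "subject_id" not in frame.columns:
        raise SchemaError(f"{path}: missing subject_id column")
    attr_cols = [c for c in frame.columns if c != "subject_id"]
    if not attr_cols:
        raise SchemaError(f"{path}: need at least one attribute column")
    dups = frame["subject_id"][frame["subject_id"].duplicated()]
    if len(dups):
        raise IntegrityError(f"duplicate subject_id {dups.iloc[0]!r}")
    frame = frame.set_index("subject_id")
    kinds: dict[str, str] = {}
    for col in attr_cols:
        numeric = pd.to_numeric(frame[col], errors="coerce")
        if numeric.notna().all():
            frame[col] = numeric
            kinds[col] = "scalar"
        else:
            kinds[col] = "categorical"
    return AttributeTable(frame=frame, kinds=kinds)


def write_attributes(table: AttributeTable, path) -> None:
    table.frame.to_csv(path, index=True, index_label="subject_id",
                       lineterminator="\n")


def write_pair_stats(pairs, path) -> None:
    """Write pair statistics as CSV, endpoints in lexicographic order.

    p-values are printed in scientific notation with 7 significant digits.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["subject_a", "subject_b", "x_obs", "x_exp",
                         "p_value", "significant"])
        for ps in pairs:
            a, b = sorted((ps.i, ps.j))
            writer.writerow([a, b, ps.x_obs, f"{ps.x_exp:.10g}",
                             f"{ps.p_value:.6e}",
                             int(bool(getattr(ps, "significant", False)))])


def read_pair_stats(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"subject_a": str, "subject_b": str})
    expected = {"subject_a", "subject_b", "x_obs", "x_exp", "p_value", "significant"}
    missing = expected - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    return frame


def network_to_graph(svcn: "SvcnResult", attributes: AttributeTable | None = None) -> nx.Graph:
    """Materialize an inference result as a graph, isolates included."""
    g = nx.Graph()
    g.add_nodes_from(svcn.nodes)
    for ps in svcn.edges:
        g.add_edge(ps.i, ps.j, x_obs=int(ps.x_obs), x_exp=float(ps.x_exp),
                   p_value=float(ps.p_value))
    if attributes is not None:
        for col in attributes.attributes:
            values = attributes.column(col)
            for node in g.nodes:
                if node in values:
                    g.nodes[node][col] = values[node]
    return g


def write_network(svcn_or_graph, path, format: str = "graphml",
                  attributes: AttributeTable | None = None) -> None:
    """Export a network (all nodes, including isolates) to disk."""
    if isinstance(svcn_or_graph, nx.Graph):
        g = svcn_or_graph
        if attributes is not None:
            for col in attributes.attributes:
                values = attributes.column(col)
                for node in g.nodes:
                    if node in values:
                        g.nodes[node][col] = values[node]
    else:
        g = network_to_graph(svcn_or_graph, attributes)
    if format == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
    elif format == "edgelist_csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, lineterminator="\n")
            writer.writerow(["subject_a", "subject_b"])
            for u, v in sorted(tuple(sorted(e)) for e in g.edges):
                writer.writerow([u, v])
    else:
        raise ParameterError(f"unknown network format {format!r}")


def read_network(path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edgelist_csv":
        return read_edge_list(path)
    raise ParameterError(f"unknown network format {format!r}")


def read_edge_list(path) -> nx.Graph:
    """Read a 2-column edge-list CSV (header optional) into a graph."""
    g = nx.Graph()
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        return g
    start = 1 if [c.strip().lower() for c in rows[0][:2]] in (
        ["subject_a", "subject_b"], ["source", "target"]) else 0
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 2 or not row[0].strip() or not row[1].strip():
            raise ParseError("edge row needs two non-empty columns", line=lineno)
        g.add_edge(row[0].strip(), row[1].strip())
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["subject_a", "subject_b"])
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            writer.writerow([u, v])
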