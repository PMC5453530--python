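import networkx as nx
import pytest

from cooccurnet.event_io import EventStream
from cooccurnet.svcn_core import Segmentation, segment_events

TAU = 300


def make_stream(segment_spec, tau=TAU):
    """Build an event stream realizing the given segments exactly.

    ``segment_spec`` is a list of (location_id, slot_index, subjects);
    each subject gets one event in the middle of the slot.
    """
    records = []
    for loc, slot, subjects in segment_spec:
        for s in subjects:
            records.append((s, slot * tau + tau // 2, loc))
    return EventStream.from_records(records)


def make_segmentation(segment_spec, tau=TAU) -> Segmentation:
    """Segmentation whose segments are exactly ``segment_spec``."""
    stream = make_stream(segment_spec, tau=tau)
    return segment_events(stream, tau, t0_policy="explicit", t0=0)


@pytest.fixture
def path_graph_abc():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g


@pytest.fixture
def triangle():
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
    return g
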