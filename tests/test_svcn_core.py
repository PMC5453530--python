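import math
from decimal import Decimal, getcontext

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cooccurnet.errors import ParameterError
from cooccurnet.event_io import EventStream
from cooccurnet.svcn_core import (build_svcn, corrected_threshold,
                                  count_cooccurrences, expected_cooccurrence,
                                  mc_null_pvalue, poisson_upper_tail,
                                  segment_events)

from conftest import TAU, make_segmentation, make_stream


def poisson_tail_oracle(x: int, mu: float, digits: int = 50) -> float:
    """Extended-precision series sum of the upper Poisson tail."""
    getcontext().prec = digits
    mud = Decimal(repr(mu))
    term = mud ** x
    for k in range(2, x + 1):
        term /= k
    total = Decimal(0)
    n = x
    while True:
        total += term
        n += 1
        term = term * mud / n
        if term < total * Decimal("1e-40"):
            break
    return float(total * (-mud).exp())


class TestSegmentation:
    def test_duplicate_occurrences_collapse(self):
        stream = EventStream.from_records([("s1", 0, "L1"), ("s1", 100, "L1")])
        seg = segment_events(stream, 300, t0_policy="explicit", t0=0)
        assert seg.K == 1 and seg.M == 1
        assert seg.n_occurrences("s1") == 1

    def test_hand_binning(self):
        stream = EventStream.from_records(
            [("s1", 0, "L1"), ("s2", 100, "L1"), ("s3", 400, "L1")])
        seg = segment_events(stream, 300, t0_policy="explicit", t0=0)
        assert seg.K == 2 and seg.M == 3
        segs = seg.segments
        assert segs[("L1", 0)] == frozenset({"s1", "s2"})
        assert segs[("L1", 1)] == frozenset({"s3"})

    def test_locations_stay_separate(self):
        stream = EventStream.from_records([("s1", 50, "L1"), ("s2", 50, "L2")])
        seg = segment_events(stream, 300, t0_policy="explicit", t0=0)
        assert seg.K == 2

    def test_bad_tau(self):
        stream = EventStream.from_records([("s1", 0, "L1")])
        with pytest.raises(ParameterError):
            segment_events(stream, 0)

    def test_empty_stream_rejected(self):
        with pytest.raises(ParameterError):
            segment_events(EventStream(), 300)

    def test_midnight_origin(self):
        stream = EventStream.from_records([("s1", 86400 * 3 + 7000, "L1")])
        seg = segment_events(stream, 300, t0_policy="midnight_of_first_day")
        assert seg.t0 == 86400 * 3

    @given(st.lists(st.tuples(st.integers(0, 9), st.integers(0, 5000),
                              st.integers(0, 3)), min_size=1, max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_conservation_sum_ni_equals_m(self, triples):
        stream = EventStream.from_records(
            [(f"s{s}", t, f"L{l}") for s, t, l in triples])
        seg = segment_events(stream, 300, t0_policy="explicit", t0=0)
        assert seg.n_by_subject.sum() == seg.M == seg.sizes.sum()
        assert seg.K == len(seg.segments)
        assert (seg.sizes >= 1).all()


class TestCountCooccurrences:
    def test_hand_count(self):
        seg = make_segmentation([("L1", 0, ["1", "2"]), ("L1", 1, ["1", "2"]),
                                 ("L1", 2, ["2", "3"])])
        counts = count_cooccurrences(seg)
        assert counts == {("1", "2"): 2, ("2", "3"): 1}

    def test_singletons_give_no_pairs(self):
        seg = make_segmentation([("L1", 0, ["a"]), ("L2", 1, ["b"])])
        assert count_cooccurrences(seg) == {}

    def test_segment_of_four(self):
        seg = make_segmentation([("L1", 0, ["a", "b", "c", "d"])])
        counts = count_cooccurrences(seg)
        assert len(counts) == 6
        assert all(v == 1 for v in counts.values())

    def test_total_identity(self):
        seg = make_segmentation([("L1", 0, ["a", "b", "c"]), ("L2", 0, ["a", "b"]),
                                 ("L1", 1, ["c", "d"])])
        counts = count_cooccurrences(seg)
        sizes = seg.sizes
        assert sum(counts.values()) == sum(s * (s - 1) // 2 for s in sizes)


class TestExpectedCooccurrence:
    def test_two_segments_of_two(self):
        seg = make_segmentation([("L1", 0, ["i", "a"]), ("L1", 1, ["j", "b"])])
        assert expected_cooccurrence(seg, "i", "j") == pytest.approx(1 / 3)

    def test_one_segment_of_three(self):
        seg = make_segmentation([("L1", 0, ["i", "j", "c"])])
        assert expected_cooccurrence(seg, "i", "j") == pytest.approx(1.0)

    def test_all_singletons_zero(self):
        seg = make_segmentation([("L1", 0, ["i"]), ("L1", 1, ["j"])])
        assert expected_cooccurrence(seg, "i", "j") == 0.0

    def test_symmetry(self):
        seg = make_segmentation([("L1", 0, ["i", "j"]), ("L1", 1, ["i", "a"]),
                                 ("L2", 0, ["j", "b", "c"])])
        assert expected_cooccurrence(seg, "i", "j") == \
            expected_cooccurrence(seg, "j", "i")

    def test_m_below_two_is_error(self):
        seg = make_segmentation([("L1", 0, ["i"])])
        with pytest.raises(ParameterError):
            expected_cooccurrence(seg, "i", "i")

    def test_mean_identity_on_random_streams(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            triples = [(f"s{rng.integers(8)}", int(rng.integers(4000)),
                        f"L{rng.integers(3)}") for _ in range(40)]
            seg = segment_events(EventStream.from_records(triples), 300,
                                 t0_policy="explicit", t0=0)
            subjects = list(seg.n_by_subject.index)
            if len(subjects) < 2 or seg.M < 2:
                continue
            total = sum(expected_cooccurrence(seg, a, b)
                        for k, a in enumerate(subjects) for b in subjects[k + 1:])
            n = seg.n_by_subject
            pair_sum = sum(int(n[a]) * int(n[b])
                           for k, a in enumerate(subjects) for b in subjects[k + 1:])
            expect = seg.sum_pairs / (seg.M * (seg.M - 1)) * pair_sum
            assert total == pytest.approx(expect, rel=1e-12)


class TestPoissonUpperTail:
    def test_x_zero_is_one(self):
        assert poisson_upper_tail(0, 5.0) == 1.0

    def test_closed_form_x1(self):
        assert poisson_upper_tail(1, 1.0) == pytest.approx(1 - math.exp(-1), rel=1e-12)

    def test_deep_tail_vs_series_oracle(self):
        p = poisson_upper_tail(10, 0.1)
        assert p == pytest.approx(poisson_tail_oracle(10, 0.1), rel=1e-10)

    def test_bad_mu(self):
        with pytest.raises(ParameterError):
            poisson_upper_tail(1, 0.0)

    def test_monotone_in_x(self):
        mu = 2.5
        ps = [poisson_upper_tail(x, mu) for x in range(0, 15)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_monotone_in_mu(self):
        for x in (1, 3, 8):
            ps = [poisson_upper_tail(x, mu) for mu in np.linspace(0.01, 10, 25)]
            assert all(a <= b + 1e-15 for a, b in zip(ps, ps[1:]))

    @given(st.integers(1, 40), st.floats(1e-3, 40))
    @settings(max_examples=60, deadline=None)
    def test_in_unit_interval(self, x, mu):
        p = poisson_upper_tail(x, mu)
        assert 0.0 < p <= 1.0


class TestCorrectedThreshold:
    def test_printed_threshold_three_sig_figs(self):
        p_b = corrected_threshold(0.01, 93_529_939)
        assert f"{p_b:.2e}" == "1.07e-10"

    def test_single_test_identity(self):
        assert corrected_threshold(0.05, 1) == 0.05

    def test_hand_arithmetic(self):
        assert corrected_threshold(0.05, 10) == pytest.approx(0.005)

    def test_bad_n_tests(self):
        with pytest.raises(ParameterError):
            corrected_threshold(0.01, 0)

    def test_unknown_method(self):
        with pytest.raises(ParameterError):
            corrected_threshold(0.01, 10, method="fdr")


class TestBuildSvcn:
    def test_strong_pair_retained(self):
        # two subjects share 20 of 20 segments among 100 subjects
        spec = []
        for k in range(20):
            spec.append(("L1", k, ["i", "j"]))
        for s in range(96):
            spec.append((f"L{2 + s % 5}", s, [f"bg{s}"]))
        stream = make_stream(spec)
        result = build_svcn(stream, tau=TAU, t0_policy="explicit", t0=0)
        assert {frozenset((e.i, e.j)) for e in result.edges} == {frozenset(("i", "j"))}
        assert len(result.nodes) == 98

    def test_single_cooccurrence_rejected(self):
        # i and j are highly active but overlap once; a crowded segment
        # supplies many other candidate tests
        spec = [("L1", k, ["i"]) for k in range(50)]
        spec += [("L2", k, ["j"]) for k in range(50)]
        spec += [("L1", 50, ["i", "j"])]
        spec += [("L3", 0, [f"bg{s}" for s in range(20)])]
        stream = make_stream(spec)
        result = build_svcn(stream, tau=TAU, t0_policy="explicit", t0=0)
        assert frozenset(("i", "j")) not in {frozenset((e.i, e.j)) for e in result.edges}

    def test_empty_stream_is_error_free(self):
        result = build_svcn(EventStream())
        assert result.nodes == [] and result.edges == []

    def test_all_nodes_present_with_isolates(self):
        stream = make_stream([("L1", 0, ["a", "b"]), ("L2", 5, ["lonely"])])
        result = build_svcn(stream, tau=TAU)
        assert "lonely" in result.nodes

    def test_edges_below_threshold(self):
        spec = [("L1", k, ["i", "j"]) for k in range(20)]
        spec += [(f"L{2 + s}", s, [f"b{s}"]) for s in range(30)]
        result = build_svcn(make_stream(spec), tau=TAU)
        for e in result.edges:
            assert e.p_value < result.corrected_threshold

    def test_ntest_policies(self):
        spec = [("L1", 0, ["a", "b", "c"])]
        stream = make_stream(spec)
        r1 = build_svcn(stream, tau=TAU, n_t_policy="candidate_pairs")
        r2 = build_svcn(stream, tau=TAU, n_t_policy="all_pairs")
        r3 = build_svcn(stream, tau=TAU, n_t_policy="explicit", explicit_n_tests=7)
        assert r1.n_tests == 3 and r2.n_tests == 3 and r3.n_tests == 7


class TestMcNullPvalue:
    def test_x_obs_zero_gives_one(self):
        seg = make_segmentation([("L1", 0, ["i", "a"]), ("L1", 1, ["j", "b"])])
        p, se = mc_null_pvalue(seg, "i", "j", n_rep=10, seed=0)
        assert p == 1.0

    def test_same_seed_identical(self):
        seg = make_segmentation([("L1", k, ["i", "j"]) for k in range(3)] +
                                [("L1", 3 + k, ["a", "b"]) for k in range(5)])
        p1, _ = mc_null_pvalue(seg, "i", "j", n_rep=500, seed=11)
        p2, _ = mc_null_pvalue(seg, "i", "j", n_rep=500, seed=11)
        assert p1 == p2

    def test_agrees_with_analytic_small(self):
        # K=50 equal segments of size 6, n_i=n_j=3, one shared segment
        spec = [("L1", 0, ["i", "j", "f1", "f2", "f3", "f4"])]
        spec += [("L1", 1 + k, ["i", f"a{k}", f"b{k}", f"c{k}", f"d{k}", f"e{k}"])
                 for k in range(2)]
        spec += [("L2", 1 + k, ["j", f"p{k}", f"q{k}", f"r{k}", f"s{k}", f"t{k}"])
                 for k in range(2)]
        spec += [("L3", k, [f"z{k}_{m}" for m in range(6)]) for k in range(45)]
        seg = make_segmentation(spec)
        assert seg.K == 50
        mu = expected_cooccurrence(seg, "i", "j")
        p_analytic = poisson_upper_tail(1, mu)
        p_hat, se = mc_null_pvalue(seg, "i", "j", n_rep=8000, seed=3)
        assert abs(p_hat - p_analytic) <= 3 * se

    def test_bad_n_rep(self):
        seg = make_segmentation([("L1", 0, ["i", "j"])])
        with pytest.raises(ParameterError):
            mc_null_pvalue(seg, "i", "j", n_rep=0, seed=0)
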