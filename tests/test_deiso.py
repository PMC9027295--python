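import numpy as np
import pytest

from mrmkit.annotate import Annotation, annotate_run
from mrmkit.chem import Ms2Mode, parse_formula
from mrmkit.dataio import Chromatogram, CompoundEntry, MrmTransition, Polarity, RunData
from mrmkit.deiso import (
    DeisoConfig,
    InterferenceEdge,
    InterferenceGraph,
    apply_deisotoping,
    find_interference_edges,
    resample_onto,
)

from conftest import make_channel

PC342 = CompoundEntry(
    name="PC_34:2",
    q1=758.57,
    q3=184.07,
    polarity=Polarity.POSITIVE,
    ce=33.0,
    formula=parse_formula("C42H81O8NP"),
    ms2_formula=parse_formula("C5H15O4NP"),
    ms2_formula_type=Ms2Mode.CONSTANT_PRODUCT,
)


def two_sig(x):
    return float(f"{x:.1e}")


def annotation_for(channel, compound):
    return Annotation(channel_id=channel.id, compound=compound, dq1=0.0, dq3=0.0)


class TestFindInterferenceEdges:
    def test_pc_342_m1_m2_edges(self):
        source = make_channel(758.57, 184.07, ce=33.0)
        m1 = make_channel(759.57, 184.07, ce=33.0)
        m2 = make_channel(760.58, 184.07, ce=33.0)
        run = RunData("r", [source, m1, m2])
        graph = find_interference_edges(run, [annotation_for(source, "PC_34:2")], [PC342])
        by_target = {(e.affected_channel_id, e.i, e.j): e.factor for e in graph.edges}
        assert two_sig(by_target[(m1.id, 1, 0)]) == 4.1e-1
        assert two_sig(by_target[(m2.id, 2, 0)]) == 9.0e-2
        assert len(graph.edges) == 2

    def test_ce_mismatch_blocks_edge(self):
        source = make_channel(758.57, 184.07, ce=33.0)
        m1 = make_channel(759.57, 184.07, ce=35.0)
        run = RunData("r", [source, m1])
        graph = find_interference_edges(run, [annotation_for(source, "PC_34:2")], [PC342])
        assert graph.edges == []

    def test_ce_within_one_volt_allows_edge(self):
        source = make_channel(758.57, 184.07, ce=33.0)
        m1 = make_channel(759.57, 184.07, ce=34.0)
        run = RunData("r", [source, m1])
        graph = find_interference_edges(run, [annotation_for(source, "PC_34:2")], [PC342])
        assert len(graph.edges) == 1

    def test_single_channel_empty_graph(self):
        source = make_channel(758.57, 184.07)
        run = RunData("r", [source])
        graph = find_interference_edges(run, [annotation_for(source, "PC_34:2")], [PC342])
        assert graph.edges == []

    def test_ineligible_annotation_produces_no_edges(self):
        bare = CompoundEntry(
            name="Bare", q1=758.57, q3=184.07, polarity=Polarity.POSITIVE, ce=33.0
        )
        source = make_channel(758.57, 184.07)
        m1 = make_channel(759.57, 184.07)
        run = RunData("r", [source, m1])
        graph = find_interference_edges(run, [annotation_for(source, "Bare")], [bare])
        assert graph.edges == []

    def test_polarity_must_match(self):
        source = make_channel(758.57, 184.07, ce=33.0)
        m1 = make_channel(759.57, 184.07, ce=33.0, polarity=Polarity.NEGATIVE)
        run = RunData("r", [source, m1])
        graph = find_interference_edges(run, [annotation_for(source, "PC_34:2")], [PC342])
        assert graph.edges == []

    def test_edges_increase_q1(self):
        source = make_channel(758.57, 184.07)
        below = make_channel(757.57, 184.07)
        run = RunData("r", [source, below])
        graph = find_interference_edges(run, [annotation_for(source, "PC_34:2")], [PC342])
        assert graph.edges == []


class TestResampleOnto:
    def test_identity_on_own_grid(self):
        c = Chromatogram([0.0, 1.0, 2.0], [5.0, 7.0, 3.0])
        out = resample_onto(c, c.times)
        np.testing.assert_array_equal(out.intensities, c.intensities)

    def test_constant_inside_zero_outside(self):
        c = Chromatogram([1.0, 2.0], [100.0, 100.0])
        out = resample_onto(c, np.array([0.5, 1.5, 2.5]))
        np.testing.assert_allclose(out.intensities, [0.0, 100.0, 0.0])

    def test_linear_interpolation(self):
        c = Chromatogram([0.0, 1.0], [0.0, 10.0])
        out = resample_onto(c, np.array([0.5]))
        assert out.intensities[0] == pytest.approx(5.0)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            resample_onto(Chromatogram([1.0], [5.0]), np.array([1.0]))


def constant_channel(q1, value, ce=33.0, n=11):
    times = np.linspace(0.0, 10.0, n)
    return make_channel(q1, 184.0, ce=ce, times=times, intensities=np.full(n, float(value)))


def edge(src, dst, factor, compound="X", i=1, j=0):
    return InterferenceEdge(
        source_channel_id=src.id,
        affected_channel_id=dst.id,
        source_compound=compound,
        i=i,
        j=j,
        factor=factor,
    )


class TestApplyDeisotoping:
    def test_single_subtraction(self):
        a = constant_channel(700.0, 100.0)
        b = constant_channel(701.0, 50.0)
        run = RunData("r", [a, b])
        graph = InterferenceGraph(edges=[edge(a, b, 0.41)])
        out, report = apply_deisotoping(run, graph)
        np.testing.assert_allclose(out.channel(b.id).chromatogram.intensities, 9.0)
        np.testing.assert_allclose(out.channel(a.id).chromatogram.intensities, 100.0)
        assert len(report) == 1
        assert report[0].affected_channel_id == b.id

    def test_no_incoming_edges_is_identity(self):
        a = constant_channel(700.0, 42.0)
        run = RunData("r", [a])
        out, report = apply_deisotoping(run, InterferenceGraph())
        np.testing.assert_array_equal(
            out.channel(a.id).chromatogram.intensities,
            run.channel(a.id).chromatogram.intensities,
        )
        assert report == []

    def test_three_channel_cascade(self):
        # a=100, b=60, c=30; a->b f=0.4, a->c f=0.1, b->c f=0.4
        # b' = 60 - 40 = 20 ; c' = 30 - 10 - 0.4*20 = 12
        a = constant_channel(700.0, 100.0)
        b = constant_channel(701.0, 60.0)
        c = constant_channel(702.0, 30.0)
        run = RunData("r", [a, b, c])
        graph = InterferenceGraph(
            edges=[
                edge(a, b, 0.4, compound="A"),
                edge(a, c, 0.1, compound="A", i=2),
                edge(b, c, 0.4, compound="B"),
            ]
        )
        out, _ = apply_deisotoping(run, graph)
        np.testing.assert_allclose(out.channel(b.id).chromatogram.intensities, 20.0)
        np.testing.assert_allclose(out.channel(c.id).chromatogram.intensities, 12.0)

    def test_redundant_sources_subtract_max_once(self):
        # duplicate source channels carrying the same compound: subtract the
        # pointwise max of the factor-scaled traces, not the sum
        a1 = constant_channel(700.0, 100.0)
        a2 = constant_channel(700.0, 100.0, ce=33.4)  # redundant duplicate
        b = constant_channel(701.0, 50.0)
        run = RunData("r", [a1, a2, b])
        graph = InterferenceGraph(
            edges=[edge(a1, b, 0.41, compound="A"), edge(a2, b, 0.41, compound="A")]
        )
        out, report = apply_deisotoping(run, graph)
        np.testing.assert_allclose(out.channel(b.id).chromatogram.intensities, 9.0)
        assert len(report) == 1
        assert set(report[0].source_channel_ids) == {a1.id, a2.id}

    def test_multi_annotation_source_uses_max_factor(self):
        a = constant_channel(700.0, 100.0)
        b = constant_channel(701.0, 50.0)
        run = RunData("r", [a, b])
        graph = InterferenceGraph(
            edges=[edge(a, b, 0.2, compound="weak"), edge(a, b, 0.41, compound="strong")]
        )
        out, report = apply_deisotoping(run, graph)
        np.testing.assert_allclose(out.channel(b.id).chromatogram.intensities, 9.0)
        assert [r.source_compound for r in report] == ["strong"]

    def test_distinct_compounds_both_subtract(self):
        a = constant_channel(700.0, 100.0)
        b = constant_channel(700.5, 80.0)
        c = constant_channel(701.2, 60.0)
        run = RunData("r", [a, b, c])
        graph = InterferenceGraph(
            edges=[edge(a, c, 0.1, compound="A"), edge(b, c, 0.2, compound="B")]
        )
        out, _ = apply_deisotoping(run, graph)
        np.testing.assert_allclose(
            out.channel(c.id).chromatogram.intensities, 60.0 - 10.0 - 16.0
        )

    def test_negative_residuals_kept_by_default(self):
        a = constant_channel(700.0, 100.0)
        b = constant_channel(701.0, 10.0)
        run = RunData("r", [a, b])
        graph = InterferenceGraph(edges=[edge(a, b, 0.41)])
        out, _ = apply_deisotoping(run, graph)
        np.testing.assert_allclose(out.channel(b.id).chromatogram.intensities, -31.0)

    def test_clamp_negative(self):
        a = constant_channel(700.0, 100.0)
        b = constant_channel(701.0, 10.0)
        run = RunData("r", [a, b])
        graph = InterferenceGraph(edges=[edge(a, b, 0.41)])
        out, _ = apply_deisotoping(run, graph, DeisoConfig(clamp_negative=True))
        np.testing.assert_allclose(out.channel(b.id).chromatogram.intensities, 0.0)

    def test_unknown_channel_in_graph_errors(self):
        a = constant_channel(700.0, 100.0)
        b = constant_channel(701.0, 50.0)
        run = RunData("r", [a])
        graph = InterferenceGraph(edges=[edge(a, b, 0.41)])
        with pytest.raises(KeyError):
            apply_deisotoping(run, graph)

    def test_resampling_across_grids(self):
        # scheduled MRM: source sampled on a different grid than affected
        src_times = np.linspace(0.0, 10.0, 21)
        dst_times = np.linspace(0.0, 10.0, 31) + 0.01
        dst_times = dst_times[dst_times <= 10.0]
        a = make_channel(700.0, 184.0, times=src_times, intensities=np.full(21, 100.0))
        b = make_channel(701.0, 184.0, times=dst_times, intensities=np.full(len(dst_times), 50.0))
        run = RunData("r", [a, b])
        out, _ = apply_deisotoping(run, InterferenceGraph(edges=[edge(a, b, 0.41)]))
        np.testing.assert_allclose(out.channel(b.id).chromatogram.intensities, 9.0)


# ---------------------------------------------------------------------------
# Randomized property suites (acceptance criterion: 1000 instances each)
# ---------------------------------------------------------------------------


def random_instance(rng):
    """Forward-modeled instance: each trace is its own signal plus incoming
    factor-scaled source signal, so corrected traces stay nonnegative (the
    regime the dominance invariant assumes)."""
    n_channels = int(rng.integers(2, 5))
    n_points = int(rng.integers(5, 25))
    times = np.sort(rng.uniform(0, 10, n_points))
    while np.any(np.diff(times) <= 0):
        times = np.sort(rng.uniform(0, 10, n_points))
    own = [rng.uniform(0, 1000, n_points) for _ in range(n_channels)]
    factors = {}
    for si in range(n_channels):
        for ti in range(si + 1, n_channels):
            if rng.random() < 0.5:
                factors[(si, ti)] = float(rng.uniform(0, 0.6))
    dirty = [y.copy() for y in own]
    for (si, ti), f in sorted(factors.items()):
        dirty[ti] += f * own[si]
    channels = []
    q1 = 500.0
    for k in range(n_channels):
        q1 += float(rng.uniform(0.5, 3.0))
        channels.append(make_channel(q1, 184.0, times=times, intensities=dirty[k]))
    run = RunData("r", channels)
    edges = [
        edge(channels[si], channels[ti], f, compound=f"c{si}", i=ti - si)
        for (si, ti), f in sorted(factors.items())
    ]
    return run, InterferenceGraph(edges=edges)


def test_pointwise_dominance_1000():
    rng = np.random.default_rng(123)
    for _ in range(1000):
        run, graph = random_instance(rng)
        out, _ = apply_deisotoping(run, graph)
        for ch in run.channels:
            assert np.all(
                out.channel(ch.id).chromatogram.intensities
                <= ch.chromatogram.intensities + 1e-9
            )


def test_identity_on_empty_graph_1000():
    rng = np.random.default_rng(456)
    for _ in range(1000):
        run, _ = random_instance(rng)
        out, report = apply_deisotoping(run, InterferenceGraph())
        assert report == []
        for ch in run.channels:
            np.testing.assert_array_equal(
                out.channel(ch.id).chromatogram.intensities, ch.chromatogram.intensities
            )


def test_linearity_1000():
    rng = np.random.default_rng(789)
    for _ in range(1000):
        run, graph = random_instance(rng)
        scale = float(rng.uniform(0.1, 10.0))
        out1, _ = apply_deisotoping(run, graph)
        scaled = RunData(
            "r",
            [
                make_channel(
                    ch.transition.q1,
                    ch.transition.q3,
                    ce=ch.transition.ce,
                    times=ch.chromatogram.times,
                    intensities=scale * ch.chromatogram.intensities,
                )
                for ch in run.channels
            ],
        )
        out2, _ = apply_deisotoping(scaled, graph)
        for ch in run.channels:
            np.testing.assert_allclose(
                out2.channel(ch.id).chromatogram.intensities,
                scale * out1.channel(ch.id).chromatogram.intensities,
                rtol=1e-9,
                atol=1e-6,
            )


def test_cascade_equals_fixed_point():
    # ascending-Q1 sequential processing must equal iterating the
    # subtraction system to convergence (the graph is a DAG ordered by Q1)
    rng = np.random.default_rng(31415)
    for _ in range(50):
        run, graph = random_instance(rng)
        out, _ = apply_deisotoping(run, graph)

        # fixed-point iteration oracle (simple compound selection: these
        # instances have one compound per source channel and distinct
        # compounds, so every edge group is a singleton)
        current = {c.id: c.chromatogram.intensities.copy() for c in run.channels}
        raw = {c.id: c.chromatogram.intensities.copy() for c in run.channels}
        times = {c.id: c.chromatogram.times for c in run.channels}
        for _ in range(len(run.channels) + 1):
            new = {}
            for c in run.channels:
                y = raw[c.id].copy()
                for e in graph.incoming(c.id):
                    y -= e.factor * np.interp(
                        times[c.id], times[e.source_channel_id],
                        current[e.source_channel_id], left=0.0, right=0.0,
                    )
                new[c.id] = y
            current = new
        for c in run.channels:
            np.testing.assert_allclose(
                out.channel(c.id).chromatogram.intensities, current[c.id], rtol=1e-9, atol=1e-9
            )


def test_end_to_end_with_annotation():
    # full pipeline: annotate -> discover -> subtract on a Gaussian peak
    times = np.linspace(0.0, 10.0, 201)
    peak = 1000.0 * np.exp(-0.5 * ((times - 5.0) / 0.2) ** 2)
    source = make_channel(758.57, 184.07, ce=33.0, times=times, intensities=peak)
    affected = make_channel(
        759.57, 184.07, ce=33.0, times=times, intensities=0.40929652 * peak
    )
    run = RunData("r", [source, affected])
    anns = annotate_run(run.channels, [PC342])
    graph = find_interference_edges(run, anns, [PC342])
    out, _ = apply_deisotoping(run, graph)
    residual = out.channel(affected.id).chromatogram.intensities
    assert np.max(np.abs(residual)) < 1e-2
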