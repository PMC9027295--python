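"""Isotopic-interference discovery and cascaded chromatogram subtraction.

A *source* channel is one annotated with a compound whose isotopologues
can appear in another (*affected*) channel: the transition shifted by
``i`` nucleons on Q1 and ``j <= i`` nucleons on Q3 lands within the mass
tolerance of the affected channel's transition, at a compatible collision
energy.  Subtraction proceeds from low to high Q1 so that cascaded
(chained) interference uses already-corrected source chromatograms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotate import Annotation
from .chem import transition_pattern
from .dataio import Chromatogram, CompoundEntry, MrmChannel, RunData

__all__ = [
    "DeisoConfig",
    "InterferenceEdge",
    "InterferenceGraph",
    "AppliedCorrection",
    "find_interference_edges",
    "resample_onto",
    "apply_deisotoping",
]

#: m/z spacing per nucleon used to predict interfered transitions
#: (13C-12C mass difference; at +-0.2 Da tolerance the exact choice is
#: immaterial through M10).
ISOTOPE_SPACING_DA = 1.00335

_FACTOR_FLOOR = 1e-12


@dataclass(frozen=True)
class DeisoConfig:
    mass_tol: float = 0.2
    ce_tol: float = 1.0
    max_order: int = 10
    isotope_spacing: float = ISOTOPE_SPACING_DA
    clamp_negative: bool = False

    def __post_init__(self) -> None:
        if self.mass_tol <= 0:
            raise ValueError("mass_tol must be positive")
        if self.ce_tol < 0:
            raise ValueError("ce_tol must be >= 0")
        if not 0 <= self.max_order <= 10:
            raise ValueError("max_order must be in [0, 10]")


@dataclass(frozen=True)
class InterferenceEdge:
    source_channel_id: str
    affected_channel_id: str
    source_compound: str
    i: int
    j: int
    factor: float


@dataclass
class InterferenceGraph:
    """All interference edges for one run plus the cascade order.

    Acyclic by construction: every edge strictly increases Q1 (i >= 1 and
    the isotope spacing exceeds the mass tolerance), so processing affected
    channels in ascending Q1 visits sources before their dependents.
    """

    edges: List[InterferenceEdge] = field(default_factory=list)
    processing_order: List[str] = field(default_factory=list)

    def incoming(self, channel_id: str) -> List[InterferenceEdge]:
        return [e for e in self.edges if e.affected_channel_id == channel_id]


def _cascade_sort_key(channel: MrmChannel) -> Tuple[float, float, float]:
    t = channel.transition
    return (t.q1, t.q3, t.ce)


def find_interference_edges(
    run: RunData,
    annotations: Sequence[Annotation],
    library: Sequence[CompoundEntry],
    config: DeisoConfig = DeisoConfig(),
) -> InterferenceGraph:
    """Discover every source-to-affected interference relation in a run.

    For each deisotoping-eligible annotation (compound C on channel S) and
    isotopologue orders ``1 <= i <= max_order``, ``0 <= j <= i``, the
    predicted interfered transition is (Q1_S + i*spacing, Q3_S + j*spacing).
    Every channel of equal polarity within ``mass_tol`` on both Q1 and Q3
    and within ``ce_tol`` of the source's collision energy receives an edge
    carrying the transition-level factor f(i, j).  Factors below 1e-12 are
    dropped.
    """
    by_name: Dict[str, CompoundEntry] = {e.name: e for e in library}
    by_channel: Dict[str, MrmChannel] = {c.id: c for c in run.channels}

    edges: List[InterferenceEdge] = []
    pattern_cache: Dict[str, Dict[Tuple[int, int], float]] = {}
    for ann in annotations:
        source = by_channel.get(ann.channel_id)
        entry = by_name.get(ann.compound)
        if source is None or entry is None or not entry.deiso_eligible:
            continue
        if entry.name not in pattern_cache:
            pattern_cache[entry.name] = dict(
                transition_pattern(
                    entry.formula, entry.ms2_formula, entry.ms2_formula_type, config.max_order
                ).factors
            )
        factors = pattern_cache[entry.name]
        st = source.transition
        for target in run.channels:
            tt = target.transition
            if tt.polarity is not st.polarity:
                continue
            if abs(tt.ce - st.ce) > config.ce_tol:
                continue
            for i in range(1, config.max_order + 1):
                dq1 = tt.q1 - (st.q1 + i * config.isotope_spacing)
                if abs(dq1) > config.mass_tol:
                    continue
                for j in range(0, i + 1):
                    dq3 = tt.q3 - (st.q3 + j * config.isotope_spacing)
                    if abs(dq3) > config.mass_tol:
                        continue
                    f = factors.get((i, j), 0.0)
                    if f < _FACTOR_FLOOR:
                        continue
                    edges.append(
                        InterferenceEdge(
                            source_channel_id=source.id,
                            affected_channel_id=target.id,
                            source_compound=entry.name,
                            i=i,
                            j=j,
                            factor=f,
                        )
                    )

    order = [c.id for c in sorted(run.channels, key=_cascade_sort_key)]
    return InterferenceGraph(edges=edges, processing_order=order)


def resample_onto(source: Chromatogram, target_times: np.ndarray) -> Chromatogram:
    """Linear interpolation of a chromatogram onto another time grid.

    Scheduled-MRM channels have channel-specific time grids, so source
    traces must be resampled before subtraction.  Outside the source's
    acquired span the signal is taken as zero.
    """
    if len(source) < 2:
        raise ValueError("source chromatogram needs at least 2 points")
    target_times = np.asarray(target_times, dtype=float)
    values = np.interp(target_times, source.times, source.intensities, left=0.0, right=0.0)
    return Chromatogram(target_times, values)


@dataclass(frozen=True)
class AppliedCorrection:
    """One subtraction applied to an affected channel (for reporting)."""

    affected_channel_id: str
    source_compound: str
    source_channel_ids: Tuple[str, ...]
    max_factor: float
    subtracted_area: float


def _select_annotations(
    edges: Sequence[InterferenceEdge],
) -> List[InterferenceEdge]:
    """Per source channel keep only the max-factor compound's edges.

    A source channel annotated with several eligible compounds would
    otherwise subtract once per compound; the max-factor annotation is the
    conservative default.
    """
    best: Dict[str, Tuple[str, float]] = {}
    for e in edges:
        cur = best.get(e.source_channel_id)
        if cur is None or e.factor > cur[1]:
            best[e.source_channel_id] = (e.source_compound, e.factor)
    return [e for e in edges if best[e.source_channel_id][0] == e.source_compound]


def apply_deisotoping(
    run: RunData,
    graph: InterferenceGraph,
    config: DeisoConfig = DeisoConfig(),
) -> Tuple[RunData, List[AppliedCorrection]]:
    """Cascaded subtraction of isotopic interference from a run.

    Affected channels are processed in ascending Q1 (ties broken by Q3,
    then CE); every subtraction uses the already-corrected source
    chromatogram, so chains resolve in one pass.  Redundant channels
    (several source channels carrying the same compound into one affected
    channel) are collapsed to a single subtraction of the point-by-point
    maximum of their factor-scaled traces, preventing over-subtraction.
    Residuals may go negative unless ``clamp_negative`` is set.
    """
    by_id: Dict[str, MrmChannel] = {c.id: c for c in run.channels}
    for e in graph.edges:
        if e.source_channel_id not in by_id or e.affected_channel_id not in by_id:
            raise KeyError(f"edge references unknown channel: {e}")

    corrected: Dict[str, np.ndarray] = {
        c.id: c.chromatogram.intensities.copy() for c in run.channels
    }
    report: List[AppliedCorrection] = []

    order = graph.processing_order or [
        c.id for c in sorted(run.channels, key=_cascade_sort_key)
    ]
    for cid in order:
        incoming = _select_annotations(graph.incoming(cid))
        if not incoming:
            continue
        channel = by_id[cid]
        times = channel.chromatogram.times
        by_compound: Dict[str, List[InterferenceEdge]] = {}
        for e in incoming:
            by_compound.setdefault(e.source_compound, []).append(e)
        for compound, comp_edges in sorted(by_compound.items()):
            traces = []
            for e in comp_edges:
                src = by_id[e.source_channel_id]
                resampled = np.interp(
                    times,
                    src.chromatogram.times,
                    corrected[e.source_channel_id],
                    left=0.0,
                    right=0.0,
                )
                traces.append(e.factor * resampled)
            subtrahend = np.max(traces, axis=0) if len(traces) > 1 else traces[0]
            corrected[cid] = corrected[cid] - subtrahend
            report.append(
                AppliedCorrection(
                    affected_channel_id=cid,
                    source_compound=compound,
                    source_channel_ids=tuple(
                        dict.fromkeys(e.source_channel_id for e in comp_edges)
                    ),
                    max_factor=max(e.factor for e in comp_edges),
                    subtracted_area=float(np.trapezoid(subtrahend, times))
                    if times.size > 1
                    else 0.0,
                )
            )
        if config.clamp_negative:
            corrected[cid] = np.maximum(corrected[cid], 0.0)

    out_channels = [
        MrmChannel(
            transition=c.transition,
            chromatogram=Chromatogram(c.chromatogram.times.copy(), corrected[c.id]),
            id=c.id,
        )
        for c in run.channels
    ]
    return RunData(run_id=run.run_id, channels=out_channels), report
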