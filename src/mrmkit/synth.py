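"""Synthetic scheduled-MRM dataset generator with forward-modeled
isotopic interference, retention-time drift, noise, and detector
saturation.

The forward model is the mirror image of the deisotoping subtraction: a
channel's contaminated trace is its own compound's Gaussian peaks plus,
for every other compound whose isotopologue-shifted transition lands on
this channel, the factor-scaled clean trace of that compound.  Clipping a
trace at a saturation ceiling breaks the linearity the subtraction
assumes, reproducing the residual-interference failure mode of saturated
detectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .chem import ChemFormula, Ms2Mode, transition_pattern
from .dataio import (
    Chromatogram,
    CompoundEntry,
    Dataset,
    MrmChannel,
    MrmTransition,
    RunData,
    channel_id,
)
from .deiso import ISOTOPE_SPACING_DA, InterferenceEdge

__all__ = [
    "GaussianPeak",
    "SyntheticCompound",
    "SimulationSpec",
    "simulate_dataset",
    "clip_saturation",
    "compounds_to_library",
]

_FACTOR_FLOOR = 1e-12


@dataclass(frozen=True)
class GaussianPeak:
    apex_rt: float  # minutes
    sigma: float  # minutes
    height: float  # arbitrary units

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.height <= 0:
            raise ValueError("peak sigma and height must be positive")


@dataclass(frozen=True)
class SyntheticCompound:
    name: str
    formula: ChemFormula
    ms2_formula: ChemFormula
    ms2_formula_type: Ms2Mode
    transition: MrmTransition
    peaks: Tuple[GaussianPeak, ...] = ()

    def __post_init__(self) -> None:
        from .chem import formula_subtract, monoisotopic_mass

        mq1 = monoisotopic_mass(self.formula)
        if abs(mq1 - self.transition.q1) > 0.2:
            warnings.warn(
                f"{self.name}: declared Q1 {self.transition.q1} differs from "
                f"formula mass {mq1:.3f} by more than 0.2 Da",
                stacklevel=2,
            )
        if self.ms2_formula_type is Ms2Mode.CONSTANT_PRODUCT:
            product = self.ms2_formula
        else:
            product = formula_subtract(self.formula, self.ms2_formula)
        mq3 = monoisotopic_mass(product)
        if abs(mq3 - self.transition.q3) > 0.2:
            warnings.warn(
                f"{self.name}: declared Q3 {self.transition.q3} differs from "
                f"product mass {mq3:.3f} by more than 0.2 Da",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SimulationSpec:
    compounds: Tuple[SyntheticCompound, ...]
    n_runs: int = 1
    sampling_interval: float = 0.01  # minutes
    time_start: float = 0.0
    time_end: float = 10.0
    noise_sd: float = 0.0
    saturation_limit: Optional[float] = None
    rt_drift: Tuple[float, ...] = ()  # minutes, one per run; empty = no drift
    max_order: int = 10
    seed: int = 0
    mass_tol: float = 0.2
    ce_tol: float = 1.0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling interval must be positive")
        if self.n_runs < 1:
            raise ValueError("need at least one run")
        if self.time_end <= self.time_start:
            raise ValueError("time_end must exceed time_start")
        if self.rt_drift and len(self.rt_drift) != self.n_runs:
            raise ValueError("rt_drift must have one entry per run")
        if self.saturation_limit is not None and self.saturation_limit <= 0:
            raise ValueError("saturation_limit must be positive")
        if not self.compounds:
            raise ValueError("at least one compound required")


def clip_saturation(chromatogram: Chromatogram, limit: float) -> Chromatogram:
    """Pointwise min with a detector ceiling."""
    if limit <= 0:
        raise ValueError("limit must be positive")
    return Chromatogram(
        chromatogram.times.copy(), np.minimum(chromatogram.intensities, limit)
    )


def compounds_to_library(compounds: Sequence[SyntheticCompound]) -> List[CompoundEntry]:
    """Compound-library rows matching the simulated compounds."""
    return [
        CompoundEntry(
            name=c.name,
            q1=c.transition.q1,
            q3=c.transition.q3,
            polarity=c.transition.polarity,
            ce=c.transition.ce,
            formula=c.formula,
            ms2_formula=c.ms2_formula,
            ms2_formula_type=c.ms2_formula_type,
        )
        for c in compounds
    ]


def _true_edges(spec: SimulationSpec) -> List[InterferenceEdge]:
    """Interference edges implied by the spec's compounds.

    Independent of the discovery code in :mod:`mrmkit.deiso`: a plain
    double loop over compounds and channels used both to contaminate the
    forward model and as ground truth for cross-validating discovery.
    """
    edges: List[InterferenceEdge] = []
    for source in spec.compounds:
        factors = transition_pattern(
            source.formula, source.ms2_formula, source.ms2_formula_type, spec.max_order
        ).factors
        st = source.transition
        for target in spec.compounds:
            tt = target.transition
            if tt.polarity is not st.polarity or abs(tt.ce - st.ce) > spec.ce_tol:
                continue
            if channel_id(tt) == channel_id(st):
                continue
            for (i, j), f in sorted(factors.items()):
                if i < 1 or f < _FACTOR_FLOOR:
                    continue
                if abs(tt.q1 - (st.q1 + i * ISOTOPE_SPACING_DA)) > spec.mass_tol:
                    continue
                if abs(tt.q3 - (st.q3 + j * ISOTOPE_SPACING_DA)) > spec.mass_tol:
                    continue
                edges.append(
                    InterferenceEdge(
                        source_channel_id=channel_id(st),
                        affected_channel_id=channel_id(tt),
                        source_compound=source.name,
                        i=i,
                        j=j,
                        factor=float(f),
                    )
                )
    return edges


def _gaussian_trace(
    times: np.ndarray, peaks: Sequence[GaussianPeak], drift: float
) -> np.ndarray:
    y = np.zeros_like(times)
    for pk in peaks:
        y += pk.height * np.exp(-0.5 * ((times - (pk.apex_rt + drift)) / pk.sigma) ** 2)
    return y


def simulate_dataset(
    spec: SimulationSpec,
) -> Tuple[Dataset, Dataset, List[InterferenceEdge]]:
    """Simulate a scheduled-MRM dataset with isotopic interference.

    Returns (contaminated dataset, interference-free ground truth, true
    edge list).  Per channel: clean = that compound's Gaussian peaks;
    contaminated = clean + sum over incoming edges of factor x source
    clean trace, then additive Gaussian noise, then saturation clipping.
    Ground truth carries the drift but neither noise nor clipping.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round((spec.time_end - spec.time_start) / spec.sampling_interval)) + 1
    times = spec.time_start + spec.sampling_interval * np.arange(n)

    edges = _true_edges(spec)
    by_compound = {c.name: c for c in spec.compounds}

    clean_runs: List[RunData] = []
    dirty_runs: List[RunData] = []
    for k in range(spec.n_runs):
        drift = spec.rt_drift[k] if spec.rt_drift else 0.0
        clean_traces = {
            c.name: _gaussian_trace(times, c.peaks, drift) for c in spec.compounds
        }
        # Aggregate per channel id: compounds sharing a transition co-add.
        clean_by_channel = {}
        transitions = {}
        for c in spec.compounds:
            cid = channel_id(c.transition)
            transitions[cid] = c.transition
            clean_by_channel[cid] = clean_by_channel.get(cid, 0.0) + clean_traces[c.name]

        dirty_by_channel = {cid: y.copy() for cid, y in clean_by_channel.items()}
        for e in edges:
            dirty_by_channel[e.affected_channel_id] += (
                e.factor * clean_traces[e.source_compound]
            )
        for cid in sorted(dirty_by_channel):
            y = dirty_by_channel[cid]
            if spec.noise_sd > 0:
                y = y + rng.normal(0.0, spec.noise_sd, size=y.shape)
            if spec.saturation_limit is not None:
                y = np.minimum(y, spec.saturation_limit)
            dirty_by_channel[cid] = y

        run_id = f"run{k + 1:03d}"
        order = sorted(transitions)
        clean_runs.append(
            RunData(
                run_id=run_id,
                channels=[
                    MrmChannel(transitions[cid], Chromatogram(times, clean_by_channel[cid]))
                    for cid in order
                ],
            )
        )
        dirty_runs.append(
            RunData(
                run_id=run_id,
                channels=[
                    MrmChannel(transitions[cid], Chromatogram(times, dirty_by_channel[cid]))
                    for cid in order
                ],
            )
        )

    return Dataset(runs=dirty_runs), Dataset(runs=clean_runs), edges
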