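"""Anchor-based global retention-time alignment.

Users designate anchor peaks mapping observed to reference retention
times; each run's time axis is warped through a piecewise-linear monotone
function built from its anchors.  Anchor selection is manual by design —
automated picking is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .dataio import Chromatogram, Dataset, MrmChannel, RunData

__all__ = ["RtAnchor", "WarpFunction", "build_warp", "warp_dataset",
           "read_anchors", "write_anchors", "median_reference_anchors"]


@dataclass(frozen=True)
class RtAnchor:
    run_id: str
    observed_rt: float
    reference_rt: float

    def __post_init__(self) -> None:
        if self.observed_rt <= 0:
            raise ValueError("observed_rt must be positive")


class WarpFunction:
    """Piecewise-linear monotone mapping observed -> corrected minutes.

    No anchors: identity.  One anchor: constant shift.  Two or more:
    linear interpolation between anchors with constant-offset extrapolation
    beyond the outermost anchors (the nearest anchor's offset), which keeps
    gradient ends well-behaved.
    """

    def __init__(self, observed: Sequence[float] = (), reference: Sequence[float] = ()):
        obs = np.asarray(observed, dtype=float)
        ref = np.asarray(reference, dtype=float)
        if obs.shape != ref.shape or obs.ndim != 1:
            raise ValueError("observed and reference must be equal-length 1-D")
        if obs.size >= 2:
            if np.any(np.diff(obs) <= 0) or np.any(np.diff(ref) <= 0):
                raise ValueError(
                    "anchors must be strictly increasing in both observed "
                    "and reference coordinates"
                )
        self._obs = obs
        self._offset = ref - obs

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        t_arr = np.asarray(t, dtype=float)
        if self._obs.size == 0:
            out = t_arr
        else:
            # np.interp clamps outside the anchor span, giving the
            # constant-offset extrapolation for free.
            out = t_arr + np.interp(t_arr, self._obs, self._offset)
        return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out

    @property
    def is_identity(self) -> bool:
        return self._obs.size == 0 or bool(np.all(self._offset == 0.0))


def build_warp(anchors: Sequence[RtAnchor]) -> WarpFunction:
    """Build a run's warp from its anchors (any count, including zero)."""
    ordered = sorted(anchors, key=lambda a: a.observed_rt)
    return WarpFunction(
        [a.observed_rt for a in ordered], [a.reference_rt for a in ordered]
    )


def warp_dataset(dataset: Dataset, anchors: Sequence[RtAnchor]) -> Dataset:
    """Warp every chromatogram's time axis; intensities are untouched.

    Runs without anchors pass through the identity.  Anchors referencing a
    run absent from the dataset are an error (likely a typo in the anchor
    file).
    """
    run_ids = {r.run_id for r in dataset.runs}
    unknown = sorted({a.run_id for a in anchors} - run_ids)
    if unknown:
        raise ValueError(f"anchors reference unknown run(s): {unknown}")
    by_run: Dict[str, List[RtAnchor]] = {}
    for a in anchors:
        by_run.setdefault(a.run_id, []).append(a)

    out_runs = []
    for run in dataset.runs:
        warp = build_warp(by_run.get(run.run_id, []))
        channels = [
            MrmChannel(
                transition=c.transition,
                chromatogram=Chromatogram(
                    np.asarray(warp(c.chromatogram.times), dtype=float),
                    c.chromatogram.intensities.copy(),
                ),
                id=c.id,
            )
            for c in run.channels
        ]
        out_runs.append(RunData(run_id=run.run_id, channels=channels))
    return Dataset(runs=out_runs)


def median_reference_anchors(
    observed_by_run: Dict[str, Sequence[float]]
) -> List[RtAnchor]:
    """Helper: use the per-anchor median observed RT across runs as reference.

    ``observed_by_run`` maps run_id to that run's observed anchor RTs; the
    k-th anchor of every run is assumed to mark the same peak.
    """
    lengths = {len(v) for v in observed_by_run.values()}
    if len(lengths) > 1:
        raise ValueError("every run must provide the same number of anchors")
    if not observed_by_run or lengths == {0}:
        return []
    matrix = np.array([list(v) for v in observed_by_run.values()], dtype=float)
    reference = np.median(matrix, axis=0)
    return [
        RtAnchor(run_id=rid, observed_rt=float(obs), reference_rt=float(ref))
        for rid, row in observed_by_run.items()
        for obs, ref in zip(row, reference)
    ]


_ANCHOR_COLUMNS = ["run_id", "observed_rt_min", "reference_rt_min"]


def read_anchors(path: str | Path) -> List[RtAnchor]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _ANCHOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"anchor file missing column(s): {missing}")
    return [
        RtAnchor(
            run_id=str(r["run_id"]),
            observed_rt=float(r["observed_rt_min"]),
            reference_rt=float(r["reference_rt_min"]),
        )
        for _, r in df.iterrows()
    ]


def write_anchors(anchors: Sequence[RtAnchor], path: str | Path) -> None:
    pd.DataFrame(
        [(a.run_id, a.observed_rt, a.reference_rt) for a in anchors],
        columns=_ANCHOR_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.9g")
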