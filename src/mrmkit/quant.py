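"""Integration targets, background-subtracted AUC, and deisotoping reports."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from .dataio import Chromatogram, Dataset, IntegrationTarget, channel_id

__all__ = ["AucRecord", "integrate_range", "deisotoping_report"]

Background = Literal["none", "linear"]


@dataclass(frozen=True)
class AucRecord:
    channel_id: str
    target: str
    auc_before: float
    auc_after: float
    percent_remaining: Optional[float]  # None when auc_before <= 0


def integrate_range(
    chromatogram: Chromatogram,
    rt_start: Optional[float] = None,
    rt_end: Optional[float] = None,
    background: Background = "none",
) -> float:
    """Trapezoidal AUC over [rt_start, rt_end] in intensity x minutes.

    Endpoint intensities are obtained by linear interpolation; the range is
    clipped to the acquired span and must intersect it.  With
    ``background="linear"`` the trapezoid under the straight line joining
    the endpoint intensities is subtracted (standard chromatographic
    baseline); ``background="none"`` subtracts nothing.  Defaults integrate
    the entire chromatogram.
    """
    t = chromatogram.times
    y = chromatogram.intensities
    if t.size == 0:
        raise ValueError("cannot integrate an empty chromatogram")
    lo = t[0] if rt_start is None else float(rt_start)
    hi = t[-1] if rt_end is None else float(rt_end)
    if not lo < hi:
        raise ValueError(f"rt_start ({lo}) must be < rt_end ({hi})")
    lo_c, hi_c = max(lo, t[0]), min(hi, t[-1])
    if not lo_c < hi_c:
        raise ValueError(
            f"range [{lo}, {hi}] does not intersect acquired span [{t[0]}, {t[-1]}]"
        )
    inside = (t > lo_c) & (t < hi_c)
    xs = np.concatenate(([lo_c], t[inside], [hi_c]))
    ys = np.concatenate(
        ([np.interp(lo_c, t, y)], y[inside], [np.interp(hi_c, t, y)])
    )
    auc = float(np.trapezoid(ys, xs))
    if background == "linear":
        auc -= 0.5 * (ys[0] + ys[-1]) * (hi_c - lo_c)
    elif background != "none":
        raise ValueError(f"unknown background model: {background!r}")
    return auc


def deisotoping_report(
    dataset_before: Dataset,
    dataset_after: Dataset,
    targets: Sequence[IntegrationTarget] = (),
    background: Background = "none",
) -> Tuple[List[AucRecord], int]:
    """Per-channel mean AUC before/after deisotoping across runs.

    With no targets, each channel is integrated over its whole chromatogram
    (its default range).  With targets, only targeted channels appear, one
    record per target.  Channels whose mean before-AUC is nonpositive are
    excluded from the report body; the second return value counts them.
    """
    before_ids = {r.run_id for r in dataset_before.runs}
    after_ids = {r.run_id for r in dataset_after.runs}
    if before_ids != after_ids:
        raise ValueError("before/after datasets must share run ids")

    targets_by_channel: Dict[str, List[IntegrationTarget]] = {}
    for tgt in targets:
        targets_by_channel.setdefault(channel_id(tgt.transition), []).append(tgt)

    # (channel_id, target name) -> list of per-run (before, after) AUCs
    acc: Dict[Tuple[str, str], List[Tuple[float, float]]] = {}
    for run_b in dataset_before.runs:
        run_a = dataset_after.run(run_b.run_id)
        after_by_id = {c.id: c for c in run_a.channels}
        for ch_b in run_b.channels:
            ch_a = after_by_id.get(ch_b.id)
            if ch_a is None:
                raise ValueError(
                    f"channel {ch_b.id!r} missing from after-run {run_a.run_id!r}"
                )
            if targets:
                jobs = [
                    (t.name, t.rt_start, t.rt_end)
                    for t in targets_by_channel.get(ch_b.id, [])
                ]
            else:
                jobs = [("", None, None)]
            for name, lo, hi in jobs:
                b = integrate_range(ch_b.chromatogram, lo, hi, background)
                a = integrate_range(ch_a.chromatogram, lo, hi, background)
                acc.setdefault((ch_b.id, name), []).append((b, a))

    records: List[AucRecord] = []
    excluded = 0
    for (cid, name), pairs in acc.items():
        mean_b = float(np.mean([p[0] for p in pairs]))
        mean_a = float(np.mean([p[1] for p in pairs]))
        if mean_b > 0:
            records.append(
                AucRecord(
                    channel_id=cid,
                    target=name,
                    auc_before=mean_b,
                    auc_after=mean_a,
                    percent_remaining=100.0 * mean_a / mean_b,
                )
            )
        else:
            excluded += 1
    return records, excluded
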