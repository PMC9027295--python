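"""Link compound-library entries to MRM channels and filter channels.

An annotation marks a library entry as a *possible* detection target for a
channel — not an identification.  A channel may carry many annotations and
one entry may hit many channels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

from .dataio import CompoundEntry, Dataset, IntegrationTarget, MrmChannel

__all__ = ["MatchConfig", "Annotation", "annotate_run", "annotate_dataset", "filter_channels"]


@dataclass(frozen=True)
class MatchConfig:
    """Tolerances for channel-to-library matching.

    CE is ignored unless ``ce_tol`` is set (strict mode); the tolerance
    intervals are closed, so a delta exactly at the tolerance matches.
    """

    q1_tol: float = 0.2
    q3_tol: float = 0.2
    require_polarity: bool = True
    ce_tol: Optional[float] = None

    def __post_init__(self) -> None:
        if self.q1_tol <= 0 or self.q3_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.ce_tol is not None and self.ce_tol <= 0:
            raise ValueError("ce_tol must be positive when set")


@dataclass(frozen=True)
class Annotation:
    channel_id: str
    compound: str
    dq1: float
    dq3: float


def _matches(channel: MrmChannel, entry: CompoundEntry, config: MatchConfig) -> Optional[Annotation]:
    t = channel.transition
    if config.require_polarity and t.polarity is not entry.polarity:
        return None
    dq1 = t.q1 - entry.q1
    dq3 = t.q3 - entry.q3
    if abs(dq1) > config.q1_tol or abs(dq3) > config.q3_tol:
        return None
    if config.ce_tol is not None and entry.ce is not None and t.ce and entry.ce:
        if abs(t.ce - entry.ce) > config.ce_tol:
            return None
    return Annotation(channel_id=channel.id, compound=entry.name, dq1=dq1, dq3=dq3)


def annotate_run(
    channels: Sequence[MrmChannel],
    library: Sequence[CompoundEntry],
    config: MatchConfig = MatchConfig(),
) -> List[Annotation]:
    """All (channel, entry) matches for one run's channels.

    Output order is (channel order, library order) but the match set is
    independent of either ordering.
    """
    out: List[Annotation] = []
    for channel in channels:
        for entry in library:
            ann = _matches(channel, entry, config)
            if ann is not None:
                out.append(ann)
    return out


def annotate_dataset(
    dataset: Dataset,
    library: Sequence[CompoundEntry],
    config: MatchConfig = MatchConfig(),
) -> List[Annotation]:
    """Annotate the union of channels across all runs (by channel id)."""
    seen: Dict[str, MrmChannel] = {}
    for run in dataset.runs:
        for channel in run.channels:
            seen.setdefault(channel.id, channel)
    return annotate_run(list(seen.values()), library, config)


def filter_channels(
    dataset: Dataset,
    query: str,
    annotations: Sequence[Annotation] = (),
    targets: Sequence[IntegrationTarget] = (),
) -> List[str]:
    """Channel ids matching a case-insensitive substring query.

    The query is checked against the channel id, the rendered transition
    label, the names of annotated compounds, and the names of targets
    attached to the channel (matched by transition).
    """
    if not query:
        raise ValueError("query must be nonempty")
    q = query.lower()
    ann_by_channel: Dict[str, List[str]] = {}
    for ann in annotations:
        ann_by_channel.setdefault(ann.channel_id, []).append(ann.compound)

    from .dataio import channel_id as make_id

    target_names: Dict[str, List[str]] = {}
    for tgt in targets:
        target_names.setdefault(make_id(tgt.transition), []).append(tgt.name)

    out: List[str] = []
    seen = set()
    for run in dataset.runs:
        for channel in run.channels:
            if channel.id in seen:
                continue
            haystack = [channel.id, channel.transition.render()]
            haystack += ann_by_channel.get(channel.id, [])
            haystack += target_names.get(channel.id, [])
            if any(q in h.lower() for h in haystack):
                out.append(channel.id)
                seen.add(channel.id)
    return out
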