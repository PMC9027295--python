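"""Dataset, library and target I/O for MRM chromatogram processing.

Two ingest routes are supported: PSI mzML files carrying SRM chromatogram
lists, and a plain tab-delimited long-format interchange table (the
reference format for round-tripping; vendor binaries are out of scope).
Times are minutes everywhere; mzML second-based time arrays are converted
on read.
"""

from __future__ import annotations

import base64
import struct
import warnings
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import ChemFormula, Ms2Mode, parse_formula

__all__ = [
    "Polarity",
    "MrmTransition",
    "Chromatogram",
    "MrmChannel",
    "RunData",
    "Dataset",
    "CompoundEntry",
    "IntegrationTarget",
    "DataIOError",
    "read_mzml",
    "read_dataset_table",
    "write_dataset_table",
    "read_compound_library",
    "write_compound_library",
    "read_targets",
    "write_targets",
]


class DataIOError(ValueError):
    pass


class Polarity(str, Enum):
    POSITIVE = "Positive"
    NEGATIVE = "Negative"

    @classmethod
    def parse(cls, text: str) -> "Polarity":
        t = str(text).strip().lower()
        if t in ("positive", "pos", "+"):
            return cls.POSITIVE
        if t in ("negative", "neg", "-"):
            return cls.NEGATIVE
        raise DataIOError(f"unknown polarity: {text!r}")

    @property
    def sign(self) -> str:
        return "+" if self is Polarity.POSITIVE else "-"


@dataclass(frozen=True)
class MrmTransition:
    """One Q1/Q3 pair with polarity and collision energy (0 = unknown)."""

    q1: float
    q3: float
    polarity: Polarity
    ce: float = 0.0

    def __post_init__(self) -> None:
        if self.q1 <= 0 or self.q3 <= 0:
            raise DataIOError(f"Q1/Q3 must be positive, got {self.q1}/{self.q3}")
        if self.ce < 0:
            raise DataIOError(f"collision energy must be >= 0, got {self.ce}")

    def render(self) -> str:
        """Human-readable label, e.g. ``(+)760.6 > 184.05@33V``."""
        ce = f"{self.ce:g}"
        return f"({self.polarity.sign}){self.q1:g} > {self.q3:g}@{ce}V"


def channel_id(transition: MrmTransition) -> str:
    """Stable channel key; Q1/Q3 rounded to 4 decimals, CE to 1 decimal.

    Rounding absorbs trailing-digit jitter in instrument exports while
    keeping genuinely distinct transitions distinct.
    """
    sign = transition.polarity.sign
    return f"{sign}|{transition.q1:.4f}|{transition.q3:.4f}|{transition.ce:.1f}"


@dataclass
class Chromatogram:
    """A time/intensity trace; times in minutes, strictly increasing."""

    times: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise DataIOError("times and intensities must be 1-D and equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise DataIOError("times must be strictly increasing")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(y)):
            raise DataIOError("times and intensities must be finite")
        self.times = t
        self.intensities = y

    def __len__(self) -> int:
        return self.times.size

    def copy(self) -> "Chromatogram":
        return Chromatogram(self.times.copy(), self.intensities.copy())


@dataclass
class MrmChannel:
    transition: MrmTransition
    chromatogram: Chromatogram
    id: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            self.id = channel_id(self.transition)


@dataclass
class RunData:
    run_id: str
    channels: List[MrmChannel] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.channels]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataIOError(f"duplicate channel ids in run {self.run_id!r}: {dupes}")

    def channel(self, cid: str) -> MrmChannel:
        for c in self.channels:
            if c.id == cid:
                return c
        raise KeyError(cid)


@dataclass
class Dataset:
    runs: List[RunData]

    def __post_init__(self) -> None:
        if not self.runs:
            raise DataIOError("dataset must contain at least one run")

    def run(self, run_id: str) -> RunData:
        for r in self.runs:
            if r.run_id == run_id:
                return r
        raise KeyError(run_id)


@dataclass
class CompoundEntry:
    """One compound-library row.

    ``formula``/``ms2_formula``/``ms2_formula_type`` are jointly optional;
    all three are required for the entry to be usable as a deisotoping
    source (:attr:`deiso_eligible`).
    """

    name: str
    q1: float
    q3: float
    polarity: Polarity
    ce: Optional[float] = None
    formula: Optional[ChemFormula] = None
    ms2_formula: Optional[ChemFormula] = None
    ms2_formula_type: Optional[Ms2Mode] = None
    tags: Tuple[str, ...] = ()

    @property
    def deiso_eligible(self) -> bool:
        return (
            self.formula is not None
            and self.ms2_formula is not None
            and self.ms2_formula_type is not None
        )


@dataclass(frozen=True)
class IntegrationTarget:
    name: str
    transition: MrmTransition
    rt_start: float
    rt_end: float

    def __post_init__(self) -> None:
        if not self.rt_start < self.rt_end:
            raise DataIOError(
                f"target {self.name!r}: rt_start ({self.rt_start}) must be < "
                f"rt_end ({self.rt_end})"
            )


# ---------------------------------------------------------------------------
# mzML ingest
#
# Hand-rolled against the PSI schema because no mzML library is available in
# the runtime environment; only the chromatogramList subset needed for SRM
# data is understood.  Spectrum lists are ignored.
# ---------------------------------------------------------------------------

_ACC_SRM = "MS:1001473"  # selected reaction monitoring chromatogram
_ACC_ISOLATION_TARGET = "MS:1000827"
_ACC_CE = "MS:1000045"
_ACC_POS = "MS:1000130"
_ACC_NEG = "MS:1000129"
_ACC_TIME_ARRAY = "MS:1000595"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NO_COMPRESSION = "MS:1000576"
_ACC_UNIT_MINUTE = "UO:0000031"
_ACC_UNIT_SECOND = "UO:0000010"


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(elem: ET.Element) -> List[ET.Element]:
    return [child for child in elem if _strip_ns(child.tag) == "cvParam"]


def _iter_named(elem: ET.Element, name: str) -> Iterable[ET.Element]:
    for child in elem.iter():
        if _strip_ns(child.tag) == name:
            yield child


def _decode_binary_array(bda: ET.Element) -> Tuple[Optional[str], np.ndarray, Optional[str]]:
    """Returns (array kind, values, time unit) for one binaryDataArray."""
    kind = None
    unit = None
    dtype = "<d"
    compressed = False
    for cv in _cv_params(bda):
        acc = cv.get("accession", "")
        if acc == _ACC_TIME_ARRAY:
            kind = "time"
            ua = cv.get("unitAccession", "")
            if ua == _ACC_UNIT_SECOND:
                unit = "second"
            elif ua == _ACC_UNIT_MINUTE:
                unit = "minute"
            elif ua:
                raise DataIOError(f"unsupported time unit accession {ua!r}")
        elif acc == _ACC_INTENSITY_ARRAY:
            kind = "intensity"
        elif acc == _ACC_F64:
            dtype = "<d"
        elif acc == _ACC_F32:
            dtype = "<f"
        elif acc == _ACC_ZLIB:
            compressed = True
        elif acc == _ACC_NO_COMPRESSION:
            compressed = False
    binary = None
    for child in bda:
        if _strip_ns(child.tag) == "binary":
            binary = child.text or ""
    if binary is None:
        raise DataIOError("binaryDataArray without <binary> element")
    raw = base64.b64decode(binary.strip() or b"")
    if compressed:
        raw = zlib.decompress(raw)
    width = struct.calcsize(dtype)
    if len(raw) % width:
        raise DataIOError("binary array length is not a multiple of item size")
    values = np.array(struct.unpack(f"<{len(raw) // width}{dtype[-1]}", raw), dtype=float)
    return kind, values, unit


def _chromatogram_polarity(chrom: ET.Element) -> Optional[Polarity]:
    for cv in _cv_params(chrom):
        if cv.get("accession") == _ACC_POS:
            return Polarity.POSITIVE
        if cv.get("accession") == _ACC_NEG:
            return Polarity.NEGATIVE
    return None


def _file_level_polarity(root: ET.Element) -> Optional[Polarity]:
    for settings in _iter_named(root, "scanSettings"):
        for cv in _cv_params(settings):
            if cv.get("accession") == _ACC_POS:
                return Polarity.POSITIVE
            if cv.get("accession") == _ACC_NEG:
                return Polarity.NEGATIVE
    return None


def _isolation_mz(chrom: ET.Element, which: str) -> Optional[float]:
    for node in _iter_named(chrom, which):
        for iso in _iter_named(node, "isolationWindow"):
            for cv in _cv_params(iso):
                if cv.get("accession") == _ACC_ISOLATION_TARGET:
                    return float(cv.get("value"))
    return None


def _collision_energy(chrom: ET.Element) -> Optional[float]:
    for node in _iter_named(chrom, "precursor"):
        for act in _iter_named(node, "activation"):
            for cv in _cv_params(act):
                if cv.get("accession") == _ACC_CE:
                    return float(cv.get("value"))
    return None


def read_mzml(path: str | Path) -> RunData:
    """Read SRM chromatograms from an mzML file into a run.

    Each SRM chromatogram becomes one channel; TIC, pressure and other
    non-SRM chromatograms are skipped.  Missing collision energy is
    recorded as 0 V (with a warning, since downstream CE matching then
    degrades); missing polarity falls back to file-level scan settings and
    errors if still undetermined.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise DataIOError(f"invalid mzML file {path}: {exc}") from exc
    root = tree.getroot()
    fallback_polarity = _file_level_polarity(root)

    channels: List[MrmChannel] = []
    for chrom in _iter_named(root, "chromatogram"):
        accs = {cv.get("accession") for cv in _cv_params(chrom)}
        if _ACC_SRM not in accs:
            continue
        q1 = _isolation_mz(chrom, "precursor")
        q3 = _isolation_mz(chrom, "product")
        if q1 is None or q3 is None:
            raise DataIOError(
                f"SRM chromatogram {chrom.get('id')!r} lacks isolation m/z values"
            )
        polarity = _chromatogram_polarity(chrom) or fallback_polarity
        if polarity is None:
            raise DataIOError(
                f"cannot determine polarity for chromatogram {chrom.get('id')!r}"
            )
        ce = _collision_energy(chrom)
        if ce is None:
            warnings.warn(
                f"chromatogram {chrom.get('id')!r} has no collision energy; "
                "recording 0 V (CE matching will degrade)",
                stacklevel=2,
            )
            ce = 0.0
        times = intensities = None
        for bda in _iter_named(chrom, "binaryDataArray"):
            kind, values, unit = _decode_binary_array(bda)
            if kind == "time":
                times = values / 60.0 if unit == "second" else values
            elif kind == "intensity":
                intensities = values
        if times is None or intensities is None:
            raise DataIOError(
                f"chromatogram {chrom.get('id')!r} lacks time or intensity array"
            )
        transition = MrmTransition(q1=q1, q3=q3, polarity=polarity, ce=ce)
        channels.append(MrmChannel(transition, Chromatogram(times, intensities)))

    if not channels:
        raise DataIOError(f"no SRM chromatograms found in {path}")
    return RunData(run_id=path.stem, channels=channels)


# ---------------------------------------------------------------------------
# Tabular interchange format (long TSV)
# ---------------------------------------------------------------------------

_DATASET_COLUMNS = ["run_id", "polarity", "q1", "q3", "ce", "time_min", "intensity"]


def write_dataset_table(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as the long-format interchange TSV."""
    rows = []
    for run in dataset.runs:
        for ch in run.channels:
            t = ch.transition
            for tm, inten in zip(ch.chromatogram.times, ch.chromatogram.intensities):
                rows.append((run.run_id, t.polarity.value, t.q1, t.q3, t.ce, tm, inten))
    df = pd.DataFrame(rows, columns=_DATASET_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_dataset_table(path: str | Path) -> Dataset:
    """Read the interchange TSV written by :func:`write_dataset_table`."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise DataIOError(f"dataset table missing column(s): {missing}")
    if df.empty:
        raise DataIOError("dataset table has no rows")
    runs: List[RunData] = []
    for run_id, run_df in df.groupby("run_id", sort=False):
        channels = []
        for (pol, q1, q3, ce), ch_df in run_df.groupby(
            ["polarity", "q1", "q3", "ce"], sort=False
        ):
            transition = MrmTransition(
                q1=float(q1), q3=float(q3), polarity=Polarity.parse(pol), ce=float(ce)
            )
            times = ch_df["time_min"].to_numpy(dtype=float)
            if times.size > 1 and np.any(np.diff(times) <= 0):
                raise DataIOError(
                    f"non-monotone times for channel {transition.render()} "
                    f"in run {run_id!r}"
                )
            channels.append(
                MrmChannel(
                    transition,
                    Chromatogram(times, ch_df["intensity"].to_numpy(dtype=float)),
                )
            )
        runs.append(RunData(run_id=str(run_id), channels=channels))
    return Dataset(runs=runs)


# ---------------------------------------------------------------------------
# Compound library
# ---------------------------------------------------------------------------

_LIBRARY_MANDATORY = ["Name", "Q1", "Q3", "Polarity"]


def read_compound_library(path: str | Path) -> List[CompoundEntry]:
    """Read a tab-delimited compound library.

    Mandatory columns: Name, Q1, Q3, Polarity.  Optional: CE, Formula,
    MS2Formula, MS2FormulaType, Tags.  Rows with a Formula but without
    MS2Formula/MS2FormulaType are kept but flagged deisotoping-ineligible.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _LIBRARY_MANDATORY if c not in df.columns]
    if missing:
        raise DataIOError(f"compound library missing column(s): {missing}")
    entries: List[CompoundEntry] = []
    for idx, row in df.iterrows():
        try:
            q1 = float(row["Q1"])
            q3 = float(row["Q3"])
        except ValueError as exc:
            raise DataIOError(f"library row {idx}: unparseable Q1/Q3") from exc
        ce_text = str(row.get("CE", "")).strip()
        try:
            ce = float(ce_text) if ce_text else None
        except ValueError as exc:
            raise DataIOError(f"library row {idx}: unparseable CE {ce_text!r}") from exc
        formula_text = str(row.get("Formula", "")).strip()
        ms2_text = str(row.get("MS2Formula", "")).strip()
        type_text = str(row.get("MS2FormulaType", "")).strip()
        ms2_type = None
        if type_text:
            try:
                ms2_type = Ms2Mode(type_text)
            except ValueError as exc:
                raise DataIOError(
                    f"library row {idx}: unknown MS2FormulaType {type_text!r}"
                ) from exc
        tags_text = str(row.get("Tags", "")).strip()
        tags = tuple(t for t in tags_text.split(",") if t) if tags_text else ()
        entries.append(
            CompoundEntry(
                name=str(row["Name"]).strip(),
                q1=q1,
                q3=q3,
                polarity=Polarity.parse(row["Polarity"]),
                ce=ce,
                formula=parse_formula(formula_text) if formula_text else None,
                ms2_formula=parse_formula(ms2_text) if ms2_text else None,
                ms2_formula_type=ms2_type,
                tags=tags,
            )
        )
    return entries


def write_compound_library(entries: Sequence[CompoundEntry], path: str | Path) -> None:
    rows = []
    for e in entries:
        rows.append(
            {
                "Name": e.name,
                "Q1": f"{e.q1:g}",
                "Q3": f"{e.q3:g}",
                "CE": "" if e.ce is None else f"{e.ce:g}",
                "Polarity": e.polarity.value,
                "Formula": str(e.formula) if e.formula else "",
                "MS2Formula": str(e.ms2_formula) if e.ms2_formula else "",
                "MS2FormulaType": e.ms2_formula_type.value if e.ms2_formula_type else "",
                "Tags": ",".join(e.tags),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Integration targets (.tdf dialect)
# ---------------------------------------------------------------------------

_TARGET_COLUMNS = ["name", "polarity", "q1", "q3", "ce", "rt_start_min", "rt_end_min"]


def write_targets(targets: Sequence[IntegrationTarget], path: str | Path) -> None:
    rows = [
        (
            t.name,
            t.transition.polarity.value,
            t.transition.q1,
            t.transition.q3,
            t.transition.ce,
            t.rt_start,
            t.rt_end,
        )
        for t in targets
    ]
    pd.DataFrame(rows, columns=_TARGET_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.9g"
    )


def read_targets(path: str | Path) -> List[IntegrationTarget]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TARGET_COLUMNS if c not in df.columns]
    if missing:
        raise DataIOError(f"target file missing column(s): {missing}")
    targets = []
    for _, row in df.iterrows():
        transition = MrmTransition(
            q1=float(row["q1"]),
            q3=float(row["q3"]),
            polarity=Polarity.parse(row["polarity"]),
            ce=float(row["ce"]),
        )
        targets.append(
            IntegrationTarget(
                name=str(row["name"]),
                transition=transition,
                rt_start=float(row["rt_start_min"]),
                rt_end=float(row["rt_end_min"]),
            )
        )
    return targets
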