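"""Chemical formulae and aggregated (nominal-mass) isotopologue distributions.

Distributions are aggregated by nucleon offset: ``M_n`` collects every
isotopologue that is *n* nucleons heavier than the monoisotopic species.
This matches unit-resolution triple-quadrupole data, where fine structure
within one nominal mass is never resolved.

The embedded isotope table uses IUPAC/CIAAW representative natural
abundances (2013 values) for C, H, N, O, P and S.  Isotope-labelled
notation (e.g. ``D`` for deuterium) is deliberately rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Mapping, Tuple

import numpy as np

__all__ = [
    "ChemFormula",
    "IsotopePattern",
    "TransitionPattern",
    "Ms2Mode",
    "ISOTOPE_TABLE",
    "MONOISOTOPIC_MASS",
    "parse_formula",
    "formula_to_string",
    "formula_add",
    "formula_subtract",
    "monoisotopic_mass",
    "isotope_pattern",
    "transition_pattern",
]

DEFAULT_MAX_ORDER = 10

#: Per element: tuple of (nucleon offset above lightest isotope, abundance).
#: Abundances sum to 1 within 1e-9 per element; offset 0 dominates for all
#: elements supported here.
ISOTOPE_TABLE: Mapping[str, Tuple[Tuple[int, float], ...]] = {
    "C": ((0, 0.9893), (1, 0.0107)),
    "H": ((0, 0.999885), (1, 0.000115)),
    "N": ((0, 0.99636), (1, 0.00364)),
    "O": ((0, 0.99757), (1, 0.00038), (2, 0.00205)),
    "P": ((0, 1.0),),
    "S": ((0, 0.9499), (1, 0.0075), (2, 0.0425), (4, 0.0001)),
}

#: Lightest-isotope masses in Da (CODATA/AME2020 values, truncated).
MONOISOTOPIC_MASS: Mapping[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
}


class FormulaError(ValueError):
    """Raised for malformed or chemically impossible formulae."""


class Ms2Mode(str, Enum):
    """Interpretation of the MS2 formula of a transition.

    ``CONSTANT_PRODUCT``: the MS2 formula is the product ion B; the neutral
    fragment is precursor minus B.  ``CONSTANT_NEUTRAL_LOSS``: the MS2
    formula is the neutral loss; the product ion is precursor minus loss.
    """

    CONSTANT_PRODUCT = "ConstantProduct"
    CONSTANT_NEUTRAL_LOSS = "ConstantNeutralLoss"


_TOKEN_RE = re.compile(r"([A-Z][a-z]?)([0-9]*)")


@dataclass(frozen=True)
class ChemFormula:
    """Element -> atom count mapping for an ion or fragment.

    Counts are nonnegative; zero-count elements are dropped on
    construction, so the empty formula is represented by an empty mapping.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: Dict[str, int] = {}
        for elem, n in self.counts.items():
            if elem not in ISOTOPE_TABLE:
                raise FormulaError(f"unsupported element: {elem!r}")
            if not isinstance(n, (int, np.integer)) or n < 0:
                raise FormulaError(f"invalid count for {elem}: {n!r}")
            if n > 0:
                clean[elem] = int(n)
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, elem: str) -> int:
        return self.counts.get(elem, 0)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __add__(self, other: "ChemFormula") -> "ChemFormula":
        return formula_add(self, other)

    def __sub__(self, other: "ChemFormula") -> "ChemFormula":
        return formula_subtract(self, other)

    def __str__(self) -> str:
        return formula_to_string(self)

    def __hash__(self) -> int:
        return hash(frozenset(self.counts.items()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ChemFormula):
            return NotImplemented
        return dict(self.counts) == dict(other.counts)

    @property
    def n_atoms(self) -> int:
        return sum(self.counts.values())


def parse_formula(text: str) -> ChemFormula:
    """Parse a plain-text molecular formula such as ``"C42H81O8NP"``.

    Each token is an element symbol (capital letter plus optional lowercase
    letter) followed by an optional count (default 1).  Counts must be
    positive with no leading zeros.  Element order is irrelevant; repeated
    symbols accumulate.
    """
    if not isinstance(text, str):
        raise FormulaError(f"formula must be a string, got {type(text).__name__}")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        elem, digits = m.group(1), m.group(2)
        if elem not in ISOTOPE_TABLE:
            raise FormulaError(f"unknown element {elem!r} in {text!r}")
        if digits == "":
            n = 1
        else:
            if digits[0] == "0":
                raise FormulaError(f"zero-prefixed count in {text!r}")
            n = int(digits)
        counts[elem] = counts.get(elem, 0) + n
        pos = m.end()
    return ChemFormula(counts)


_HILL_TAIL = ("N", "O", "P", "S")


def formula_to_string(f: ChemFormula) -> str:
    """Canonical Hill-order writer: C, H, then remaining alphabetically."""
    parts = []
    for elem in ("C", "H") + tuple(sorted(set(f.counts) - {"C", "H"})):
        n = f[elem]
        if n == 0:
            continue
        parts.append(elem if n == 1 else f"{elem}{n}")
    return "".join(parts)


def formula_add(a: ChemFormula, b: ChemFormula) -> ChemFormula:
    out = dict(a.counts)
    for elem, n in b.counts.items():
        out[elem] = out.get(elem, 0) + n
    return ChemFormula(out)


def formula_subtract(a: ChemFormula, b: ChemFormula) -> ChemFormula:
    """Elementwise difference ``a - b``.

    Raises :class:`FormulaError` if any count would go negative, which
    signals an inconsistent library row (the fragment is not a sub-formula
    of the precursor).
    """
    out = dict(a.counts)
    for elem, n in b.counts.items():
        rem = out.get(elem, 0) - n
        if rem < 0:
            raise FormulaError(
                f"cannot subtract {formula_to_string(b)} from "
                f"{formula_to_string(a)}: negative {elem} count"
            )
        out[elem] = rem
    return ChemFormula(out)


def monoisotopic_mass(f: ChemFormula) -> float:
    """Sum of lightest-isotope masses in Da (electron mass ignored)."""
    return float(sum(MONOISOTOPIC_MASS[e] * n for e, n in f.counts.items()))


@dataclass(frozen=True)
class IsotopePattern:
    """Aggregated isotopologue distribution truncated at ``max_order``.

    ``p[n]`` is the absolute abundance of the aggregate M_n isotopologue;
    ``r[n] = p[n] / p[0]`` is the ratio to the monoisotopic species.  Tail
    mass beyond ``max_order`` is discarded, never renormalised, so lower
    orders are unaffected by the truncation point.
    """

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("pattern must be a nonempty 1-D array")
        if p[0] <= 0:
            raise ValueError("monoisotopic abundance must be positive")
        if np.any(p < 0):
            raise ValueError("abundances must be nonnegative")
        object.__setattr__(self, "p", p)

    @property
    def r(self) -> np.ndarray:
        return self.p / self.p[0]

    @property
    def max_order(self) -> int:
        return self.p.size - 1

    def __len__(self) -> int:
        return self.p.size


def _element_vector(elem: str, max_order: int) -> np.ndarray:
    v = np.zeros(max_order + 1)
    for offset, abundance in ISOTOPE_TABLE[elem]:
        if offset <= max_order:
            v[offset] = abundance
    return v


def _conv_trunc(a: np.ndarray, b: np.ndarray, max_order: int) -> np.ndarray:
    """Discrete convolution truncated at ``max_order``.

    Each output order sums exactly the terms up to that order, so p[n] for
    n below a truncation point is bit-identical whatever ``max_order`` is —
    unlike length-dependent summation in ``np.convolve``.
    """
    pad_a = np.zeros(max_order + 1)
    pad_a[: min(a.size, max_order + 1)] = a[: max_order + 1]
    pad_b = np.zeros(max_order + 1)
    pad_b[: min(b.size, max_order + 1)] = b[: max_order + 1]
    out = np.zeros(max_order + 1)
    for n in range(max_order + 1):
        out[n] = np.dot(pad_a[: n + 1], pad_b[n::-1])
    return out


def _truncated_power(base: np.ndarray, n: int, max_order: int) -> np.ndarray:
    """``base`` self-convolved ``n`` times, truncated at ``max_order``.

    Exponentiation by squaring; each convolution is clipped so cost stays
    O(log n * max_order^2) regardless of atom count.
    """
    acc = np.zeros(max_order + 1)
    acc[0] = 1.0
    sq = base[: max_order + 1].copy()
    while n:
        if n & 1:
            acc = _conv_trunc(acc, sq, max_order)
        n >>= 1
        if n:
            sq = _conv_trunc(sq, sq, max_order)
    return acc


def isotope_pattern(f: ChemFormula, max_order: int = DEFAULT_MAX_ORDER) -> IsotopePattern:
    """Aggregated isotopologue distribution of a formula.

    Computed by per-element polynomial self-convolution followed by
    cross-element convolution, all truncated at ``max_order``.  The empty
    formula yields the trivial pattern ``p = [1]`` padded with zeros.
    """
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    p = np.zeros(max_order + 1)
    p[0] = 1.0
    for elem in sorted(f.counts):
        p = _conv_trunc(
            p, _truncated_power(_element_vector(elem, max_order), f.counts[elem], max_order),
            max_order,
        )
    return IsotopePattern(p)


@dataclass(frozen=True)
class TransitionPattern:
    """Transition-level isotopic factors ``f(i, j)``.

    ``factors[(i, j)]`` is the signal of the transition shifted by *i*
    nucleons on the precursor and *j* nucleons (j <= i) on the product,
    relative to the monoisotopic transition: the product of the
    neutral-fragment ratio at order ``i - j`` and the product-ion ratio at
    order ``j``.
    """

    factors: Mapping[Tuple[int, int], float]
    ms2_mode: Ms2Mode
    precursor: ChemFormula
    product: ChemFormula
    neutral_fragment: ChemFormula

    def factor(self, i: int, j: int) -> float:
        if j > i:
            return 0.0
        return self.factors.get((i, j), 0.0)

    @property
    def max_order(self) -> int:
        return max(i for i, _ in self.factors)


def transition_pattern(
    precursor: ChemFormula,
    ms2: ChemFormula,
    ms2_mode: Ms2Mode | str,
    max_order: int = DEFAULT_MAX_ORDER,
) -> TransitionPattern:
    """Compute ``f(i, j)`` for a transition from precursor and MS2 formulae.

    ``ms2_mode`` selects whether ``ms2`` is the product ion
    (``ConstantProduct``) or the neutral loss (``ConstantNeutralLoss``);
    the other fragment is derived by subtraction from the precursor.
    """
    mode = Ms2Mode(ms2_mode)
    if mode is Ms2Mode.CONSTANT_PRODUCT:
        product = ms2
        neutral = formula_subtract(precursor, ms2)
    else:
        neutral = ms2
        product = formula_subtract(precursor, ms2)
    r_neutral = isotope_pattern(neutral, max_order).r
    r_product = isotope_pattern(product, max_order).r
    factors = {
        (i, j): float(r_neutral[i - j] * r_product[j])
        for i in range(max_order + 1)
        for j in range(i + 1)
    }
    return TransitionPattern(
        factors=factors,
        ms2_mode=mode,
        precursor=precursor,
        product=product,
        neutral_fragment=neutral,
    )
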