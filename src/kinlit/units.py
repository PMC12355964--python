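"""Parsing and canonicalization of kinetic quantities.

Literature tables print turnover numbers and Michaelis constants in a zoo
of unit dialects (``s^-1``, ``min−1``, ``μM``, ``uM``, ``mmol/L`` ...).
This module parses a quantity string into a :class:`QuantityWithUnit`,
canonicalizes rates to s⁻¹ and concentrations to molar, and flags the two
ambiguities that dominate transcription error in this domain:

* scientific notation (the sign of the exponent is easily misread), and
* the confusable micro/milli prefix glyphs {m, μ, µ, u}, which differ by a
  factor of exactly 10³.
"""

from __future__ import annotations

import math
import re
import unicodedata
from dataclasses import dataclass
from enum import Enum


class BaseUnit(str, Enum):
    per_second = "per_second"
    per_minute = "per_minute"
    molar = "molar"
    dimensionless_ratio = "dimensionless_ratio"
    unknown = "unknown"


#: SI prefix factors recognized in concentration units.
PREFIX_FACTORS = {"": 1.0, "m": 1e-3, "μ": 1e-6, "n": 1e-9, "k": 1e3}

#: Prefix glyphs that a reader (human or OCR) can plausibly swap.
CONFUSABLE_PREFIX_GLYPHS = {"m", "μ", "µ", "u"}

_SUPERSCRIPTS = "⁰¹²³⁴⁵⁶⁷⁸⁹⁻⁺"
_SUPERSCRIPT_MAP = str.maketrans(_SUPERSCRIPTS, "0123456789-+")


class UnitParseError(ValueError):
    """Raised when a quantity string carries no numeric token, or when a
    canonical value is requested for an unrecognized unit."""


def normalize_text(text: str) -> str:
    """Typographic normalization shared by the parser and the document
    search: micro sign -> Greek mu, unicode minus/multiplication signs ->
    ASCII, superscript runs -> ``^`` + ASCII digits (``s⁻¹`` -> ``s^-1``,
    ``10³`` -> ``10^3``)."""
    text = text.replace("µ", "μ")  # micro sign -> greek small mu
    text = text.replace("−", "-").replace("–", "-")
    text = text.replace("×", "x").replace("⋅", "x").replace("·", "x")
    text = re.sub(
        f"[{_SUPERSCRIPTS}]+", lambda m: "^" + m.group().translate(_SUPERSCRIPT_MAP), text
    )
    return text


def strip_thousands_separators(text: str) -> str:
    """Remove digit-grouping commas: ``1,204`` -> ``1204``."""
    return re.sub(r"(?<=\d),(?=\d{3}\b)", "", text)


# mantissa x 10^k, with optional caret after normalization
_SCI_RE = re.compile(
    r"(?P<mant>[+-]?\d+(?:\.\d+)?)\s*x\s*10\s*\^?\s*(?P<exp>[+-]?\d+)"
)
_ENOT_RE = re.compile(r"(?P<mant>[+-]?\d+(?:\.\d+)?)[eE](?P<exp>[+-]?\d+)")
_PLAIN_RE = re.compile(r"[+-]?\d+(?:\.\d+)?")

_RATE_SECOND_RE = re.compile(r"^(?:1\s*/\s*|/)?\s*(?:s|sec|second)(?:\s*\^\s*-\s*1|-1)?$")
_RATE_MINUTE_RE = re.compile(r"^(?:1\s*/\s*|/)?\s*(?:min|minute)(?:\s*\^\s*-\s*1|-1)?$")
_CONC_RE = re.compile(r"^(?P<prefix>[mμnk]?)(?:M|mol\s*/\s*L|mol\s*L\s*\^\s*-\s*1)$")


@dataclass
class QuantityWithUnit:
    """A numeric quantity as printed, plus its canonical SI value.

    ``canonical_value`` is in s⁻¹ for rate kinds and molar for
    concentration kinds; it equals ``value * prefix_factor *
    base_conversion`` with base_conversion exactly 1/60 for per-minute
    rates.  ``value_text`` and ``unit_text`` preserve the printed tokens
    for audit and for hallucination checks against the source document.
    """

    value: float
    prefix: str  # "", "m", "μ", "n", "k"
    base_unit: BaseUnit
    canonical_value: float
    raw_text: str
    sci_notation: bool = False
    glyph_ambiguous: bool = False
    value_text: str = ""
    unit_text: str = ""

    def __post_init__(self) -> None:
        if self.prefix not in PREFIX_FACTORS:
            raise ValueError(f"unrecognized prefix {self.prefix!r}")


def _base_conversion(base_unit: BaseUnit) -> float:
    return 1.0 / 60.0 if base_unit is BaseUnit.per_minute else 1.0


def _parse_unit(unit_text: str, kind: str) -> tuple[str, BaseUnit, bool]:
    """Return (prefix, base_unit, glyph_ambiguous) for a normalized unit
    token.  Unrecognized dialects (specific activity, per-mg, ...) map to
    ``unknown``."""
    u = unit_text.strip().strip("()[]").strip()
    if not u:
        return "", BaseUnit.unknown, False
    # ASCII "u" standing in for the micro prefix: uM, umol/L
    u = re.sub(r"^u(?=M$|mol)", "μ", u)
    if u == "%":
        return "", BaseUnit.dimensionless_ratio, False
    if _RATE_SECOND_RE.match(u):
        return "", BaseUnit.per_second, False
    if _RATE_MINUTE_RE.match(u):
        return "", BaseUnit.per_minute, False
    m = _CONC_RE.match(u)
    if m:
        prefix = m.group("prefix")
        return prefix, BaseUnit.molar, prefix in CONFUSABLE_PREFIX_GLYPHS
    return "", BaseUnit.unknown, False


def parse_quantity(text: str, kind: str = "rate") -> QuantityWithUnit:
    """Parse a printed quantity string such as ``"2.5 × 10^3 s−1"``.

    Parameters
    ----------
    text:
        The cell or phrase as printed.  Thousands commas are stripped;
        micro-sign/Greek-mu variants and superscript exponents are
        normalized before matching.
    kind:
        ``"rate"`` or ``"concentration"``; selects the canonical unit
        (s⁻¹ vs molar) and is recorded for error messages only.

    Raises
    ------
    UnitParseError
        If no numeric token exists in ``text``.
    """
    if kind not in ("rate", "concentration"):
        raise ValueError(f"kind must be 'rate' or 'concentration', got {kind!r}")
    if not text or not text.strip():
        raise UnitParseError("empty quantity string")
    norm = strip_thousands_separators(normalize_text(text))

    sci = False
    m = _SCI_RE.search(norm)
    if m:
        value = float(m.group("mant")) * 10.0 ** int(m.group("exp"))
        sci = True
    else:
        m = _ENOT_RE.search(norm)
        if m:
            value = float(m.group())  # a valid float literal; parse exactly
            sci = True
        else:
            m = _PLAIN_RE.search(norm)
            if m is None:
                raise UnitParseError(f"no numeric token in {text!r}")
            value = float(m.group())
    value_text = norm[m.start() : m.end()].strip()
    # the caret in "10^3" may also appear as "10 ^ 3"; detect explicit
    # mantissa-exponent forms typed with a caret even without the sign
    unit_text = (norm[: m.start()] + " " + norm[m.end() :]).strip()

    prefix, base_unit, ambiguous = _parse_unit(unit_text, kind)
    canonical = value * PREFIX_FACTORS[prefix] * _base_conversion(base_unit)
    return QuantityWithUnit(
        value=value,
        prefix=prefix,
        base_unit=base_unit,
        canonical_value=canonical,
        raw_text=text,
        sci_notation=sci,
        glyph_ambiguous=ambiguous,
        value_text=value_text,
        unit_text=unit_text,
    )


def canonicalize(q: QuantityWithUnit, kind: str = "rate") -> float:
    """Canonical value in s⁻¹ (rate) or M (concentration).

    Raises :class:`UnitParseError` naming the raw text when the base unit
    is unknown or inconsistent with ``kind``.
    """
    if q.base_unit is BaseUnit.unknown:
        raise UnitParseError(f"cannot canonicalize unknown unit in {q.raw_text!r}")
    if kind == "rate" and q.base_unit not in (BaseUnit.per_second, BaseUnit.per_minute):
        raise UnitParseError(f"{q.raw_text!r} is not a rate unit")
    if kind == "concentration" and q.base_unit is not BaseUnit.molar:
        raise UnitParseError(f"{q.raw_text!r} is not a concentration unit")
    return q.canonical_value


def log10_value(canonical: float) -> float:
    """Base-10 log of a canonical value; non-positive input is a domain
    error (kinetic constants are strictly positive)."""
    if canonical <= 0:
        raise ValueError(f"log10 requires a positive value, got {canonical}")
    return math.log10(canonical)


_UNIT_STR = {
    BaseUnit.per_second: "s^-1",
    BaseUnit.per_minute: "min^-1",
    BaseUnit.molar: "M",
    BaseUnit.dimensionless_ratio: "%",
}


def format_quantity(q: QuantityWithUnit) -> str:
    """Render a quantity back to a parseable string; ``parse_quantity``
    of the result reproduces ``canonical_value`` to relative 1e-12."""
    if q.base_unit is BaseUnit.unknown:
        return q.raw_text
    unit = _UNIT_STR[q.base_unit]
    if q.base_unit is BaseUnit.molar and q.prefix:
        unit = q.prefix + unit
    return f"{q.value!r} {unit}"
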