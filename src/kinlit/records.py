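"""Shared domain records for the kinetics-mining pipeline.

A :class:`KineticMeasurement` is one enzyme–substrate–kinetics row as it
flows through extraction, curation, resolution and benchmarking.  The
matching identity of a measurement is its :class:`EntryKey`: the
(enzyme, mutation, substrate, organism) tuple after deterministic text
normalization, which is what cross-dataset record linkage compares.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .units import QuantityWithUnit, parse_quantity

SOURCE_FORMATS = ("pdf_text", "xml", "markdown_fixture")
CONFIDENCE_TIERS = ("high", "medium", "low", "unmapped")

#: Exact field order of the flat JSON-lines serialization.
JSONL_FIELDS = (
    "enzyme_name", "organism", "mutation", "substrate_name", "substrate_smiles",
    "kcat_value", "kcat_unit", "km_value", "km_unit", "ph", "temperature_C",
    "uniprot", "ncbi", "pdb", "ec", "sequence", "confidence", "flags",
    "doc_id", "source_format", "table_id", "row_index",
)

_FLAG_NAMES = ("hallucinated", "repetitive", "scientific_notation", "duplicate", "empty_row")

# leading/trailing characters stripped by key normalization; Greek letters
# and internal punctuation are preserved
_EDGE_PUNCT = "".join(
    c for c in map(chr, range(0x21, 0x7F)) if not c.isalnum()
) + "“”‘’«»…"

_MUTATION_RE = re.compile(r"^\s*([A-Za-z])\s*(\d+)\s*([A-Za-z])\s*$")


def normalize_name(s: str) -> str:
    """Key normalization: Unicode NFKC, lower-case, collapse internal
    whitespace, strip leading/trailing punctuation.  Idempotent."""
    s = unicodedata.normalize("NFKC", s)
    s = s.lower()
    s = " ".join(s.split())
    return s.strip(_EDGE_PUNCT + " ")


def normalize_mutation(s: str) -> str:
    """Canonicalize single-letter site variants: ``"a 123 g"`` ->
    ``"A123G"``.  Strings not matching the one-letter grammar pass
    through with only outer whitespace stripped."""
    m = _MUTATION_RE.match(s)
    if m:
        return f"{m.group(1).upper()}{m.group(2)}{m.group(3).upper()}"
    return s.strip()


@dataclass(frozen=True)
class EntryKey:
    """Normalized matching key of one kinetic measurement."""

    enzyme_name_norm: str
    mutation_norm: str
    substrate_norm: str
    organism_norm: str

    @classmethod
    def from_fields(cls, enzyme: str, mutation: str, substrate: str, organism: str) -> "EntryKey":
        return cls(
            enzyme_name_norm=normalize_name(enzyme),
            mutation_norm=normalize_mutation(mutation),
            substrate_norm=normalize_name(substrate),
            organism_norm=normalize_name(organism),
        )


@dataclass
class Provenance:
    doc_id: str
    source_format: str = "markdown_fixture"
    table_id: str = ""
    row_index: int = 0


class QualityFlags:
    """Per-row curation flags.  Monotone: curation may set a flag but
    never clear it (attempting to clear raises)."""

    __slots__ = _FLAG_NAMES

    def __init__(self, **kw: bool) -> None:
        for name in _FLAG_NAMES:
            object.__setattr__(self, name, bool(kw.pop(name, False)))
        if kw:
            raise TypeError(f"unknown flags: {sorted(kw)}")

    def __setattr__(self, name: str, value: bool) -> None:
        if getattr(self, name) and not value:
            raise ValueError(f"quality flags are monotone; cannot clear {name!r}")
        object.__setattr__(self, name, bool(value))

    def set_names(self) -> list[str]:
        return [n for n in _FLAG_NAMES if getattr(self, n)]

    @property
    def any_exclusion(self) -> bool:
        return self.hallucinated or self.repetitive or self.scientific_notation

    def __eq__(self, other: object) -> bool:
        return isinstance(other, QualityFlags) and self.set_names() == other.set_names()

    def __repr__(self) -> str:
        return f"QualityFlags({', '.join(self.set_names()) or 'none'})"

    def copy(self) -> "QualityFlags":
        return QualityFlags(**{n: getattr(self, n) for n in _FLAG_NAMES})


@dataclass
class KineticMeasurement:
    """One enzyme–substrate–kinetics record with conditions, identifiers,
    curation flags and provenance."""

    enzyme_name: str = ""
    organism: str = ""
    mutation: str = ""
    substrate_name: str = ""
    substrate_smiles: str = ""
    kcat: Optional[QuantityWithUnit] = None
    km: Optional[QuantityWithUnit] = None
    ph: Optional[float] = None
    temperature_C: Optional[float] = None
    identifiers: dict = field(default_factory=dict)  # keys among uniprot/ncbi/pdb/ec
    sequence: str = ""
    confidence: Optional[str] = None
    flags: QualityFlags = field(default_factory=QualityFlags)
    provenance: Provenance = field(default_factory=lambda: Provenance(doc_id="unknown"))

    def entry_key(self) -> EntryKey:
        return EntryKey.from_fields(
            self.enzyme_name, self.mutation, self.substrate_name, self.organism
        )

    @property
    def is_empty_row(self) -> bool:
        """True when the row carries none of enzyme name, substrate name,
        kcat or Km — the paper-style 'entirely empty row'."""
        return not (
            self.enzyme_name.strip() or self.substrate_name.strip()
            or self.kcat is not None or self.km is not None
        )

    # -- flat JSON-lines serialization ------------------------------------
    def to_json_dict(self) -> dict:
        d: dict = {
            "enzyme_name": self.enzyme_name,
            "organism": self.organism,
            "mutation": self.mutation,
            "substrate_name": self.substrate_name,
            "substrate_smiles": self.substrate_smiles,
            "kcat_value": self.kcat.value if self.kcat else None,
            "kcat_unit": self.kcat.unit_text if self.kcat else None,
            "km_value": self.km.value if self.km else None,
            "km_unit": self.km.unit_text if self.km else None,
            "ph": self.ph,
            "temperature_C": self.temperature_C,
            "uniprot": self.identifiers.get("uniprot", ""),
            "ncbi": self.identifiers.get("ncbi", ""),
            "pdb": self.identifiers.get("pdb", ""),
            "ec": self.identifiers.get("ec", ""),
            "sequence": self.sequence,
            "confidence": self.confidence,
            "flags": self.flags.set_names(),
            "doc_id": self.provenance.doc_id,
            "source_format": self.provenance.source_format,
            "table_id": self.provenance.table_id,
            "row_index": self.provenance.row_index,
        }
        return d

    @classmethod
    def from_json_dict(cls, d: dict) -> "KineticMeasurement":
        def _q(vkey: str, ukey: str, kind: str) -> Optional[QuantityWithUnit]:
            v = d.get(vkey)
            if v is None or v == "":
                return None
            unit = d.get(ukey) or ""
            return parse_quantity(f"{v} {unit}".strip(), kind)

        identifiers = {
            k: d[k] for k in ("uniprot", "ncbi", "pdb", "ec") if d.get(k)
        }
        flags = d.get("flags") or []
        if isinstance(flags, str):
            flags = [f for f in flags.split("|") if f]
        return cls(
            enzyme_name=d.get("enzyme_name") or "",
            organism=d.get("organism") or "",
            mutation=d.get("mutation") or "",
            substrate_name=d.get("substrate_name") or "",
            substrate_smiles=d.get("substrate_smiles") or "",
            kcat=_q("kcat_value", "kcat_unit", "rate"),
            km=_q("km_value", "km_unit", "concentration"),
            ph=None if d.get("ph") is None else float(d["ph"]),
            temperature_C=None if d.get("temperature_C") is None else float(d["temperature_C"]),
            identifiers=identifiers,
            sequence=d.get("sequence") or "",
            confidence=d.get("confidence") or None,
            flags=QualityFlags(**{n: True for n in flags}),
            provenance=Provenance(
                doc_id=d.get("doc_id") or "",
                source_format=d.get("source_format") or "markdown_fixture",
                table_id=d.get("table_id") or "",
                row_index=int(d.get("row_index") or 0),
            ),
        )


@dataclass(frozen=True)
class Violation:
    """One validation finding: the field, the violated rule, and whether
    it rejects the record (error) or only warns."""

    field: str
    rule: str
    severity: str  # "error" | "warning"
    message: str


#: Span of assay temperatures observed in the mined corpus; values outside
#: it are suspicious but not invalid, hence a warning.
OBSERVED_TEMPERATURE_SPAN = (0.0, 100.0)
TEMPERATURE_HARD_BOUNDS = (-20.0, 150.0)


def validate_measurement(m: KineticMeasurement) -> list[Violation]:
    """Check every type invariant; returns an empty list iff the record is
    valid.  Pure — never mutates or raises."""
    out: list[Violation] = []
    if m.is_empty_row:
        out.append(Violation(
            "record", "empty_row", "error",
            "record carries no enzyme name, substrate name, kcat or Km",
        ))
    for name, q in (("kcat", m.kcat), ("km", m.km)):
        if q is not None and q.canonical_value is not None and q.canonical_value <= 0:
            out.append(Violation(
                name, "positive_canonical_value", "error",
                f"canonical {name} must be strictly positive, got {q.canonical_value}",
            ))
    if m.ph is not None and not (0.0 <= m.ph <= 14.0):
        out.append(Violation("ph", "ph_range", "error", f"pH {m.ph} outside [0, 14]"))
    if m.temperature_C is not None:
        lo, hi = TEMPERATURE_HARD_BOUNDS
        if not (lo <= m.temperature_C <= hi):
            out.append(Violation(
                "temperature_C", "temperature_hard_bounds", "error",
                f"temperature {m.temperature_C} degC outside [{lo}, {hi}]",
            ))
        else:
            olo, ohi = OBSERVED_TEMPERATURE_SPAN
            if not (olo <= m.temperature_C <= ohi):
                out.append(Violation(
                    "temperature_C", "temperature_observed_span", "warning",
                    f"temperature {m.temperature_C} degC outside the observed "
                    f"assay span {olo}-{ohi} degC",
                ))
    if not m.provenance.doc_id:
        out.append(Violation("doc_id", "doc_id_nonempty", "error", "doc_id must be non-empty"))
    if m.provenance.row_index < 0:
        out.append(Violation("row_index", "row_index_nonneg", "error", "row_index must be >= 0"))
    if m.confidence is not None and m.confidence not in CONFIDENCE_TIERS:
        out.append(Violation("confidence", "confidence_enum", "error",
                             f"unknown confidence tier {m.confidence!r}"))
    return out


# -- JSON Lines I/O --------------------------------------------------------

def write_jsonl(measurements: Iterable[KineticMeasurement], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for m in measurements:
            fh.write(json.dumps(m.to_json_dict(), ensure_ascii=False) + "\n")


def read_jsonl(path: str | Path) -> list[KineticMeasurement]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(KineticMeasurement.from_json_dict(json.loads(line)))
    return out
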