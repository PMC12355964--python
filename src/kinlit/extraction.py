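"""Extraction-backend contract and the deterministic reference extractor.

In production pipelines this stage is played by a language model that
turns parsed documents into structured JSON records.  Here the contract
(:class:`ExtractorBackend`) is pluggable, and the shipped reference
backend extracts :class:`RawExtraction` rows from Markdown tables by
header-synonym lookup — a pure function of (document, lexicon), so every
downstream stage is testable offline.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Protocol

from .corpus import DocumentRecord, MarkdownTable
from .records import KineticMeasurement, Provenance, QualityFlags
from .units import parse_quantity, UnitParseError


@dataclass
class RawExtraction:
    """JSON-serializable precursor of a KineticMeasurement; kinetic values
    and units are raw strings, not yet canonicalized."""

    doc_id: str
    source_format: str = "markdown_fixture"
    table_id: str = ""
    row_index: int = 0
    enzyme_name: str = ""
    organism: str = ""
    mutation: str = ""
    substrate_name: str = ""
    substrate_smiles: str = ""
    kcat_value: str = ""
    kcat_unit: str = ""
    km_value: str = ""
    km_unit: str = ""
    ph: str = ""
    temperature_C: str = ""
    uniprot: str = ""
    ncbi: str = ""
    pdb: str = ""
    ec: str = ""
    backend_name: str = "reference"

    def to_json_dict(self) -> dict:
        return asdict(self)

    def to_measurement(self) -> KineticMeasurement:
        """Parse units and lift to the shared record type."""
        def _q(value: str, unit: str, kind: str):
            if not value.strip():
                return None
            return parse_quantity(f"{value} {unit}".strip(), kind)

        def _f(s: str) -> Optional[float]:
            s = s.strip()
            if not s:
                return None
            m = re.search(r"[+-]?\d+(?:\.\d+)?", s)
            return float(m.group()) if m else None

        identifiers = {
            k: v for k, v in (("uniprot", self.uniprot), ("ncbi", self.ncbi),
                              ("pdb", self.pdb), ("ec", self.ec)) if v
        }
        return KineticMeasurement(
            enzyme_name=self.enzyme_name,
            organism=self.organism,
            mutation=self.mutation,
            substrate_name=self.substrate_name,
            substrate_smiles=self.substrate_smiles,
            kcat=_q(self.kcat_value, self.kcat_unit, "rate"),
            km=_q(self.km_value, self.km_unit, "concentration"),
            ph=_f(self.ph),
            temperature_C=_f(self.temperature_C),
            identifiers=identifiers,
            flags=QualityFlags(),
            provenance=Provenance(
                doc_id=self.doc_id, source_format=self.source_format,
                table_id=self.table_id, row_index=self.row_index,
            ),
        )


class ExtractorBackend(Protocol):
    """Contract for pluggable extraction backends.  A backend never
    mutates the document, and every output row carries provenance."""

    name: str

    def extract(self, doc: DocumentRecord) -> list[RawExtraction]: ...


# -- column-role lexicon ---------------------------------------------------

#: Role -> header synonyms, in priority order.  Kinetics roles come first
#: so that an ambiguous header resolves in their favor.
DEFAULT_LEXICON: dict[str, tuple[str, ...]] = {
    "kcat": ("kcat", "k_cat", "k cat", "turnover number", "turnover"),
    "km": ("km", "k_m", "k m", "michaelis constant", "michaelis-menten constant"),
    "ph": ("ph",),
    "temperature": ("temperature", "temp", "t", "assay temperature"),
    "mutation": ("mutation", "mutant", "variant", "site variant"),
    "substrate": ("substrate", "substrate name", "compound"),
    "enzyme": ("enzyme", "enzyme name", "protein"),
    "organism": ("organism", "species", "source organism"),
    "uniprot": ("uniprot", "uniprot id", "uniprot accession"),
    "ncbi": ("ncbi", "ncbi accession", "genbank"),
    "pdb": ("pdb", "pdb id"),
    "ec": ("ec", "ec number",),
}

_HEADER_UNIT_RE = re.compile(r"^(?P<name>.*?)\s*[\(,]\s*(?P<unit>[^)]*?)\)?\s*$")


def split_header_unit(header_cell: str) -> tuple[str, str]:
    """Split a merged header/unit cell on the last parenthesis or comma
    group: ``"kcat (s−1)"`` -> ``("kcat", "s−1")``."""
    m = _HEADER_UNIT_RE.match(header_cell.strip())
    if m and m.group("unit"):
        return m.group("name").strip(), m.group("unit").strip()
    return header_cell.strip(), ""


def _norm_header(s: str) -> str:
    return " ".join(re.sub(r"[_\-./]", " ", s.lower()).split())


def resolve_column_roles(header: list[str], lexicon: dict[str, tuple[str, ...]] | None = None,
                         ) -> dict[int, tuple[str, str]]:
    """Map column index -> (role, header_unit).  Longest-synonym match,
    case-insensitive; lexicon order breaks ties (kinetics roles win)."""
    lexicon = lexicon or DEFAULT_LEXICON
    roles: dict[int, tuple[str, str]] = {}
    for idx, cell in enumerate(header):
        name, unit = split_header_unit(cell)
        name_n = _norm_header(name)
        if not name_n:
            continue
        best: tuple[int, int] | None = None  # (-synlen, lexicon position)
        best_role = None
        for pos, (role, syns) in enumerate(lexicon.items()):
            for syn in syns:
                syn_n = _norm_header(syn)
                if name_n == syn_n or re.search(rf"(?<![a-z0-9]){re.escape(syn_n)}(?![a-z0-9])", name_n):
                    cand = (-len(syn_n), pos)
                    if best is None or cand < best:
                        best, best_role = cand, role
        if best_role is not None:
            roles[idx] = (best_role, unit)
    return roles


_DOC_FIELD_RES = {
    "enzyme": re.compile(r"(?im)^enzyme\s*[:：]\s*(.+?)\s*$"),
    "organism": re.compile(r"(?im)^organism\s*[:：]\s*(.+?)\s*$"),
}

_HAS_DIGIT_RE = re.compile(r"\d")
_HAS_UNIT_HINT_RE = re.compile(r"[a-zA-Zμµ]")


def _cell_value_unit(cell: str, header_unit: str) -> tuple[str, str]:
    """Unit precedence: a unit embedded in the cell overrides the header
    unit."""
    cell = cell.strip()
    if _HAS_UNIT_HINT_RE.search(re.sub(r"[eEx×]", "", cell)):
        return cell, ""  # cell embeds its own unit ("3.1 min−1")
    return cell, header_unit


def reference_extract(doc: DocumentRecord,
                      lexicon: dict[str, tuple[str, ...]] | None = None,
                      ) -> list[RawExtraction]:
    """Deterministic table extraction: one RawExtraction per table row
    carrying at least one kinetic value.

    Document-level ``Enzyme:`` / ``Organism:`` statements are attached to
    every row when the table lacks those columns.  Tables without any
    recognizable kinetic column yield no rows (not an error).
    """
    doc_fields = {}
    for key, rx in _DOC_FIELD_RES.items():
        m = rx.search(doc.full_text)
        if m:
            doc_fields[key] = m.group(1)

    out: list[RawExtraction] = []
    for table in doc.tables:
        roles = resolve_column_roles(table.header, lexicon)
        role_cols = {role: idx for idx, (role, _unit) in roles.items()}
        if "kcat" not in role_cols and "km" not in role_cols:
            continue
        for ridx, row in enumerate(table.rows):
            rec = RawExtraction(
                doc_id=doc.doc_id, source_format=doc.source_format,
                table_id=table.table_id, row_index=ridx,
            )
            has_kinetic = False
            for idx, (role, header_unit) in roles.items():
                cell = row[idx].strip() if idx < len(row) else ""
                if not cell:
                    continue
                if role in ("kcat", "km"):
                    if not _HAS_DIGIT_RE.search(cell):
                        continue
                    value, unit = _cell_value_unit(cell, header_unit)
                    setattr(rec, f"{role}_value", value)
                    setattr(rec, f"{role}_unit", unit)
                    has_kinetic = True
                elif role == "enzyme":
                    rec.enzyme_name = cell
                elif role == "temperature":
                    rec.temperature_C = cell
                else:
                    setattr(rec, role if role != "substrate" else "substrate_name", cell)
            if not rec.enzyme_name and "enzyme" in doc_fields:
                rec.enzyme_name = doc_fields["enzyme"]
            if not rec.organism and "organism" in doc_fields:
                rec.organism = doc_fields["organism"]
            if has_kinetic:
                out.append(rec)
    return out


class ReferenceBackend:
    """The shipped deterministic backend."""

    name = "reference"

    def __init__(self, lexicon: dict[str, tuple[str, ...]] | None = None) -> None:
        self.lexicon = lexicon

    def extract(self, doc: DocumentRecord) -> list[RawExtraction]:
        return reference_extract(doc, self.lexicon)


_BACKENDS: dict[str, Callable[[], ExtractorBackend]] = {"reference": ReferenceBackend}


def register_backend(name: str, factory: Callable[[], ExtractorBackend]) -> None:
    _BACKENDS[name] = factory


def get_backend(name: str) -> ExtractorBackend:
    try:
        return _BACKENDS[name]()
    except KeyError:
        raise KeyError(f"unknown backend {name!r}; registered: {sorted(_BACKENDS)}")


# -- schema validation -----------------------------------------------------

_RAW_FIELDS = {f.name for f in RawExtraction.__dataclass_fields__.values()}  # type: ignore[attr-defined]
_STRINGY = _RAW_FIELDS - {"row_index"}


def schema_validate(record: dict) -> tuple[Optional[RawExtraction], list[str]]:
    """Validate a JSON record against the RawExtraction schema.

    Returns ``(RawExtraction, [])`` for a well-formed record, otherwise
    ``(None, violations)``.  Never raises."""
    violations: list[str] = []
    for k in record:
        if k not in _RAW_FIELDS:
            violations.append(f"unknown key {k!r}")
    if not record.get("doc_id"):
        violations.append("provenance.doc_id required")
    ridx = record.get("row_index", 0)
    if not isinstance(ridx, int) or isinstance(ridx, bool) or ridx < 0:
        violations.append("row_index must be a non-negative integer")
    for k in ("kcat_value", "km_value"):
        v = record.get(k, "")
        if v in ("", None):
            continue
        if not re.search(r"\d", str(v)):
            violations.append(f"{k} must contain a numeric token, got {v!r}")
    for k in _STRINGY:
        v = record.get(k)
        if v is not None and not isinstance(v, (str, int, float)):
            violations.append(f"{k} must be a scalar, got {type(v).__name__}")
    if violations:
        return None, violations
    clean = {k: (str(v) if k != "row_index" else int(v))
             for k, v in record.items() if v is not None}
    return RawExtraction(**clean), []
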