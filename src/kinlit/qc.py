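"""Post-extraction curation: duplicates, empty rows, hallucination,
repetition and scientific-notation flags.

The hallucination check is a grounding test: every extracted kinetic
value string must be locatable in its source document by regex token
search; documents in which fewer than a configurable fraction of values
can be found are flagged wholesale.  The repetition check flags documents
whose extracted values contain too few distinct numbers — the signature
of a degenerate generative-model output.  Scientific-notation rows are
flagged individually because the sign of a printed exponent is easy to
misread.  Flag categories may overlap; tallies are kept independently.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .corpus import DocumentRecord, find_value_in_text
from .records import KineticMeasurement

log = logging.getLogger(__name__)


@dataclass
class QCConfig:
    #: flag a document as hallucinated when the fraction of its extracted
    #: kinetic values found in the text is strictly below this
    hallucination_min_found_fraction: float = 0.5
    #: flag a document as repetitive when the fraction of distinct value
    #: strings is strictly below this
    repetition_min_unique_fraction: float = 0.3
    exclude_flagged: bool = True

    def __post_init__(self) -> None:
        for name in ("hallucination_min_found_fraction", "repetition_min_unique_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    n_input: int = 0
    n_duplicates: int = 0
    n_format_dedup: int = 0  # pdf rows dropped in favor of xml twins
    n_empty: int = 0
    n_hallucinated_rows: int = 0
    n_repetitive_rows: int = 0
    n_sci_notation_rows: int = 0
    n_excluded: int = 0
    n_kept: int = 0
    # row-level grounding ledger (per extracted kinetic value)
    n_values_total: int = 0
    n_values_not_found: int = 0
    per_doc: dict = field(default_factory=dict)  # doc_id -> {"hallucinated": bool, "repetitive": bool}

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def _value_strings(m: KineticMeasurement) -> list[str]:
    """Kinetic value tokens exactly as extracted (pre-canonicalization).

    Scientific-notation values are omitted: they are already marked
    unreliable row-wise, and keeping them out of the document-level
    grounding statistics makes curation idempotent (a second pass sees
    the same value population the first one scored)."""
    out = []
    for q in (m.kcat, m.km):
        if q is not None and q.value_text and not q.sci_notation:
            out.append(q.value_text)
    return out


def flag_hallucination(doc: DocumentRecord, extractions: list[KineticMeasurement],
                       cfg: QCConfig | None = None) -> bool:
    """Document-level hallucination flag: found_fraction < threshold
    (strict).  Zero extracted values -> not flagged, warning logged."""
    cfg = cfg or QCConfig()
    values = [v for m in extractions for v in _value_strings(m)]
    if not values:
        log.warning("doc %s: no extracted numeric values; hallucination check skipped", doc.doc_id)
        return False
    found = sum(find_value_in_text(v, doc) for v in values)
    return found / len(values) < cfg.hallucination_min_found_fraction


def flag_repetition(extractions: list[KineticMeasurement],
                    cfg: QCConfig | None = None) -> bool:
    """Document-level repetition flag: unique_fraction < threshold
    (strict).  Empty list -> not flagged."""
    cfg = cfg or QCConfig()
    values = [v for m in extractions for v in _value_strings(m)]
    if not values:
        return False
    return len(set(values)) / len(values) < cfg.repetition_min_unique_fraction


def curate(entries: Iterable[KineticMeasurement],
           docs: Mapping[str, DocumentRecord] | Iterable[DocumentRecord],
           cfg: QCConfig | None = None,
           ) -> tuple[list[KineticMeasurement], QCReport]:
    """Run the curation pipeline and return (kept entries, report).

    Order: (1) drop exact duplicates (all serialized fields equal);
    (2) for doc_ids present in both pdf_text and xml form keep the xml
    rows; (3) drop empty rows; (4) set hallucinated/repetitive flags per
    document; (5) set scientific-notation flags per row; (6) if
    configured, exclude rows carrying any of the three flags.
    Conservation: ``n_kept = n_input - n_duplicates - n_format_dedup -
    n_empty - n_excluded``.
    """
    cfg = cfg or QCConfig()
    if not isinstance(docs, Mapping):
        docs = {d.doc_id: d for d in docs}
    entries = list(entries)
    report = QCReport(n_input=len(entries))

    # (1) exact duplicates
    seen: set[str] = set()
    stage: list[KineticMeasurement] = []
    for m in entries:
        key = json.dumps(m.to_json_dict(), sort_keys=True, ensure_ascii=False)
        if key in seen:
            report.n_duplicates += 1
            m.flags.duplicate = True
        else:
            seen.add(key)
            stage.append(m)

    # (2) prefer xml over pdf_text for doubly ingested documents
    formats_by_doc: dict[str, set[str]] = {}
    for m in stage:
        formats_by_doc.setdefault(m.provenance.doc_id, set()).add(m.provenance.source_format)
    both = {d for d, f in formats_by_doc.items() if {"pdf_text", "xml"} <= f}
    kept2 = []
    for m in stage:
        if m.provenance.doc_id in both and m.provenance.source_format == "pdf_text":
            report.n_format_dedup += 1
        else:
            kept2.append(m)

    # (3) empty rows
    stage3 = []
    for m in kept2:
        if m.is_empty_row:
            m.flags.empty_row = True
            report.n_empty += 1
        else:
            stage3.append(m)

    # (4) per-document hallucination / repetition flags
    by_doc: dict[str, list[KineticMeasurement]] = {}
    for m in stage3:
        by_doc.setdefault(m.provenance.doc_id, []).append(m)
    for doc_id, group in by_doc.items():
        doc = docs.get(doc_id)
        halluc = flag_hallucination(doc, group, cfg) if doc is not None else False
        rep = flag_repetition(group, cfg)
        report.per_doc[doc_id] = {"hallucinated": halluc, "repetitive": rep}
        if doc is not None:
            for m in group:
                for v in _value_strings(m):
                    report.n_values_total += 1
                    if not find_value_in_text(v, doc):
                        report.n_values_not_found += 1
        for m in group:
            if halluc:
                m.flags.hallucinated = True
            if rep:
                m.flags.repetitive = True

    # (5) scientific-notation flags per row
    for m in stage3:
        if (m.kcat is not None and m.kcat.sci_notation) or (m.km is not None and m.km.sci_notation):
            m.flags.scientific_notation = True

    report.n_hallucinated_rows = sum(m.flags.hallucinated for m in stage3)
    report.n_repetitive_rows = sum(m.flags.repetitive for m in stage3)
    report.n_sci_notation_rows = sum(m.flags.scientific_notation for m in stage3)

    # (6) exclusion
    if cfg.exclude_flagged:
        kept = [m for m in stage3 if not m.flags.any_exclusion]
        report.n_excluded = len(stage3) - len(kept)
    else:
        kept = stage3
    report.n_kept = len(kept)
    return kept, report
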