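"""Fixture-document reading: Markdown pipe tables and a minimal XML dialect.

Real literature ingestion (PDF layout analysis, OCR) is out of scope; the
pipeline consumes pre-converted text.  A :class:`DocumentRecord` exposes
both the raw ``full_text`` (searched by the hallucination check) and the
structured tables (consumed by extraction).
"""

from __future__ import annotations

import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .units import normalize_text, strip_thousands_separators

log = logging.getLogger(__name__)


@dataclass
class MarkdownTable:
    table_id: str
    header: list[str]
    rows: list[list[str]]

    def render(self) -> str:
        """Render back to a pipe table; ``parse`` of the result round-trips."""
        lines = ["| " + " | ".join(self.header) + " |"]
        lines.append("|" + "|".join(" --- " for _ in self.header) + "|")
        for row in self.rows:
            lines.append("| " + " | ".join(row) + " |")
        return "\n".join(lines)


@dataclass
class DocumentRecord:
    doc_id: str
    source_format: str
    full_text: str
    tables: list[MarkdownTable] = field(default_factory=list)


_SEP_ROW_RE = re.compile(r"^\s*:?-{3,}:?\s*$")


def _split_pipe_row(line: str) -> list[str]:
    line = line.strip()
    if line.startswith("|"):
        line = line[1:]
    if line.endswith("|"):
        line = line[:-1]
    return [c.strip() for c in line.split("|")]


def parse_markdown(text: str, doc_id: str, source_format: str = "markdown_fixture") -> DocumentRecord:
    """Parse a Markdown fixture document.  Tables are pipe-row blocks whose
    second line is a dash separator.  Ragged rows are padded with empty
    cells (a warning is logged); ``full_text`` is the document verbatim,
    so every table is searchable as text."""
    tables: list[MarkdownTable] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        if lines[i].strip().startswith("|"):
            block = []
            while i < len(lines) and lines[i].strip().startswith("|"):
                block.append(lines[i])
                i += 1
            if len(block) >= 2:
                cells = [_split_pipe_row(ln) for ln in block]
                if all(_SEP_ROW_RE.match(c) for c in cells[1]):
                    header = cells[0]
                    rows = []
                    for r in cells[2:]:
                        if len(r) != len(header):
                            log.warning(
                                "doc %s table T%d: ragged row with %d cells, header has %d; padding",
                                doc_id, len(tables) + 1, len(r), len(header),
                            )
                            r = (r + [""] * len(header))[: len(header)]
                        rows.append(r)
                    tables.append(MarkdownTable(f"T{len(tables) + 1}", header, rows))
        else:
            i += 1
    return DocumentRecord(doc_id=doc_id, source_format=source_format,
                          full_text=text, tables=tables)


def parse_xml(text: str, doc_id: str) -> DocumentRecord:
    """Parse the minimal XML dialect ``<doc><p>..</p><table><tr><td>..``.
    Malformed XML raises :class:`xml.etree.ElementTree.ParseError`, which
    names the offending line."""
    root = ET.fromstring(text)
    parts: list[str] = []
    tables: list[MarkdownTable] = []
    for el in root:
        if el.tag == "p":
            parts.append("".join(el.itertext()).strip())
        elif el.tag == "table":
            trs = el.findall("tr")
            if not trs:
                continue
            header = ["".join(td.itertext()).strip() for td in trs[0]]
            rows = []
            for tr in trs[1:]:
                r = ["".join(td.itertext()).strip() for td in tr]
                if len(r) != len(header):
                    log.warning("doc %s: ragged XML row padded", doc_id)
                    r = (r + [""] * len(header))[: len(header)]
                rows.append(r)
            table = MarkdownTable(el.get("id", f"T{len(tables) + 1}"), header, rows)
            tables.append(table)
            parts.append(table.render())
    return DocumentRecord(doc_id=doc_id, source_format="xml",
                          full_text="\n\n".join(parts), tables=tables)


def read_document(path: str | Path, doc_id: str | None = None,
                  source_format: str | None = None) -> DocumentRecord:
    """Read one fixture document; format inferred from the extension when
    not given (.xml vs anything else = Markdown)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if doc_id is None:
        doc_id = path.stem
    if source_format == "xml" or (source_format is None and path.suffix == ".xml"):
        return parse_xml(text, doc_id)
    return parse_markdown(text, doc_id, source_format or "markdown_fixture")


def load_manifest(manifest_csv: str | Path) -> list[DocumentRecord]:
    """Load a corpus from a manifest CSV with columns
    ``doc_id, path, source_format`` (paths relative to the manifest)."""
    manifest_csv = Path(manifest_csv)
    df = pd.read_csv(manifest_csv, dtype=str)
    docs = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest_csv.parent / p
        docs.append(read_document(p, row["doc_id"], row.get("source_format")))
    return docs


def find_value_in_text(value_text: str, doc: DocumentRecord) -> bool:
    """True iff ``value_text`` occurs in the document as a standalone
    numeric token.

    Word-boundary semantics: the match may not be immediately preceded or
    followed by a digit or decimal point ("4.2" does not match inside
    "14.25").  Thousands commas and typographic variants (superscripts,
    micro glyphs, unicode minus) are normalized on both sides; trailing
    zeros are neither added nor removed.
    """
    query = strip_thousands_separators(normalize_text(value_text)).strip()
    if not query:
        return False
    hay = strip_thousands_separators(normalize_text(doc.full_text))
    pattern = r"(?<![\d.])" + re.escape(query) + r"(?![\d.])"
    return re.search(pattern, hay) is not None
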