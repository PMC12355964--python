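"""Synthetic literature corpus with known ground truth and controlled
corruptions.

Each generated document is narrative filler plus one pipe-delimited
kinetics table (enzyme, organism, optional mutation, substrate, kcat,
Km, pH, temperature) in a sampled unit dialect.  kcat and Km values are
drawn from truncated log10-normal distributions spanning the ranges seen
in large mined corpora (log10 kcat in [-5.8, 5.3] s⁻¹, log10 Km in
[-5.5, 4.5] M).  Ground truth holds the uncorrupted canonical values.

Corruption kinds (each logged and reversible):

* ``sci_notation`` — a printed value is reformatted as mantissa × 10^k
  (value-preserving; document and extraction sides both change);
* ``glyph_swap`` — the micro/milli prefix of a Km unit is swapped
  (document and extraction sides; a factor-1000 error);
* ``rate_unit_swap`` — a kcat unit is relabeled s⁻¹ <-> min⁻¹ without
  rescaling the number (document and extraction sides);
* ``hallucinate_value`` — the extraction-side value is perturbed so it
  no longer appears anywhere in the document text (the structured table
  the extractor reads diverges from the rendered text, emulating a
  generative extractor inventing a number; the document on disk stays
  self-consistent);
* ``repeat_value`` — per document: one value is copied across all of the
  document's kinetic cells on the extraction side (degenerate repetitive
  output).

Generation is fully deterministic for a fixed seed, and the corruption
log is sufficient to undo every corruption byte-identically.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from decimal import Decimal
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import _wordlists as words
from .corpus import DocumentRecord, MarkdownTable
from .records import KineticMeasurement, Provenance, QualityFlags
from .units import parse_quantity

KCAT_LOG10_BOUNDS = (-5.8, 5.3)
KM_LOG10_BOUNDS = (-5.5, 4.5)

CORRUPTION_KINDS = ("glyph_swap", "rate_unit_swap", "hallucinate_value",
                    "repeat_value", "sci_notation")

_KCAT_DIALECTS = ("s^-1", "s−1", "/s", "1/s", "min^-1", "/min")
_KCAT_WEIGHTS = (0.30, 0.20, 0.10, 0.10, 0.20, 0.10)
_KM_DIALECTS = ("μM", "µM", "uM", "mM", "nM", "M", "μmol/L", "mmol/L")
_KM_WEIGHTS = (0.25, 0.08, 0.07, 0.30, 0.10, 0.05, 0.08, 0.07)

_KM_UNIT_FACTOR = {"μM": 1e-6, "µM": 1e-6, "uM": 1e-6, "mM": 1e-3, "nM": 1e-9,
                   "M": 1.0, "μmol/L": 1e-6, "mmol/L": 1e-3}

_GLYPH_SWAP = {"μM": "mM", "µM": "mM", "uM": "mM", "mM": "μM",
               "μmol/L": "mmol/L", "mmol/L": "μmol/L"}
_RATE_SWAP = {"s^-1": "min^-1", "min^-1": "s^-1", "s−1": "min−1", "min−1": "s−1",
              "/s": "/min", "/min": "/s", "1/s": "1/min", "1/min": "1/s"}


@dataclass
class CorpusSpec:
    """Study conditions of the synthetic corpus.

    Default corruption rates follow the flagged-row fractions observed in
    large-scale mining (hallucination 7.1%, repetition 4.4%, scientific
    notation 9.6%); the two unit-swap rates are small plausible values.
    ``repeat_value`` is a per-document probability; the other kinds are
    per-row Bernoulli draws.
    """

    n_docs: int = 50
    rows_per_doc: tuple[int, int] = (3, 8)
    log10_kcat_dist: tuple[float, float] = (0.8, 1.5)   # mean, sd (s^-1)
    kcat_bounds: tuple[float, float] = KCAT_LOG10_BOUNDS
    log10_km_dist: tuple[float, float] = (-4.2, 1.2)    # mean, sd (M)
    km_bounds: tuple[float, float] = KM_LOG10_BOUNDS
    kcat_dialect_weights: dict = field(
        default_factory=lambda: dict(zip(_KCAT_DIALECTS, _KCAT_WEIGHTS)))
    km_dialect_weights: dict = field(
        default_factory=lambda: dict(zip(_KM_DIALECTS, _KM_WEIGHTS)))
    corruption_rates: dict = field(default_factory=lambda: {
        "glyph_swap": 0.01, "rate_unit_swap": 0.01, "hallucinate_value": 0.071,
        "repeat_value": 0.044, "sci_notation": 0.096})
    km_missing_prob: float = 0.23
    mutation_prob: float = 0.3
    typo_rate: float = 0.0  # single-character edits on printed enzyme/organism names
    units_in_cell_prob: float = 0.3
    doc_level_names_prob: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.rows_per_doc
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid rows_per_doc range {self.rows_per_doc}")
        for k, v in self.corruption_rates.items():
            if k not in CORRUPTION_KINDS:
                raise ValueError(f"unknown corruption kind {k!r}")
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"corruption rate {k}={v} outside [0, 1]")
        if self.n_docs < 1:
            raise ValueError("n_docs must be >= 1")
        if self.n_docs > len(words.ENZYMES) * len(words.ORGANISMS):
            raise ValueError("n_docs exceeds the number of unique enzyme-organism pairs")
        if hi > len(words.SUBSTRATES):
            raise ValueError("rows_per_doc exceeds the substrate pool")
        for bounds in (self.kcat_bounds, self.km_bounds):
            if bounds[0] >= bounds[1]:
                raise ValueError(f"empty log10 range {bounds}")


@dataclass
class CorruptionEvent:
    doc_id: str
    row_index: int
    kind: str
    fld: str           # "kcat" | "km"
    col: int           # column index in the table
    original: str      # cell content before
    corrupted: str     # cell content after
    display: bool      # whether the rendered document text changed too


@dataclass
class SyntheticDocument:
    document: DocumentRecord
    truth: list[KineticMeasurement]
    narrative: str
    display_table: MarkdownTable  # what the rendered text shows
    kcat_col: int
    km_col: int

    def rebuild_text(self) -> None:
        self.document.full_text = self.narrative + "\n\n" + self.display_table.render() + "\n"


@dataclass
class SyntheticCorpus:
    docs: list[SyntheticDocument]
    log: list[CorruptionEvent]
    spec: CorpusSpec

    @property
    def documents(self) -> list[DocumentRecord]:
        return [d.document for d in self.docs]

    @property
    def truth(self) -> list[KineticMeasurement]:
        return [m for d in self.docs for m in d.truth]


def _fmt(v: float, sig: int = 4) -> str:
    """Plain-decimal format with ``sig`` significant digits (no
    e-notation in printed tables)."""
    s = f"{v:.{sig}g}"
    if "e" in s or "E" in s:
        s = format(Decimal(s), "f")
    return s


def _sci_format(decimal_str: str) -> str:
    """Rewrite a plain decimal string as mantissa × 10^k, digit-exactly:
    ``"2500"`` -> ``"2.5 × 10^3"``."""
    s = decimal_str.lstrip("+")
    digits = s.replace(".", "")
    point = s.index(".") if "." in s else len(s)
    first = next((i for i, c in enumerate(digits) if c != "0"), None)
    if first is None:
        return s
    exp = point - first - 1
    mant_digits = digits[first:].rstrip("0") or "0"
    mantissa = mant_digits[0] + ("." + mant_digits[1:] if len(mant_digits) > 1 else "")
    return f"{mantissa} × 10^{exp}"


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: tuple[float, float]) -> float:
    while True:
        x = rng.normal(mean, sd)
        if bounds[0] <= x <= bounds[1]:
            return x


def _typo(rng: np.random.Generator, name: str) -> str:
    """One-character substitution, only on names long enough to stay
    above a 0.90 similarity to the original."""
    if len(name) < 10:
        return name
    idx = [i for i, c in enumerate(name) if c.isalpha()]
    i = int(rng.choice(idx))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    c = name[i].lower()
    repl = alphabet[(alphabet.index(c) + 1) % 26] if c in alphabet else "x"
    repl = repl.upper() if name[i].isupper() else repl
    return name[:i] + repl + name[i + 1 :]


def _sample_value(rng: np.random.Generator, dist: tuple[float, float],
                  bounds: tuple[float, float], unit_factor: float,
                  ) -> tuple[str, float]:
    """Draw a canonical value, print it in the target unit at 4
    significant digits, and return (printed string, canonical value of
    the printed string).  Resamples the rare draw whose printed rounding
    escapes the log10 bounds."""
    while True:
        x = _truncated_normal(rng, dist[0], dist[1], bounds)
        printed = _fmt((10.0 ** x) / unit_factor)
        canonical = float(printed) * unit_factor
        if canonical > 0 and bounds[0] <= math.log10(canonical) <= bounds[1]:
            return printed, canonical


def generate_corpus(spec: CorpusSpec | None = None) -> SyntheticCorpus:
    """Generate the corpus.  Content and corruption use independent
    random streams derived from ``spec.seed``, so the same seed with all
    corruption rates at zero reproduces the clean corpus byte-identically."""
    spec = spec or CorpusSpec()
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    content_rng, corrupt_rng = (np.random.default_rng(s) for s in ss.spawn(2))

    # unique enzyme-organism pair per document -> globally unique keys
    pairs = [(e, o) for e in words.ENZYMES for o in words.ORGANISMS]
    pair_idx = content_rng.choice(len(pairs), size=spec.n_docs, replace=False)

    kc_dialects = list(spec.kcat_dialect_weights)
    kc_w = np.array(list(spec.kcat_dialect_weights.values()), dtype=float)
    kc_w /= kc_w.sum()
    km_dialects = list(spec.km_dialect_weights)
    km_w = np.array(list(spec.km_dialect_weights.values()), dtype=float)
    km_w /= km_w.sum()

    docs: list[SyntheticDocument] = []
    for d in range(spec.n_docs):
        rng = content_rng
        doc_id = f"10.9999/synthdoc.{d:04d}"
        enzyme, organism = pairs[pair_idx[d]]
        printed_enzyme, printed_organism = enzyme, organism
        if rng.random() < spec.typo_rate:
            printed_enzyme = _typo(rng, enzyme)
        if rng.random() < spec.typo_rate:
            printed_organism = _typo(rng, organism)

        n_rows = int(rng.integers(spec.rows_per_doc[0], spec.rows_per_doc[1] + 1))
        sub_idx = rng.choice(len(words.SUBSTRATES), size=n_rows, replace=False)
        kc_unit = kc_dialects[int(rng.choice(len(kc_dialects), p=kc_w))]
        km_unit = km_dialects[int(rng.choice(len(km_dialects), p=km_w))]
        kc_factor = (1.0 / 60.0) if "min" in kc_unit else 1.0
        km_factor = _KM_UNIT_FACTOR[km_unit]
        units_in_cell = rng.random() < spec.units_in_cell_prob
        doc_level_names = rng.random() < spec.doc_level_names_prob
        ph = round(float(np.clip(rng.normal(7.2, 1.0), 2.0, 12.0)), 1)
        temp = round(float(np.clip(rng.normal(25.9, 8.0), 0.0, 100.0)), 1)

        any_mut = False
        rows, truth = [], []
        for r in range(n_rows):
            substrate, smiles = words.SUBSTRATES[int(sub_idx[r])]
            mutation = ""
            if rng.random() < spec.mutation_prob:
                aa = rng.choice(list(words.AMINO_ACIDS), size=2, replace=False)
                mutation = f"{aa[0]}{int(rng.integers(2, 400))}{aa[1]}"
                any_mut = True
            kc_printed, kc_val = _sample_value(rng, spec.log10_kcat_dist,
                                               spec.kcat_bounds, kc_factor)
            has_km = rng.random() >= spec.km_missing_prob
            if has_km:
                km_printed, km_val = _sample_value(rng, spec.log10_km_dist,
                                                   spec.km_bounds, km_factor)
            else:
                km_printed, km_val = "", None
            rows.append({"substrate": substrate, "mutation": mutation,
                         "kcat": kc_printed, "km": km_printed})
            truth.append(KineticMeasurement(
                enzyme_name=enzyme, organism=organism, mutation=mutation,
                substrate_name=substrate, substrate_smiles=smiles,
                kcat=parse_quantity(f"{kc_printed} {kc_unit}", "rate"),
                km=(parse_quantity(f"{km_printed} {km_unit}", "concentration")
                    if has_km else None),
                ph=ph, temperature_C=temp,
                flags=QualityFlags(),
                provenance=Provenance(doc_id=doc_id, source_format="markdown_fixture",
                                      table_id="T1", row_index=r),
            ))

        header, make_row = _table_layout(any_mut, doc_level_names, units_in_cell,
                                         kc_unit, km_unit)
        table_rows = [make_row(printed_enzyme, printed_organism, row, ph, temp)
                      for row in rows]
        kcat_col = header.index(_kin_header("kcat", kc_unit, units_in_cell))
        km_col = header.index(_kin_header("Km", km_unit, units_in_cell))

        extract_table = MarkdownTable("T1", list(header), [list(r) for r in table_rows])
        display_table = MarkdownTable("T1", list(header), [list(r) for r in table_rows])

        filler = list(rng.choice(len(words.FILLER_SENTENCES), size=2, replace=False))
        narrative = [f"# Kinetic characterization of {printed_enzyme} from {printed_organism}", ""]
        if doc_level_names:
            narrative += [f"Enzyme: {printed_enzyme}", f"Organism: {printed_organism}", ""]
        narrative += [words.FILLER_SENTENCES[i] for i in filler]
        narrative.append(f"Assays were performed at pH {ph} and {temp} °C.")

        sd = SyntheticDocument(
            document=DocumentRecord(doc_id=doc_id, source_format="markdown_fixture",
                                    full_text="", tables=[extract_table]),
            truth=truth, narrative="\n".join(narrative),
            display_table=display_table, kcat_col=kcat_col, km_col=km_col,
        )
        sd.rebuild_text()
        docs.append(sd)

    log = _apply_corruptions(docs, spec, corrupt_rng)
    return SyntheticCorpus(docs=docs, log=log, spec=spec)


def _kin_header(name: str, unit: str, units_in_cell: bool) -> str:
    return name if units_in_cell else f"{name} ({unit})"


def _table_layout(any_mut: bool, doc_level_names: bool, units_in_cell: bool,
                  kc_unit: str, km_unit: str):
    header = []
    if not doc_level_names:
        header += ["Enzyme", "Organism"]
    if any_mut:
        header.append("Mutation")
    header += ["Substrate",
               _kin_header("kcat", kc_unit, units_in_cell),
               _kin_header("Km", km_unit, units_in_cell),
               "pH", "T (°C)"]

    def make_row(enzyme: str, organism: str, row: dict, ph: float, temp: float) -> list[str]:
        cells = []
        if not doc_level_names:
            cells += [enzyme, organism]
        if any_mut:
            cells.append(row["mutation"])
        kc = f"{row['kcat']} {kc_unit}" if units_in_cell and row["kcat"] else row["kcat"]
        km = f"{row['km']} {km_unit}" if units_in_cell and row["km"] else row["km"]
        cells += [row["substrate"], kc, km, str(ph), str(temp)]
        return cells

    return header, make_row


_NUM_RE = re.compile(r"\d+(?:\.\d+)?")


def _cell_number(cell: str) -> Optional[str]:
    m = _NUM_RE.search(cell)
    return m.group() if m else None


def _perturb_number(num: str, text: str, rng: np.random.Generator) -> str:
    """A replacement numeric string guaranteed absent from ``text``."""
    v = float(num)
    for factor in (1.7, 1.9, 2.3, 3.1, 4.7, 6.1, 7.3, 8.9):
        cand = _fmt(v * factor * (1.0 + 1e-3 * float(rng.integers(1, 9))))
        if cand != num and cand not in text:
            return cand
    return _fmt(v * 12.345)  # pathological fallback


def _swap_unit_in_cell(cell: str, old_unit: str, new_unit: str,
                       units_in_cell: bool) -> str:
    if units_in_cell:
        return cell.replace(old_unit, new_unit, 1)
    # unit lived in the header: write the swapped unit into the cell,
    # which takes precedence over the header on extraction
    return f"{cell} {new_unit}"


def _apply_corruptions(docs: list[SyntheticDocument], spec: CorpusSpec,
                       rng: np.random.Generator) -> list[CorruptionEvent]:
    rates = spec.corruption_rates
    log: list[CorruptionEvent] = []

    for sd in docs:
        doc_id = sd.document.doc_id
        ext, disp = sd.document.tables[0], sd.display_table
        units_in_cell = "(" not in ext.header[sd.kcat_col]
        kc_unit_hdr = _header_unit(ext.header[sd.kcat_col])
        km_unit_hdr = _header_unit(ext.header[sd.km_col])

        def corrupt_both(r: int, c: int, fld: str, kind: str, new: str) -> None:
            old = ext.rows[r][c]
            if new == old:
                return
            ext.rows[r][c] = new
            disp.rows[r][c] = new
            log.append(CorruptionEvent(doc_id, r, kind, fld, c, old, new, display=True))

        for r in range(len(ext.rows)):
            # value-preserving scientific notation rewrite; falls back to
            # the kcat cell when the drawn Km cell is empty, so the
            # per-row rate matches the nominal one
            if rng.random() < rates.get("sci_notation", 0.0):
                fld, c = ("kcat", sd.kcat_col) if rng.random() < 0.5 else ("km", sd.km_col)
                if not _cell_number(ext.rows[r][c]):
                    fld, c = "kcat", sd.kcat_col
                num = _cell_number(ext.rows[r][c])
                if num:
                    corrupt_both(r, c, fld, "sci_notation",
                                 ext.rows[r][c].replace(num, _sci_format(num), 1))
            # micro <-> milli swap on the Km unit
            if rng.random() < rates.get("glyph_swap", 0.0):
                cell = ext.rows[r][sd.km_col]
                unit = _cell_unit(cell) if units_in_cell else km_unit_hdr
                num = _cell_number(cell)
                if num and unit in _GLYPH_SWAP:
                    corrupt_both(r, sd.km_col, "km", "glyph_swap",
                                 _swap_unit_in_cell(cell, unit, _GLYPH_SWAP[unit],
                                                    units_in_cell))
            # s-1 <-> min-1 relabel without rescaling
            if rng.random() < rates.get("rate_unit_swap", 0.0):
                cell = ext.rows[r][sd.kcat_col]
                unit = _cell_unit(cell) if units_in_cell else kc_unit_hdr
                num = _cell_number(cell)
                if num and unit in _RATE_SWAP:
                    corrupt_both(r, sd.kcat_col, "kcat", "rate_unit_swap",
                                 _swap_unit_in_cell(cell, unit, _RATE_SWAP[unit],
                                                    units_in_cell))

        sd.rebuild_text()  # display-side corruptions are now in the text

        # extraction-side value hallucination: one kinetic cell per selected
        # row gets a number absent from the document text
        for r in range(len(ext.rows)):
            if rng.random() < rates.get("hallucinate_value", 0.0):
                for fld, c in (("kcat", sd.kcat_col), ("km", sd.km_col)):
                    cell = ext.rows[r][c]
                    num = _cell_number(cell)
                    if not num:
                        continue
                    new = cell.replace(num, _perturb_number(num, sd.document.full_text, rng), 1)
                    log.append(CorruptionEvent(doc_id, r, "hallucinate_value", fld, c,
                                               cell, new, display=False))
                    ext.rows[r][c] = new
                    break

        # extraction-side repetition: one value across all kinetic cells
        if rng.random() < rates.get("repeat_value", 0.0) and ext.rows:
            source = _cell_number(disp.rows[0][sd.kcat_col]) or "1.0"
            for r in range(len(ext.rows)):
                for fld, c in (("kcat", sd.kcat_col), ("km", sd.km_col)):
                    cell = ext.rows[r][c]
                    num = _cell_number(cell)
                    if num is None or num == source:
                        continue
                    new = cell.replace(num, source, 1)
                    log.append(CorruptionEvent(doc_id, r, "repeat_value", fld, c,
                                               cell, new, display=False))
                    ext.rows[r][c] = new
    return log


def _header_unit(header_cell: str) -> str:
    m = re.search(r"\(([^)]*)\)", header_cell)
    return m.group(1) if m else ""


def _cell_unit(cell: str) -> str:
    num = _cell_number(cell)
    if num is None:
        return ""
    return cell[cell.index(num) + len(num):].strip()


def _cell_number_end(cell: str) -> int:
    m = _NUM_RE.search(cell)
    return m.end() if m else len(cell)


def undo_corruptions(corpus: SyntheticCorpus) -> SyntheticCorpus:
    """Revert every logged corruption (in reverse order) and re-render
    the documents; the result is byte-identical to a clean generation
    with the same seed."""
    by_doc = {sd.document.doc_id: sd for sd in corpus.docs}
    for ev in reversed(corpus.log):
        sd = by_doc[ev.doc_id]
        ext = sd.document.tables[0]
        assert ext.rows[ev.row_index][ev.col] == ev.corrupted, (
            f"corruption log out of sync at {ev.doc_id} row {ev.row_index}")
        ext.rows[ev.row_index][ev.col] = ev.original
        if ev.display:
            sd.display_table.rows[ev.row_index][ev.col] = ev.original
    for sd in corpus.docs:
        sd.rebuild_text()
    corpus.log = []
    return corpus


# -- serialization ---------------------------------------------------------

def emit_ground_truth(corpus: SyntheticCorpus) -> pd.DataFrame:
    """Benchmark-format ground truth: one row per (entry, parameter),
    canonical units (s^-1 for kcat, M for Km)."""
    rows = []
    for m in corpus.truth:
        base = {"enzyme": m.enzyme_name, "mutation": m.mutation,
                "substrate": m.substrate_name, "organism": m.organism,
                "smiles": m.substrate_smiles}
        if m.kcat is not None:
            rows.append({**base, "value": repr(m.kcat.canonical_value),
                         "unit": "s^-1", "parameter": "kcat"})
        if m.km is not None:
            rows.append({**base, "value": repr(m.km.canonical_value),
                         "unit": "M", "parameter": "km"})
    return pd.DataFrame(rows, columns=["enzyme", "mutation", "substrate", "organism",
                                       "smiles", "value", "unit", "parameter"])


def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> None:
    """Write documents (.md), a manifest CSV, the ground-truth CSV and
    the corruption log CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for sd in corpus.docs:
        fname = sd.document.doc_id.split("/")[-1] + ".md"
        (out / fname).write_text(sd.document.full_text, encoding="utf-8")
        manifest.append({"doc_id": sd.document.doc_id, "path": fname,
                         "source_format": sd.document.source_format})
    pd.DataFrame(manifest).to_csv(out / "manifest.csv", index=False)
    emit_ground_truth(corpus).to_csv(out / "ground_truth.csv", index=False)
    pd.DataFrame([ev.__dict__ for ev in corpus.log]).to_csv(
        out / "corruption_log.csv", index=False)
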