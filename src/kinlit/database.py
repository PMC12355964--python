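"""Compilation of curated, resolved entries into database files plus
corpus-level summary statistics (EC class distribution, condition means,
log10 value ranges, confidence tiers)."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import KineticMeasurement, write_jsonl


@dataclass
class SummaryStats:
    n_entries: int = 0
    n_kcat: int = 0
    n_km: int = 0
    confidence_counts: dict = field(default_factory=dict)
    ec_first_digit_hist: dict = field(default_factory=dict)  # {1..7} -> count
    n_ec_classified: int = 0
    temp_mean: Optional[float] = None
    ph_mean: Optional[float] = None
    log10_kcat_range: Optional[tuple[float, float]] = None
    log10_km_range: Optional[tuple[float, float]] = None

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["confidence_counts"] = dict(sorted(self.confidence_counts.items()))
        d["ec_first_digit_hist"] = {str(k): v for k, v in sorted(self.ec_first_digit_hist.items())}
        return json.dumps(d, indent=2)


CSV_COLUMNS = [
    "enzyme_name", "organism", "mutation", "substrate_name", "substrate_smiles",
    "kcat_value", "kcat_unit", "kcat_canonical", "km_value", "km_unit", "km_canonical",
    "ph", "temperature_C", "uniprot", "ncbi", "pdb", "ec", "sequence",
    "confidence", "flags", "doc_id", "source_format", "table_id", "row_index",
]


def _to_frame(entries: Sequence[KineticMeasurement]) -> pd.DataFrame:
    rows = []
    for m in entries:
        d = m.to_json_dict()
        d["flags"] = "|".join(d["flags"])
        d["kcat_canonical"] = m.kcat.canonical_value if m.kcat else None
        d["km_canonical"] = m.km.canonical_value if m.km else None
        rows.append(d)
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return df.sort_values(["doc_id", "row_index"], kind="stable").reset_index(drop=True)


def _stats_from_frame(df: pd.DataFrame) -> SummaryStats:
    s = SummaryStats(n_entries=len(df))
    if df.empty:
        return s
    kcat = pd.to_numeric(df["kcat_canonical"], errors="coerce")
    km = pd.to_numeric(df["km_canonical"], errors="coerce")
    s.n_kcat = int(kcat.notna().sum())
    s.n_km = int(km.notna().sum())
    conf = df["confidence"].fillna("")
    s.confidence_counts = {k: int(v) for k, v in conf.value_counts().items() if k}
    ec_first = df["ec"].fillna("").astype(str).str.extract(r"^([1-7])\.")[0]
    hist = ec_first.dropna().astype(int).value_counts()
    s.ec_first_digit_hist = {int(k): int(v) for k, v in hist.items()}
    s.n_ec_classified = int(sum(s.ec_first_digit_hist.values()))
    temp = pd.to_numeric(df["temperature_C"], errors="coerce")
    phs = pd.to_numeric(df["ph"], errors="coerce")
    s.temp_mean = float(temp.mean()) if temp.notna().any() else None
    s.ph_mean = float(phs.mean()) if phs.notna().any() else None
    lk = np.log10(kcat[kcat > 0])
    lm = np.log10(km[km > 0])
    s.log10_kcat_range = (float(lk.min()), float(lk.max())) if len(lk) else None
    s.log10_km_range = (float(lm.min()), float(lm.max())) if len(lm) else None
    return s


def build(entries: Sequence[KineticMeasurement], out_dir: str | Path,
          ) -> tuple[dict[str, Path], SummaryStats]:
    """Write the full table (CSV + Parquet), the sequence-mapped subset
    (non-empty sequence and a confidence tier other than unmapped) and
    the summary JSON.  Deterministic: entries are sorted by
    (doc_id, row_index) and equal inputs give byte-identical CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = _to_frame(entries)
    stats = _stats_from_frame(df)
    paths = {
        "csv": out / "database.csv",
        "parquet": out / "database.parquet",
        "sequence_mapped": out / "sequence_mapped.csv",
        "summary": out / "summary.json",
        "jsonl": out / "database.jsonl",
    }
    df.to_csv(paths["csv"], index=False)
    df.to_parquet(paths["parquet"], index=False)
    mapped = df[(df["sequence"].fillna("") != "")
                & df["confidence"].isin(["high", "medium", "low"])]
    mapped.to_csv(paths["sequence_mapped"], index=False)
    paths["summary"].write_text(stats.to_json(), encoding="utf-8")
    ordered = sorted(entries, key=lambda m: (m.provenance.doc_id, m.provenance.row_index))
    write_jsonl(ordered, paths["jsonl"])
    return paths, stats


def summarize(database_csv: str | Path) -> SummaryStats:
    """Recompute SummaryStats from a built CSV; equals the build-time
    stats.  A schema mismatch raises with the missing columns listed."""
    df = pd.read_csv(database_csv, dtype={"ec": str, "confidence": str,
                                          "sequence": str, "doc_id": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"database schema mismatch; missing columns: {missing}")
    return _stats_from_frame(df)
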