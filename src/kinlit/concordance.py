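"""Large-scale agreement analysis between two kinetic-value sources.

Matched enzyme–substrate pairs are compared in log10 space: Pearson and
Spearman correlations, R², mean absolute deviation (MAD) and root mean
square deviation (RMSD).  Beyond global statistics, the module detects
clusters of pairs shifted by a *fixed* log offset — the fingerprint of a
systematic unit error: ±log10(60) for s⁻¹/min⁻¹ confusion, ±3 for a
micro/milli prefix swap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .records import EntryKey
from .units import parse_quantity, log10_value

#: log10(60): one minute expressed in seconds
MINUTE_OFFSET = math.log10(60.0)
#: log10(1000): the micro <-> milli prefix swap
PREFIX_OFFSET = 3.0

DEFAULT_CANDIDATE_OFFSETS = (MINUTE_OFFSET, -MINUTE_OFFSET, PREFIX_OFFSET, -PREFIX_OFFSET)


@dataclass
class ConcordancePair:
    key: Optional[EntryKey]
    log10_a: float
    log10_b: float


@dataclass
class OffsetCluster:
    offset: float
    n_members: int
    diagnosis: str  # "minute_vs_second" | "micro_vs_milli" | "fixed_offset"
    member_indices: list[int] = field(default_factory=list)


@dataclass
class ConcordanceReport:
    n: int
    pearson_r: float
    spearman_rho: float
    r_squared: float
    mad: float
    rmsd: float
    offset_clusters: list[OffsetCluster] = field(default_factory=list)

    def to_json(self) -> str:
        d = dict(self.__dict__)
        d["offset_clusters"] = [c.__dict__ for c in self.offset_clusters]
        return json.dumps(d, indent=2, sort_keys=True)


def paired_stats(pairs: Sequence[ConcordancePair]) -> ConcordanceReport:
    """Correlations and deviations of paired log10 values.

    Spearman uses mid-ranks for ties.  With fewer than two pairs, or a
    constant vector, correlations are reported as NaN while MAD/RMSD are
    still computed.
    """
    a = np.array([p.log10_a for p in pairs], dtype=float)
    b = np.array([p.log10_b for p in pairs], dtype=float)
    n = len(a)
    diff = a - b
    mad = float(np.mean(np.abs(diff))) if n else float("nan")
    rmsd = float(np.sqrt(np.mean(diff ** 2))) if n else float("nan")
    if n < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        r = rho = r2 = float("nan")
    else:
        r = float(stats.pearsonr(a, b).statistic)
        rho = float(stats.spearmanr(a, b).statistic)
        r2 = r * r
    return ConcordanceReport(n=n, pearson_r=r, spearman_rho=rho, r_squared=r2,
                             mad=mad, rmsd=rmsd)


def _diagnose(offset: float, tol: float = 0.01) -> str:
    if abs(abs(offset) - MINUTE_OFFSET) <= tol:
        return "minute_vs_second"
    if abs(abs(offset) - PREFIX_OFFSET) <= tol:
        return "micro_vs_milli"
    return "fixed_offset"


def detect_offset_clusters(pairs: Sequence[ConcordancePair],
                           candidate_offsets: Sequence[float] = DEFAULT_CANDIDATE_OFFSETS,
                           tol: float = 0.15,
                           min_members: int = 5) -> list[OffsetCluster]:
    """Pairs whose log10 discrepancy sits within ``tol`` of a candidate
    offset form a cluster; clusters smaller than ``min_members`` are
    dropped.  Each reported cluster carries a diagnosis tag naming the
    unit error it is consistent with."""
    diff = np.array([p.log10_a - p.log10_b for p in pairs], dtype=float)
    clusters = []
    for delta in candidate_offsets:
        members = np.nonzero(np.abs(diff - delta) <= tol)[0]
        if len(members) >= min_members:
            clusters.append(OffsetCluster(
                offset=float(delta), n_members=int(len(members)),
                diagnosis=_diagnose(delta), member_indices=[int(i) for i in members],
            ))
    return clusters


def analyze(pairs: Sequence[ConcordancePair],
            candidate_offsets: Sequence[float] = DEFAULT_CANDIDATE_OFFSETS,
            tol: float = 0.15, min_members: int = 5) -> ConcordanceReport:
    """paired_stats + offset-cluster detection in one report."""
    rep = paired_stats(pairs)
    rep.offset_clusters = detect_offset_clusters(pairs, candidate_offsets, tol, min_members)
    return rep


def load_pairs(path: str | Path, kind: str = "rate") -> list[ConcordancePair]:
    """Read matched pairs from CSV with columns ``value_a, unit_a,
    value_b, unit_b`` plus optional key columns (enzyme, mutation,
    substrate, organism); values are canonicalized then log10'd."""
    df = pd.read_csv(path, dtype=str).fillna("")
    out = []
    for _, r in df.iterrows():
        qa = parse_quantity(f"{r['value_a']} {r['unit_a']}".strip(), kind)
        qb = parse_quantity(f"{r['value_b']} {r['unit_b']}".strip(), kind)
        key = None
        if "enzyme" in df.columns:
            key = EntryKey.from_fields(r.get("enzyme", ""), r.get("mutation", ""),
                                       r.get("substrate", ""), r.get("organism", ""))
        out.append(ConcordancePair(key=key,
                                   log10_a=log10_value(qa.canonical_value),
                                   log10_b=log10_value(qb.canonical_value)))
    return out


def export_cluster_members(pairs: Sequence[ConcordancePair],
                           clusters: Sequence[OffsetCluster]) -> pd.DataFrame:
    """Flagged cluster members with diagnosis, for manual review."""
    rows = []
    for c in clusters:
        for i in c.member_indices:
            p = pairs[i]
            rows.append({
                "pair_index": i, "offset": c.offset, "diagnosis": c.diagnosis,
                "log10_a": p.log10_a, "log10_b": p.log10_b,
                "enzyme": p.key.enzyme_name_norm if p.key else "",
                "substrate": p.key.substrate_norm if p.key else "",
            })
    return pd.DataFrame(rows, columns=["pair_index", "offset", "diagnosis",
                                       "log10_a", "log10_b", "enzyme", "substrate"])
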