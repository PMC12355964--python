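"""Assignment-based validation against a curated ground truth.

The framework aligns extracted entries with ground-truth entries on the
(enzyme, mutation, substrate, organism) key: a candidate pair is
admissible when enzyme and organism names each reach a similarity
threshold (default 0.90, normalized edit-distance similarity), the
substrate matches exactly by normalized name or by identical canonical
SMILES, and the mutation strings agree.  Among admissible pairs a
one-to-one assignment maximizing total similarity is found by linear sum
assignment; matched pairs are then classified by value agreement:

* TP — values agree within a relative tolerance (default 1%) after unit
  canonicalization;
* FN — a matched key whose extracted value is absent;
* FP — a matched key with a disagreeing value, additionally tallied as
  off-by-10^k when the log10 discrepancy sits within a tolerance of k in
  {1, 2, 3} (either direction), plus key-less extracted entries;
* Unresolved — ground-truth entries with no admissible partner; excluded
  from the accuracy/precision denominators.

accuracy = TP/(TP+FP+FN); precision = TP/(TP+FP).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .records import EntryKey, KineticMeasurement
from .units import parse_quantity


def levenshtein(a: str, b: str) -> int:
    """Character-level edit distance (unit-cost substitution, insertion,
    deletion)."""
    if len(a) < len(b):
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def name_similarity(a: str, b: str) -> float:
    """Normalized similarity 1 - d(a,b)/max(|a|,|b|) in [0, 1]; symmetric;
    two empty strings are identical (1.0).  Inputs are expected to be
    key-normalized already."""
    if not a and not b:
        return 1.0
    return 1.0 - levenshtein(a, b) / max(len(a), len(b))


def _canonical_smiles(s: str) -> str:
    """Canonicalize a SMILES string when RDKit is available and the string
    parses; fall back to byte equality otherwise."""
    if not s:
        return ""
    try:
        from rdkit import Chem  # optional
        from rdkit import RDLogger
        RDLogger.DisableLog("rdApp.*")
        mol = Chem.MolFromSmiles(s)
        if mol is not None:
            return Chem.MolToSmiles(mol)
    except ImportError:
        pass
    return s


@dataclass
class AlignmentConfig:
    name_similarity_threshold: float = 0.90
    substrate_match: str = "exact_name_or_smiles"
    value_rel_tolerance: float = 0.01
    off_by_log_tolerance: float = 0.05
    parameter: str = "kcat"  # "kcat" | "km"
    min_off_by_k: int = 1
    max_off_by_k: int = 3
    similarity_fn: Callable[[str, str], float] = field(default=name_similarity, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.name_similarity_threshold <= 1.0):
            raise ValueError("name_similarity_threshold must be in (0, 1]")
        if not (0.0 < self.value_rel_tolerance <= 1.0):
            raise ValueError("value_rel_tolerance must be in (0, 1]")
        if not (0.0 < self.off_by_log_tolerance < 0.5):
            raise ValueError("off_by_log_tolerance must be in (0, 0.5)")
        if self.parameter not in ("kcat", "km"):
            raise ValueError("parameter must be 'kcat' or 'km'")


@dataclass
class BenchmarkEntry:
    """One alignable entry: a normalized key, an optional canonical
    SMILES, and the canonical value of the benchmarked parameter
    (s^-1 for kcat, M for Km), or None when not extracted."""

    key: EntryKey
    smiles: str = ""
    value: Optional[float] = None

    @classmethod
    def from_measurement(cls, m: KineticMeasurement, parameter: str) -> "BenchmarkEntry":
        q = m.kcat if parameter == "kcat" else m.km
        return cls(key=m.entry_key(), smiles=m.substrate_smiles,
                   value=None if q is None else q.canonical_value)


@dataclass
class BenchmarkReport:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    unresolved: int = 0
    off_by_10: int = 0
    off_by_100: int = 0
    off_by_1000: int = 0
    accuracy: float = 0.0
    precision: float = 0.0

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    def to_table_row(self) -> dict:
        return {"FP": self.fp, "FN": self.fn, "TP": self.tp,
                "Off by 10": self.off_by_10, "Off by 10^2": self.off_by_100,
                "Off by 10^3": self.off_by_1000, "Accuracy": round(self.accuracy, 2),
                "Unresolved": self.unresolved, "Precision": round(self.precision, 2)}


def metrics(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """accuracy = TP/(TP+FP+FN), precision = TP/(TP+FP); 0 on zero
    denominators; negative counts are an error."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    accuracy = tp / (tp + fp + fn) if (tp + fp + fn) else 0.0
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    return accuracy, precision


def pair_admissible(p: BenchmarkEntry, t: BenchmarkEntry, cfg: AlignmentConfig,
                    ) -> tuple[bool, float]:
    """(admissible, composite score).  The composite score is the mean of
    the enzyme and organism similarities."""
    sim = cfg.similarity_fn
    se = sim(p.key.enzyme_name_norm, t.key.enzyme_name_norm)
    so = sim(p.key.organism_norm, t.key.organism_norm)
    if se < cfg.name_similarity_threshold or so < cfg.name_similarity_threshold:
        return False, 0.0
    if p.key.mutation_norm != t.key.mutation_norm:
        return False, 0.0
    substrate_ok = p.key.substrate_norm == t.key.substrate_norm
    if not substrate_ok and p.smiles and t.smiles:
        substrate_ok = _canonical_smiles(p.smiles) == _canonical_smiles(t.smiles)
    if not substrate_ok:
        return False, 0.0
    return True, (se + so) / 2.0


def align_entries(pred: Sequence[BenchmarkEntry], truth: Sequence[BenchmarkEntry],
                  cfg: AlignmentConfig | None = None,
                  ) -> tuple[list[tuple[int, int, float]], list[int], list[int]]:
    """One-to-one alignment maximizing total composite similarity over
    admissible pairs.

    Returns (matched [(pred_idx, truth_idx, score)], unmatched pred
    indices, unmatched truth indices).
    """
    cfg = cfg or AlignmentConfig()
    np_, nt = len(pred), len(truth)
    if np_ == 0 or nt == 0:
        return [], list(range(np_)), list(range(nt))
    score = np.zeros((np_, nt))
    admissible = np.zeros((np_, nt), dtype=bool)
    for i, p in enumerate(pred):
        for j, t in enumerate(truth):
            ok, s = pair_admissible(p, t, cfg)
            admissible[i, j] = ok
            score[i, j] = s if ok else 0.0
    rows, cols = linear_sum_assignment(score, maximize=True)
    matched = [(int(i), int(j), float(score[i, j]))
               for i, j in zip(rows, cols) if admissible[i, j]]
    mp = {i for i, _, _ in matched}
    mt = {j for _, j, _ in matched}
    return (matched,
            [i for i in range(np_) if i not in mp],
            [j for j in range(nt) if j not in mt])


def classify(matched: list[tuple[BenchmarkEntry, BenchmarkEntry]],
             unmatched_pred: list[BenchmarkEntry],
             unmatched_truth: list[BenchmarkEntry],
             cfg: AlignmentConfig | None = None) -> BenchmarkReport:
    """Classify aligned entries into TP/FP/FN/Unresolved and tally
    off-by-10^k factors (a subset of FP)."""
    cfg = cfg or AlignmentConfig()
    rep = BenchmarkReport()
    log_tol = math.log10(1.0 + cfg.value_rel_tolerance)
    for p, t in matched:
        if t.value is None:
            continue  # nothing to verify against for this parameter
        if p.value is None:
            rep.fn += 1
            continue
        ratio = math.log10(p.value / t.value)
        if abs(ratio) <= log_tol:
            rep.tp += 1
        else:
            rep.fp += 1
            for k in range(cfg.min_off_by_k, cfg.max_off_by_k + 1):
                if abs(abs(ratio) - k) <= cfg.off_by_log_tolerance:
                    if k == 1:
                        rep.off_by_10 += 1
                    elif k == 2:
                        rep.off_by_100 += 1
                    else:
                        rep.off_by_1000 += 1
                    break
    # an unmatched extracted entry asserts a value for a key absent from
    # the truth -> FP; one without a value asserts nothing and is skipped
    rep.fp += sum(1 for p in unmatched_pred if p.value is not None)
    rep.unresolved = len(unmatched_truth)
    rep.accuracy, rep.precision = metrics(rep.tp, rep.fp, rep.fn)
    return rep


def run_benchmark(pred: Sequence[BenchmarkEntry], truth: Sequence[BenchmarkEntry],
                  cfg: AlignmentConfig | None = None) -> BenchmarkReport:
    """Align then classify; the one-call entry point."""
    cfg = cfg or AlignmentConfig()
    matched_idx, up, ut = align_entries(pred, truth, cfg)
    matched = [(pred[i], truth[j]) for i, j, _ in matched_idx]
    return classify(matched, [pred[i] for i in up], [truth[j] for j in ut], cfg)


GROUND_TRUTH_COLUMNS = ("enzyme", "mutation", "substrate", "organism",
                        "smiles", "value", "unit", "parameter")


def load_ground_truth(path: str | Path, parameter: str) -> list[BenchmarkEntry]:
    """Read a ground-truth CSV (columns: enzyme, mutation, substrate,
    organism, smiles, value, unit, parameter) and canonicalize values for
    the requested parameter."""
    df = pd.read_csv(path, dtype=str).fillna("")
    kind = "rate" if parameter == "kcat" else "concentration"
    out = []
    for _, r in df.iterrows():
        if r["parameter"] != parameter:
            continue
        q = parse_quantity(f"{r['value']} {r['unit']}".strip(), kind)
        out.append(BenchmarkEntry(
            key=EntryKey.from_fields(r["enzyme"], r["mutation"], r["substrate"], r["organism"]),
            smiles=r["smiles"],
            value=q.canonical_value,
        ))
    return out


def entries_from_measurements(measurements: Sequence[KineticMeasurement],
                              parameter: str) -> list[BenchmarkEntry]:
    """Benchmark entries for all measurements that carry the parameter or
    at least a key (value may be None -> potential FN)."""
    return [BenchmarkEntry.from_measurement(m, parameter) for m in measurements]
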