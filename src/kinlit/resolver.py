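"""Name-to-sequence and name-to-SMILES resolution with confidence tiers.

Lookups are pluggable contracts; the shipped implementations are offline
TSV fixture tables so the pipeline is hermetic.  Live web clients
(UniProt, PubChem) can implement the same contracts behind a flag.

The confidence tier of an entry counts how many of five metadata fields
were recovered — enzyme name, organism, UniProt, NCBI and PDB
identifiers: >= 3 is high, 2 medium, 1 low, 0 unmapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Protocol

import pandas as pd

from .records import KineticMeasurement, normalize_name

#: identifier precedence for direct sequence retrieval
IDENTIFIER_PRECEDENCE = ("uniprot", "ncbi", "pdb")

#: generic polymeric substrates with no meaningful single structure
DEFAULT_GENERIC_SUBSTRATES = frozenset({"dna", "rna", "protein", "starch"})


@dataclass
class ResolutionConfig:
    metadata_fields: tuple = ("enzyme_name", "organism", "uniprot", "ncbi", "pdb")
    high_min: int = 3
    medium_eq: int = 2
    low_eq: int = 1

    def __post_init__(self) -> None:
        if not (self.high_min > self.medium_eq > self.low_eq >= 1):
            raise ValueError("tier thresholds must satisfy high_min > medium_eq > low_eq >= 1")


def metadata_field_count(m: KineticMeasurement, cfg: ResolutionConfig | None = None) -> int:
    cfg = cfg or ResolutionConfig()
    n = 0
    for f in cfg.metadata_fields:
        if f in ("enzyme_name", "organism"):
            n += bool(getattr(m, f).strip())
        else:
            n += bool(m.identifiers.get(f, "").strip())
    return n


def score_confidence(m: KineticMeasurement, cfg: ResolutionConfig | None = None) -> str:
    """Tier from the metadata-field count; monotone in the count."""
    cfg = cfg or ResolutionConfig()
    n = metadata_field_count(m, cfg)
    if n >= cfg.high_min:
        return "high"
    if n == cfg.medium_eq:
        return "medium"
    if n >= cfg.low_eq:
        return "low"
    return "unmapped"


class SequenceLookup(Protocol):
    def by_identifier(self, kind: str, identifier: str) -> Optional[str]: ...
    def by_name_organism(self, name: str, organism: str) -> list[tuple[int, str]]:
        """Ranked (rank, sequence) hits, best first."""


class CompoundLookup(Protocol):
    def by_name(self, name: str) -> list[tuple[str, str]]:
        """Ranked (name, smiles) hits, best first."""
    def expand_abbreviation(self, abbrev: str) -> Optional[str]: ...


class TableSequenceLookup:
    """Sequence fixture table: TSV with columns
    ``kind, id, name, organism, sequence`` and an optional ``rank``
    column used to order name+organism hits (file order otherwise)."""

    def __init__(self, frame: pd.DataFrame) -> None:
        frame = frame.fillna("")
        if "rank" not in frame.columns:
            frame = frame.assign(rank=range(len(frame)))
        self._frame = frame

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TableSequenceLookup":
        return cls(pd.read_csv(path, sep="\t", dtype={"kind": str, "id": str, "name": str,
                                                      "organism": str, "sequence": str}))

    def by_identifier(self, kind: str, identifier: str) -> Optional[str]:
        df = self._frame
        hit = df[(df["kind"] == kind) & (df["id"] == identifier)]
        if hit.empty:
            return None
        return hit.iloc[0]["sequence"]

    def by_name_organism(self, name: str, organism: str) -> list[tuple[int, str]]:
        df = self._frame
        mask = (df["name"].map(normalize_name) == normalize_name(name)) & (
            df["organism"].map(normalize_name) == normalize_name(organism))
        hits = df[mask].sort_values("rank", kind="stable")
        return [(int(r["rank"]), r["sequence"]) for _, r in hits.iterrows()]


class TableCompoundLookup:
    """Compound fixture tables: compounds TSV (``name, rank, smiles``) and
    an optional abbreviations TSV (``abbrev, full_name``)."""

    def __init__(self, compounds: pd.DataFrame,
                 abbreviations: pd.DataFrame | None = None) -> None:
        self._compounds = compounds.fillna("")
        self._abbrev = (abbreviations.fillna("")
                        if abbreviations is not None else pd.DataFrame(columns=["abbrev", "full_name"]))

    @classmethod
    def from_tsv(cls, compounds_path: str | Path,
                 abbreviations_path: str | Path | None = None) -> "TableCompoundLookup":
        comp = pd.read_csv(compounds_path, sep="\t", dtype=str)
        abbr = pd.read_csv(abbreviations_path, sep="\t", dtype=str) if abbreviations_path else None
        return cls(comp, abbr)

    def by_name(self, name: str) -> list[tuple[str, str]]:
        df = self._compounds
        hits = df[df["name"].map(normalize_name) == normalize_name(name)]
        if "rank" in hits.columns:
            hits = hits.sort_values("rank", key=lambda s: s.astype(int), kind="stable")
        return [(r["name"], r["smiles"]) for _, r in hits.iterrows()]

    def expand_abbreviation(self, abbrev: str) -> Optional[str]:
        df = self._abbrev
        hit = df[df["abbrev"].map(normalize_name) == normalize_name(abbrev)]
        if hit.empty:
            return None
        return hit.iloc[0]["full_name"]


def resolve_sequence(m: KineticMeasurement, lookup: SequenceLookup,
                     ) -> tuple[Optional[str], str]:
    """Retrieve a sequence for a measurement.

    Identifier precedence UniProt -> NCBI -> PDB; the first identifier
    that resolves wins (method ``identifier:<kind>``).  Otherwise a
    combined enzyme-name + organism search is run and the top-ranked hit
    selected (method ``name_search``).  Lookup failures yield
    ``(None, "unresolved")`` — never an exception.
    """
    for kind in IDENTIFIER_PRECEDENCE:
        identifier = m.identifiers.get(kind, "").strip()
        if not identifier:
            continue
        try:
            seq = lookup.by_identifier(kind, identifier)
        except Exception:  # fixture missing / backend failure
            seq = None
        if seq:
            return seq, f"identifier:{kind}"
    if m.enzyme_name.strip() and m.organism.strip():
        try:
            hits = lookup.by_name_organism(m.enzyme_name, m.organism)
        except Exception:
            hits = []
        if hits:
            return hits[0][1], "name_search"
    return None, "unresolved"


@dataclass
class SubstrateResolution:
    smiles: Optional[str]
    resolved_name: str
    reason: str  # "ok" | "generic_substrate" | "no_match"


def resolve_substrate(name: str, lookup: CompoundLookup,
                      generic_stop_list: frozenset[str] = DEFAULT_GENERIC_SUBSTRATES,
                      ) -> SubstrateResolution:
    """Resolve a substrate name to a SMILES string.

    Abbreviations are expanded first; generic polymeric names (DNA, RNA,
    protein, starch by default) return no structure with reason
    ``generic_substrate``; with multiple hits the top-ranked one wins.
    """
    if not name.strip():
        raise ValueError("substrate name must be non-empty")
    if normalize_name(name) in generic_stop_list:
        return SubstrateResolution(None, name, "generic_substrate")
    expanded = lookup.expand_abbreviation(name) or name
    if normalize_name(expanded) in generic_stop_list:
        return SubstrateResolution(None, expanded, "generic_substrate")
    hits = lookup.by_name(expanded)
    if not hits:
        return SubstrateResolution(None, expanded, "no_match")
    top_name, smiles = hits[0]
    return SubstrateResolution(smiles, top_name, "ok")


def resolve_entries(entries: list[KineticMeasurement],
                    sequences: SequenceLookup | None = None,
                    compounds: CompoundLookup | None = None,
                    cfg: ResolutionConfig | None = None) -> list[KineticMeasurement]:
    """Assign confidence tiers and fill sequences/SMILES in place;
    returns the same list for chaining."""
    cfg = cfg or ResolutionConfig()
    for m in entries:
        m.confidence = score_confidence(m, cfg)
        if sequences is not None and not m.sequence:
            seq, _method = resolve_sequence(m, sequences)
            if seq:
                m.sequence = seq
        if compounds is not None and not m.substrate_smiles and m.substrate_name.strip():
            res = resolve_substrate(m.substrate_name, compounds)
            if res.smiles:
                m.substrate_smiles = res.smiles
    return entries
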