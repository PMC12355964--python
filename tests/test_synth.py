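"""Synthetic corpus generator: determinism, bounds, corruption logging
and reversibility."""

import math
from dataclasses import replace
from itertools import combinations

import numpy as np
import pytest

from kinlit import synth
from kinlit._wordlists import ENZYMES, ORGANISMS, SUBSTRATES
from kinlit.benchmark import name_similarity
from kinlit.corpus import load_manifest, parse_markdown
from kinlit.records import normalize_name
from kinlit.units import log10_value

from conftest import ZERO_RATES, make_corpus


def test_same_seed_same_corpus():
    a = make_corpus(n_docs=15, seed=3, sci_notation=0.2, glyph_swap=0.2)
    b = make_corpus(n_docs=15, seed=3, sci_notation=0.2, glyph_swap=0.2)
    assert a.docs == b.docs
    assert a.log == b.log


def test_different_seeds_differ():
    a = make_corpus(n_docs=5, seed=1)
    b = make_corpus(n_docs=5, seed=2)
    assert a.docs != b.docs


def test_log10_values_within_truncation_bounds(clean_corpus):
    for m in clean_corpus.truth:
        assert synth.KCAT_LOG10_BOUNDS[0] <= log10_value(m.kcat.canonical_value) \
            <= synth.KCAT_LOG10_BOUNDS[1]
        if m.km is not None:
            assert synth.KM_LOG10_BOUNDS[0] <= log10_value(m.km.canonical_value) \
                <= synth.KM_LOG10_BOUNDS[1]


def test_entry_keys_globally_unique(clean_corpus):
    keys = [m.entry_key() for m in clean_corpus.truth]
    assert len(keys) == len(set(keys))


def test_enzyme_name_pool_pairwise_dissimilar():
    """No two pool enzymes reach the 0.90 alignment threshold (with
    margin for a one-character typo), so distinct keys are never
    cross-admissible."""
    for a, b in combinations(ENZYMES, 2):
        assert name_similarity(normalize_name(a), normalize_name(b)) < 0.85


def test_corruption_rates_followed_binomially():
    rate = 0.15
    c = make_corpus(n_docs=200, seed=13, glyph_swap=rate)
    n_rows = sum(len(sd.document.tables[0].rows) for sd in c.docs)
    # only rows with a swappable (micro/milli) Km unit can be corrupted
    eligible = 0
    clean = make_corpus(n_docs=200, seed=13)
    for sd in clean.docs:
        for r, m in enumerate(sd.truth):
            if m.km is not None and m.km.prefix in ("m", "μ"):
                eligible += 1
    n_events = sum(1 for e in c.log if e.kind == "glyph_swap")
    sigma = math.sqrt(eligible * rate * (1 - rate))
    assert abs(n_events - eligible * rate) <= 3 * sigma


def test_undo_restores_clean_corpus():
    spec = synth.CorpusSpec(n_docs=25, seed=21)  # default (nonzero) rates
    corrupted = synth.generate_corpus(spec)
    assert corrupted.log, "default rates should corrupt something"
    restored = synth.undo_corruptions(corrupted)
    clean = synth.generate_corpus(replace(spec, corruption_rates=dict(ZERO_RATES)))
    assert restored.docs == clean.docs


def test_glyph_swap_changes_canonical_by_1000():
    c = make_corpus(n_docs=40, seed=22, glyph_swap=1.0)
    swapped = {(e.doc_id, e.row_index) for e in c.log if e.kind == "glyph_swap"}
    assert swapped
    from kinlit.extraction import reference_extract
    truth_by_key = {(sd.document.doc_id, r): m
                    for sd in c.docs for r, m in enumerate(sd.truth)}
    for sd in c.docs:
        for raw in reference_extract(sd.document):
            if (raw.doc_id, raw.row_index) not in swapped:
                continue
            m = raw.to_measurement()
            t = truth_by_key[(raw.doc_id, raw.row_index)]
            ratio = m.km.canonical_value / t.km.canonical_value
            assert math.log10(ratio) == pytest.approx(3.0, abs=1e-9) or \
                math.log10(ratio) == pytest.approx(-3.0, abs=1e-9)


def test_rate_unit_swap_changes_canonical_by_60():
    c = make_corpus(n_docs=40, seed=23, rate_unit_swap=1.0)
    swapped = {(e.doc_id, e.row_index) for e in c.log if e.kind == "rate_unit_swap"}
    assert swapped
    from kinlit.extraction import reference_extract
    truth_by_key = {(sd.document.doc_id, r): m
                    for sd in c.docs for r, m in enumerate(sd.truth)}
    for sd in c.docs:
        for raw in reference_extract(sd.document):
            if (raw.doc_id, raw.row_index) not in swapped:
                continue
            ratio = raw.to_measurement().kcat.canonical_value / \
                truth_by_key[(raw.doc_id, raw.row_index)].kcat.canonical_value
            assert ratio == pytest.approx(60.0, rel=1e-9) or \
                ratio == pytest.approx(1 / 60.0, rel=1e-9)


def test_sci_notation_corruption_preserves_value():
    c = make_corpus(n_docs=30, seed=24, sci_notation=1.0)
    from kinlit.extraction import reference_extract
    truth_by_key = {(sd.document.doc_id, r): m
                    for sd in c.docs for r, m in enumerate(sd.truth)}
    n_sci = 0
    for sd in c.docs:
        for raw in reference_extract(sd.document):
            m = raw.to_measurement()
            t = truth_by_key[(raw.doc_id, raw.row_index)]
            for got, want in ((m.kcat, t.kcat), (m.km, t.km)):
                if want is None:
                    continue
                assert got.canonical_value == pytest.approx(
                    want.canonical_value, rel=1e-9)
                n_sci += got.sci_notation
    assert n_sci > 0


def test_hallucinated_values_absent_from_text():
    from kinlit.corpus import find_value_in_text
    from kinlit.units import parse_quantity
    c = make_corpus(n_docs=30, seed=25, hallucinate_value=0.5)
    by_doc = {sd.document.doc_id: sd for sd in c.docs}
    events = [e for e in c.log if e.kind == "hallucinate_value"]
    assert events
    for e in events:
        sd = by_doc[e.doc_id]
        corrupted_num = synth._cell_number(e.corrupted)
        original_num = synth._cell_number(e.original)
        assert not find_value_in_text(corrupted_num, sd.document)
        assert find_value_in_text(original_num, sd.document)


class TestGroundTruthEmission:
    def test_row_per_entry_parameter(self):
        c = make_corpus(n_docs=10, seed=26)
        df = synth.emit_ground_truth(c)
        n_kcat = sum(m.kcat is not None for m in c.truth)
        n_km = sum(m.km is not None for m in c.truth)
        assert len(df) == n_kcat + n_km
        assert set(df["parameter"]) == {"kcat", "km"}

    def test_csv_round_trip_equals_memory(self, tmp_path):
        from kinlit.benchmark import load_ground_truth
        c = make_corpus(n_docs=10, seed=27)
        path = tmp_path / "truth.csv"
        synth.emit_ground_truth(c).to_csv(path, index=False)
        for param in ("kcat", "km"):
            entries = load_ground_truth(path, param)
            mem = [m for m in c.truth
                   if (m.kcat if param == "kcat" else m.km) is not None]
            assert len(entries) == len(mem)
            for e, m in zip(entries, mem):
                q = m.kcat if param == "kcat" else m.km
                assert e.key == m.entry_key()
                assert e.value == q.canonical_value  # exact, not approximate


def test_write_corpus_and_reload(tmp_path):
    c = make_corpus(n_docs=8, seed=28, sci_notation=0.3)
    synth.write_corpus(c, tmp_path)
    docs = load_manifest(tmp_path / "manifest.csv")
    assert len(docs) == 8
    by_id = {sd.document.doc_id: sd for sd in c.docs}
    for doc in docs:
        sd = by_id[doc.doc_id]
        assert doc.full_text == sd.document.full_text
        # reparsed tables equal the rendered (display) table
        assert doc.tables[0].header == sd.display_table.header
        assert doc.tables[0].rows == sd.display_table.rows


def test_impossible_spec_rejected():
    with pytest.raises(ValueError):
        synth.generate_corpus(synth.CorpusSpec(rows_per_doc=(5, 2)))
    with pytest.raises(ValueError):
        synth.generate_corpus(synth.CorpusSpec(
            corruption_rates={"glyph_swap": 1.5}))
    with pytest.raises(ValueError):
        synth.generate_corpus(synth.CorpusSpec(kcat_bounds=(2.0, 1.0)))


def test_typo_injection_stays_matchable():
    spec = synth.CorpusSpec(n_docs=30, seed=29, typo_rate=1.0,
                            corruption_rates=dict(ZERO_RATES))
    c = synth.generate_corpus(spec)
    printed = set()
    for sd in c.docs:
        truth_enzyme = sd.truth[0].enzyme_name
        header_line = sd.document.full_text.splitlines()[0]
        printed_enzyme = header_line.removeprefix(
            "# Kinetic characterization of ").rsplit(" from ", 1)[0]
        printed.add(printed_enzyme != truth_enzyme)
        assert name_similarity(normalize_name(printed_enzyme),
                               normalize_name(truth_enzyme)) >= 0.90
    assert True in printed  # typos actually happened somewhere
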