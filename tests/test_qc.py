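"""Curation filters: duplicates, empties, hallucination, repetition,
scientific notation; threshold boundaries and conservation."""

import math

import pytest

from kinlit.corpus import DocumentRecord, parse_markdown
from kinlit.extraction import reference_extract
from kinlit.qc import QCConfig, curate, flag_hallucination, flag_repetition
from kinlit.records import KineticMeasurement, Provenance
from kinlit.units import parse_quantity

from conftest import make_corpus


def _doc_with_values(values, doc_id="d1"):
    body = "\n".join(f"| s{i} | {v} |" for i, v in enumerate(values))
    text = f"| Substrate | kcat (s−1) |\n| --- | --- |\n{body}\n"
    return parse_markdown(text, doc_id)


def _measurements(values, doc_id="d1"):
    out = []
    for i, v in enumerate(values):
        out.append(KineticMeasurement(
            enzyme_name="e", organism="o", substrate_name=f"s{i}",
            kcat=parse_quantity(f"{v} s^-1", "rate"),
            provenance=Provenance(doc_id=doc_id, row_index=i)))
    return out


class TestHallucinationFlag:
    def test_all_found_not_flagged(self):
        vals = [f"{i}.5" for i in range(10)]
        doc = _doc_with_values(vals)
        assert flag_hallucination(doc, _measurements(vals)) is False

    def test_none_found_flagged(self):
        doc = _doc_with_values(["1.1"] * 10)
        ms = _measurements([f"{i + 100}.9" for i in range(10)])
        assert flag_hallucination(doc, ms) is True

    def test_strict_threshold_boundary(self):
        """4 of 10 found -> flagged; exactly 5 of 10 -> kept (strict <)."""
        in_text = [f"{i}.5" for i in range(5)]
        absent = [f"{i + 50}.9" for i in range(5)]
        doc = _doc_with_values(in_text)
        assert flag_hallucination(doc, _measurements(in_text[:4] + absent + ["999.1"])) is True
        assert flag_hallucination(doc, _measurements(in_text + absent)) is False

    def test_no_values_warns_not_flags(self, caplog):
        doc = _doc_with_values(["1.0"])
        m = KineticMeasurement(enzyme_name="e", substrate_name="s",
                               provenance=Provenance(doc_id="d1"))
        with caplog.at_level("WARNING"):
            assert flag_hallucination(doc, [m]) is False
        assert any("no extracted numeric" in r.message for r in caplog.records)


class TestRepetitionFlag:
    def test_ten_copies_flagged(self):
        assert flag_repetition(_measurements(["3.2"] * 10)) is True

    def test_ten_distinct_not_flagged(self):
        assert flag_repetition(_measurements([f"{i}.1" for i in range(10)])) is False

    def test_boundary_is_strict(self):
        """3 distinct among 10 gives fraction 0.3, not < 0.3 -> kept."""
        vals = ["1.1"] * 4 + ["2.2"] * 3 + ["3.3"] * 3
        assert flag_repetition(_measurements(vals)) is False
        vals2 = ["1.1"] * 5 + ["2.2"] * 5  # 2/10 < 0.3
        assert flag_repetition(_measurements(vals2)) is True

    def test_empty_list_not_flagged(self):
        assert flag_repetition([]) is False


class TestCurate:
    def test_exact_duplicates_removed(self):
        vals = ["1.5", "2.5"]
        doc = _doc_with_values(vals)
        ms = _measurements(vals) + _measurements(vals)[:1]
        kept, rep = curate(ms, [doc])
        assert rep.n_duplicates == 1
        assert rep.n_kept == 2

    def test_empty_rows_dropped(self):
        doc = _doc_with_values(["1.5"])
        empty = KineticMeasurement(ph=7.0, provenance=Provenance(doc_id="d1", row_index=9))
        kept, rep = curate(_measurements(["1.5"]) + [empty], [doc])
        assert rep.n_empty == 1
        assert all(not m.is_empty_row for m in kept)

    def test_xml_preferred_over_pdf(self):
        doc = _doc_with_values(["1.5", "2.5"])
        pdf = _measurements(["1.5", "2.5"])
        for m in pdf:
            m.provenance.source_format = "pdf_text"
        xml = _measurements(["1.5", "2.5"])
        for m in xml:
            m.provenance.source_format = "xml"
        kept, rep = curate(pdf + xml, [doc])
        assert rep.n_format_dedup == 2
        assert {m.provenance.source_format for m in kept} == {"xml"}

    def test_sci_notation_rows_flagged_and_excluded(self):
        text = ("| Substrate | kcat (s−1) |\n| --- | --- |\n"
                "| s0 | 2.5 × 10^3 |\n| s1 | 4.2 |\n")
        doc = parse_markdown(text, "d1")
        ms = [r.to_measurement() for r in reference_extract(doc)]
        kept, rep = curate(ms, [doc])
        assert rep.n_sci_notation_rows == 1
        assert len(kept) == 1 and kept[0].kcat.value == 4.2
        kept2, rep2 = curate(ms, [doc], QCConfig(exclude_flagged=False))
        assert rep2.n_kept == 2 and rep2.n_excluded == 0

    def test_conservation_ledger(self):
        corpus = make_corpus(n_docs=40, seed=7, sci_notation=0.2,
                             hallucinate_value=0.1, repeat_value=0.1)
        ms = [r.to_measurement() for sd in corpus.docs
              for r in reference_extract(sd.document)]
        kept, rep = curate(ms, corpus.documents)
        assert rep.n_input == len(ms)
        assert rep.n_kept == (rep.n_input - rep.n_duplicates - rep.n_format_dedup
                              - rep.n_empty - rep.n_excluded)

    def test_idempotent(self):
        corpus = make_corpus(n_docs=40, seed=8, sci_notation=0.15,
                             hallucinate_value=0.1, repeat_value=0.1)
        ms = [r.to_measurement() for sd in corpus.docs
              for r in reference_extract(sd.document)]
        kept, rep = curate(ms, corpus.documents)
        kept2, rep2 = curate(kept, corpus.documents)
        assert len(kept2) == len(kept)
        assert rep2.n_duplicates == rep2.n_empty == rep2.n_excluded == 0

    def test_flag_counts_independent_and_overlapping(self):
        """A row may carry several flags; tallies are independent."""
        corpus = make_corpus(n_docs=60, seed=9, sci_notation=0.3, repeat_value=0.5)
        ms = [r.to_measurement() for sd in corpus.docs
              for r in reference_extract(sd.document)]
        _, rep = curate(ms, corpus.documents)
        assert rep.n_sci_notation_rows > 0 and rep.n_repetitive_rows > 0
        assert rep.n_excluded <= rep.n_sci_notation_rows + rep.n_repetitive_rows \
            + rep.n_hallucinated_rows


def _binomial_3sigma(n, p):
    return 3 * math.sqrt(n * p * (1 - p))


class TestCorruptionRateRecovery:
    """Injected corruption rates are recovered by the QC tallies within
    3 sigma of the corresponding binomial count."""

    def test_sci_notation_rate(self):
        rate = 0.1
        corpus = make_corpus(n_docs=200, seed=10, sci_notation=rate)
        ms = [r.to_measurement() for sd in corpus.docs
              for r in reference_extract(sd.document)]
        _, rep = curate(ms, corpus.documents)
        n = rep.n_input
        assert abs(rep.n_sci_notation_rows - n * rate) <= _binomial_3sigma(n, rate)

    def test_hallucination_rate_via_grounding_ledger(self):
        rate = 0.1
        corpus = make_corpus(n_docs=200, seed=11, hallucinate_value=rate)
        ms = [r.to_measurement() for sd in corpus.docs
              for r in reference_extract(sd.document)]
        _, rep = curate(ms, corpus.documents)
        # one kinetic cell per selected row is perturbed -> per-row binomial
        n = rep.n_input
        assert n >= 1000
        assert abs(rep.n_values_not_found - n * rate) <= _binomial_3sigma(n, rate)

    def test_repetition_rate_per_document(self):
        rate = 0.3
        corpus = make_corpus(n_docs=200, seed=12, repeat_value=rate)
        ms = [r.to_measurement() for sd in corpus.docs
              for r in reference_extract(sd.document)]
        _, rep = curate(ms, corpus.documents)
        n_flagged_docs = sum(d["repetitive"] for d in rep.per_doc.values())
        n = len(corpus.docs)
        assert abs(n_flagged_docs - n * rate) <= _binomial_3sigma(n, rate)
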