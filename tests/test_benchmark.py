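"""Alignment-and-classification benchmark: similarity metric, optimal
assignment vs brute force, TP/FP/FN/Unresolved semantics, Table-style
accuracy/precision."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinlit.benchmark import (
    AlignmentConfig,
    BenchmarkEntry,
    align_entries,
    classify,
    entries_from_measurements,
    levenshtein,
    load_ground_truth,
    metrics,
    name_similarity,
    run_benchmark,
)
from kinlit.records import EntryKey


def _entry(enzyme="hexokinase", mutation="", substrate="glucose",
           organism="saccharomyces cerevisiae", smiles="", value=1.0):
    return BenchmarkEntry(key=EntryKey.from_fields(enzyme, mutation, substrate, organism),
                          smiles=smiles, value=value)


class TestSimilarity:
    @pytest.mark.parametrize("a,b,expected", [
        ("glucose", "glucose", 1.0),
        ("lactase", "lactate", 6 / 7),
        ("", "", 1.0),
        ("abc", "", 0.0),
    ])
    def test_examples(self, a, b, expected):
        assert name_similarity(a, b) == pytest.approx(expected)

    def test_normalization_forces_identity(self):
        k = EntryKey.from_fields("Glucose ", "", "", "")
        assert name_similarity(k.enzyme_name_norm, "glucose") == 1.0

    @settings(deadline=None, max_examples=200)
    @given(st.text(max_size=24), st.text(max_size=24))
    def test_symmetric_and_bounded(self, a, b):
        s = name_similarity(a, b)
        assert s == name_similarity(b, a)
        assert 0.0 <= s <= 1.0

    @settings(deadline=None, max_examples=150)
    @given(st.text(alphabet=st.characters(min_codepoint=32, max_codepoint=126),
                   min_size=1, max_size=16),
           st.text(alphabet=st.characters(min_codepoint=32, max_codepoint=126),
                   min_size=1, max_size=16))
    def test_levenshtein_matches_edlib(self, a, b):
        """Cross-check the DP edit distance against an independent
        implementation."""
        edlib = pytest.importorskip("edlib")
        assert levenshtein(a, b) == edlib.align(a, b)["editDistance"]


class TestMetrics:
    @pytest.mark.parametrize("tp,fp,fn,acc,prec", [
        (301, 59, 17, 0.80, 0.84),
        (486, 127, 26, 0.76, 0.79),
        (80, 16, 23, 0.67, 0.83),
        (1134, 314, 9, 0.78, 0.78),
        (10, 0, 0, 1.00, 1.00),
    ])
    def test_reported_count_sets(self, tp, fp, fn, acc, prec):
        a, p = metrics(tp, fp, fn)
        assert round(a, 2) == acc
        assert round(p, 2) == prec

    def test_zero_denominators(self):
        assert metrics(0, 0, 0) == (0.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            metrics(-1, 0, 0)

    @settings(deadline=None, max_examples=300)
    @given(st.integers(0, 10_000), st.integers(0, 10_000), st.integers(0, 10_000))
    def test_accuracy_never_exceeds_precision(self, tp, fp, fn):
        a, p = metrics(tp, fp, fn)
        assert a <= p + 1e-15


def _brute_force_best(score, admissible):
    """Maximum total score over all one-to-one pairings (oracle)."""
    n, m = score.shape
    best = 0.0
    cols = range(m)
    for k in range(0, min(n, m) + 1):
        for rows in itertools.combinations(range(n), k):
            for perm in itertools.permutations(cols, k):
                if all(admissible[i, j] for i, j in zip(rows, perm)):
                    best = max(best, sum(score[i, j] for i, j in zip(rows, perm)))
    return best


class TestAlignment:
    def test_crossed_similarities_pick_max_sum(self):
        """p1-t2 and p2-t1 score higher jointly than the greedy p1-t1."""
        preds = [_entry(enzyme="glucose oxidase aa"), _entry(enzyme="glucose oxidase bb")]
        truths = [_entry(enzyme="glucose oxidase bb"), _entry(enzyme="glucose oxidase aa")]
        matched, up, ut = align_entries(preds, truths)
        assert {(i, j) for i, j, _ in matched} == {(0, 1), (1, 0)}
        assert up == [] and ut == []

    def test_below_threshold_inadmissible(self):
        pred = [_entry(enzyme="abcdefghij")]
        truth = [_entry(enzyme="abcdefgzzz")]  # similarity 0.7
        matched, up, ut = align_entries(pred, truth)
        assert matched == [] and up == [0] and ut == [0]

    def test_mutation_mismatch_inadmissible(self):
        matched, _, _ = align_entries([_entry(mutation="A123G")], [_entry(mutation="")])
        assert matched == []

    def test_smiles_identity_substitutes_for_name(self):
        p = [_entry(substrate="D-glucose", smiles="OCC1OC(O)C(O)C(O)C1O")]
        t = [_entry(substrate="dextrose", smiles="C(C1C(C(C(C(O1)O)O)O)O)O")]
        rdkit = pytest.importorskip("rdkit")
        matched, _, _ = align_entries(p, t)
        assert len(matched) == 1  # same molecule, different SMILES spellings

    def test_identical_lists_perfect_matching(self):
        entries = [_entry(substrate=s) for s in ("glucose", "urea", "maltose")]
        matched, up, ut = align_entries(entries, entries)
        assert len(matched) == 3 and not up and not ut

    def test_assignment_optimal_vs_brute_force(self):
        """Total assigned score equals exhaustive enumeration on random
        instances up to 6x6."""
        rng = np.random.default_rng(42)
        sim_cache = {}

        for trial in range(60):
            n, m = rng.integers(1, 7, size=2)
            score = np.round(rng.uniform(0.9, 1.0, size=(n, m)), 3)
            admissible = rng.random((n, m)) < 0.6
            score = score * admissible

            # feed align_entries through an injected similarity function
            pred = [_entry(enzyme=f"p{i}", substrate="s") for i in range(n)]
            truth = [_entry(enzyme=f"t{j}", substrate="s") for j in range(m)]

            def sim(a, b, _s=score, _adm=admissible):
                if a.startswith("p") and b.startswith("t"):
                    i, j = int(a[1:]), int(b[1:])
                elif a.startswith("t") and b.startswith("p"):
                    j, i = int(a[1:]), int(b[1:])
                else:
                    return 1.0  # organism comparison
                return float(_s[i, j]) if _adm[i, j] else 0.0

            cfg = AlignmentConfig(similarity_fn=sim, name_similarity_threshold=0.9)
            matched, _, _ = align_entries(pred, truth, cfg)
            total = sum(s for _, _, s in matched)
            # composite = (enzyme_sim + organism_sim)/2 = (score + 1)/2
            comp = (score + 1.0) / 2.0 * admissible
            best = _brute_force_best(comp, admissible)
            assert total == pytest.approx(best, abs=1e-9)


class TestClassify:
    def test_off_by_1000(self):
        matched = [(_entry(value=300.0), _entry(value=0.3))]
        rep = classify(matched, [], [])
        assert (rep.fp, rep.off_by_1000) == (1, 1)

    def test_off_by_both_directions(self):
        matched = [(_entry(value=0.3), _entry(value=300.0)),
                   (_entry(value=42.0), _entry(value=4.2))]
        rep = classify(matched, [], [])
        assert rep.off_by_1000 == 1 and rep.off_by_10 == 1

    def test_missing_pred_value_is_fn(self):
        rep = classify([(_entry(value=None), _entry(value=1.0))], [], [])
        assert rep.fn == 1 and rep.fp == 0

    def test_unmatched_truth_is_unresolved(self):
        rep = classify([], [], [_entry(value=1.0)])
        assert rep.unresolved == 1 and rep.fp == rep.fn == 0

    def test_unmatched_pred_with_value_is_fp(self):
        rep = classify([], [_entry(value=1.0)], [])
        assert rep.fp == 1

    def test_value_within_one_percent_is_tp(self):
        rep = classify([(_entry(value=1.009), _entry(value=1.0))], [], [])
        assert rep.tp == 1
        rep2 = classify([(_entry(value=1.02), _entry(value=1.0))], [], [])
        assert rep2.fp == 1

    def test_off_by_counts_are_subset_of_fp(self):
        matched = [(_entry(value=v), _entry(value=1.0))
                   for v in (10.0, 100.0, 1000.0, 3.0)]
        rep = classify(matched, [], [])
        assert rep.off_by_10 + rep.off_by_100 + rep.off_by_1000 <= rep.fp == 4

    def test_conservation_ledger(self):
        """Every truth entry and every valued unmatched pred lands in
        exactly one of TP/FP/FN/Unresolved."""
        matched = [(_entry(value=1.0), _entry(value=1.0)),
                   (_entry(value=None), _entry(value=2.0)),
                   (_entry(value=30.0), _entry(value=3.0))]
        up = [_entry(value=9.0)]
        ut = [_entry(value=4.0)]
        rep = classify(matched, up, ut)
        assert rep.tp + rep.fp + rep.fn + rep.unresolved == len(matched) + len(up) + len(ut)


def test_self_benchmark_is_perfect(clean_measurements):
    """Any entry list benchmarked against itself gives accuracy =
    precision = 1 with zero FP/FN/Unresolved."""
    entries = entries_from_measurements(clean_measurements, "kcat")
    rep = run_benchmark(entries, entries)
    assert rep.fp == rep.fn == rep.unresolved == 0
    assert rep.accuracy == rep.precision == 1.0


def test_ground_truth_loader_canonicalizes(tmp_path):
    csv = tmp_path / "truth.csv"
    csv.write_text(
        "enzyme,mutation,substrate,organism,smiles,value,unit,parameter\n"
        "urease,,urea,jack bean,,120,min^-1,kcat\n"
        "urease,,urea,jack bean,,2.9,mM,km\n")
    kcat = load_ground_truth(csv, "kcat")
    km = load_ground_truth(csv, "km")
    assert len(kcat) == len(km) == 1
    assert kcat[0].value == pytest.approx(2.0)
    assert km[0].value == pytest.approx(2.9e-3)
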