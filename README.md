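# kinlit

Tools for mining, curating and benchmarking enzyme kinetic constants
(k<sub>cat</sub>, K<sub>m</sub>) from literature-style tables.

Most published enzyme kinetics never reaches a structured database: the
turnover number k<sub>cat</sub> (s⁻¹), the Michaelis constant
K<sub>m</sub> (molar), the enzyme, organism, mutation, substrate, pH and
temperature sit in heterogeneous tables inside papers. Automated
extraction of those tables — increasingly done with generative language
models — introduces failure modes of its own: invented ("hallucinated")
numbers, degenerate repetitive output, misread exponent signs in
scientific notation, and the notorious μ/m prefix confusion that shifts
a concentration by a factor of exactly 10³. `kinlit` implements the
deterministic stages of such a pipeline, with a pluggable extraction
backend and a ground-truthed synthetic corpus so every stage is testable
offline — no language model, no web services, no harvested PDFs.

## What is in the box

| module | role |
| --- | --- |
| `kinlit.corpus` | Markdown/XML fixture documents; standalone-numeric-token search |
| `kinlit.units` | unit-dialect parsing; canonicalization to s⁻¹ / M; ambiguity flags |
| `kinlit.extraction` | backend contract + deterministic reference table extractor |
| `kinlit.qc` | duplicate/empty removal; hallucination, repetition, sci-notation flags |
| `kinlit.resolver` | offline name→sequence / name→SMILES lookups; confidence tiers |
| `kinlit.benchmark` | key alignment by linear sum assignment; TP/FP/FN/Unresolved; off-by-10^k |
| `kinlit.concordance` | paired log10 statistics; fixed-offset (unit-error) cluster detection |
| `kinlit.glyphs` | synthetic glyph renderer + trainable m/μ/other classifier |
| `kinlit.synth` | corpus generator with controlled, logged, reversible corruptions |
| `kinlit.database` | database compilation and summary statistics; hosts the CLI |

### The validation model

Extracted entries are matched to ground truth on the entry key
(enzyme, mutation, substrate, organism). A pred/truth pair is
*admissible* when enzyme and organism names each reach 90% normalized
edit-distance similarity, the substrate matches exactly by name or by
identical canonical SMILES, and the mutation strings agree. Among
admissible pairs, a one-to-one assignment maximizing total similarity is
chosen by linear sum assignment. Matched pairs are then scored on the
canonicalized values:

- **TP** — |log₁₀(v_pred/v_truth)| ≤ log₁₀(1.01) (1% relative tolerance);
- **FN** — matched key, no extracted value;
- **FP** — matched key, disagreeing value (tallied *off-by-10^k* when the
  log₁₀ discrepancy is within 0.05 of k ∈ {1,2,3}), plus key-less
  extractions;
- **Unresolved** — truth entries with no admissible partner (excluded from
  the denominators).

Accuracy = TP/(TP+FP+FN); Precision = TP/(TP+FP).

## Worked example

```python
from kinlit import synth
from kinlit.extraction import reference_extract
from kinlit.qc import curate
from kinlit.benchmark import (AlignmentConfig, entries_from_measurements,
                              load_ground_truth, run_benchmark)

# 50 synthetic papers; the micro/milli glyph swap injected everywhere
rates = {k: 0.0 for k in synth.CORRUPTION_KINDS}
rates["glyph_swap"] = 1.0
corpus = synth.generate_corpus(synth.CorpusSpec(n_docs=50, seed=7,
                                                corruption_rates=rates))

measurements = [raw.to_measurement() for sd in corpus.docs
                for raw in reference_extract(sd.document)]
synth.emit_ground_truth(corpus).to_csv("truth.csv", index=False)

pred = entries_from_measurements(measurements, "km")
truth = load_ground_truth("truth.csv", "km")
report = run_benchmark(pred, truth, AlignmentConfig(parameter="km"))
print(report.to_json())
```

prints

```json
{
  "accuracy": 0.15165876777251186,
  "fn": 0,
  "fp": 179,
  "off_by_10": 0,
  "off_by_100": 0,
  "off_by_1000": 179,
  "precision": 0.15165876777251186,
  "tp": 32,
  "unresolved": 0
}
```

Every Km printed with a swappable micro/milli prefix (179 of the 211
ground-truth Km entries) comes back wrong by exactly a factor of 1000
and is tallied under `off_by_1000`; rows whose units carry no confusable
prefix (nM, M) survive as true positives. This is the factor-1000 signature that the
glyph classifier (`kinlit.glyphs`) and the concordance offset detector
(`kinlit.concordance`, offsets ±3 and ±log₁₀60) are built to catch.

The same stages are available from the shell:

```bash
kinlit synth --out corpus/ --n-docs 50 --seed 7
kinlit extract --corpus corpus/ --backend reference --out records.jsonl
kinlit qc --records records.jsonl --corpus corpus/ --out kept.jsonl
kinlit benchmark --pred kept.jsonl --truth corpus/ground_truth.csv --param km
```

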