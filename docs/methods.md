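# Methods

This note documents the models, parameter choices and numerical
decisions behind `kinlit`, and what the synthetic-data results do and do
not show about real literature mining.

## Scope and assumptions

`kinlit` implements the *deterministic* stages of a kinetics-mining
pipeline: unit canonicalization, quality filtering, identity resolution
with confidence tiers, assignment-based validation, concordance
analysis, glyph disambiguation, and database compilation. The
generative extraction step itself is represented by a contract
(`ExtractorBackend`) plus a deterministic reference backend that maps
table columns to roles via a header-synonym lexicon. Everything runs
offline; web resources (UniProt, PubChem) appear only as lookup
contracts backed by TSV fixture tables.

Modeling assumptions: one substrate and at most one site mutation per
record; k<sub>cat</sub> canonicalizes to s⁻¹ and K<sub>m</sub> to molar
(the molar choice over millimolar is arbitrary but fixed and documented
in the schema); values are compared in log10 space throughout.

## Unit engine

Accepted dialects: rates {`s^-1`, `s−1`, `/s`, `1/s`, `sec^-1`,
`min^-1`, `/min`, `1/min`, superscript forms}; concentrations {`M`,
`mM`, `μM`/`µM`/`uM`, `nM`, `mol/L` with the same prefixes}. The
minute→second conversion is exactly 1/60. Scientific notation
(`2.5 × 10^3`, e-notation, superscript exponents) is parsed at face
value and *flagged*, never dropped — exclusion is the curation layer's
decision. Decimal commas are unsupported; thousands separators are
stripped. Units outside the two canonical kinds (e.g. per-mg specific
activity) parse to `base_unit = unknown` and refuse canonicalization.
The confusable prefix set is {m, μ, µ, u}; any of these sets
`glyph_ambiguous`.

## Quality filters

Three document/row-level checks mirror the failure modes of generative
extraction:

- **Hallucination** (document-level): the fraction of extracted kinetic
  value strings locatable in the document text as standalone numeric
  tokens (word-boundary semantics, comma/typography-normalized) must be
  ≥ 0.5; below that (strict `<`) the whole document's rows are flagged.
- **Repetition** (document-level): the fraction of *distinct* value
  strings must be ≥ 0.3.
- **Scientific notation** (row-level): flagged from the parse.

The two thresholds are not prescribed anywhere authoritative; 0.5 and
0.3 were chosen once so that clean synthetic documents are never flagged
while fully corrupted ones always are, and both are configurable in
`QCConfig`. Only kinetic values (not pH/temperature) enter the
statistics. Scientific-notation values are excluded from the
document-level fractions: they are already marked row-wise, and keeping
them out makes `curate` idempotent — a second pass scores exactly the
value population the first pass left behind. Flag categories may
overlap; tallies are independent (and therefore non-additive). For
doubly ingested documents (same DOI in PDF and XML form) the XML rows
are kept, since XML carries native markup.

## Benchmark

String similarity is 1 − d/max(|a|,|b|) with d the unit-cost character
edit distance, computed on key-normalized strings (NFKC, lower-case,
collapsed whitespace, edge punctuation stripped, Greek preserved). The
metric is injectable. The admissibility threshold is 0.90 for both
enzyme and organism; substrates must match exactly by normalized name or
by identical canonical SMILES (RDKit canonicalization when the string
parses, byte equality otherwise); mutation strings must agree because
the entry key includes the mutation identifier. Optimal pairing uses
`scipy.optimize.linear_sum_assignment` (maximize the mean of enzyme and
organism similarities); inadmissible cells carry weight 0 and are
discarded after assignment, which preserves optimality because all
admissible weights are positive.

Value agreement uses a 1% relative tolerance after canonicalization, to
absorb printed rounding. Off-by-10^k tallies (k = 1, 2, 3) use a 0.05
log10 tolerance, count both directions, and are a subset of FP.
Unresolved counts truth-side entries only; key-less extractions with a
value land in FP, and an extracted entry *without* a value asserts
nothing and is not penalized when unmatched.

## Concordance

Pearson/Spearman (mid-ranks for ties) via `scipy.stats`, plus MAD and
RMSD of the log10 differences (MAD ≤ RMSD by the power-mean inequality —
a property test). Fixed-offset clusters use candidate offsets ±log₁₀60
(s⁻¹/min⁻¹ confusion) and ±3 (micro/milli swap), membership tolerance
0.15 log units, minimum cluster size 5; all three are configurable since
no authoritative quantification exists for them.

## Synthetic corpus

The generator emulates papers whose single kinetics table carries
enzyme/organism (as columns or as document-level statements), optional
mutation, substrate, k<sub>cat</sub>, K<sub>m</sub>, pH and temperature.
Study conditions:

- log₁₀ k<sub>cat</sub> ~ N(0.8, 1.5) truncated to [−5.8, 5.3] (s⁻¹);
  log₁₀ K<sub>m</sub> ~ N(−4.2, 1.2) truncated to [−5.5, 4.5] (M). The
  truncation bounds are the observed ranges of large mined corpora; the
  means/SDs are plausibility choices within the approximately Gaussian
  shapes such corpora show.
- pH ~ N(7.2, 1.0) clipped to [2, 12]; temperature ~ N(25.9, 8) °C
  clipped to [0, 100] — matching the reported corpus means and spans.
- 23% of rows lack K<sub>m</sub> (the approximate deficit of
  K<sub>m</sub> relative to k<sub>cat</sub> counts in mined data).
- Default corruption rates follow the reported flagged fractions where
  one exists: hallucination 0.071, repetition 0.044 (per document),
  scientific notation 0.096; the two unit swaps are unquantified in the
  source material and default to 0.01 each.

Each document uses one enzyme–organism pair, drawn without replacement,
and substrates drawn without replacement within the document, so entry
keys are globally unique — distinct keys can never be cross-admissible
(the enzyme name pool is verified pairwise < 0.85 similarity). Printed
values use 4 significant digits; ground truth is derived from the
*printed* value, so extraction on a clean corpus reproduces the truth
exactly.

Corruption mechanics worth knowing:

- `sci_notation` rewrites the printed decimal digit-exactly as mantissa
  × 10^k (value-preserving) on both the rendered text and the structured
  table.
- `glyph_swap` / `rate_unit_swap` change the printed unit on both sides;
  when units live in the table header, the swapped unit is written into
  the cell, which takes precedence over the header on extraction (mixed
  units within a column, as happens in real tables).
- `hallucinate_value` perturbs one kinetic cell of the *structured*
  table only, verifying the new number is absent from the rendered text
  — the extractor's view diverges from the document, which is precisely
  the hallucination failure mode. A corpus written to disk and re-read
  is therefore self-consistent and loses this corruption; hallucination
  experiments run on the in-memory corpus.
- `repeat_value` copies one document value across all the document's
  kinetic cells on the extraction side (per-document probability).

Every corruption is logged with before/after cell contents; replaying
the log in reverse restores the clean corpus byte-identically (tested
against a fresh clean generation — content and corruption use
independent random streams spawned from one seed).

What the synthetic corpus does **not** model: PDF layout and OCR noise,
multi-table papers, free-text kinetic sentences, inconsistent reporting
of the same measurement across papers, and real-world name ambiguity
beyond single-character typos. Passing benchmarks here demonstrates the
pipeline's bookkeeping and unit algebra are sound, not that any
particular language model extracts well.

## Glyph classifier

The disambiguator is a compact multilayer perceptron (one hidden layer
of 128 units) over 32×32 grayscale crops, trained with Adam at learning
rate 0.001 for 10 epochs (batch 32) — a desk-scale architecture; the
estimator is injectable for anyone wanting a convolutional or
transfer-learning variant. Synthetic crops are rendered from the DejaVu
font family (sans, serif, mono) at 16–24 pt with ±5° rotation, 2×
downsampling and Gaussian pixel noise; classes are m, μ/µ, and a
confusable "other" set (u, n, w, h, rn) whose composition is a guess.
On the 1500/600 synthetic benchmark the held-out accuracy is ≥ 0.99.
That number speaks to the synthetic render distribution only; accuracy
on glyphs cropped from scanned PDFs would require a labeled real-world
symbol set. The pipeline consumes the classifier's output only through
the `glyph_ambiguous` flag pathway; correcting a μ→m misread changes a
canonical K<sub>m</sub> by exactly 10³.

## Numerical and degenerate-input conventions

- Correlations on fewer than two pairs, or constant vectors, are NaN;
  deviations are still computed.
- `metrics(0,0,0)` returns (0, 0) rather than raising.
- Validation never raises: out-of-range pH is an error-level violation,
  temperature outside the observed 0–100 °C span but within [−20, 150]
  is a warning (observed spans are not validity bounds).
- Quality flags are monotone: curation can set but never clear them.
- Database builds sort by (doc_id, row_index) and are byte-deterministic.

## Problem sizes

Test and acceptance runs use 8–200 synthetic documents (roughly 40–1100
rows), 200 random assignment instances up to 6×6 against brute-force
enumeration, and the 1500/600 glyph benchmark — sizes chosen so the full
suite exercises every statistical claim (binomial 3σ checks need ≥ 1000
rows) while staying desk-scale.
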