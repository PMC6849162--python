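# Methods

## The matching model

`farmatch` treats recognition of a misspelt drug name as a two-score
decision problem. For a canonical name *d* and a token *w* it computes

* `StringSim(d, w) = 1 − ED(d, w) / max(|d|, |w|)`, with `ED` plain
  Levenshtein distance (unit-cost insertions, deletions, substitutions).
  There is no transposition operation: an adjacent swap such as
  "fluoxetina" → "fluxoetina" costs 2. Max-length normalization keeps the
  score in [0, 1] and makes it 1 exactly on identity.
* `PhoneticSim(d, w)`: the same normalized edit distance computed between
  the phoneme-symbol sequences of the two words, each symbol counting as
  one editable unit.

A token is accepted as a variant of *d* iff both scores clear their
respective cutoffs (`PhoneticSim ≥ θ_p` and `StringSim ≥ θ_s`). The
conjunction is deliberate: the phonetic channel is generous (whole
homophone classes collapse), and the string channel acts as a
complementary filter that keeps phonetically identical but orthographically
distant words out.

Underlying distance computations are delegated to edlib; the test suite
checks them against an independent recursive Levenshtein oracle.

## Phonetic encoding

The encoder is an ordered table of rewrite rules
(`src/farmatch/data/phonetic_rules_pt.json`, version 1): pattern, optional
left/right letter context, emitted symbols. Scanning is left-to-right,
first applicable rule wins. The closed symbol alphabet is
A E I O U B D F G J K L M N P R S T V Z SH LH NH RR; vowel symbols are
flagged vocalic, everything else consonantal.

Main rule groups: silent `h`; digraphs `ch`→SH, `lh`→LH, `nh`→NH, `ss`→S,
`rr`→RR; sibilant merges (`ç`→S, `c`→S before e/i else K, intervocalic
`s`→Z, word-final `z`→S); `g`→J before e/i; `qu`/`gu` digraph handling;
`x`→SH word-initially and after a consonant, K+S otherwise (the
"fluoxetina" case); nasal codas `m`/`n` before a consonant or word-finally
merge into a single N; `w`→V, `y`→I, `k`→K. Two degemination steps make
doubled spellings collapse: a run of one repeated letter is consumed by a
single rule application, and adjacent identical *symbols* merge afterwards.
The second step is what makes "fluoxetiina" a true homophone of
"fluoxetina" and keeps silent-`h` removal between equal vowels
("bahia"-style spellings) encoding-invariant.

This table is an explicit, versioned approximation of Brazilian Portuguese
orthography designed for misspelling robustness. It is **not** an IPA
transcription: stress, vowel quality (open/closed e, o) and syllable
structure are ignored, and the published similarity metrics it stands in
for were never released in rule form, so absolute threshold values found
with this encoder need not coincide with values tuned under other
encoders. A caller can supply a replacement table (`--phonetic-rules` /
`PhoneticEncoder(path)`).

Normalization lowercases, strips every diacritic except the cedilla (kept
because `ç` is phonemically informative; misspellings routinely drop other
accents) and removes non-letters. A token with no letters left raises
`DegenerateTokenError`.

Because `x` expands to two symbols, a phoneme sequence can be slightly
longer than its source word; it is bounded by word length plus the number
of `x` characters.

## Candidate blocking and filtering

A vocabulary word enters the candidate list of a drug when it shares **at
least 3 consonantal phonemes in order** with the drug or lies within
**edit distance 3** of it. The consonant count is the longest common
subsequence of the two consonantal phoneme sequences — order-preserving,
so anagrams do not inflate it (a multiset mode is available via
`ordered=False`). Tokens shorter than 4 letters are never blocked: at
these lengths an ED ≤ 3 ball covers most of the vocabulary. An optional
string-similarity pre-filter (default cutoff 0.6, read as a *lower*
bound) reproduces the deliberately permissive candidate-collection stage
that feeds manual labelling.

## Threshold tuning

`grid_search(train, valid, grid)` walks the grid **in input order** and
replaces the incumbent only when a candidate threshold pair *strictly*
improves the F1-score on both the training and the validation pairs
simultaneously; ties never replace. The train/validation split is by drug
(the seeded `random_drug_split` gives a 10/10 split of the default
20-name list). Grid points where F1 is undefined (no true positive) are
skipped; if every point is undefined, `TuningFailureError` is raised.

The default grid is the Cartesian product of phonetic cutoffs
{0.50, 0.505, …, 1.00} with string cutoffs {0} ∪ {0.50, 0.505, …, 1.00}
(10 302 pairs). Including `θ_s = 0` keeps the phonetic-only configuration
reachable. All comparisons are inclusive (≥). Metrics are kept at full
float precision internally; three-decimal rounding happens only in
reports. Per-point confusion counts are computed vectorized over the whole
grid, so a full search on ~1 200 labelled pairs takes well under a second.

The same procedure is packaged as `HybridThresholdClassifier`, a
scikit-learn estimator over feature rows `[phonetic_sim, string_sim]`
(fit = grid search, predict = joint-threshold rule), so it composes with
sklearn pipelines and model selection.

`build_variant_dictionary` applies block → (optional pre-filter) →
classify at the tuned thresholds and maps every accepted variant to its
canonical name. A variant claimed by several drugs keeps the highest
(phonetic, string) similarity, ties broken by lexicographic canonical
name; a variant equal to a canonical name always maps to itself.

## Trie-based fuzzy lookup

The variant dictionary is indexed in a character trie. A lookup propagates
one Levenshtein DP row down each edge and abandons a subtree as soon as
the row minimum exceeds the bound, which shares work across common
prefixes; `max_ed = 0` short-circuits to a hash lookup. Results carry
their true distance and are sorted by (distance, entry). The bound is
capped at 3 and lookups above 1 log a performance warning — pruning loses
most of its effect beyond ED 2. Correctness is established in the tests by
exact equivalence with a brute-force edit-distance scan on random
dictionaries.

## Annotation

Documents are tokenized into maximal letter runs with 0-based half-open
offsets. Tokens of ≥ 4 characters are normalized and looked up in an index
over lexicon ∪ variant dictionary at `max_ed = 1` by default. A token
matching several entries keeps the minimum-distance match; equal-distance
ties go to the lexicographically smallest canonical name and are logged
(proper disambiguation is out of scope). Mention-level evaluation counts a
prediction as correct only on exact (document, span, canonical) agreement;
when a side is empty the affected metrics are reported as 0.0 rather than
raising.

## The misspelling simulator

The simulator generates the labelled data the pipeline is tuned and
evaluated on:

* **typo positives** — random inserts/deletes/substitutes/adjacent swaps
  drawn uniformly over a–z within a declared edit budget (default ≤ 2). A
  swap consumes two units of the budget so the plain-Levenshtein label
  bound `ED(base, surface) ≤ n_edits` always holds. No keyboard-adjacency
  model is used: none is published for this error source.
* **phonetic positives** — one homophone-class substitution (`ss`/`ç`/`c`,
  intervocalic `s`/`z`, `ch`/`x` in fricative contexts only, `qu`/`k`,
  silent-`h` insertion/removal) applied where the surrounding letters keep
  the substitution encoding-invariant; such variants have phonetic
  similarity exactly 1.0. Bases with no applicable context (e.g.
  "captopril") fall back to a *near-homophone* unstressed-vowel swap
  (e↔i, o↔u), flagged `near_homophone=True` because it perturbs the
  encoding slightly.
* **concatenation positives** — the name glued to a following short word
  ("fluoxetinapara"), emulating missing whitespace.
* **decoy negatives** — common Portuguese clinical-note words (packaged
  list), drug names outside the benchmark's own list, and derivational
  forms of the drug itself ("insulinizar"), which are the hard negatives
  the string filter exists for.

Default mixture 50% typo / 30% phonetic / 20% concatenation, configurable.
Everything is deterministic under a seed. Each positive is also embedded
into a small synthetic document between filler words, with gold offsets
recorded, so annotation recall can be measured.

What the simulator does **not** model: real token frequency and context,
Spanish-interference errors beyond the homophone classes, OCR noise,
multi-word drug names, and realistic error-class proportions (the mixture
is a knob, not an estimate). Passing synthetic benchmarks therefore
demonstrates internal correctness and separability under these error
processes, not field performance on clinical corpora.

## Problem sizes and defaults

The bundled study runs 20 drug names with 30 positives and 30 decoys each
(1 200 labelled pairs; 600 train / 600 validation after the 10/10 drug
split), a typo budget of 2, the 10 302-point default grid, and a held-out
benchmark of the same shape generated under an independent seed. Oracle
equivalence of the trie is checked on 1 000-word dictionaries with 200
queries at bounds 0–2. Test-level score comparisons use absolute tolerance
1e−9 where exactness is asserted.

## Known limitations

* The phoneme rule table is a stated approximation; tuned threshold values
  are meaningful relative to this encoder, not universal constants.
* Multi-word lexicon entries are indexed but can only match single tokens.
* Disambiguation of a token similar to several drugs is by distance then
  lexicographic tie-break, and only logged.
* The blocking consonant threshold (3) and minimum token length (4) are
  heuristics tuned for drug-name-length tokens; very short brand names
  would need different settings.
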