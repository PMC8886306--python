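# Methods

`phonosim` simulates six well-attested child speech error patterns in
phonemically transcribed word lists and quantifies their phonological
effects with five complexity/accuracy measures. This note documents the
model, its assumptions, the tunable parameters, and the design choices
made where the procedure was genuinely open.

## Transcription model

Input is SAMPA, one word per lexicon row, with syllable boundaries given
by the lexicon (no automatic syllabification). Conventions: `"` primary
stress (accent 1 in the Scandinavian languages), `""` accent 2 (two
characters), `%` secondary stress, `$` syllable delimiter, `:` length.
Length folds into the preceding segment, so a long vowel like `2:` is one
segment but two characters. Prosodic markers and delimiters are not
segments, yet they are characters of the raw string: character-level
distance (LVN) is computed on the raw string, so `""sp2:$ket` has length
10. Parsing is greedy longest-match against a per-language symbol table;
multi-character symbols (English affricates `tS`/`dZ`, diphthongs,
retroflex `t``-style tokens) are single segments. Onset = consonants
before the first vowel of the syllable, coda = consonants after the last.
Serialization inverts parsing byte-for-byte; this round trip is property
tested on randomly assembled inventory-valid strings.

Retroflexes are encoded with an X-SAMPA-style backtick (`t`` `d`` `n``
`l`` `s``, Norwegian flap `r``) rather than `rt`-style digraphs, which
would collide with genuine /r/+C sequences. Words without a vowel
(interjections like *hm*) are rejected by default because every measure
assumes a syllable nucleus; a lenient flag admits them for corpus triage.

Classification decisions that matter downstream: /j/ is a voiced palatal
fricative in Swedish and Norwegian but an approximant in English (this is
what makes /r/→/j/ *raise* WCM complexity in the Scandinavian languages
and lower it in English); palatals are grouped with the coronals for
place, so /r/→/j/ never changes a cluster's place profile; the Norwegian
labiodental approximant is grouped with the fricatives so that stopping
(v→b) applies to it.

## Error patterns

Each pattern is applied across the board — every applicable context in
the word — and patterns are never composed. An application-rate option
(apply each site with probability *p*, seeded) exists for sensitivity
studies and defaults to 1.0. Each application returns the misarticulated
transcription plus an edit record: one substitution or deletion per
affected segment, indexed against the original's consonant sequence.

* **Fronting** k→t, g→d, ŋ→n. **Backing** t→k, d→g, n→ŋ, with the
  retroflex series included for Swedish/Norwegian.
* **Stopping** maps fricatives/affricates to plosives (f→p, v→b,
  s/ɕ/ʃ/θ/tʃ→t, ð/z/ʒ/dʒ→d, ʂ→ʈ, ɧ→k, per language). A fricative
  immediately preceding a plosive in the same onset or coda cluster is
  deleted instead of substituted, avoiding illegal plosive+plosive
  clusters (so */spøːket/* becomes */pøːket/* via deletion of /s/); a
  config option substitutes anyway.
* **/r/-weakening** maps the language's rhotic set (including the
  Norwegian tap/flap) to /j/ in onset and coda alike. /j/ was chosen as
  the substitute in all three languages for cross-linguistic
  comparability, even though [w] is the commoner English realization.
* **Weak syllable deletion** removes exactly one syllable: the one
  immediately preceding the first syllable bearing primary stress or a
  tonal accent. Initial-stress and monosyllabic words are unchanged.
  Secondary stress is not treated as an anchor or barrier; with
  lexicon-given syllabification this reproduces the attested pre-tonic
  omissions (*banana*→[ˈnænə], *potatis*→[ˈtɑːtɪs]).
* **Cluster reduction** reduces every syllable onset of length ≥ 2 (word
  initial or medial; codas untouched) using a per-language retention
  table, first match wins: three-member onsets keep the middle member
  (*street*→[tit]); /s/-initial onsets keep the second member, with the
  English-specific exception that /sl/ keeps /s/ (*slide*→[saɪd] but
  Swedish *slåss*→[lɔs]); all other two-member onsets keep the first.
  Onsets matched by no rule are left unchanged and counted in the
  diagnostics.

All six patterns are idempotent: their outputs contain no remaining
applicable context. Substitution-only patterns preserve segment count;
deletions reduce it by exactly the number of delete edits.

## Measures

* **IPC** (Index of Phonetic Complexity), default table: +1 per singleton
  (non-cluster) fricative/affricate, +1 per dorsal consonant, +1 per
  onset/coda cluster, +1 extra per heterorganic cluster (members spanning
  ≥ 2 places). Rhotics and /j/ earn no sound-class points. This compact
  table reproduces the published worked values (*gubbar* 1 → fronted 0;
  *spöket* 3 → stopped 1) and makes the /r/-weakening IPC effect exactly
  zero. Effects are reported as error-minus-original differences.
* **WCM** (Word Complexity Measure), the original parameter set: +1 for
  ≥ 3 syllables, +1 for non-initial primary stress/accent (initial accent
  of either type scores nothing), +1 for a word-final consonant, +1 per
  cluster, and per consonant +1 for velars, +1 for liquids (taps
  included), +1 for fricatives/affricates with +1 more when voiced. The
  Swedish adaptation's /j/-as-voiced-fricative classification is carried
  by the inventory; Norwegian reuses the Swedish tables.
* **PCC**: 100 × (unaffected consonants)/(consonants in the target),
  computed from the simulation's edit record rather than by re-alignment
  — the simulation *is* the ground truth. Zero-consonant words are
  undefined and excluded from aggregation with a logged count.
* **LVN**: Levenshtein distance between the raw SAMPA strings (markers
  and delimiters included), normalized by the summed string lengths, so
  `""sp2:$ket` vs `""p2:$ket` gives 1/(10+9) ≈ 0.053. The distance is
  computed with the `edlib` alignment library and cross-checked against a
  textbook dynamic-programming oracle in the tests.
* **pMLU / PWP**: pMLU = segment count + correct consonants (a target's
  own pMLU uses its full consonant count); PWP = pMLU(production) /
  pMLU(target). For the implemented patterns (no insertions) PWP ∈ (0, 1].

## Corpus aggregation

Hapax legomena are removed before analysis. Each word type is scored once
and weighted by its token count; the aggregation is identical to
expanding every type into `count` tokens (property tested). IPC/WCM
differences and PWP aggregate over open-class words only; PCC and LVN
aggregate over all tokens, following the measures' original definitions.
Closed-class lists are inputs; a helper emits the most frequent types as
candidates for manual curation. Words with no lexicon transcription are
skipped and counted (the original study used grapheme-to-phoneme
conversion as a fallback, which is out of scope here; an external
word→SAMPA table can be supplied as a second lexicon). SD uses the
population formula (÷ n), SEM = SD/√n_tokens. Words where a pattern is
inapplicable contribute their neutral values (PCC 100, LVN 0, PWP 1,
diffs 0) by default — consistent with near-ceiling published PCC means —
and an `applicable_only` switch exists for sensitivity analysis.

## Rank analysis

Severity orderings from the five measures are compared with clinicians'
mean intuitive rankings via Kendall's τ-b with average-rank tie handling,
τ-b = (C−D)/√((n0−n1)(n0−n2)). Absolute mean effects are used for the two
structural measures (a complexity change of either sign is a change); the
other measures enter raw. With six patterns the normal approximation for
p is unreliable, so the two-sided p is computed exactly by enumerating
all n! pairings for n ≤ 8 (720 permutations here); the tie structure, and
hence the τ-b denominator, is permutation-invariant. The implementation
is plain pair counting and is cross-checked against scipy's τ-b in tests.

Applied to the bundled published per-pattern mean table, the matrix
reproduces 14 of the 15 published correlation cells to two decimals. The
remaining cell (WCM–PCC) computes to −.87 against a published .87; since
WCM and PCC move in opposite directions for five of the six patterns, the
published sign appears to be a misprint, and the tests assert the
computed value.

## Synthetic data

The generator emulates the *structural dials* that drive pattern effects:
probabilities of onset clusters, fricatives, velars, rhotics, and of a
pre-tonic (non-initially-stressed) word shape; syllable counts within a
configurable range; Zipf-like token counts with a floor of two plus
explicitly injected hapax rows (so hapax filtering is exercised
deterministically, not by chance). Defaults (25 % cluster onsets, 25 %
fricatives, 15 % velars, 10 % rhotics, 30 % pre-tonic, 1–3 syllables)
give every pattern a realistic mix of applicable and neutral words.
Everything is deterministic under the spec's seed.

What the generator does **not** emulate: real lexical phonotactics,
morphology, word-frequency/phonology correlations, or any specific
corpus's distributions. Passing tests on synthetic corpora therefore
demonstrate the correctness of the machinery (parsing, rule application,
weighting, dose–response direction), not the magnitudes one would obtain
on real child-speech data: published corpus-scale magnitudes require the
original multi-million-token corpora and are out of scope. Test and
example corpora use 20–60 word types, which keeps every suite run in
seconds while still exercising all code paths.

## Known limitations

* One transcription per word (first lexicon entry wins); pronunciation
  variation is not modeled.
* Context-dependent patterns (assimilation, metathesis), probabilistic
  misarticulation as a studied condition, and phonotactic-frequency
  conditioning are out of scope.
* The published worked example's WCM absolute scores (2 and 0) are not
  reproducible under any single parameter table that also yields the
  published positive backing effect; the difference (−2) is consistent
  and is what this package asserts and reports.
* Feature-weighted distances (e.g. weighting fricative-for-fricative
  substitutions as nearer) are not implemented.
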