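# phonosim

Simulation of child speech error patterns in phonemically transcribed
word lists, and quantification of their phonological effects.

Children acquiring a language systematically simplify adult targets:
velars become coronals (*key* → [ti]), fricatives become plosives
(*thumb* → [tʌm]), clusters lose members (*bread* → [bɛd]), weak
pre-tonic syllables disappear (*banana* → [ˈnænə]). `phonosim` injects
six such error patterns — velar fronting, (atypical) backing, stopping,
/r/-weakening, weak syllable deletion and cluster reduction — into SAMPA
pronunciation lexica for Swedish, Norwegian and English, and measures
what each pattern does to the words phonologically. It is aimed at
clinical phonologists and speech-corpus researchers who want large-scale,
fully controlled estimates of pattern severity without recordings of
disordered speech.

Five measures quantify the effect of turning a target transcription
*T*<sub>orig</sub> into a misarticulated *T*<sub>err</sub>:

| Measure | Type | Definition |
|---|---|---|
| IPC | structural | Index of Phonetic Complexity; effect = IPC(*T*<sub>err</sub>) − IPC(*T*<sub>orig</sub>) |
| WCM | structural | Word Complexity Measure; effect = WCM(*T*<sub>err</sub>) − WCM(*T*<sub>orig</sub>) |
| PCC | relational | % of target consonants left unaffected |
| LVN | relational | Levenshtein(*T*<sub>orig</sub>, *T*<sub>err</sub>) / (&#124;*T*<sub>orig</sub>&#124; + &#124;*T*<sub>err</sub>&#124;) |
| pMLU / PWP | combined | pMLU = segments + correct consonants; PWP = pMLU(*T*<sub>err</sub>)/pMLU(*T*<sub>orig</sub>) |

Corpus-level effects are token-weighted means/SDs over frequency lists
(hapax legomena excluded; structural and combined measures over
open-class words only), and measure-based severity orderings can be
correlated with clinicians' intuitive severity rankings via Kendall τ-b
with exact permutation p-values. See `docs/methods.md` for the full
model description and design rationale.

## Worked example

The Swedish word *spöket* ("the ghost"), SAMPA `""sp2:$ket`, under
stopping: the onset fricative /s/ sits before a plosive, so it is deleted
rather than substituted, giving `""p2:$ket`.

```sh
$ printf 'spöket\t""sp2:$ket\nkaka\t""kA:$ka\n' > lex.tsv
$ phonosim score --pattern stopping --language sv --lexicon lex.tsv
word	sampa_orig	sampa_error	ipc_orig	ipc_err	ipc_diff	wcm_orig	wcm_err	wcm_diff	pcc	lvn	pmlu_orig	pmlu_err	pwp
spöket	""sp2:$ket	""p2:$ket	3	1	-2	4	2	-2	75.0	0.0526	10	8	0.8000
kaka	""kA:$ka	""kA:$ka	2	2	0	2	2	0	100.0	0.0000	6	6	1.0000
```

Reading the *spöket* row: losing /s/ costs the word its cluster and
heterorganic-cluster IPC points (3 → 1, effect −2) and its fricative and
cluster WCM points (effect −2); three of the four target consonants
survive (PCC 75 %); one character changed out of 10 + 9 (LVN ≈ 0.053);
and the production keeps 8 of the target's 10 pMLU points (PWP 0.8).
*kaka* contains no fricative, so stopping leaves it at the neutral
values (PCC 100, LVN 0, PWP 1). Swapping `--pattern` for any of the
other five names simulates those patterns instead; `phonosim aggregate`
rolls per-word scores up into token-weighted corpus reports, `phonosim
synth` generates seeded synthetic lexica with controllable phonotactics,
and `phonosim correlate` computes the τ-b matrix from a per-pattern
severity table:

```sh
$ phonosim correlate --ranktable src/phonosim/data/severity_means_sv.tsv --p-method exact
pair	tau	p
clinical-wcm	0.33	0.469
clinical-pcc	-0.20	0.719
clinical-pwp	-0.55	0.189
wcm-ipc	0.73	0.056
...
```

No measure correlates significantly with the clinicians' intuitive
ranking — phonological effect size is not the same thing as perceived
impact on intelligibility.

## Layout

- `src/phonosim/phonology.py` — SAMPA parsing/serialization against
  per-language inventories
- `src/phonosim/errors.py` — the six error patterns and edit records
- `src/phonosim/metrics.py` — IPC, WCM, PCC, LVN, pMLU/PWP
- `src/phonosim/pipeline.py` — frequency lists, lexica, token-weighted
  aggregation
- `src/phonosim/ranking.py` — Kendall τ-b and the severity correlation
  matrix
- `src/phonosim/synth.py` — synthetic lexicon generator and the bundled
  worked example
- `src/phonosim/data/` — editable YAML language profiles (sv, no, en)
  and the bundled severity-means table
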