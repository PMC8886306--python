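# Swedish phoneme inventory, error-pattern rules and metric scoring tables.
#
# SAMPA conventions: '"' primary stress (accent 1), '""' accent 2,
# '%' secondary stress, '$' syllable boundary, ':' segment length.
# Retroflexes carry an X-SAMPA-style backtick (t` d` n` l` s`) so that
# they tokenize as single segments and never collide with /r/+C spellings.
language: sv

consonants:
  "p":  {place: labial,    manner: plosive,   voiced: false}
  "b":  {place: labial,    manner: plosive,   voiced: true}
  "t":  {place: coronal,   manner: plosive,   voiced: false}
  "d":  {place: coronal,   manner: plosive,   voiced: true}
  "k":  {place: dorsal,    manner: plosive,   voiced: false}
  "g":  {place: dorsal,    manner: plosive,   voiced: true}
  "t`": {place: retroflex, manner: plosive,   voiced: false}
  "d`": {place: retroflex, manner: plosive,   voiced: true}
  "f":  {place: labial,    manner: fricative, voiced: false}
  "v":  {place: labial,    manner: fricative, voiced: true}
  "s":  {place: coronal,   manner: fricative, voiced: false}
  "s`": {place: retroflex, manner: fricative, voiced: false}
  # C = the "tje" sound (alveolo-palatal fricative), S = the "sje" sound.
  "C":  {place: coronal,   manner: fricative, voiced: false}
  "S":  {place: dorsal,    manner: fricative, voiced: false}
  "h":  {place: glottal,   manner: fricative, voiced: false}
  # /j/ is classified as a voiced palatal fricative (grouped with coronals),
  # the classification used by the Swedish WCM adaptation.
  "j":  {place: coronal,   manner: fricative, voiced: true}
  "m":  {place: labial,    manner: nasal,     voiced: true}
  "n":  {place: coronal,   manner: nasal,     voiced: true}
  "n`": {place: retroflex, manner: nasal,     voiced: true}
  "N":  {place: dorsal,    manner: nasal,     voiced: true}
  "l":  {place: coronal,   manner: liquid,    voiced: true}
  "l`": {place: retroflex, manner: liquid,    voiced: true}
  "r":  {place: coronal,   manner: liquid,    voiced: true}

vowels: ["i", "I", "y", "Y", "}", "0", "u", "U", "o", "O",
         "A", "a", "e", "E", "2", "9", "@"]

patterns:
  fronting:
    substitutions: {"k": "t", "g": "d", "N": "n"}
  backing:
    substitutions: {"t": "k", "d": "g", "n": "N",
                    "t`": "k", "d`": "g", "n`": "N"}
  stopping:
    substitutions: {"f": "p", "v": "b", "s": "t", "C": "t",
                    "s`": "t`", "S": "k"}
    cluster_fricative: delete
  r_weakening:
    substitutions: {"r": "j"}
  weak_syllable_deletion: {}
  cluster_reduction:
    # Onset-cluster retention rules, first match wins; `keep` is a
    # zero-based index into the cluster.
    rules:
      - {size: 3, keep: 1}
      - {first: ["s", "s`"], keep: 1}
      - {keep: 0}

scoring:
  ipc:
    singleton_fricative_affricate: 1
    dorsal: 1
    per_cluster: 1
    heterorganic_bonus: 1
    # rhotics and the /j/ glide earn no sound-class points under the IPC
    excluded_symbols: ["r", "j"]
  wcm:
    three_or_more_syllables: 1
    noninitial_stress: 1
    final_consonant: 1
    per_cluster: 1
    velar: 1
    liquid: 1
    fricative_affricate: 1
    voiced_fricative_affricate_bonus: 1
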