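# Norwegian (Bokmål) phoneme inventory, error-pattern rules and scoring.
# Same SAMPA conventions as the Swedish file. No Norwegian WCM adaptation
# exists, so the Swedish scoring tables are reused unchanged.
language: "no"

consonants:
  "p":  {place: labial,    manner: plosive,   voiced: false}
  "b":  {place: labial,    manner: plosive,   voiced: true}
  "t":  {place: coronal,   manner: plosive,   voiced: false}
  "d":  {place: coronal,   manner: plosive,   voiced: true}
  "t`": {place: retroflex, manner: plosive,   voiced: false}
  "d`": {place: retroflex, manner: plosive,   voiced: true}
  "k":  {place: dorsal,    manner: plosive,   voiced: false}
  "g":  {place: dorsal,    manner: plosive,   voiced: true}
  "f":  {place: labial,    manner: fricative, voiced: false}
  # the labiodental approximant is grouped with the fricatives so that
  # stopping (v -> b) applies to it
  "v":  {place: labial,    manner: fricative, voiced: true}
  "s":  {place: coronal,   manner: fricative, voiced: false}
  "s`": {place: retroflex, manner: fricative, voiced: false}
  "C":  {place: coronal,   manner: fricative, voiced: false}
  "h":  {place: glottal,   manner: fricative, voiced: false}
  "j":  {place: coronal,   manner: fricative, voiced: true}
  "m":  {place: labial,    manner: nasal,     voiced: true}
  "n":  {place: coronal,   manner: nasal,     voiced: true}
  "n`": {place: retroflex, manner: nasal,     voiced: true}
  "N":  {place: dorsal,    manner: nasal,     voiced: true}
  "l":  {place: coronal,   manner: liquid,    voiced: true}
  "l`": {place: retroflex, manner: liquid,    voiced: true}
  "r":  {place: coronal,   manner: tap,       voiced: true}
  "r`": {place: retroflex, manner: tap,       voiced: true}
  "w":  {place: labial,    manner: approximant, voiced: true}

vowels: ["i", "I", "y", "Y", "}", "u", "U", "o", "O", "A", "a", "e", "E",
         "2", "9", "{", "@", "{j", "2j", "{w"]

patterns:
  fronting:
    substitutions: {"k": "t", "g": "d", "N": "n"}
  backing:
    substitutions: {"t": "k", "d": "g", "n": "N",
                    "t`": "k", "d`": "g", "n`": "N"}
  stopping:
    substitutions: {"f": "p", "v": "b", "s": "t", "C": "t", "s`": "t`"}
    cluster_fricative: delete
  r_weakening:
    # both the alveolar tap and the retroflex flap weaken to /j/
    substitutions: {"r": "j", "r`": "j"}
  weak_syllable_deletion: {}
  cluster_reduction:
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
    excluded_symbols: ["r", "r`", "j"]
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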