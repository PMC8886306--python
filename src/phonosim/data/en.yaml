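# English (North American reference pronunciation) inventory, pattern
# rules and scoring. Affricates (tS, dZ) and diphthongs (aI, eI, ...) are
# multi-character symbols and count as single segments.
language: en

consonants:
  "p":  {place: labial,  manner: plosive,     voiced: false}
  "b":  {place: labial,  manner: plosive,     voiced: true}
  "t":  {place: coronal, manner: plosive,     voiced: false}
  "d":  {place: coronal, manner: plosive,     voiced: true}
  "k":  {place: dorsal,  manner: plosive,     voiced: false}
  "g":  {place: dorsal,  manner: plosive,     voiced: true}
  "f":  {place: labial,  manner: fricative,   voiced: false}
  "v":  {place: labial,  manner: fricative,   voiced: true}
  "T":  {place: coronal, manner: fricative,   voiced: false}
  "D":  {place: coronal, manner: fricative,   voiced: true}
  "s":  {place: coronal, manner: fricative,   voiced: false}
  "z":  {place: coronal, manner: fricative,   voiced: true}
  "S":  {place: coronal, manner: fricative,   voiced: false}
  "Z":  {place: coronal, manner: fricative,   voiced: true}
  "h":  {place: glottal, manner: fricative,   voiced: false}
  "tS": {place: coronal, manner: affricate,   voiced: false}
  "dZ": {place: coronal, manner: affricate,   voiced: true}
  "m":  {place: labial,  manner: nasal,       voiced: true}
  "n":  {place: coronal, manner: nasal,       voiced: true}
  "N":  {place: dorsal,  manner: nasal,       voiced: true}
  "l":  {place: coronal, manner: liquid,      voiced: true}
  "r":  {place: coronal, manner: liquid,      voiced: true}
  # /j/ is a palatal approximant in English (no WCM/IPC points)
  "j":  {place: coronal, manner: approximant, voiced: true}
  "w":  {place: labial,  manner: approximant, voiced: true}

vowels: ["i", "I", "e", "E", "{", "@", "V", "u", "U", "o", "O", "A",
         "aI", "aU", "OI", "eI", "oU"]

patterns:
  fronting:
    substitutions: {"k": "t", "g": "d", "N": "n"}
  backing:
    substitutions: {"t": "k", "d": "g", "n": "N"}
  stopping:
    substitutions: {"f": "p", "v": "b",
                    "s": "t", "S": "t", "T": "t", "tS": "t",
                    "z": "d", "D": "d", "Z": "d", "dZ": "d"}
    cluster_fricative: delete
  r_weakening:
    substitutions: {"r": "j"}
  weak_syllable_deletion: {}
  cluster_reduction:
    rules:
      - {size: 3, keep: 1}
      # English-specific: /sl/ keeps the /s/ ("slide" -> [saId])
      - {exact: ["s", "l"], keep: 0}
      - {first: ["s"], keep: 1}
      - {keep: 0}

scoring:
  ipc:
    singleton_fricative_affricate: 1
    dorsal: 1
    per_cluster: 1
    heterorganic_bonus: 1
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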