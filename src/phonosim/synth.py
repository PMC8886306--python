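"""Synthetic lexica and frequency lists with controllable phonotactics.

Real child-speech corpora and pronunciation lexica are large licensed
resources; this module generates small stand-ins whose *structural* dials
matter for the error patterns: how often onsets are clusters (cluster
reduction), how often consonants are fricatives (stopping), velars
(fronting), or rhotics (r-weakening), and how often a word carries
non-initial stress (weak syllable deletion). Raising a dial raises the
frequency of the matching pattern's applicable contexts, which is exactly
the dose–response property the test suite exercises.

Token counts follow a Zipf-like curve with a floor of two, so hapax
filtering is exercised only through explicitly injected hapax rows.
Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path

from .languages import LanguageProfile, load_language
from .phonology import Segment, Syllable, Transcription, from_syllables
from .pipeline import FrequencyList, write_frequency_list

__all__ = ["FixtureSpec", "SynthCorpus", "generate_lexicon", "worked_example"]


@dataclass(frozen=True)
class FixtureSpec:
    language: str = "sv"
    n_types: int = 100
    zipf_exponent: float = 1.1
    base_count: int = 300
    p_onset_cluster: float = 0.25
    p_fricative: float = 0.25
    p_velar: float = 0.15
    p_rhotic: float = 0.10
    p_pretonic_syllable: float = 0.30
    p_hapax: float = 0.05
    syllables_range: tuple[int, int] = (1, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_onset_cluster", "p_fricative", "p_velar",
                     "p_rhotic", "p_pretonic_syllable", "p_hapax"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.p_fricative + self.p_velar + self.p_rhotic > 1.0:
            raise ValueError("consonant-class probabilities exceed 1")
        if self.n_types < 1:
            raise ValueError("n_types must be at least 1")
        lo, hi = self.syllables_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid syllables_range")
        if self.p_pretonic_syllable > 0 and hi < 2:
            raise ValueError("pre-tonic syllables require at least 2 syllables")


@dataclass(frozen=True)
class SynthCorpus:
    frequencies: FrequencyList
    lexicon: dict[str, str]
    closed_class: tuple[str, ...]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_frequency_list(self.frequencies, out / "freq.tsv")
        with open(out / "lexicon.tsv", "w", encoding="utf-8") as fh:
            for word, sampa in self.lexicon.items():
                fh.write(f"{word}\t{sampa}\n")
        with open(out / "closed_class.txt", "w", encoding="utf-8") as fh:
            for word in self.closed_class:
                fh.write(word + "\n")


def _consonant_classes(profile: LanguageProfile) -> dict[str, list[str]]:
    inv = profile.inventory
    rhotics = sorted(profile.patterns["r_weakening"].substitution_map)
    classes: dict[str, list[str]] = {
        "fricative": [], "velar": [], "rhotic": rhotics, "other": []
    }
    for sym, f in sorted(inv.consonants.items()):
        if sym in rhotics:
            continue
        if f.manner in ("fricative", "affricate") and f.place != "glottal":
            classes["fricative"].append(sym)
        elif f.place == "dorsal":
            classes["velar"].append(sym)
        elif f.manner in ("plosive", "nasal", "liquid"):
            classes["other"].append(sym)
    return classes


def _sample_consonant(
    rng: random.Random, spec: FixtureSpec, classes: dict[str, list[str]]
) -> str:
    u = rng.random()
    if u < spec.p_fricative:
        pool = classes["fricative"]
    elif u < spec.p_fricative + spec.p_velar:
        pool = classes["velar"]
    elif u < spec.p_fricative + spec.p_velar + spec.p_rhotic:
        pool = classes["rhotic"]
    else:
        pool = classes["other"]
    return rng.choice(pool or classes["other"])


def _sample_word(
    rng: random.Random, spec: FixtureSpec, profile: LanguageProfile
) -> Transcription:
    inv = profile.inventory
    classes = _consonant_classes(profile)
    short_vowels = sorted(v for v in inv.vowels if len(v) == 1)
    lo, hi = spec.syllables_range
    n_syll = rng.randint(lo, hi)
    stress_at = 0
    if n_syll >= 2 and rng.random() < spec.p_pretonic_syllable:
        stress_at = 1
    accent2 = inv.language in ("sv", "no") and rng.random() < 0.5

    def consonant(sym: str) -> Segment:
        return Segment(sym, True, features=inv.features(sym))

    syllables = []
    for i in range(n_syll):
        u = rng.random()
        if u < spec.p_onset_cluster:
            onset = tuple(
                consonant(_sample_consonant(rng, spec, classes)) for _ in range(2)
            )
        elif u < spec.p_onset_cluster + 0.1:
            onset = ()
        else:
            onset = (consonant(_sample_consonant(rng, spec, classes)),)
        vowel = rng.choice(short_vowels)
        nucleus = (Segment(vowel, False, long=rng.random() < 0.25),)
        coda = ()
        if i == n_syll - 1 and rng.random() < 0.5:
            coda = (consonant(_sample_consonant(rng, spec, classes)),)
        prosody = "none"
        if i == stress_at:
            prosody = "accent2" if accent2 else "primary"
        syllables.append(Syllable(onset, nucleus, coda, prosody))
    return from_syllables(syllables, inv.language)


def generate_lexicon(
    spec: FixtureSpec, profile: LanguageProfile | None = None
) -> SynthCorpus:
    """Generate a deterministic synthetic frequency list + lexicon.

    Counts are Zipf-like with floor 2; an extra ``p_hapax`` share of
    types is appended with count 1. The three most frequent types are
    nominated as the closed-class list.
    """
    profile = profile or load_language(spec.language)
    rng = random.Random(spec.seed)
    entries: dict[str, int] = {}
    lexicon: dict[str, str] = {}
    for rank in range(1, spec.n_types + 1):
        word = f"w{rank:04d}"
        count = max(2, round(spec.base_count / rank**spec.zipf_exponent))
        entries[word] = count
        lexicon[word] = _sample_word(rng, spec, profile).raw
    n_hapax = math.ceil(spec.n_types * spec.p_hapax)
    for k in range(n_hapax):
        word = f"h{k:04d}"
        entries[word] = 1
        lexicon[word] = _sample_word(rng, spec, profile).raw
    closed = tuple(
        w for w, _ in sorted(entries.items(), key=lambda wc: (-wc[1], wc[0]))[:3]
    )
    label = f"synthetic-{spec.language}-seed{spec.seed}"
    return SynthCorpus(FrequencyList(entries, label), lexicon, closed)


@dataclass(frozen=True)
class WorkedExample:
    """The Swedish 'spöket' stopping example with its expected scores."""

    word: str
    language: str
    pattern: str
    sampa_orig: str
    sampa_err: str
    expected: dict[str, float] = field(default_factory=dict)


def worked_example() -> WorkedExample:
    """Swedish *spöket* ("the ghost") under stopping: the onset fricative
    of /""sp2:$ket/ is deleted, giving /""p2:$ket/. Expected effects:
    IPC −2, WCM −2, PCC 75%, LVN 1/19, PWP 8/10."""
    return WorkedExample(
        word="spöket",
        language="sv",
        pattern="stopping",
        sampa_orig='""sp2:$ket',
        sampa_err='""p2:$ket',
        expected={
            "ipc_diff": -2,
            "wcm_diff": -2,
            "pcc": 75.0,
            "lvn": 1.0 / 19.0,
            "pwp": 0.8,
            "pmlu_orig": 10,
            "pmlu_err": 8,
        },
    )
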