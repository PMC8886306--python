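"""SAMPA phonemic transcriptions as structured, feature-annotated objects.

A transcription like ``""sp2:$ket`` (Swedish *spöket*, "the ghost") is a
sequence of syllables separated by ``$``, each optionally prefixed by a
prosodic marker (``"`` primary stress / accent 1, ``""`` accent 2, ``%``
secondary stress). Within a syllable, segments are tokenized greedily
against a per-language phoneme inventory; a trailing ``:`` marks the
preceding segment as long and is folded into it. Prosodic markers and the
syllable delimiter are not segments, but they *are* characters of the raw
string, which matters for character-level distance measures.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Mapping, Sequence

__all__ = [
    "ConsonantFeatures",
    "PhonemeInventory",
    "Segment",
    "Syllable",
    "Transcription",
    "ParseError",
    "parse_transcription",
    "serialize",
    "consonant_tokens",
]

PLACES = frozenset({"labial", "coronal", "retroflex", "dorsal", "glottal"})
MANNERS = frozenset(
    {"plosive", "fricative", "affricate", "nasal", "liquid", "approximant", "tap"}
)

SYLLABLE_DELIMITER = "$"
LENGTH_MARKER = ":"
# Ordered longest-first so that accent 2 ('""') wins over primary ('"').
STRESS_MARKERS = (('""', "accent2"), ('"', "primary"), ("%", "secondary"))
PROSODY_TO_MARKER = {p: m for m, p in STRESS_MARKERS}
PROSODY_TO_MARKER["none"] = ""
#: prosodies that anchor word stress (accent 2 implies primary stress)
STRESSED_PROSODIES = frozenset({"primary", "accent2"})


class ParseError(ValueError):
    """Raised when a raw SAMPA string cannot be resolved against an inventory."""

    def __init__(self, message: str, raw: str = "", position: int | None = None):
        self.raw = raw
        self.position = position
        super().__init__(message)


@dataclass(frozen=True)
class ConsonantFeatures:
    place: str
    manner: str
    voiced: bool

    def __post_init__(self) -> None:
        if self.place not in PLACES:
            raise ValueError(f"unknown place of articulation: {self.place!r}")
        if self.manner not in MANNERS:
            raise ValueError(f"unknown manner of articulation: {self.manner!r}")


@dataclass(frozen=True)
class PhonemeInventory:
    """Per-language symbol table governing tokenization and classification."""

    language: str
    consonants: Mapping[str, ConsonantFeatures]
    vowels: frozenset[str]

    def __post_init__(self) -> None:
        overlap = set(self.consonants) & self.vowels
        if overlap:
            raise ValueError(f"symbols in both classes: {sorted(overlap)}")
        reserved = {SYLLABLE_DELIMITER, LENGTH_MARKER, '"', "%"}
        bad = reserved & (set(self.consonants) | self.vowels)
        if bad:
            raise ValueError(f"marker characters used as segments: {sorted(bad)}")

    @property
    def symbols(self) -> frozenset[str]:
        return frozenset(self.consonants) | self.vowels

    @property
    def multichar_symbols(self) -> tuple[str, ...]:
        """All symbols, longest first, for deterministic greedy tokenization."""
        return tuple(sorted(self.symbols, key=lambda s: (-len(s), s)))

    def is_consonant(self, symbol: str) -> bool:
        return symbol in self.consonants

    def is_vowel(self, symbol: str) -> bool:
        return symbol in self.vowels

    def features(self, symbol: str) -> ConsonantFeatures:
        return self.consonants[symbol]


@dataclass(frozen=True)
class Segment:
    """One phonemic segment; a long segment carries the fold-in length mark."""

    symbol: str
    is_consonant: bool
    long: bool = False
    features: ConsonantFeatures | None = None

    @property
    def sampa(self) -> str:
        return self.symbol + (LENGTH_MARKER if self.long else "")

    def with_symbol(self, symbol: str, inventory: PhonemeInventory) -> "Segment":
        """A copy carrying ``symbol``, re-classified against ``inventory``."""
        is_c = inventory.is_consonant(symbol)
        return Segment(
            symbol=symbol,
            is_consonant=is_c,
            long=self.long,
            features=inventory.features(symbol) if is_c else None,
        )


@dataclass(frozen=True)
class Syllable:
    onset: tuple[Segment, ...]
    nucleus: tuple[Segment, ...]
    coda: tuple[Segment, ...]
    prosody: str = "none"

    def __post_init__(self) -> None:
        if self.prosody not in PROSODY_TO_MARKER:
            raise ValueError(f"unknown prosody: {self.prosody!r}")

    @property
    def segments(self) -> tuple[Segment, ...]:
        return self.onset + self.nucleus + self.coda

    @property
    def sampa(self) -> str:
        return PROSODY_TO_MARKER[self.prosody] + "".join(
            s.sampa for s in self.segments
        )


@dataclass(frozen=True)
class Transcription:
    raw: str
    syllables: tuple[Syllable, ...]
    language: str

    def __iter__(self) -> Iterator[Syllable]:
        return iter(self.syllables)

    @property
    def segments(self) -> tuple[Segment, ...]:
        return tuple(s for syl in self.syllables for s in syl.segments)

    @property
    def consonants(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.is_consonant)

    @property
    def stressed_index(self) -> int | None:
        """Index of the first syllable bearing primary stress or accent 2."""
        for i, syl in enumerate(self.syllables):
            if syl.prosody in STRESSED_PROSODIES:
                return i
        return None


def _tokenize_segments(
    text: str,
    inventory: PhonemeInventory,
    raw: str,
    offset: int,
) -> list[Segment]:
    """Greedy longest-match tokenization of one syllable body."""
    symbols = inventory.multichar_symbols
    segments: list[Segment] = []
    i = 0
    while i < len(text):
        if text[i] == LENGTH_MARKER:
            if not segments or segments[-1].long:
                raise ParseError(
                    f"dangling length marker at position {offset + i} in {raw!r}",
                    raw,
                    offset + i,
                )
            segments[-1] = replace(segments[-1], long=True)
            i += 1
            continue
        for sym in symbols:
            if text.startswith(sym, i):
                is_c = inventory.is_consonant(sym)
                segments.append(
                    Segment(
                        symbol=sym,
                        is_consonant=is_c,
                        features=inventory.features(sym) if is_c else None,
                    )
                )
                i += len(sym)
                break
        else:
            raise ParseError(
                f"unknown symbol {text[i]!r} at position {offset + i} in {raw!r}",
                raw,
                offset + i,
            )
    return segments


def _split_syllable(
    segments: Sequence[Segment],
    prosody: str,
    raw: str,
    allow_empty_nucleus: bool,
) -> Syllable:
    vowel_idx = [i for i, s in enumerate(segments) if not s.is_consonant]
    if not vowel_idx:
        if not allow_empty_nucleus:
            raise ParseError(f"syllable without a vowel nucleus in {raw!r}", raw)
        return Syllable(tuple(segments), (), (), prosody)
    first, last = vowel_idx[0], vowel_idx[-1]
    return Syllable(
        onset=tuple(segments[:first]),
        nucleus=tuple(segments[first : last + 1]),
        coda=tuple(segments[last + 1 :]),
        prosody=prosody,
    )


def parse_transcription(
    raw: str,
    inventory: PhonemeInventory,
    *,
    allow_empty_nucleus: bool = False,
) -> Transcription:
    """Parse a raw SAMPA string into syllables of classified segments.

    Onsets are the consonants before the first vowel of a syllable, codas
    the consonants after the last vowel; syllable boundaries come from the
    ``$`` delimiters in the input (no automatic syllabification).
    """
    if not raw:
        raise ParseError("empty transcription", raw)
    syllables: list[Syllable] = []
    offset = 0
    for chunk in raw.split(SYLLABLE_DELIMITER):
        prosody = "none"
        body = chunk
        for marker, name in STRESS_MARKERS:
            if chunk.startswith(marker):
                prosody, body = name, chunk[len(marker) :]
                break
        if not body:
            raise ParseError(f"empty syllable in {raw!r}", raw, offset)
        segments = _tokenize_segments(
            body, inventory, raw, offset + len(chunk) - len(body)
        )
        syllables.append(_split_syllable(segments, prosody, raw, allow_empty_nucleus))
        offset += len(chunk) + 1
    return Transcription(raw=raw, syllables=tuple(syllables), language=inventory.language)


def serialize(t: Transcription) -> str:
    """Render the structured form back to its raw SAMPA string."""
    return SYLLABLE_DELIMITER.join(syl.sampa for syl in t.syllables)


def from_syllables(
    syllables: Sequence[Syllable], language: str
) -> Transcription:
    """Build a transcription from syllables, deriving the raw string."""
    t = Transcription(raw="", syllables=tuple(syllables), language=language)
    return replace(t, raw=serialize(t))


def consonant_tokens(t: Transcription) -> tuple[Segment, ...]:
    """Consonants in left-to-right word order, clusters flattened."""
    return t.consonants
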