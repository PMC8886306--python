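"""Phonological complexity and accuracy measures.

Two structural measures score a single transcription in isolation:

* **IPC** (Index of Phonetic Complexity): points for singleton (non-
  cluster) fricatives/affricates, dorsal consonants, consonant clusters,
  and a bonus for heterorganic clusters (members spanning two or more
  places of articulation). Rhotics and the /j/ glide earn no points.
* **WCM** (Word Complexity Measure): points for word patterns (three or
  more syllables; non-initial stress), syllable structures (word-final
  consonant; each cluster) and sound classes (velars, liquids, fricatives
  and affricates, with an extra point when the latter are voiced).

Three relational measures compare a target with its misarticulated form:

* **PCC** (Percentage of Consonants Correct): the share of target
  consonants a simulated pattern left untouched, from the edit record.
* **LVN**: Levenshtein distance on the raw SAMPA strings (prosodic
  markers and delimiters included), normalized by the summed lengths.
* **pMLU / PWP**: phonological mean length of utterance (segments plus
  correct consonants) and its ratio production/target, the Proportion of
  Whole-word Proximity.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .errors import EditRecord, apply_pattern
from .languages import LanguageProfile, ScoringConfig
from .phonology import Segment, Transcription

__all__ = [
    "MetricResult",
    "ZeroConsonantWord",
    "ipc_score",
    "wcm_score",
    "structural_diff",
    "pcc",
    "levenshtein",
    "lvn",
    "pmlu",
    "pwp",
    "score_word",
]


class ZeroConsonantWord(ValueError):
    """PCC is undefined for words without consonants."""


@dataclass(frozen=True)
class MetricResult:
    """All five measures for one word under one error pattern."""

    word: str
    pattern: str
    raw_orig: str
    raw_err: str
    ipc_orig: int
    ipc_err: int
    wcm_orig: int
    wcm_err: int
    pcc: float | None  # None for zero-consonant words
    lvn: float
    pmlu_orig: int
    pmlu_err: int
    applicable: bool
    unmatched_clusters: int = 0

    @property
    def ipc_diff(self) -> int:
        return self.ipc_err - self.ipc_orig

    @property
    def wcm_diff(self) -> int:
        return self.wcm_err - self.wcm_orig

    @property
    def pwp(self) -> float:
        return self.pmlu_err / self.pmlu_orig


def _clusters(t: Transcription) -> list[tuple[Segment, ...]]:
    """Tautosyllabic onset and coda clusters of two or more consonants."""
    out = []
    for syl in t.syllables:
        for part in (syl.onset, syl.coda):
            if len(part) >= 2 and all(s.is_consonant for s in part):
                out.append(part)
    return out


def _is_heterorganic(cluster: tuple[Segment, ...]) -> bool:
    return len({s.features.place for s in cluster}) >= 2


def ipc_score(t: Transcription, cfg: ScoringConfig) -> int:
    params = cfg.ipc
    excluded = set(params.get("excluded_symbols", ()))
    clusters = _clusters(t)
    clustered = {id(s) for c in clusters for s in c}
    points = 0
    for c in clusters:
        points += params.get("per_cluster", 0)
        if _is_heterorganic(c):
            points += params.get("heterorganic_bonus", 0)
    for seg in t.consonants:
        if seg.symbol in excluded:
            continue
        f = seg.features
        if (
            f.manner in ("fricative", "affricate")
            and id(seg) not in clustered
        ):
            points += params.get("singleton_fricative_affricate", 0)
        if f.place == "dorsal":
            points += params.get("dorsal", 0)
    return points


def wcm_score(t: Transcription, cfg: ScoringConfig) -> int:
    params = cfg.wcm
    points = 0
    if len(t.syllables) >= 3:
        points += params.get("three_or_more_syllables", 0)
    stressed = t.stressed_index
    if stressed is not None and stressed > 0:
        points += params.get("noninitial_stress", 0)
    segments = t.segments
    if segments and segments[-1].is_consonant:
        points += params.get("final_consonant", 0)
    points += len(_clusters(t)) * params.get("per_cluster", 0)
    for seg in t.consonants:
        f = seg.features
        if f.place == "dorsal" and f.manner in ("plosive", "nasal", "fricative"):
            points += params.get("velar", 0)
        if f.manner in ("liquid", "tap"):
            points += params.get("liquid", 0)
        if f.manner in ("fricative", "affricate"):
            points += params.get("fricative_affricate", 0)
            if f.voiced:
                points += params.get("voiced_fricative_affricate_bonus", 0)
    return points


def structural_diff(
    orig: Transcription, err: Transcription, cfg: ScoringConfig
) -> tuple[int, int]:
    """(IPC, WCM) score of the error form minus the original; negative
    values mean the pattern reduced phonological complexity."""
    return (
        ipc_score(err, cfg) - ipc_score(orig, cfg),
        wcm_score(err, cfg) - wcm_score(orig, cfg),
    )


def pcc(orig: Transcription, edits: EditRecord) -> float:
    """Percentage of the target's consonants left unaffected by the edits."""
    n = len(orig.consonants)
    if n == 0:
        raise ZeroConsonantWord(orig.raw)
    touched = {e.consonant_index for e in edits.consonant_edits}
    bad = [i for i in touched if not 0 <= i < n]
    if bad:
        raise ValueError(f"edit references nonexistent consonant index {bad}")
    return 100.0 * (n - len(touched)) / n


def levenshtein(a: str, b: str) -> int:
    """Minimal number of single-character insertions, deletions or
    substitutions turning ``a`` into ``b``."""
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def lvn(a: str, b: str) -> float:
    """Levenshtein distance normalized by the summed string lengths."""
    if not a and not b:
        raise ValueError("LVN undefined for two empty strings")
    return levenshtein(a, b) / (len(a) + len(b))


def pmlu(t: Transcription, correct_consonants: int) -> int:
    """Phonological mean length of utterance for one word production:
    number of segments plus number of correct consonants. For a target
    form, pass its own consonant count."""
    if correct_consonants < 0:
        raise ValueError("correct consonant count cannot be negative")
    if correct_consonants > len(t.consonants):
        raise ValueError("more correct consonants than consonants produced")
    return len(t.segments) + correct_consonants


def pwp(orig: Transcription, err: Transcription, edits: EditRecord) -> float:
    """Proportion of Whole-word Proximity: pMLU(production)/pMLU(target)."""
    n_cons = len(orig.consonants)
    target = pmlu(orig, n_cons)
    if target == 0:
        raise ValueError("target pMLU is zero")
    unaffected = n_cons - len(edits.consonant_edits)
    return pmlu(err, unaffected) / target


def score_word(
    word: str,
    orig: Transcription,
    pattern: str,
    profile: LanguageProfile,
) -> MetricResult:
    """Apply one pattern to one word and fill in all five measures.

    The single edit record produced by the simulation feeds PCC and the
    correct-consonant term of the production pMLU, keeping the measures
    mutually consistent.
    """
    err, edits = apply_pattern(orig, pattern, profile)
    cfg = profile.scoring
    n_cons = len(orig.consonants)
    try:
        pcc_value: float | None = pcc(orig, edits)
    except ZeroConsonantWord:
        pcc_value = None
    return MetricResult(
        word=word,
        pattern=pattern,
        raw_orig=orig.raw,
        raw_err=err.raw,
        ipc_orig=ipc_score(orig, cfg),
        ipc_err=ipc_score(err, cfg),
        wcm_orig=wcm_score(orig, cfg),
        wcm_err=wcm_score(err, cfg),
        pcc=pcc_value,
        lvn=lvn(orig.raw, err.raw),
        pmlu_orig=pmlu(orig, n_cons),
        pmlu_err=pmlu(err, n_cons - len(edits.consonant_edits)),
        applicable=not edits.is_empty,
        unmatched_clusters=edits.unmatched_clusters,
    )
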