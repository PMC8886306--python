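"""From frequency lists and pronunciation lexica to aggregate effect reports.

The pipeline mirrors common corpus-phonology conventions: hapax legomena
(count 1) are excluded up front; each word *type* is scored once and
contributes to the aggregate with its token count as weight; structural
and combined measures (IPC, WCM, PWP) aggregate over open-class words
only, while the purely relational measures (PCC, LVN) aggregate over all
tokens. Means and standard deviations are token-weighted; the SD uses the
population formula (divide by n) and the SEM divides by sqrt(n_tokens).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .languages import LanguageProfile
from .metrics import MetricResult, score_word
from .phonology import ParseError, parse_transcription

__all__ = [
    "FrequencyList",
    "MetricStats",
    "EffectReport",
    "read_frequency_list",
    "write_frequency_list",
    "read_lexicon",
    "read_closed_class",
    "exclude_hapax",
    "filter_closed_class",
    "top_types",
    "aggregate",
]

log = logging.getLogger(__name__)

#: metrics aggregated over open-class tokens only
STRUCTURAL_METRICS = ("ipc_diff", "wcm_diff", "pwp")
#: metrics aggregated over all tokens
RELATIONAL_METRICS = ("pcc", "lvn")
ALL_METRICS = STRUCTURAL_METRICS + RELATIONAL_METRICS


@dataclass(frozen=True)
class FrequencyList:
    """Case-folded word -> token count mapping."""

    entries: Mapping[str, int]
    source_label: str = ""

    def __post_init__(self) -> None:
        bad = {w: c for w, c in self.entries.items() if c < 1}
        if bad:
            raise ValueError(f"non-positive token counts: {bad}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_tokens(self) -> int:
        return sum(self.entries.values())


def read_frequency_list(path: str | Path, source_label: str = "") -> FrequencyList:
    """Read a ``word<TAB>count`` TSV; duplicate words have counts summed."""
    entries: dict[str, int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'word<TAB>count'")
            word, count = parts[0].casefold(), parts[1]
            try:
                n = int(count)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: bad count {count!r}") from None
            if n < 1:
                raise ValueError(f"{path}:{lineno}: count must be positive")
            entries[word] = entries.get(word, 0) + n
    return FrequencyList(entries, source_label or str(path))


def write_frequency_list(fl: FrequencyList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for word, count in fl.entries.items():
            fh.write(f"{word}\t{count}\n")


def read_lexicon(path: str | Path) -> dict[str, str]:
    """Read a ``word<TAB>sampa`` TSV; the first entry for a word wins."""
    lexicon: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'word<TAB>sampa'")
            word = parts[0].casefold()
            if word not in lexicon:
                lexicon[word] = parts[1]
    return lexicon


def read_closed_class(path: str | Path) -> frozenset[str]:
    """One closed-class word per line; blank lines and '#' comments ignored."""
    words = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            w = line.strip()
            if w and not w.startswith("#"):
                words.add(w.casefold())
    return frozenset(words)


def exclude_hapax(fl: FrequencyList) -> FrequencyList:
    """Drop hapax legomena (words occurring exactly once)."""
    kept = {w: c for w, c in fl.entries.items() if c >= 2}
    if not kept:
        log.warning("hapax exclusion removed every entry of %s", fl.source_label)
    return FrequencyList(kept, fl.source_label)


def filter_closed_class(
    fl: FrequencyList, closed_class: Iterable[str]
) -> FrequencyList:
    """Drop closed-class (function) words; used for the structural and
    combined measures, which are computed over open-class words only."""
    closed = {w.casefold() for w in closed_class}
    return FrequencyList(
        {w: c for w, c in fl.entries.items() if w not in closed}, fl.source_label
    )


def top_types(fl: FrequencyList, k: int = 100) -> list[tuple[str, int]]:
    """Most frequent word types — candidates for manual closed-class curation."""
    return sorted(fl.entries.items(), key=lambda wc: (-wc[1], wc[0]))[:k]


@dataclass(frozen=True)
class MetricStats:
    mean: float
    sd: float
    sem: float
    n_tokens: int
    n_types: int


@dataclass(frozen=True)
class EffectReport:
    pattern: str
    corpus_label: str
    stats: Mapping[str, MetricStats]
    diagnostics: Mapping[str, int] = field(default_factory=dict)


def _weighted_stats(pairs: list[tuple[float, int]]) -> MetricStats:
    n_tokens = sum(w for _, w in pairs)
    mean = sum(x * w for x, w in pairs) / n_tokens
    var = sum(w * (x - mean) ** 2 for x, w in pairs) / n_tokens
    sd = math.sqrt(var)
    return MetricStats(mean, sd, sd / math.sqrt(n_tokens), n_tokens, len(pairs))


def score_corpus(
    pattern: str,
    fl: FrequencyList,
    lexicon: Mapping[str, str],
    profile: LanguageProfile,
) -> tuple[list[tuple[MetricResult, int]], dict[str, int]]:
    """Score every covered word type once; returns (result, count) pairs
    plus skip diagnostics."""
    scored: list[tuple[MetricResult, int]] = []
    diagnostics = {"n_skipped_no_transcription": 0, "n_unparseable": 0,
                   "n_zero_consonant": 0, "n_unmatched_clusters": 0}
    # sorted so that reports are independent of frequency-list row order
    for word, count in sorted(fl.entries.items()):
        sampa = lexicon.get(word)
        if sampa is None:
            diagnostics["n_skipped_no_transcription"] += 1
            continue
        try:
            orig = parse_transcription(sampa, profile.inventory)
        except ParseError as exc:
            log.warning("skipping %r (%s)", word, exc)
            diagnostics["n_unparseable"] += 1
            continue
        result = score_word(word, orig, pattern, profile)
        if result.pcc is None:
            diagnostics["n_zero_consonant"] += 1
        diagnostics["n_unmatched_clusters"] += result.unmatched_clusters
        scored.append((result, count))
    return scored, diagnostics


def aggregate(
    pattern: str,
    fl: FrequencyList,
    lexicon: Mapping[str, str],
    profile: LanguageProfile,
    closed_class: Iterable[str] = (),
    *,
    applicable_only: bool = False,
) -> EffectReport:
    """Token-weighted effect report for one pattern over one corpus subset.

    ``applicable_only`` restricts the aggregation to words where the
    pattern actually applied (a sensitivity analysis; by default words
    with no applicable context contribute their neutral values).
    """
    scored, diagnostics = score_corpus(pattern, fl, lexicon, profile)
    if applicable_only:
        scored = [(r, c) for r, c in scored if r.applicable]
    if not scored:
        raise ValueError("no scorable words in the frequency list")
    closed = {w.casefold() for w in closed_class}
    open_scored = [(r, c) for r, c in scored if r.word not in closed]
    stats: dict[str, MetricStats] = {}
    for metric in STRUCTURAL_METRICS:
        pairs = [(float(getattr(r, metric)), c) for r, c in open_scored]
        if pairs:
            stats[metric] = _weighted_stats(pairs)
    stats["pcc"] = _weighted_stats(
        [(r.pcc, c) for r, c in scored if r.pcc is not None]
    )
    stats["lvn"] = _weighted_stats([(r.lvn, c) for r, c in scored])
    return EffectReport(
        pattern=pattern,
        corpus_label=fl.source_label,
        stats=stats,
        diagnostics=diagnostics,
    )
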