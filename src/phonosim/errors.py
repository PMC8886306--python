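"""Simulation of the six child speech error patterns.

Each pattern turns a target transcription into a "misarticulated" one and
returns an edit record — the ground truth of which consonants were
substituted or deleted, which downstream accuracy measures (notably the
percentage of consonants correct) are computed from.

Patterns are applied across the board: every applicable context in the
word is transformed (an optional application ``rate`` below 1.0, with a
seeded generator, exists for sensitivity studies). Patterns are never
composed with one another.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable, Iterable

from .languages import PATTERN_NAMES, LanguageProfile, PatternSpec
from .phonology import (
    STRESSED_PROSODIES,
    PhonemeInventory,
    Segment,
    Syllable,
    Transcription,
    from_syllables,
)

__all__ = [
    "Edit",
    "EditRecord",
    "apply_pattern",
    "apply_fronting",
    "apply_backing",
    "apply_stopping",
    "apply_r_weakening",
    "apply_weak_syllable_deletion",
    "apply_cluster_reduction",
]


@dataclass(frozen=True)
class Edit:
    """One segmental edit; ``consonant_index`` counts consonants word-wide."""

    kind: str  # 'substitute' | 'delete'
    original_symbol: str
    new_symbol: str | None = None
    consonant_index: int | None = None
    syllable_index: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("substitute", "delete"):
            raise ValueError(f"unknown edit kind: {self.kind!r}")
        if self.kind == "substitute" and self.new_symbol is None:
            raise ValueError("substitute edit requires new_symbol")
        if self.kind == "delete" and self.new_symbol is not None:
            raise ValueError("delete edit carries no new_symbol")


@dataclass(frozen=True)
class EditRecord:
    edits: tuple[Edit, ...] = ()
    #: onset clusters for which no retention rule matched (left unchanged)
    unmatched_clusters: int = 0

    def __len__(self) -> int:
        return len(self.edits)

    def __iter__(self):
        return iter(self.edits)

    @property
    def is_empty(self) -> bool:
        return not self.edits

    @property
    def consonant_edits(self) -> tuple[Edit, ...]:
        """Edits touching consonants, one per affected consonant."""
        return tuple(e for e in self.edits if e.consonant_index is not None)

    @property
    def n_deleted_segments(self) -> int:
        return sum(1 for e in self.edits if e.kind == "delete")


def _always(_: int) -> bool:
    return True


def _rate_gate(rate: float, rng: random.Random | None) -> Callable[[int], bool]:
    if rate >= 1.0:
        return _always
    if rng is None:
        raise ValueError("rate < 1.0 requires a seeded random generator")
    return lambda _i: rng.random() < rate


def _walk_substitute(
    t: Transcription,
    inventory: PhonemeInventory,
    decide: Callable[[Segment, Segment | None], str | None],
    gate: Callable[[int], bool],
) -> tuple[Transcription, EditRecord]:
    """Shared walker for the purely segmental patterns.

    ``decide(segment, next_in_cluster)`` returns a replacement symbol,
    the sentinel ``"-"`` for deletion, or None to leave the segment alone.
    """
    edits: list[Edit] = []
    new_syllables: list[Syllable] = []
    ci = -1
    for si, syl in enumerate(t.syllables):
        parts: list[tuple[Segment, ...]] = []
        for part in (syl.onset, syl.nucleus, syl.coda):
            out: list[Segment] = []
            for k, seg in enumerate(part):
                if not seg.is_consonant:
                    out.append(seg)
                    continue
                ci += 1
                nxt = part[k + 1] if k + 1 < len(part) else None
                action = decide(seg, nxt)
                if action is None or not gate(ci):
                    out.append(seg)
                elif action == "-":
                    edits.append(
                        Edit("delete", seg.symbol, None, ci, si)
                    )
                else:
                    out.append(seg.with_symbol(action, inventory))
                    edits.append(
                        Edit("substitute", seg.symbol, action, ci, si)
                    )
            parts.append(tuple(out))
        new_syllables.append(Syllable(parts[0], parts[1], parts[2], syl.prosody))
    if not edits:
        return t, EditRecord()
    return from_syllables(new_syllables, t.language), EditRecord(tuple(edits))


def _simple_map_pattern(
    t: Transcription,
    spec: PatternSpec,
    inventory: PhonemeInventory,
    gate: Callable[[int], bool],
) -> tuple[Transcription, EditRecord]:
    mapping = spec.substitution_map

    def decide(seg: Segment, _nxt: Segment | None) -> str | None:
        return mapping.get(seg.symbol)

    return _walk_substitute(t, inventory, decide, gate)


def apply_fronting(
    t: Transcription,
    spec: PatternSpec,
    inventory: PhonemeInventory,
    gate: Callable[[int], bool] = _always,
) -> tuple[Transcription, EditRecord]:
    """Velar fronting: velar stops and nasals become coronals (k->t, g->d, N->n)."""
    return _simple_map_pattern(t, spec, inventory, gate)


def apply_backing(
    t: Transcription,
    spec: PatternSpec,
    inventory: PhonemeInventory,
    gate: Callable[[int], bool] = _always,
) -> tuple[Transcription, EditRecord]:
    """Backing: coronal (incl. retroflex) stops and nasals become velars."""
    return _simple_map_pattern(t, spec, inventory, gate)


def apply_r_weakening(
    t: Transcription,
    spec: PatternSpec,
    inventory: PhonemeInventory,
    gate: Callable[[int], bool] = _always,
) -> tuple[Transcription, EditRecord]:
    """Rhotic weakening: every rhotic, onset or coda, is realized as /j/."""
    return _simple_map_pattern(t, spec, inventory, gate)


def apply_stopping(
    t: Transcription,
    spec: PatternSpec,
    inventory: PhonemeInventory,
    gate: Callable[[int], bool] = _always,
) -> tuple[Transcription, EditRecord]:
    """Stopping: fricatives/affricates become plosives.

    A fricative immediately preceding a plosive within the same onset or
    coda cluster is deleted instead (default), avoiding illegal
    plosive+plosive clusters — e.g. ``""sp2:$ket`` loses its /s/. Set the
    pattern option ``cluster_fricative: substitute`` to substitute anyway.
    """
    mapping = spec.substitution_map
    delete_in_cluster = spec.options.get("cluster_fricative", "delete") == "delete"

    def decide(seg: Segment, nxt: Segment | None) -> str | None:
        if seg.symbol not in mapping:
            return None
        if (
            delete_in_cluster
            and nxt is not None
            and nxt.features is not None
            and nxt.features.manner == "plosive"
        ):
            return "-"
        return mapping[seg.symbol]

    return _walk_substitute(t, inventory, decide, gate)


def apply_weak_syllable_deletion(
    t: Transcription,
    spec: PatternSpec,
    inventory: PhonemeInventory,
    gate: Callable[[int], bool] = _always,
) -> tuple[Transcription, EditRecord]:
    """Omission of the pre-tonic syllable.

    If the first syllable bearing primary stress (or a tonal accent) is
    not word-initial, the single syllable immediately preceding it is
    deleted; otherwise the word is unchanged. Only one syllable is ever
    removed.
    """
    stress = t.stressed_index
    if stress is None or stress == 0 or not gate(0):
        return t, EditRecord()
    target = stress - 1
    edits: list[Edit] = []
    ci = -1
    for si, syl in enumerate(t.syllables):
        for seg in syl.segments:
            if seg.is_consonant:
                ci += 1
            if si == target:
                edits.append(
                    Edit(
                        "delete",
                        seg.symbol,
                        None,
                        ci if seg.is_consonant else None,
                        si,
                    )
                )
    remaining = [syl for i, syl in enumerate(t.syllables) if i != target]
    return from_syllables(remaining, t.language), EditRecord(tuple(edits))


def _match_cluster_rule(
    rules: Iterable[dict], cluster: tuple[Segment, ...]
) -> int | None:
    """Index of the cluster member to retain, or None if no rule matches."""
    symbols = [s.symbol for s in cluster]
    for rule in rules:
        if "size" in rule and len(cluster) != rule["size"]:
            continue
        if "exact" in rule and symbols != list(rule["exact"]):
            continue
        if "first" in rule and symbols[0] not in rule["first"]:
            continue
        keep = rule.get("keep", 0)
        if 0 <= keep < len(cluster):
            return keep
    return None


def apply_cluster_reduction(
    t: Transcription,
    spec: PatternSpec,
    inventory: PhonemeInventory,
    gate: Callable[[int], bool] = _always,
) -> tuple[Transcription, EditRecord]:
    """Cluster reduction: every syllable onset of two or more consonants is
    reduced to a single member, chosen by the language's retention rules
    (three-member clusters keep the middle one; /s/-initial clusters keep
    the second member, with the English /sl/ exception; other two-member
    clusters keep the first). Codas are untouched.
    """
    edits: list[Edit] = []
    unmatched = 0
    new_syllables: list[Syllable] = []
    ci = -1
    for si, syl in enumerate(t.syllables):
        onset = syl.onset
        if len(onset) >= 2 and gate(si):
            keep = _match_cluster_rule(spec.cluster_rules, onset)
            if keep is None:
                unmatched += 1
                ci += len(onset)
            else:
                new_onset = []
                for k, seg in enumerate(onset):
                    ci += 1
                    if k == keep:
                        new_onset.append(seg)
                    else:
                        edits.append(Edit("delete", seg.symbol, None, ci, si))
                onset = tuple(new_onset)
        else:
            ci += sum(1 for s in onset if s.is_consonant)
        ci += sum(1 for s in syl.nucleus + syl.coda if s.is_consonant)
        new_syllables.append(Syllable(onset, syl.nucleus, syl.coda, syl.prosody))
    if not edits:
        return t, EditRecord(unmatched_clusters=unmatched)
    return (
        from_syllables(new_syllables, t.language),
        EditRecord(tuple(edits), unmatched_clusters=unmatched),
    )


_DISPATCH = {
    "fronting": apply_fronting,
    "backing": apply_backing,
    "stopping": apply_stopping,
    "r_weakening": apply_r_weakening,
    "weak_syllable_deletion": apply_weak_syllable_deletion,
    "cluster_reduction": apply_cluster_reduction,
}


def apply_pattern(
    t: Transcription,
    name: str,
    profile: LanguageProfile,
    *,
    rate: float = 1.0,
    rng: random.Random | None = None,
) -> tuple[Transcription, EditRecord]:
    """Apply one named error pattern; patterns are never composed."""
    if name not in PATTERN_NAMES:
        raise ValueError(
            f"unknown pattern {name!r}; expected one of {PATTERN_NAMES}"
        )
    gate = _rate_gate(rate, rng)
    return _DISPATCH[name](t, profile.patterns[name], profile.inventory, gate)
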