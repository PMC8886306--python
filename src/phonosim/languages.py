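"""Loading of per-language configuration: inventory, pattern rules, scoring.

Each language ships as one YAML file (``phonosim/data/<code>.yaml``) so
that phoneme classifications, substitution maps, cluster-retention rules
and metric point tables can all be edited without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .phonology import ConsonantFeatures, PhonemeInventory

__all__ = ["LanguageProfile", "load_language", "load_language_file", "available_languages"]

PATTERN_NAMES = (
    "fronting",
    "backing",
    "stopping",
    "r_weakening",
    "weak_syllable_deletion",
    "cluster_reduction",
)


@dataclass(frozen=True)
class ScoringConfig:
    """Point tables for the IPC and WCM complexity indices."""

    ipc: Mapping[str, Any]
    wcm: Mapping[str, Any]


@dataclass(frozen=True)
class PatternSpec:
    """Rules for one error pattern in one language."""

    name: str
    substitution_map: Mapping[str, str]
    cluster_rules: tuple[Mapping[str, Any], ...] = ()
    options: Mapping[str, Any] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.options is None:
            object.__setattr__(self, "options", {})


@dataclass(frozen=True)
class LanguageProfile:
    inventory: PhonemeInventory
    patterns: Mapping[str, PatternSpec]
    scoring: ScoringConfig

    @property
    def language(self) -> str:
        return self.inventory.language


def _build_profile(cfg: dict) -> LanguageProfile:
    consonants = {
        sym: ConsonantFeatures(**feats) for sym, feats in cfg["consonants"].items()
    }
    inventory = PhonemeInventory(
        language=str(cfg["language"]),
        consonants=consonants,
        vowels=frozenset(cfg["vowels"]),
    )
    patterns: dict[str, PatternSpec] = {}
    for name in PATTERN_NAMES:
        entry = cfg.get("patterns", {}).get(name, {})
        subs = dict(entry.get("substitutions", {}))
        unknown = (set(subs) | set(subs.values())) - set(inventory.consonants)
        if unknown:
            raise ValueError(
                f"{name}: symbols not in the {inventory.language!r} "
                f"inventory: {sorted(unknown)}"
            )
        rules = tuple(entry.get("rules", ()))
        options = {
            k: v for k, v in entry.items() if k not in ("substitutions", "rules")
        }
        patterns[name] = PatternSpec(name, subs, rules, options)
    scoring = cfg.get("scoring", {})
    for sym in scoring.get("ipc", {}).get("excluded_symbols", ()):
        if sym not in inventory.consonants:
            raise ValueError(f"IPC exclusion {sym!r} not in inventory")
    return LanguageProfile(
        inventory=inventory,
        patterns=patterns,
        scoring=ScoringConfig(
            ipc=scoring.get("ipc", {}), wcm=scoring.get("wcm", {})
        ),
    )


def load_language_file(path: str | Path) -> LanguageProfile:
    with open(path, encoding="utf-8") as fh:
        return _build_profile(yaml.safe_load(fh))


def load_language(code: str) -> LanguageProfile:
    """Load a bundled language profile by its code ('sv', 'no', 'en')."""
    ref = resources.files("phonosim.data").joinpath(f"{code}.yaml")
    if not ref.is_file():
        raise ValueError(
            f"no bundled language {code!r}; available: {available_languages()}"
        )
    return _build_profile(yaml.safe_load(ref.read_text(encoding="utf-8")))


def available_languages() -> tuple[str, ...]:
    return tuple(
        sorted(
            p.name[:-5]
            for p in resources.files("phonosim.data").iterdir()
            if p.name.endswith(".yaml")
        )
    )
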