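"""Declarative configuration for the extraction pipeline.

A single YAML file drives every stage: cue lists and guard lists for the
extractor, indicator lists for the corpus-level exclusions, and the
association window. The package ships a default file
(``auccaliper/data/default_config.yaml``); users can load a modified copy
with :func:`load_config`. Keeping the lists in data rather than code
makes the inevitably judgement-laden choices (which MeSH headings mark a
pharmacokinetic study, which words are competing statistics) auditable
and easy to override.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["ExtractionConfig", "ExclusionConfig", "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class ExtractionConfig:
    phrase_cues: dict[str, tuple[str, ...]]
    acronym_cues: dict[str, tuple[str, ...]]
    competing_cues: tuple[str, ...]
    unit_suffixes: tuple[str, ...]
    association_window: int
    scale_definition_patterns: tuple[str, ...]


@dataclass(frozen=True)
class ExclusionConfig:
    max_short_words: int
    pharmacokinetic_mesh: tuple[str, ...]
    pharmacokinetic_pubtypes: tuple[str, ...]
    meta_analysis_pubtypes: tuple[str, ...]
    meta_analysis_title_keywords: tuple[str, ...]
    tutorial_pubtypes: tuple[str, ...]
    tutorial_title_keywords: tuple[str, ...]


@dataclass(frozen=True)
class PipelineConfig:
    extraction: ExtractionConfig
    exclusions: ExclusionConfig
    raw: dict = field(compare=False, repr=False, default_factory=dict)

    def digest(self) -> str:
        """Stable hash of the effective configuration, for provenance."""
        payload = json.dumps(self.raw, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _tup(seq) -> tuple:
    return tuple(seq or ())


def _from_mapping(data: dict) -> PipelineConfig:
    ex = data["extraction"]
    xc = data["exclusions"]
    extraction = ExtractionConfig(
        phrase_cues={k: _tup(v) for k, v in ex["phrase_cues"].items()},
        acronym_cues={k: _tup(v) for k, v in ex["acronym_cues"].items()},
        competing_cues=_tup(ex["competing_cues"]),
        unit_suffixes=_tup(ex["unit_suffixes"]),
        association_window=int(ex["association_window"]),
        scale_definition_patterns=_tup(ex["scale_definition_patterns"]),
    )
    exclusions = ExclusionConfig(
        max_short_words=int(xc["max_short_words"]),
        pharmacokinetic_mesh=_tup(xc["pharmacokinetic_mesh"]),
        pharmacokinetic_pubtypes=_tup(xc["pharmacokinetic_pubtypes"]),
        meta_analysis_pubtypes=_tup(xc["meta_analysis_pubtypes"]),
        meta_analysis_title_keywords=_tup(xc["meta_analysis_title_keywords"]),
        tutorial_pubtypes=_tup(xc["tutorial_pubtypes"]),
        tutorial_title_keywords=_tup(xc["tutorial_title_keywords"]),
    )
    return PipelineConfig(extraction=extraction, exclusions=exclusions, raw=data)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a pipeline configuration; with no path, the packaged default."""
    if path is None:
        text = (resources.files("auccaliper.data") / "default_config.yaml").read_text()
    else:
        text = Path(path).read_text()
    return _from_mapping(yaml.safe_load(text))


DEFAULT_CONFIG = load_config()
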