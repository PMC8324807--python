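"""Run configuration: one structured file driving every pipeline stage.

A config is a YAML mapping with optional sections ``template``, ``generator``,
``cleaning``, ``extraction``, ``stats``, ``screen`` and top-level ``seed`` /
``outdir``.  Unknown keys raise with the offending field named, so typos
fail before any work is done; the resolved config is written next to the
outputs of every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .amplicon import AmpliconTemplate, DEFAULT_TEMPLATE
from .processing import CleanParams
from .reads import DEFAULT_EDIT_TRIPLET, ReadErrorModel
from .selection import ScreenParams
from .stats import ENRICHED_THRESHOLD, FUNCTIONAL_THRESHOLD

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """A config file failed validation; message names the field."""


@dataclass(frozen=True)
class GeneratorConfig:
    n_reads: int = 200_000
    substitution_rate: float = 0.002
    n_rate: float = 0.0005
    adapter_seq: str = "AGATCGGAAGAGCACACGTC"
    adapter_rate: float = 0.01
    quality_high: int = 37
    quality_low: int = 10
    revcomp_prob: float = 0.5
    edit_triplet: dict = field(default_factory=lambda: dict(DEFAULT_EDIT_TRIPLET))

    def error_model(self) -> ReadErrorModel:
        return ReadErrorModel(
            substitution_rate=self.substitution_rate,
            n_rate=self.n_rate,
            adapter_seq=self.adapter_seq,
            adapter_rate=self.adapter_rate,
            quality_high=self.quality_high,
            quality_low=self.quality_low,
        )


@dataclass(frozen=True)
class ExtractionConfig:
    max_anchor_mm: int = 2
    min_base_q: int = 20


@dataclass(frozen=True)
class StatsConfig:
    functional_threshold: float = FUNCTIONAL_THRESHOLD
    enriched_threshold: float = ENRICHED_THRESHOLD
    ef_numerator: str = "edited"


def _build(cls, section: dict, name: str):
    known = set(cls.__dataclass_fields__)
    extra = set(section) - known
    if extra:
        raise ConfigError(f"{name}: unknown keys {sorted(extra)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{name}: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration for one pipeline run."""

    template: AmpliconTemplate = DEFAULT_TEMPLATE
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cleaning: CleanParams = field(default_factory=CleanParams)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    screen: ScreenParams = field(default_factory=ScreenParams)
    seed: int = 0
    outdir: str = "bess_out"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        known = {
            "template", "generator", "cleaning", "extraction", "stats",
            "screen", "seed", "outdir",
        }
        extra = set(raw) - known
        if extra:
            raise ConfigError(f"unknown top-level keys {sorted(extra)}")
        tmpl = raw.get("template")
        if tmpl is None:
            template = DEFAULT_TEMPLATE
        elif isinstance(tmpl, str):
            template = AmpliconTemplate.from_yaml(tmpl)
        else:
            try:
                template = AmpliconTemplate.from_dict(tmpl)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"template: {exc}") from exc
        screen_raw = dict(raw.get("screen", {}))
        if "seed" not in screen_raw and "seed" in raw:
            screen_raw["seed"] = int(raw["seed"])
        return cls(
            template=template,
            generator=_build(GeneratorConfig, raw.get("generator", {}), "generator"),
            cleaning=_build(CleanParams, raw.get("cleaning", {}), "cleaning"),
            extraction=_build(ExtractionConfig, raw.get("extraction", {}), "extraction"),
            stats=_build(StatsConfig, raw.get("stats", {}), "stats"),
            screen=_build(ScreenParams, screen_raw, "screen"),
            seed=int(raw.get("seed", 0)),
            outdir=str(raw.get("outdir", "bess_out")),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if raw is not None and not isinstance(raw, dict):
            raise ConfigError(f"config {path} must be a YAML mapping")
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return {
            "template": self.template.to_dict(),
            "generator": asdict(self.generator),
            "cleaning": asdict(self.cleaning),
            "extraction": asdict(self.extraction),
            "stats": asdict(self.stats),
            "screen": asdict(self.screen),
            "seed": self.seed,
            "outdir": self.outdir,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
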