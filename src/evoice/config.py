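"""YAML configuration covering every tunable of the chain."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .frontend import AnalysisConfig, BandMap, make_band_map
from .gain import GainParams
from .noise import NoiseTrackerParams
from .strategy import StrategyConfig


@dataclass(frozen=True)
class BandConfig:
    m: int = 24
    f_low: float = 200.0
    f_high: float = 7800.0


@dataclass(frozen=True)
class FullConfig:
    """Everything needed to run the chain end to end."""

    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    bands: BandConfig = field(default_factory=BandConfig)
    noise: NoiseTrackerParams = field(default_factory=NoiseTrackerParams)
    gain: GainParams = field(default_factory=GainParams)
    strategy: StrategyConfig = field(default_factory=StrategyConfig)

    def band_map(self) -> BandMap:
        return make_band_map(rate=self.analysis.rate, m=self.bands.m,
                             f_low=self.bands.f_low, f_high=self.bands.f_high,
                             fft_size=self.analysis.fft_size)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None) -> FullConfig:
    """Load a YAML config; missing sections/keys keep their defaults."""
    if path is None:
        return FullConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    sections = {
        "analysis": AnalysisConfig,
        "bands": BandConfig,
        "noise": NoiseTrackerParams,
        "gain": GainParams,
        "strategy": StrategyConfig,
    }
    kwargs = {}
    for name, cls in sections.items():
        kwargs[name] = cls(**raw.get(name, {}))
    unknown = set(raw) - set(sections)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return FullConfig(**kwargs)


def save_config(config: FullConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
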