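"""Analysis configuration: one nested dataclass, YAML round-trippable.

Every knob the estimation and statistics layers consult lives here so a whole
analysis is reproducible from (data, config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class LaguerreConfig:
    alpha: float = 0.7      # DLF decay, in (0,1)
    L: int = 5              # number of basis functions
    M: int = 120            # memory in bins (480 ms at 4 ms)


@dataclass
class FitConfig:
    test_fraction: float = 0.2   # contiguous tail held out for out-of-sample rho
    ridge_lambda: float = 0.0    # optional Tikhonov penalty on the Gram matrix
    smooth_sigma: float = 0.0    # optional Gaussian smoothing (bins) before rho


@dataclass
class SelectConfig:
    epsilon: float = 0.01        # minimum out-of-sample rho gain to add an input


@dataclass
class SurrogateConfig:
    n: int = 40                  # surrogate models per significance test
    threshold: float = 1e-4      # model deemed significant when p < threshold
    mode: str = "circular"       # "circular" shift (default) or "permute"
    min_shift: float = 1.0       # minimum circular shift, seconds


@dataclass
class BandsConfig:
    filter_theta: tuple[float, float] = (4.0, 9.0)   # filter-domain theta, Hz
    signal_theta: tuple[float, float] = (4.0, 7.0)   # spike-train theta, Hz
    norm_band: tuple[float, float] = (1.0, 50.0)     # signal-spectrum norm band


@dataclass
class GpdmConfig:
    n_modes: int = 3
    center: bool = False         # mean-centre rows before SVD (PCA variant)


@dataclass
class AnalysisConfig:
    bin_width: float = 0.004
    laguerre: LaguerreConfig = field(default_factory=LaguerreConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    select: SelectConfig = field(default_factory=SelectConfig)
    surrogate: SurrogateConfig = field(default_factory=SurrogateConfig)
    bands: BandsConfig = field(default_factory=BandsConfig)
    gpdm: GpdmConfig = field(default_factory=GpdmConfig)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "AnalysisConfig":
        cfg = cls()
        for section, sub in raw.items():
            if not hasattr(cfg, section):
                continue
            target = getattr(cfg, section)
            if isinstance(sub, dict):
                for key, val in sub.items():
                    if hasattr(target, key):
                        if isinstance(val, list):
                            val = tuple(val)
                        setattr(target, key, val)
            else:
                setattr(cfg, section, sub)
        return cfg


def default_config() -> AnalysisConfig:
    return AnalysisConfig()
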