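"""Pipeline configuration.

Every tunable of the extraction algorithm lives here, with defaults equal
to the published values of the retrieval method where one exists (PELT
penalty 0.5, minimum segment 14 days, thresholds 10/25/50 %, 0.25-of-max
peak floor, 2.0 g C m⁻² day⁻¹ vegetation floor, 30° N latitude cut, up to
20 smoothing iterations, 100 bootstrap replicates).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # amplitude thresholds, as fractions of the bottom→peak amplitude
    thresholds: tuple[float, ...] = (0.10, 0.25, 0.50)
    # PELT
    penalty: float = 0.5
    min_segment_days: int = 14
    normalize: bool = False  # z-score before PELT (robustness option, off)
    # Savitzky-Golay smoothing + Grubbs outlier loop
    sg_window_days: int = 31
    sg_polyorder: int = 3
    grubbs_alpha: float = 0.05
    max_iter: int = 20
    # cycle detection/filtering
    relative_peak_floor: float = 0.25
    # alternations shallower than this fraction of the segment-mean range
    # are noise wiggles, merged before cycle assembly
    min_relative_amplitude: float = 0.25
    # grid masking
    gpp_floor: float = 2.0
    latitude_min: float = 30.0
    # bootstrap
    bootstrap_n: int = 100
    bootstrap_scheme: str = "residual"  # "residual" | "case"
    min_bootstrap_successes: int = 50
    # randomness: a single seed feeds every stochastic step
    seed: int = 0

    def __post_init__(self) -> None:
        self.thresholds = tuple(sorted(float(t) for t in self.thresholds))
        if not all(0.0 < t < 1.0 for t in self.thresholds):
            raise ValueError("thresholds must be fractions in (0, 1)")
        if self.sg_window_days % 2 == 0 or self.sg_window_days < 5:
            raise ValueError("sg_window_days must be odd and >= 5")
        if self.sg_polyorder >= self.sg_window_days:
            raise ValueError("sg_polyorder must be < sg_window_days")
        if self.penalty < 0:
            raise ValueError("penalty must be non-negative")
        if self.bootstrap_scheme not in ("residual", "case"):
            raise ValueError("bootstrap_scheme must be 'residual' or 'case'")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["thresholds"] = list(self.thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
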