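"""End-to-end per-series extraction: raw GPP → phenology records."""

from __future__ import annotations

from dataclasses import dataclass

from .changepoints import pelt_changepoints
from .config import PipelineConfig
from .cycles import detect_cycles, filter_cycles
from .series_prep import interpolate_to_daily, iterative_smooth
from .transitions import extract_transitions
from .types import Cycle, GppSeries, PhenologyMetrics, SmoothedSeries


@dataclass
class ExtractionResult:
    """Everything the pipeline produced for one series-year."""

    series: GppSeries
    smoothed: SmoothedSeries
    cycles: list[Cycle]  # retained cycles, in calendar order
    metrics: list[PhenologyMetrics]  # one per retained cycle

    @property
    def season_count(self) -> int:
        return len(self.cycles)


class NoCycleError(ValueError):
    """The series has no retained photosynthesis cycle (e.g. flat GPP)."""


def extract_phenology(series: GppSeries,
                      config: PipelineConfig | None = None) -> ExtractionResult:
    """Run interpolation → iterative smoothing → PELT → cycles → transitions.

    Raises :class:`InsufficientDataError` for unusable input and
    :class:`NoCycleError` when no cycle survives (callers processing many
    pixels emit the pixel as missing).
    """
    cfg = config or PipelineConfig()
    daily = interpolate_to_daily(series)
    smoothed = iterative_smooth(daily,
                                window_days=cfg.sg_window_days,
                                polyorder=cfg.sg_polyorder,
                                grubbs_alpha=cfg.grubbs_alpha,
                                max_iter=cfg.max_iter)
    cps = pelt_changepoints(smoothed, penalty=cfg.penalty,
                            min_segment_days=cfg.min_segment_days,
                            normalize=cfg.normalize)
    cycles = filter_cycles(detect_cycles(cps, smoothed,
                                         cfg.min_relative_amplitude),
                           cfg.relative_peak_floor)
    if not cycles:
        raise NoCycleError("no retained photosynthesis cycle in this year")
    metrics = [extract_transitions(c, smoothed, cfg.thresholds,
                                   year=series.year, season_index=i + 1)
               for i, c in enumerate(cycles)]
    return ExtractionResult(series=series, smoothed=smoothed,
                            cycles=cycles, metrics=metrics)


def result_records(result: ExtractionResult) -> list[dict]:
    """Flat per-season dict records (year, season, sos10 … los50)."""
    return [m.to_record() for m in result.metrics]
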