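"""Pipeline configuration: every methodological constant as a named key.

The defaults are the production settings of the methodology — 5-min sampling,
48-sample windows with 5 presamples (seasonality 53), the 18-missing-sample
discard rule, 30-min gap filling on training data, a 10-day test split, the
{30, 45, 60, 75}-min horizons, and the full identification grids.  Scaled-down
grids for quick runs are an explicit override, never a silent default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .benchmarks import BenchmarkGrid
from .clustering import ClusterSearchGrid
from .seasonal_models import SarimaGrid


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    sampling_minutes: int = 5
    pp_window_samples: int = 48
    presamples: int = 5
    seasonality: int = 53
    burn_in_samples: int = 3
    max_missing_pp: int = 18
    gap_fill_max_minutes: int = 30
    test_days: int = 10
    ph_minutes: tuple[int, ...] = (30, 45, 60, 75)
    include_hypo_treatments: bool = True
    cluster_grid: ClusterSearchGrid = field(default_factory=ClusterSearchGrid)
    sarima_grid: SarimaGrid = field(default_factory=SarimaGrid)
    benchmark_grid: BenchmarkGrid = field(default_factory=BenchmarkGrid)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seasonality != self.pp_window_samples + self.presamples:
            raise ConfigError(
                "seasonality must equal pp_window_samples + presamples "
                f"({self.pp_window_samples} + {self.presamples})"
            )
        if self.burn_in_samples < 1:
            raise ConfigError("burn_in_samples must be >= 1")
        if any(ph % self.sampling_minutes for ph in self.ph_minutes):
            raise ConfigError("every horizon must be a multiple of the sampling interval")

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload)
        for key, grid_cls in (
            ("cluster_grid", ClusterSearchGrid),
            ("sarima_grid", SarimaGrid),
            ("benchmark_grid", BenchmarkGrid),
        ):
            if key in payload and isinstance(payload[key], dict):
                payload[key] = grid_cls(
                    **{k: _as_tuple(v) for k, v in payload[key].items()}
                )
        if "ph_minutes" in payload:
            payload["ph_minutes"] = tuple(payload["ph_minutes"])
        return cls(**payload)


def _as_tuple(value):
    return tuple(value) if isinstance(value, list) else value
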