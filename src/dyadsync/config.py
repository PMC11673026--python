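"""Pipeline configuration: every tunable of the analysis in one record."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field

import yaml


@dataclass
class PipelineConfig:
    """Parameters of the preprocessing, spectral and concordance stages.

    Defaults follow the acquisition/processing recipe the pipeline
    implements: 0.1-40 Hz zero-phase bandpass, channel rejection at a 0.9
    correlation criterion, continuous artifact rejection in the 20-40 Hz
    band at a 10 dB spectral threshold, 500 ms epochs, alpha = 8-12 Hz
    (relative power by default), 2 s bins (4 epochs) and lags 0-3 bins.
    """

    sampling_rate_hz: float = 250.0
    band_low_hz: float = 0.1
    band_high_hz: float = 40.0
    filter_order: int = 5
    channel_reject_threshold: float = 0.9
    channel_reject_window_s: float = 1.0
    artifact_band_hz: tuple[float, float] = (20.0, 40.0)
    artifact_threshold_db: float = 10.0
    artifact_window_s: float = 0.5
    artifact_per_condition: bool = True
    epoch_length_s: float = 0.5
    alpha_band_hz: tuple[float, float] = (8.0, 12.0)
    total_band_hz: tuple[float, float] = (1.0, 40.0)
    alpha_mode: str = "relative"  # "relative" | "absolute"
    spectrum_resolution_hz: float = 0.5
    bin_epochs: int = 4
    lags_bins: tuple[int, ...] = (0, 1, 2, 3)
    ccc_ddof: int = 0  # 0 = population moments, 1 = sample moments
    fdr_method: str = "fdr_bh"
    winsorize: bool = False
    winsorize_limits: tuple[float, float] = (0.05, 0.05)
    interp_n_neighbors: int = 6
    interp_radius_m: float | None = None  # None = 3x median nearest-neighbour distance

    def __post_init__(self) -> None:
        n = self.epoch_length_s * self.sampling_rate_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("epoch_length_s x sampling_rate_hz must be an integer")
        if self.bin_epochs < 1:
            raise ValueError("bin_epochs must be >= 1")
        if any(l < 0 for l in self.lags_bins):
            raise ValueError("lags must be nonnegative")
        if self.alpha_mode not in ("relative", "absolute"):
            raise ValueError("alpha_mode must be 'relative' or 'absolute'")

    @property
    def epoch_samples(self) -> int:
        return int(round(self.epoch_length_s * self.sampling_rate_hz))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        # tuples -> lists for clean YAML
        with open(path, "w") as fh:
            yaml.safe_dump({k: list(v) if isinstance(v, tuple) else v
                            for k, v in d.items()}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        fields = cls.__dataclass_fields__
        kwargs = {}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown config key: {k}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)
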