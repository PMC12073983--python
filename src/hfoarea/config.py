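"""Analysis configuration: every tunable constant of the pipeline in one place."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    """Pipeline constants.

    Detection: the envelope threshold is median + ``threshold_k`` scaled-MAD
    units of the analytic envelope, computed per channel and epoch; events
    shorter than the band's minimum duration are dropped, events separated by
    less than ``merge_gap_ms`` are merged, and each surviving event must show
    an in-band spectral peak >= ``spectral_prominence_db`` above the trough
    towards the low-frequency range.
    """

    ripple_band: tuple[float, float] = (80.0, 240.0)
    fast_ripple_band: tuple[float, float] = (250.0, 490.0)
    threshold_k: float = 3.0
    min_duration_ms: dict = field(
        default_factory=lambda: {"ripple": 20.0, "fast_ripple": 10.0}
    )
    merge_gap_ms: float = 10.0
    spectral_prominence_db: float = 6.0
    validation_pad_ms: float = 10.0
    # HFO-area rule
    rate_quantile: float = 0.95
    quantile_method: str = "linear"
    consistency_threshold_pct: float = 50.0
    # preprocessing
    epoch_length_s: float = 300.0
    target_fs: float = 2000.0
    # statistics
    ci_level: float = 0.95
    meta_transform: str = "logit"  # or "freeman_tukey"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ripple_band", "fast_ripple_band"):
            low, high = getattr(self, name)
            if not (0 < low < high):
                raise ValueError(f"{name} must satisfy 0 < low < high")
        for band, dur in self.min_duration_ms.items():
            if dur <= 0:
                raise ValueError(f"min_duration_ms[{band!r}] must be positive")
        if self.threshold_k <= 0:
            raise ValueError("threshold_k must be positive")
        if not 0 < self.rate_quantile < 1:
            raise ValueError("rate_quantile must be in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")
        if self.meta_transform not in ("logit", "freeman_tukey"):
            raise ValueError("meta_transform must be 'logit' or 'freeman_tukey'")

    def min_duration_s(self, band: str) -> float:
        return self.min_duration_ms[band] / 1000.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["ripple_band"] = list(d["ripple_band"])
        d["fast_ripple_band"] = list(d["fast_ripple_band"])
        return d

    def config_hash(self) -> str:
        """Stable hash identifying the configuration in reports/logs."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for name in ("ripple_band", "fast_ripple_band"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)
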