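"""Core data containers shared across the pipeline.

Conventions: times are seconds from recording start, sample indices are
0-based, and every time interval is half-open ``[t_start, t_end)``.
Signal amplitudes are in microvolts (uV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

RIPPLE_BAND = (80.0, 240.0)
FAST_RIPPLE_BAND = (250.0, 490.0)

#: band name -> (low, high) Hz
BANDS: dict[str, tuple[float, float]] = {
    "ripple": RIPPLE_BAND,
    "fast_ripple": FAST_RIPPLE_BAND,
}


@dataclass
class ChannelMeta:
    """Metadata for one recorded channel (contact or bipolar derivation)."""

    name: str
    electrode: str | None = None  # None for channels that are already bipolar
    contact: int | None = None
    ch_type: str = "sEEG"  # sEEG | ECoG
    cephalic: bool = True
    bad: bool = False

    def __post_init__(self) -> None:
        if self.ch_type not in ("sEEG", "ECoG"):
            raise ValueError(f"ch_type must be sEEG or ECoG, got {self.ch_type!r}")


@dataclass
class ArtifactSection:
    """A marked artefact interval, on one channel or on all (channel=None)."""

    channel: str | None
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("artifact section requires t_end > t_start")


@dataclass
class Recording:
    """Multichannel iEEG segment: ``samples`` is (n_channels, n_times) in uV."""

    samples: np.ndarray
    fs: float
    channels: list[ChannelMeta]
    artifact_sections: list[ArtifactSection] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError("channel metadata length does not match samples")
        for sec in self.artifact_sections:
            if sec.t_end > self.duration_s + 1e-9:
                raise ValueError("artifact section extends past recording end")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)


@dataclass
class Epoch:
    """A 5-minute analysis window cut from a recording.

    ``artifact_intervals`` maps channel index to (t0, t1) pairs in seconds
    relative to the epoch start; those stretches are excluded from event
    detection and from the effective duration used for rate computation.
    """

    samples: np.ndarray
    fs: float
    epoch_index: int
    t_start: float
    channel_names: list[str]
    valid_mask: np.ndarray  # per-channel bool: channel analysable this epoch
    artifact_intervals: dict[int, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    def masked_seconds(self, ch_idx: int) -> float:
        return float(sum(t1 - t0 for t0, t1 in self.artifact_intervals.get(ch_idx, [])))

    def effective_minutes(self, ch_idx: int) -> float:
        """Epoch duration minus marked artefact time, in minutes."""
        return max(self.duration_s - self.masked_seconds(ch_idx), 0.0) / 60.0


@dataclass
class BandEvent:
    """A single band-limited oscillation burst on one channel."""

    channel_id: str
    band: str  # "ripple" or "fast_ripple"
    t_start: float
    t_end: float
    peak_envelope: float
    peak_freq: float

    def __post_init__(self) -> None:
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if not self.t_end > self.t_start:
            raise ValueError("event requires t_end > t_start")
        low, high = BANDS[self.band]
        if not (low <= self.peak_freq <= high):
            raise ValueError(
                f"peak_freq {self.peak_freq:.1f} Hz outside {self.band} band"
            )

    def overlaps(self, other: "BandEvent") -> bool:
        return self.t_start < other.t_end and other.t_start < self.t_end


@dataclass
class HfoEvent:
    """A ripple co-occurring with >=1 fast ripple on the same channel."""

    channel_id: str
    t_start: float
    t_end: float
    ripple: BandEvent
    fast_ripple: BandEvent

    def __post_init__(self) -> None:
        if self.ripple.channel_id != self.channel_id or self.fast_ripple.channel_id != self.channel_id:
            raise ValueError("paired events must share the HFO's channel")
        if not self.ripple.overlaps(self.fast_ripple):
            raise ValueError("ripple and fast ripple must overlap in time")


@dataclass
class RateMatrix:
    """Per-channel, per-epoch HFO rates (events/min).

    ``rates`` and ``effective_minutes`` are channels x epochs DataFrames with
    identical indices; NaN marks channel-epochs that were not analysable.
    """

    rates: pd.DataFrame
    effective_minutes: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.rates.index.equals(self.effective_minutes.index) or not self.rates.columns.equals(
            self.effective_minutes.columns
        ):
            raise ValueError("rates and effective_minutes must be aligned")
        if (self.rates.to_numpy() < -1e-12).any():
            raise ValueError("rates must be non-negative")

    @property
    def n_epochs(self) -> int:
        return self.rates.shape[1]

    @property
    def channels(self) -> list[str]:
        return list(self.rates.index)


@dataclass
class HfoArea:
    """The patient's HFO area: channels with sustained top-percentile rates."""

    channels: frozenset[str]
    consistency: dict[str, float]  # channel -> % of analysable epochs in candidate set
    conclusive: bool
    n_epochs: int
    rate_thresholds: list[float]  # per-epoch 95th-percentile rate (events/min)

    def __post_init__(self) -> None:
        self.channels = frozenset(self.channels)
        if self.conclusive != bool(self.channels):
            raise ValueError("conclusive must equal non-emptiness of the channel set")


@dataclass
class PatientRecord:
    """One patient's analysis result joined with clinical data."""

    patient_id: str
    centre_id: str
    hfo_area: HfoArea | None
    resected_channels: frozenset[str]
    ilae: int
    electrode_type: str = "sEEG"  # sEEG | ECoG | both
    age: float | None = None
    sex: str | None = None
    pathology: int | None = None  # 0 n/a, 1 non-FCD lesion, 2 MTLE, 3 FCD
    n_channels: int | None = None  # i
    n_resected_channels: int | None = None  # k
    follow_up_months: float = 24.0  # fu

    def __post_init__(self) -> None:
        self.resected_channels = frozenset(self.resected_channels)
        if self.ilae not in range(1, 7):
            raise ValueError(f"ilae must be in 1..6, got {self.ilae}")
        if self.follow_up_months < 24:
            raise ValueError("follow_up_months >= 24 is an inclusion criterion")
        if self.electrode_type not in ("sEEG", "ECoG", "both"):
            raise ValueError(f"bad electrode_type {self.electrode_type!r}")

    @property
    def conclusive(self) -> bool:
        return self.hfo_area is not None and self.hfo_area.conclusive

    @property
    def seizure_free(self) -> bool:
        return self.ilae == 1

    @property
    def n_area_channels(self) -> int:  # j
        return len(self.hfo_area.channels) if self.hfo_area is not None else 0


@dataclass(frozen=True)
class ConfusionMatrix:
    """Patient-level 2x2 table of HFO-area prediction vs seizure outcome."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        for name in ("TP", "TN", "FP", "FN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def as_dict(self) -> dict[str, int]:
        return {"TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN}
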