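"""Two-stage HFO detection: robust envelope threshold + spectral validation.

Stage 1 marks stretches where the analytic (Hilbert) envelope of the
band-filtered trace exceeds a per-channel, per-epoch robust threshold
(median + k scaled-MAD units, default k = 3). Stage 2 rejects "false" events
whose raw-signal spectrum lacks an isolated in-band peak — the signature that
separates genuine band-limited oscillations from sharp broadband transients.
Ripples and fast ripples detected this way are then paired by temporal
co-occurrence into HFOs, and rates are counts per effective minute.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import AnalysisConfig
from .containers import BANDS, BandEvent, Epoch, HfoEvent, RateMatrix
from .preprocessing import bandpass

MAD_SCALE = 1.4826  # consistency factor: scaled MAD estimates Gaussian sigma
_LOWFREQ_EDGE_HZ = 60.0


def analytic_envelope(x: np.ndarray) -> np.ndarray:
    """Magnitude of the analytic signal along the last axis."""
    return np.abs(sps.hilbert(x, axis=-1))


def _mask_array(epoch: Epoch, ch_idx: int) -> np.ndarray:
    """Boolean mask of artefact samples for one channel of an epoch."""
    n = epoch.samples.shape[1]
    mask = np.zeros(n, dtype=bool)
    for t0, t1 in epoch.artifact_intervals.get(ch_idx, []):
        mask[int(t0 * epoch.fs) : int(np.ceil(t1 * epoch.fs))] = True
    return mask


def _runs(above: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where `above` is True."""
    diff = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    stops = np.flatnonzero(diff == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, len(above)]
    return list(zip(starts.tolist(), stops.tolist()))


def detect_band_events(
    filtered_epoch: Epoch,
    band: str,
    config: AnalysisConfig | None = None,
    raw_epoch: Epoch | None = None,
) -> list[BandEvent]:
    """Detect band-limited oscillation bursts in a band-filtered epoch.

    ``filtered_epoch`` must already be band-passed to ``band``. When
    ``raw_epoch`` is given, each candidate is additionally screened with
    :func:`validate_event_spectrum` on the unfiltered signal.
    Times in the returned events are absolute (seconds from recording start).
    """
    config = config or AnalysisConfig()
    if band not in BANDS:
        raise ValueError(f"unknown band {band!r}")
    min_dur = config.min_duration_s(band)
    if min_dur <= 0:
        raise ValueError("min_duration must be positive")
    low, high = BANDS[band]
    fs = filtered_epoch.fs
    merge_gap = int(round(config.merge_gap_ms / 1000.0 * fs))
    min_len = int(round(min_dur * fs))

    events: list[BandEvent] = []
    env = analytic_envelope(filtered_epoch.samples)
    for ci, name in enumerate(filtered_epoch.channel_names):
        if not filtered_epoch.valid_mask[ci]:
            continue
        mask = _mask_array(filtered_epoch, ci)
        e = env[ci]
        usable = e[~mask] if mask.any() else e
        med = np.median(usable)
        mad = MAD_SCALE * np.median(np.abs(usable - med))
        thresh = med + config.threshold_k * mad
        if mad == 0:
            continue  # flat channel: nothing to detect
        above = e > thresh
        if not above.any():
            continue
        runs = _runs(above)
        # merge runs separated by < merge_gap samples
        merged: list[list[int]] = [list(runs[0])]
        for start, stop in runs[1:]:
            if start - merged[-1][1] < merge_gap:
                merged[-1][1] = stop
            else:
                merged.append([start, stop])
        x_f = filtered_epoch.samples[ci]
        for start, stop in merged:
            if stop - start < min_len:
                continue
            if mask[start:stop].any():
                continue  # overlaps marked artefact time
            seg = x_f[start:stop]
            freqs, psd = sps.periodogram(seg, fs=fs, window="hann")
            in_band = (freqs >= low) & (freqs <= high)
            if in_band.any() and psd[in_band].sum() > 0:
                peak_freq = float(freqs[in_band][np.argmax(psd[in_band])])
            else:
                peak_freq = (low + high) / 2.0
            peak_freq = min(max(peak_freq, low), high)
            ev = BandEvent(
                channel_id=name,
                band=band,
                t_start=filtered_epoch.t_start + start / fs,
                t_end=filtered_epoch.t_start + stop / fs,
                peak_envelope=float(e[start:stop].max()),
                peak_freq=peak_freq,
            )
            if raw_epoch is None or validate_event_spectrum(ev, raw_epoch, config):
                events.append(ev)
    events.sort(key=lambda ev: (ev.channel_id, ev.t_start))
    return events


def validate_event_spectrum(
    event: BandEvent, raw_epoch: Epoch, config: AnalysisConfig | None = None
) -> bool:
    """True iff the raw-signal periodogram over the (padded) event window has
    an in-band local maximum standing >= 6 dB above the spectral trough
    between that peak and the low-frequency (<60 Hz) range.

    Sharp transients have monotonically decaying spectra with no isolated
    in-band peak, so they fail this check ("false ripple" rejection).
    """
    config = config or AnalysisConfig()
    low, high = BANDS[event.band]
    fs = raw_epoch.fs
    pad = config.validation_pad_ms / 1000.0
    try:
        ci = raw_epoch.channel_names.index(event.channel_id)
    except ValueError:
        raise ValueError(f"event channel {event.channel_id!r} not in epoch") from None
    i0 = max(int((event.t_start - raw_epoch.t_start - pad) * fs), 0)
    i1 = min(int(np.ceil((event.t_end - raw_epoch.t_start + pad) * fs)),
             raw_epoch.samples.shape[1])
    if i1 - i0 < 8:
        return False
    seg = raw_epoch.samples[ci, i0:i1]
    freqs, psd = sps.periodogram(seg, fs=fs, window="hann")
    in_band = (freqs >= low) & (freqs <= high)
    if not in_band.any() or psd[in_band].max() <= 0:
        return False
    peak_idx = np.flatnonzero(in_band)[np.argmax(psd[in_band])]
    peak = psd[peak_idx]
    # the in-band maximum must be a genuine local maximum: a burst centred
    # outside the band leaves only a rising spectral slope inside it
    if peak_idx > 0 and psd[peak_idx - 1] > peak:
        return False
    if peak_idx < len(psd) - 1 and psd[peak_idx + 1] > peak:
        return False
    between = (freqs >= _LOWFREQ_EDGE_HZ) & (freqs <= freqs[peak_idx])
    if not between.any():
        return False
    trough = psd[between].min()
    if trough <= 0:
        return True
    prominence_db = 10.0 * np.log10(peak / trough)
    return bool(prominence_db >= config.spectral_prominence_db)


def pair_cooccurrence(
    ripples: list[BandEvent], fast_ripples: list[BandEvent]
) -> list[HfoEvent]:
    """Pair each ripple with temporally overlapping fast ripples into HFOs.

    One HFO per ripple at most (several nested fast ripples do not double
    count); the HFO extent is the union of the paired events' extents.
    """
    channels = {ev.channel_id for ev in ripples} | {ev.channel_id for ev in fast_ripples}
    if len(channels) > 1:
        raise ValueError(f"cross-channel pairing attempted: {sorted(channels)}")
    hfos: list[HfoEvent] = []
    for r in ripples:
        partners = [f for f in fast_ripples if r.overlaps(f)]
        if not partners:
            continue
        t0 = min([r.t_start] + [f.t_start for f in partners])
        t1 = max([r.t_end] + [f.t_end for f in partners])
        hfos.append(
            HfoEvent(channel_id=r.channel_id, t_start=t0, t_end=t1,
                     ripple=r, fast_ripple=partners[0])
        )
    hfos.sort(key=lambda h: h.t_start)
    return hfos


def detect_hfos_in_epoch(
    raw_epoch: Epoch, config: AnalysisConfig | None = None
) -> dict[str, list[HfoEvent]]:
    """Full per-epoch detection: band filter both bands, detect, validate,
    pair. Returns channel -> HFO events."""
    config = config or AnalysisConfig()
    rip_epoch = bandpass(raw_epoch, *config.ripple_band)
    fr_epoch = bandpass(raw_epoch, *config.fast_ripple_band)
    ripples = detect_band_events(rip_epoch, "ripple", config, raw_epoch=raw_epoch)
    frs = detect_band_events(fr_epoch, "fast_ripple", config, raw_epoch=raw_epoch)
    by_ch_r: dict[str, list[BandEvent]] = defaultdict(list)
    by_ch_f: dict[str, list[BandEvent]] = defaultdict(list)
    for ev in ripples:
        by_ch_r[ev.channel_id].append(ev)
    for ev in frs:
        by_ch_f[ev.channel_id].append(ev)
    out: dict[str, list[HfoEvent]] = {}
    for ch in raw_epoch.channel_names:
        out[ch] = pair_cooccurrence(by_ch_r.get(ch, []), by_ch_f.get(ch, []))
    return out


def compute_rates(
    counts: pd.DataFrame, effective_minutes: pd.DataFrame
) -> RateMatrix:
    """rate[c, e] = count[c, e] / effective_minutes[c, e].

    Channel-epochs with zero effective minutes are marked missing (NaN), never
    divided.
    """
    if not counts.index.equals(effective_minutes.index) or not counts.columns.equals(
        effective_minutes.columns
    ):
        raise ValueError("counts and effective_minutes must be aligned")
    minutes = effective_minutes.astype(float)
    rates = counts.astype(float).where(minutes > 0) / minutes.where(minutes > 0)
    return RateMatrix(rates=rates, effective_minutes=minutes.where(minutes > 0))


def rate_matrix_from_epochs(
    epochs: list[Epoch], config: AnalysisConfig | None = None
) -> tuple[RateMatrix, dict[tuple[str, int], list[HfoEvent]]]:
    """Detect HFOs in every epoch of a preprocessed recording and assemble the
    channel x epoch rate matrix. Also returns the events keyed by
    (channel, epoch_index)."""
    config = config or AnalysisConfig()
    if not epochs:
        raise ValueError("no epochs supplied")
    channels = epochs[0].channel_names
    counts = pd.DataFrame(0, index=channels, columns=[e.epoch_index for e in epochs])
    minutes = pd.DataFrame(0.0, index=channels, columns=counts.columns)
    events: dict[tuple[str, int], list[HfoEvent]] = {}
    for ep in epochs:
        hfos = detect_hfos_in_epoch(ep, config)
        for ci, ch in enumerate(ep.channel_names):
            if not ep.valid_mask[ci]:
                continue
            events[(ch, ep.epoch_index)] = hfos.get(ch, [])
            counts.loc[ch, ep.epoch_index] = len(hfos.get(ch, []))
            minutes.loc[ch, ep.epoch_index] = ep.effective_minutes(ci)
    return compute_rates(counts, minutes), events
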