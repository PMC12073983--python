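"""Raw-recording conditioning: resampling, bipolar montage, exclusions, epochs, filters.

The pipeline order is fixed: resample -> bipolar -> exclusions -> epoch
segmentation -> band filtering. Filtering is zero-phase FIR (forward-backward)
so that ripple / fast-ripple co-occurrence timing is not skewed by group delay.
"""

from __future__ import annotations

import logging
import math
from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import ArtifactSection, ChannelMeta, Epoch, Recording

logger = logging.getLogger(__name__)

TARGET_FS = 2000.0
EPOCH_LEN_S = 300.0


def _fir_bandpass(low: float, high: float, fs: float, numtaps: int | None = None) -> np.ndarray:
    """Linear-phase band-pass FIR. Default length gives a ~13 Hz transition at
    fs=2000 (>=53 dB Hamming stop-band, doubled by filtfilt), comfortably
    meeting 40 dB one octave outside the band."""
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= fs / 2:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {fs / 2} Hz")
    if numtaps is None:
        numtaps = int(round(fs / 2000.0 * 513))
        numtaps += 1 - numtaps % 2  # odd length, type-I FIR
    return signal.firwin(numtaps, [low, high], pass_zero=False, fs=fs)


def bandpass_array(x: np.ndarray, low: float, high: float, fs: float) -> np.ndarray:
    """Zero-phase band-pass of an (..., n_times) array."""
    taps = _fir_bandpass(low, high, fs)
    n = x.shape[-1]
    padlen = min(3 * len(taps), n - 1)
    return signal.filtfilt(taps, [1.0], x, axis=-1, padlen=padlen)


def resample_to_2000(rec: Recording) -> Recording:
    """Downsample to 2000 Hz with a polyphase anti-aliasing filter.

    Identity when the recording is already at 2000 Hz. Sampling rates below
    2000 Hz are rejected: they cannot cover the fast-ripple band and
    upsampling is out of scope.
    """
    if rec.fs < TARGET_FS:
        raise ValueError(f"fs {rec.fs} Hz < 2000 Hz unsupported (would require upsampling)")
    if rec.fs > 5000:
        raise ValueError(f"fs {rec.fs} Hz outside the supported 2000-5000 Hz range")
    if rec.fs == TARGET_FS:
        return rec
    frac = Fraction(int(round(TARGET_FS)), int(round(rec.fs)))
    out = signal.resample_poly(rec.samples, frac.numerator, frac.denominator, axis=-1)
    return Recording(
        samples=out,
        fs=TARGET_FS,
        channels=[ChannelMeta(**vars(c)) for c in rec.channels],
        artifact_sections=list(rec.artifact_sections),
    )


def make_bipolar(rec: Recording) -> Recording:
    """Derive within-electrode bipolar channels from adjacent contacts.

    Contact k minus contact k+1, named ``ELEC<k>-ELEC<k+1>``; pairs are formed
    only between consecutive contact indices on the same electrode. A bipolar
    channel is flagged bad if either contact is bad or non-cephalic.
    Channels whose ``electrode`` is None are taken as already bipolar and pass
    through unchanged.
    """
    passthrough = [i for i, c in enumerate(rec.channels) if c.electrode is None]
    if len(passthrough) == len(rec.channels):
        return rec

    by_electrode: dict[str, list[int]] = {}
    for i, c in enumerate(rec.channels):
        if c.electrode is not None:
            by_electrode.setdefault(c.electrode, []).append(i)

    rows: list[np.ndarray] = []
    meta: list[ChannelMeta] = []
    contact_of: dict[str, list[str]] = {}  # bipolar name -> contact names
    for elec in by_electrode:
        idxs = sorted(by_electrode[elec], key=lambda i: rec.channels[i].contact)
        if len(idxs) < 2:
            logger.info("electrode %s has a single usable contact; skipped", elec)
            continue
        for a, b in zip(idxs[:-1], idxs[1:]):
            ca, cb = rec.channels[a], rec.channels[b]
            if cb.contact != ca.contact + 1:
                continue  # gap in the contact run: not adjacent
            name = f"{elec}{ca.contact}-{elec}{cb.contact}"
            rows.append(rec.samples[a] - rec.samples[b])
            bad = ca.bad or cb.bad or not ca.cephalic or not cb.cephalic
            meta.append(
                ChannelMeta(
                    name=name,
                    electrode=None,
                    contact=None,
                    ch_type=ca.ch_type,
                    cephalic=ca.cephalic and cb.cephalic,
                    bad=bad,
                )
            )
            contact_of[name] = [ca.name, cb.name]

    for i in passthrough:
        rows.append(rec.samples[i])
        meta.append(ChannelMeta(**vars(rec.channels[i])))
        contact_of[rec.channels[i].name] = [rec.channels[i].name]

    if not rows:
        raise ValueError("no electrode with >=2 adjacent contacts; cannot build bipolar montage")

    # artefact sections on a contact apply to every bipolar channel using it
    sections: list[ArtifactSection] = []
    for sec in rec.artifact_sections:
        if sec.channel is None:
            sections.append(ArtifactSection(None, sec.t_start, sec.t_end))
        else:
            for name, contacts in contact_of.items():
                if sec.channel in contacts:
                    sections.append(ArtifactSection(name, sec.t_start, sec.t_end))
    return Recording(np.vstack(rows), rec.fs, meta, sections)


def apply_exclusions(rec: Recording) -> Recording:
    """Drop bad channels; keep artefact sections for masking downstream."""
    keep = [i for i, c in enumerate(rec.channels) if not c.bad]
    if len(keep) == len(rec.channels):
        return rec
    names = {rec.channels[i].name for i in keep}
    sections = [
        s for s in rec.artifact_sections if s.channel is None or s.channel in names
    ]
    return Recording(
        rec.samples[keep],
        rec.fs,
        [ChannelMeta(**vars(rec.channels[i])) for i in keep],
        sections,
    )


def segment_epochs(rec: Recording, epoch_len_s: float = EPOCH_LEN_S) -> list[Epoch]:
    """Cut consecutive non-overlapping epochs from t=0; the trailing partial
    epoch is discarded. Artefact sections are clipped into per-epoch masks and
    a channel-epoch fully covered by artefact is marked not analysable."""
    n_epochs = math.floor(rec.duration_s / epoch_len_s + 1e-9)
    if n_epochs < 1:
        raise ValueError(
            f"no eligible epoch: recording is {rec.duration_s:.1f} s < {epoch_len_s:.0f} s"
        )
    n_samp = int(round(epoch_len_s * rec.fs))
    name_to_idx = {c.name: i for i, c in enumerate(rec.channels)}
    epochs: list[Epoch] = []
    for e in range(n_epochs):
        t0, t1 = e * epoch_len_s, (e + 1) * epoch_len_s
        intervals: dict[int, list[tuple[float, float]]] = {}
        for sec in rec.artifact_sections:
            lo, hi = max(sec.t_start, t0), min(sec.t_end, t1)
            if hi <= lo:
                continue
            targets = range(rec.n_channels) if sec.channel is None else [name_to_idx[sec.channel]]
            for i in targets:
                intervals.setdefault(i, []).append((lo - t0, hi - t0))
        valid = np.ones(rec.n_channels, dtype=bool)
        epoch = Epoch(
            samples=rec.samples[:, e * n_samp : (e + 1) * n_samp],
            fs=rec.fs,
            epoch_index=e,
            t_start=t0,
            channel_names=rec.channel_names,
            valid_mask=valid,
            artifact_intervals=intervals,
        )
        for i in range(rec.n_channels):
            if epoch.effective_minutes(i) <= 0:
                valid[i] = False
        epochs.append(epoch)
    return epochs


def bandpass(epoch: Epoch, low: float, high: float) -> Epoch:
    """Zero-phase band-pass of every channel in an epoch; length preserved."""
    filtered = bandpass_array(epoch.samples, low, high, epoch.fs)
    return Epoch(
        samples=filtered,
        fs=epoch.fs,
        epoch_index=epoch.epoch_index,
        t_start=epoch.t_start,
        channel_names=list(epoch.channel_names),
        valid_mask=epoch.valid_mask.copy(),
        artifact_intervals={k: list(v) for k, v in epoch.artifact_intervals.items()},
    )
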