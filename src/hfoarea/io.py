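"""File formats: EDF, the raw+JSON fixture format, event/clinical CSV, reports.

EDF reading goes through MNE. Writing uses a minimal 16-bit EDF encoder
(1-second data records, physical units uV) since no installed library exports
EDF; round-trips are covered by tests against MNE's independent reader.
The fixture format is raw little-endian float32 (channels x time, C order)
plus a JSON sidecar carrying fs, channel metadata and exclusions.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ArtifactSection, ChannelMeta, PatientRecord, Recording

_TIME_DECIMALS = 4  # 0.1 ms precision in event tables


class FormatError(ValueError):
    """A file failed to parse or violated format constraints."""


# ---------------------------------------------------------------------------
# fixture format
# ---------------------------------------------------------------------------

def write_fixture(rec: Recording, stem: str | Path) -> tuple[Path, Path]:
    """Write ``<stem>.raw`` (float32 LE) and ``<stem>.json`` sidecar."""
    stem = Path(stem)
    raw_path = stem.with_suffix(".raw")
    json_path = stem.with_suffix(".json")
    rec.samples.astype("<f4").tofile(raw_path)
    sidecar = {
        "fs": rec.fs,
        "units": "uV",
        "n_channels": rec.n_channels,
        "n_times": rec.n_times,
        "channels": [asdict(c) for c in rec.channels],
        "artifact_sections": [
            {"channel": s.channel, "t_start": s.t_start, "t_end": s.t_end}
            for s in rec.artifact_sections
        ],
    }
    json_path.write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return raw_path, json_path


def read_fixture(stem: str | Path) -> Recording:
    stem = Path(stem)
    json_path = stem.with_suffix(".json")
    raw_path = stem.with_suffix(".raw")
    if not json_path.exists():
        raise FormatError(f"missing sidecar {json_path}")
    meta = json.loads(json_path.read_text())
    for key in ("fs", "n_channels", "n_times", "channels"):
        if key not in meta:
            raise FormatError(f"fixture sidecar missing required field {key!r}")
    data = np.fromfile(raw_path, dtype="<f4")
    n_ch, n_t = meta["n_channels"], meta["n_times"]
    if data.size != n_ch * n_t:
        raise FormatError(
            f"raw payload has {data.size} samples, sidecar promises {n_ch}x{n_t}"
        )
    channels = [ChannelMeta(**c) for c in meta["channels"]]
    sections = [
        ArtifactSection(s["channel"], s["t_start"], s["t_end"])
        for s in meta.get("artifact_sections", [])
    ]
    return Recording(data.reshape(n_ch, n_t).astype(np.float64), meta["fs"], channels, sections)


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF (physical units uV, 1-s data records).

    Trailing samples beyond the last whole second are dropped. Requires an
    integer sampling rate.
    """
    path = Path(path)
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    n_records = int(rec.n_times // fs)
    if n_records < 1:
        raise FormatError("recording shorter than one EDF data record (1 s)")
    ns = rec.n_channels

    phys_min, phys_max = [], []
    scaled = np.empty((ns, n_records * fs), dtype="<i2")
    for i in range(ns):
        x = rec.samples[i, : n_records * fs]
        amp = max(np.abs(x).max(), 1e-6)
        pmin, pmax = -amp, amp
        phys_min.append(pmin)
        phys_max.append(pmax)
        scaled[i] = np.round((x - pmin) / (pmax - pmin) * 65534 - 32767).astype("<i2")

    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X X X X", 80),
        _pad("01.01.00", 8),
        _pad("00.00.00", 8),
        _pad(str(256 * (1 + ns)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])

    def fmt(v: float) -> str:
        s = f"{v:.8g}"
        return s[:8]

    header += b"".join(_pad(c.name, 16) for c in rec.channels)
    header += b"".join(_pad("", 80) for _ in range(ns))
    header += b"".join(_pad("uV", 8) for _ in range(ns))
    header += b"".join(_pad(fmt(v), 8) for v in phys_min)
    header += b"".join(_pad(fmt(v), 8) for v in phys_max)
    header += b"".join(_pad("-32767", 8) for _ in range(ns))
    header += b"".join(_pad("32767", 8) for _ in range(ns))
    header += b"".join(_pad("", 80) for _ in range(ns))
    header += b"".join(_pad(str(fs), 8) for _ in range(ns))
    header += b"".join(_pad("", 32) for _ in range(ns))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(scaled[:, r * fs : (r + 1) * fs].tobytes())
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file via MNE; samples are returned in uV."""
    import mne

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - malformed files
        raise FormatError(f"failed to parse EDF {path}: {exc}") from exc
    fs = float(raw.info["sfreq"])
    if fs < 2000:
        raise FormatError(f"fs {fs:g} Hz < 2000 unsupported")
    samples = raw.get_data() * 1e6  # MNE loads EEG in volts
    channels = [ChannelMeta(name=nm, electrode=None) for nm in raw.ch_names]
    return Recording(samples, fs, channels)


def read_recording(path: str | Path, fmt: str = "auto") -> Recording:
    """Dispatch on format: 'edf', 'fixture', or 'auto' (by extension)."""
    path = Path(path)
    if fmt == "auto":
        fmt = "edf" if path.suffix.lower() == ".edf" else "fixture"
    if fmt == "edf":
        return read_edf(path)
    if fmt == "fixture":
        return read_fixture(path.with_suffix(""))
    raise FormatError(f"unsupported format {fmt!r}")


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def events_to_frame(events) -> pd.DataFrame:
    """Tabulate ground-truth or detected events (times at 0.1 ms)."""
    rows = []
    for ev in events:
        band = getattr(ev, "kind", None) or getattr(ev, "band", None) or "hfo"
        rows.append({
            "channel": ev.channel_id,
            "kind": band,
            "t_start": round(ev.t_start, _TIME_DECIMALS),
            "t_end": round(ev.t_end, _TIME_DECIMALS),
        })
    return pd.DataFrame(rows, columns=["channel", "kind", "t_start", "t_end"])


def write_events_csv(events, path: str | Path) -> Path:
    path = Path(path)
    events_to_frame(events).to_csv(path, index=False, float_format=f"%.{_TIME_DECIMALS}f")
    return path


def read_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"channel", "kind", "t_start", "t_end"} - set(df.columns)
    if missing:
        raise FormatError(f"events table missing columns: {sorted(missing)}")
    return df


CLINICAL_COLUMNS = [
    "patient_id", "centre", "resected_channels", "ilae", "age", "sex",
    "pathology", "electrode_type", "follow_up_months",
]


def write_clinical_csv(patients: list[PatientRecord], path: str | Path) -> Path:
    rows = []
    for p in patients:
        rows.append({
            "patient_id": p.patient_id,
            "centre": p.centre_id,
            "resected_channels": ";".join(sorted(p.resected_channels)),
            "ilae": p.ilae,
            "age": p.age,
            "sex": p.sex,
            "pathology": p.pathology,
            "electrode_type": p.electrode_type,
            "follow_up_months": p.follow_up_months,
        })
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_clinical_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"clinical table missing columns: {sorted(missing)}")
    df["resected_channels"] = df["resected_channels"].fillna("").map(
        lambda s: frozenset(x for x in str(s).split(";") if x)
    )
    return df


def write_report_json(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=1, sort_keys=True, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
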