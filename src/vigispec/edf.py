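"""Recording I/O: EDF (16-bit) and a raw float32+JSON fixture format.

EDF (European Data Format) is the interchange format of polygraphic
recordings and the format the pipeline expects deposited data in.
Reading goes through :mod:`mne`; writing uses a minimal EDF writer
implemented here (plain EDF, not EDF+, one data-record duration chosen so
the per-record sample count is integral even for non-integer sampling
rates such as 1084.7 Hz).  Because EDF quantises to 16 bits against
per-channel physical ranges, unit tests that need exact round-trips use
the raw format instead: a float32 little-endian binary plus a JSON
sidecar carrying sampling rate, channel names/roles and subject metadata.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path

import numpy as np

from .preprocess import Channel, Recording

__all__ = ["write_edf", "read_edf", "write_raw", "read_raw", "load_recording"]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _infer_role(label: str) -> str:
    return "emg" if label.upper().startswith("EMG") else "eeg"


def _record_geometry(fs: float, n_samples: int) -> tuple[float, int]:
    """Pick a data-record duration giving an integer sample count.

    1 s when fs is integral; otherwise the smallest duration (up to 10 s)
    that makes fs*duration integral, e.g. 10 s for fs = 1084.7 Hz.
    """
    frac = Fraction(fs).limit_denominator(1000)
    dur = frac.denominator
    if dur > 10:
        raise ValueError(f"cannot express fs={fs} with integral record length <= 10 s")
    return float(dur), int(round(fs * dur))


def write_edf(recording: Recording, path: str | Path) -> Path:
    """Write a recording as plain 16-bit EDF.

    Physical min/max are taken per channel from the data; the trailing
    partial record is dropped.  The subject id goes into the patient
    field and ``group sex age`` into the recording-id field so that
    :func:`read_edf` can restore the metadata.
    """
    path = Path(path)
    dur, spr = _record_geometry(recording.fs, recording.n_samples)
    n_rec = int(recording.n_samples // spr)
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record")
    chans = recording.channels
    nsig = len(chans)

    header = b"".join([
        _field("0", 8),
        _field(recording.subject, 80),
        _field(f"{recording.group} {recording.sex} {recording.age if recording.age is not None else 'x'}", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(256 * (1 + nsig), 8),
        _field("", 44),
        _field(n_rec, 8),
        _field(f"{dur:g}", 8),
        _field(nsig, 4),
    ])

    phys_min, phys_max, scale = [], [], []
    for ch in chans:
        lo = float(np.min(ch.data[: n_rec * spr]))
        hi = float(np.max(ch.data[: n_rec * spr]))
        if hi <= lo:
            lo, hi = lo - 1.0, lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        scale.append((hi - lo) / (_DIG_MAX - _DIG_MIN))

    # per-signal header blocks: each field repeated for all signals in turn
    sig_fields = [
        ([c.name for c in chans], 16),
        (["" for _ in chans], 80),
        (["uV" for _ in chans], 8),
        ([f"{v:.6g}"[:8] for v in phys_min], 8),
        ([f"{v:.6g}"[:8] for v in phys_max], 8),
        ([_DIG_MIN for _ in chans], 8),
        ([_DIG_MAX for _ in chans], 8),
        (["" for _ in chans], 80),
        ([spr for _ in chans], 8),
        (["" for _ in chans], 32),
    ]
    sig_header = b"".join(
        b"".join(_field(v, w) for v in values) for values, w in sig_fields
    )

    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            for i, ch in enumerate(chans):
                seg = ch.data[r * spr : (r + 1) * spr]
                dig = np.round((seg - phys_min[i]) / scale[i]) + _DIG_MIN
                fh.write(
                    np.clip(dig, _DIG_MIN, _DIG_MAX).astype("<i2").tobytes()
                )
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (µV), roles from labels.

    Channels whose label starts with ``EMG`` get the ``emg`` role.  Mixed
    per-channel sampling rates are resampled to the maximum by the reader
    backend (with a warning from mne).  Malformed or truncated files
    raise a ``ValueError`` naming the file.
    """
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises various header errors
        raise ValueError(f"not a readable EDF file: {path} ({exc})") from exc
    data = raw.get_data() * 1e6  # mne loads Volts; recordings are in µV
    # the patient / recording-id header fields carry the subject metadata
    with open(path, "rb") as fh:
        header = fh.read(192)
    subject = header[8:88].decode("ascii", "replace").strip() or path.stem
    rec_id = header[88:168].decode("ascii", "replace").strip()
    group, sex, age = "none", "na", None
    parts = rec_id.split()
    if len(parts) >= 2:
        group, sex = parts[0], parts[1]
        if len(parts) >= 3 and parts[2] != "x":
            try:
                age = float(parts[2])
            except ValueError:
                age = None
    channels = [
        Channel(name=name, data=data[i], role=_infer_role(name))
        for i, name in enumerate(raw.ch_names)
    ]
    return Recording(channels=channels, fs=float(raw.info["sfreq"]),
                     subject=str(subject), group=group, sex=sex, age=age)


def write_raw(recording: Recording, stem: str | Path) -> Path:
    """Write the raw fixture format: ``stem.bin`` (float32) + ``stem.json``."""
    stem = Path(stem)
    data = np.stack([c.data for c in recording.channels]).astype("<f4")
    data.tofile(stem.with_suffix(".bin"))
    meta = {
        "fs": recording.fs,
        "n_samples": recording.n_samples,
        "subject": recording.subject,
        "group": recording.group,
        "sex": recording.sex,
        "age": recording.age,
        "channels": [{"name": c.name, "role": c.role} for c in recording.channels],
    }
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2)
    return stem.with_suffix(".json")


def read_raw(json_path: str | Path) -> Recording:
    """Read the raw fixture format back from its JSON sidecar path."""
    json_path = Path(json_path)
    with open(json_path) as fh:
        meta = json.load(fh)
    data = np.fromfile(json_path.with_suffix(".bin"), dtype="<f4")
    nch = len(meta["channels"])
    data = data.reshape(nch, meta["n_samples"]).astype(float)
    channels = [
        Channel(name=c["name"], data=data[i], role=c["role"])
        for i, c in enumerate(meta["channels"])
    ]
    return Recording(channels=channels, fs=float(meta["fs"]),
                     subject=meta["subject"], group=meta["group"],
                     sex=meta["sex"], age=meta.get("age"))


def load_recording(path: str | Path) -> Recording:
    """Dispatch on extension: ``.edf`` -> EDF reader, ``.json`` -> raw fixture."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    if path.suffix.lower() == ".json":
        return read_raw(path)
    raise ValueError(f"unsupported recording file {path}")
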