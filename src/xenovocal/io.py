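"""On-disk formats: columnar CSV + JSON sidecar for recordings, WAV audio.

A recording is stored as a CSV with one column per channel (header =
channel role, documented order preserved) next to a JSON sidecar holding
the sample rate, channel roles, stimulus times and metadata. Audio can be
round-tripped through 32-bit float WAV. Write-then-read reproduces the
channels to float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import FormatError
from .recording import CHANNEL_ROLES, ROLE_AUDIO, Recording


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path) -> Path:
    """Write a recording as ``<path>.csv`` plus a ``.json`` sidecar.

    Returns the CSV path.
    """
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    df = pd.DataFrame({role: sig for role, sig in rec.channels.items()})
    df.to_csv(path, index=False, float_format="%.9g")
    sidecar = {
        "sample_rate": rec.sample_rate,
        "channel_roles": list(rec.channels),
        "stim_times": _jsonable(rec.stim_times),
        "meta": _jsonable(rec.meta),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`."""
    path = Path(path)
    if path.suffix != ".csv":
        path = path.with_suffix(".csv")
    side_path = _sidecar_path(path)
    if not side_path.exists():
        raise FormatError(f"missing sidecar {side_path}")
    try:
        side = json.loads(side_path.read_text())
    except json.JSONDecodeError as err:
        raise FormatError(f"corrupt sidecar {side_path}: {err}") from err
    for key in ("sample_rate", "channel_roles"):
        if key not in side:
            raise FormatError(f"sidecar missing required field {key!r}")
    roles = side["channel_roles"]
    bad = [r for r in roles if r not in CHANNEL_ROLES]
    if bad:
        raise FormatError(
            f"sidecar declares unknown channel role(s) {bad}; "
            f"valid roles: {list(CHANNEL_ROLES)}")
    df = pd.read_csv(path)
    if list(df.columns) != roles:
        raise FormatError(
            f"CSV columns {list(df.columns)} do not match sidecar "
            f"channel_roles {roles}")
    channels = {r: df[r].to_numpy(dtype=float) for r in roles}
    return Recording(sample_rate=float(side["sample_rate"]), channels=channels,
                     stim_times=np.asarray(side.get("stim_times", []), dtype=float),
                     meta=side.get("meta", {}))


def write_wav(rec_or_signal, path, sample_rate: float | None = None) -> Path:
    """Write mono float32 WAV from a Recording's audio channel or a vector."""
    path = Path(path)
    if isinstance(rec_or_signal, Recording):
        x = rec_or_signal.channel(ROLE_AUDIO)
        sample_rate = rec_or_signal.sample_rate
    else:
        x = np.asarray(rec_or_signal, dtype=float)
        if sample_rate is None:
            raise FormatError("sample_rate required when writing a raw vector")
    wavfile.write(path, int(round(sample_rate)), x.astype(np.float32))
    return path


def read_wav(path) -> Recording:
    """Read a mono WAV into a Recording with an audio channel."""
    rate, data = wavfile.read(Path(path))
    data = np.asarray(data)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data / float(np.iinfo(data.dtype).max)
    return Recording(sample_rate=float(rate),
                     channels={ROLE_AUDIO: data.astype(float)},
                     meta={"source": str(path)})
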