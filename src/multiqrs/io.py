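"""Reading and writing recordings, R-peak annotations and templates.

The canonical on-disk interchange is plain text: a delimited matrix with one
column per channel (header row = channel labels) plus a JSON metadata sidecar
``<name>.json`` holding the sampling rate, labels and duration.  Annotations
are one peak time in seconds per line, with an optional trailing marker
column (used to flag prediction gaps).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up

__all__ = [
    "Recording",
    "as_peak_train",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
]


@dataclass
class Recording:
    """A multichannel biopotential recording.

    Attributes
    ----------
    sampling_rate : float
        Sampling frequency in Hz; strictly positive.
    labels : list of str
        Unique channel names, one per row of ``data``.
    data : ndarray, shape (n_channels, n_samples)
        Signal values in amplifier units.
    start_time : float
        Time of the first sample in seconds (default 0).
    """

    sampling_rate: float
    labels: list[str]
    data: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = [str(l) for l in self.labels]
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.data.shape[1] / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D signal for a channel label."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None
        return self.data[idx]


def as_peak_train(peaks: Sequence[int] | np.ndarray) -> np.ndarray:
    """Validate and return a strictly increasing int64 array of sample indices."""
    arr = np.asarray(peaks)
    if arr.size and not np.issubdtype(arr.dtype, np.number):
        raise ValueError("peak train must be numeric")
    arr = arr.astype(np.int64)
    if arr.size and np.any(np.diff(arr) <= 0):
        raise ValueError("peak train must be strictly increasing")
    return arr


# ---------------------------------------------------------------------------
# recordings


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.suffix != ".json" else path


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as a delimited matrix plus a JSON sidecar.

    Values are written with 17 significant digits so that a read/write
    round-trip is bit-exact for float64 data.
    """
    path = Path(path)
    header = ",".join(recording.labels)
    np.savetxt(
        path, recording.data.T, delimiter=",", header=header, comments="", fmt="%.17g"
    )
    meta = {
        "sampling_rate": recording.sampling_rate,
        "labels": recording.labels,
        "duration": recording.duration,
        "start_time": recording.start_time,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_recording(path: str | Path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Raises
    ------
    ValueError
        If the sidecar is missing or incomplete, the label count does not
        match the column count, labels are duplicated, or columns are ragged.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    if "sampling_rate" not in meta:
        raise ValueError(f"sidecar {sidecar} lacks 'sampling_rate'")
    if "labels" not in meta:
        raise ValueError(f"sidecar {sidecar} lacks 'labels'")
    try:
        table = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:  # ragged columns
        raise ValueError(f"malformed recording file {path}: {exc}") from exc
    if list(table.columns) != [str(l) for l in meta["labels"]]:
        raise ValueError(
            f"labels in sidecar {meta['labels']} do not match columns "
            f"{list(table.columns)}"
        )
    if table.isna().any().any():
        raise ValueError(f"non-numeric or ragged values in {path}")
    return Recording(
        sampling_rate=float(meta["sampling_rate"]),
        labels=[str(l) for l in meta["labels"]],
        data=table.to_numpy(dtype=float).T,
        start_time=float(meta.get("start_time", 0.0)),
    )


# ---------------------------------------------------------------------------
# annotations


def write_annotations(
    train: np.ndarray,
    path: str | Path,
    sampling_rate: float,
    flags: Sequence[bool] | None = None,
) -> None:
    """Write a peak train as one time (seconds) per line.

    Flagged entries (e.g. re-anchored prediction gaps) get a trailing
    ``gap`` marker column.
    """
    train = as_peak_train(train)
    lines = []
    for i, p in enumerate(train):
        t = p / sampling_rate
        if flags is not None and flags[i]:
            lines.append(f"{t:.6f}\tgap")
        else:
            lines.append(f"{t:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_annotations(path: str | Path, sampling_rate: float) -> np.ndarray:
    """Read peak times (seconds, one per line) into a sample-index train.

    Unsorted input is sorted with a warning; duplicate times are collapsed
    with a warning; negative or non-numeric times are rejected.
    """
    times = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        raw = raw.strip()
        if not raw:
            continue
        tok = raw.split()[0]
        try:
            t = float(tok)
        except ValueError:
            raise ValueError(f"{path}:{ln}: non-numeric time {tok!r}") from None
        if t < 0:
            raise ValueError(f"{path}:{ln}: negative time {t}")
        times.append(t)
    arr = np.asarray(times, dtype=float)
    if arr.size and np.any(np.diff(arr) < 0):
        warnings.warn(f"annotations in {path} were not sorted; sorting")
        arr = np.sort(arr)
    samples = np.array([round_half_up(t * sampling_rate) for t in arr], dtype=np.int64)
    uniq = np.unique(samples)
    if uniq.size != samples.size:
        warnings.warn(f"annotations in {path} contain duplicate times; collapsing")
    return uniq


# ---------------------------------------------------------------------------
# templates (serialization lives here; the type in .template)


def write_templates(templates, path: str | Path) -> None:
    """Serialize a list of QRS templates to JSON."""
    payload = [
        {
            "channel": t.channel,
            "sampling_rate": t.sampling_rate,
            "waveform": list(map(float, t.waveform)),
            "per_sample_sd": list(map(float, t.per_sample_sd)),
            "n_cycles_used": int(t.n_cycles_used),
            "quality": None if t.quality is None else float(t.quality),
        }
        for t in templates
    ]
    Path(path).write_text(json.dumps(payload))


def read_templates(path: str | Path):
    """Read templates serialized by :func:`write_templates`."""
    from .template import QRSTemplate

    payload = json.loads(Path(path).read_text())
    return [
        QRSTemplate(
            waveform=np.asarray(d["waveform"], dtype=float),
            per_sample_sd=np.asarray(d["per_sample_sd"], dtype=float),
            n_cycles_used=int(d["n_cycles_used"]),
            quality=d["quality"],
            channel=d["channel"],
            sampling_rate=float(d["sampling_rate"]),
        )
        for d in payload
    ]
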