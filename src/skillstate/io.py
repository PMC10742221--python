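"""Reading and writing of EEG recordings, montages, and run manifests.

The in-memory convention throughout the package is ``samples x channels``
(microvolts), 0-based half-open sample intervals, and events as
``(sample_index, label)`` pairs.  BrainVision triplets (.vhdr/.vmrk/.eeg,
IEEE float32) and EDF+ files with annotations are supported on disk.
Writers are implemented here; reading goes through :mod:`mne`, which keeps
the round-trip check honest (two independent codepaths).
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
import re
from dataclasses import dataclass, field
from typing import Literal, Sequence

import mne
import numpy as np

__all__ = [
    "Recording",
    "Montage",
    "ValidationError",
    "IntegrityError",
    "FormatError",
    "read_recording",
    "write_recording",
    "load_montage",
    "save_montage",
    "default_montage",
    "RunManifest",
]


class ValidationError(ValueError):
    """Input violates a documented precondition."""


class IntegrityError(ValueError):
    """File contents are internally inconsistent (e.g. header vs data size)."""


class FormatError(ValueError):
    """File cannot be parsed as the requested format."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Scalp potential in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str
        One identifier per column of ``data``.
    events : list of (int, str)
        Marker positions as 0-based sample indices with free-string labels.
    reference : {"as-recorded", "common-average"}
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    events: list[tuple[int, str]] = field(default_factory=list)
    reference: Literal["as-recorded", "common-average"] = "as-recorded"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be 2-D (samples x channels)")
        if len(self.channel_names) != self.n_channels:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.n_channels} data columns"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValidationError("channel names must be unique")
        if not self.fs > 0:
            raise ValidationError("sampling rate must be positive")
        self.events = [(int(s), str(lbl)) for s, lbl in self.events]
        for s, lbl in self.events:
            if not 0 <= s < self.n_samples:
                raise ValidationError(
                    f"event {lbl!r} at sample {s} outside [0, {self.n_samples})"
                )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, **kw) -> "Recording":
        out = dataclasses.replace(self, **kw)
        return out

    def event_samples(self, label: str) -> list[int]:
        return [s for s, lbl in self.events if lbl == label]


@dataclass
class Montage:
    """Electrode labels with unit-sphere 3-D positions (head-centred)."""

    labels: list[str]
    positions: np.ndarray  # (n, 3), unit norm

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise ValidationError("positions must be (n_labels, 3)")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("duplicate electrode labels")
        norms = np.linalg.norm(self.positions, axis=1)
        if np.any(norms < 1e-12):
            raise ValidationError("electrode position at origin")
        self.positions = self.positions / norms[:, None]

    def __len__(self) -> int:
        return len(self.labels)

    def position_of(self, label: str) -> np.ndarray:
        try:
            return self.positions[self.labels.index(label)]
        except ValueError:
            raise KeyError(f"electrode {label!r} not in montage") from None

    def subset(self, labels: Sequence[str]) -> "Montage":
        idx = [self.labels.index(l) for l in labels]
        return Montage(list(labels), self.positions[idx])


#: 32-channel layout emulating the study montage (10-20/10-10 names covering
#: frontal through occipital sites); positions from MNE's standard_1020.
DEFAULT_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "PO4", "PO8",
    "O1", "Oz", "O2",
]


def default_montage(labels: Sequence[str] = DEFAULT_32) -> Montage:
    """Standard-position montage for the default 32-channel layout."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        std = mne.channels.make_standard_montage("standard_1020")
    pos = std.get_positions()["ch_pos"]
    pts = np.array([pos[l] for l in labels])
    pts = pts - pts.mean(axis=0) * 0.0  # head-centred already in MNE frame
    return Montage(list(labels), pts)


# --------------------------------------------------------------------------
# montage files
# --------------------------------------------------------------------------

def load_montage(path: str | pathlib.Path) -> Montage:
    """Load a montage from a TSV table ``label\\tx\\ty\\tz``.

    Positions are normalized to the unit sphere; duplicate labels raise
    :class:`ValidationError`.
    """
    labels: list[str] = []
    pts: list[list[float]] = []
    for line in pathlib.Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if parts[0].lower() == "label":
            continue  # header row
        if len(parts) != 4:
            raise FormatError(f"expected 'label x y z', got {line!r}")
        labels.append(parts[0])
        pts.append([float(v) for v in parts[1:]])
    if not labels:
        raise FormatError(f"no electrode rows in {path}")
    return Montage(labels, np.array(pts))


def save_montage(montage: Montage, path: str | pathlib.Path) -> None:
    lines = ["label\tx\ty\tz"]
    for lbl, p in zip(montage.labels, montage.positions):
        lines.append(f"{lbl}\t{p[0]:.10g}\t{p[1]:.10g}\t{p[2]:.10g}")
    pathlib.Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# BrainVision
# --------------------------------------------------------------------------

_VHDR_TEMPLATE = """Brain Vision Data Exchange Header File Version 1.0
; Written by skillstate

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={nch}
SamplingInterval={sampling_interval}

[Binary Infos]
BinaryFormat=IEEE_FLOAT_32

[Channel Infos]
{channels}
"""

_VMRK_TEMPLATE = """Brain Vision Data Exchange Marker File, Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg

[Marker Infos]
Mk1=New Segment,,1,1,0,00000000000000000000
{markers}
"""


def _write_brainvision(rec: Recording, path: pathlib.Path) -> None:
    stem = path.with_suffix("").name
    base = path.with_suffix("")
    ch_lines = "\n".join(
        f"Ch{i + 1}={name},,1,µV" for i, name in enumerate(rec.channel_names)
    )
    vhdr = _VHDR_TEMPLATE.format(
        stem=stem,
        nch=rec.n_channels,
        sampling_interval=f"{1e6 / rec.fs:.10g}",  # microseconds per sample
        channels=ch_lines,
    )
    base.with_suffix(".vhdr").write_text(vhdr, encoding="utf-8")

    markers = "\n".join(
        f"Mk{i + 2}=Stimulus,{lbl},{s + 1},1,0"
        for i, (s, lbl) in enumerate(rec.events)
    )
    vmrk = _VMRK_TEMPLATE.format(stem=stem, markers=markers)
    base.with_suffix(".vmrk").write_text(vmrk, encoding="utf-8")

    rec.data.astype("<f4").tofile(base.with_suffix(".eeg"))


def _check_brainvision_integrity(vhdr_path: pathlib.Path) -> None:
    text = vhdr_path.read_text(encoding="utf-8", errors="replace")
    m = re.search(r"NumberOfChannels\s*=\s*(\d+)", text)
    if not m:
        raise FormatError(f"{vhdr_path}: missing NumberOfChannels")
    nch = int(m.group(1))
    n_ch_lines = len(re.findall(r"^Ch\d+=", text, flags=re.MULTILINE))
    if n_ch_lines and n_ch_lines != nch:
        raise IntegrityError(
            f"{vhdr_path}: header claims {nch} channels but lists {n_ch_lines}"
        )
    fmt = re.search(r"BinaryFormat\s*=\s*(\S+)", text)
    itemsize = {"IEEE_FLOAT_32": 4, "INT_16": 2}.get(
        fmt.group(1) if fmt else "IEEE_FLOAT_32", 4
    )
    data_file = re.search(r"DataFile\s*=\s*(\S+)", text)
    eeg_path = vhdr_path.parent / (
        data_file.group(1) if data_file else vhdr_path.with_suffix(".eeg").name
    )
    if eeg_path.exists():
        nbytes = eeg_path.stat().st_size
        if nbytes % (itemsize * nch) != 0:
            raise IntegrityError(
                f"{eeg_path}: {nbytes} bytes not a whole number of "
                f"{nch}-channel frames"
            )


def _read_mne_raw(raw: mne.io.BaseRaw) -> Recording:
    data = raw.get_data().T * 1e6  # volts -> microvolts
    fs = float(raw.info["sfreq"])
    events: list[tuple[int, str]] = []
    for ann in raw.annotations:
        label = ann["description"]
        label = re.sub(r"^(Stimulus|Response|Comment)/", "", label).strip()
        if label.startswith("New Segment") or label.startswith("EDF Annotations"):
            continue
        sample = int(round(ann["onset"] * fs))
        if 0 <= sample < data.shape[0]:
            events.append((sample, label))
    rec = Recording(data, fs, list(raw.ch_names), events)
    if np.isnan(rec.data).any():
        raise IntegrityError("loaded data contains NaN")
    return rec


# --------------------------------------------------------------------------
# EDF+
# --------------------------------------------------------------------------

def _edf_ascii(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        if isinstance(value, float):
            s = f"{value:.{max(1, width - 7)}g}"
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: pathlib.Path) -> None:
    fs = rec.fs
    spr = fs  # one-second data records
    if abs(spr - round(spr)) > 1e-9:
        raise ValidationError("EDF+ writer requires an integer sampling rate")
    spr = int(round(spr))
    n_records = math.ceil(rec.n_samples / spr)
    nch = rec.n_channels

    absmax = float(np.max(np.abs(rec.data))) if rec.data.size else 1.0
    if absmax == 0:
        absmax = 1.0
    # round the physical range up to 6 significant digits so the header
    # field is exact and quantization stays ~absmax/32767
    physmax = float(f"{absmax * 1.000001:.6g}")
    # same affine map readers use: phys = (dig - digmin) * scale + physmin
    scale = 2 * physmax / 65535.0

    # annotation payloads: one timekeeping TAL per record + event TALs
    tal_per_record: list[bytes] = []
    for r in range(n_records):
        tal = f"+{r}\x14\x14\x00".encode("ascii")
        for s, lbl in rec.events:
            t = s / fs
            if r <= t < r + 1:
                tal += f"+{t:.6g}\x14{lbl}\x14\x00".encode("utf-8")
        tal_per_record.append(tal)
    ann_bytes = max(64, max(len(t) for t in tal_per_record))
    ann_bytes += ann_bytes % 2  # whole number of 2-byte samples
    ann_spr = ann_bytes // 2

    ns = nch + 1
    header = b""
    header += _edf_ascii("0", 8)
    header += _edf_ascii("X X X X", 80)
    header += _edf_ascii("Startdate 01-JAN-2000 X X X", 80)
    header += _edf_ascii("01.01.00", 8)
    header += _edf_ascii("00.00.00", 8)
    header += _edf_ascii(256 * (ns + 1), 8)
    header += _edf_ascii("EDF+C", 44)
    header += _edf_ascii(n_records, 8)
    header += _edf_ascii(1, 8)
    header += _edf_ascii(ns, 4)

    def col(values, width):
        return b"".join(_edf_ascii(v, width) for v in values)

    labels = list(rec.channel_names) + ["EDF Annotations"]
    header += col(labels, 16)
    header += col([""] * ns, 80)                      # transducer
    header += col(["uV"] * nch + [""], 8)             # physical dimension
    header += col([f"{-physmax:.6g}"] * nch + [-1], 8)
    header += col([f"{physmax:.6g}"] * nch + [1], 8)
    header += col([-32768] * ns, 8)
    header += col([32767] * ns, 8)
    header += col([""] * ns, 80)                      # prefiltering
    header += col([spr] * nch + [ann_spr], 8)
    header += col([""] * ns, 32)
    assert len(header) == 256 * (ns + 1)

    padded = np.zeros((n_records * spr, nch))
    padded[: rec.n_samples] = rec.data
    digital = np.clip(
        np.round((padded + physmax) / scale) - 32768, -32768, 32767
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            fh.write(digital[r * spr : (r + 1) * spr].T.tobytes())
            fh.write(tal_per_record[r].ljust(ann_bytes, b"\x00"))


# --------------------------------------------------------------------------
# public read/write
# --------------------------------------------------------------------------

def _infer_format(path: pathlib.Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".vhdr", ".eeg", ".vmrk"}:
        return "brainvision"
    if suffix == ".edf":
        return "edf+"
    raise FormatError(f"cannot infer EEG format from {path.name!r}")


def read_recording(path: str | pathlib.Path, format: str | None = None) -> Recording:
    """Read a recording from disk.

    Parameters
    ----------
    path : path
        ``.vhdr`` of a BrainVision triplet, or an ``.edf`` file.
    format : {"brainvision", "edf+"}, optional
        Inferred from the suffix when omitted.
    """
    path = pathlib.Path(path)
    fmt = format or _infer_format(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "brainvision":
        _check_brainvision_integrity(path)
        try:
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        except Exception as exc:  # header unparseable
            raise FormatError(f"{path}: {exc}") from exc
    elif fmt in {"edf+", "edf"}:
        try:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        except Exception as exc:
            raise FormatError(f"{path}: {exc}") from exc
    else:
        raise ValidationError(f"unknown format {fmt!r}")
    return _read_mne_raw(raw)


def write_recording(
    rec: Recording, path: str | pathlib.Path, format: str | None = None
) -> pathlib.Path:
    """Write a recording; returns the path to read it back from.

    Data containing NaN is refused.  BrainVision is written as IEEE float32
    (quantization ~1e-7 relative); EDF+ as 16-bit with a symmetric physical
    range (quantization ~max|x|/32767).
    """
    path = pathlib.Path(path)
    fmt = format or _infer_format(path)
    if np.isnan(rec.data).any():
        raise ValidationError("refusing to write data containing NaN")
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "brainvision":
        _write_brainvision(rec, path)
        return path.with_suffix(".vhdr")
    if fmt in {"edf+", "edf"}:
        _write_edf(rec, path.with_suffix(".edf"))
        return path.with_suffix(".edf")
    raise ValidationError(f"unknown format {fmt!r}")


# --------------------------------------------------------------------------
# run manifest
# --------------------------------------------------------------------------

class RunManifest:
    """Append-only log of pipeline stages, parameters and seeds.

    Every CLI stage and the pipeline runner records what it did here, so a
    run can be audited (and the preprocessing stage order asserted) after
    the fact.
    """

    def __init__(self) -> None:
        self.entries: list[dict] = []

    def log(self, stage: str, **params) -> None:
        self.entries.append({"stage": stage, "params": _jsonable(params)})

    @property
    def stages(self) -> list[str]:
        return [e["stage"] for e in self.entries]

    def save(self, path: str | pathlib.Path) -> None:
        pathlib.Path(path).write_text(json.dumps(self.entries, indent=2))

    @classmethod
    def load(cls, path: str | pathlib.Path) -> "RunManifest":
        m = cls()
        m.entries = json.loads(pathlib.Path(path).read_text())
        return m


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
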