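"""Readers/writers for the interchange formats the pipeline touches.

Signals travel as 16-bit EDF in physical units of microvolts; hypnograms as
30-s-epoch CSV with lights-off/on metadata lines; montages as JSON label ->
[x, y, z]; detected events as a long-format CSV table.  Electrode adjacency
for cluster statistics is derived from the montage, either by a Euclidean
distance cutoff or by Delaunay triangulation of the 2-D projection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STAGES = ("W", "N1", "N2", "N3", "REM")

EPOCH_S = 30.0


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected format."""


@dataclass
class Recording:
    """Multichannel EEG time series in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Unique channel identifiers, file order preserved.
    reference : {"as-recorded", "average"}
    start_time : float
        Offset convention in seconds (sample i is at ``start_time + i / fs``).
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    reference: str = "as-recorded"
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per channel required")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def n_epochs(self) -> int:
        """Number of whole 30-s epochs the recording covers."""
        return int(self.n_samples // round(EPOCH_S * self.fs))


@dataclass
class Hypnogram:
    """Stage labels on 30-s epochs with lights-off/on anchors (seconds)."""

    stages: list[str]
    lights_off: float = 0.0
    lights_on: float | None = None
    epoch_s: float = EPOCH_S

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(set(bad))}")
        if self.lights_on is None:
            self.lights_on = self.lights_off + len(self.stages) * self.epoch_s
        if not self.lights_off < self.lights_on:
            raise ValueError("lights_off must precede lights_on")

    def __len__(self) -> int:
        return len(self.stages)

    @property
    def duration_min(self) -> float:
        return len(self.stages) * self.epoch_s / 60.0

    def as_array(self) -> np.ndarray:
        return np.asarray(self.stages, dtype=object)


@dataclass
class Montage:
    """Electrode labels with 3-D positions and a 2-D topographic projection."""

    labels: list[str]
    positions: np.ndarray  # (n, 3)
    projection: np.ndarray | None = None  # (n, 2)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_labels, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("montage labels must be unique")
        if self.projection is None:
            self.projection = azimuthal_projection(self.positions)
        else:
            self.projection = np.asarray(self.projection, dtype=float)

    @property
    def n_channels(self) -> int:
        return len(self.labels)


@dataclass
class AdjacencyGraph:
    """Symmetric channel adjacency used for supra-threshold clustering."""

    labels: list[str]
    edges: set[tuple[int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        n = len(self.labels)
        canon = set()
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-edges not allowed")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("edge endpoint outside label list")
            canon.add((min(i, j), max(i, j)))
        self.edges = canon

    def neighbors(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in self.labels]
        for i, j in self.edges:
            nbrs[i].append(j)
            nbrs[j].append(i)
        return nbrs

    def matrix(self) -> np.ndarray:
        n = len(self.labels)
        m = np.zeros((n, n), dtype=bool)
        for i, j in self.edges:
            m[i, j] = m[j, i] = True
        return m


def azimuthal_projection(positions: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection of unit-sphere positions onto 2-D.

    Distance from the origin equals the polar angle from +z (the vertex), so
    the vertex maps to the centre and the equator to a circle of radius π/2.
    """
    pos = np.asarray(positions, dtype=float)
    r = np.linalg.norm(pos, axis=1)
    r = np.where(r == 0, 1.0, r)
    theta = np.arccos(np.clip(pos[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(pos[:, 1], pos[:, 0])
    return np.column_stack([theta * np.cos(phi), theta * np.sin(phi)])


# ---------------------------------------------------------------------------
# EDF (European Data Format), 16-bit
# ---------------------------------------------------------------------------

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF field too long: {text!r} > {width}")
    return b.ljust(width)


def write_recording(rec: Recording, path) -> None:
    """Write a Recording as a 16-bit EDF file (physical units µV).

    One-second data records are used when the sample count divides evenly at
    an integral rate; otherwise the whole signal is stored as a single
    record.  Per-channel physical ranges are symmetric around zero so the
    quantisation step is ``2·max|x| / 65535``.
    """
    if not np.all(np.isfinite(rec.data)):
        raise ValueError("recording contains non-finite samples")
    n_ch, n_samp = rec.data.shape
    if n_samp == 0:
        raise ValueError("empty recording")

    fs_int = int(round(rec.fs))
    if abs(rec.fs - fs_int) < 1e-9 and n_samp % fs_int == 0 and n_samp > fs_int:
        n_records, spr, rec_dur = n_samp // fs_int, fs_int, 1.0
    else:
        n_records, spr, rec_dur = 1, n_samp, n_samp / rec.fs

    data_max = np.abs(rec.data).max(axis=1)
    # the 8-char header field truncates the range; inflate until the parsed
    # string covers the data so quantisation uses the value a reader sees
    phys_strs: list[str] = []
    phys_max = np.empty(n_ch)
    for ci, m in enumerate(np.maximum(data_max, 1.0)):
        s = f"{m:.6g}"[:7]
        while float(s) < data_max[ci]:
            m *= 1.0001
            s = f"{m:.6g}"[:7]
        phys_strs.append(s)
        phys_max[ci] = float(s)
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (2.0 * phys_max)

    header_bytes = 256 + 256 * n_ch
    head = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad(f"Startdate X X X X ref={rec.reference}", 80),
        _pad("01.01.01", 8),
        _pad("00.00.00", 8),
        _pad(str(header_bytes), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad(f"{rec_dur:.8g}"[:8], 8),
        _pad(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(_pad(lb[:16], 16) for lb in rec.labels),
        b"".join(_pad("", 80) for _ in range(n_ch)),
        b"".join(_pad("uV", 8) for _ in range(n_ch)),
        b"".join(_pad("-" + s, 8) for s in phys_strs),
        b"".join(_pad(s, 8) for s in phys_strs),
        b"".join(_pad(str(_EDF_DIG_MIN), 8) for _ in range(n_ch)),
        b"".join(_pad(str(_EDF_DIG_MAX), 8) for _ in range(n_ch)),
        b"".join(_pad("", 80) for _ in range(n_ch)),
        b"".join(_pad(str(spr), 8) for _ in range(n_ch)),
        b"".join(_pad("", 32) for _ in range(n_ch)),
    ])

    # physical->digital; the 0.5 shift centres the asymmetric int16 range so
    # the affine map dig -> (dig - dmin)·gain + pmin inverts within step/2
    dig = np.clip(np.rint(rec.data * scale[:, None] - 0.5),
                  _EDF_DIG_MIN, _EDF_DIG_MAX)
    dig = dig.astype("<i2").reshape(n_ch, n_records, spr)
    records = np.ascontiguousarray(dig.transpose(1, 0, 2))

    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(sig)
        fh.write(records.tobytes())


def read_recording(path) -> Recording:
    """Read a 16-bit EDF file into a Recording (µV).

    All signals must share one sampling rate; EDF physical scaling is applied
    per channel.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 256:
        raise FormatError("truncated EDF header")

    def fld(lo: int, hi: int) -> str:
        return raw[lo:hi].decode("ascii", errors="replace").strip()

    try:
        header_bytes = int(fld(184, 192))
        n_records = int(fld(236, 244))
        rec_dur = float(fld(244, 252))
        n_ch = int(fld(252, 256))
    except ValueError as exc:
        raise FormatError(f"unreadable EDF header: {exc}") from None
    if n_ch <= 0 or len(raw) < 256 + 256 * n_ch:
        raise FormatError("truncated EDF signal headers")

    base = 256

    def sig_fld(width: int, offset: int, i: int) -> str:
        lo = base + offset * n_ch + i * width
        return raw[lo:lo + width].decode("ascii", errors="replace").strip()

    labels = [sig_fld(16, 0, i) for i in range(n_ch)]
    # field offsets in bytes-per-channel units: label 16, transducer 80,
    # dimension 8, phys min 8, phys max 8, dig min 8, dig max 8, prefilter 80,
    # samples-per-record 8, reserved 32
    offs = np.cumsum([0, 16, 80, 8, 8, 8, 8, 8, 80, 8])

    def col(idx: int, width: int) -> list[str]:
        lo0 = base + offs[idx] * n_ch
        return [raw[lo0 + i * width: lo0 + (i + 1) * width].decode("ascii").strip()
                for i in range(n_ch)]

    try:
        pmin = np.array([float(x) for x in col(3, 8)])
        pmax = np.array([float(x) for x in col(4, 8)])
        dmin = np.array([float(x) for x in col(5, 8)])
        dmax = np.array([float(x) for x in col(6, 8)])
        spr = np.array([int(x) for x in col(8, 8)])
    except ValueError as exc:
        raise FormatError(f"unreadable EDF signal header: {exc}") from None

    if len(set(spr.tolist())) != 1:
        raise FormatError("mixed per-signal sampling rates are not supported")
    spr0 = int(spr[0])
    fs = spr0 / rec_dur

    expected = header_bytes + n_records * n_ch * spr0 * 2
    if len(raw) < expected:
        raise FormatError("truncated EDF data section")

    dig = np.frombuffer(raw, dtype="<i2", count=n_records * n_ch * spr0,
                        offset=header_bytes)
    dig = dig.reshape(n_records, n_ch, spr0).transpose(1, 0, 2).reshape(n_ch, -1)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (dig - dmin[:, None]) * gain[:, None] + pmin[:, None]
    return Recording(data=data, fs=fs, labels=labels)


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------

def write_hypnogram(hyp: Hypnogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#lights_off={hyp.lights_off:g}\n")
        fh.write(f"#lights_on={hyp.lights_on:g}\n")
        fh.write("epoch,stage\n")
        for i, st in enumerate(hyp.stages):
            fh.write(f"{i},{st}\n")


def read_hypnogram(path) -> Hypnogram:
    """Parse a hypnogram CSV (``epoch,stage`` rows, ``#lights_*`` metadata).

    Epochs that end before lights-off are marked W regardless of their label.
    """
    meta: dict[str, float] = {}
    stages: list[str] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise FormatError("empty hypnogram file")
    body: list[str] = []
    for ln in lines:
        if ln.startswith("#"):
            key, _, val = ln[1:].partition("=")
            try:
                meta[key.strip()] = float(val)
            except ValueError:
                raise FormatError(f"bad metadata line: {ln!r}") from None
        else:
            body.append(ln)
    if not body or body[0].split(",")[:2] != ["epoch", "stage"]:
        raise FormatError("missing 'epoch,stage' header row")
    for row_no, ln in enumerate(body[1:], start=2):
        parts = [p.strip() for p in ln.split(",")]
        if len(parts) < 2 or parts[1] not in STAGES:
            raise FormatError(f"unknown stage label at row {row_no}: {ln!r}")
        stages.append(parts[1])
    if not stages:
        raise FormatError("hypnogram contains no epochs")
    lights_off = meta.get("lights_off", 0.0)
    lights_on = meta.get("lights_on", lights_off + len(stages) * EPOCH_S)
    for i in range(len(stages)):
        if (i + 1) * EPOCH_S <= lights_off:
            stages[i] = "W"
    return Hypnogram(stages=stages, lights_off=lights_off, lights_on=lights_on)


# ---------------------------------------------------------------------------
# Montage JSON and adjacency
# ---------------------------------------------------------------------------

def write_montage(mon: Montage, path) -> None:
    obj = {lb: [float(v) for v in xyz] for lb, xyz in zip(mon.labels, mon.positions)}
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def read_montage(path) -> Montage:
    with open(path) as fh:
        obj = json.load(fh)
    if not isinstance(obj, dict) or not obj:
        raise FormatError("montage JSON must be a non-empty label->[x,y,z] map")
    labels = list(obj.keys())
    positions = np.array([obj[lb] for lb in labels], dtype=float)
    return Montage(labels=labels, positions=positions)


def build_adjacency(montage: Montage, method: str = "distance",
                    param: float | None = None) -> AdjacencyGraph:
    """Electrode adjacency by distance cutoff or Delaunay triangulation.

    ``distance``: connect pairs with 3-D Euclidean distance <= ``param``
    (default 1.3x the median nearest-neighbour distance).  ``triangulation``:
    connect Delaunay neighbours of the 2-D projection.
    """
    n = montage.n_channels
    edges: set[tuple[int, int]] = set()
    if method == "distance":
        if n >= 2:
            d = np.linalg.norm(
                montage.positions[:, None, :] - montage.positions[None, :, :], axis=-1)
            if param is None:
                nn = np.where(np.eye(n, dtype=bool), np.inf, d).min(axis=1)
                param = 1.3 * float(np.median(nn))
            if param <= 0:
                raise ValueError("distance radius must be positive")
            ii, jj = np.nonzero(np.triu(d <= param, k=1))
            edges = {(int(i), int(j)) for i, j in zip(ii, jj)}
        elif param is not None and param <= 0:
            raise ValueError("distance radius must be positive")
    elif method == "triangulation":
        if n >= 3:
            from scipy.spatial import Delaunay

            tri = Delaunay(montage.projection)
            for simplex in tri.simplices:
                for a in range(3):
                    for b in range(a + 1, 3):
                        i, j = int(simplex[a]), int(simplex[b])
                        edges.add((min(i, j), max(i, j)))
        elif n == 2:
            edges = {(0, 1)}
    else:
        raise ValueError(f"unknown adjacency method: {method!r}")
    return AdjacencyGraph(labels=list(montage.labels), edges=edges)


# ---------------------------------------------------------------------------
# Event tables (long format)
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["subject", "channel", "kind", "start_s", "end_s", "feature", "value"]


def events_to_table(events, subject: str, kind: str) -> pd.DataFrame:
    """Flatten detected events into the long-format event table."""
    rows = []
    for ev in events:
        for feat, val in ev.features().items():
            rows.append((subject, ev.channel, kind, ev.start, ev.end, feat, val))
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_event_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    bad = df[df["start_s"] >= df["end_s"]]
    if len(bad):
        raise ValueError("event table rows must satisfy start < end")
    df[EVENT_COLUMNS].to_csv(path, index=False)


def read_event_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"event table missing columns: {missing}")
    return df
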