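"""Recording containers, montage helpers, EDF and schedule I/O.

The interchange format for continuous EEG is EDF (16-bit, one data record
per second).  Reading goes through :func:`mne.io.read_raw_edf`; writing uses
a small self-contained EDF writer, so a written file can be validated
against an independent reader.

All internal indexing is 0-based with half-open ``[start, start + n)``
sample intervals.  Schedules are given in seconds in files and converted
once to samples (rounding half-up) on read.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "ClusterSpec",
    "DEFAULT_CLUSTERS",
    "montage_positions",
    "reduced_montage",
    "read_schedule",
    "write_schedule",
    "write_edf",
    "read_recording",
]


@dataclass
class RawRecording:
    """Continuous multichannel EEG for one subject.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts.
    channel_labels : list of str
        Montage names, geodesic ``E1..E128`` convention.
    sampling_rate_hz : float
    subject_id, dyad_id : str
    schedule : list of (str, int, int)
        ``(condition_label, start_sample, n_samples)``, non-overlapping,
        within the recording.
    """

    samples: np.ndarray
    channel_labels: list[str]
    sampling_rate_hz: float
    subject_id: str = ""
    dyad_id: str = ""
    schedule: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a channels x time matrix")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channel rows"
            )
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        self._check_schedule()

    def _check_schedule(self) -> None:
        n = self.samples.shape[1]
        prev_end = None
        for label, start, length in sorted(self.schedule, key=lambda s: s[1]):
            if start < 0 or length <= 0 or start + length > n:
                raise ValueError(
                    f"schedule segment {label!r} [{start}, {start + length}) "
                    f"outside recording of {n} samples"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(f"schedule segment {label!r} overlaps previous")
            prev_end = start + length

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.sampling_rate_hz

    def condition_slice(self, label: str) -> np.ndarray:
        for lab, start, length in self.schedule:
            if lab == label:
                return self.samples[:, start : start + length]
        raise KeyError(label)


@dataclass(frozen=True)
class ClusterSpec:
    """Left/right frontal channel clusters used for the asymmetry score."""

    left_labels: tuple[str, ...]
    right_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.left_labels or not self.right_labels:
            raise ValueError("clusters must be non-empty")
        if set(self.left_labels) & set(self.right_labels):
            raise ValueError("left and right clusters must be disjoint")

    def validate_montage(self, channel_labels: list[str]) -> None:
        missing = (set(self.left_labels) | set(self.right_labels)) - set(
            channel_labels
        )
        if missing:
            raise ValueError(f"cluster channels missing from montage: {sorted(missing)}")


#: Frontal clusters on the 128-channel geodesic net: left F3/F7 region vs
#: the homologous right region.
DEFAULT_CLUSTERS = ClusterSpec(
    left_labels=("E23", "E24", "E26", "E27", "E33"),
    right_labels=("E2", "E3", "E122", "E123", "E124"),
)


def montage_positions(channel_labels: list[str]) -> np.ndarray:
    """3-D sensor positions (meters) from the bundled GSN-HydroCel-128 layout."""
    import mne

    montage = mne.channels.make_standard_montage("GSN-HydroCel-128")
    pos = montage.get_positions()["ch_pos"]
    missing = [ch for ch in channel_labels if ch not in pos]
    if missing:
        raise ValueError(f"channels not on GSN-HydroCel-128 layout: {missing}")
    return np.array([pos[ch] for ch in channel_labels])


def reduced_montage(n_channels: int = 32) -> list[str]:
    """A subset of the 128-channel net that always contains both frontal clusters.

    The ten cluster channels come first; the remainder are spread evenly
    over the rest of the cap so that interpolation neighbourhoods exist.
    """
    clusters = list(DEFAULT_CLUSTERS.left_labels + DEFAULT_CLUSTERS.right_labels)
    if n_channels < len(clusters):
        raise ValueError(f"need at least {len(clusters)} channels for the clusters")
    rest = [f"E{i}" for i in range(1, 129) if f"E{i}" not in clusters]
    extra = n_channels - len(clusters)
    if extra:
        idx = np.linspace(0, len(rest) - 1, extra).round().astype(int)
        chosen = [rest[i] for i in idx]
    else:
        chosen = []
    labels = clusters + chosen
    # keep natural montage order
    return sorted(labels, key=lambda s: int(s[1:]))


# ---------------------------------------------------------------------------
# schedule files:  CSV with columns label,start_s,duration_s
# ---------------------------------------------------------------------------

def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def read_schedule(path, sampling_rate_hz: float, n_times: int | None = None,
                  logger=None) -> list[tuple[str, int, int]]:
    """Read a condition schedule CSV and convert seconds to samples.

    Segments extending beyond ``n_times`` are dropped with a log message.
    An empty schedule is an error.
    """
    df = pd.read_csv(path)
    required = {"label", "start_s", "duration_s"}
    if not required <= set(df.columns):
        raise ValueError(f"schedule must have columns {sorted(required)}")
    schedule = []
    for row in df.itertuples(index=False):
        start = _round_half_up(float(row.start_s) * sampling_rate_hz)
        length = _round_half_up(float(row.duration_s) * sampling_rate_hz)
        if n_times is not None and start + length > n_times:
            if logger is not None:
                logger.warning(
                    "dropping schedule segment %r: extends beyond recording", row.label
                )
            continue
        schedule.append((str(row.label), start, length))
    if not schedule:
        raise ValueError("schedule is empty (or every segment was out of range)")
    return schedule


def write_schedule(path, schedule_s: list[tuple[str, float, float]]) -> None:
    """Write ``(label, start_s, duration_s)`` rows to CSV."""
    pd.DataFrame(schedule_s, columns=["label", "start_s", "duration_s"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, rec: RawRecording) -> None:
    """Write a recording as 16-bit EDF, one data record per second.

    The per-channel physical range is fitted to the data, so quantization
    error is at most ``max|x| / 32767`` per channel.  The recording is
    zero-padded to a whole number of one-second records; schedule segments
    always lie inside the original data, so padding never affects analysis.
    """
    fs = rec.sampling_rate_hz
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch, n_times = rec.samples.shape
    n_records = int(math.ceil(n_times / spr))
    data = np.zeros((n_ch, n_records * spr))
    data[:, :n_times] = rec.samples

    dig_min, dig_max = -32768, 32767
    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    phys_min = -phys_max
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data - phys_min[:, None]) * scale[:, None] + dig_min),
        dig_min,
        dig_max,
    ).astype("<i2")

    header = b"".join(
        [
            _edf_field("0", 8),
            _edf_field(rec.subject_id or "X", 80),
            _edf_field(f"Startdate 01-JAN-2000 {rec.dyad_id or 'X'}", 80),
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(str(256 * (1 + n_ch)), 8),
            _edf_field("", 44),
            _edf_field(str(n_records), 8),
            _edf_field("1", 8),
            _edf_field(str(n_ch), 4),
        ]
    )
    sig_headers = b"".join(
        [
            b"".join(_edf_field(lab, 16) for lab in rec.channel_labels),
            b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(n_ch)),
            b"".join(_edf_field("uV", 8) for _ in range(n_ch)),
            b"".join(_edf_field(f"{phys_min[i]:.6g}"[:8], 8) for i in range(n_ch)),
            b"".join(_edf_field(f"{phys_max[i]:.6g}"[:8], 8) for i in range(n_ch)),
            b"".join(_edf_field(str(dig_min), 8) for _ in range(n_ch)),
            b"".join(_edf_field(str(dig_max), 8) for _ in range(n_ch)),
            b"".join(_edf_field("", 80) for _ in range(n_ch)),
            b"".join(_edf_field(str(spr), 8) for _ in range(n_ch)),
            b"".join(_edf_field("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_headers)
        # record-major, then channel-major within record
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())


def read_recording(
    path,
    schedule_path,
    subject_id: str = "",
    dyad_id: str = "",
    expected_rate_hz: float | None = None,
    clusters: ClusterSpec = DEFAULT_CLUSTERS,
    logger=None,
) -> RawRecording:
    """Read an EDF file and its schedule CSV into a :class:`RawRecording`.

    Raises if the file's sampling rate disagrees with ``expected_rate_hz``
    or if any cluster channel is missing from the montage.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    fs = float(raw.info["sfreq"])
    if expected_rate_hz is not None and abs(fs - expected_rate_hz) > 1e-6:
        raise ValueError(
            f"sampling rate {fs} Hz does not match configured {expected_rate_hz} Hz"
        )
    labels = list(raw.ch_names)
    clusters.validate_montage(labels)
    samples = raw.get_data(units="uV")
    schedule = read_schedule(schedule_path, fs, n_times=samples.shape[1], logger=logger)
    return RawRecording(
        samples=samples,
        channel_labels=labels,
        sampling_rate_hz=fs,
        subject_id=subject_id,
        dyad_id=dyad_id,
        schedule=schedule,
    )


def write_sidecar(path, payload: dict) -> None:
    """Write a JSON sidecar (ground truth, config echo) next to an EDF pair."""

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_default)
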