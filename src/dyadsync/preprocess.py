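"""Continuous-EEG cleaning.

Stage order (fixed contract): zero-phase bandpass -> bad-channel
detection -> spectral-threshold segment rejection -> interpolation of bad
channels -> average re-reference.

Bad channels are those whose signal cannot be predicted from the rest of
the montage: in sliding 1 s windows the channel's multiple correlation
with all other channels is computed from the (ridge-regularised) window
correlation matrix, and the median across windows is compared with the
rejection threshold (default 0.9).  Flat channels are always bad.

Segment rejection marks sliding windows whose mean 20-40 Hz band power
exceeds the recording's median band power by >= 10 dB; the mask is
returned at sample resolution.  By default the median is computed per
condition (a sensitivity toggle recomputes it across the recording).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .config import PipelineConfig
from .io import RawRecording, montage_positions

__all__ = [
    "CleanRecording",
    "bandpass",
    "reject_channels",
    "reject_segments",
    "interpolate_and_rereference",
    "preprocess_recording",
]


@dataclass
class CleanRecording:
    """Cleaned continuous EEG plus the bookkeeping downstream stages need."""

    samples: np.ndarray
    channel_labels: list[str]
    sampling_rate_hz: float
    subject_id: str
    dyad_id: str
    schedule: list[tuple[str, int, int]]
    kept_mask: np.ndarray  # per-sample bool, True = retained
    interpolated_labels: list[str] = field(default_factory=list)
    reference: str = "average"

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]


def bandpass(rec: RawRecording, low_hz: float, high_hz: float,
             order: int = 5) -> RawRecording:
    """Zero-phase Butterworth bandpass (two-pass ``sosfiltfilt``).

    A fifth-order section filtered forward and backward gives > 20 dB
    attenuation one octave outside the passband while leaving the
    passband amplitude within a few percent.
    """
    nyq = rec.sampling_rate_hz / 2.0
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(f"high edge {high_hz} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass",
                        fs=rec.sampling_rate_hz, output="sos")
    # the low cut's impulse response is ~1/low_hz seconds long; pad well
    # beyond it so edge transients do not leak into the recording
    padlen = min(rec.n_times - 1,
                 int(round(3.0 * rec.sampling_rate_hz / low_hz)))
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1, padlen=padlen)
    return RawRecording(
        samples=filtered,
        channel_labels=list(rec.channel_labels),
        sampling_rate_hz=rec.sampling_rate_hz,
        subject_id=rec.subject_id,
        dyad_id=rec.dyad_id,
        schedule=list(rec.schedule),
    )


def _window_view(x: np.ndarray, win: int, step: int) -> np.ndarray:
    """(channels, n_windows, win) strided view of a (channels, time) array."""
    n = (x.shape[1] - win) // step + 1
    if n < 1:
        return x[:, :0].reshape(x.shape[0], 0, win)
    shape = (x.shape[0], n, win)
    strides = (x.strides[0], step * x.strides[1], x.strides[1])
    return np.lib.stride_tricks.as_strided(x, shape, strides, writeable=False)


def reject_channels(
    rec: RawRecording,
    threshold: float = 0.9,
    window_s: float = 1.0,
    ridge: float = 0.05,
) -> tuple[RawRecording, list[str]]:
    """Flag channels unpredictable from the rest of the montage.

    Returns the (unchanged) recording and the bad-channel labels.  Raises
    if more than half of the montage is flagged, which indicates the
    recording needs manual inspection rather than automated cleaning.
    """
    if rec.n_channels < 2:
        raise ValueError("need at least 2 channels")
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    win = int(round(window_s * rec.sampling_rate_hz))
    views = _window_view(rec.samples, win, win)
    n_ch, n_win, _ = views.shape
    if n_win == 0:
        raise ValueError("recording shorter than one analysis window")

    r_per_window = np.zeros((n_ch, n_win))
    flat = np.zeros(n_ch, dtype=bool)
    sd_global = rec.samples.std(axis=1)
    flat |= sd_global < 1e-12
    active = ~flat
    for w in range(n_win):
        x = views[:, w, :]
        sd = x.std(axis=1)
        ok = active & (sd > 1e-12)
        idx = np.flatnonzero(ok)
        if len(idx) < 2:
            continue
        z = (x[idx] - x[idx].mean(axis=1, keepdims=True)) / sd[idx][:, None]
        corr = z @ z.T / z.shape[1]
        corr[np.diag_indices_from(corr)] = 1.0
        # ridge keeps the inverse stable when a common source makes the
        # window correlation matrix near-singular
        prec = np.linalg.inv(corr + ridge * np.eye(len(idx)))
        # multiple correlation of channel i with the others, from the
        # precision matrix of the (unit-diagonal) correlation matrix
        r2 = 1.0 - 1.0 / np.maximum(np.diag(prec), 1.0)
        r_per_window[idx, w] = np.sqrt(np.clip(r2, 0.0, 1.0))

    med = np.median(r_per_window, axis=1)
    bad = flat | (med < threshold)
    bad_labels = [rec.channel_labels[i] for i in np.flatnonzero(bad)]
    if len(bad_labels) > rec.n_channels / 2:
        raise ValueError(
            f"{len(bad_labels)}/{rec.n_channels} channels flagged bad; "
            "inspect the recording before automated cleaning"
        )
    return rec, bad_labels


def _band_power_windows(x: np.ndarray, fs: float, band: tuple[float, float],
                        win: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean band power per window (averaged over channels) and window starts."""
    views = _window_view(x, win, step)
    n_ch, n_win, _ = views.shape
    taper = np.hanning(win)
    freqs = np.fft.rfftfreq(win, 1 / fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    spec = np.fft.rfft(views * taper, axis=2)
    power = (np.abs(spec[:, :, sel]) ** 2).mean(axis=2).mean(axis=0)
    starts = np.arange(n_win) * step
    return power, starts


def reject_segments(
    rec: RawRecording,
    band_hz: tuple[float, float] = (20.0, 40.0),
    threshold_db: float = 10.0,
    window_s: float = 0.5,
    per_condition: bool = True,
    prior_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Sample-resolution keep mask from sliding-window spectral thresholding.

    Windows (50% overlap) whose mean band power exceeds the median window
    band power by ``threshold_db`` are rejected; adjacent rejected windows
    merge naturally at sample resolution.  Passing a ``prior_mask``
    excludes already-rejected windows from the median, which makes the
    operation idempotent.
    """
    fs = rec.sampling_rate_hz
    win = int(round(window_s * fs))
    step = max(1, win // 2)
    kept = np.ones(rec.n_times, dtype=bool)
    if prior_mask is not None:
        kept &= prior_mask.astype(bool)

    segments = rec.schedule if (per_condition and rec.schedule) else [
        ("__all__", 0, rec.n_times)
    ]
    for _, start, length in segments:
        x = rec.samples[:, start : start + length]
        if x.shape[1] < win:
            continue
        power, starts = _band_power_windows(x, fs, band_hz, win, step)
        clean = np.array(
            [kept[start + s : start + s + win].all() for s in starts]
        )
        base = power[clean] if clean.any() else power
        median = np.median(base)
        if median <= 0:
            continue  # e.g. an all-zero recording: nothing to reject
        bad = 10.0 * np.log10(power / median) >= threshold_db
        for s in starts[bad]:
            kept[start + s : start + s + win] = False
    return kept


def interpolate_and_rereference(
    rec: RawRecording,
    bad_labels: list[str],
    kept_mask: np.ndarray | None = None,
    n_neighbors: int = 6,
    radius_m: float | None = None,
) -> CleanRecording:
    """Replace bad channels by inverse-distance neighbour averages, then
    subtract the channel mean at every sample (average reference).

    ``radius_m=None`` sets the neighbour radius adaptively to 3x the
    median nearest-neighbour distance of the montage, so the same rule
    works for dense and sparse channel subsets.
    """
    samples = rec.samples.copy()
    if bad_labels:
        pos = montage_positions(rec.channel_labels)
        bad_idx = [rec.channel_labels.index(lab) for lab in bad_labels]
        good_idx = [i for i in range(rec.n_channels) if i not in bad_idx]
        if radius_m is None:
            dists = np.linalg.norm(pos[:, None] - pos[None, :], axis=2)
            np.fill_diagonal(dists, np.inf)
            radius_m = 3.0 * float(np.median(dists.min(axis=1)))
        for i in bad_idx:
            d = np.linalg.norm(pos[good_idx] - pos[i], axis=1)
            order = np.argsort(d)
            near = [good_idx[j] for j in order[:n_neighbors] if d[j] <= radius_m]
            if not near:
                raise ValueError(
                    f"bad channel {rec.channel_labels[i]!r} has no good "
                    f"neighbour within {radius_m} m"
                )
            w = 1.0 / np.maximum(
                np.array([np.linalg.norm(pos[j] - pos[i]) for j in near]), 1e-6
            )
            samples[i] = (w[:, None] * samples[near]).sum(axis=0) / w.sum()
    samples -= samples.mean(axis=0, keepdims=True)
    if kept_mask is None:
        kept_mask = np.ones(rec.n_times, dtype=bool)
    return CleanRecording(
        samples=samples,
        channel_labels=list(rec.channel_labels),
        sampling_rate_hz=rec.sampling_rate_hz,
        subject_id=rec.subject_id,
        dyad_id=rec.dyad_id,
        schedule=list(rec.schedule),
        kept_mask=kept_mask,
        interpolated_labels=list(bad_labels),
    )


def preprocess_recording(rec: RawRecording, config: PipelineConfig,
                         logger=None) -> tuple[CleanRecording, dict]:
    """Run the full cleaning chain; returns the recording and a QC report."""
    filtered = bandpass(rec, config.band_low_hz, config.band_high_hz,
                        order=config.filter_order)
    _, bad_labels = reject_channels(
        filtered,
        threshold=config.channel_reject_threshold,
        window_s=config.channel_reject_window_s,
    )
    kept = reject_segments(
        filtered,
        band_hz=config.artifact_band_hz,
        threshold_db=config.artifact_threshold_db,
        window_s=config.artifact_window_s,
        per_condition=config.artifact_per_condition,
    )
    clean = interpolate_and_rereference(
        filtered, bad_labels, kept_mask=kept,
        n_neighbors=config.interp_n_neighbors,
        radius_m=config.interp_radius_m,
    )
    pct_rejected = {}
    for label, start, length in rec.schedule:
        pct_rejected[label] = 100.0 * (~kept[start : start + length]).mean()
    qc = {
        "subject_id": rec.subject_id,
        "bad_channels": bad_labels,
        "pct_samples_rejected": pct_rejected,
        "reference_check_max_abs_mean": float(
            np.abs(clean.samples.mean(axis=0)).max()
        ),
    }
    if logger is not None:
        logger.info("preprocess %s: %d bad channels, rejection %s",
                    rec.subject_id, len(bad_labels),
                    {k: f"{v:.1f}%" for k, v in pct_rejected.items()})
    return clean, qc
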