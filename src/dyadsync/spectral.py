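"""Epoching, alpha-band power, and frontal alpha asymmetry (FAA).

The cleaned recording is cut into non-overlapping 500 ms epochs from each
condition's start (a trailing partial window is dropped; epochs touching
any rejected sample are invalid).  Per epoch and channel a Hann-tapered
periodogram is evaluated on a zero-padded 0.5 Hz grid; absolute alpha
power is the mean periodogram power over 8-12 Hz inclusive and relative
alpha divides by the total over 1-40 Hz.

FAA is the cluster log-power ratio

    faa = ln(mean alpha power over right cluster)
        - ln(mean alpha power over left cluster)

computed after cluster averaging; positive values mean more right- than
left-cluster alpha.  Relative alpha is the default measure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .config import PipelineConfig
from .io import ClusterSpec
from .preprocess import CleanRecording

__all__ = ["EpochSpectrum", "epoch", "band_power", "compute_faa", "faa_for_recording"]


@dataclass
class EpochSpectrum:
    """Per-epoch, per-channel band powers for one subject."""

    subject_id: str
    dyad_id: str
    channel_labels: list[str]
    conditions: np.ndarray          # (n_epochs,) condition label per epoch
    epoch_index: np.ndarray         # (n_epochs,) 0-based within condition
    valid: np.ndarray               # (n_epochs,) bool
    abs_power: np.ndarray           # (n_epochs, n_channels), µV²
    rel_power: np.ndarray           # (n_epochs, n_channels), in [0, 1]


def epoch(rec: CleanRecording, epoch_length_s: float = 0.5,
          logger=None) -> list[tuple[str, int, int, bool]]:
    """Cut each condition into contiguous epochs.

    Returns ``(condition, epoch_index, start_sample, valid)`` tuples;
    ``valid`` is False when the epoch overlaps any rejected sample.
    """
    n = int(round(epoch_length_s * rec.sampling_rate_hz))
    out = []
    for label, start, length in rec.schedule:
        n_epochs = length // n
        if n_epochs == 0:
            msg = f"condition {label!r} shorter than one epoch; zero epochs"
            if logger is not None:
                logger.warning(msg)
            else:
                warnings.warn(msg, stacklevel=2)
            continue
        for i in range(n_epochs):
            s = start + i * n
            valid = bool(rec.kept_mask[s : s + n].all())
            out.append((label, i, s, valid))
    return out


def band_power(
    samples: np.ndarray,
    fs: float,
    alpha_band: tuple[float, float] = (8.0, 12.0),
    total_band: tuple[float, float] = (1.0, 40.0),
    resolution_hz: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Absolute and relative alpha power per channel for a stack of epochs.

    ``samples`` has shape (..., n_channels, n_samples).  Absolute power is
    the integrated Hann periodogram over the alpha band, evaluated on a
    zero-padded grid of ``resolution_hz`` (sum of density x bin width, so
    the value is in µV²); relative power divides by the integral over the
    total band and lies in [0, 1] whenever alpha_band is inside
    total_band.  Rows with zero total power get relative power NaN.
    """
    nfft = int(round(fs / resolution_hz))
    freqs, pxx = signal.periodogram(
        samples, fs=fs, window="hann", nfft=nfft, detrend=False, axis=-1
    )
    df = freqs[1] - freqs[0]
    in_alpha = (freqs >= alpha_band[0]) & (freqs <= alpha_band[1])
    in_total = (freqs >= total_band[0]) & (freqs <= total_band[1])
    absolute = pxx[..., in_alpha].sum(axis=-1) * df
    total = pxx[..., in_total].sum(axis=-1) * df
    with np.errstate(invalid="ignore", divide="ignore"):
        relative = np.where(total > 0, absolute / np.maximum(total, 1e-300), np.nan)
    return absolute, relative


def epoch_spectra(rec: CleanRecording, config: PipelineConfig,
                  logger=None) -> EpochSpectrum:
    """Epoch a recording and compute per-channel band powers."""
    epochs = epoch(rec, config.epoch_length_s, logger=logger)
    n = config.epoch_samples
    if epochs:
        stack = np.stack([rec.samples[:, s : s + n] for (_, _, s, _) in epochs])
    else:
        stack = np.zeros((0, rec.samples.shape[0], n))
    absolute, relative = band_power(
        stack, rec.sampling_rate_hz,
        alpha_band=config.alpha_band_hz,
        total_band=config.total_band_hz,
        resolution_hz=config.spectrum_resolution_hz,
    )
    valid = np.array([v for (_, _, _, v) in epochs], dtype=bool)
    # an all-zero epoch has undefined relative power -> invalid
    valid &= ~np.isnan(relative).any(axis=1)
    return EpochSpectrum(
        subject_id=rec.subject_id,
        dyad_id=rec.dyad_id,
        channel_labels=list(rec.channel_labels),
        conditions=np.array([c for (c, _, _, _) in epochs]),
        epoch_index=np.array([i for (_, i, _, _) in epochs], dtype=int),
        valid=valid,
        abs_power=absolute,
        rel_power=np.nan_to_num(relative, nan=0.0),
    )


def compute_faa(
    spectra: EpochSpectrum,
    clusters: ClusterSpec,
    mode: str = "relative",
) -> pd.DataFrame:
    """FAA per epoch: ln(right-cluster power) - ln(left-cluster power).

    Cluster power is the mean of the chosen alpha measure over the
    cluster's channels; epochs with nonpositive cluster power are marked
    invalid.  Returns a tidy frame with columns ``subject_id, dyad_id,
    condition, epoch_index, faa, valid, alpha_mode``.
    """
    clusters.validate_montage(spectra.channel_labels)
    if mode not in ("relative", "absolute"):
        raise ValueError("mode must be 'relative' or 'absolute'")
    power = spectra.rel_power if mode == "relative" else spectra.abs_power
    idx = {lab: i for i, lab in enumerate(spectra.channel_labels)}
    left = [idx[lab] for lab in clusters.left_labels]
    right = [idx[lab] for lab in clusters.right_labels]
    p_left = power[:, left].mean(axis=1)
    p_right = power[:, right].mean(axis=1)
    ok = (p_left > 0) & (p_right > 0)
    faa = np.full(len(p_left), np.nan)
    faa[ok] = np.log(p_right[ok]) - np.log(p_left[ok])
    return pd.DataFrame(
        {
            "subject_id": spectra.subject_id,
            "dyad_id": spectra.dyad_id,
            "condition": spectra.conditions,
            "epoch_index": spectra.epoch_index,
            "faa": faa,
            "valid": spectra.valid & ok,
            "alpha_mode": mode,
        }
    )


def faa_for_recording(rec: CleanRecording, config: PipelineConfig,
                      clusters: ClusterSpec, logger=None) -> pd.DataFrame:
    """Convenience: epoch, band power and FAA in one call."""
    spectra = epoch_spectra(rec, config, logger=logger)
    return compute_faa(spectra, clusters, mode=config.alpha_mode)
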