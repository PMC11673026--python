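"""Synthetic dyadic EEG with a known frontal-asymmetry ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: two sample-aligned 250 Hz recordings whose left/right frontal
alpha (8-12 Hz) amplitudes are driven by a slowly varying latent
asymmetry process per subject, with configurable inter-partner coupling
at a configurable delay.

Latent driver
-------------
For partner 1 the driver ``d1`` is an AR(1) process at 2 s resolution,
piecewise per condition (mean-reverting to that condition's mean, started
at a stationary draw).  Partner 2's driver is a convex mixture

    d2(t) = c * d1(t - delay) + (1 - c) * e(t)

with ``e`` an independent AR(1) of the same law and ``c`` the coupling
strength.  Drivers are held constant within each 2 s step (the bin
resolution of the concordance analysis), so an integer-bin delay shifts
the binned driver exactly.

Amplitude mapping
-----------------
Left-cluster channels carry an alpha sinusoid with amplitude
``A * exp(-d/2)`` and right-cluster channels ``A * exp(+d/2)``, so that

    ln(right alpha power) - ln(left alpha power) = 2 d

exactly in absolute-power terms on the raw channels.  Two later stages
reshape (but never re-order) this mapping: average re-referencing
subtracts the montage-mean alpha component, which steepens the transfer
curve, and relative alpha normalises by broadband power.  Both are
monotone for |d| up to about 1 with the default montage, so recovery is
assessed by correlation with the latent driver; the exact ``2 d`` form
is asserted on raw cluster powers in absolute mode.

Noise is the sum of a broadband background shared across channels
(volume conduction makes real montage channels mutually predictable;
per-channel gain ~ N(1, 0.1)) and independent per-channel sensor noise.
Optional high-frequency (20-40 Hz) artifact bursts and flat/noisy bad
channels exercise the preprocessing stages.

Randomness: one global seed spawns independent child streams, in this
fixed order: driver_p1, driver_p2, phase/gains, noise_p1, noise_p2,
artifacts_p1, artifacts_p2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import RawRecording, DEFAULT_CLUSTERS, ClusterSpec, write_edf, write_schedule, write_sidecar

__all__ = ["SynthConfig", "SynthDyad", "generate_dyad", "generate_covariates",
           "write_dyad", "DEFAULT_SCHEDULE"]

#: The five-condition task schedule: 2 min per condition, fixed order.
DEFAULT_SCHEDULE: tuple[tuple[str, float], ...] = (
    ("No Connection", 120.0),
    ("Gaze Only", 120.0),
    ("Hands Only", 120.0),
    ("Gaze and Hands", 120.0),
    ("Embrace", 120.0),
)


@dataclass
class SynthConfig:
    """Ground-truth parameters of a synthetic dyad.

    Amplitudes and noise are in microvolts; the latent driver is in
    log-power-ratio units (the asymmetry score recovers ``2 d`` in
    absolute-alpha mode).
    """

    sampling_rate_hz: float = 250.0
    n_channels: int = 128
    channel_labels: tuple[str, ...] | None = None  # overrides n_channels
    condition_schedule: tuple[tuple[str, float], ...] = DEFAULT_SCHEDULE
    alpha_freq_hz: float = 10.0
    alpha_amp_uv: float = 10.0
    noncluster_alpha_frac: float = 0.3
    # latent driver: AR(1) at driver_step_s resolution
    driver_step_s: float = 2.0
    ar_coef: float = 0.8
    ar_innovation_sd: float = 0.18
    condition_means: dict[str, float] = field(default_factory=dict)
    # inter-partner coupling
    coupling_delay_s: float = 0.0
    coupling_strength: float = 0.0
    # noise
    background_sd_uv: float = 15.0
    noise_sd_uv: float = 5.0
    # artifacts & bad channels
    artifact_rate_per_min: float = 0.0
    artifact_duration_s: float = 1.0
    artifact_db: float = 15.0
    bad_channel_labels: tuple[str, ...] = ()
    clusters: ClusterSpec = DEFAULT_CLUSTERS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if not -1 < self.ar_coef < 1:
            raise ValueError("ar_coef must lie in (-1, 1)")
        if self.ar_innovation_sd < 0 or self.noise_sd_uv <= 0 or self.background_sd_uv < 0:
            raise ValueError("noise standard deviations must be positive")
        if not 0 <= self.coupling_strength <= 1:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.coupling_delay_s < 0:
            raise ValueError("coupling_delay_s must be nonnegative")
        k = self.coupling_delay_s * self.sampling_rate_hz
        if abs(k - round(k)) > 1e-9:
            raise ValueError("coupling_delay_s must be a multiple of 1/sampling_rate")
        if not self.condition_schedule:
            raise ValueError("condition_schedule must be non-empty")
        if self.coupling_delay_s >= min(d for _, d in self.condition_schedule):
            raise ValueError("coupling delay longer than a condition segment")
        if self.channel_labels is None:
            if self.n_channels < 1:
                raise ValueError("n_channels must be positive")
            from .io import reduced_montage

            self.channel_labels = tuple(reduced_montage(self.n_channels))
        else:
            self.channel_labels = tuple(self.channel_labels)
            self.n_channels = len(self.channel_labels)
        labset = set(self.channel_labels)
        if not (set(self.clusters.left_labels) <= labset
                and set(self.clusters.right_labels) <= labset):
            raise ValueError("every cluster channel must be in the montage")

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for _, d in self.condition_schedule))

    @property
    def schedule_samples(self) -> list[tuple[str, int, int]]:
        fs = self.sampling_rate_hz
        out, start = [], 0
        for label, dur in self.condition_schedule:
            n = int(round(dur * fs))
            out.append((label, start, n))
            start += n
        return out


@dataclass
class SynthDyad:
    """A generated dyad: two recordings plus the latent truth that made them."""

    recording_p1: RawRecording
    recording_p2: RawRecording
    latent_faa_p1: np.ndarray  # per-sample latent driver
    latent_faa_p2: np.ndarray
    truth: SynthConfig

    def latent_bins(self, partner: int) -> np.ndarray:
        """Bin-resolution latent driver (mean over each driver step)."""
        d = self.latent_faa_p1 if partner == 1 else self.latent_faa_p2
        step = int(round(self.truth.driver_step_s * self.truth.sampling_rate_hz))
        n = len(d) // step
        return d[: n * step].reshape(n, step).mean(axis=1)


def _ar1_driver(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-sample driver: AR(1) at driver_step_s, held constant within steps."""
    fs = cfg.sampling_rate_hz
    step = int(round(cfg.driver_step_s * fs))
    phi, sd = cfg.ar_coef, cfg.ar_innovation_sd
    stat_sd = sd / np.sqrt(1 - phi**2) if sd > 0 else 0.0
    pieces = []
    for label, dur in cfg.condition_schedule:
        n_samp = int(round(dur * fs))
        n_steps = int(np.ceil(n_samp / step))
        mu = cfg.condition_means.get(label, 0.0)
        x = np.empty(n_steps)
        x[0] = mu + rng.normal(0, stat_sd) if stat_sd else mu
        eps = rng.normal(0, sd, n_steps) if sd else np.zeros(n_steps)
        for t in range(1, n_steps):
            x[t] = mu + phi * (x[t - 1] - mu) + eps[t]
        pieces.append(np.repeat(x, step)[:n_samp])
    return np.concatenate(pieces)


def _delay_shift(x: np.ndarray, k: int) -> np.ndarray:
    """Shift right by k samples, edge-padding with the first value."""
    if k == 0:
        return x.copy()
    return np.concatenate([np.full(k, x[0]), x[:-k]])


def _render_partner(
    cfg: SynthConfig,
    driver: np.ndarray,
    rng_misc: np.random.Generator,
    rng_noise: np.random.Generator,
    rng_artifact: np.random.Generator,
    subject_id: str,
    dyad_id: str,
) -> RawRecording:
    fs = cfg.sampling_rate_hz
    n_times = len(driver)
    n_ch = cfg.n_channels
    t = np.arange(n_times) / fs

    phase = rng_misc.uniform(0, 2 * np.pi)
    gains = rng_misc.normal(1.0, 0.1, n_ch)
    alpha = np.sin(2 * np.pi * cfg.alpha_freq_hz * t + phase)

    left = set(cfg.clusters.left_labels)
    right = set(cfg.clusters.right_labels)
    amp = np.empty((n_ch, n_times))
    for i, lab in enumerate(cfg.channel_labels):
        if lab in left:
            amp[i] = cfg.alpha_amp_uv * np.exp(-driver / 2.0)
        elif lab in right:
            amp[i] = cfg.alpha_amp_uv * np.exp(+driver / 2.0)
        else:
            amp[i] = cfg.alpha_amp_uv * cfg.noncluster_alpha_frac

    background = rng_noise.normal(0, cfg.background_sd_uv, n_times)
    samples = amp * alpha[None, :] + gains[:, None] * background[None, :]
    samples += rng_noise.normal(0, cfg.noise_sd_uv, (n_ch, n_times))

    # artifact bursts: narrowband 20-40 Hz on all channels, amplitude set
    # so the burst's 20-40 Hz band power exceeds the background's by artifact_db
    n_bursts = rng_artifact.poisson(cfg.artifact_rate_per_min * n_times / fs / 60.0)
    if n_bursts:
        burst_len = int(round(cfg.artifact_duration_s * fs))
        # white-noise band power density in 20-40 Hz: var * bw / nyquist
        bg_var = cfg.background_sd_uv**2 + cfg.noise_sd_uv**2
        bg_band = bg_var * 20.0 / (fs / 2.0)
        burst_power = bg_band * 10 ** (cfg.artifact_db / 10.0)
        burst_amp = np.sqrt(2 * burst_power)
        for _ in range(n_bursts):
            start = rng_artifact.integers(0, max(1, n_times - burst_len))
            f = rng_artifact.uniform(22.0, 38.0)
            ph = rng_artifact.uniform(0, 2 * np.pi)
            tt = np.arange(burst_len) / fs
            # flat-top envelope: the burst holds its nominal band power over
            # its whole extent instead of fading at the edges
            from scipy.signal.windows import tukey

            window = tukey(burst_len, 0.2)
            samples[:, start : start + burst_len] += (
                burst_amp * window * np.sin(2 * np.pi * f * tt + ph)
            )[None, :]

    # bad channels: alternate flat / high-variance by list position
    for j, lab in enumerate(cfg.bad_channel_labels):
        if lab not in cfg.channel_labels:
            raise ValueError(f"bad channel {lab!r} not in montage")
        i = cfg.channel_labels.index(lab)
        if j % 2 == 0:
            samples[i] = 0.0
        else:
            samples[i] = rng_noise.normal(0, 10 * cfg.background_sd_uv, n_times)

    return RawRecording(
        samples=samples,
        channel_labels=list(cfg.channel_labels),
        sampling_rate_hz=fs,
        subject_id=subject_id,
        dyad_id=dyad_id,
        schedule=cfg.schedule_samples,
    )


def generate_dyad(config: SynthConfig, dyad_id: str = "dyad01") -> SynthDyad:
    """Generate a time-locked dyad of recordings with known latent coupling.

    Deterministic given ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(7)]
    (rng_d1, rng_d2, rng_misc, rng_n1, rng_n2, rng_a1, rng_a2) = streams

    d1 = _ar1_driver(config, rng_d1)
    indep = _ar1_driver(config, rng_d2)
    k = int(round(config.coupling_delay_s * config.sampling_rate_hz))
    c = config.coupling_strength
    d2 = c * _delay_shift(d1, k) + (1 - c) * indep

    rec1 = _render_partner(config, d1, rng_misc, rng_n1, rng_a1,
                           subject_id=f"{dyad_id}_p1", dyad_id=dyad_id)
    rec2 = _render_partner(config, d2, rng_misc, rng_n2, rng_a2,
                           subject_id=f"{dyad_id}_p2", dyad_id=dyad_id)
    return SynthDyad(rec1, rec2, d1, d2, config)


def generate_covariates(n_dyads: int, seed: int = 0) -> pd.DataFrame:
    """Per-subject individual-difference table, two rows per dyad.

    Survey-style constructs (perceived love, loving/negative/positive
    feelings, wellbeing) are bounded in [1, 10]; time variables are in
    hours.  Partners share a dyad-level component so that within-dyad
    scores correlate, as questionnaire data from couples do.
    """
    if n_dyads < 1:
        raise ValueError("n_dyads must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for d in range(1, n_dyads + 1):
        rel_years = rng.uniform(1, 20)
        shared = rng.normal(0, 0.7)
        for p in (1, 2):
            def survey(mu, sd=1.0):
                return float(np.clip(mu + shared + rng.normal(0, sd), 1, 10))

            rows.append(
                {
                    "dyad_id": f"dyad{d:02d}",
                    "subject_id": f"dyad{d:02d}_p{p}",
                    "age_years": float(np.clip(rng.normal(28, 5), 18, 40)),
                    "relationship_duration_years": rel_years,
                    "weekday_time_hours": float(np.clip(rng.normal(41, 19), 5, 100)),
                    "weekend_time_hours": float(np.clip(rng.normal(76, 19), 5, 100)),
                    "perceived_love": survey(9.0, 0.8),
                    "wellbeing": survey(6.7, 1.2),
                    "weekly_perceived_love": survey(8.3, 1.2),
                    "weekly_loving_feelings": survey(7.1, 1.4),
                    "weekly_negative_feelings": survey(1.9, 0.6),
                    "weekly_positive_feelings": survey(6.9, 1.6),
                    "weekly_wellbeing": survey(6.1, 0.9),
                    "weekly_shared_time_hours": float(np.clip(rng.normal(5.8, 2.3), 0.5, 16)),
                    "weekly_communication_time_hours": float(np.clip(rng.normal(5.5, 3.6), 0.5, 20)),
                }
            )
    return pd.DataFrame(rows)


def write_dyad(dyad: SynthDyad, outdir) -> dict:
    """Write a dyad to disk: EDF per partner, schedule CSV, JSON sidecar.

    The sidecar carries the generating config and the bin-resolution
    latent drivers (the scale at which recovery is assessed).
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    did = dyad.recording_p1.dyad_id
    p1 = outdir / f"{did}_p1.edf"
    p2 = outdir / f"{did}_p2.edf"
    write_edf(p1, dyad.recording_p1)
    write_edf(p2, dyad.recording_p2)
    sched = outdir / f"{did}_schedule.csv"
    rows, start = [], 0.0
    for label, dur in dyad.truth.condition_schedule:
        rows.append((label, start, dur))
        start += dur
    write_schedule(sched, rows)
    cfg = asdict(dyad.truth)
    cfg["clusters"] = {
        "left_labels": list(dyad.truth.clusters.left_labels),
        "right_labels": list(dyad.truth.clusters.right_labels),
    }
    sidecar = outdir / f"{did}_truth.json"
    write_sidecar(
        sidecar,
        {
            "config": cfg,
            "latent_bins_p1": dyad.latent_bins(1),
            "latent_bins_p2": dyad.latent_bins(2),
        },
    )
    return {"edf_p1": p1, "edf_p2": p2, "schedule": sched, "truth": sidecar}
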