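"""Ground-truth-bearing simulators for every input the pipeline consumes.

Three generators:

* :func:`simulate_culture` — per-neuron calcium recordings across sessions.
  Each neuron fires as a Poisson process whose rate is modulated over 24 h
  (``rate(t) = baseline × (1 + amplitude·cos(2π(t−φ)/period))``) with a
  per-neuron phase φ drawn around ``phase_mean_h`` (partial desynchronization
  of the culture).  Events are turned into indicator fluorescence by an
  exponential-decay ΔF/F0 kernel, scaled to a baseline and given Gaussian
  read noise.  A TTX condition scales the event rate by ``epsilon_ttx``.
* :func:`simulate_reporter` — a destabilized GFP driven by a 24 h-modulated
  promoter; first-order decay with 2 h half-life, solved in closed form.
* :func:`simulate_micrograph` — two-channel puncta images: marker and signal
  spots at shared, minimum-separated centers, with condition-dependent signal
  scaling (active / TTX-silenced / knockdown) and Poisson + read noise.

All draws come from one seeded generator per simulation; per-neuron and
per-image sub-streams are spawned deterministically so outputs are bitwise
reproducible for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .traces import TraceRecording

__all__ = [
    "CultureSimConfig",
    "ReporterSimConfig",
    "ImageSimConfig",
    "simulate_culture",
    "simulate_reporter",
    "reporter_solution",
    "simulate_micrograph",
]


# ---------------------------------------------------------------------------
# calcium culture


@dataclass
class CultureSimConfig:
    """Study-condition defaults: 156 neurons imaged 45 s at 10 Hz every 4 h
    over 64 h, 24 h rate modulation of amplitude 0.6 peaking at 14 h clock
    time, 1 h phase jitter across neurons.  The 0.1 Hz baseline event rate
    (≈4.5 transients per 45 s recording) keeps transients sparse relative to
    the 1 s indicator decay, so the trace's own MAD remains a noise estimate
    and the activity score responds near-linearly to the firing rate."""

    n_neurons: int = 156
    session_times_h: Sequence[float] = tuple(range(0, 68, 4))
    recording_duration_s: float = 45.0
    sampling_rate_hz: float = 10.0
    baseline_rate_hz: float = 0.1
    rhythm_amplitude: float = 0.6
    period_h: float = 24.0
    phase_mean_h: float = 14.0
    phase_jitter_sd_h: float = 1.0
    indicator_tau_s: float = 1.0
    transient_amplitude_dff: float = 1.0
    noise_sd_dff: float = 0.05
    f_baseline_au: float = 100.0
    ttx: bool = False
    epsilon_ttx: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.rhythm_amplitude <= 1:
            raise ValueError("rhythm_amplitude must be in [0, 1]")
        if self.period_h <= 0 or self.baseline_rate_hz < 0 or self.sampling_rate_hz <= 0:
            raise ValueError("rates and period must be positive")


def _modulated_rate(cfg: CultureSimConfig, phase_h: float, t_h: float) -> float:
    r = cfg.baseline_rate_hz * (
        1.0 + cfg.rhythm_amplitude * math.cos(2 * math.pi * (t_h - phase_h) / cfg.period_h)
    )
    if cfg.ttx:
        r *= cfg.epsilon_ttx
    return max(r, 0.0)


def simulate_culture(config: CultureSimConfig) -> tuple[list[TraceRecording], pd.DataFrame]:
    """Simulate one culture; returns recordings plus a ground-truth table
    (neuron, session, phase, true rate, event count)."""
    rng_streams = np.random.SeedSequence(config.seed).spawn(config.n_neurons)
    n_frames = int(round(config.sampling_rate_hz * config.recording_duration_s))
    dt = 1.0 / config.sampling_rate_hz
    decay = math.exp(-dt / config.indicator_tau_s)
    recordings: list[TraceRecording] = []
    truth_rows = []
    for i, ss in enumerate(rng_streams):
        rng = np.random.default_rng(ss)
        phase = rng.normal(config.phase_mean_h, config.phase_jitter_sd_h)
        nid = f"n{i:04d}"
        for t_h in config.session_times_h:
            rate = _modulated_rate(config, phase, float(t_h))
            n_events = rng.poisson(rate * config.recording_duration_s)
            event_times = np.sort(rng.uniform(0, config.recording_duration_s, n_events))
            spikes = np.zeros(n_frames)
            if n_events:
                idx = np.minimum((event_times / dt).astype(int), n_frames - 1)
                np.add.at(spikes, idx, config.transient_amplitude_dff)
            # exponential indicator kernel: one-pole IIR filter over the spike train
            dff = lfilter([1.0], [1.0, -decay], spikes)
            raw = config.f_baseline_au * (1.0 + dff) + rng.normal(
                0.0, config.noise_sd_dff * config.f_baseline_au, n_frames
            )
            raw = np.clip(raw, 1e-6, None)  # raw fluorescence stays positive
            recordings.append(
                TraceRecording(
                    neuron_id=nid,
                    session_time_h=float(t_h),
                    clock_time_h=float(t_h) % 24.0,
                    sampling_rate_hz=config.sampling_rate_hz,
                    values=raw,
                    duration_s=config.recording_duration_s,
                )
            )
            truth_rows.append(
                {
                    "neuron_id": nid,
                    "session_time_h": float(t_h),
                    "phase_h": phase,
                    "rate_hz": rate,
                    "n_events": int(n_events),
                }
            )
    return recordings, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# destabilized reporter


def promoter_phase_for_reporter_peak(
    peak_h: float, half_life_h: float = 2.0, period_h: float = 24.0
) -> float:
    """Promoter phase that places the steady-state reporter peak at ``peak_h``.

    The reporter lags its promoter by atan(ω/k)/ω hours (ω = 2π/period,
    k = ln2/half_life); for a 2 h half-life and 24 h period that is ≈2.5 h.
    """
    k = math.log(2) / half_life_h
    w = 2 * math.pi / period_h
    return (peak_h - math.atan2(w, k) / w) % period_h


@dataclass
class ReporterSimConfig:
    """Destabilized-GFP reporter: dG/dt = P(t) − kG, k = ln2 / half_life.

    The promoter drive is P(t) = mean + amplitude·cos(2π(t − phase)/24).
    The default phase places the *reporter* peak at 2 h clock time — exactly
    anti-phase to the default 14 h activity peak — by backing the promoter
    off by the ≈2.5 h phase lag the first-order decay imposes
    (see :func:`promoter_phase_for_reporter_peak`).
    """

    half_life_h: float = 2.0
    promoter_mean: float = 1.0
    promoter_amplitude: float = 0.6
    promoter_phase_h: float = promoter_phase_for_reporter_peak(2.0, 2.0, 24.0)
    period_h: float = 24.0
    sampling_times_h: Sequence[float] = tuple(range(0, 28, 4))
    noise_sd: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError("half_life_h must be positive")
        if self.promoter_amplitude > self.promoter_mean:
            raise ValueError("promoter drive must stay non-negative")

    @property
    def k_per_h(self) -> float:
        return math.log(2) / self.half_life_h


def reporter_solution(
    times_h,
    cfg: ReporterSimConfig,
    g0: float | None = None,
) -> np.ndarray:
    """Closed-form reporter level G(t).

    The periodic particular solution of dG/dt = P − kG with sinusoidal P is
    G_p(t) = mean/k + amplitude/√(k² + ω²) · cos(ω(t − phase) − ψ) with
    ψ = atan(ω/k) — the oscillation is attenuated by 1/√(k² + ω²) and lags
    the promoter by ψ/ω hours.  With ``g0`` given, the transient
    (g0 − G_p(0))·e^{−kt} is added; by default the system starts on the
    periodic orbit.
    """
    t = np.asarray(times_h, dtype=float)
    k = cfg.k_per_h
    w = 2 * math.pi / cfg.period_h
    amp = cfg.promoter_amplitude / math.sqrt(k**2 + w**2)
    lag = math.atan2(w, k)
    gp = cfg.promoter_mean / k + amp * np.cos(w * (t - cfg.promoter_phase_h) - lag)
    if g0 is None:
        return gp
    gp0 = cfg.promoter_mean / k + amp * math.cos(w * (0.0 - cfg.promoter_phase_h) - lag)
    return gp + (g0 - gp0) * np.exp(-k * t)


def simulate_reporter(
    config: ReporterSimConfig, g0: float | None = None
) -> tuple[pd.DataFrame, dict]:
    """Sample the analytic reporter at the configured times, plus noise.

    Returns (table with times_h / g_true / g_observed, ground-truth dict with
    the oscillation mean, amplitude and peak time).
    """
    t = np.asarray(config.sampling_times_h, dtype=float)
    g_true = reporter_solution(t, config, g0=g0)
    rng = np.random.default_rng(config.seed)
    g_obs = g_true + rng.normal(0.0, config.noise_sd, t.size)
    k = config.k_per_h
    w = 2 * math.pi / config.period_h
    truth = {
        "mean": config.promoter_mean / k,
        "amplitude": config.promoter_amplitude / math.sqrt(k**2 + w**2),
        "peak_time_h": (config.promoter_phase_h + math.atan2(w, k) / w) % config.period_h,
        "k_per_h": k,
    }
    table = pd.DataFrame({"time_h": t, "g_true": g_true, "g_observed": g_obs})
    return table, truth


# ---------------------------------------------------------------------------
# puncta micrographs

CONDITION_SCALES = {"active": "active", "ttx": "ttx_scale", "kd": "kd_scale"}


@dataclass
class ImageSimConfig:
    """Two-channel synaptic puncta image generator.

    Marker and signal spots share centers (synapses); the signal amplitude is
    multiplied by a condition factor: active 1×, TTX ``ttx_scale`` (silenced
    uptake), knockdown ``kd_scale``.  Poisson shot noise plus Gaussian read
    noise on both channels.
    """

    image_shape_px: tuple[int, int] = (256, 256)
    pixel_size_nm: float = 100.0
    n_puncta: int = 30
    spot_sigma_nm: float = 150.0
    marker_intensity_mean: float = 600.0
    marker_intensity_sd: float = 120.0
    signal_intensity_mean: float = 400.0
    signal_intensity_sd: float = 80.0
    ttx_scale: float = 0.3
    kd_scale: float = 1.5
    background_level: float = 100.0
    poisson_noise: bool = True
    gaussian_read_noise_sd: float = 3.0
    min_separation_px: float = 6.0
    edge_margin_px: int = 6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_puncta < 0:
            raise ValueError("n_puncta must be >= 0")
        if min(self.ttx_scale, self.kd_scale) < 0:
            raise ValueError("condition scales must be >= 0")


def _draw_centers(cfg: ImageSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Uniform random centers with a minimum pairwise separation."""
    h, w = cfg.image_shape_px
    m = cfg.edge_margin_px
    centers: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = 1000 * max(cfg.n_puncta, 1)
    while len(centers) < cfg.n_puncta:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {cfg.n_puncta} puncta with separation "
                f"{cfg.min_separation_px} px in {cfg.image_shape_px}"
            )
        attempts += 1
        cand = (rng.uniform(m, h - 1 - m), rng.uniform(m, w - 1 - m))
        if all(
            (cand[0] - c[0]) ** 2 + (cand[1] - c[1]) ** 2 >= cfg.min_separation_px**2
            for c in centers
        ):
            centers.append(cand)
    return np.array(centers).reshape(-1, 2)


def _render_spots(
    shape: tuple[int, int], centers: np.ndarray, amplitudes: np.ndarray, sigma_px: float
) -> np.ndarray:
    img = np.zeros(shape)
    half = int(math.ceil(4 * sigma_px))
    for (cy, cx), amp in zip(centers, amplitudes):
        y0, y1 = int(cy) - half, int(cy) + half + 1
        x0, x1 = int(cx) - half, int(cx) + half + 1
        y0c, x0c = max(y0, 0), max(x0, 0)
        y1c, x1c = min(y1, shape[0]), min(x1, shape[1])
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
        img[y0c:y1c, x0c:x1c] += amp * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma_px**2)
        )
    return img


def simulate_micrograph(config: ImageSimConfig, condition: str = "active"):
    """Render one two-channel image for the given condition.

    Returns (:class:`~neurorhythm.puncta.MicrographStack`, ground-truth table
    of spot centers and noiseless amplitudes).
    """
    from .puncta import MicrographStack

    if condition not in CONDITION_SCALES:
        raise ValueError(f"condition must be one of {sorted(CONDITION_SCALES)}")
    scale = {"active": 1.0, "ttx": config.ttx_scale, "kd": config.kd_scale}[condition]
    rng = np.random.default_rng(config.seed)
    centers = _draw_centers(config, rng)
    marker_amp = np.clip(
        rng.normal(config.marker_intensity_mean, config.marker_intensity_sd, config.n_puncta),
        config.marker_intensity_mean * 0.2,
        None,
    )
    signal_amp = (
        np.clip(
            rng.normal(config.signal_intensity_mean, config.signal_intensity_sd, config.n_puncta),
            config.signal_intensity_mean * 0.2,
            None,
        )
        * scale
    )
    sigma_px = config.spot_sigma_nm / config.pixel_size_nm
    marker = config.background_level + _render_spots(
        config.image_shape_px, centers, marker_amp, sigma_px
    )
    signal = config.background_level + _render_spots(
        config.image_shape_px, centers, signal_amp, sigma_px
    )
    channels = {}
    for name, clean in (("marker", marker), ("signal", signal)):
        img = rng.poisson(clean).astype(float) if config.poisson_noise else clean.copy()
        if config.gaussian_read_noise_sd > 0:
            img = img + rng.normal(0.0, config.gaussian_read_noise_sd, clean.shape)
        channels[name] = np.clip(img, 0.0, None)
    stack = MicrographStack(
        channels=channels,
        pixel_size_nm=config.pixel_size_nm,
        image_id=f"{condition}_sim",
        condition={"condition": condition},
    )
    truth = pd.DataFrame(
        {
            "y_px": centers[:, 0] if config.n_puncta else np.array([]),
            "x_px": centers[:, 1] if config.n_puncta else np.array([]),
            "marker_amplitude": marker_amp,
            "signal_amplitude": signal_amp,
        }
    )
    return stack, truth
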