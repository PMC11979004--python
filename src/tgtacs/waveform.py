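"""Theta-gamma tACS waveform synthesis and validation metrics.

The active stimulus is a 6 Hz theta carrier with 80 Hz gamma bursts
phase-amplitude coupled to the theta peaks: a continuous gamma sinusoid
gated on during the positive theta half-cycle, the composite rescaled so
the plateau peak-to-peak current is exactly 2 mA, with linear fade-in/out
ramps (15 s each) at the ends of the 20-minute stimulation.

The sham protocol mimics the skin sensation of real stimulation without
sustained neuromodulation: two 90 s active phases (15 s ramp up, 60 s
plateau, 15 s ramp down) at the start and end, with a low-amplitude
85 Hz / 50 uA impedance-control current in between.

Validation metrics (peak-to-peak, periodogram peaks, Tort modulation
index of the theta-phase-binned gamma envelope) let tests and the
acceptance pipeline confirm each published property of the stimulus from
the sampled signal itself rather than from the construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "WaveformConfig",
    "ShamConfig",
    "Waveform",
    "WaveformMetrics",
    "generate_active",
    "generate_sham",
    "measure_waveform",
]


@dataclass(frozen=True)
class WaveformConfig:
    """Parameters of the active theta-gamma composite.

    ``amp_ratio`` is the theta:gamma amplitude ratio before the composite
    is rescaled to ``pp_amplitude``; the published protocol fixes only the
    composite peak-to-peak, so the split is exposed here.  ``gate_threshold``
    sets where on the theta cycle the gamma gate opens (gate is on where
    sin(theta phase) exceeds it; 0 gives the full positive half-cycle).
    """

    theta_freq: float = 6.0
    gamma_freq: float = 80.0
    pp_amplitude: float = 2.0          # mA peak-to-peak on the plateau
    duration: float = 1200.0           # s
    fade: float = 15.0                 # s, each of fade-in and fade-out
    sample_rate: float = 10_000.0      # samples/s
    coupling: str = "peak"             # "peak" or "trough"
    gate_threshold: float = 0.0
    amp_ratio: float = 1.0             # theta amplitude / gamma amplitude
    fade_shape: str = "linear"         # "linear" or "raised_cosine"

    def __post_init__(self) -> None:
        if not (self.gamma_freq > self.theta_freq > 0):
            raise ValueError("need gamma_freq > theta_freq > 0")
        if 2 * self.fade >= self.duration:
            raise ValueError("fades leave no plateau: need 2*fade < duration")
        if self.sample_rate < 10 * self.gamma_freq:
            raise ValueError("sample_rate must be >= 10x gamma_freq")
        if self.coupling not in ("peak", "trough"):
            raise ValueError(f"unknown coupling {self.coupling!r}")
        if self.fade_shape not in ("linear", "raised_cosine"):
            raise ValueError(f"unknown fade shape {self.fade_shape!r}")
        if self.pp_amplitude <= 0 or self.duration <= 0:
            raise ValueError("pp_amplitude and duration must be positive")


@dataclass(frozen=True)
class ShamConfig:
    """Parameters of the modified sham protocol.

    Two active theta-gamma phases of ``active_phase`` seconds each
    bracket an interim low-intensity sinusoid used for impedance control.
    """

    active_phase: float = 90.0         # s per active phase, fades included
    interim_freq: float = 85.0         # Hz
    interim_pp: float = 0.05           # mA peak-to-peak (50 uA)
    active: WaveformConfig = field(default_factory=WaveformConfig)

    def __post_init__(self) -> None:
        if 2 * self.active_phase >= self.active.duration:
            raise ValueError("active phases overlap: 2*active_phase must be < duration")
        if self.interim_pp >= self.active.pp_amplitude:
            raise ValueError("interim amplitude must be below the active amplitude")
        if self.active_phase <= 2 * self.active.fade:
            raise ValueError("active phase shorter than its fades")


@dataclass
class Waveform:
    """Sampled stimulation current with labelled time segments.

    ``segments`` maps a label (fade_in, plateau, fade_out, interim, ...) to
    a (start_s, end_s) interval; the intervals partition [0, duration].
    """

    samples: np.ndarray                # current in mA
    sample_rate: float
    segments: dict[str, tuple[float, float]]

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    def segment_samples(self, label: str) -> np.ndarray:
        if label not in self.segments:
            raise KeyError(f"no segment {label!r}; have {sorted(self.segments)}")
        t0, t1 = self.segments[label]
        i0 = int(round(t0 * self.sample_rate))
        i1 = int(round(t1 * self.sample_rate))
        return self.samples[i0:i1]

    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate

    def to_csv(self, path, stride: int = 1) -> None:
        """Write (time_s, current_mA) columns plus a JSON segment sidecar."""
        import pandas as pd

        t = self.times()[::stride]
        pd.DataFrame({"time_s": t, "current_mA": self.samples[::stride]}).to_csv(
            path, index=False
        )
        with open(str(path) + ".segments.json", "w") as fh:
            json.dump({k: list(v) for k, v in self.segments.items()}, fh, indent=1)


@dataclass(frozen=True)
class WaveformMetrics:
    pp: float                     # mA, max - min on the segment
    dominant_freq_low: float      # Hz, periodogram peak in [0.5, 40]
    dominant_freq_high: float     # Hz, periodogram peak in [40, 120]
    pac_mi: float                 # Tort modulation index in [0, 1]
    preferred_phase: float        # envelope-weighted circular mean theta phase
    preferred_phase_bin: tuple[float, float]  # phase bin containing preferred_phase


def _fade_envelope(n: int, n_fade: int, shape: str) -> np.ndarray:
    env = np.ones(n)
    if n_fade == 0:
        return env
    if shape == "linear":
        ramp = np.linspace(0.0, 1.0, n_fade, endpoint=False)
    else:  # raised cosine
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_fade) / n_fade))
    env[:n_fade] = ramp
    env[-n_fade:] = ramp[::-1]
    return env


def _composite(cfg: WaveformConfig, t: np.ndarray) -> np.ndarray:
    """Unit-scale theta-gamma composite before peak-to-peak normalisation."""
    theta_phase = 2 * np.pi * cfg.theta_freq * t
    theta = np.sin(theta_phase)
    if cfg.coupling == "peak":
        gate = (theta > cfg.gate_threshold).astype(float)
    else:
        gate = (theta < -cfg.gate_threshold).astype(float)
    a_theta = cfg.amp_ratio / (1.0 + cfg.amp_ratio)
    a_gamma = 1.0 / (1.0 + cfg.amp_ratio)
    return a_theta * theta + a_gamma * gate * np.sin(2 * np.pi * cfg.gamma_freq * t)


def generate_active(config: WaveformConfig | None = None) -> Waveform:
    """Synthesise the active theta-gamma waveform.

    The composite is rescaled so the plateau (between the fades) has
    peak-to-peak current exactly ``pp_amplitude``; fades are applied
    afterwards, so they only attenuate.  Deterministic: identical configs
    give identical arrays.
    """
    cfg = config or WaveformConfig()
    n = int(round(cfg.duration * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    raw = _composite(cfg, t)

    n_fade = int(round(cfg.fade * cfg.sample_rate))
    plateau = raw[n_fade : n - n_fade] if n_fade else raw
    pp_raw = float(plateau.max() - plateau.min())
    if pp_raw == 0:
        raise ValueError("degenerate composite: zero peak-to-peak")
    samples = raw * (cfg.pp_amplitude / pp_raw)
    samples *= _fade_envelope(n, n_fade, cfg.fade_shape)

    segments = {
        "fade_in": (0.0, cfg.fade),
        "plateau": (cfg.fade, cfg.duration - cfg.fade),
        "fade_out": (cfg.duration - cfg.fade, cfg.duration),
    }
    return Waveform(samples=samples, sample_rate=cfg.sample_rate, segments=segments)


def generate_sham(config: ShamConfig | None = None) -> Waveform:
    """Synthesise the modified sham waveform.

    Layout: active phase (fade in / plateau / fade out), interim 85 Hz
    low-amplitude sinusoid, active phase again; total duration equals the
    active config's duration.
    """
    cfg = config or ShamConfig()
    acfg = cfg.active
    sr = acfg.sample_rate
    total = acfg.duration
    n = int(round(total * sr))
    t = np.arange(n) / sr

    phase_cfg = WaveformConfig(
        theta_freq=acfg.theta_freq,
        gamma_freq=acfg.gamma_freq,
        pp_amplitude=acfg.pp_amplitude,
        duration=cfg.active_phase,
        fade=acfg.fade,
        sample_rate=sr,
        coupling=acfg.coupling,
        gate_threshold=acfg.gate_threshold,
        amp_ratio=acfg.amp_ratio,
        fade_shape=acfg.fade_shape,
    )
    active = generate_active(phase_cfg).samples
    n_phase = len(active)

    samples = 0.5 * cfg.interim_pp * np.sin(2 * np.pi * cfg.interim_freq * t)
    samples[:n_phase] = active
    samples[n - n_phase :] = active

    a, f = cfg.active_phase, acfg.fade
    segments = {
        "fade_in": (0.0, f),
        "active_1": (f, a - f),
        "fade_out_1": (a - f, a),
        "interim": (a, total - a),
        "fade_in_2": (total - a, total - a + f),
        "active_2": (total - a + f, total - f),
        "fade_out": (total - f, total),
    }
    return Waveform(samples=samples, sample_rate=sr, segments=segments)


def _band_peak(freqs: np.ndarray, power: np.ndarray, lo: float, hi: float) -> float:
    band = (freqs >= lo) & (freqs <= hi)
    if not band.any():
        return float("nan")
    f, p = freqs[band], power[band]
    return float(f[np.argmax(p)])


def tort_mi(x: np.ndarray, sample_rate: float, phase_freq: float,
            amp_band: tuple[float, float], n_bins: int = 18
            ) -> tuple[float, float, tuple[float, float]]:
    """Tort modulation index of phase-amplitude coupling.

    Band-passes ``x`` around ``phase_freq`` for phase and in ``amp_band``
    for amplitude (4th-order Butterworth, zero-phase), bins the Hilbert
    amplitude envelope by phase into ``n_bins`` bins, and returns the
    normalised-entropy MI, the envelope-weighted circular-mean phase
    (robust against ripple on a flat-topped burst envelope, unlike a
    per-bin argmax), and the phase bin containing it.

    Phase convention matches the sin() parameterisation of the
    generator: the carrier peak sits at +pi/2, the trough at -pi/2.
    """
    nyq = sample_rate / 2
    # SOS form: (b, a) Butterworth is ill-conditioned for cutoffs this far below Nyquist
    sos = sps.butter(4, [phase_freq * 0.5 / nyq, phase_freq * 2.0 / nyq],
                     "bandpass", output="sos")
    theta = sps.sosfiltfilt(sos, x)
    sos = sps.butter(4, [amp_band[0] / nyq, amp_band[1] / nyq], "bandpass", output="sos")
    gamma = sps.sosfiltfilt(sos, x)

    # cos-convention analytic phase (peak at 0) shifted to sin convention (peak at pi/2)
    phase = np.angle(sps.hilbert(theta)) + np.pi / 2
    phase = np.angle(np.exp(1j * phase))  # wrap to (-pi, pi]
    env = np.abs(sps.hilbert(gamma))

    # MI is scale-invariant, so phase-locked filter leakage in an empty
    # amplitude band would otherwise masquerade as coupling: require the
    # amplitude band to carry a non-negligible share of signal power
    freqs, power = sps.periodogram(x, fs=sample_rate)
    total_power = float(power.sum())
    in_band = (freqs >= amp_band[0]) & (freqs <= amp_band[1])
    if total_power == 0 or power[in_band].sum() < 1e-6 * total_power:
        edges = np.linspace(-np.pi, np.pi, n_bins + 1)
        return 0.0, 0.0, (float(edges[0]), float(edges[1]))

    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    mean_env = np.array([env[idx == k].mean() if (idx == k).any() else 0.0
                         for k in range(n_bins)])
    total = mean_env.sum()
    if total <= 0:
        return 0.0, 0.0, (float(edges[0]), float(edges[1]))
    p = mean_env / total
    nz = p[p > 0]
    entropy = -(nz * np.log(nz)).sum()
    mi = (np.log(n_bins) - entropy) / np.log(n_bins)
    pref = float(np.angle(np.sum(env * np.exp(1j * phase))))
    k = int(np.clip(np.digitize(pref, edges) - 1, 0, n_bins - 1))
    return float(mi), pref, (float(edges[k]), float(edges[k + 1]))


def measure_waveform(w: Waveform, segment: str = "plateau",
                     theta_freq: float = 6.0, gamma_freq: float = 80.0,
                     pac_window_s: float = 30.0) -> WaveformMetrics:
    """Validation metrics of one labelled segment of a waveform.

    Peak-to-peak is max - min over the whole segment; dominant
    frequencies are periodogram argmax in the 0.5-40 Hz and 40-120 Hz
    bands; the PAC modulation index is computed on at most
    ``pac_window_s`` seconds (centred) to keep the Hilbert transforms
    cheap on long recordings.
    """
    x = w.segment_samples(segment)
    min_len = 2.0 / theta_freq
    if len(x) / w.sample_rate < max(2.0, min_len):
        raise ValueError(f"segment {segment!r} too short to measure")
    pp = float(x.max() - x.min())

    freqs, power = sps.periodogram(x, fs=w.sample_rate)
    f_low = _band_peak(freqs, power, 0.5, 40.0)
    f_high = _band_peak(freqs, power, 40.0, 120.0)

    n_win = min(len(x), int(pac_window_s * w.sample_rate))
    start = (len(x) - n_win) // 2
    mi, pref, phase_bin = tort_mi(
        x[start : start + n_win],
        w.sample_rate,
        phase_freq=theta_freq,
        amp_band=(gamma_freq * 0.75, min(gamma_freq * 1.25, w.sample_rate / 2 * 0.95)),
    )
    return WaveformMetrics(
        pp=pp,
        dominant_freq_low=f_low,
        dominant_freq_high=f_high,
        pac_mi=mi,
        preferred_phase=pref,
        preferred_phase_bin=phase_bin,
    )
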