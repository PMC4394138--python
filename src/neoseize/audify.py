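"""Algorithm-driven audification of neonatal EEG.

The 32 Hz EEG is time-stretched by a factor of 100 with a phase vocoder —
the spectrogram's time base is stretched while short-time spectral content is
preserved — and the result is written at 32 kHz. The combination maps the
0.5–13 Hz EEG band to 0.5–13 kHz audio (dominant seizure rhythms of 0.5–6 Hz
land in the highly audible 0.5–6 kHz range) and plays one hour of EEG in
roughly six minutes (stretch x100, playback x1000 ⇒ net speed-up x10).

The rendering is stereo: one channel per brain hemisphere, each hemisphere
represented by the bipolar channel with the highest cumulative seizure
probability over the rendered segment. The sample gain is modulated by the
detector's probability so suspicious segments are accentuated while the
background stays audible: ``gain(t) = floor + (1 - floor) * p(t)`` with the
probability linearly interpolated from the 4 s epoch grid.

Phase-vocoder defaults: 64-sample (2 s) Hann analysis window, 16-sample hop,
75% overlap, standard phase-propagation resynthesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import EEGRecording
from .detector import ProbabilityTrace

__all__ = [
    "AudificationConfig",
    "AudioRendering",
    "phase_vocoder_stretch",
    "select_hemisphere_channels",
    "render_stereo",
    "DEFAULT_HEMISPHERES",
]

#: Hemisphere assignment of the default bipolar montage. Midline-involving
#: derivations (C4-Cz, Cz-C3) follow their lateral electrode.
DEFAULT_HEMISPHERES: dict[str, str] = {
    "F4-C4": "right",
    "C4-O2": "right",
    "T4-C4": "right",
    "C4-Cz": "right",
    "F3-C3": "left",
    "C3-O1": "left",
    "Cz-C3": "left",
    "C3-T3": "left",
}


@dataclass
class AudificationConfig:
    stretch_factor: float = 100.0
    output_rate_hz: int = 32000
    window: int = 64
    hop: int = 16
    gain_floor: float = 0.2
    hemisphere_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_HEMISPHERES)
    )
    use_fused_gain: bool = False
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.stretch_factor < 1:
            raise ValueError("stretch_factor must be >= 1")
        if not 0.0 <= self.gain_floor <= 1.0:
            raise ValueError("gain_floor must lie in [0, 1]")


@dataclass
class AudioRendering:
    """Stereo audio in [-1, 1] at ``rate_hz`` (frames x 2)."""

    samples: np.ndarray
    rate_hz: int
    left_label: str
    right_label: str

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.rate_hz


def phase_vocoder_stretch(
    x: np.ndarray,
    factor: float,
    window: int = 64,
    hop: int = 16,
) -> np.ndarray:
    """Time-stretch a mono signal by ``factor`` with a phase vocoder.

    STFT analysis at ``hop``; output frames are resynthesized at the same hop
    but read the analysis spectrogram at 1/factor speed — magnitudes linearly
    interpolated between frames, phases advanced by the locally estimated
    instantaneous frequency. Output length is exactly
    ``round(len(x) * factor)`` samples.
    """
    x = np.asarray(x, dtype=float)
    if x.size < window:
        raise ValueError(f"input ({x.size} samples) shorter than one {window}-sample window")

    win = np.hanning(window + 1)[:-1]  # periodic Hann
    n_frames = 1 + (x.size - window) // hop
    frames = np.lib.stride_tricks.sliding_window_view(x, window)[::hop][:n_frames]
    S = np.fft.rfft(frames * win, axis=1).astype(np.complex64)  # n_frames x bins

    omega = 2.0 * np.pi * np.arange(window // 2 + 1) * hop / window
    phase = np.angle(S)
    dphi = np.diff(phase, axis=0) - omega
    dphi = (dphi + np.pi) % (2.0 * np.pi) - np.pi
    advance = (dphi + omega).astype(np.float32)  # true phase advance per hop

    target_len = int(round(x.size * factor))
    n_out = max(1, int(np.ceil((target_len - window) / hop)) + 1)
    pos = np.arange(n_out, dtype=np.float64) / factor  # analysis frame position
    pos = np.minimum(pos, n_frames - 1 - 1e-9)
    i0 = np.floor(pos).astype(int)
    frac = (pos - i0).astype(np.float32)

    mag = np.abs(S)
    mag_out = mag[i0] * (1.0 - frac[:, None]) + mag[np.minimum(i0 + 1, n_frames - 1)] * frac[:, None]

    adv_idx = np.minimum(i0, advance.shape[0] - 1) if advance.shape[0] else None
    if adv_idx is None:  # single analysis frame: advance by the bin frequency
        steps = np.broadcast_to(omega.astype(np.float32), (n_out, omega.size))
    else:
        steps = advance[adv_idx]
    phase_out = np.empty((n_out, omega.size), dtype=np.float32)
    phase_out[0] = phase[0]
    np.cumsum(steps[:-1], axis=0, out=phase_out[1:])
    phase_out[1:] += phase[0]

    frames_out = np.fft.irfft(mag_out * np.exp(1j * phase_out), n=window, axis=1)
    frames_out *= win

    out_len = window + (n_out - 1) * hop
    out = np.zeros(out_len, dtype=np.float64)
    env = np.zeros(out_len, dtype=np.float64)
    win_sq = win**2
    for j in range(window):
        out[j : j + n_out * hop : hop] += frames_out[:, j]
        env[j : j + n_out * hop : hop] += win_sq[j]
    out /= np.maximum(env, 1e-8 * env.max())

    if out.size >= target_len:
        return out[:target_len]
    return np.pad(out, (0, target_len - out.size))


def select_hemisphere_channels(
    trace: ProbabilityTrace,
    hemisphere_map: dict[str, str] | None = None,
) -> tuple[str, str]:
    """Pick, per hemisphere, the channel with the highest cumulative seizure
    probability (sum over the trace); ties break on channel order.

    Returns ``(left_label, right_label)``.
    """
    hemisphere_map = hemisphere_map or DEFAULT_HEMISPHERES
    best: dict[str, tuple[float, str]] = {}
    for i, label in enumerate(trace.channel_labels):
        side = hemisphere_map.get(label)
        if side is None:
            raise KeyError(f"channel {label!r} has no hemisphere assignment")
        total = float(np.sum(trace.per_channel[i]))
        if side not in best or total > best[side][0]:
            best[side] = (total, label)
    for side in ("left", "right"):
        if side not in best:
            raise ValueError(f"no channel assigned to the {side} hemisphere")
    return best["left"][1], best["right"][1]


def _gain_for_channel(
    trace: ProbabilityTrace,
    label: str,
    n_samples: int,
    sample_rate: float,
    config: AudificationConfig,
) -> np.ndarray:
    if config.use_fused_gain:
        p = trace.fused
    else:
        p = trace.per_channel[trace.channel_labels.index(label)]
    t = np.arange(n_samples) / sample_rate
    p_t = np.interp(t, trace.times_s, p)
    return config.gain_floor + (1.0 - config.gain_floor) * p_t


def render_stereo(
    rec: EEGRecording,
    trace: ProbabilityTrace | None,
    config: AudificationConfig | None = None,
) -> AudioRendering:
    """Audify a 32 Hz recording into stereo at the configured output rate.

    With a probability trace, one channel per hemisphere is selected by
    cumulative probability and gain-modulated before stretching; without one
    (``trace=None``) the first channel of each hemisphere is used at constant
    unit gain. Channels are stretched independently and peak-normalized
    jointly so no sample exceeds |1|.
    """
    config = config or AudificationConfig()
    if abs(rec.sample_rate_hz - 32.0) > 1e-6:
        raise ValueError("audification expects a 32 Hz recording; resample first")

    if trace is not None:
        left, right = select_hemisphere_channels(trace, config.hemisphere_map)
    else:
        def first(side: str) -> str:
            for lbl in rec.channel_labels:
                if config.hemisphere_map.get(lbl) == side:
                    return lbl
            raise ValueError(f"no channel assigned to the {side} hemisphere")

        left, right = first("left"), first("right")

    channels = []
    for label in (left, right):
        x = rec.channel(label).copy()
        if trace is not None:
            x *= _gain_for_channel(trace, label, x.size, rec.sample_rate_hz, config)
        stretched = phase_vocoder_stretch(
            x, config.stretch_factor, config.window, config.hop
        )
        channels.append(stretched)

    stereo = np.stack(channels, axis=1)
    if config.normalize:
        peak = np.max(np.abs(stereo))
        if peak > 0:
            stereo = stereo / peak
    return AudioRendering(
        samples=stereo,
        rate_hz=int(config.output_rate_hz),
        left_label=left,
        right_label=right,
    )
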