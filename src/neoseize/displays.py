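"""Clinical visualization transforms: aEEG, decision traces, colormap.

Three bedside views of the detector output are produced:

* **aEEG** — the amplitude-integrated EEG familiar to neonatal staff: the
  band-passed signal is rectified, smoothed with a moving average, and its
  per-display-step maximum and minimum peak-to-peak amplitudes are drawn on a
  semilogarithmic scale that is linear from 0 to 10 μV and logarithmic from
  10 to 100 μV.
* **binary / probabilistic traces** — the fused seizure probability plotted
  against time (blue below the decision threshold, red above), and the
  thresholded 0/1 decision trace.
* **spatio-temporal colormap** — a channels x epochs grid of per-channel
  probabilities quantized into 10 discrete diverging colours from cold blue
  (probability 0) through neutral white (0.5) to warm red (1), showing how a
  seizure evolves in space and time.

The semilog display map is ``d(x) = x`` for ``x <= 10`` and
``d(x) = 10 * (1 + log10(x/10))`` above — the unique continuous piecewise map
with unit slope on the linear segment and one decade (10–100 μV) occupying
the same display height. Values above 100 μV clip to the display ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

import matplotlib

matplotlib.use("Agg")  # headless rendering
import matplotlib.pyplot as plt
from matplotlib.colors import ListedColormap

from .core import EEGRecording
from .detector import DecisionTrace, ProbabilityTrace

__all__ = [
    "AEEGTrace",
    "ColormapGrid",
    "semilog_display",
    "compute_aeeg",
    "build_colormap",
    "probability_trace_segments",
    "render_probability_trace",
    "render_binary_trace",
    "render_colormap",
    "render_aeeg",
    "render_bundle",
    "COLOR_TABLE",
]

AEEG_BAND_HZ = (2.0, 15.0)
AEEG_SMOOTH_S = 0.5
AEEG_STEP_S = 15.0
DISPLAY_CEILING_UV = 100.0

#: 10-entry diverging blue-white-red table; bin 0 = coldest blue, bin 9 =
#: warmest red, bins 4/5 straddle the neutral 0.5 point.
COLOR_TABLE = [
    "#053061", "#2166ac", "#4393c3", "#92c5de", "#d1e5f0",
    "#fddbc7", "#f4a582", "#d6604d", "#b2182b", "#67001f",
]


@dataclass
class AEEGTrace:
    """Upper/lower aEEG envelopes (μV) and their semilog display values."""

    upper_uv: np.ndarray
    lower_uv: np.ndarray
    upper_display: np.ndarray
    lower_display: np.ndarray
    step_s: float
    channel: str


@dataclass
class ColormapGrid:
    """channels x epochs integer probability bins in {0..9}."""

    bins: np.ndarray
    bin_edges: np.ndarray
    colors: list[str]
    channel_labels: list[str]
    times_s: np.ndarray


def semilog_display(x) -> np.ndarray:
    """Map smoothed amplitude (μV) to aEEG display units.

    Linear below 10 μV, one log decade from 10 to 100 μV mapped onto the next
    10 display units; continuous with d(10) = 10 from both branches; input is
    clipped to the 100 μV ceiling (display 20).
    """
    x = np.clip(np.asarray(x, dtype=float), 0.0, DISPLAY_CEILING_UV)
    return np.where(x <= 10.0, x, 10.0 * (1.0 + np.log10(np.maximum(x, 10.0) / 10.0)))


def compute_aeeg(
    rec: EEGRecording,
    channel: str,
    band_hz: tuple[float, float] = AEEG_BAND_HZ,
    smooth_s: float = AEEG_SMOOTH_S,
    step_s: float = AEEG_STEP_S,
) -> AEEGTrace:
    """Band-pass, rectify, smooth, and envelope one channel into an aEEG trace."""
    x = rec.channel(channel)
    fs = rec.sample_rate_hz
    hi = min(band_hz[1], 0.45 * fs)
    sos = signal.butter(4, [band_hz[0], hi], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, x)
    rectified = np.abs(filtered)
    win = max(1, int(round(smooth_s * fs)))
    smoothed = np.convolve(rectified, np.ones(win) / win, mode="same")

    step = max(1, int(round(step_s * fs)))
    n_steps = max(1, len(smoothed) // step)
    trimmed = smoothed[: n_steps * step].reshape(n_steps, step)
    upper = trimmed.max(axis=1)
    lower = trimmed.min(axis=1)
    return AEEGTrace(
        upper_uv=upper,
        lower_uv=lower,
        upper_display=semilog_display(upper),
        lower_display=semilog_display(lower),
        step_s=step / fs,
        channel=channel,
    )


def build_colormap(trace: ProbabilityTrace) -> ColormapGrid:
    """Quantize per-channel probabilities into the 10 colour bins.

    ``bin = min(floor(10 p), 9)``: each bin covers 0.1 of probability, the
    top bin is right-closed so p = 1 lands in bin 9 and p = 0.5 in bin 5.
    """
    p = np.asarray(trace.per_channel, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    bins = np.minimum(np.floor(10.0 * p), 9.0).astype(int)
    return ColormapGrid(
        bins=bins,
        bin_edges=np.linspace(0.0, 1.0, 11),
        colors=list(COLOR_TABLE),
        channel_labels=list(trace.channel_labels),
        times_s=trace.times_s.copy(),
    )


def probability_trace_segments(trace: ProbabilityTrace, threshold: float):
    """Split the fused trace into maximal constant-colour runs.

    Returns a list of ``(colour, start_idx, end_idx)`` with half-open index
    ranges; 'red' where fused >= threshold, 'blue' below. This is the
    segmentation the renderer draws, exposed for testing.
    """
    above = trace.fused >= threshold
    segments = []
    start = 0
    for i in range(1, len(above) + 1):
        if i == len(above) or above[i] != above[start]:
            segments.append(("red" if above[start] else "blue", start, i))
            start = i
    return segments


def render_probability_trace(trace: ProbabilityTrace, threshold: float, ax=None):
    """Plot the fused probability vs time (minutes), colour-split at the
    threshold crossings."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2))
    tmin = trace.times_s / 60.0
    for colour, i0, i1 in probability_trace_segments(trace, threshold):
        j1 = min(i1 + 1, len(tmin))  # extend to the crossing epoch for continuity
        ax.plot(tmin[i0:j1], trace.fused[i0:j1], color=colour, lw=1.0)
    ax.axhline(threshold, color="0.6", ls="--", lw=0.8)
    ax.set_ylim(0, 1)
    ax.set_ylabel("P(seizure)")
    ax.set_xlabel("time (min)")
    return ax


def render_binary_trace(decisions: DecisionTrace, ax=None):
    """Step plot of the 0/1 decision trace (pointwise equal to ``binary``)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 1.2))
    ax.step(decisions.times_s / 60.0, decisions.binary, where="post", color="k")
    ax.set_ylim(-0.1, 1.1)
    ax.set_yticks([0, 1])
    ax.set_ylabel("seizure")
    ax.set_xlabel("time (min)")
    return ax


def render_colormap(grid: ColormapGrid, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.5))
    cmap = ListedColormap(grid.colors)
    extent = (
        grid.times_s[0] / 60.0,
        grid.times_s[-1] / 60.0,
        len(grid.channel_labels) - 0.5,
        -0.5,
    )
    ax.imshow(grid.bins, aspect="auto", cmap=cmap, vmin=0, vmax=9, extent=extent)
    ax.set_yticks(range(len(grid.channel_labels)), grid.channel_labels, fontsize=6)
    ax.set_xlabel("time (min)")
    return ax


def render_aeeg(aeeg: AEEGTrace, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2))
    t = np.arange(len(aeeg.upper_display)) * aeeg.step_s / 60.0
    ax.fill_between(t, aeeg.lower_display, aeeg.upper_display, color="k", alpha=0.7)
    ax.set_ylim(0, 20)
    ax.set_yticks([0, 5, 10, 15, 20], ["0", "5", "10", "32", "100"])
    ax.set_ylabel(f"aEEG {aeeg.channel} (µV)")
    ax.set_xlabel("time (min)")
    return ax


def render_bundle(
    rec: EEGRecording,
    trace: ProbabilityTrace,
    decisions: DecisionTrace,
    aeeg_channel: str | None = None,
    out_path=None,
):
    """Four-panel figure: aEEG, binary trace, probability trace, colormap."""
    fig, axes = plt.subplots(4, 1, figsize=(11, 8), constrained_layout=True)
    channel = aeeg_channel or rec.channel_labels[0]
    render_aeeg(compute_aeeg(rec, channel), ax=axes[0])
    render_binary_trace(decisions, ax=axes[1])
    render_probability_trace(trace, decisions.threshold, ax=axes[2])
    render_colormap(build_colormap(trace), ax=axes[3])
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
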