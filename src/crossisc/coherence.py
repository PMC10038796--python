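"""Wavelet coherence between two stimulus descriptor streams.

A naturalistic movie carries correspondences between its auditory and
visual streams — cuts, dialogues, musical passages — that unfold on
timescales from fractions of a second to minutes.  The continuous wavelet
transform (analytic Morlet, centre frequency omega0 = 6) localizes each
stream in time and period; magnitude-squared coherence of the smoothed
cross-spectrum then marks when and at which timescale the two streams
share structure.  Highly coherent cells outside the cone of influence are
segmented into discrete events with an onset, a duration and a
characteristic period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

OMEGA0 = 6.0
#: Fourier factor of the omega0=6 Morlet: period = FOURIER_FACTOR * scale
FOURIER_FACTOR = 4 * np.pi / (OMEGA0 + np.sqrt(2 + OMEGA0 ** 2))


@dataclass
class DescriptorStream:
    """A single stimulus descriptor sampled at a fixed rate."""

    fs_hz: float
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("values must be a 1-D series of >= 2 samples")
        if not np.isfinite(self.values).all():
            raise ValueError("values must be finite")

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs_hz


@dataclass
class CoherenceResult:
    """Time-by-period wavelet coherence with event segmentation."""

    periods_s: np.ndarray
    times_s: np.ndarray
    coherence: np.ndarray              # (n_periods, n_times) in [0, 1]
    cone_of_influence: np.ndarray      # True where edge-contaminated
    event_mask: np.ndarray | None = None
    events: list[tuple[float, float, float]] | None = None


def default_period_grid(stream: DescriptorStream, voices_per_octave: int = 12) -> np.ndarray:
    """Log-spaced periods from 4/fs to duration/4 at the given voice density."""
    p_min = 4.0 / stream.fs_hz
    p_max = stream.duration_s / 4.0
    n_octaves = np.log2(p_max / p_min)
    n = int(np.floor(n_octaves * voices_per_octave)) + 1
    return p_min * 2 ** (np.arange(n) / voices_per_octave)


def cwt_morlet(stream: DescriptorStream, periods_s: Sequence[float]) -> np.ndarray:
    """Analytic Morlet (omega0=6) CWT at the requested Fourier periods.

    Computed in the frequency domain: the transform at scale s is the
    inverse FFT of ``x_hat(w) * sqrt(2*pi*s/dt) * pi**-0.25 *
    exp(-(s*w - omega0)**2 / 2)`` over positive frequencies.  Returns a
    complex (n_periods, n_times) array.
    """
    periods = np.asarray(periods_s, dtype=float)
    dt = 1.0 / stream.fs_hz
    bad = periods[(periods < 2 * dt - 1e-12) | (periods > stream.duration_s / 2 + 1e-12)]
    if bad.size:
        raise ValueError(
            f"periods outside [2/fs, duration/2] = "
            f"[{2 * dt:.4g}, {stream.duration_s / 2:.4g}]s: {bad.tolist()}"
        )
    x = stream.values - stream.values.mean()
    n = x.size
    omega = 2 * np.pi * np.fft.fftfreq(n, d=dt)
    x_hat = np.fft.fft(x)
    scales = periods / FOURIER_FACTOR
    out = np.empty((periods.size, n), dtype=complex)
    pos = omega > 0
    for i, s in enumerate(scales):
        psi_hat = np.zeros(n)
        psi_hat[pos] = (np.pi ** -0.25) * np.sqrt(2 * np.pi * s / dt) \
            * np.exp(-0.5 * (s * omega[pos] - OMEGA0) ** 2)
        out[i] = np.fft.ifft(x_hat * psi_hat)
    return out


#: time-smoothing std in units of scale; 2 gives enough averaging that
#: independent noise rarely clears the default event threshold
TIME_SMOOTH_SCALES = 2.0


def _smooth(field2d: np.ndarray, scales: np.ndarray, dt: float,
            voices_per_octave: int) -> np.ndarray:
    """Cross-wavelet smoothing: Gaussian in time (std proportional to scale)
    per scale row, then a 0.6-octave boxcar across scales."""
    out = np.empty_like(field2d)
    for i, s in enumerate(scales):
        out[i] = ndimage.gaussian_filter1d(
            field2d[i], sigma=TIME_SMOOTH_SCALES * s / dt, mode="nearest")
    width = max(1, int(round(0.6 * voices_per_octave)))
    return ndimage.uniform_filter1d(out, size=width, axis=0, mode="nearest")


def wavelet_coherence(
    a: DescriptorStream,
    b: DescriptorStream,
    periods_s: Sequence[float] | None = None,
    voices_per_octave: int = 12,
) -> CoherenceResult:
    """Magnitude-squared wavelet coherence of two equally sampled streams.

    Coherence is ``|S(W_ab / s)|**2 / (S(|W_a|**2 / s) * S(|W_b|**2 / s))``
    with the scale-dependent smoothing operator ``S`` of :func:`_smooth`.
    The cone of influence marks cells within the e-folding distance
    ``sqrt(2) * scale`` of either series edge.
    """
    if a.fs_hz != b.fs_hz or a.values.size != b.values.size:
        raise ValueError(
            f"streams differ: fs {a.fs_hz} vs {b.fs_hz} Hz, "
            f"length {a.values.size} vs {b.values.size}"
        )
    if periods_s is None:
        periods_s = default_period_grid(a, voices_per_octave)
    periods = np.asarray(periods_s, dtype=float)
    dt = 1.0 / a.fs_hz
    scales = periods / FOURIER_FACTOR

    Wa = cwt_morlet(a, periods)
    Wb = cwt_morlet(b, periods)
    inv_s = 1.0 / scales[:, None]
    Saa = _smooth(np.abs(Wa) ** 2 * inv_s, scales, dt, voices_per_octave)
    Sbb = _smooth(np.abs(Wb) ** 2 * inv_s, scales, dt, voices_per_octave)
    cross = Wa * np.conj(Wb) * inv_s
    Sab = _smooth(cross.real, scales, dt, voices_per_octave) \
        + 1j * _smooth(cross.imag, scales, dt, voices_per_octave)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(Sab) ** 2 / (Saa * Sbb)
    coh = np.clip(np.nan_to_num(coh, nan=0.0), 0.0, 1.0)

    times = a.times_s
    edge = np.minimum(times, times[-1] - times)
    coi = edge[None, :] < (np.sqrt(2.0) * scales)[:, None]
    return CoherenceResult(
        periods_s=periods,
        times_s=times,
        coherence=coh,
        cone_of_influence=coi,
    )


def smoothing_width_s(period_s: float) -> float:
    """FWHM of the time-smoothing Gaussian at a given period (seconds).

    This is the temporal resolution of the coherence map at that period:
    detected event boundaries are smeared by about this much.
    """
    scale = period_s / FOURIER_FACTOR
    return 2.355 * TIME_SMOOTH_SCALES * scale


def coherent_events(
    result: CoherenceResult,
    threshold: float = 0.9,
    min_cells: int = 64,
) -> CoherenceResult:
    """Segment highly coherent cells into discrete events.

    Cells with coherence >= ``threshold`` outside the cone of influence are
    grouped by 8-connectivity in the period-by-time plane; components of at
    least ``min_cells`` cells become events summarized by onset (earliest
    time), duration (time extent) and a coherence-weighted mean period.
    Events are returned sorted by onset.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    mask = (result.coherence >= threshold) & ~result.cone_of_influence
    labels = measure.label(mask, connectivity=2)
    events = []
    for region in measure.regionprops(labels):
        if region.area < min_cells:
            mask[labels == region.label] = False
            continue
        rows, cols = np.nonzero(labels == region.label)
        t = result.times_s[cols]
        weights = result.coherence[rows, cols]
        onset = float(t.min())
        duration = float(t.max() - t.min())
        period = float(np.average(result.periods_s[rows], weights=weights))
        events.append((onset, duration, period))
    events.sort(key=lambda ev: ev[0])
    return CoherenceResult(
        periods_s=result.periods_s,
        times_s=result.times_s,
        coherence=result.coherence,
        cone_of_influence=result.cone_of_influence,
        event_mask=mask,
        events=events,
    )
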