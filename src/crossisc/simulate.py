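"""Synthetic multi-subject BOLD-like data with known ground truth.

The generator emulates the statistical structure of preprocessed
naturalistic-stimulus fMRI recordings: two groups of subjects exposed to
corresponding stimulus streams share, at designated voxels, a latent
stimulus-locked signal band-limited at a known timescale; optional
feature-model-driven components are added with known per-voxel weights;
and each subject carries independent autocorrelated noise.  Defaults
mirror the study conditions of the motivating experiments: 10 subjects
per group, TR = 2 s, 1,614 timepoints split into six runs.

The latent of a voxel "tuned" to timescale w is narrowband noise whose
band is centred at the period for which a rectangular smoothing window of
width w maximizes the intersubject correlation — so the timescale
parameter *is* the voxel's temporal receptive window by construction
(see ``PEAK_WINDOW_FRACTION``).  Noise is AR(1) at lag TR (default coefficient 0.3,
typical of BOLD residuals), with unit innovation variance and re-initialized
at every run boundary, mirroring concatenated-run preprocessing.  All
series are emitted already "preprocessed": the shared component is
z-scored, so with shared amplitude a and white noise the expected pair
correlation at a shared voxel is a^2 / (a^2 + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage, signal

from .isc import BoldGroup
from .mediation import FeatureModel
from .coherence import DescriptorStream


def _default_run_lengths() -> tuple[int, ...]:
    return (269,) * 6


@dataclass
class SimSpec:
    """Generative parameters of one synthetic two-group dataset.

    ``voxel_timescale_s`` gives, per voxel, the moving-average window of
    the shared latent signal in seconds; 0 means no shared signal at that
    voxel.  ``None`` selects a default chronotopic block layout: the first
    quarter of voxels has no shared signal and the remaining quarters are
    tuned to 10, 60 and 120 s.
    """

    n_subjects_per_group: int = 10
    n_voxels: int = 216
    n_timepoints: int = 1614
    tr_seconds: float = 2.0
    run_lengths: Sequence[int] = field(default_factory=_default_run_lengths)
    voxel_timescale_s: np.ndarray | None = None
    shared_amplitude: float = 1.0
    model_amplitude: float = 0.0
    noise_ar1: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        self.run_lengths = tuple(int(r) for r in self.run_lengths)
        if sum(self.run_lengths) != self.n_timepoints:
            raise ValueError(
                f"run_lengths sum to {sum(self.run_lengths)}, "
                f"expected n_timepoints={self.n_timepoints}"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        if not 0 <= self.noise_ar1 < 1:
            raise ValueError("noise_ar1 must lie in [0, 1)")
        if self.shared_amplitude < 0 or self.model_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.voxel_timescale_s is None:
            self.voxel_timescale_s = default_timescale_map(self.n_voxels)
        self.voxel_timescale_s = np.asarray(self.voxel_timescale_s, dtype=float)
        if self.voxel_timescale_s.shape != (self.n_voxels,):
            raise ValueError(
                f"voxel_timescale_s has shape {self.voxel_timescale_s.shape}, "
                f"expected ({self.n_voxels},)"
            )
        ts = self.voxel_timescale_s
        if np.any((ts != 0) & (ts < self.tr_seconds)) or np.any(ts < 0):
            raise ValueError("every timescale must be 0 or >= tr_seconds")


@dataclass
class GroundTruth:
    """Recovery targets of one synthetic dataset."""

    shared_voxel_mask: np.ndarray
    voxel_timescale_s: np.ndarray
    model_weights: np.ndarray          # (n_voxels, n_features); all-zero if no models
    grid_shape: tuple[int, int, int]


def default_timescale_map(n_voxels: int) -> np.ndarray:
    """Block layout: quarter null, then quarters tuned to 10, 60 and 120 s."""
    ts = np.zeros(n_voxels)
    q = n_voxels // 4
    ts[q:2 * q] = 10.0
    ts[2 * q:3 * q] = 60.0
    ts[3 * q:] = 120.0
    return ts


def grid_shape_for(n_voxels: int) -> tuple[int, int, int]:
    """Smallest near-cubic 3-D grid holding ``n_voxels`` (used for NIfTI export)."""
    nx = max(1, int(np.ceil(n_voxels ** (1 / 3))))
    ny = max(1, int(np.ceil(np.sqrt(n_voxels / nx))))
    nz = int(np.ceil(n_voxels / (nx * ny)))
    return (nx, ny, nz)


# ---------------------------------------------------------------------------
# BOLD groups
# ---------------------------------------------------------------------------

#: For a narrowband signal of period P in white noise, ISC under a
#: rectangular window of width W peaks at W* = x*/pi * P with x* solving
#: tan x = 2x (maximize sin^2(x)/x), i.e. W* ~= 0.371 P.  This closed form
#: seeds the numerical calibration below.
PEAK_WINDOW_FRACTION = 1.16556 / np.pi

#: relative (Gaussian) bandwidth of the latent band; narrow enough that a
#: voxel has one well-defined temporal tuning, wide enough not to be a
#: pure sinusoid
_BAND_REL_WIDTH = 0.15
_band_center_cache: dict = {}


def _window_gain_sq(freqs: np.ndarray, width: int, tr: float) -> np.ndarray:
    """Squared transfer of a ``width``-sample rectangular average (Dirichlet)."""
    x = np.pi * freqs * tr
    num = np.sin(width * x)
    den = width * np.sin(x)
    g = np.ones_like(freqs)
    nz = den != 0
    g[nz] = num[nz] / den[nz]
    return g ** 2


def _band_center_frequency(timescale_s: float, n: int, tr: float,
                           rho: float, run_lengths: tuple = ()) -> float:
    """Band centre such that the expected windowed-ISC peaks at ``timescale_s``.

    The expected pair correlation at window width W is monotone in the
    signal-to-noise variance ratio after window-averaging, so the peak
    width solves argmax_W sum_f B^2(f) |G_W(f)|^2 / sum_f N(f) |G_W(f)|^2
    with B the Gaussian signal band, G_W the discrete rectangular-window
    transfer and N the AR(1) noise spectrum.  The centre frequency is
    found by bisection so that this argmax equals the requested timescale.
    """
    key = (round(timescale_s, 6), n, round(tr, 6), round(rho, 6), tuple(run_lengths))
    if key in _band_center_cache:
        return _band_center_cache[key]
    freqs = np.fft.rfftfreq(n, d=tr)[1:]
    noise = 1.0 / (1.0 - 2 * rho * np.cos(2 * np.pi * freqs * tr) + rho ** 2)
    if run_lengths:
        # per-run mean removal before correlating attenuates low-frequency
        # variance by roughly 1 - |G_L(f)|^2 for a run of L samples
        rd = 1.0 - sum(
            (L / n) * _window_gain_sq(freqs, int(L), tr) for L in run_lengths)
        rd = np.clip(rd, 0.0, 1.0)
        noise = noise * rd
    else:
        rd = np.ones_like(freqs)
    max_w = int(min(2.5 * timescale_s / tr, n / 4))
    widths = np.arange(1, max(max_w, 3) + 1)
    gains = np.stack([_window_gain_sq(freqs, int(w), tr) for w in widths])

    def peak_width(f0: float) -> float:
        band = np.exp(-0.5 * ((freqs - f0) / (_BAND_REL_WIDTH * f0)) ** 2) ** 2 * rd
        snr = (gains @ band) / (gains @ noise)
        return float(widths[int(np.argmax(snr))] * tr)

    # peak_width is decreasing in f0; centre the band on the f0-plateau
    # that maps exactly to the requested timescale
    def boundary(target_above: float) -> float:
        lo, hi = 0.05 / timescale_s, 1.2 / timescale_s
        for _ in range(40):
            mid = np.sqrt(lo * hi)
            if peak_width(mid) >= target_above:
                lo = mid
            else:
                hi = mid
        return np.sqrt(lo * hi)

    f_upper = boundary(timescale_s + tr / 2)   # last f0 giving a wider peak
    f_lower = boundary(timescale_s - tr / 2)   # last f0 still reaching the peak
    f0 = np.sqrt(f_upper * f_lower)
    _band_center_cache[key] = f0
    return f0


def _bandlimited_noise(rng: np.random.Generator, n: int, tr: float,
                       timescale_s: float, rho: float,
                       run_lengths: tuple = ()) -> np.ndarray:
    """Unit-variance latent band-limited so its ISC peaks at ``timescale_s``.

    The amplitude spectrum is deterministic (the calibrated Gaussian band)
    and only the phases are random: every realization then has the same
    power profile, so the window width maximizing its signal-to-noise
    ratio — the voxel's temporal receptive window — is fixed by
    construction rather than fluctuating with the few frequency bins a
    narrow band contains at long timescales.
    """
    freqs = np.fft.rfftfreq(n, d=tr)
    f0 = _band_center_frequency(timescale_s, n, tr, rho, run_lengths)
    gain = np.exp(-0.5 * ((freqs - f0) / (_BAND_REL_WIDTH * f0)) ** 2)
    gain[0] = 0.0
    if n % 2 == 0:
        gain[-1] = 0.0                 # Nyquist bin must stay real; drop it
    if gain.max() < 1e-3:
        # short scans can leave no grid support under a very slow band;
        # place the power on the nearest usable bin instead
        gain[max(1, int(np.argmin(np.abs(freqs - f0))))] = 1.0
    phases = np.exp(2j * np.pi * rng.random(gain.size))
    x = np.fft.irfft(gain * phases, n)
    return (x - x.mean()) / x.std()


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...],
               run_lengths: Sequence[int], rho: float) -> np.ndarray:
    """AR(1) noise with unit innovation variance, re-initialized per run."""
    eps = rng.standard_normal(shape)
    if rho == 0:
        return eps
    out = np.empty_like(eps)
    start = 0
    for length in run_lengths:
        seg = eps[..., start:start + length]
        out[..., start:start + length] = signal.lfilter([1.0], [1.0, -rho], seg, axis=-1)
        start += length
    return out


def _resampled_design(designs, spec: SimSpec) -> np.ndarray:
    """Stack non-editing model columns on the TR grid, z-scored per column."""
    from .mediation import build_design

    cols = []
    for model in designs:
        if model.level == "editing":
            continue
        D = build_design(model, spec.tr_seconds, spec.n_timepoints,
                         spec.run_lengths, hrf=False)
        cols.append(D[:, : model.n_features])       # strip run intercepts
    if not cols:
        return np.empty((spec.n_timepoints, 0))
    D = np.column_stack(cols)
    sd = D.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("feature model columns must be non-constant on the TR grid")
    return (D - D.mean(axis=0)) / sd


def generate_bold_groups(
    spec: SimSpec,
    designs: Sequence[FeatureModel] | None = None,
    model_weights: np.ndarray | None = None,
) -> tuple[BoldGroup, BoldGroup, GroundTruth]:
    """Two matched groups sharing latent stimulus-locked signals.

    Every shared voxel carries one latent series (white noise moving-averaged
    over the voxel's timescale and z-scored) embedded with weight
    ``shared_amplitude`` in every subject of *both* groups, emulating the
    across-condition setting in which subjects exposed to different sensory
    versions of the same stimulus are paired.  If feature models are given,
    a model-driven component ``model_amplitude * z(D @ w_v)`` is added with
    per-voxel weights ``w_v`` (drawn N(0,1) unless supplied).  Subjects then
    receive independent AR(1) noise.  Fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    T, V, S = spec.n_timepoints, spec.n_voxels, spec.n_subjects_per_group
    ts = spec.voxel_timescale_s

    # shared latent signals (continuous across runs)
    base = np.zeros((V, T))
    for v in np.flatnonzero(ts > 0):
        base[v] = _bandlimited_noise(rng, T, spec.tr_seconds, ts[v],
                                     spec.noise_ar1, tuple(spec.run_lengths))

    # model-driven components
    if designs is not None and spec.model_amplitude > 0:
        D = _resampled_design(designs, spec)
        if D.shape[0] != T:
            raise ValueError(
                f"design has {D.shape[0]} rows, expected {T} timepoints"
            )
        n_feat = D.shape[1]
        if model_weights is None:
            model_weights = rng.standard_normal((V, n_feat))
        model_weights = np.asarray(model_weights, dtype=float)
        if model_weights.shape != (V, n_feat):
            raise ValueError(
                f"model_weights shape {model_weights.shape} != ({V}, {n_feat})"
            )
        comp = model_weights @ D.T                  # (V, T)
        sd = comp.std(axis=1, keepdims=True)
        nz = sd[:, 0] > 0
        comp[nz] = (comp[nz] - comp[nz].mean(axis=1, keepdims=True)) / sd[nz]
        base = spec.shared_amplitude * base
        base[nz] += spec.model_amplitude * comp[nz]
        weights_out = model_weights
    else:
        base = spec.shared_amplitude * base
        weights_out = np.zeros((V, 0))

    groups = []
    for condition in ("A", "V"):
        noise = _ar1_noise(rng, (S, V, T), spec.run_lengths, spec.noise_ar1)
        data = base[None, :, :] + noise
        groups.append(BoldGroup(
            subject_ids=[f"{condition}{i + 1:02d}" for i in range(S)],
            data=data,
            tr_seconds=spec.tr_seconds,
            run_lengths=spec.run_lengths,
            condition=condition,
            population="TD",
        ))

    shared_mask = (ts > 0)
    if weights_out.size:
        shared_mask = shared_mask | (np.abs(weights_out).sum(axis=1) > 0)
    truth = GroundTruth(
        shared_voxel_mask=shared_mask,
        voxel_timescale_s=ts.copy(),
        model_weights=weights_out,
        grid_shape=grid_shape_for(V),
    )
    return groups[0], groups[1], truth


# ---------------------------------------------------------------------------
# feature models
# ---------------------------------------------------------------------------

@dataclass
class FeatureModelSet:
    """The four feature-model levels of one synthetic stimulus."""

    low_auditory: FeatureModel
    low_visual: FeatureModel
    high_semantic: FeatureModel
    editing: FeatureModel

    def __iter__(self):
        return iter((self.low_auditory, self.low_visual,
                     self.high_semantic, self.editing))


def _boxcar_train(rng: np.random.Generator, n: int, tr: float) -> np.ndarray:
    """Random boxcar train: events every ~30 s lasting 2-10 s."""
    x = np.zeros(n)
    t = 0.0
    duration_s = n * tr
    while t < duration_s:
        t += rng.exponential(30.0)
        dur = rng.uniform(2.0, 10.0)
        i0, i1 = int(t / tr), int((t + dur) / tr)
        x[i0:min(i1 + 1, n)] = 1.0
    return x


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate constant column in feature generation")
    return (x - x.mean()) / sd


def generate_feature_models(
    spec: SimSpec,
    n_low: int = 2,
    n_high: int = 2,
    n_editing: int = 3,
    collinearity: float = 0.3,
) -> FeatureModelSet:
    """Synthetic stimulus feature models with known collinearity structure.

    Editing descriptors are independent boxcar trains (cuts, transitions,
    dialogue presence).  Each low- and high-level column is a mixture
    ``collinearity * e + sqrt(1 - collinearity^2) * u`` of a standardized
    combination ``e`` of editing columns and a unique smooth component ``u``
    orthogonalized against the editing span — so the squared multiple
    correlation of every model column on the editing set equals
    ``collinearity**2`` by construction.  All columns are standardized and
    sampled on the TR grid.
    """
    if min(n_low, n_high, n_editing) < 1:
        raise ValueError("all column counts must be >= 1")
    if not 0 <= collinearity < 1:
        raise ValueError("collinearity must lie in [0, 1)")
    rng = np.random.default_rng(spec.seed + 1)
    T, tr = spec.n_timepoints, spec.tr_seconds
    times = np.arange(T) * tr

    E = np.column_stack([
        _standardize(_boxcar_train(rng, T, tr)) for _ in range(n_editing)
    ])
    # orthonormal basis of the editing span (plus intercept) for projections
    Q, _ = np.linalg.qr(np.column_stack([np.ones(T), E]))

    def mixed_columns(n_cols: int, smooth_sigma_s: float) -> np.ndarray:
        cols = []
        for _ in range(n_cols):
            w = rng.random(n_editing) + 0.2
            e = _standardize(E @ w)
            u = ndimage.gaussian_filter1d(rng.standard_normal(T), smooth_sigma_s / tr)
            u = u - Q @ (Q.T @ u)                  # orthogonal to editing span
            u = _standardize(u)
            cols.append(collinearity * e + np.sqrt(1 - collinearity ** 2) * u)
        return np.column_stack(cols)

    def make(name: str, level: str, matrix: np.ndarray) -> FeatureModel:
        return FeatureModel(name=name, level=level, times_s=times,
                            matrix=matrix, native_rate_hz=1.0 / tr)

    return FeatureModelSet(
        low_auditory=make("low_auditory", "low_auditory", mixed_columns(n_low, 8.0)),
        low_visual=make("low_visual", "low_visual", mixed_columns(n_low, 8.0)),
        high_semantic=make("high_semantic", "high_semantic", mixed_columns(n_high, 20.0)),
        editing=make("editing", "editing", E),
    )


# ---------------------------------------------------------------------------
# stimulus streams
# ---------------------------------------------------------------------------

def generate_stimulus_streams(
    duration_s: float,
    fs_hz: float,
    events: Sequence[tuple[float, float, float]],
    seed: int = 0,
    noise_amplitude: float = 1.0,
    event_amplitude: float = 3.0,
) -> tuple[DescriptorStream, DescriptorStream, list[tuple[float, float, float]]]:
    """Two noise streams sharing band-limited oscillations inside known events.

    ``events`` is a sequence of ``(onset_s, duration_s, period_s)``: inside
    each interval both streams receive a common sinusoid at the stated
    period (random phase, short cosine taper at the edges), emulating
    audio-visual correspondences in a movie.  Outside events the streams
    are independent Gaussian noise.  Returns the two streams and the event
    list as ground truth.
    """
    if fs_hz <= 0 or duration_s <= 0:
        raise ValueError("duration and sampling rate must be positive")
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz
    rng = np.random.default_rng(seed)
    a = noise_amplitude * rng.standard_normal(n)
    b = noise_amplitude * rng.standard_normal(n)
    events = [tuple(map(float, ev)) for ev in events]
    for onset, dur, period in events:
        if period < 2.0 / fs_hz:
            raise ValueError(
                f"event period {period}s violates Nyquist at fs={fs_hz}Hz"
            )
        if onset < 0 or onset + dur > duration_s + 1e-9:
            raise ValueError(f"event ({onset}, {dur}) outside [0, {duration_s}]s")
        sel = (t >= onset) & (t < onset + dur)
        phase = rng.uniform(0, 2 * np.pi)
        osc = np.sin(2 * np.pi * (t[sel] - onset) / period + phase)
        # Hann envelope keeps the oscillation band-limited: a rectangular
        # burst would splatter coherent power far from the stated period
        taper = np.hanning(sel.sum())
        a[sel] += event_amplitude * osc * taper
        b[sel] += event_amplitude * osc * taper
    return (
        DescriptorStream(fs_hz=fs_hz, values=a, name="stream_a"),
        DescriptorStream(fs_hz=fs_hz, values=b, name="stream_b"),
        events,
    )
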