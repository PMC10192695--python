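"""Synthetic multichannel EEG with controllable band energy and coupling.

Two regimes are emulated.  The between-seizure (interictal) regime puts most
signal power in the delta band at baseline amplitude with weak inter-channel
coupling; the seizure (ictal) regime shifts power toward the higher bands,
scales the amplitude up and couples a six-channel "focus" block strongly.
Directed influence is realized by adding lagged, scaled copies of each
driver channel into its receivers, the simplest mechanism a transfer-entropy
estimator provably detects; the ground-truth coupling matrix is returned
alongside every segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .defaults import (
    BAND_ORDER,
    BANDS,
    CHANNEL_NAMES,
    COUPLING_LAG,
    N_CHANNELS,
    RATE,
    SEGMENT_SAMPLES,
)
from .signal_io import EEGSegment, Recording

#: Baseline channel RMS in microvolts (scalp EEG scale).
BASE_RMS_UV = 50.0

#: Depth and rate bounds of the slow amplitude modulation applied to each
#: band component (Hz).
AM_DEPTH = 0.3
AM_FREQ_RANGE = (0.2, 0.5)

#: Focus block: the first six channels, strongly inter-coupled in the
#: ictal regime.
FOCUS_BLOCK = tuple(range(6))

#: Background ring-coupling weight relative to the within-focus weight.
RING_WEIGHT = 0.3


@dataclass(frozen=True)
class RegimeSpec:
    """Generative settings for one regime.

    ``band_weights`` are the fractions of signal power placed in the
    delta/theta/alpha/beta bands (must sum to 1); ``coupling_strength``
    scales the ground-truth directed coupling template; ``noise_sd`` is the
    pink-noise amplitude relative to unit signal RMS.
    """

    label: str
    band_weights: tuple = (0.25, 0.25, 0.25, 0.25)
    amplitude_scale: float = 1.0
    coupling_strength: float = 0.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.label not in ("ictal", "interictal"):
            raise ValueError(f"label must be ictal|interictal, got {self.label!r}")
        w = np.asarray(self.band_weights, dtype=float)
        if w.shape != (4,):
            raise ValueError("band_weights must have 4 entries (delta,theta,alpha,beta)")
        if np.any(w < 0):
            raise ValueError("band_weights must be nonnegative")
        if abs(float(w.sum()) - 1.0) > 1e-12:
            raise ValueError(f"band_weights must sum to 1, got {w.sum()!r}")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """True directed coupling used to generate a segment.

    ``coupling[i, j]`` is the strength with which channel ``i`` drives
    channel ``j`` (row = source); diagonal is exactly zero.
    """

    coupling: np.ndarray
    label: str

    def __post_init__(self):
        c = np.asarray(self.coupling, dtype=float)
        if c.shape != (N_CHANNELS, N_CHANNELS):
            raise ValueError(f"coupling must be {N_CHANNELS}x{N_CHANNELS}")
        if np.any(c < 0):
            raise ValueError("coupling must be nonnegative")
        if np.any(np.diag(c) != 0):
            raise ValueError("coupling diagonal must be exactly 0")
        object.__setattr__(self, "coupling", c)


def default_interictal_spec(seed: int = 0) -> RegimeSpec:
    """Delta-dominant, baseline amplitude, weak coupling."""
    return RegimeSpec(label="interictal", band_weights=(0.70, 0.15, 0.10, 0.05),
                      amplitude_scale=1.0, coupling_strength=0.3,
                      noise_sd=0.5, seed=seed)


def default_ictal_spec(seed: int = 0) -> RegimeSpec:
    """Power shifted to higher bands, doubled amplitude, strong coupling."""
    return RegimeSpec(label="ictal", band_weights=(0.15, 0.20, 0.25, 0.40),
                      amplitude_scale=2.0, coupling_strength=0.9,
                      noise_sd=0.5, seed=seed)


def coupling_template() -> np.ndarray:
    """Directed coupling topology before regime scaling.

    Dense unit-weight coupling inside the six-channel focus block plus a
    weak one-way ring over all channels, so ictal scaling produces a
    clustered, well-connected subnetwork by construction.
    """
    c = np.zeros((N_CHANNELS, N_CHANNELS))
    for i in FOCUS_BLOCK:
        for j in FOCUS_BLOCK:
            if i != j:
                c[i, j] = 1.0
    for i in range(N_CHANNELS):
        c[i, (i + 1) % N_CHANNELS] = max(c[i, (i + 1) % N_CHANNELS], RING_WEIGHT)
    np.fill_diagonal(c, 0.0)
    return c


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS pink (1/f power) noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_component(n: int, rate: float, band: str, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS amplitude-modulated sinusoid with its carrier inside `band`."""
    lo, hi = BANDS[band]
    f_am = rng.uniform(*AM_FREQ_RANGE)
    # inset the carrier so AM sidebands stay inside the band
    f_c = rng.uniform(lo + f_am, hi - f_am)
    t = np.arange(n) / rate
    x = (1.0 + AM_DEPTH * np.sin(2 * np.pi * f_am * t + rng.uniform(0, 2 * np.pi))) \
        * np.cos(2 * np.pi * f_c * t + rng.uniform(0, 2 * np.pi))
    return x / x.std()


def generate_segment(spec: RegimeSpec) -> tuple:
    """Generate one labeled 23 x 2560 segment with its ground truth.

    Each channel is a weighted sum of per-band AM sinusoids (weights =
    ``band_weights`` on the power scale) plus pink noise; directed coupling
    adds a lagged, scaled copy of each driver's intrinsic signal into its
    receivers.  Same spec (same seed) reproduces the arrays exactly.
    """
    rng = np.random.default_rng(spec.seed)
    n = SEGMENT_SAMPLES
    w = np.asarray(spec.band_weights, dtype=float)

    intrinsic = np.empty((N_CHANNELS, n))
    for ch in range(N_CHANNELS):
        x = np.zeros(n)
        for b, band in enumerate(BAND_ORDER):
            if w[b] > 0:
                x += np.sqrt(w[b]) * _band_component(n, RATE, band, rng)
        x += spec.noise_sd * pink_noise(n, rng)
        intrinsic[ch] = x

    coupling = spec.coupling_strength * coupling_template()
    data = intrinsic.copy()
    if spec.coupling_strength > 0:
        lagged = np.empty_like(intrinsic)
        lagged[:, COUPLING_LAG:] = intrinsic[:, :-COUPLING_LAG]
        lagged[:, :COUPLING_LAG] = intrinsic[:, :1]
        data += coupling.T @ lagged  # receiver j gets sum_i coupling[i,j]*lagged_i

    data *= BASE_RMS_UV * spec.amplitude_scale
    seg = EEGSegment(data=data, rate=RATE, label=spec.label,
                     source_id=f"synth-{spec.label}-{spec.seed}")
    return seg, GroundTruth(coupling=coupling, label=spec.label)


def derive_seed(master_seed: int, class_index: int, item_index: int) -> int:
    """Deterministic per-segment seed from a master seed.

    Uses ``numpy.random.SeedSequence([master, class, item])`` so datasets
    are reconstructable from the master seed alone; the result is reduced
    below 2**31.
    """
    ss = np.random.SeedSequence([int(master_seed), int(class_index), int(item_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def generate_dataset(n_per_class: int, ictal_spec: RegimeSpec = None,
                     interictal_spec: RegimeSpec = None,
                     master_seed: int = 0) -> list:
    """Balanced labeled dataset of ``2 * n_per_class`` segments.

    Returns a list of ``(EEGSegment, GroundTruth)`` pairs, interictal class
    first.  Per-segment seeds are derived from ``master_seed`` via
    :func:`derive_seed`; the ``seed`` field of the supplied specs is
    overridden per segment.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    from dataclasses import replace as dc_replace
    if interictal_spec is None:
        interictal_spec = default_interictal_spec()
    if ictal_spec is None:
        ictal_spec = default_ictal_spec()

    out = []
    for cls_idx, spec in enumerate((interictal_spec, ictal_spec)):
        for i in range(n_per_class):
            s = dc_replace(spec, seed=derive_seed(master_seed, cls_idx, i))
            out.append(generate_segment(s))
    return out


def generate_coupled_pair(n: int, c: float, seed: int,
                          a: float = 0.5, b: float = 0.5) -> tuple:
    """Unidirectionally coupled autoregressive pair X -> Y.

    ``x[t+1] = a*x[t] + eps``, ``y[t+1] = b*y[t] + c*x[t] + eta`` with
    standard-normal innovations; a validation fixture for directed
    estimators (the true direction is X to Y by construction).
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    if not (0 <= c <= 1):
        raise ValueError("coupling coefficient c must be in [0, 1]")
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n)
    eta = rng.standard_normal(n)
    x = np.zeros(n)
    y = np.zeros(n)
    for t in range(n - 1):
        x[t + 1] = a * x[t] + eps[t]
        y[t + 1] = b * y[t] + c * x[t] + eta[t]
    return x, y


def dataset_to_recording(pairs: list) -> Recording:
    """Concatenate segments of a dataset into one long recording."""
    data = np.concatenate([seg.data for seg, _gt in pairs], axis=1)
    return Recording(data=data, rate=RATE, channel_names=list(CHANNEL_NAMES))
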