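"""Hilbert-Huang analysis: EMD, analytic signal, Hilbert spectrum.

The signal is adaptively decomposed into intrinsic mode functions (IMFs) by
sifting: at each step the mean of the cubic-spline envelopes through the
local maxima and minima is subtracted until the component satisfies the
Cauchy-type SD criterion and the IMF admissibility condition (extrema and
zero-crossing counts differing by at most one).  Each IMF is then given an
analytic signal z(t) = a(t) e^{j theta(t)} via the Hilbert transform;
squared instantaneous amplitude accumulated at instantaneous frequency over
a time-frequency grid is the Hilbert spectrum H(omega, t), its time
integral the marginal spectrum.

Boundary handling mirrors two extrema at each end before spline fitting,
which suppresses envelope swings at the edges; this and the stopping
thresholds are free choices of the implementation (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import hilbert as _scipy_hilbert

from .defaults import BAND_ORDER, BANDS, HS_FREQ_RANGE, HS_N_FREQ_BINS, HS_N_TIME_BINS

#: Sifting SD stop threshold (Cauchy criterion).
DEFAULT_STOP_SD = 0.2
#: Sift-iteration cap per IMF.
MAX_SIFTINGS = 10
#: Hard cap on extra sifts spent restoring IMF admissibility.
ADMISSIBILITY_EXTRA_SIFTS = 40
#: Amplitude floor (relative to the max) below which instantaneous
#: frequency is masked: the phase derivative is division noise there.
AMP_MASK_REL = 1e-8


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions plus the monotone-ish residual."""

    imfs: list
    residual: np.ndarray

    def reconstruct(self) -> np.ndarray:
        out = self.residual.copy()
        for imf in self.imfs:
            out += imf
        return out

    def __len__(self) -> int:
        return len(self.imfs)


@dataclass
class AnalyticSignal:
    """Envelope, unwrapped phase and instantaneous frequency of one IMF.

    ``inst_freq`` is in Hz and is NaN where the envelope is below the
    masking floor.
    """

    amplitude: np.ndarray
    phase: np.ndarray
    inst_freq: np.ndarray


@dataclass
class HilbertSpectrum:
    """Time x frequency energy grid |a(t)|^2 accumulated over IMFs."""

    grid: np.ndarray           # (n_time_bins, n_freq_bins)
    time_edges: np.ndarray     # seconds, length n_time_bins + 1
    freq_edges: np.ndarray     # Hz, length n_freq_bins + 1

    @property
    def total_energy(self) -> float:
        return float(self.grid.sum())


@dataclass
class MarginalSpectrum:
    """Time-integral of the Hilbert spectrum: energy per frequency bin."""

    energy: np.ndarray
    freq_edges: np.ndarray

    @property
    def freq_centers(self) -> np.ndarray:
        return 0.5 * (self.freq_edges[:-1] + self.freq_edges[1:])


@dataclass
class BandEnergies:
    """Energy fractions in the conventional delta/theta/alpha/beta bands."""

    fractions: dict
    total: float
    zero_energy: bool = False


# ---------------------------------------------------------------------------
# EMD
# ---------------------------------------------------------------------------

def _local_extrema(x: np.ndarray):
    """Indices of strict local maxima and minima (plateaus take the first sample)."""
    dx = np.diff(x)
    # treat flat runs by propagating the sign of the previous slope
    sign = np.sign(dx)
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    flips = np.diff(sign)
    maxima = np.where(flips < 0)[0] + 1
    minima = np.where(flips > 0)[0] + 1
    return maxima, minima


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.sum(s[:-1] != s[1:]))


def _mirror_envelope(x: np.ndarray, idx: np.ndarray, n: int, nbsym: int = 2) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirror-extended at both ends."""
    pos = idx.astype(float)
    val = x[idx]
    k = min(nbsym, len(idx) - 1) if len(idx) > 1 else 0
    if k > 0:
        left_pos = 2 * 0.0 - pos[1:k + 1][::-1]
        left_val = val[1:k + 1][::-1]
        right_pos = 2 * (n - 1.0) - pos[-k - 1:-1][::-1]
        right_val = val[-k - 1:-1][::-1]
        pos = np.concatenate([left_pos, pos, right_pos])
        val = np.concatenate([left_val, val, right_val])
    # anchor the ends if mirroring did not reach them
    if pos[0] > 0:
        pos = np.concatenate([[2 * 0.0 - pos[0]], pos])
        val = np.concatenate([[val[0]], val])
    if pos[-1] < n - 1:
        pos = np.concatenate([pos, [2 * (n - 1.0) - pos[-1]]])
        val = np.concatenate([val, [val[-1]]])
    cs = CubicSpline(pos, val)
    return cs(np.arange(n))


def _is_admissible(h: np.ndarray) -> bool:
    maxima, minima = _local_extrema(h)
    return abs((len(maxima) + len(minima)) - _zero_crossings(h)) <= 1


def emd(signal: np.ndarray, max_imfs: int = 10,
        stop_sd: float = DEFAULT_STOP_SD) -> IMFSet:
    """Empirical mode decomposition by envelope-mean sifting.

    Sifting of a prospective IMF stops when the SD criterion
    ``sum((h_prev - h)^2) / sum(h_prev^2) < stop_sd`` is met and the
    component is admissible, or at the sift cap.  Decomposition stops at
    ``max_imfs`` or when the residual has fewer than two maxima or minima.
    The IMFs and residual sum to the input exactly (each step is a
    subtraction).
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("emd expects a 1-D series")
    if len(x) < 16:
        raise ValueError("series too short for EMD (need >= 16 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")

    n = len(x)
    residual = x.copy()
    imfs = []
    for _ in range(max_imfs):
        maxima, minima = _local_extrema(residual)
        if len(maxima) < 2 or len(minima) < 2:
            break
        h = residual.copy()
        for sift in range(MAX_SIFTINGS + ADMISSIBILITY_EXTRA_SIFTS):
            maxima, minima = _local_extrema(h)
            if len(maxima) < 2 or len(minima) < 2:
                break
            upper = _mirror_envelope(h, maxima, n)
            lower = _mirror_envelope(h, minima, n)
            mean = 0.5 * (upper + lower)
            h_new = h - mean
            denom = float(np.sum(h * h))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            # stop once the SD criterion is met on an admissible component;
            # an inadmissible one earns extra sifts up to the hard cap
            if sd < stop_sd and _is_admissible(h):
                break
        imfs.append(h)
        residual = residual - h
    return IMFSet(imfs=imfs, residual=residual)


# ---------------------------------------------------------------------------
# Hilbert stages
# ---------------------------------------------------------------------------

def hilbert_analytic(imf: np.ndarray, rate: float) -> AnalyticSignal:
    """Analytic signal of one component.

    z(t) = c(t) + j y(t); amplitude a(t) = |z|, phase theta(t) unwrapped,
    instantaneous frequency d theta / dt / 2 pi by central differences.
    Samples whose amplitude falls below ``AMP_MASK_REL`` of the maximum get
    NaN instantaneous frequency (phase is meaningless there).
    """
    x = np.asarray(imf, dtype=float)
    if len(x) < 4:
        raise ValueError("series too short for analytic signal (need >= 4)")
    z = _scipy_hilbert(x)
    amp = np.abs(z)
    phase = np.unwrap(np.angle(z))
    inst = np.gradient(phase) * rate / (2 * np.pi)
    amax = amp.max()
    if amax > 0:
        inst = np.where(amp < AMP_MASK_REL * amax, np.nan, inst)
    else:
        inst = np.full_like(inst, np.nan)
    return AnalyticSignal(amplitude=amp, phase=phase, inst_freq=inst)


def hilbert_spectrum(imfset: IMFSet, rate: float,
                     freq_range: tuple = HS_FREQ_RANGE,
                     n_freq_bins: int = HS_N_FREQ_BINS,
                     n_time_bins: int = HS_N_TIME_BINS) -> HilbertSpectrum:
    """Accumulate |a(t)|^2 at (t, instantaneous frequency) over all IMFs.

    Samples whose instantaneous frequency falls outside ``freq_range`` (or
    is masked) are discarded; their energy is excluded from the grid total,
    so the grid total equals the in-range energy sum exactly.
    """
    if n_freq_bins < 2:
        raise ValueError("n_freq_bins must be >= 2")
    if imfset.imfs:
        n = len(imfset.imfs[0])
    else:
        n = len(imfset.residual)
    f_lo, f_hi = freq_range
    freq_edges = np.linspace(f_lo, f_hi, n_freq_bins + 1)
    time_edges = np.linspace(0.0, n / rate, n_time_bins + 1)
    grid = np.zeros((n_time_bins, n_freq_bins))
    t_bins = np.minimum((np.arange(n) * n_time_bins) // n, n_time_bins - 1)
    for imf in imfset.imfs:
        a = hilbert_analytic(imf, rate)
        energy = a.amplitude ** 2
        f = a.inst_freq
        ok = np.isfinite(f) & (f >= f_lo) & (f <= f_hi)
        f_bins = np.minimum(
            ((f[ok] - f_lo) / (f_hi - f_lo) * n_freq_bins).astype(int),
            n_freq_bins - 1,
        )
        np.add.at(grid, (t_bins[ok], f_bins), energy[ok])
    return HilbertSpectrum(grid=grid, time_edges=time_edges, freq_edges=freq_edges)


def marginal_spectrum(hs: HilbertSpectrum) -> MarginalSpectrum:
    """Time-sum of the Hilbert spectrum per frequency bin."""
    return MarginalSpectrum(energy=hs.grid.sum(axis=0), freq_edges=hs.freq_edges.copy())


def band_energy_fractions(ms: MarginalSpectrum) -> BandEnergies:
    """Fraction of marginal energy in each conventional band.

    Bins belong to a band when their center lies inside the band's edges;
    the fractions may sum below 1 because the bands have gaps.  Zero total
    energy yields all-zero fractions with ``zero_energy`` set.
    """
    total = float(ms.energy.sum())
    centers = ms.freq_centers
    fractions = {}
    if total <= 0:
        return BandEnergies(fractions={b: 0.0 for b in BAND_ORDER},
                            total=total, zero_energy=True)
    for band in BAND_ORDER:
        lo, hi = BANDS[band]
        mask = (centers >= lo) & (centers <= hi)
        fractions[band] = float(ms.energy[mask].sum()) / total
    return BandEnergies(fractions=fractions, total=total, zero_energy=False)


def segment_band_fractions(seg, max_imfs: int = 10, channels=None) -> dict:
    """Mean per-band energy fraction over a segment's channels.

    Convenience wrapper used by the pipeline: runs the full HHT chain per
    channel and averages the band fractions (channels with zero energy are
    skipped).  ``channels`` restricts the computation to a subset.
    """
    idx = range(seg.n_channels) if channels is None else channels
    acc = {b: [] for b in BAND_ORDER}
    for ch in idx:
        imfset = emd(seg.data[ch], max_imfs=max_imfs)
        be = band_energy_fractions(marginal_spectrum(
            hilbert_spectrum(imfset, seg.rate)))
        if not be.zero_energy:
            for b in BAND_ORDER:
                acc[b].append(be.fractions[b])
    return {b: float(np.mean(v)) if v else 0.0 for b, v in acc.items()}


def save_spectrum_png(hs: HilbertSpectrum, path) -> None:
    """Render a Hilbert spectrum as a PNG image (time on x, frequency on y)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    mesh = ax.pcolormesh(hs.time_edges, hs.freq_edges, hs.grid.T,
                         shading="flat", cmap="viridis")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    fig.colorbar(mesh, ax=ax, label="energy")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def segment_spectra(seg, max_imfs: int = 10,
                    n_freq_bins: int = HS_N_FREQ_BINS,
                    n_time_bins: int = HS_N_TIME_BINS) -> list:
    """Per-channel Hilbert spectra of a segment (input to image stacking)."""
    return [
        hilbert_spectrum(emd(seg.data[ch], max_imfs=max_imfs), seg.rate,
                         n_freq_bins=n_freq_bins, n_time_bins=n_time_bins)
        for ch in range(seg.n_channels)
    ]
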