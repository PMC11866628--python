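"""Multitaper cross-spectra, imaginary coherence, and band adjacency matrices.

The connectivity estimator follows the standard coherency construction:
the recording is cut into fixed-length epochs; per epoch, the channels
are tapered with DPSS (Slepian) windows and Fourier transformed; the
cross-spectral density

    Sxy(w) = < X(w) conj(Y(w)) >        (averaged over tapers and epochs)

is normalized into the complex coherency Sxy / sqrt(Sxx * Syy), whose
magnitude is the ordinary coherence in [0, 1]. The edge weight used for
network construction is the magnitude of the *imaginary part* of the
coherency, which is blind to zero-lag coupling and therefore robust to
instantaneous volume conduction: an instantaneous real mixture of
independent sources produces purely real coherency in expectation.
Channel pairs whose cross-spectral phase is within a small tolerance of
zero (equivalently 2*pi) are forced to zero, removing residual
zero-phase coupling.

Per-frequency values are averaged within each of the five canonical EEG
bands (delta 1-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-55 Hz,
half-open intervals) into symmetric non-negative adjacency matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import dpss

from .recording import Recording

logger = logging.getLogger(__name__)

#: Band name -> (low, high) Hz; half-open [low, high) intervals.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 55.0),
}

DEFAULT_EPOCH_LENGTH = 10.0  # seconds
DEFAULT_HALF_BANDWIDTH = 0.5  # Hz; with 10-s epochs: NW = 5, 9 tapers
DEFAULT_PHASE_TOL = 0.01  # radians; zero-phase exclusion tolerance


@dataclass
class EpochSet:
    """Non-overlapping equal-length epochs: (n_epochs, n_channels, n_samples)."""

    epochs: np.ndarray
    fs: float
    epoch_length: float
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be 3-D (epoch, channel, sample)")
        expected = int(round(self.fs * self.epoch_length))
        if self.epochs.shape[2] != expected:
            raise ValueError("epoch sample count inconsistent with fs * epoch_length")

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass
class CrossSpectra:
    """Complex channel x channel x frequency cross-spectral densities.

    The diagonal holds the (real, non-negative) power estimates Sxx; the
    array is Hermitian in its channel indices at every frequency.
    """

    S: np.ndarray
    freqs: np.ndarray
    taper_count: int
    n_epochs: int = 0
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.S.ndim != 3 or self.S.shape[0] != self.S.shape[1]:
            raise ValueError("S must be (channel, channel, frequency)")
        if self.S.shape[2] != self.freqs.size:
            raise ValueError("frequency axis mismatch")


@dataclass
class BandAdjacency:
    """Symmetric non-negative connectivity matrix for one frequency band."""

    band: str
    low: float
    high: float
    W: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        W = np.asarray(self.W, float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("W diagonal must be exactly 0")
        if W.min() < 0 or W.max() > 1:
            raise ValueError("W entries must lie in [0, 1]")
        self.W = W

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]


def segment_epochs(rec: Recording, epoch_length: float = DEFAULT_EPOCH_LENGTH) -> EpochSet:
    """Cut into consecutive non-overlapping epochs; trailing remainder dropped."""
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    spe = int(round(rec.fs * epoch_length))
    n_epochs = rec.n_samples // spe
    if n_epochs < 1:
        raise ValueError(
            f"recording of {rec.duration:.1f} s shorter than epoch length {epoch_length} s"
        )
    trimmed = rec.data[:, : n_epochs * spe]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, spe).transpose(1, 0, 2)
    return EpochSet(epochs=epochs.copy(), fs=rec.fs, epoch_length=epoch_length,
                    labels=rec.labels)


def cross_spectra_multitaper(
    ep: EpochSet, half_bandwidth: float = DEFAULT_HALF_BANDWIDTH
) -> CrossSpectra:
    """DPSS-tapered cross-spectral densities averaged over tapers and epochs.

    The taper count follows the 2*NW - 1 rule for time-bandwidth product
    NW = half_bandwidth * epoch_length; fewer than 2 tapers is an error.
    """
    n_ep, n_ch, n_s = ep.epochs.shape
    nw = half_bandwidth * ep.epoch_length
    if nw <= 1:
        raise ValueError(
            f"half_bandwidth x epoch_length = {nw:.2f} must exceed 1"
        )
    k = int(2 * nw - 1)
    if k < 2:
        raise ValueError(f"taper count {k} < 2; increase half_bandwidth or epoch length")
    tapers = dpss(n_s, nw, Kmax=k)  # (k, n_s), unit energy

    freqs = np.fft.rfftfreq(n_s, 1.0 / ep.fs)
    S = np.zeros((n_ch, n_ch, freqs.size), dtype=complex)
    for e in range(n_ep):
        tapered = tapers[:, None, :] * ep.epochs[e][None, :, :]  # (k, ch, samp)
        X = np.fft.rfft(tapered, axis=-1)
        S += np.einsum("kcf,kdf->cdf", X, X.conj())
    S /= k * n_ep
    return CrossSpectra(S=S, freqs=freqs, taper_count=k, n_epochs=n_ep, labels=ep.labels)


def _coherency(cs: CrossSpectra) -> np.ndarray:
    """Complex coherency Sxy / sqrt(Sxx Syy); zero-power bins -> 0, logged."""
    power = np.real(np.einsum("iif->if", cs.S))  # (ch, freq)
    denom = np.sqrt(power[:, None, :] * power[None, :, :])
    bad = denom <= 0
    if np.any(bad):
        logger.warning("zero power at %d (pair, frequency) bins; coherency set to 0",
                       int(bad.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.where(bad, 0.0, cs.S / np.where(bad, 1.0, denom))
    # |coherency| <= 1 holds exactly (Cauchy-Schwarz); guard the float tail
    mag = np.abs(coh)
    over = mag > 1.0
    if np.any(over):
        coh = np.where(over, coh / mag, coh)
    return coh


def coherence(cs: CrossSpectra) -> np.ndarray:
    """Coherence magnitude |Sxy| / sqrt(Sxx Syy) in [0, 1], per pair and frequency."""
    return np.abs(_coherency(cs))


def imaginary_coherence(
    cs: CrossSpectra,
    phase_tol: float = DEFAULT_PHASE_TOL,
    signed: bool = False,
) -> np.ndarray:
    """Imaginary part of coherency per (channel, channel, frequency).

    Pairs whose cross-spectral phase lies within ``phase_tol`` of zero
    (or equivalently 2*pi) are set to 0 — the zero-phase exclusion that
    discards purely instantaneous coupling. Returns |Im coherency| by
    default (non-negative weights for thresholding); ``signed=True``
    keeps the sign.
    """
    coh = _coherency(cs)
    icoh = np.imag(coh)
    phase = np.angle(cs.S)
    icoh = np.where(np.abs(phase) < phase_tol, 0.0, icoh)
    if not signed:
        icoh = np.abs(icoh)
    n = icoh.shape[0]
    icoh[np.arange(n), np.arange(n), :] = 0.0
    return icoh


def band_adjacency(
    icoh: np.ndarray,
    freqs: np.ndarray,
    bands: dict[str, tuple[float, float]] | None = None,
    labels: tuple[str, ...] = (),
) -> list[BandAdjacency]:
    """Average per-frequency values into one adjacency matrix per band.

    Bins are assigned by half-open interval [low, high) on the bin
    centre frequency; a band containing no bins is an error.
    """
    bands = bands or BANDS
    out = []
    for name, (low, high) in bands.items():
        sel = (freqs >= low) & (freqs < high)
        if not np.any(sel):
            raise ValueError(f"band {name!r} [{low}, {high}) contains no frequency bins")
        W = icoh[:, :, sel].mean(axis=2)
        W = 0.5 * (W + W.T)  # enforce exact symmetry against float noise
        np.fill_diagonal(W, 0.0)
        out.append(BandAdjacency(band=name, low=low, high=high, W=W, labels=labels))
    return out


def connectivity(
    rec: Recording,
    epoch_length: float = DEFAULT_EPOCH_LENGTH,
    half_bandwidth: float = DEFAULT_HALF_BANDWIDTH,
    bands: dict[str, tuple[float, float]] | None = None,
    phase_tol: float = DEFAULT_PHASE_TOL,
) -> list[BandAdjacency]:
    """Recording -> five band adjacency matrices in one call."""
    ep = segment_epochs(rec, epoch_length)
    cs = cross_spectra_multitaper(ep, half_bandwidth)
    icoh = imaginary_coherence(cs, phase_tol=phase_tol)
    return band_adjacency(icoh, cs.freqs, bands=bands, labels=rec.labels)
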