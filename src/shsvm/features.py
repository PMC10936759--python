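"""Per-segment EEG feature views: wavelet, STFT and KPCA representations.

Three complementary views of the same segment are produced:

* **WPD** (frequency domain): Daubechies-4 wavelet-packet decomposition;
  packet energies pooled into six clinical EEG bands
  (0-2, 2-4, 4-8, 8-15, 16-30, 31-60 Hz) and normalized to sum to one.
* **STFT** (time-frequency domain): magnitude-squared short-time Fourier
  transform with a Hamming window, band energies averaged over frames and
  normalized by total 0-60 Hz energy.  Frame averaging of the squared STFT
  is Welch's method, which is what the implementation uses.
* **KPCA** (time domain): Gaussian-kernel principal component scores of the
  raw sample vectors, with out-of-sample projection of unseen segments.

Each view yields a fixed-length vector per segment so that the two-view
learner can operate on any pair of views.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pywt
from scipy.signal import welch
from scipy.signal import windows as _windows
from scipy.spatial.distance import pdist
from sklearn.decomposition import KernelPCA
from sklearn.preprocessing import StandardScaler

from .eeg_io import EEGSegment

__all__ = [
    "EEG_BANDS",
    "FeatureView",
    "STFTConfig",
    "KPCAConfig",
    "wpd_band_energies",
    "stft_band_energies",
    "kpca_fit_transform",
    "KPCAModel",
    "band_energy_view",
    "zscore_fit",
    "zscore_apply",
]

EEG_BANDS: Tuple[Tuple[float, float], ...] = (
    (0.0, 2.0),
    (2.0, 4.0),
    (4.0, 8.0),
    (8.0, 15.0),
    (16.0, 30.0),
    (31.0, 60.0),
)
"""The six analysis bands (Hz) used by both spectral views."""

_BAND_NAMES = tuple(f"{lo:g}-{hi:g}Hz" for lo, hi in EEG_BANDS)


@dataclass
class FeatureView:
    """A named N x d feature matrix with labels in {-1, +1}."""

    matrix: np.ndarray
    view_name: str
    feature_names: Tuple[str, ...]
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.size == 0:
            raise ValueError("feature matrix must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains non-finite entries")
        if self.matrix.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length must match matrix width")


def wpd_band_energies(
    segment: EEGSegment,
    bands: Sequence[Tuple[float, float]] = EEG_BANDS,
    level: int = 5,
    wavelet: str = "db4",
    normalize: bool = True,
) -> np.ndarray:
    """Wavelet-packet band energies of one segment.

    A ``level``-deep Daubechies-4 packet decomposition splits [0, fs/2] into
    ``2**level`` uniform sub-bands.  Each packet is assigned to the analysis
    band whose center frequency is closest to the packet center; packets
    centered above the top band edge are discarded.  Band energy is the sum
    of squared packet coefficients, normalized by total retained energy
    (a zero signal yields all zeros).
    """
    x = np.asarray(segment.samples, dtype=float)
    if len(x) < 2**level:
        raise ValueError(
            f"segment of {len(x)} samples too short for a level-{level} decomposition"
        )
    wp = pywt.WaveletPacket(x, wavelet, mode="symmetric", maxlevel=level)
    nodes = wp.get_level(level, order="freq")
    width = segment.fs / 2.0 / 2**level
    centers = np.array([(lo + hi) / 2.0 for lo, hi in bands])
    top_edge = bands[-1][1]
    energies = np.zeros(len(bands))
    for k, node in enumerate(nodes):
        c = (k + 0.5) * width
        if c > top_edge:
            continue
        energies[int(np.argmin(np.abs(centers - c)))] += float(
            np.sum(np.asarray(node.data) ** 2)
        )
    if normalize:
        total = energies.sum()
        if total > 0:
            energies = energies / total
    return energies


@dataclass(frozen=True)
class STFTConfig:
    """Short-time Fourier transform settings for band-energy extraction."""

    window_len: int = 256
    hop: int = 128
    window: str = "hamming"
    bands: Tuple[Tuple[float, float], ...] = EEG_BANDS

    def __post_init__(self) -> None:
        if not 0 < self.hop <= self.window_len:
            raise ValueError("need 0 < hop <= window_len")


def stft_band_energies(
    segment: EEGSegment, config: STFTConfig = STFTConfig(), normalize: bool = True
) -> np.ndarray:
    """Frame-averaged squared-STFT energy per band.

    Spectral bins are partitioned among the bands by proximity (boundaries
    midway inside inter-band gaps) up to the top band edge, so that the sum
    of the unnormalized band energies equals the total spectral power below
    that edge.  With ``normalize=True`` the vector is scaled to sum to one.
    """
    x = np.asarray(segment.samples, dtype=float)
    cfg = config
    if cfg.window_len > len(x):
        raise ValueError(
            f"window of {cfg.window_len} samples exceeds segment length {len(x)}"
        )
    win = getattr(_windows, cfg.window)(cfg.window_len)
    freqs, psd = welch(
        x,
        fs=segment.fs,
        window=win,
        noverlap=cfg.window_len - cfg.hop,
        detrend=False,
        scaling="density",
        average="mean",
    )
    df = freqs[1] - freqs[0]
    bands = cfg.bands
    top_edge = bands[-1][1]
    # proximity partition: split the gaps between adjacent bands in half
    edges = [0.0]
    for (lo, hi), (lo2, _hi2) in zip(bands[:-1], bands[1:]):
        edges.append((hi + lo2) / 2.0)
    edges.append(top_edge)
    keep = freqs <= top_edge
    idx = np.digitize(freqs[keep], np.asarray(edges)[1:-1])
    energies = np.zeros(len(bands))
    np.add.at(energies, idx, psd[keep] * df)
    if normalize:
        total = energies.sum()
        if total > 0:
            energies = energies / total
    return energies


def band_energy_view(
    segments: Sequence[EEGSegment],
    method: str,
    labels: np.ndarray | None = None,
    stft_config: STFTConfig = STFTConfig(),
) -> FeatureView:
    """Stack per-segment band energies into a FeatureView ('WPD' or 'STFT')."""
    if method == "WPD":
        rows = [wpd_band_energies(s) for s in segments]
    elif method == "STFT":
        rows = [stft_band_energies(s, stft_config) for s in segments]
    else:
        raise ValueError(f"unknown band-energy method {method!r}")
    return FeatureView(np.vstack(rows), method, _BAND_NAMES, labels)


@dataclass(frozen=True)
class KPCAConfig:
    """Gaussian-kernel PCA settings.

    ``width`` is the kernel bandwidth sigma of
    ``k(x, x') = exp(-||x - x'||^2 / (2 sigma^2))``; the default
    "median-heuristic" sets it to the median pairwise distance of the
    training sample vectors.  ``n_components`` defaults to 6 so every view
    shares the same dimension.
    """

    width: float | str = "median-heuristic"
    n_components: int = 6
    kernel: str = "rbf"  # "linear" reduces to ordinary PCA (cross-check path)

    def __post_init__(self) -> None:
        if self.kernel not in ("rbf", "linear"):
            raise ValueError("kernel must be 'rbf' or 'linear'")
        if isinstance(self.width, str):
            if self.width != "median-heuristic":
                raise ValueError("width must be positive or 'median-heuristic'")
        elif self.width <= 0:
            raise ValueError("kernel width must be positive")
        if self.n_components < 1:
            raise ValueError("n_components must be positive")


@dataclass
class KPCAModel:
    """Fitted KPCA view: projects raw segments onto kernel principal axes."""

    kpca: KernelPCA = field(repr=False)
    width: float
    n_samples_train: int
    min_length: int

    def transform_segments(self, segments: Sequence[EEGSegment]) -> np.ndarray:
        return self.kpca.transform(_raw_matrix(segments, self.min_length))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.kpca.transform(np.asarray(X, dtype=float)[:, : self.min_length])


def _raw_matrix(segments: Sequence[EEGSegment], length: int) -> np.ndarray:
    return np.vstack([np.asarray(s.samples, dtype=float)[:length] for s in segments])


def kpca_fit_transform(
    segments: Sequence[EEGSegment], config: KPCAConfig = KPCAConfig()
) -> Tuple[KPCAModel, np.ndarray]:
    """Fit Gaussian-kernel PCA on raw sample vectors; return (model, scores).

    Segments are truncated to the shortest length so the Gram matrix is
    well defined.  The double-centered Gram matrix is eigendecomposed and
    scores are computed with eigenvectors scaled by inverse root eigenvalues;
    unseen segments are projected through the centered cross-kernel.
    """
    n = len(segments)
    if n < 2:
        raise ValueError("KPCA needs at least two training segments")
    if config.n_components >= n:
        raise ValueError(
            f"n_components={config.n_components} must be < n_samples={n}"
        )
    length = min(len(s) for s in segments)
    X = _raw_matrix(segments, length)
    if config.kernel == "linear":
        width = 1.0
        kpca = KernelPCA(n_components=config.n_components, kernel="linear")
    else:
        if config.width == "median-heuristic":
            dists = pdist(X)
            width = float(np.median(dists[dists > 0]))
            if width == 0 or not np.isfinite(width):
                raise ValueError("median-heuristic width degenerate (identical inputs)")
        else:
            width = float(config.width)
        kpca = KernelPCA(
            n_components=config.n_components,
            kernel="rbf",
            gamma=1.0 / (2.0 * width**2),
        )
    scores = kpca.fit_transform(X)
    model = KPCAModel(kpca=kpca, width=width, n_samples_train=n, min_length=length)
    return model, scores


def zscore_fit(view: FeatureView) -> StandardScaler:
    """Fit a per-feature standardizer on a training view.

    Constant features are mapped to zero when the scaler is applied (the
    scale of a zero-variance column is left at one by the underlying
    implementation, so centering alone zeroes it).
    """
    scaler = StandardScaler()
    scaler.fit(view.matrix)
    return scaler


def zscore_apply(scaler: StandardScaler, view: FeatureView) -> FeatureView:
    """Apply a previously fitted standardizer to a (train or test) view."""
    return FeatureView(
        scaler.transform(view.matrix), view.view_name, view.feature_names, view.labels
    )
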