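"""Synthetic data generators for two-view learning and EEG-like signals.

Two generators are provided:

* :func:`gen_two_view` draws paired samples from a shared low-dimensional
  latent class signal observed through two different row-orthonormal linear
  mixings plus isotropic Gaussian noise.  This is the minimal generative
  model under which a shared hidden space between the two views exists, and
  the ground-truth mixings are returned so that subspace-recovery tests can
  compare against a known optimum.
* :func:`gen_eeg` synthesizes single-channel EEG-like segments: a sum of
  band-limited sinusoids plus noise for background activity, with an added
  high-amplitude spike train and boosted 2-8 Hz power for seizure-like
  activity.

All outputs are deterministic functions of the configuration (including its
seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Tuple

import numpy as np

from .eeg_io import EEGSegment

__all__ = [
    "TwoViewGenConfig",
    "SyntheticEEGConfig",
    "TwoViewDataset",
    "gen_two_view",
    "gen_eeg",
    "write_bonn_format",
    "oracle_shared_subspace",
]


@dataclass(frozen=True)
class TwoViewGenConfig:
    """Configuration for the paired two-view generator.

    Parameters
    ----------
    n_samples:
        Number of paired samples.  Labels are balanced to within one sample.
    r_true:
        Dimension of the shared latent signal.
    d:
        Observed dimension of each view (``d >= r_true``).
    class_separation:
        Euclidean distance between the two latent class means.  The means are
        placed at ``+/- class_separation/2`` along the first latent axis so the
        discriminative direction is known exactly.
    noise_sd:
        Standard deviation of the isotropic observation noise in each view.
    seed:
        Seed for all randomness (mixing matrices, latent draws, noise).
    """

    n_samples: int = 200
    r_true: int = 2
    d: int = 6
    class_separation: float = 3.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not (self.d >= self.r_true >= 1):
            raise ValueError(
                f"need d >= r_true >= 1, got d={self.d}, r_true={self.r_true}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.class_separation < 0:
            raise ValueError("class_separation must be nonnegative")


@dataclass
class TwoViewDataset:
    """Paired two-view samples with binary labels and the generating oracle.

    ``xa`` and ``xb`` hold one sample per row; ``y`` is in ``{-1, +1}``.
    ``mixing_a``/``mixing_b`` are the true row-orthonormal mixing matrices
    (``r_true x d``) and ``z`` the latent draws, kept for recovery tests.
    """

    xa: np.ndarray
    xb: np.ndarray
    y: np.ndarray
    z: np.ndarray = field(repr=False)
    mixing_a: np.ndarray = field(repr=False)
    mixing_b: np.ndarray = field(repr=False)
    config: TwoViewGenConfig | None = None

    @property
    def n_samples(self) -> int:
        return self.xa.shape[0]


def _row_orthonormal(rng: np.random.Generator, r: int, d: int) -> np.ndarray:
    """Deterministically reduce a seeded Gaussian matrix to orthonormal rows."""
    m = rng.standard_normal((d, r))
    q, rr = np.linalg.qr(m)
    # fix signs so the factorization (hence the output) is unique
    q = q * np.sign(np.diag(rr))
    return q.T


def gen_two_view(config: TwoViewGenConfig) -> TwoViewDataset:
    """Draw a paired two-view dataset with a shared Gaussian latent signal.

    Latent draws follow class-conditional Gaussians
    ``z | y ~ N(y * (class_separation/2) * e1, I_r)`` and each view observes
    ``x^V = M_V^T z + eps`` with ``eps ~ N(0, noise_sd^2 I_d)`` and ``M_V``
    a fixed row-orthonormal ``r_true x d`` matrix derived from the seed.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    mixing_a = _row_orthonormal(rng, cfg.r_true, cfg.d)
    mixing_b = _row_orthonormal(rng, cfg.r_true, cfg.d)

    n_pos = cfg.n_samples // 2
    y = np.concatenate([np.full(cfg.n_samples - n_pos, -1.0), np.full(n_pos, 1.0)])
    rng.shuffle(y)

    mean = np.zeros((cfg.n_samples, cfg.r_true))
    mean[:, 0] = y * (cfg.class_separation / 2.0)
    z = mean + rng.standard_normal((cfg.n_samples, cfg.r_true))

    xa = z @ mixing_a + cfg.noise_sd * rng.standard_normal((cfg.n_samples, cfg.d))
    xb = z @ mixing_b + cfg.noise_sd * rng.standard_normal((cfg.n_samples, cfg.d))
    return TwoViewDataset(
        xa=xa, xb=xb, y=y, z=z, mixing_a=mixing_a, mixing_b=mixing_b, config=cfg
    )


def oracle_shared_subspace(dataset: TwoViewDataset, r: int) -> np.ndarray:
    """Population optimum of the between-view discrepancy for this generator.

    The shared-space objective sums squared distances between all cross-view
    pairs of projected points; its population version is the quadratic form
    ``trace(Omega S Omega^T)`` with
    ``S = Cov(x^A) + Cov(x^B) + (m_A - m_B)(m_A - m_B)^T``.  Under this
    generator the view means coincide and the covariances are known in closed
    form from the mixings, so the optimal ``Omega`` (for any noise level) is
    the bottom-``r`` eigenspace of
    ``M_A^T C_z M_A + M_B^T C_z M_B`` with latent covariance
    ``C_z = I + (sep^2/4) e1 e1^T``.  Returns an orthonormal ``r x d`` basis.
    """
    cfg = dataset.config
    if cfg is None:
        raise ValueError("dataset carries no generator configuration")
    cz = np.eye(cfg.r_true)
    cz[0, 0] += cfg.class_separation**2 / 4.0
    s = dataset.mixing_a.T @ cz @ dataset.mixing_a
    s += dataset.mixing_b.T @ cz @ dataset.mixing_b
    evals, evecs = np.linalg.eigh(s)
    return evecs[:, :r].T


@dataclass(frozen=True)
class SyntheticEEGConfig:
    """Configuration for EEG-like segment synthesis.

    ``component_freqs`` are the sinusoidal constituents (Hz, all below
    Nyquist); background defaults emulate mixed theta/alpha/beta activity.
    Seizure-like segments add a high-amplitude spike train at ``spike_rate``
    events per second and boost 2-8 Hz power, mimicking the large rhythmic
    discharges of ictal recordings.
    """

    duration_s: float = 23.6
    fs: float = 173.61
    class_label: str = "background"
    component_freqs: Sequence[float] = (4.0, 10.0, 21.0)
    spike_rate: float = 3.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fs <= 0:
            raise ValueError("duration_s and fs must be positive")
        if self.class_label not in ("background", "seizure-like"):
            raise ValueError("class_label must be 'background' or 'seizure-like'")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be nonnegative")
        for f in self.component_freqs:
            if not 0 < f < self.fs / 2:
                raise ValueError(
                    f"component frequency {f} Hz must lie below Nyquist "
                    f"({self.fs / 2:g} Hz)"
                )


def gen_eeg(config: SyntheticEEGConfig) -> EEGSegment:
    """Synthesize one EEG-like segment according to ``config``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    x = np.zeros(n)
    for k, f in enumerate(cfg.component_freqs):
        amp = 1.0 / (1.0 + 0.5 * k)
        x += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if cfg.noise_sd > 0:
        x += cfg.noise_sd * rng.standard_normal(n)

    if cfg.class_label == "seizure-like":
        # rhythmic delta/theta surge typical of ictal traces
        for f_low, amp in ((2.5, 2.0), (5.5, 1.5)):
            if f_low < cfg.fs / 2:
                x += amp * np.sin(2 * np.pi * f_low * t + rng.uniform(0, 2 * np.pi))
        if cfg.spike_rate > 0:
            period = 1.0 / cfg.spike_rate
            spike_times = np.arange(period / 2, cfg.duration_s, period)
            spike_times += rng.uniform(-0.1, 0.1, size=spike_times.shape) * period
            width = 0.02  # seconds; sharp transient
            for ts in spike_times:
                x += 6.0 * np.exp(-0.5 * ((t - ts) / width) ** 2)

    return EEGSegment(
        samples=x,
        fs=cfg.fs,
        group="synthetic",
        source_id=f"synthetic-{cfg.class_label}-{cfg.seed}",
    )


def write_bonn_format(segment: EEGSegment, path) -> None:
    """Write a segment as plain text, one sample value per line."""
    if len(segment.samples) == 0:
        raise ValueError("cannot write an empty segment")
    np.savetxt(path, np.asarray(segment.samples), fmt="%.6f")
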