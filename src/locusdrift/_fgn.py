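"""Fractional Gaussian noise sampling.

Provides stationary unit-variance fractional Gaussian noise (fGn), the
increment process of fractional Brownian motion with Hurst index H.  The
primary sampler is circulant embedding (Davies-Harte), which is exact and
O(n log n); when the embedding is not non-negative definite (possible for
some H/length combinations) we fall back to the exact but O(n^2)
Durbin-Levinson recursion (Hosking's method).
"""
from __future__ import annotations

import numpy as np


def fgn_autocovariance(lags: np.ndarray | int, hurst: float) -> np.ndarray:
    """Autocovariance of unit-variance fGn at integer lags.

    gamma(k) = 0.5 * (|k-1|^{2H} - 2|k|^{2H} + |k+1|^{2H}).
    At lag 1 this equals 2^{2H-1} - 1: negative (antipersistent) for H < 1/2,
    zero at H = 1/2 (white noise), positive for H > 1/2.
    """
    k = np.abs(np.asarray(lags, dtype=float))
    h2 = 2.0 * hurst
    return 0.5 * (np.abs(k - 1) ** h2 - 2.0 * k**h2 + (k + 1) ** h2)


def _davies_harte_eigenvalues(n: int, hurst: float) -> np.ndarray | None:
    gamma = fgn_autocovariance(np.arange(n + 1), hurst)
    # first row of the 2n circulant: gamma(0..n), gamma(n-1..1)
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.fft(row).real
    if lam.min() < -1e-9 * max(lam.max(), 1.0):
        return None
    return np.maximum(lam, 0.0)


def _sample_davies_harte(
    lam: np.ndarray, n: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    m = lam.shape[0]  # 2n
    z1 = rng.standard_normal((size, n + 1))
    z2 = rng.standard_normal((size, n - 1))
    w = np.zeros((size, m), dtype=complex)
    w[:, 0] = np.sqrt(lam[0] / m) * z1[:, 0]
    w[:, n] = np.sqrt(lam[n] / m) * z1[:, n]
    half = np.sqrt(lam[1:n] / (2.0 * m))
    w[:, 1:n] = half * (z1[:, 1:n] + 1j * z2)
    w[:, n + 1 :] = np.conj(w[:, n - 1 : 0 : -1])
    return np.fft.fft(w, axis=1)[:, :n].real


def _sample_hosking(
    n: int, hurst: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    gamma = fgn_autocovariance(np.arange(n), hurst)
    out = np.empty((size, n))
    out[:, 0] = np.sqrt(gamma[0]) * rng.standard_normal(size)
    phi = np.zeros(n)
    v = gamma[0]
    for k in range(1, n):
        phi_kk = (gamma[k] - phi[1:k] @ gamma[k - 1 : 0 : -1]) / v
        phi[1:k] = phi[1:k] - phi_kk * phi[k - 1 : 0 : -1]
        phi[k] = phi_kk
        v *= 1.0 - phi_kk**2
        mean = out[:, :k] @ phi[k:0:-1]
        out[:, k] = mean + np.sqrt(v) * rng.standard_normal(size)
    return out


def sample_fgn(
    n_steps: int,
    hurst: float,
    rng: np.random.Generator,
    size: int = 1,
) -> tuple[np.ndarray, str]:
    """Draw `size` independent unit-variance fGn sequences of length `n_steps`.

    Returns (samples of shape (size, n_steps), sampler name), where the
    sampler name records whether circulant embedding succeeded or the
    Durbin-Levinson fallback ran.
    """
    if not 0.0 < hurst <= 1.0:
        raise ValueError(f"hurst must be in (0, 1], got {hurst}")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if n_steps == 1:
        return rng.standard_normal((size, 1)), "davies-harte"
    lam = _davies_harte_eigenvalues(n_steps, hurst)
    if lam is not None:
        return _sample_davies_harte(lam, n_steps, size, rng), "davies-harte"
    return _sample_hosking(n_steps, hurst, size, rng), "hosking"
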