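"""Shared fixtures and independent oracles.

The oracles here are deliberately coded apart from the library's main path:
the DFT is a term-by-term complex-exponential sum (no FFT), the Tukey taper
is written from its closed-form definition, and the ANOVA oracle uses
explicit textbook loops.  They exist so the pipeline can be checked against
arithmetic that shares none of its code.
"""

from __future__ import annotations

import numpy as np
import pytest

from vfwave.spectral import SpectralConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20160818)


@pytest.fixture
def config():
    return SpectralConfig()


# ---------------------------------------------------------------- oracles


def tukey_oracle(n: int, alpha: float) -> np.ndarray:
    """Closed-form periodic Tukey taper: symmetric window of n+1, last dropped."""
    m = n + 1
    w = np.ones(m)
    if alpha > 0:
        edge = alpha * (m - 1) / 2.0
        for i in range(m):
            if i < edge:
                w[i] = 0.5 * (1 + np.cos(np.pi * (2 * i / (alpha * (m - 1)) - 1)))
            elif i > (m - 1) - edge:
                w[i] = 0.5 * (1 + np.cos(np.pi * (2 * i / (alpha * (m - 1)) - 2 / alpha + 1)))
    return w[:n]


def dft_oracle(x: np.ndarray) -> np.ndarray:
    """Brute-force one-sided DFT: X_k = sum_n x_n exp(-2 pi i n k / N)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    k = np.arange(n // 2 + 1)
    phase = np.exp(-2j * np.pi * np.outer(k, np.arange(n)) / n)
    return phase @ x


def amplitude_oracle(segment: np.ndarray, config: SpectralConfig) -> np.ndarray:
    """One-sided coherent-gain amplitude spectrum via the brute-force DFT."""
    x = np.asarray(segment, dtype=float)
    if config.detrend:
        x = x - x.mean()
    w = tukey_oracle(x.size, config.tukey_alpha)
    spec = np.abs(dft_oracle(x * w))
    scale = np.full(spec.size, 2.0 / w.sum())
    scale[0] = 1.0 / w.sum()
    if x.size % 2 == 0:
        scale[-1] = 1.0 / w.sum()
    return spec * scale


def amsa_oracle(segment: np.ndarray, fs: float, config: SpectralConfig) -> float:
    """In-band summed amplitude x frequency via the brute-force spectrum."""
    amps = amplitude_oracle(segment, config)
    freqs = np.arange(amps.size) * fs / len(segment)
    band = (freqs >= config.band_lo) & (freqs <= config.band_hi)
    return float(np.sum(amps[band] * freqs[band]))


def rm_anova_oracle(x: np.ndarray) -> tuple[float, int, int]:
    """Textbook one-way within-subject F via explicit loops over cells."""
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    ss_time = 0.0
    for j in range(k):
        col = sum(x[i, j] for i in range(n)) / n
        ss_time += n * (col - grand) ** 2
    ss_subj = 0.0
    for i in range(n):
        row = sum(x[i, j] for j in range(k)) / k
        ss_subj += k * (row - grand) ** 2
    ss_total = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_error = ss_total - ss_time - ss_subj
    f = (ss_time / (k - 1)) / (ss_error / ((n - 1) * (k - 1)))
    return f, k - 1, (n - 1) * (k - 1)
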