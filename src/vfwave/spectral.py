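"""Sliding-window amplitude spectra and AMSA for ventricular-fibrillation ECG.

AMSA (amplitude spectral area) summarises a VF segment's frequency content as
the summed product of one-sided spectral amplitude and frequency over the
2-48 Hz band, in mV.Hz.  The analysis convention implemented here is a
2.1-second Tukey-tapered frame advanced every 0.5 s, with the per-frame AMSA
values averaged over 60-second (one-minute) bins anchored at VF onset.

Amplitude normalisation uses the coherent gain of the taper (the sum of the
window coefficients), so that a unit-amplitude in-band sinusoid reads ~1 mV at
its bin and the mV.Hz unit of AMSA is literal.  Because AMSA is a summed (not
integrated) spectrum, its magnitude depends on the bin width fs/N; frames are
not zero-padded, so N = round(window_s * fs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy.signal import windows

__all__ = [
    "WaveformRecord",
    "SpectralConfig",
    "SpectralFrame",
    "AMSASeries",
    "WaveformTooShortError",
    "BandCoverageError",
    "extract_frames",
    "amplitude_spectrum",
    "compute_amsa",
    "flag_artifacts",
    "amsa_timeseries",
]

_EPS = 1e-9  # guards float jitter in duration / frame-count arithmetic


class WaveformTooShortError(ValueError):
    """Record shorter than one analysis window."""


class BandCoverageError(ValueError):
    """Spectral frame does not cover the requested frequency band."""


@dataclass(frozen=True)
class WaveformRecord:
    """A uniformly sampled single-channel VF voltage trace.

    Parameters
    ----------
    subject_id : str
        Opaque subject label.
    samples : ndarray
        Voltage samples in mV.
    fs : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample relative to VF onset, in seconds.
    """

    subject_id: str
    samples: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(samples)):
            idx = int(np.flatnonzero(~np.isfinite(samples))[0])
            raise ValueError(f"non-finite sample at index {idx}")

    @property
    def duration_s(self) -> float:
        """Record duration in seconds (n_samples / fs)."""
        return self.samples.size / self.fs

    def scaled(self, c: float) -> "WaveformRecord":
        """Return a copy with all samples multiplied by ``c``."""
        return replace(self, samples=self.samples * c)


@dataclass(frozen=True)
class SpectralConfig:
    """Parameters of the sliding-window spectral analysis.

    window_s
        Frame length in seconds (default 2.1).
    step_s
        Hop between successive frames in seconds (default 0.5).
    tukey_alpha
        Taper fraction of the Tukey window in [0, 1]; 0 is rectangular,
        1 is a Hann window (default 0.5).
    band_lo, band_hi
        AMSA band edges in Hz, inclusive at both ends (default 2-48 Hz).
    detrend
        Remove the frame mean before tapering (default True); prevents DC
        leakage into the lower band edge.
    """

    window_s: float = 2.1
    step_s: float = 0.5
    tukey_alpha: float = 0.5
    band_lo: float = 2.0
    band_hi: float = 48.0
    detrend: bool = True

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.step_s <= 0:
            raise ValueError("step_s must be positive")
        if not 0.0 <= self.tukey_alpha <= 1.0:
            raise ValueError("tukey_alpha must lie in [0, 1]")
        if not 0 < self.band_lo < self.band_hi:
            raise ValueError("band edges must satisfy 0 < band_lo < band_hi")

    def n_samples(self, fs: float) -> int:
        """Frame length in samples at sampling rate ``fs``."""
        return int(round(self.window_s * fs))


@dataclass(frozen=True)
class SpectralFrame:
    """One windowed segment's one-sided amplitude spectrum.

    ``freqs`` runs from DC to Nyquist; ``amplitudes`` are one-sided
    amplitudes in mV (coherent-gain normalised).  ``valid`` flags frames
    usable for AMSA (cleared by artifact detection).
    """

    center_time: float
    freqs: np.ndarray
    amplitudes: np.ndarray
    valid: bool = True

    def __post_init__(self) -> None:
        if len(self.freqs) != len(self.amplitudes):
            raise ValueError("freqs and amplitudes must have equal length")
        if np.any(np.diff(self.freqs) <= 0) or self.freqs[0] != 0:
            raise ValueError("freqs must start at 0 and be strictly increasing")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")


@dataclass
class AMSASeries:
    """AMSA trajectory for one subject: per-frame values and minute means.

    ``minute_index`` is 1-based from VF onset and lists only *complete*
    minutes (fully covered by the record); a minute mean is NaN if no valid
    frame center falls in it.  An incomplete trailing minute, if any, is
    reported separately and never averaged into the minute means.
    """

    subject_id: str
    frame_times: np.ndarray
    frame_amsa: np.ndarray
    frame_valid: np.ndarray
    minute_index: np.ndarray
    minute_amsa: np.ndarray
    config: SpectralConfig
    partial_minute: int | None = None
    partial_minute_amsa: float = float("nan")

    def minute_mean(self, minute: int) -> float:
        """Minute-mean AMSA (mV.Hz) for a 1-based minute index."""
        hit = np.flatnonzero(self.minute_index == minute)
        if hit.size == 0:
            raise KeyError(f"minute {minute} not covered by record")
        return float(self.minute_amsa[hit[0]])


def frame_count(duration_s: float, config: SpectralConfig) -> int:
    """Number of frames for a record of the given duration.

    count = floor((T - window_s) / step_s) + 1; raises if T < window_s.
    """
    if duration_s + _EPS < config.window_s:
        raise WaveformTooShortError(
            f"record of {duration_s:.3f} s is shorter than one "
            f"{config.window_s:.3f} s analysis window"
        )
    return int(np.floor((duration_s - config.window_s) / config.step_s + _EPS)) + 1


def _frame_starts(record: WaveformRecord, config: SpectralConfig) -> np.ndarray:
    n = frame_count(record.duration_s, config)
    return np.round(np.arange(n) * config.step_s * record.fs).astype(int)


def extract_frames(
    record: WaveformRecord, config: SpectralConfig | None = None
) -> Iterator[tuple[float, np.ndarray]]:
    """Yield ``(center_time, segment)`` for each analysis frame.

    Frame k covers samples in [t0 + k*step_s, t0 + k*step_s + window_s);
    center_time is the segment start plus window_s / 2.

    Raises
    ------
    WaveformTooShortError
        If the record is shorter than one window.
    """
    config = config or SpectralConfig()
    nwin = config.n_samples(record.fs)
    for start in _frame_starts(record, config):
        center = record.t0 + start / record.fs + config.window_s / 2.0
        yield center, record.samples[start : start + nwin]


def _taper(n: int, alpha: float) -> np.ndarray:
    return windows.tukey(n, alpha=alpha, sym=False)


def _one_sided_scale(n: int, coherent_gain: float) -> np.ndarray:
    """Per-bin factors turning |rfft| into one-sided amplitude."""
    n_bins = n // 2 + 1
    scale = np.full(n_bins, 2.0 / coherent_gain)
    scale[0] = 1.0 / coherent_gain
    if n % 2 == 0:  # Nyquist bin is not doubled
        scale[-1] = 1.0 / coherent_gain
    return scale


def amplitude_spectrum(
    segment: np.ndarray,
    fs: float,
    config: SpectralConfig | None = None,
    center_time: float = 0.0,
) -> SpectralFrame:
    """One-sided amplitude spectrum of a voltage segment.

    The segment is mean-removed (if ``config.detrend``), multiplied by a
    Tukey taper, and transformed by DFT.  Amplitudes are normalised by the
    taper's coherent gain (sum of window coefficients): an in-bin
    unit-amplitude sinusoid under a rectangular taper yields ~1 mV at its
    bin.  Bin spacing is fs / N with no zero padding.
    """
    config = config or SpectralConfig()
    x = np.asarray(segment, dtype=float)
    if x.size < 4:
        raise ValueError(f"segment too short for spectral analysis ({x.size} samples)")
    if not np.all(np.isfinite(x)):
        idx = int(np.flatnonzero(~np.isfinite(x))[0])
        raise ValueError(f"non-finite sample at index {idx}")
    if config.detrend:
        x = x - x.mean()
    w = _taper(x.size, config.tukey_alpha)
    spec = np.fft.rfft(x * w)
    amplitudes = np.abs(spec) * _one_sided_scale(x.size, w.sum())
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    return SpectralFrame(center_time=center_time, freqs=freqs, amplitudes=amplitudes)


def compute_amsa(frame: SpectralFrame, config: SpectralConfig | None = None) -> float:
    """AMSA of one spectral frame: sum of A_i * F_i over band_lo <= F_i <= band_hi.

    Both band edges are inclusive.  Raises :class:`BandCoverageError` if the
    frame's maximum frequency is below ``band_hi``.
    """
    config = config or SpectralConfig()
    if frame.freqs[-1] < config.band_hi - _EPS:
        raise BandCoverageError(
            f"frame covers only up to {frame.freqs[-1]:.2f} Hz; "
            f"band requires {config.band_hi:.2f} Hz"
        )
    in_band = (frame.freqs >= config.band_lo - _EPS) & (
        frame.freqs <= config.band_hi + _EPS
    )
    return float(np.sum(frame.amplitudes[in_band] * frame.freqs[in_band]))


def flag_artifacts(
    freqs: np.ndarray,
    amplitude_matrix: np.ndarray,
    ratio_threshold: float = 0.5,
    band_lo: float = 2.0,
) -> np.ndarray:
    """Validity mask for a stack of amplitude spectra (frames x bins).

    A frame is invalid when its sub-band amplitude fraction
    sum(A_i for F_i < band_lo) / sum(A_i) exceeds ``ratio_threshold`` --
    i.e. when slow pulsatile content (ECC/compression artifact) dominates.
    An all-zero frame has ratio 0 and is valid.
    """
    amps = np.atleast_2d(np.asarray(amplitude_matrix, dtype=float))
    sub = amps[:, freqs < band_lo].sum(axis=1)
    total = amps.sum(axis=1)
    ratio = np.divide(sub, total, out=np.zeros_like(sub), where=total > 0)
    return ratio <= ratio_threshold


def _batch_spectra(
    record: WaveformRecord, config: SpectralConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All frames' spectra at once: (center_times, freqs, amplitude_matrix).

    Vectorised equivalent of extract_frames + amplitude_spectrum per frame.
    """
    nwin = config.n_samples(record.fs)
    starts = _frame_starts(record, config)
    segs = record.samples[starts[:, None] + np.arange(nwin)[None, :]]
    if config.detrend:
        segs = segs - segs.mean(axis=1, keepdims=True)
    w = _taper(nwin, config.tukey_alpha)
    spec = np.fft.rfft(segs * w, axis=1)
    amps = np.abs(spec) * _one_sided_scale(nwin, w.sum())
    freqs = np.fft.rfftfreq(nwin, d=1.0 / record.fs)
    centers = record.t0 + starts / record.fs + config.window_s / 2.0
    return centers, freqs, amps


def amsa_timeseries(
    record: WaveformRecord,
    config: SpectralConfig | None = None,
    artifact_ratio_threshold: float = 0.5,
) -> AMSASeries:
    """Full AMSA trajectory of a record: per-frame AMSA and minute means.

    Minute bins are half-open [(m-1)*60, m*60) anchored at VF onset (t = 0),
    1-based.  Minute means average the AMSA of *valid* frames whose center
    time falls in the bin; only minutes fully covered by the record appear in
    ``minute_index`` (an incomplete trailing minute is reported separately).
    A covered minute with zero valid frames gets a NaN mean.
    """
    config = config or SpectralConfig()
    if config.band_hi > record.fs / 2.0 + _EPS:
        raise BandCoverageError(
            f"band_hi={config.band_hi} Hz exceeds Nyquist ({record.fs / 2:.1f} Hz)"
        )
    centers, freqs, amps = _batch_spectra(record, config)
    valid = flag_artifacts(freqs, amps, artifact_ratio_threshold, config.band_lo)
    in_band = (freqs >= config.band_lo - _EPS) & (freqs <= config.band_hi + _EPS)
    frame_amsa = amps[:, in_band] @ freqs[in_band]

    t_end = record.t0 + record.duration_s
    first = int(np.ceil(record.t0 / 60.0 - _EPS)) + 1
    last = int(np.floor(t_end / 60.0 + _EPS))
    minute_of_frame = np.floor(centers / 60.0 + _EPS).astype(int) + 1

    minutes = np.arange(first, last + 1)
    means = np.full(minutes.size, np.nan)
    for i, m in enumerate(minutes):
        sel = (minute_of_frame == m) & valid
        if sel.any():
            means[i] = frame_amsa[sel].mean()

    partial_minute: int | None = None
    partial_mean = float("nan")
    trailing = minute_of_frame > last
    if trailing.any():
        partial_minute = last + 1
        sel = trailing & valid
        if sel.any():
            partial_mean = float(frame_amsa[sel].mean())

    return AMSASeries(
        subject_id=record.subject_id,
        frame_times=centers,
        frame_amsa=frame_amsa,
        frame_valid=valid,
        minute_index=minutes,
        minute_amsa=means,
        config=config,
        partial_minute=partial_minute,
        partial_minute_amsa=partial_mean,
    )
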