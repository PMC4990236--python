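"""Synthetic VF-waveform cohorts with a prescribed AMSA time course.

The generator makes no claim to electrophysiological realism: a VF trace is
modelled as band-limited Gaussian noise (white noise band-pass filtered to
``center_freq +/- bandwidth/2``) whose amplitude envelope follows a
piecewise-linear interpolation between per-minute AMSA targets ("knots").
Because AMSA is linear in signal amplitude, one closed-loop gain calibration
against the spectral pipeline -- measured at the first knot's minute -- makes
the computed minute-mean AMSA track the whole profile.

The default profile reproduces the three-phase AMSA trajectory of VF arrest
followed by simulated resuscitation: decline during untreated VF (minutes
1-8), recovery to a plateau during low-flow extracorporeal circulation
(minutes 8-14), and a transient rise at minute 19 followed by rapid decline
to minute 22 during high-flow ECC and defibrillation attempts.

Between-subject spread is modelled as a persistent multiplicative lognormal
offset per subject, mimicking the intrinsic, subject-specific AMSA level that
makes early and late AMSA highly correlated across a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .spectral import SpectralConfig, WaveformRecord, amsa_timeseries

__all__ = [
    "VFProfile",
    "GeneratorSpec",
    "EccArtifact",
    "default_arrest_profile",
    "generate_vf",
    "generate_cohort",
    "inject_ecc_artifact",
]


@dataclass(frozen=True)
class VFProfile:
    """Target AMSA trajectory and spectral placement of the synthetic VF.

    knots
        ``(minute, target_amsa)`` pairs; minutes 1-based from VF onset,
        targets in mV.Hz.  The envelope is linear between knot minutes and
        flat beyond the first/last knot.
    center_freq, bandwidth
        Pass band of the carrier noise in Hz.  VF spectral content in swine
        and humans concentrates near 5-12 Hz; default 9 +/- 3 Hz.
    """

    knots: tuple[tuple[float, float], ...]
    center_freq: float = 9.0
    bandwidth: float = 6.0

    def __post_init__(self) -> None:
        knots = tuple((float(m), float(a)) for m, a in self.knots)
        object.__setattr__(self, "knots", knots)
        minutes = [m for m, _ in knots]
        if sorted(set(minutes)) != minutes:
            raise ValueError("knots must be sorted and unique by minute")
        if any(a <= 0 for _, a in knots):
            raise ValueError("target AMSA values must be positive")
        lo = self.center_freq - self.bandwidth / 2.0
        hi = self.center_freq + self.bandwidth / 2.0
        if not (2.0 < lo and hi < 48.0):
            raise ValueError(
                f"profile band {lo:.1f}-{hi:.1f} Hz must lie strictly inside (2, 48) Hz"
            )

    def envelope(self, t_s: np.ndarray) -> np.ndarray:
        """Target AMSA (mV.Hz) at times ``t_s``, knots placed at minute centers."""
        knot_t = np.array([(m - 0.5) * 60.0 for m, _ in self.knots])
        knot_a = np.array([a for _, a in self.knots])
        return np.interp(t_s, knot_t, knot_a)


@dataclass(frozen=True)
class EccArtifact:
    """Pulsatile sub-band artifact mimicking ECC/compression interference."""

    onset_s: float
    rate_hz: float
    relative_amplitude: float

    def __post_init__(self) -> None:
        if not 0 < self.rate_hz < 2.0:
            raise ValueError(
                f"artifact rate must be sub-band (0 < rate < 2 Hz), got {self.rate_hz}"
            )


@dataclass(frozen=True)
class GeneratorSpec:
    """Sampling, duration, randomness and cohort-spread parameters."""

    fs: float = 250.0
    duration_s: float = 1320.0  # 22 minutes: untreated VF + low-flow + high-flow ECC
    seed: int = 0
    subject_sigma: float = 0.25
    artifact: EccArtifact | None = None

    def __post_init__(self) -> None:
        if self.fs <= 2 * 48:
            raise ValueError("fs must exceed 96 Hz so the 2-48 Hz band is resolvable")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.subject_sigma < 0:
            raise ValueError("subject_sigma must be non-negative")


def default_arrest_profile() -> VFProfile:
    """Seven-knot AMSA profile of the VF / low-flow ECC / high-flow ECC course.

    Knots (minute: mV.Hz): 1: 11.9, 6: 6.9, 8: 7.0, 14: 12.8, 18: 11.9,
    19: 14.3, 22: 9.1 -- cohort means of the three experimental phases.
    """
    return VFProfile(
        knots=(
            (1, 11.9),
            (6, 6.9),
            (8, 7.0),
            (14, 12.8),
            (18, 11.9),
            (19, 14.3),
            (22, 9.1),
        )
    )


def _carrier_noise(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float
) -> np.ndarray:
    """Unit-ish band-limited Gaussian noise in [lo, hi] Hz."""
    white = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, white)


def _calibration_minute(profile: VFProfile) -> float:
    return profile.knots[0][0]


def generate_vf(
    profile: VFProfile,
    spec: GeneratorSpec,
    subject_id: str = "synthetic",
    config: SpectralConfig | None = None,
) -> WaveformRecord:
    """Generate one VF-like record whose minute-mean AMSA tracks ``profile``.

    The gain is calibrated closed-loop: the uncalibrated signal's minute-mean
    AMSA at the first knot's minute is measured with the spectral pipeline
    and the whole signal scaled so that minute hits its target.  Linearity of
    AMSA in amplitude then carries the calibration to every other minute.

    Identical (profile, spec, subject_id) inputs give identical samples.
    """
    config = config or SpectralConfig()
    n = int(round(spec.duration_s * spec.fs))
    rng = np.random.default_rng(spec.seed)
    lo = profile.center_freq - profile.bandwidth / 2.0
    hi = profile.center_freq + profile.bandwidth / 2.0
    carrier = _carrier_noise(rng, n, spec.fs, lo, hi)
    t = np.arange(n) / spec.fs
    raw = carrier * profile.envelope(t)
    record = WaveformRecord(subject_id=subject_id, samples=raw, fs=spec.fs)

    cal_minute = _calibration_minute(profile)
    cal_target = profile.knots[0][1]
    cal_end = min(cal_minute * 60.0, spec.duration_s)
    cal_rec = replace(record, samples=raw[: int(round(cal_end * spec.fs))])
    series = amsa_timeseries(cal_rec, config)
    try:
        measured = series.minute_mean(int(cal_minute))
    except KeyError:  # record shorter than the calibration minute
        measured = float(np.nanmean(series.frame_amsa[series.frame_valid]))
    if not np.isfinite(measured) or measured <= 0:
        raise RuntimeError("calibration failed: no valid AMSA in calibration minute")
    gain = cal_target / measured

    record = replace(record, samples=raw * gain)
    if spec.artifact is not None:
        record = inject_ecc_artifact(record, spec.artifact)
    return record


def generate_cohort(
    n_subjects: int,
    profile: VFProfile | None = None,
    spec: GeneratorSpec | None = None,
    config: SpectralConfig | None = None,
) -> tuple[list[WaveformRecord], pd.DataFrame]:
    """Generate a cohort with persistent per-subject multiplicative offsets.

    Subject j's record is the calibrated single-subject waveform (with its
    own noise seed) scaled by s_j = exp(eps_j), eps_j ~ N(0, subject_sigma^2),
    drawn once per subject and applied to the whole recording.  Returns the
    records and a table of (subject_id, seed, scale).
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    profile = profile or default_arrest_profile()
    spec = spec or GeneratorSpec()
    master = np.random.default_rng(spec.seed)
    # one stream for offsets, independent child seeds for each waveform
    eps = master.normal(0.0, spec.subject_sigma, size=n_subjects)
    scales = np.exp(eps) if spec.subject_sigma > 0 else np.ones(n_subjects)
    child_seeds = master.integers(0, 2**31 - 1, size=n_subjects)

    records: list[WaveformRecord] = []
    rows = []
    for j in range(n_subjects):
        sid = f"S{j + 1:02d}"
        sub_spec = replace(spec, seed=int(child_seeds[j]), artifact=None)
        rec = generate_vf(profile, sub_spec, subject_id=sid, config=config)
        rec = rec.scaled(float(scales[j]))
        if spec.artifact is not None:
            rec = inject_ecc_artifact(rec, spec.artifact)
        records.append(rec)
        rows.append({"subject_id": sid, "seed": int(child_seeds[j]), "scale": float(scales[j])})
    return records, pd.DataFrame(rows)


def inject_ecc_artifact(record: WaveformRecord, artifact: EccArtifact) -> WaveformRecord:
    """Add a smooth unipolar sub-band pulse train from ``onset_s`` onward.

    Pulses are Hann-shaped with 80% duty cycle at ``rate_hz``, peak amplitude
    ``relative_amplitude`` times the record's RMS.  The wide duty keeps the
    pulse energy concentrated below 2 Hz (at the pulse rate and its first
    harmonic) so the artifact stays sub-band, as the interference it models.
    Samples before the onset are unchanged.
    """
    if artifact.onset_s >= record.duration_s:
        raise ValueError(
            f"artifact onset {artifact.onset_s} s beyond record end "
            f"({record.duration_s:.1f} s)"
        )
    if artifact.relative_amplitude == 0:
        return record
    n = record.samples.size
    t = np.arange(n) / record.fs
    phase = (t - artifact.onset_s) * artifact.rate_hz  # pulse index + fraction
    frac = np.mod(phase, 1.0)
    duty = 0.8  # Hann pulse over 80% of each period; brief diastolic baseline
    pulse = np.where(frac < duty, np.sin(np.pi * frac / duty) ** 2, 0.0)
    pulse[t < artifact.onset_s] = 0.0
    rms = float(np.sqrt(np.mean(record.samples**2)))
    return replace(record, samples=record.samples + artifact.relative_amplitude * rms * pulse)
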