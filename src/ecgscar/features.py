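"""Per-lead ECG feature extraction from fiducial-annotated beats.

Each beat is reduced to 23 depolarization/repolarization descriptors of the
QRS complex, ST segment, T wave and TP segment; per-beat values are averaged
arithmetically over the beats of a lead, and the 12 per-lead vectors are
concatenated lead-major into a 276-dimensional ECG vector.

Conventions
-----------
* Indices are 0-based.  Segments are half-open ``[onset, offset)`` for
  membership/duration; peak indices are inclusive.  Windowed numerics
  (least-squares slopes, trapezoid integrals) use the closed index range
  ``[onset, offset]`` so that the shared boundary sample acts as the common
  trapezoid endpoint of adjacent segments.
* The per-beat baseline is the median of the TP segment; amplitudes are the
  sample value at the wave peak minus that baseline (positive above baseline).
* An absent Q or S wave (peak index ``None``) contributes amplitude 0 and does
  not move the QRS duration boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import find_peaks

from .registry import FEATURE_NAMES, LEADS, N_FEATURES, VECTOR_LENGTH

__all__ = [
    "FiducialBeat",
    "LeadFeatures",
    "extract_beat_features",
    "extract_lead_features",
    "extract_ecg_features",
    "fragmentation_count",
]

#: fragmentation extrema must deviate by at least this fraction of the
#: R amplitude to count (noise guard)
FRAGMENTATION_THRESHOLD = 0.05

#: T amplitudes below this (mV) count as an absent T wave: inversion sign 0
T_SIGN_EPS = 1e-6


def _t_sign(t_amp: float) -> float:
    return float(np.sign(t_amp)) if abs(t_amp) >= T_SIGN_EPS else 0.0


class FiducialError(ValueError):
    """Raised when a beat's fiducial annotation violates the ordering rules."""


@dataclass(frozen=True)
class FiducialBeat:
    """Sample indices of one beat's wave landmarks in one lead."""

    qrs_onset: int
    r_peak: int
    qrs_offset: int
    t_onset: int
    t_peak: int
    t_offset: int
    next_p_onset: int
    sampling_rate: float
    q_peak: int | None = None
    s_peak: int | None = None

    def validate(self, n_samples: int | None = None, label: str = "beat") -> None:
        if self.sampling_rate <= 0:
            raise FiducialError(f"{label}: sampling_rate must be positive")
        seq = [
            ("qrs_onset", self.qrs_onset),
            ("r_peak", self.r_peak),
            ("qrs_offset", self.qrs_offset),
        ]
        for name, idx in seq:
            if idx < 0:
                raise FiducialError(f"{label}: negative index for {name}")
        if not (self.qrs_onset < self.r_peak < self.qrs_offset):
            raise FiducialError(
                f"{label}: require qrs_onset < r_peak < qrs_offset, got "
                f"{self.qrs_onset}, {self.r_peak}, {self.qrs_offset}"
            )
        if not (self.qrs_offset <= self.t_onset < self.t_peak < self.t_offset):
            raise FiducialError(
                f"{label}: require qrs_offset <= t_onset < t_peak < t_offset, got "
                f"{self.qrs_offset}, {self.t_onset}, {self.t_peak}, {self.t_offset}"
            )
        if not (self.t_offset <= self.next_p_onset):
            raise FiducialError(f"{label}: require t_offset <= next_p_onset")
        if self.q_peak is not None and not (self.qrs_onset <= self.q_peak < self.r_peak):
            raise FiducialError(f"{label}: q_peak outside [qrs_onset, r_peak)")
        if self.s_peak is not None and not (self.r_peak < self.s_peak <= self.qrs_offset):
            raise FiducialError(f"{label}: s_peak outside (r_peak, qrs_offset]")
        if n_samples is not None and self.next_p_onset >= n_samples:
            raise FiducialError(f"{label}: fiducials exceed signal length {n_samples}")


@dataclass(frozen=True)
class LeadFeatures:
    """The 23 per-lead feature values in registry order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} feature values")

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(FEATURE_NAMES, self.values)}


def _lsq_slope(samples: np.ndarray, lo: int, hi: int, fs: float) -> float:
    """Least-squares slope (mV/s) over the closed index range [lo, hi]."""
    y = np.asarray(samples[lo : hi + 1], dtype=float)
    if y.size < 2:
        return 0.0
    t = np.arange(y.size) / fs
    t = t - t.mean()
    denom = float(t @ t)
    if denom == 0.0:
        return 0.0
    return float(t @ (y - y.mean()) / denom)


def _trapz(samples: np.ndarray, lo: int, hi: int, fs: float) -> float:
    """Trapezoid integral over the closed index range [lo, hi] in seconds."""
    if hi <= lo:
        return 0.0
    return float(np.trapezoid(samples[lo : hi + 1], dx=1.0 / fs))


def fragmentation_count(
    samples: np.ndarray,
    beat: FiducialBeat,
    threshold: float = FRAGMENTATION_THRESHOLD,
) -> int:
    """Number of extra local extrema strictly inside the QRS window.

    Local maxima and minima whose prominence is at least ``threshold`` times
    the absolute R amplitude are counted; the canonical deflections (the
    annotated Q, R, S peaks present in the beat) are subtracted.  A clean
    monophasic R therefore scores 0, an RSR' pattern scores 1, and
    sub-threshold ripple does not change the count.
    """
    v = np.asarray(samples, dtype=float)
    lo, hi = beat.qrs_onset, beat.qrs_offset
    if hi - lo < 3:
        return 0
    baseline = _baseline(v, beat)
    r_amp = abs(v[beat.r_peak] - baseline)
    prominence = threshold * r_amp if r_amp > 0 else None
    window = v[lo : hi + 1]
    kwargs = {"prominence": prominence} if prominence else {}
    n_extrema = len(find_peaks(window, **kwargs)[0]) + len(find_peaks(-window, **kwargs)[0])
    canonical = 1 + (beat.q_peak is not None) + (beat.s_peak is not None)
    return max(0, n_extrema - canonical)


def _baseline(v: np.ndarray, beat: FiducialBeat) -> float:
    tp = v[beat.t_offset : beat.next_p_onset + 1]
    if tp.size == 0:
        return float(v[beat.qrs_onset])
    return float(np.median(tp))


def extract_beat_features(samples: np.ndarray, beat: FiducialBeat) -> LeadFeatures:
    """Compute the 23 features of a single annotated beat."""
    v = np.asarray(samples, dtype=float)
    beat.validate(n_samples=v.size)
    fs = beat.sampling_rate
    base = _baseline(v, beat)
    w = v - base

    q_amp = float(w[beat.q_peak]) if beat.q_peak is not None else 0.0
    r_amp = float(w[beat.r_peak])
    s_amp = float(w[beat.s_peak]) if beat.s_peak is not None else 0.0
    t_amp = float(w[beat.t_peak])

    st_mid = (beat.qrs_offset + beat.t_onset) // 2
    vals = np.empty(N_FEATURES)
    vals[:] = (
        q_amp,
        r_amp,
        s_amp,
        (beat.qrs_offset - beat.qrs_onset) / fs,
        (beat.r_peak - beat.qrs_onset) / fs,
        (beat.qrs_offset - beat.r_peak) / fs,
        _lsq_slope(v, beat.qrs_onset, beat.r_peak, fs),
        _lsq_slope(v, beat.r_peak, beat.qrs_offset, fs),
        fragmentation_count(v, beat),
        _trapz(w**2, beat.qrs_onset, beat.qrs_offset, fs),
        _trapz(w, beat.qrs_onset, beat.qrs_offset, fs),
        (beat.t_onset - beat.qrs_offset) / fs,
        float(w[st_mid]),
        _lsq_slope(v, beat.qrs_offset, beat.t_onset, fs),
        t_amp,
        (beat.t_offset - beat.t_onset) / fs,
        _t_sign(t_amp),
        _lsq_slope(v, beat.t_onset, beat.t_peak, fs),
        _lsq_slope(v, beat.t_peak, beat.t_offset, fs),
        _trapz(w**2, beat.t_onset, beat.t_offset, fs),
        _trapz(w, beat.t_onset, beat.t_offset, fs),
        _lsq_slope(v, beat.t_offset, beat.next_p_onset, fs),
        (beat.next_p_onset - beat.t_offset) / fs,
    )
    return LeadFeatures(vals)


def extract_lead_features(
    samples: np.ndarray, beats: Sequence[FiducialBeat]
) -> LeadFeatures:
    """Average the per-beat features of one lead arithmetically over beats."""
    if len(beats) == 0:
        raise ValueError("at least one annotated beat is required")
    per_beat = []
    for i, beat in enumerate(beats):
        try:
            per_beat.append(extract_beat_features(samples, beat).values)
        except FiducialError as exc:
            raise FiducialError(f"beat {i}: {exc}") from None
    return LeadFeatures(np.mean(per_beat, axis=0))


def extract_ecg_features(
    lead_signals: Mapping[str, np.ndarray],
    lead_beats: Mapping[str, Sequence[FiducialBeat]],
) -> np.ndarray:
    """Concatenate the 12 per-lead feature vectors into the 276-dim ECG vector.

    ``lead_signals`` and ``lead_beats`` must cover exactly the 12 standard
    leads (I, II, III, aVR, aVL, aVF, V1-V6).
    """
    for name, mapping in (("signals", lead_signals), ("beats", lead_beats)):
        got = set(mapping)
        expected = set(LEADS)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise ValueError(
                f"lead {name} must cover exactly the 12 standard leads; "
                f"missing={missing}, unexpected={extra}"
            )
    blocks = [
        extract_lead_features(lead_signals[lead], lead_beats[lead]).values
        for lead in LEADS
    ]
    out = np.concatenate(blocks)
    assert out.shape == (VECTOR_LENGTH,)
    return out
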