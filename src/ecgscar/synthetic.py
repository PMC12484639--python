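"""Synthetic ECG data with known ground truth.

Two generators live here:

* :func:`generate_beat` builds a single-lead beat as a sum of Gaussian-shaped
  Q/R/S/T waves on a piecewise-smooth baseline (an ECGSYN-style morphology
  model), together with exact fiducial indices and the analytic values of all
  23 per-lead features.  Because wave amplitudes, supports and integrals of
  the continuous model are known, the feature extractor can be validated
  against closed-form / high-resolution-quadrature oracles.

* :func:`generate_cohort` builds a full cohort directly in the 276-dimensional
  feature space: latent patient clusters with a configurable separation,
  per-region scar labels at configured prevalences, planted scar effects on
  specific (lead, feature) pairs, and confounder structure coupling LV mass
  index to QRS energy in V4 and to scar burden through a Gaussian copula.

The cohort generator emulates the statistical structure the pipeline is built
to exploit — it does not simulate cardiac electrophysiology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from .features import FiducialBeat, LeadFeatures, _t_sign
from .registry import (
    FEATURE_NAMES,
    LEADS,
    N_FEATURES,
    VECTOR_COLUMNS,
    VECTOR_LENGTH,
    feature_index,
)

__all__ = [
    "WaveParams",
    "BeatShapeParams",
    "InvalidBeatParameters",
    "generate_beat",
    "default_beat_params",
    "random_beat_params",
    "ScarEffect",
    "CohortConfig",
    "CohortTruth",
    "generate_cohort",
    "REGIONS",
    "DEFAULT_SCAR_EFFECTS",
]

REGIONS: tuple[str, ...] = ("basal", "mid", "apical")

#: half-width of each wave's support in units of the Gaussian width
SUPPORT_SIGMAS = 3.0
#: ramp width (s) of the smooth ST plateau / TP ramp onsets
_RAMP_W = 0.004


class InvalidBeatParameters(ValueError):
    """Beat shape parameters violate ordering/support constraints."""


@dataclass(frozen=True)
class WaveParams:
    """One Gaussian wave: ``amplitude * exp(-(t-center)^2 / (2 width^2))``."""

    amplitude: float  # mV, signed; 0 means the wave is absent
    center: float     # s
    width: float      # s (Gaussian sigma)


@dataclass(frozen=True)
class BeatShapeParams:
    """Shape parameters of one synthetic beat on one lead."""

    q: WaveParams
    r: WaveParams
    s: WaveParams
    t: WaveParams
    st_level: float = 0.0       # mV offset of the ST plateau
    tp_slope: float = 0.0       # mV/s drift of the TP segment
    baseline: float = 0.0       # mV
    sampling_rate: float = 1000.0  # Hz
    beat_duration: float = 0.8     # s

    # --- derived continuous-time segment boundaries -------------------------
    @property
    def qrs_onset_time(self) -> float:
        return self.q.center - SUPPORT_SIGMAS * self.q.width

    @property
    def qrs_offset_time(self) -> float:
        return self.s.center + SUPPORT_SIGMAS * self.s.width

    @property
    def t_onset_time(self) -> float:
        return self.t.center - SUPPORT_SIGMAS * self.t.width

    @property
    def t_offset_time(self) -> float:
        return self.t.center + SUPPORT_SIGMAS * self.t.width

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise InvalidBeatParameters("sampling_rate must be positive")
        for name, wave in (("q", self.q), ("r", self.r), ("s", self.s), ("t", self.t)):
            if wave.width <= 0:
                raise InvalidBeatParameters(f"{name} wave width must be positive")
        if not (self.q.center < self.r.center < self.s.center < self.t.center):
            raise InvalidBeatParameters(
                "wave centers must be strictly ordered Q < R < S < T"
            )
        if self.qrs_onset_time < 0:
            raise InvalidBeatParameters("Q wave support starts before t=0")
        if self.qrs_offset_time > self.t_onset_time:
            raise InvalidBeatParameters(
                "overlapping wave supports: QRS support runs into the T wave"
            )
        if self.t_offset_time >= self.beat_duration:
            raise InvalidBeatParameters(
                "T wave support must end before beat_duration (no TP segment left)"
            )


def _model(params: BeatShapeParams, t: np.ndarray) -> np.ndarray:
    """Evaluate the continuous beat model at times ``t`` (s)."""
    t = np.asarray(t, dtype=float)
    y = np.full(t.shape, params.baseline, dtype=float)
    for wave in (params.q, params.r, params.s, params.t):
        if wave.amplitude != 0.0:
            y += wave.amplitude * np.exp(-0.5 * ((t - wave.center) / wave.width) ** 2)
    if params.st_level != 0.0:
        # smooth plateau spanning the ST segment
        y += params.st_level * (
            expit((t - params.qrs_offset_time) / _RAMP_W)
            - expit((t - params.t_onset_time) / _RAMP_W)
        )
    if params.tp_slope != 0.0:
        # smooth ramp starting at the T offset (softplus knee)
        y += params.tp_slope * _RAMP_W * np.logaddexp(
            0.0, (t - params.t_offset_time) / _RAMP_W
        )
    return y


def _fiducials(params: BeatShapeParams, n_samples: int) -> FiducialBeat:
    fs = params.sampling_rate

    def idx(time: float) -> int:
        return int(round(time * fs))

    return FiducialBeat(
        qrs_onset=idx(params.qrs_onset_time),
        q_peak=idx(params.q.center) if params.q.amplitude != 0.0 else None,
        r_peak=idx(params.r.center),
        s_peak=idx(params.s.center) if params.s.amplitude != 0.0 else None,
        qrs_offset=idx(params.qrs_offset_time),
        t_onset=idx(params.t_onset_time),
        t_peak=idx(params.t.center),
        t_offset=idx(params.t_offset_time),
        next_p_onset=n_samples - 1,
        sampling_rate=fs,
    )


def _polyfit_slope(t: np.ndarray, y: np.ndarray) -> float:
    if t.size < 2 or np.ptp(t) == 0.0:
        return 0.0
    return float(np.polyfit(t, y, 1)[0])


def _dense_extrema_count(y: np.ndarray, threshold: float) -> int:
    """Strict interior extrema of a densely sampled curve, swing-filtered.

    An extremum counts only if the signal swings by at least ``threshold`` on
    both sides (to the adjacent extrema or window edges) — a prominence-style
    criterion that ignores shallow ripple on an otherwise monotone stretch.
    """
    d = np.diff(y)
    sign = np.sign(d)
    nz = sign != 0
    s = sign[nz]
    turn = np.flatnonzero(s[1:] * s[:-1] < 0)
    if turn.size == 0:
        return 0
    idx_nz = np.flatnonzero(nz)
    extrema = [idx_nz[t] + 1 for t in turn]
    anchors = [0, *extrema, y.size - 1]
    count = 0
    for k in range(1, len(anchors) - 1):
        left = abs(y[anchors[k]] - y[anchors[k - 1]])
        right = abs(y[anchors[k]] - y[anchors[k + 1]])
        if min(left, right) >= threshold:
            count += 1
    return count


def _analytic_features(
    params: BeatShapeParams, beat: FiducialBeat, oversample: int = 16
) -> LeadFeatures:
    """Feature values of the continuous model, by definition not extraction.

    Durations come from the fiducial indices; amplitudes and the ST deviation
    are the model evaluated at the landmark times minus the baseline; energies
    and signed areas are high-resolution trapezoid quadrature of the model at
    ``oversample`` times the native rate; slopes are least-squares line fits of
    the model evaluated on the native sample times of each window.  The
    baseline is the median of the model over the native TP sample times (the
    extractor's definition, applied to the noise-free model).
    """
    fs = params.sampling_rate

    def tgrid(lo: int, hi: int) -> np.ndarray:
        return np.arange(lo, hi + 1) / fs

    def dense(lo: int, hi: int) -> np.ndarray:
        return np.linspace(lo / fs, hi / fs, (hi - lo) * oversample + 1)

    base = float(np.median(_model(params, tgrid(beat.t_offset, beat.next_p_onset))))

    def at(i: int) -> float:
        return float(_model(params, np.array([i / fs]))[0]) - base

    def quad(lo: int, hi: int, squared: bool) -> float:
        tt = dense(lo, hi)
        y = _model(params, tt) - base
        return float(np.trapezoid(y**2 if squared else y, tt))

    def slope(lo: int, hi: int) -> float:
        tt = tgrid(lo, hi)
        return _polyfit_slope(tt, _model(params, tt))

    q_amp = at(beat.q_peak) if beat.q_peak is not None else 0.0
    r_amp = at(beat.r_peak)
    s_amp = at(beat.s_peak) if beat.s_peak is not None else 0.0
    t_amp = at(beat.t_peak)

    # fragmentation of the continuous model: interior extrema beyond Q/R/S
    frag_grid = dense(beat.qrs_onset, beat.qrs_offset)
    frag_y = _model(params, frag_grid)
    thr = 0.05 * abs(r_amp)
    canonical = 1 + (beat.q_peak is not None) + (beat.s_peak is not None)
    frag = max(0, _dense_extrema_count(frag_y, thr) - canonical)

    st_mid = (beat.qrs_offset + beat.t_onset) // 2
    vals = np.array(
        [
            q_amp,
            r_amp,
            s_amp,
            (beat.qrs_offset - beat.qrs_onset) / fs,
            (beat.r_peak - beat.qrs_onset) / fs,
            (beat.qrs_offset - beat.r_peak) / fs,
            slope(beat.qrs_onset, beat.r_peak),
            slope(beat.r_peak, beat.qrs_offset),
            float(frag),
            quad(beat.qrs_onset, beat.qrs_offset, squared=True),
            quad(beat.qrs_onset, beat.qrs_offset, squared=False),
            (beat.t_onset - beat.qrs_offset) / fs,
            at(st_mid),
            slope(beat.qrs_offset, beat.t_onset),
            t_amp,
            (beat.t_offset - beat.t_onset) / fs,
            _t_sign(t_amp),
            slope(beat.t_onset, beat.t_peak),
            slope(beat.t_peak, beat.t_offset),
            quad(beat.t_onset, beat.t_offset, squared=True),
            quad(beat.t_onset, beat.t_offset, squared=False),
            slope(beat.t_offset, beat.next_p_onset),
            (beat.next_p_onset - beat.t_offset) / fs,
        ]
    )
    return LeadFeatures(vals)


def generate_beat(
    params: BeatShapeParams, noise_sd: float = 0.0, seed: int | None = None
) -> tuple[np.ndarray, FiducialBeat, LeadFeatures]:
    """Sample one synthetic beat.

    Returns the sampled waveform (mV), the exact fiducial annotation derived
    from the known wave supports, and the analytic values of all 23 features
    of the noise-free model.  ``noise_sd`` adds i.i.d. Gaussian noise to the
    samples only — the analytic features always refer to the clean model.
    """
    params.validate()
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    fs = params.sampling_rate
    n = int(round(params.beat_duration * fs))
    t = np.arange(n) / fs
    samples = _model(params, t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        samples = samples + rng.normal(0.0, noise_sd, size=n)
    beat = _fiducials(params, n)
    beat.validate(n_samples=n)
    return samples, beat, _analytic_features(params, beat)


def default_beat_params(**overrides) -> BeatShapeParams:
    """A typical upright sinus-beat morphology (on-grid wave centers at 1 kHz)."""
    params = BeatShapeParams(
        q=WaveParams(-0.10, 0.040, 0.008),
        r=WaveParams(1.00, 0.070, 0.012),
        s=WaveParams(-0.25, 0.100, 0.009),
        t=WaveParams(0.30, 0.320, 0.035),
    )
    return replace(params, **overrides)


def random_beat_params(rng: np.random.Generator) -> BeatShapeParams:
    """Random, valid beat morphology for extractor-vs-oracle sweeps.

    Amplitudes keep the conventional signs (Q, S non-positive; R positive) and
    the T amplitude stays away from zero so its sign is well defined.
    """
    q_amp = 0.0 if rng.random() < 0.2 else -rng.uniform(0.05, 0.4)
    s_amp = 0.0 if rng.random() < 0.2 else -rng.uniform(0.05, 0.8)
    t_amp = rng.uniform(0.1, 0.8) * (1 if rng.random() < 0.7 else -1)
    return BeatShapeParams(
        q=WaveParams(q_amp, rng.uniform(0.035, 0.05), rng.uniform(0.006, 0.010)),
        r=WaveParams(rng.uniform(0.4, 2.0), rng.uniform(0.065, 0.085), rng.uniform(0.010, 0.014)),
        s=WaveParams(s_amp, rng.uniform(0.10, 0.115), rng.uniform(0.007, 0.011)),
        t=WaveParams(t_amp, rng.uniform(0.30, 0.36), rng.uniform(0.025, 0.04)),
        st_level=rng.uniform(-0.1, 0.1),
        tp_slope=rng.uniform(-0.1, 0.1),
        baseline=rng.uniform(-0.2, 0.2),
    )


def generate_ecg_waveforms(
    seed: int = 0, n_beats: int = 3
) -> tuple[dict[str, np.ndarray], dict[str, list[FiducialBeat]]]:
    """A full annotated 12-lead synthetic ECG (waveforms + fiducials).

    Each lead gets its own random beat morphology repeated ``n_beats`` times;
    fiducial indices are shifted per beat.  Useful as an end-to-end input for
    the extraction front end.
    """
    rng = np.random.default_rng(seed)
    signals: dict[str, np.ndarray] = {}
    beats: dict[str, list[FiducialBeat]] = {}
    for lead in LEADS:
        params = random_beat_params(rng)
        samples, beat, _ = generate_beat(params)
        n = samples.size
        signals[lead] = np.tile(samples, n_beats)
        shifted = []
        for k in range(n_beats):
            off = k * n
            shifted.append(
                FiducialBeat(
                    qrs_onset=beat.qrs_onset + off,
                    q_peak=None if beat.q_peak is None else beat.q_peak + off,
                    r_peak=beat.r_peak + off,
                    s_peak=None if beat.s_peak is None else beat.s_peak + off,
                    qrs_offset=beat.qrs_offset + off,
                    t_onset=beat.t_onset + off,
                    t_peak=beat.t_peak + off,
                    t_offset=beat.t_offset + off,
                    next_p_onset=beat.next_p_onset + off,
                    sampling_rate=beat.sampling_rate,
                )
            )
        beats[lead] = shifted
    return signals, beats


# ---------------------------------------------------------------------------
# cohort generation in feature space
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScarEffect:
    """A planted regional scar signature: shift of one (lead, feature) column.

    ``effect_sd`` is the shift applied to scar-positive patients, in units of
    the within-cluster patient SD of that column.
    """

    region: str
    lead: str
    feature: str
    effect_sd: float


# Directions follow the regional ECG signatures of LV scar in hypertrophic
# cardiomyopathy: deeper Q waves and prolonged intrinsicoid deflection in
# aVR/I/V1 for basal scar; lateral-lead T amplitude loss (with reciprocal aVR
# gain) for mid scar; T-wave inversion across the chest leads V2-V6 with a
# more positive QRS area for apical scar.  Magnitudes are idealized (about
# 1.5-2 within-cluster SDs) so that planted signals are unambiguously
# recoverable; they are configuration, not clinical estimates.
DEFAULT_SCAR_EFFECTS: tuple[ScarEffect, ...] = (
    ScarEffect("basal", "aVR", "q_amplitude", -2.0),
    ScarEffect("basal", "I", "q_amplitude", -2.0),
    ScarEffect("basal", "V1", "q_amplitude", -2.0),
    ScarEffect("basal", "aVR", "qrs_nonterminal_duration", 1.5),
    ScarEffect("basal", "V1", "qrs_auc", 1.5),
    ScarEffect("mid", "V5", "t_amplitude", -2.0),
    ScarEffect("mid", "V6", "t_amplitude", -2.0),
    ScarEffect("mid", "aVL", "t_amplitude", -2.0),
    ScarEffect("mid", "aVR", "t_amplitude", 2.0),
    ScarEffect("mid", "V5", "t_energy", 1.5),
    ScarEffect("apical", "V2", "t_amplitude", -2.0),
    ScarEffect("apical", "V3", "t_amplitude", -2.0),
    ScarEffect("apical", "V4", "t_amplitude", -2.0),
    ScarEffect("apical", "V5", "t_amplitude", -2.0),
    ScarEffect("apical", "V6", "t_amplitude", -2.0),
    ScarEffect("apical", "V4", "qrs_auc", 1.5),
)


def _default_prevalence() -> dict[str, float]:
    return {"basal": 0.40, "mid": 0.38, "apical": 0.36}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the synthetic cohort.

    The latent patient clusters emulate heterogeneous ECG phenotypes.  Two
    aspects of scar are cluster-dependent, mirroring what makes recursive
    dominance-merging and per-group learning worthwhile on real cohorts:

    * ``cluster_scar_shift`` (cycled over clusters) offsets each cluster's
      scar prevalence from the cohort-level target, so some ECG-pattern
      clusters are scar-enriched or scar-depleted (class-dominated) while
      others stay balanced;
    * ``cluster_effect_sign`` (cycled) together with
      ``cluster_effect_modulation`` m sets how a planted effect appears in a
      cluster: the shift is multiplied by 1 in +1 clusters and by (1 - 2m)
      in -1 clusters, so at m = 1 the signature reverses direction and a
      single global model faces conflicting evidence.
    """

    n_patients: int = 600
    n_clusters: int = 3
    cluster_separation: float = 7.0          # Euclidean distance in within-SD units
    prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    scar_effect_map: tuple[ScarEffect, ...] = DEFAULT_SCAR_EFFECTS
    r_lvmi_qrs_energy: float = 0.6           # target Pearson r with V4 QRS energy
    r_lvmi_scar_burden: float = 0.4          # target Pearson r with scar burden
    ecgs_per_patient_mean: float = 3.0
    ecgs_per_patient_sd: float = 2.0
    ecg_noise_sd: float = 0.3                # ECG-level noise, within-SD units
    cluster_scar_shift: tuple[float, ...] = (0.35, -0.25, 0.0)
    cluster_effect_sign: tuple[int, ...] = (1, 1, -1)
    #: mixing proportions of the clusters (cycled/renormalized); the default
    #: weights the balanced, sign-reversed cluster so that the pooled
    #: scar-vs-noscar marginal shift of the planted features roughly cancels
    cluster_weights: tuple[float, ...] | None = (0.25, 0.25, 0.50)
    cluster_effect_modulation: float = 1.0   # 0: same effect everywhere; 1: sign flips
    burden_label_coupling: float = 0.8       # corr of regional label latents w/ burden
    lvmi_log_mean: float = math.log(95.0)    # g/m^2 median
    lvmi_log_sd: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_clusters < 1:
            raise ValueError("n_patients and n_clusters must be >= 1")
        if set(self.prevalence) != set(REGIONS):
            raise ValueError(f"prevalence must cover exactly the regions {REGIONS}")
        for region, p in self.prevalence.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"prevalence for {region} must be in (0, 1)")
        for r in (self.r_lvmi_qrs_energy, self.r_lvmi_scar_burden):
            if not abs(r) < 1.0:
                raise ValueError("correlation targets must satisfy |r| < 1")
        if not 0.0 <= self.cluster_effect_modulation <= 1.0:
            raise ValueError("cluster_effect_modulation must be in [0, 1]")
        if not self.cluster_scar_shift or not self.cluster_effect_sign:
            raise ValueError("cluster_scar_shift and cluster_effect_sign must be nonempty")
        if any(s not in (-1, 1) for s in self.cluster_effect_sign):
            raise ValueError("cluster_effect_sign entries must be +1 or -1")
        if self.cluster_weights is not None and (
            not self.cluster_weights or any(w <= 0 for w in self.cluster_weights)
        ):
            raise ValueError("cluster_weights must be positive")
        if self.cluster_separation < 0:
            raise ValueError("cluster_separation must be non-negative")
        for eff in self.scar_effect_map:
            if eff.region not in REGIONS:
                raise ValueError(f"unknown region {eff.region!r} in scar_effect_map")
            feature_index(eff.lead, eff.feature)  # raises on unknown pair


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth planted by :func:`generate_cohort` (per patient)."""

    cluster_id: np.ndarray
    cluster_sign: np.ndarray      # +1/-1 modulation sign of each patient's cluster
    scar_burden: np.ndarray       # fraction of LV mass, in [0, 1]
    effects: tuple[ScarEffect, ...]


#: column whose coupling to LVMI is planted (excluded from cluster offsets)
_ENERGY_COL = "V4_qrs_energy"
_ENERGY_MEAN, _ENERGY_SCALE = 15.0, 5.0


def _cluster_means(
    rng: np.random.Generator, k: int, separation: float, excluded: np.ndarray
) -> np.ndarray:
    if k == 1:
        return np.zeros((1, VECTOR_LENGTH))
    g = rng.normal(size=(k, VECTOR_LENGTH))
    g -= g.mean(axis=0, keepdims=True)
    g[:, excluded] = 0.0
    dists = [
        np.linalg.norm(g[i] - g[j]) for i in range(k) for j in range(i + 1, k)
    ]
    dmin = min(dists)
    if dmin == 0.0:
        raise RuntimeError("degenerate cluster means")
    return g * (separation / dmin)


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, CohortTruth]:
    """Generate a synthetic cohort as a feature table (one row per ECG).

    The returned DataFrame has columns ``ecg_id``, ``patient_id``, the 276
    lead-major feature columns, ``lvmi``, ``age``, ``sex`` and the three
    regional labels ``label_basal``/``label_mid``/``label_apical``.  The
    accompanying :class:`CohortTruth` records the planted per-patient cluster
    memberships and scar burden.

    Correlation targets are de-attenuated analytically for the log-normal
    LVMI marginal and the ECG-level noise so that the empirical Pearson r on
    the generated table lands near the configured values.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    # latent confounder structure (Gaussian copula)
    g = rng.normal(size=n)
    lvmi = np.exp(config.lvmi_log_mean + config.lvmi_log_sd * g)
    age = np.clip(rng.normal(52.0, 13.0, size=n), 20.0, 85.0)
    sex = rng.integers(0, 2, size=n)

    # de-attenuation: corr(exp(s*g), g) = s / sqrt(expm1(s^2))
    s = config.lvmi_log_sd
    lognorm_att = s / math.sqrt(math.expm1(s * s))
    noise_att = 1.0 / math.sqrt(1.0 + config.ecg_noise_sd**2)
    rho_e = config.r_lvmi_qrs_energy / (lognorm_att * noise_att)
    rho_b = config.r_lvmi_scar_burden / (lognorm_att * math.sqrt(3.0 / math.pi))
    for name, rho in (("QRS-energy", rho_e), ("scar-burden", rho_b)):
        if abs(rho) >= 1.0:
            raise ValueError(f"infeasible {name} correlation target after de-attenuation")

    burden_latent = rho_b * g + math.sqrt(1.0 - rho_b**2) * rng.normal(size=n)
    burden = ndtr(burden_latent)

    # cluster structure; the planted-correlation column and the derived
    # T-inversion indicator columns carry no cluster offset
    t_inv_cols = np.array(
        [feature_index(lead, "t_inversion") for lead in LEADS]
    )
    energy_col = feature_index(*_ENERGY_COL.split("_", 1))
    excluded = np.concatenate([[energy_col], t_inv_cols])
    means = _cluster_means(rng, config.n_clusters, config.cluster_separation, excluded)
    if config.cluster_weights is None:
        cluster_id = rng.integers(0, config.n_clusters, size=n)
    else:
        w = np.array(
            [config.cluster_weights[k % len(config.cluster_weights)]
             for k in range(config.n_clusters)],
            dtype=float,
        )
        cluster_id = rng.choice(config.n_clusters, size=n, p=w / w.sum())
    n_shift = len(config.cluster_scar_shift)
    shift_of_patient = np.array(
        [config.cluster_scar_shift[k % n_shift] for k in cluster_id]
    )
    n_sign = len(config.cluster_effect_sign)
    cluster_sign = np.array(
        [float(config.cluster_effect_sign[k % n_sign]) for k in cluster_id]
    )

    # regional labels coupled to burden; per-cluster prevalence is the
    # cohort-level target offset by the cluster's scar shift
    alpha = config.burden_label_coupling
    labels = {}
    for region in REGIONS:
        z = alpha * burden_latent + math.sqrt(1.0 - alpha**2) * rng.normal(size=n)
        p_k = np.clip(config.prevalence[region] + shift_of_patient, 0.02, 0.98)
        labels[region] = (z >= ndtri(1.0 - p_k)).astype(int)

    base_mean = np.zeros(VECTOR_LENGTH)
    t_amp_cols = np.array([feature_index(lead, "t_amplitude") for lead in LEADS])
    base_mean[t_amp_cols] = 1.0  # upright T waves by default

    X = base_mean + means[cluster_id] + rng.normal(size=(n, VECTOR_LENGTH))
    X[:, energy_col] = _ENERGY_MEAN + _ENERGY_SCALE * (
        rho_e * g + math.sqrt(1.0 - rho_e**2) * rng.normal(size=n)
    )

    col_scale = np.ones(VECTOR_LENGTH)
    col_scale[energy_col] = _ENERGY_SCALE

    # planted regional effects, optionally sign-modulated by cluster
    m = config.cluster_effect_modulation
    patient_factor = np.where(cluster_sign > 0, 1.0, 1.0 - 2.0 * m)
    for eff in config.scar_effect_map:
        col = feature_index(eff.lead, eff.feature)
        mask = labels[eff.region].astype(bool)
        X[mask, col] += eff.effect_sd * col_scale[col] * patient_factor[mask]

    # replicate into ECG rows with per-ECG noise
    n_ecgs = np.clip(
        np.rint(rng.normal(config.ecgs_per_patient_mean, config.ecgs_per_patient_sd, size=n)),
        1,
        None,
    ).astype(int)
    pat_idx = np.repeat(np.arange(n), n_ecgs)
    rows = X[pat_idx] + rng.normal(size=(pat_idx.size, VECTOR_LENGTH)) * (
        config.ecg_noise_sd * col_scale
    )
    rows[:, t_inv_cols] = np.sign(rows[:, t_amp_cols])

    df = pd.DataFrame(rows, columns=list(VECTOR_COLUMNS))
    df.insert(0, "patient_id", pat_idx)
    df.insert(0, "ecg_id", np.arange(pat_idx.size))
    df["lvmi"] = lvmi[pat_idx]
    df["age"] = age[pat_idx]
    df["sex"] = sex[pat_idx]
    for region in REGIONS:
        df[f"label_{region}"] = labels[region][pat_idx]

    truth = CohortTruth(
        cluster_id=cluster_id,
        cluster_sign=cluster_sign,
        scar_burden=burden,
        effects=tuple(config.scar_effect_map),
    )
    return df, truth
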