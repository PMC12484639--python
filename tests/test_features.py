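"""Feature extraction: registry layout, per-beat definitions, invariances."""

import numpy as np
import pytest

from ecgscar.features import (
    FiducialBeat,
    FiducialError,
    extract_beat_features,
    extract_ecg_features,
    extract_lead_features,
    fragmentation_count,
)
from ecgscar.registry import (
    FEATURE_NAMES,
    LEADS,
    VECTOR_COLUMNS,
    VECTOR_LENGTH,
    feature_index,
)
from ecgscar.synthetic import (
    WaveParams,
    default_beat_params,
    generate_beat,
    random_beat_params,
)


def simple_beat(fs=1000.0, n=800):
    return FiducialBeat(
        qrs_onset=20, q_peak=40, r_peak=70, s_peak=100, qrs_offset=130,
        t_onset=220, t_peak=320, t_offset=420, next_p_onset=n - 1,
        sampling_rate=fs,
    )


def test_registry_is_bijective_and_276_long():
    assert len(FEATURE_NAMES) == 23
    assert len(VECTOR_COLUMNS) == VECTOR_LENGTH == 276
    assert len(set(VECTOR_COLUMNS)) == 276
    assert feature_index("I", "q_amplitude") == 0
    assert feature_index("V6", "tp_duration") == 275
    with pytest.raises(KeyError):
        feature_index("V7", "q_amplitude")


def test_flat_zero_signal_yields_zero_features_and_fiducial_durations():
    beat = simple_beat()
    feats = extract_beat_features(np.zeros(800), beat).as_dict()
    assert feats["q_amplitude"] == feats["r_amplitude"] == feats["t_amplitude"] == 0.0
    assert feats["qrs_energy"] == feats["t_auc"] == 0.0
    assert feats["qrs_duration"] == pytest.approx(0.110)
    assert feats["st_duration"] == pytest.approx(0.090)
    assert feats["t_duration"] == pytest.approx(0.200)


def test_beat_features_average_arithmetically_across_beats():
    """Two beats with T amplitudes 0.2 and 0.6 mV average to 0.4 mV."""
    p1 = default_beat_params(t=WaveParams(0.2, 0.320, 0.035))
    p2 = default_beat_params(t=WaveParams(0.6, 0.320, 0.035))
    s1, b1, _ = generate_beat(p1)
    s2, b2, _ = generate_beat(p2)
    samples = np.concatenate([s1, s2])
    n = s1.size
    b2s = FiducialBeat(
        qrs_onset=b2.qrs_onset + n, q_peak=b2.q_peak + n, r_peak=b2.r_peak + n,
        s_peak=b2.s_peak + n, qrs_offset=b2.qrs_offset + n, t_onset=b2.t_onset + n,
        t_peak=b2.t_peak + n, t_offset=b2.t_offset + n,
        next_p_onset=b2.next_p_onset + n, sampling_rate=b2.sampling_rate,
    )
    lead = extract_lead_features(samples, [b1, b2s])
    assert lead["t_amplitude"] == pytest.approx(0.4, abs=1e-3)


def test_qrs_duration_partition_is_exact():
    rng = np.random.default_rng(7)
    for _ in range(10):
        samples, beat, _ = generate_beat(random_beat_params(rng), noise_sd=0.02, seed=1)
        f = extract_beat_features(samples, beat).as_dict()
        assert f["qrs_nonterminal_duration"] + f["qrs_terminal_duration"] == pytest.approx(
            f["qrs_duration"], abs=1e-12
        )


def test_amplitude_scaling_covariance():
    """Scaling samples by k scales amplitudes/slopes/AUC by k, energy by k^2,
    and leaves durations and fragmentation unchanged."""
    samples, beat, _ = generate_beat(default_beat_params(st_level=0.05, tp_slope=0.08))
    k = 3.7
    f1 = extract_beat_features(samples, beat).values
    f2 = extract_beat_features(k * samples, beat).values
    names = list(FEATURE_NAMES)
    linear = ["q_amplitude", "r_amplitude", "s_amplitude", "r_upstroke_slope",
              "r_downstroke_slope", "qrs_auc", "st_deviation", "st_slope",
              "t_amplitude", "t_upslope", "t_downslope", "t_auc", "tp_slope"]
    quadratic = ["qrs_energy", "t_energy"]
    invariant = ["qrs_duration", "qrs_nonterminal_duration", "qrs_terminal_duration",
                 "qrs_fragmentation", "st_duration", "t_duration", "t_inversion",
                 "tp_duration"]
    for name in linear:
        i = names.index(name)
        assert f2[i] == pytest.approx(k * f1[i], rel=1e-9, abs=1e-12)
    for name in quadratic:
        i = names.index(name)
        assert f2[i] == pytest.approx(k**2 * f1[i], rel=1e-9)
    for name in invariant:
        i = names.index(name)
        assert f2[i] == f1[i]


def test_time_resampling_changes_features_below_one_percent():
    """Doubling the sampling rate (fiducial indices rescaled x2) leaves every
    feature within 1% on smooth synthetic beats."""
    import dataclasses

    rng = np.random.default_rng(11)
    params = random_beat_params(rng)
    s1, b1, _ = generate_beat(params)
    params2 = dataclasses.replace(params, sampling_rate=2000.0)
    s2, _, _ = generate_beat(params2)
    b2 = FiducialBeat(
        qrs_onset=2 * b1.qrs_onset,
        q_peak=None if b1.q_peak is None else 2 * b1.q_peak,
        r_peak=2 * b1.r_peak,
        s_peak=None if b1.s_peak is None else 2 * b1.s_peak,
        qrs_offset=2 * b1.qrs_offset,
        t_onset=2 * b1.t_onset,
        t_peak=2 * b1.t_peak,
        t_offset=2 * b1.t_offset,
        next_p_onset=2 * b1.next_p_onset,
        sampling_rate=2000.0,
    )
    f1 = extract_beat_features(s1, b1).values
    f2 = extract_beat_features(s2, b2).values
    # relative floors by unit: slopes in mV/s live on a ~100 mV/s scale, so a
    # near-zero ST/TP slope is held to an absolute, not relative, standard
    floors = np.full(f1.size, 1e-2)
    slope_idx = [FEATURE_NAMES.index(n) for n in
                 ("r_upstroke_slope", "r_downstroke_slope", "st_slope",
                  "t_upslope", "t_downslope", "tp_slope")]
    floors[slope_idx] = 0.1
    rel = np.abs(f2 - f1) / np.maximum(np.abs(f1), floors)
    assert rel.max() < 0.01


class TestFragmentation:
    fs = 1000.0

    def _beat(self, n):
        return FiducialBeat(
            qrs_onset=10, r_peak=40, s_peak=55, qrs_offset=90,
            t_onset=150, t_peak=200, t_offset=250, next_p_onset=n - 1,
            sampling_rate=self.fs,
        )

    @staticmethod
    def _bump(t, a, c, w=0.004):
        return a * np.exp(-0.5 * ((t - c) / w) ** 2)

    def test_monophasic_r_wave_scores_zero(self):
        t = np.arange(400) / self.fs
        v = self._bump(t, 1.0, 0.040, 0.008)
        beat = FiducialBeat(qrs_onset=10, r_peak=40, qrs_offset=90, t_onset=150,
                            t_peak=200, t_offset=250, next_p_onset=399,
                            sampling_rate=self.fs)
        assert fragmentation_count(v, beat) == 0

    def test_rsr_prime_counts_one_extra_extremum(self):
        t = np.arange(400) / self.fs
        v = (self._bump(t, 1.0, 0.040) + self._bump(t, -0.3, 0.055)
             + self._bump(t, 1.0, 0.070))
        assert fragmentation_count(v, self._beat(400)) == 1

    def test_subthreshold_ripple_does_not_change_count(self):
        t = np.arange(400) / self.fs
        base = (self._bump(t, 1.0, 0.040) + self._bump(t, -0.3, 0.055)
                + self._bump(t, 1.0, 0.070))
        ripple = 0.01 * np.sin(2 * np.pi * 300 * t)
        beat = self._beat(400)
        assert fragmentation_count(base + ripple, beat) == fragmentation_count(base, beat)


class TestEcgVector:
    def _ecg(self, seed=0):
        from ecgscar.synthetic import generate_ecg_waveforms

        return generate_ecg_waveforms(seed=seed, n_beats=2)

    def test_vector_has_length_276_in_lead_major_order(self):
        signals, beats = self._ecg()
        vec = extract_ecg_features(signals, beats)
        assert vec.shape == (276,)
        lead_i = extract_lead_features(signals["I"], beats["I"]).values
        assert np.array_equal(vec[:23], lead_i)

    def test_identical_leads_give_identical_blocks(self):
        signals, beats = self._ecg()
        same_sig = {lead: signals["V1"] for lead in LEADS}
        same_beats = {lead: beats["V1"] for lead in LEADS}
        vec = extract_ecg_features(same_sig, same_beats)
        blocks = vec.reshape(12, 23)
        assert np.allclose(blocks, blocks[0])

    def test_beat_order_does_not_matter(self):
        signals, beats = self._ecg()
        flipped = {lead: list(reversed(b)) for lead, b in beats.items()}
        assert np.array_equal(
            extract_ecg_features(signals, beats),
            extract_ecg_features(signals, flipped),
        )

    def test_missing_lead_raises_with_lead_names(self):
        signals, beats = self._ecg()
        del signals["V3"]
        with pytest.raises(ValueError, match="V3"):
            extract_ecg_features(signals, beats)


def test_no_beats_raises():
    with pytest.raises(ValueError, match="at least one"):
        extract_lead_features(np.zeros(100), [])


def test_fiducial_ordering_violation_names_the_beat():
    bad = FiducialBeat(qrs_onset=50, r_peak=40, qrs_offset=90, t_onset=150,
                       t_peak=200, t_offset=250, next_p_onset=399, sampling_rate=1000)
    with pytest.raises(FiducialError, match="beat 0"):
        extract_lead_features(np.zeros(400), [bad])
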