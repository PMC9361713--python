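"""Protocol generator and signal synthesis: arithmetic, spectra, SNR control."""

import numpy as np
import pytest
from scipy import signal as sps

from emgclean import SynthParams, generate_protocol, mix, synthesize_eeg, synthesize_emg
from emgclean.synth import NEUTRAL_GAP_S, DurationClass, EyeCondition, Muscle


class TestProtocol:
    def test_event_count_per_participant(self):
        tl = generate_protocol(1, seed=1)
        assert len(tl.events) == 150

    def test_total_contaminated_duration_ten_participants(self):
        tl = generate_protocol(10, seed=1)
        assert tl.total_contaminated_s == pytest.approx(2250.0)

    def test_per_muscle_per_condition_composition(self):
        tl = generate_protocol(1, seed=3)
        for muscle in Muscle:
            for cond in EyeCondition:
                block = [
                    e for e in tl.events
                    if e.muscle is muscle and e.eye_condition is cond
                ]
                assert len(block) == 15
                durations = sorted(e.duration_s for e in block)
                assert durations == [0.5] * 5 + [1.0] * 5 + [3.0] * 5
                assert sum(durations) == pytest.approx(22.5)

    def test_events_separated_by_neutral_gap(self):
        tl = generate_protocol(2, seed=4)
        for a, b in zip(tl.events, tl.events[1:]):
            assert b.onset_s - a.end_s >= NEUTRAL_GAP_S - 1e-9

    def test_duration_order_is_seeded_permutation(self):
        a = generate_protocol(1, seed=5)
        b = generate_protocol(1, seed=5)
        c = generate_protocol(1, seed=6)
        assert [e.duration_class for e in a.events] == [e.duration_class for e in b.events]
        assert [e.duration_class for e in a.events] != [e.duration_class for e in c.events]

    def test_rejects_nonpositive_participants(self):
        with pytest.raises(ValueError):
            generate_protocol(0, seed=1)


@pytest.fixture(scope="module")
def short_timeline():
    return generate_protocol(1, seed=7, fs=1000, muscles=[Muscle.MASSETER])


class TestEEG:

    def test_alpha_gain_identity_when_one(self, short_timeline):
        p = SynthParams(
            fs=1000, alpha_closed_gain=1.0, seed=8,
            eeg_band_powers={"Alpha": 16.0},
        )
        x = synthesize_eeg(short_timeline, p)
        ratio = _alpha_var_ratio(x, short_timeline)
        assert ratio == pytest.approx(1.0, rel=0.15)

    def test_alpha_gain_four_reflected_in_band_variance(self, short_timeline):
        # alpha-only configuration isolates the band from spectral leakage
        p = SynthParams(
            fs=1000, alpha_closed_gain=4.0, seed=8,
            eeg_band_powers={"Alpha": 16.0},
        )
        x = synthesize_eeg(short_timeline, p)
        ratio = _alpha_var_ratio(x, short_timeline)
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_fixed_seed_reproducible(self, short_timeline):
        p = SynthParams(fs=1000, seed=9)
        a = synthesize_eeg(short_timeline, p)
        b = synthesize_eeg(short_timeline, p)
        np.testing.assert_array_equal(a.samples, b.samples)


def _alpha_var_ratio(x, timeline):
    sos = sps.butter(4, [7, 13], btype="bandpass", fs=x.fs, output="sos")
    a = sps.sosfiltfilt(sos, x.samples)
    (start, end), = timeline.closed_eyes_intervals()
    i0, i1 = int(start * x.fs), int(min(end, x.duration) * x.fs)
    return a[i0:i1].var() / a[:i0].var()


class TestEMG:
    def test_mask_marks_exactly_the_events(self, muscle_block):
        mask = muscle_block["mask"]
        tl = muscle_block["timeline"]
        assert len(mask.intervals) == len(tl.events)
        assert mask.n_high / mask.fs == pytest.approx(tl.total_contaminated_s, abs=0.1)

    def test_burst_spectral_centroid_inside_emg_band(self, muscle_block):
        emg, mask = muscle_block["emg"], muscle_block["mask"]
        lo, hi = muscle_block["params"].emg_band
        f, p = sps.periodogram(mask.high_samples_of(emg.samples), emg.fs)
        centroid = (f * p).sum() / p.sum()
        assert lo < centroid < hi

    def test_baseline_far_below_burst_level(self, muscle_block):
        emg, mask = muscle_block["emg"], muscle_block["mask"]
        burst_rms = mask.high_samples_of(emg.samples).std()
        base_rms = mask.low_samples_of(emg.samples).std()
        assert 20 * np.log10(base_rms / burst_rms) < -30


class TestMix:
    @pytest.mark.parametrize("snr_db", [0.0, -10.0, -20.0])
    def test_requested_in_burst_snr_achieved(self, muscle_block, snr_db):
        eeg, emg, mask = muscle_block["eeg"], muscle_block["emg"], muscle_block["mask"]
        mixture = mix(eeg, emg, mask, snr_db)
        scaled_emg = mixture.samples - eeg.samples
        p_eeg = np.mean(mask.high_samples_of(eeg.samples) ** 2)
        p_emg = np.mean(mask.high_samples_of(scaled_emg) ** 2)
        assert 10 * np.log10(p_eeg / p_emg) == pytest.approx(snr_db, abs=0.1)

    def test_empty_mask_is_degenerate(self, muscle_block):
        from emgclean import ContaminationMask

        eeg, emg = muscle_block["eeg"], muscle_block["emg"]
        empty = ContaminationMask(np.zeros(eeg.n, dtype=bool), eeg.fs)
        with pytest.raises(ValueError):
            mix(eeg, emg, empty, -10.0)
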