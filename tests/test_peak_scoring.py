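import numpy as np
import pytest
from hypothesis import given, strategies as st

from cvemp.containers import NormalizedSequence, ParticipantRecord
from cvemp.exceptions import ProtocolError
from cvemp.peak_scoring import (
    Extremum, find_extrema, identify_n1_anchored, identify_n1_initial,
    pick_participant, pick_sequence, score_peaks,
)
from cvemp.synthetic_data import vemp_template

from _oracle import oracle_pick

FS = 3000.0
ONSET = 54
N_SAMPLES = 204


def _nseq(waveform, order=0, level=40.0):
    return NormalizedSequence("P1", "F", level, FS, ONSET,
                              np.asarray(waveform, float), sequence_order=order)


def _bump(center_ms, height, width_ms=2.0):
    """A smooth positive bump (negative height for a dip) on the epoch grid."""
    t = (np.arange(N_SAMPLES) - ONSET) * 1000.0 / FS
    return height * np.exp(-0.5 * ((t - center_ms) / width_ms) ** 2)


class TestFindExtrema:
    def test_single_triangular_bump(self):
        x = np.zeros(31)
        x[10:21] = np.concatenate([np.arange(6), np.arange(4, -1, -1)]) * 2.0
        ext = find_extrema(x, FS, onset_index=0)
        peaks = [e for e in ext if e.kind == "peak"]
        assert len(peaks) == 1
        assert peaks[0].prominence == pytest.approx(10.0)

    def test_two_bump_saddle_prominences(self):
        # heights 10 and 6 with a saddle at 2 on a zero baseline:
        # taller peak has prominence 10, smaller one 6 - 2 = 4
        x = np.concatenate([
            np.linspace(0, 10, 10), np.linspace(10, 2, 8),
            np.linspace(2, 6, 6), np.linspace(6, 0, 10)])
        peaks = [e for e in find_extrema(x, FS, 0) if e.kind == "peak"]
        assert sorted(round(p.prominence, 6) for p in peaks) == [4.0, 10.0]

    def test_monotone_ramp_has_no_extrema(self):
        assert find_extrema(np.linspace(0, 1, 50), FS, 0) == []

    def test_flat_trace_empty(self):
        assert find_extrema(np.zeros(50), FS, 0) == []

    def test_troughs_reported_with_signed_value(self):
        x = -_bump(25.0, 5.0)
        troughs = [e for e in find_extrema(x, FS, ONSET) if e.kind == "trough"]
        assert len(troughs) == 1
        assert troughs[0].value == pytest.approx(-5.0, rel=1e-3)
        assert troughs[0].prominence == pytest.approx(5.0, rel=1e-3)

    def test_matches_brute_force_prominence(self, rng):
        from _oracle import local_maxima, prominence
        for _ in range(25):
            x = np.cumsum(rng.normal(size=120))
            peaks = {round(e.latency, 6): e.prominence
                     for e in find_extrema(x, FS, 0) if e.kind == "peak"}
            for i in local_maxima(x):
                lat = round(i * 1000.0 / FS, 6)
                assert lat in peaks
                assert peaks[lat] == pytest.approx(prominence(list(x), i))


class TestIdentifyN1:
    def test_template_trough_recovered(self):
        wave = np.zeros(N_SAMPLES)
        wave[ONSET:] = vemp_template(15.0, 25.0, 10.0, FS, 50.0)
        n1 = identify_n1_initial(_nseq(wave))
        assert abs(n1.latency - 25.0) <= 1000.0 / FS

    def test_window_excludes_early_trough(self):
        # deeper trough at 14 ms is outside the 15-37 ms window
        wave = -_bump(14.0, 9.0) - _bump(20.0, 3.0)
        n1 = identify_n1_initial(_nseq(wave))
        assert n1.latency == pytest.approx(20.0, abs=0.34)

    def test_larger_prominence_wins(self):
        wave = -_bump(20.0, 3.0) - _bump(30.0, 5.0)
        n1 = identify_n1_initial(_nseq(wave))
        assert n1.latency == pytest.approx(30.0, abs=0.34)

    def test_no_trough_returns_none(self):
        assert identify_n1_initial(_nseq(np.zeros(N_SAMPLES))) is None

    def test_anchored_window_arithmetic(self):
        wave = -_bump(24.0, 3.0) - _bump(33.0, 8.0)
        n1 = identify_n1_anchored(_nseq(wave), anchor=25.0)
        assert n1.latency == pytest.approx(24.0, abs=0.34)  # 33 outside +-5

    def test_anchored_empty_window_none(self):
        wave = -_bump(33.0, 8.0)
        assert identify_n1_anchored(_nseq(wave), anchor=20.0) is None


def _cand(lat, prom):
    return Extremum(latency=lat, value=prom, prominence=prom, kind="peak")


class TestScorePeaks:
    def test_hand_enumerated_awards(self):
        # prominences 9/5/2 at 20/17/10 ms, n1 at 24 ms:
        # 20 ms: 5 prom + 3 weight + 5 proximity = 13
        # 17 ms: 4 prom + 2 weight + 4 proximity = 10
        # 10 ms: 3 prom + 1 weight + 3 proximity = 7
        cands = [_cand(20.0, 9.0), _cand(17.0, 5.0), _cand(10.0, 2.0)]
        table = score_peaks(cands, _n1(24.0))
        assert table.totals == [13, 10, 7]

    def test_weight_boundary_two_thirds_inclusive(self):
        # prominence ratio exactly 2/3 earns the full 3 weight points
        cands = [_cand(20.0, 9.0), _cand(17.0, 6.0)]
        table = score_peaks(cands, _n1(24.0))
        assert table.weight_points[1] == 3

    def test_single_candidate_gets_thirteen(self):
        table = score_peaks([_cand(18.0, 4.0)], _n1(24.0))
        assert table.totals == [13]

    def test_at_most_three_prominence_awards(self):
        cands = [_cand(6.0 + i, 10.0 - i) for i in range(6)]
        table = score_peaks(cands, _n1(24.0))
        assert sum(1 for p in table.prominence_points if p) == 3
        assert sum(1 for p in table.proximity_points if p) == 5

    def test_scale_invariance(self):
        cands = [_cand(20.0, 9.0), _cand(17.0, 5.0), _cand(10.0, 2.0)]
        scaled = [_cand(c.latency, 37.5 * c.prominence) for c in cands]
        assert score_peaks(cands, _n1(24.0)).totals == \
            score_peaks(scaled, _n1(24.0)).totals


def _n1(lat):
    return Extremum(latency=lat, value=-1.0, prominence=1.0, kind="trough")


class TestPickSequence:
    def test_noiseless_template_recovery(self):
        wave = np.zeros(N_SAMPLES)
        wave[ONSET:] = vemp_template(15.0, 25.0, 10.0, FS, 50.0)
        pick = pick_sequence(_nseq(wave))
        assert not pick.is_null
        assert pick.p1_latency == pytest.approx(15.0, abs=0.34)
        assert pick.n1_latency == pytest.approx(25.0, abs=0.34)
        assert pick.p1n1_latency == pytest.approx(10.0, abs=0.67)

    def _null_rule_wave(self, peak_value):
        wave = np.zeros(N_SAMPLES)
        wave[:ONSET] = np.tile([2.0, -2.0], ONSET // 2)  # prestim RMS = 2
        p1_idx = ONSET + 45  # 15 ms
        n1_idx = ONSET + 75  # 25 ms
        wave[p1_idx] = peak_value
        wave[n1_idx] = -1.0
        return _nseq(wave)

    def test_amplitude_below_null_rule(self):
        seq = self._null_rule_wave(peak_value=1.0)  # amp 2.0 < 1.65 * 2
        assert pick_sequence(seq).is_null

    def test_amplitude_exactly_at_cut_is_not_null(self):
        cut = 1.65 * 2.0
        seq = self._null_rule_wave(peak_value=cut - 1.0)  # amp == cut
        pick = pick_sequence(seq)
        assert not pick.is_null
        assert pick.p1n1_amplitude == pytest.approx(cut)

    def test_latencies_on_sample_grid(self, rng):
        for _ in range(20):
            wave = _smooth_noise(rng) + _bump(15, 40) - _bump(25, 40)
            pick = pick_sequence(_nseq(wave))
            if pick.is_null:
                continue
            for lat in (pick.p1_latency, pick.n1_latency):
                steps = lat * FS / 1000.0
                assert abs(steps - round(steps)) < 1e-9

    @given(scale=st.floats(0.01, 100.0))
    def test_uniform_scaling_leaves_pick_invariant(self, scale):
        rng = np.random.default_rng(77)
        wave = _smooth_noise(rng) + _bump(15, 30) - _bump(25, 30)
        base = pick_sequence(_nseq(wave))
        scaled = pick_sequence(_nseq(scale * wave))
        assert base.is_null == scaled.is_null
        if not base.is_null:
            assert base.p1_latency == scaled.p1_latency
            assert base.n1_latency == scaled.n1_latency


def _smooth_noise(rng, n=N_SAMPLES, sd=2.0):
    from scipy.ndimage import gaussian_filter1d
    x = gaussian_filter1d(rng.normal(size=n), sigma=3.0)
    return sd * x / np.std(x)


class TestOracleEquivalence:
    def test_pick_matches_brute_force_on_random_waveforms(self, rng):
        agree = 0
        for i in range(250):
            wave = _smooth_noise(rng, sd=rng.uniform(0.5, 4.0))
            if i % 2:  # half with a planted response
                wave += _bump(rng.uniform(10, 20), rng.uniform(5, 50))
                wave -= _bump(rng.uniform(22, 34), rng.uniform(5, 50))
            seq = _nseq(wave)
            anchor = None if i % 3 else 25.0
            ours = pick_sequence(seq, anchor=anchor)
            ref = oracle_pick(wave, FS, ONSET, seq.prestim_rms, anchor=anchor)
            if ref is None:
                assert ours.is_null
            else:
                assert not ours.is_null
                assert ours.p1_latency == pytest.approx(ref[0])
                assert ours.n1_latency == pytest.approx(ref[1])
                assert ours.p1n1_amplitude == pytest.approx(ref[2])
                agree += 1
        assert agree > 50  # the comparison must exercise non-null picks


class TestPickParticipant:
    def _record(self, levels=(40, 38, 36, 34, 39, 37), amp=30.0):
        seqs = []
        for i, level in enumerate(levels):
            wave = np.zeros(N_SAMPLES)
            wave[ONSET:] = vemp_template(15.0, 25.0, amp, FS, 50.0)
            seqs.append(_nseq(wave, order=i, level=level))
        return ParticipantRecord("P1", "F", seqs, background_rms=1.0)

    def test_noiseless_sequences_identical_picks(self):
        rec = self._record()
        picks = pick_participant(rec)
        assert len(picks) == 6
        assert all(not p.is_null for p in picks)
        assert len({(p.p1_latency, p.n1_latency) for p in picks}) == 1

    def test_order_permutation_invariant(self, rng):
        rec = self._record()
        shuffled = list(rec.sequences)
        rng.shuffle(shuffled)
        rec2 = ParticipantRecord("P1", "F", shuffled, background_rms=1.0)
        assert pick_participant(rec) == pick_participant(rec2)

    def test_missing_initial_max_level_sequence(self):
        rec = self._record(levels=(38, 40, 36))  # first acquired is not 40
        with pytest.raises(ProtocolError):
            pick_participant(rec)

    def test_low_level_nulls_do_not_break_others(self):
        # amplitudes straddling the 1.65x prestim-RMS rule: give the low
        # levels a sub-threshold response on a noisy prestim baseline
        seqs = []
        for i, (level, amp) in enumerate(
                [(40, 50.0), (38, 50.0), (36, 50.0), (34, 1.0),
                 (39, 50.0), (37, 50.0)]):
            wave = np.zeros(N_SAMPLES)
            wave[:ONSET] = np.tile([1.0, -1.0], ONSET // 2)
            wave[ONSET:] += vemp_template(15.0, 25.0, amp, FS, 50.0)
            seqs.append(_nseq(wave, order=i, level=level))
        picks = pick_participant(ParticipantRecord("P1", "F", seqs,
                                                   background_rms=1.0))
        by_level = {p.stimulus_level: p.is_null for p in picks}
        assert by_level[34] is True
        assert sum(by_level.values()) == 1
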