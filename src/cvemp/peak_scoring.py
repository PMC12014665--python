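"""Prominence-based p1/n1 identification with a points ranking.

The algorithm scores normalized sequence averages:

1. All local maxima (peaks) and minima (troughs, via the inverted trace) are
   located with their topographic prominence, as per MATLAB's ``findpeaks``.
2. For a participant's initial maximum-level sequence, n1 is the most
   prominent trough between 15 and 37 ms post-onset; for every other
   sequence, trough search is anchored within +-5 ms of that initial n1.
3. Candidate peaks earlier than 5 ms or at/after n1 are discarded. The three
   most prominent candidates receive 5/4/3 points; the same three receive
   weight points from their prominence ratio r to the most prominent
   candidate (3 if r >= 2/3, 2 if 1/3 < r < 2/3, else 1); the five candidates
   with latencies closest to n1 receive 5..1 points (closest first). The
   candidate with the highest total is p1; ties go to the candidate closest
   to n1.
4. The pick is a null response when the p1-n1 amplitude is less than 1.65x
   the pre-stimulus RMS of the sequence being evaluated.

Latencies are quantized to the sample grid (0.33 ms steps at 3 kHz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .containers import NormalizedSequence, ParticipantRecord
from .epoch_processing import response_level
from .exceptions import ProtocolError, UndefinedResponseError

__all__ = [
    "Extremum",
    "PeakPick",
    "ScoreTable",
    "find_extrema",
    "identify_n1_initial",
    "identify_n1_anchored",
    "score_peaks",
    "pick_sequence",
    "pick_participant",
    "N1_WINDOW_MS",
    "P1_MIN_LATENCY_MS",
    "NULL_RMS_FACTOR",
    "ANCHOR_HALFWIDTH_MS",
]

N1_WINDOW_MS = (15.0, 37.0)  # inclusive search window for the initial n1
P1_MIN_LATENCY_MS = 5.0  # candidates earlier than this are discarded
NULL_RMS_FACTOR = 1.65  # null response when amplitude < factor * prestim RMS
ANCHOR_HALFWIDTH_MS = 5.0  # trough tracking window around the initial n1


@dataclass(frozen=True)
class Extremum:
    """A local maximum or minimum on the sample grid.

    ``value`` is the signed waveform value (a trough's value is negative of
    the inverted-trace height); ``prominence`` is always reported on the
    trace in which the extremum is a peak, so it is non-negative.
    """

    latency: float  # ms post-onset, multiple of the sample period
    value: float
    prominence: float
    kind: str  # "peak" | "trough"


@dataclass(frozen=True)
class PeakPick:
    """The scored p1/n1 outcome for one sequence."""

    participant_id: str
    sex: str
    stimulus_level: float
    sequence_order: int
    p1_latency: float | None
    n1_latency: float | None
    p1n1_latency: float | None
    p1n1_amplitude: float | None  # dimensionless (normalized waveform units)
    response_level: float | None  # dB RL
    is_null: bool


@dataclass
class ScoreTable:
    """Per-candidate point awards backing a p1 decision."""

    candidates: list[Extremum]
    prominence_points: list[int]
    weight_points: list[int]
    proximity_points: list[int]
    totals: list[int] = field(init=False)

    def __post_init__(self) -> None:
        self.totals = [p + w + x for p, w, x in
                       zip(self.prominence_points, self.weight_points,
                           self.proximity_points)]


def _extrema_one_sign(waveform: np.ndarray, onset_index: int, sample_rate: float,
                      kind: str) -> list[Extremum]:
    x = waveform if kind == "peak" else -waveform
    idx, _ = _signal.find_peaks(x)
    if idx.size == 0:
        return []
    prom = _signal.peak_prominences(x, idx)[0]
    out = []
    for i, p in zip(idx, prom):
        latency = (i - onset_index) * 1000.0 / sample_rate
        out.append(Extremum(latency=latency, value=float(waveform[i]),
                            prominence=float(p), kind=kind))
    return out


def find_extrema(waveform: np.ndarray, sample_rate: float,
                 onset_index: int = 0) -> list[Extremum]:
    """All strict local maxima and minima with topographic prominence.

    Prominence of a peak is its height above the higher of the two lowest
    points separating it from the nearest higher peaks; the search extends to
    the trace ends when no higher peak exists on a side. Troughs are peaks of
    the inverted trace. Latencies are relative to ``onset_index``. A flat
    trace yields an empty list.
    """
    waveform = np.asarray(waveform, dtype=float)
    if waveform.size < 3:
        return []
    out = _extrema_one_sign(waveform, onset_index, sample_rate, "peak")
    out += _extrema_one_sign(waveform, onset_index, sample_rate, "trough")
    out.sort(key=lambda e: e.latency)
    return out


def _most_prominent_trough(troughs: list[Extremum], lo: float, hi: float
                           ) -> Extremum | None:
    eligible = [t for t in troughs if lo <= t.latency <= hi]
    if not eligible:
        return None
    # maximal prominence; ties broken by earlier latency
    return max(eligible, key=lambda t: (t.prominence, -t.latency))


def identify_n1_initial(seq: NormalizedSequence) -> Extremum | None:
    """n1 for the initial maximum-level sequence: the most prominent trough
    with latency in the inclusive 15-37 ms window (None when no trough)."""
    troughs = [e for e in find_extrema(seq.waveform, seq.sample_rate, seq.onset_index)
               if e.kind == "trough"]
    return _most_prominent_trough(troughs, *N1_WINDOW_MS)


def identify_n1_anchored(seq: NormalizedSequence, anchor: float,
                         window_halfwidth: float = ANCHOR_HALFWIDTH_MS
                         ) -> Extremum | None:
    """n1 for a non-initial sequence: the most prominent trough within
    +-``window_halfwidth`` ms of the initial n1, clipped to 15-37 ms."""
    lo = max(N1_WINDOW_MS[0], anchor - window_halfwidth)
    hi = min(N1_WINDOW_MS[1], anchor + window_halfwidth)
    troughs = [e for e in find_extrema(seq.waveform, seq.sample_rate, seq.onset_index)
               if e.kind == "trough"]
    return _most_prominent_trough(troughs, lo, hi)


def score_peaks(candidates: list[Extremum], n1: Extremum) -> ScoreTable:
    """Apply the three-tier points scheme to already-filtered candidates.

    Candidates must satisfy 5 ms <= latency < n1 latency. With fewer than
    three (or five) candidates the awards simply run down the available list.
    Prominence-rank ties are broken by earlier latency; equal n1 distances
    share the award order by earlier latency.
    """
    k = len(candidates)
    prominence_points = [0] * k
    weight_points = [0] * k
    proximity_points = [0] * k

    # (a) 5/4/3 by prominence, ties -> earlier latency first
    by_prom = sorted(range(k), key=lambda i: (-candidates[i].prominence,
                                              candidates[i].latency))
    for award, i in zip((5, 4, 3), by_prom):
        prominence_points[i] = award

    # (b) weight of the top-3 relative to the maximal prominence
    if k:
        prom_max = candidates[by_prom[0]].prominence
        for i in by_prom[:3]:
            r = candidates[i].prominence / prom_max if prom_max > 0 else 1.0
            if r >= 2.0 / 3.0:
                weight_points[i] = 3
            elif r > 1.0 / 3.0:
                weight_points[i] = 2
            else:
                weight_points[i] = 1

    # (c) 5..1 for the five latencies closest to n1, closest first
    by_near = sorted(range(k), key=lambda i: (abs(candidates[i].latency - n1.latency),
                                              candidates[i].latency))
    for award, i in zip((5, 4, 3, 2, 1), by_near):
        proximity_points[i] = award

    return ScoreTable(candidates=list(candidates),
                      prominence_points=prominence_points,
                      weight_points=weight_points,
                      proximity_points=proximity_points)


def _null_pick(seq: NormalizedSequence) -> PeakPick:
    return PeakPick(participant_id=seq.participant_id, sex=seq.sex,
                    stimulus_level=seq.stimulus_level,
                    sequence_order=seq.sequence_order,
                    p1_latency=None, n1_latency=None, p1n1_latency=None,
                    p1n1_amplitude=None, response_level=None, is_null=True)


def pick_sequence(seq: NormalizedSequence, anchor: float | None = None,
                  background: float = 1.0) -> PeakPick:
    """Full p1/n1 identification for one normalized sequence.

    ``anchor`` is the initial-sequence n1 latency (None for the initial
    sequence itself). ``background`` is the denominator for the dB RL
    transform; normalized waveforms use the default 1. Failures to find a
    trough or any candidate peak, and amplitudes below 1.65x the sequence's
    own pre-stimulus RMS, are returned as null picks, never raised.
    """
    if anchor is None:
        n1 = identify_n1_initial(seq)
    else:
        n1 = identify_n1_anchored(seq, anchor)
    if n1 is None:
        return _null_pick(seq)

    extrema = find_extrema(seq.waveform, seq.sample_rate, seq.onset_index)
    candidates = [e for e in extrema if e.kind == "peak"
                  and P1_MIN_LATENCY_MS <= e.latency < n1.latency]
    if not candidates:
        return _null_pick(seq)

    table = score_peaks(candidates, n1)
    best = max(range(len(candidates)),
               key=lambda i: (table.totals[i],
                              -abs(candidates[i].latency - n1.latency),
                              -candidates[i].latency))
    p1 = candidates[best]

    amplitude = p1.value - n1.value
    if amplitude < NULL_RMS_FACTOR * seq.prestim_rms:  # strict "less than"
        return _null_pick(seq)
    try:
        rl = response_level(amplitude, background)
    except UndefinedResponseError:
        return _null_pick(seq)
    return PeakPick(participant_id=seq.participant_id, sex=seq.sex,
                    stimulus_level=seq.stimulus_level,
                    sequence_order=seq.sequence_order,
                    p1_latency=p1.latency, n1_latency=n1.latency,
                    p1n1_latency=n1.latency - p1.latency,
                    p1n1_amplitude=amplitude, response_level=rl,
                    is_null=False)


def pick_participant(record: ParticipantRecord,
                     sequences: list[NormalizedSequence] | None = None
                     ) -> list[PeakPick]:
    """Score every sequence of a participant, anchoring on the initial one.

    ``sequences`` defaults to the record's own sequences, which must already
    be normalized. The earliest sequence in acquisition order must be at the
    session's maximum stimulus level (the initial anchor sequence); its n1
    anchors trough detection for all remaining sequences. Output order
    follows acquisition order regardless of input list order.
    """
    seqs = sorted(sequences if sequences is not None else record.sequences,
                  key=lambda s: s.sequence_order)
    if not seqs:
        raise ProtocolError("participant has no sequences")
    top_level = max(s.stimulus_level for s in seqs)
    initial = seqs[0]
    if initial.stimulus_level != top_level:
        raise ProtocolError(
            f"initial sequence is at {initial.stimulus_level} dB HL, not the "
            f"maximum {top_level} dB HL anchor level"
        )
    picks = [pick_sequence(initial, anchor=None)]
    anchor = picks[0].n1_latency
    for seq in seqs[1:]:
        picks.append(pick_sequence(seq, anchor=anchor))
    return picks
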