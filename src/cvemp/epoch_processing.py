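"""Raw epochs -> normalized sequence averages and response levels.

The processing chain mirrors the study's recording software and offline
scripts: epochs whose amplitude exceeds +-800 uV are rejected; each sequence
is the mean of exactly 300 accepted epochs; a participant's background EMG
tension is the RMS of the 18 ms pre-stimulus span of the mean of the first
six sequence averages; every sequence is normalized by dividing it by that
background tension; and p1-n1 amplitudes are expressed on the dB response
level (RL) scale, 20*log10(amp / background) - 20, where 0 dB RL is a
projected response threshold.
"""

from __future__ import annotations

import numpy as np

from .containers import EpochSet, NormalizedSequence, ParticipantRecord, SequenceAverage
from .exceptions import ConfigurationError, InsufficientDataError, UndefinedResponseError

__all__ = [
    "reject_epochs",
    "average_sequence",
    "background_rms",
    "normalize_sequence",
    "response_level",
    "REJECTION_THRESHOLD_UV",
    "BACKGROUND_N_SEQUENCES",
]

REJECTION_THRESHOLD_UV = 800.0
BACKGROUND_N_SEQUENCES = 6


def reject_epochs(epochs: EpochSet, threshold: float = REJECTION_THRESHOLD_UV) -> EpochSet:
    """Drop epochs containing any sample with magnitude strictly above ``threshold``.

    An epoch whose most extreme sample equals the threshold exactly is kept
    ("larger than +-800 uV" read as a strict inequality). Order is preserved.
    """
    if threshold <= 0:
        raise ConfigurationError("rejection threshold must be positive")
    keep = np.max(np.abs(epochs.epochs), axis=1) <= threshold
    return EpochSet(
        participant_id=epochs.participant_id,
        sex=epochs.sex,
        stimulus_level=epochs.stimulus_level,
        sample_rate=epochs.sample_rate,
        onset_index=epochs.onset_index,
        epochs=epochs.epochs[keep],
        sequence_order=epochs.sequence_order,
    )


def average_sequence(epochs: EpochSet, n: int = 300) -> SequenceAverage:
    """Pointwise mean of the first ``n`` accepted epochs (acquisition order).

    Raises :class:`InsufficientDataError` naming the shortfall when fewer
    than ``n`` epochs are available; extra accepted epochs beyond the first
    ``n`` are ignored, mirroring the recorder's online compensation.
    """
    if epochs.n_epochs < n:
        raise InsufficientDataError(
            f"need {n} accepted epochs, have {epochs.n_epochs} "
            f"(short by {n - epochs.n_epochs})"
        )
    return SequenceAverage(
        participant_id=epochs.participant_id,
        sex=epochs.sex,
        stimulus_level=epochs.stimulus_level,
        sample_rate=epochs.sample_rate,
        onset_index=epochs.onset_index,
        waveform=epochs.epochs[:n].mean(axis=0),
        sequence_order=epochs.sequence_order if epochs.sequence_order is not None else 0,
    )


def background_rms(record: ParticipantRecord) -> float:
    """Background EMG tension: RMS of the 18 ms pre-onset span of the mean of
    the participant's first six sequence averages (acquisition order).

    The value is stored on the record and returned.
    """
    seqs = record.ordered()
    if len(seqs) < BACKGROUND_N_SEQUENCES:
        raise InsufficientDataError(
            f"background tension needs {BACKGROUND_N_SEQUENCES} sequences, "
            f"have {len(seqs)}"
        )
    first = seqs[:BACKGROUND_N_SEQUENCES]
    mean_wave = np.mean([s.waveform for s in first], axis=0)
    span = mean_wave[first[0].prestim_window]
    value = float(np.sqrt(np.mean(span**2)))
    record.background_rms = value
    return value


def normalize_sequence(seq: SequenceAverage, background: float) -> NormalizedSequence:
    """Divide a sequence average elementwise by the background EMG tension."""
    if background <= 0:
        raise ConfigurationError("background tension must be positive")
    return NormalizedSequence(
        participant_id=seq.participant_id,
        sex=seq.sex,
        stimulus_level=seq.stimulus_level,
        sample_rate=seq.sample_rate,
        onset_index=seq.onset_index,
        waveform=seq.waveform / background,
        sequence_order=seq.sequence_order,
    )


def response_level(p1n1_amplitude: float, background: float = 1.0) -> float:
    """dB RL transform: 20*log10(p1n1_amplitude / background) - 20.

    For already-normalized (dimensionless) amplitudes pass ``background=1``.
    Zero dB RL corresponds to an amplitude 10x the background tension, the
    projected response threshold of the scale.
    """
    if background <= 0:
        raise ConfigurationError("background tension must be positive")
    if p1n1_amplitude <= 0:
        raise UndefinedResponseError("response level undefined for non-positive amplitude")
    return 20.0 * np.log10(p1n1_amplitude / background) - 20.0
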