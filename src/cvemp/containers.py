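"""Waveform-level data containers shared by the generator and the analysis.

Amplitudes are in microvolts (uV) until a sequence is normalized, after which
waveforms are dimensionless (uV/uV). Latencies are in milliseconds relative to
stimulus onset; stimulus levels are on the study's bone-conduction dB HL
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "EpochSet",
    "SequenceAverage",
    "NormalizedSequence",
    "ParticipantRecord",
]


@dataclass
class EpochSet:
    """Raw stimulus-locked EMG epochs for one participant x stimulus level.

    ``epochs`` is a 2-D array (n_epochs, n_samples); every epoch shares the
    sampling rate and the stimulus-onset index. The pre-onset span must cover
    at least the 18 ms window used for background-tension estimation.
    """

    participant_id: str
    sex: str
    stimulus_level: float
    sample_rate: float
    onset_index: int
    epochs: np.ndarray
    sequence_order: int | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 2:
            raise ConfigurationError("epochs must be a 2-D (n_epochs, n_samples) array")
        n_samples = self.epochs.shape[1]
        if not 0 <= self.onset_index < n_samples:
            raise ConfigurationError(
                f"onset_index {self.onset_index} outside epoch of {n_samples} samples"
            )
        prestim_ms = 1000.0 * self.onset_index / self.sample_rate
        if prestim_ms < 18.0 - 1e-9:
            raise ConfigurationError(
                f"pre-onset span is {prestim_ms:.2f} ms; at least 18 ms required"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[1]


def _prestim_slice(onset_index: int, sample_rate: float, window_ms: float = 18.0) -> slice:
    """Half-open [onset - window, onset) span on the sample grid."""
    n = int(round(window_ms * sample_rate / 1000.0))
    return slice(onset_index - n, onset_index)


@dataclass
class SequenceAverage:
    """Mean waveform of exactly ``n`` accepted epochs at one stimulus level."""

    participant_id: str
    sex: str
    stimulus_level: float
    sample_rate: float
    onset_index: int
    waveform: np.ndarray
    sequence_order: int
    prestim_rms: float = field(init=False)

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        span = self.waveform[_prestim_slice(self.onset_index, self.sample_rate)]
        self.prestim_rms = float(np.sqrt(np.mean(span**2)))

    @property
    def prestim_window(self) -> slice:
        return _prestim_slice(self.onset_index, self.sample_rate)


@dataclass
class NormalizedSequence(SequenceAverage):
    """A sequence average divided by the participant's background EMG tension.

    The waveform and its pre-stimulus RMS are dimensionless ratios.
    """


@dataclass
class ParticipantRecord:
    """All sequence averages for one participant, in acquisition order.

    ``background_rms`` (uV) is the participant's background EMG tension: the
    RMS of the 18 ms pre-onset span of the pointwise mean of the first six
    sequence averages. It is populated by
    :func:`cvemp.epoch_processing.background_rms`.
    """

    participant_id: str
    sex: str
    sequences: list[SequenceAverage]
    age: float | None = None
    background_rms: float | None = None

    def ordered(self) -> list[SequenceAverage]:
        return sorted(self.sequences, key=lambda s: s.sequence_order)
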