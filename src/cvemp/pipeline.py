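"""Convenience glue: simulate -> process -> pick -> long-format tables.

These helpers chain the generator, epoch processing and peak scoring into
the long-format latency dataset consumed by the statistics layer. Two routes
exist: the epoch-level reference route (raw epochs, rejection, averaging)
and a fast route that draws sequence averages directly from their exact
sampling distribution (see
:func:`cvemp.synthetic_data.synth_sequence_average`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import epoch_processing as ep
from . import synthetic_data as sd
from .containers import EpochSet, NormalizedSequence, ParticipantRecord
from .peak_scoring import PeakPick, pick_participant

__all__ = [
    "process_epoch_sets",
    "normalize_record",
    "simulate_participant_picks",
    "simulate_cohort",
    "picks_to_frame",
    "EPOCH_RATE_HZ",
]

EPOCH_RATE_HZ = 5.1  # stimulus presentation rate; sets per-sequence duration


def process_epoch_sets(epoch_sets: list[EpochSet], n: int = 300,
                       threshold: float = ep.REJECTION_THRESHOLD_UV
                       ) -> ParticipantRecord:
    """Reject, average and assemble a participant record from raw epoch sets."""
    first = epoch_sets[0]
    seqs = [ep.average_sequence(ep.reject_epochs(es, threshold), n)
            for es in epoch_sets]
    record = ParticipantRecord(participant_id=first.participant_id,
                               sex=first.sex, sequences=seqs)
    ep.background_rms(record)
    return record


def normalize_record(record: ParticipantRecord) -> list[NormalizedSequence]:
    """Normalize every sequence by the record's background EMG tension."""
    if record.background_rms is None:
        ep.background_rms(record)
    return [ep.normalize_sequence(s, record.background_rms)
            for s in record.ordered()]


def simulate_participant_picks(truth: sd.ParticipantTruth, config: sd.GeneratorConfig,
                               rng: np.random.Generator, fast: bool = False
                               ) -> list[PeakPick]:
    """Generate, process and score one participant's full session."""
    if fast:
        seqs = [sd.synth_sequence_average(truth, level, config, rng, sequence_order=i)
                for i, level in enumerate(sd.level_schedule(config))]
        record = ParticipantRecord(participant_id=truth.participant_id,
                                   sex=truth.sex, sequences=seqs)
        ep.background_rms(record)
    else:
        record = process_epoch_sets(
            sd.simulate_record_epochs(truth, config, rng),
            n=config.epochs_per_sequence)
    return pick_participant(record, normalize_record(record))


def picks_to_frame(picks: list[PeakPick], epochs_per_sequence: int = 300,
                   include_null: bool = False) -> pd.DataFrame:
    """Long-format latency dataset: one row per (non-null) pick.

    ``elapsed_time`` (s) is reconstructed from the acquisition index and the
    presentation rate. ``db_rl`` carries the dB RL amplitude used as the
    response of the amplitude models.
    """
    rows = []
    seq_duration = epochs_per_sequence / EPOCH_RATE_HZ
    for p in picks:
        if p.is_null and not include_null:
            continue
        rows.append({
            "participant_id": p.participant_id,
            "sex": p.sex,
            "stimulus_level": p.stimulus_level,
            "sequence_order": p.sequence_order,
            "elapsed_time": p.sequence_order * seq_duration,
            "p1_latency": p.p1_latency,
            "n1_latency": p.n1_latency,
            "p1n1_latency": p.p1n1_latency,
            "p1n1_amp": p.p1n1_amplitude,
            "db_rl": p.response_level,
            "is_null": p.is_null,
        })
    return pd.DataFrame(rows, columns=[
        "participant_id", "sex", "stimulus_level", "sequence_order",
        "elapsed_time", "p1_latency", "n1_latency", "p1n1_latency",
        "p1n1_amp", "db_rl", "is_null"])


def simulate_cohort(config: sd.GeneratorConfig, rng: np.random.Generator | int | None = None,
                    fast: bool = False, include_null: bool = False) -> pd.DataFrame:
    """Simulate a whole cohort and return the long-format latency dataset."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    cohort = sd.make_cohort(config, rng)
    picks: list[PeakPick] = []
    for truth in cohort:
        picks.extend(simulate_participant_picks(truth, config, rng, fast=fast))
    return picks_to_frame(picks, config.epochs_per_sequence, include_null=include_null)
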