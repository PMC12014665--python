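"""Seeded generator for synthetic cervical VEMP recording sessions.

The generator emulates the statistical structure the analysis pipeline
assumes: tonic sternocleidomastoid EMG recorded at 3 kHz with an 18 ms
pre-stimulus window and a ~50 uV RMS background-tension target, a biphasic
VEMP response (positive p1 peak followed by the n1 trough) whose p1-n1
latency differs by sex, amplitude growth linear on the dB response-level
scale with a per-participant slope, two descending stimulus-level series plus
a closing maximum-level repeat, 300 epochs per sequence, and occasional
artifact epochs exceeding the +-800 uV rejection bound.

All randomness flows through :class:`numpy.random.Generator` objects; a fixed
seed yields bit-identical cohorts and epoch sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np
from scipy import signal

from .containers import EpochSet, SequenceAverage
from .exceptions import ConfigurationError

__all__ = [
    "GeneratorConfig",
    "ParticipantTruth",
    "make_cohort",
    "vemp_template",
    "synth_epochs",
    "synth_sequence_average",
    "true_amplitude",
    "level_schedule",
    "make_schedule",
    "PRESETS",
]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic recording session.

    Defaults are the ``paper2025`` preset: the study design this package's
    acceptance suite simulates (24 women + 24 men; per-participant p1-n1
    latency means 9.99 +- 2.74 ms for women and 12.41 +- 2.54 ms for men;
    amplitude-growth slope 1.89 +- 0.25 dB RL per dB HL; 50 uV RMS
    background; 3 kHz sampling; the 40->34 / 39->35 dB HL descending series
    with a closing 40 dB HL repeat; 300 epochs per sequence).
    """

    n_women: int = 24
    n_men: int = 24
    # per-participant true p1-n1 latency distribution (ms)
    latency_mean_f: float = 9.99
    latency_sd_f: float = 2.74
    latency_mean_m: float = 12.41
    latency_sd_m: float = 2.54
    # absolute-latency anchors (ms post-onset): p1/n1 group centres
    p1_center_f: float = 15.3
    n1_center_f: float = 25.3
    p1_center_m: float = 14.6
    n1_center_m: float = 27.0
    # amplitude growth on the response-level scale (dB RL per dB HL)
    slope_mean: float = 1.89
    slope_sd: float = 0.25
    background_rms: float = 50.0  # uV, biofeedback target
    sample_rate: float = 3000.0  # Hz
    prestim_duration: float = 18.0  # ms
    poststim_duration: float = 50.0  # ms
    epochs_per_sequence: int = 300
    level_series: tuple[float, ...] = (40, 38, 36, 34, 39, 37, 35, 40)
    artifact_prob: float = 0.02
    artifact_amp: float = 800.0  # uV, artifacts exceed this bound
    # stimulus level (dB HL) at which the true amplitude sits at 0 dB RL,
    # i.e. 10x the raw background RMS
    threshold_level: float = 37.0
    # per-sequence latency jitter applied independently to p1 and n1 (ms)
    jitter_sd: float = 0.5
    template_width: float = 3.0  # ms, Gaussian lobe width
    # spectral band of the simulated surface-EMG background (Hz)
    emg_band_low: float = 20.0
    emg_band_high: float = 450.0
    # additive-noise RMS override; None -> background_rms. The amplitude
    # scale always anchors on background_rms, so a tiny value here gives the
    # noiseless limit without collapsing the normalization denominator.
    noise_rms: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_women <= 0 or self.n_men <= 0:
            raise ConfigurationError("participant counts must be positive")
        if self.sample_rate <= 0:
            raise ConfigurationError("sample_rate must be positive")
        if self.prestim_duration < 18.0:
            raise ConfigurationError("prestim_duration must be >= 18 ms")
        for name in ("latency_sd_f", "latency_sd_m", "slope_sd", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.artifact_prob < 1.0:
            raise ConfigurationError("artifact_prob must lie in [0, 1)")
        if self.epochs_per_sequence <= 0:
            raise ConfigurationError("epochs_per_sequence must be positive")
        self.level_series = tuple(float(v) for v in self.level_series)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def paper2025(cls, **overrides) -> "GeneratorConfig":
        """The shipped default preset (see class docstring)."""
        return cls(**overrides)

    # -- derived geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(round((self.prestim_duration + self.poststim_duration)
                         * self.sample_rate / 1000.0))

    @property
    def onset_index(self) -> int:
        return int(round(self.prestim_duration * self.sample_rate / 1000.0))


PRESETS = {"paper2025": GeneratorConfig.paper2025}


@dataclass
class ParticipantTruth:
    """Latent per-participant parameters behind the simulated measurements."""

    participant_id: str
    sex: str  # "F" or "M"
    true_p1_latency: float  # ms
    true_n1_latency: float  # ms
    true_slope: float  # dB RL per dB HL
    true_threshold: float  # dB HL at which true amplitude gives 0 dB RL

    def __post_init__(self) -> None:
        if not 0.0 < self.true_p1_latency < self.true_n1_latency:
            raise ConfigurationError("need 0 < p1 < n1 latency")

    @property
    def true_p1n1_latency(self) -> float:
        return self.true_n1_latency - self.true_p1_latency


_MIN_P1N1 = 2.0  # ms; truncation floor keeping p1 and n1 separable


def make_cohort(config: GeneratorConfig, rng: np.random.Generator | None = None
                ) -> list[ParticipantTruth]:
    """Draw a cohort of latent participants from the configured distributions.

    Per-sex true p1-n1 latencies are normal draws (truncated below at 2 ms so
    the biphasic template stays well defined); the absolute p1/n1 latencies
    place the drawn separation symmetrically about the sex-specific p1/n1
    midpoint. Amplitude-growth slopes are N(slope_mean, slope_sd^2).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cohort: list[ParticipantTruth] = []
    groups = (
        ("F", config.n_women, config.latency_mean_f, config.latency_sd_f,
         0.5 * (config.p1_center_f + config.n1_center_f)),
        ("M", config.n_men, config.latency_mean_m, config.latency_sd_m,
         0.5 * (config.p1_center_m + config.n1_center_m)),
    )
    for sex, n, mu, sd, midpoint in groups:
        for i in range(n):
            diff = rng.normal(mu, sd)
            while diff < _MIN_P1N1:  # truncate pathological draws
                diff = rng.normal(mu, sd)
            slope = rng.normal(config.slope_mean, config.slope_sd)
            cohort.append(ParticipantTruth(
                participant_id=f"{sex}{i + 1:02d}",
                sex=sex,
                true_p1_latency=midpoint - diff / 2.0,
                true_n1_latency=midpoint + diff / 2.0,
                true_slope=slope,
                true_threshold=config.threshold_level,
            ))
    return cohort


def vemp_template(p1_latency: float, n1_latency: float, p1n1_amplitude: float,
                  sample_rate: float, duration: float,
                  width: float = 3.0) -> np.ndarray:
    """Smooth biphasic VEMP waveform on the sample grid starting at onset.

    Built from two Gaussian lobes (positive centred at ``p1_latency``,
    negative at ``n1_latency``); the lobe width shrinks automatically when the
    latencies are close so the waveform's global extrema stay at the requested
    latencies. The trace is rescaled so max - min equals ``p1n1_amplitude``
    exactly on the returned grid and zeroed outside the response region.

    Parameters are in ms, uV and Hz; the waveform starts at stimulus onset
    (t = 0) and spans ``duration`` ms.
    """
    if not 0.0 < p1_latency < n1_latency:
        raise ValueError("need 0 < p1_latency < n1_latency")
    if n1_latency >= duration:
        raise ValueError("duration must cover both latencies")
    if p1n1_amplitude < 0:
        raise ValueError("p1n1_amplitude must be >= 0")
    n = int(round(duration * sample_rate / 1000.0))
    t = np.arange(n) * 1000.0 / sample_rate
    # cap the lobe width so extrema interaction and pre-onset leakage are
    # negligible (< a sample period) for any admissible latency pair
    sep = n1_latency - p1_latency
    sigma = min(width, sep / 3.5, p1_latency / 4.0, (duration - n1_latency) / 4.0)
    sigma = max(sigma, 1.0 / sample_rate)  # never degenerate
    wave = (np.exp(-0.5 * ((t - p1_latency) / sigma) ** 2)
            - np.exp(-0.5 * ((t - n1_latency) / sigma) ** 2))
    # hard zero outside the response region
    outside = (np.abs(t - p1_latency) > 4.5 * sigma) & (np.abs(t - n1_latency) > 4.5 * sigma)
    wave[outside] = 0.0
    span = wave.max() - wave.min()
    if span > 0:
        wave *= p1n1_amplitude / span
    else:
        wave[:] = 0.0
    return wave


def true_amplitude(truth: ParticipantTruth, level: float,
                   config: GeneratorConfig) -> float:
    """True p1-n1 amplitude (uV) at a stimulus level.

    Defined so that 20*log10(amp / background_rms) - 20 grows linearly in
    level with the participant's slope and crosses 0 dB RL at the
    participant's threshold: at threshold the amplitude is 10x the raw
    background RMS.
    """
    rl = truth.true_slope * (level - truth.true_threshold)
    return config.background_rms * 10.0 ** ((rl + 20.0) / 20.0)


def _noise_sos(config: GeneratorConfig):
    """Spectral shaping of the simulated EMG background.

    Surface EMG concentrates its power at roughly 20-450 Hz; Gaussian noise
    is shaped with a 2nd-order band-pass over that band (configurable) and
    then rescaled to the target RMS. The band sits inside the recording
    chain's 10 Hz high-pass / 1500 Hz low-pass, so those filters are
    subsumed. A flat-to-Nyquist noise model would pepper the averaged
    waveforms with sub-millisecond local extrema that real tonic EMG does
    not produce, destabilising the prominence-scoring stage.
    """
    nyq = config.sample_rate / 2.0
    hi = min(config.emg_band_high, 0.9 * nyq)
    return _cached_sos(config.sample_rate, config.emg_band_low, hi)


@lru_cache(maxsize=32)
def _cached_sos(fs: float, lo: float, hi: float):
    return signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _filtered_noise(shape: tuple[int, ...], rms: float,
                    config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    noise = rng.standard_normal(shape)
    if rms <= 0:
        return np.zeros(shape)
    noise = signal.sosfilt(_noise_sos(config), noise, axis=-1)
    scale = rms / np.sqrt(np.mean(noise**2))
    return noise * scale


def _noise_amp(config: GeneratorConfig) -> float:
    return config.background_rms if config.noise_rms is None else config.noise_rms


def _sequence_template(truth: ParticipantTruth, level: float,
                       config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Template for one sequence, with per-sequence latency jitter applied
    independently to p1 and n1, embedded in a full epoch-length trace."""
    p1 = truth.true_p1_latency + rng.normal(0.0, config.jitter_sd)
    n1 = truth.true_n1_latency + rng.normal(0.0, config.jitter_sd)
    if n1 - p1 < _MIN_P1N1 / 2.0:  # keep the jittered pair ordered
        mid = 0.5 * (p1 + n1)
        p1, n1 = mid - _MIN_P1N1 / 4.0, mid + _MIN_P1N1 / 4.0
    amp = true_amplitude(truth, level, config)
    post = vemp_template(p1, n1, amp, config.sample_rate,
                         config.poststim_duration, config.template_width)
    trace = np.zeros(config.n_samples)
    k = min(len(post), config.n_samples - config.onset_index)
    trace[config.onset_index:config.onset_index + k] = post[:k]
    return trace


def synth_epochs(truth: ParticipantTruth, level: float, config: GeneratorConfig,
                 rng: np.random.Generator, sequence_order: int | None = None,
                 ) -> EpochSet:
    """Simulate the raw epochs recorded for one sequence.

    Epochs are band-limited Gaussian EMG noise at the configured background
    RMS plus the participant's (jittered) response template after onset. With
    probability ``artifact_prob`` an epoch is contaminated by a deflection
    exceeding ``artifact_amp``. Blocks of epochs are generated until at least
    ``epochs_per_sequence`` epochs survive the +-``artifact_amp`` rejection
    bound, mirroring the online compensation of the recording software.
    """
    template = _sequence_template(truth, level, config, rng)
    blocks: list[np.ndarray] = []
    accepted = 0
    want = config.epochs_per_sequence
    n_next = int(np.ceil(want / (1.0 - config.artifact_prob)))
    for _ in range(64):  # online compensation: top up until enough survive
        block = _filtered_noise((n_next, config.n_samples),
                                _noise_amp(config), config, rng)
        block += template
        contaminated = rng.random(n_next) < config.artifact_prob
        for i in np.flatnonzero(contaminated):
            pos = rng.integers(0, config.n_samples)
            sign = rng.choice((-1.0, 1.0))
            peak = config.artifact_amp * rng.uniform(2.5, 4.0)
            width = max(2, int(round(config.sample_rate * 0.002)))  # ~2 ms
            lo, hi = max(0, pos - width), min(config.n_samples, pos + width + 1)
            shape = np.hanning(2 * width + 1)[lo - (pos - width):hi - (pos - width)]
            block[i, lo:hi] += sign * peak * shape
        blocks.append(block)
        accepted += int(np.sum(np.max(np.abs(block), axis=1) <= config.artifact_amp))
        if accepted >= want:
            break
        n_next = max(16, 2 * (want - accepted))
    epochs = np.vstack(blocks)
    return EpochSet(
        participant_id=truth.participant_id,
        sex=truth.sex,
        stimulus_level=level,
        sample_rate=config.sample_rate,
        onset_index=config.onset_index,
        epochs=epochs,
        sequence_order=sequence_order,
    )


def synth_sequence_average(truth: ParticipantTruth, level: float,
                           config: GeneratorConfig, rng: np.random.Generator,
                           sequence_order: int = 0,
                           n_presentations: int | None = None) -> SequenceAverage:
    """Draw a 300-epoch sequence average directly from its sampling law.

    The mean of ``n`` independent Gaussian-noise epochs plus a fixed template
    is itself the template plus band-limited Gaussian noise at RMS
    ``background_rms / sqrt(n)``; this samples that distribution exactly,
    bypassing per-epoch synthesis. Used by the power-simulation layer where
    thousands of cohorts are required; the epoch-level path
    (:func:`synth_epochs`) remains the reference route.
    """
    n = n_presentations or config.epochs_per_sequence
    template = _sequence_template(truth, level, config, rng)
    noise = _filtered_noise((config.n_samples,),
                            _noise_amp(config) / np.sqrt(n), config, rng)
    return SequenceAverage(
        participant_id=truth.participant_id,
        sex=truth.sex,
        stimulus_level=level,
        sample_rate=config.sample_rate,
        onset_index=config.onset_index,
        waveform=template + noise,
        sequence_order=sequence_order,
    )


def make_schedule(primary_start: float = 40, primary_floor: float = 34,
                  secondary_start: float | None = 39,
                  secondary_floor: float | None = 35,
                  step: float = 2,
                  closing_repeat: float | None = 40) -> list[float]:
    """Build a stimulus-level schedule from descending-series parameters.

    The default reproduces the study design: a 40->34 dB HL series in 2 dB
    steps, a second 39->35 series, then a closing repeat at the 40 dB HL
    maximum.
    """
    out = list(np.arange(primary_start, primary_floor - step / 2, -step))
    if secondary_start is not None and secondary_floor is not None:
        out += list(np.arange(secondary_start, secondary_floor - step / 2, -step))
    if closing_repeat is not None:
        out.append(closing_repeat)
    return [float(v) for v in out]


def level_schedule(config: GeneratorConfig) -> list[float]:
    """The ordered stimulus levels of one session (default 40,38,36,34,39,37,35,40)."""
    return list(config.level_series)


def simulate_record_epochs(truth: ParticipantTruth, config: GeneratorConfig,
                           rng: np.random.Generator) -> list[EpochSet]:
    """All raw epoch sets for one participant, following the level schedule."""
    return [synth_epochs(truth, level, config, rng, sequence_order=i)
            for i, level in enumerate(level_schedule(config))]
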