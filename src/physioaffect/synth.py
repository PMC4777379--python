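"""Synthetic multimodal physiology for a picture-block affect-induction session.

The generator emulates a five-condition block design (neutral plus the four
quadrants of the valence-arousal plane: HVHA, HVLA, LVHA, LVLA).  Each
stimulation block is a run of pictures shown back to back, preceded by a
fixation-cross interval that lets electrodermal and cardiac activity return
toward baseline.  Four channels are synthesised per subject:

* ``emg_corrugator`` / ``emg_zygomaticus`` — zero-mean broadband noise whose
  standard deviation follows a per-condition envelope target (corrugator
  reactive to negative-valence blocks, zygomaticus to positive-valence
  blocks), plus 50 Hz power-line interference.
* ``scl`` — an age-dependent tonic level, one skin-conductance response (SCR,
  difference-of-exponentials) per picture onset, a slow sinusoidal drift and
  white measurement noise.
* ``bvp`` — a pulse waveform whose inter-beat intervals are drawn per beat
  from a condition-dependent mean heart period plus Gaussian jitter.

Effect structure injected by default: tonic SCL decreases with age
(target Pearson r ~ -0.45 over a uniform 20-75 year cohort), and phasic
reactivity (SCR amplitude, EMG envelope excursion) is modulated by a
gender x condition gain — females more reactive to LVHA, males to HVHA.

All randomness flows from a single integer seed through
:class:`numpy.random.SeedSequence`; per-subject substreams are spawned from
the subject index so cohorts are reproducible element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .exceptions import ConfigurationError

CONDITIONS: tuple[str, ...] = ("neutral", "HVHA", "HVLA", "LVHA", "LVLA")
FIXATION = "fixation"

CHANNELS: tuple[str, ...] = ("emg_corrugator", "emg_zygomaticus", "scl", "bvp")
CHANNEL_UNITS = {
    "emg_corrugator": "mV",
    "emg_zygomaticus": "mV",
    "scl": "uS",
    "bvp": "a.u.",
}

DEFAULT_SAMPLING_RATES = {
    "emg_corrugator": 1000.0,
    "emg_zygomaticus": 1000.0,
    "scl": 32.0,
    "bvp": 128.0,
}

#: Trait-scale score ranges (instrument-level sums / means).
TRAIT_RANGES = {
    "extraversion": (0.0, 48.0),
    "neuroticism": (0.0, 48.0),
    "bis": (7.0, 28.0),
    "bas": (13.0, 52.0),
    "femininity": (1.0, 7.0),
    "masculinity": (1.0, 7.0),
}


def _default_gender_gain() -> dict:
    # Phasic-reactivity multipliers; >1 marks the condition the gender is
    # preferentially reactive to (females: LVHA, males: HVHA), with the
    # opposite gender correspondingly hypo-reactive to that condition.
    female = {c: 1.0 for c in CONDITIONS}
    male = {c: 1.0 for c in CONDITIONS}
    female["LVHA"], female["HVHA"] = 1.8, 0.4
    male["HVHA"], male["LVHA"] = 1.8, 0.4
    return {"female": female, "male": male}


@dataclass(frozen=True)
class EffectParams:
    """Effect sizes and noise levels injected into the synthetic signals.

    The tonic-SCL calibration: for ages uniform on [20, 75] the age SD is
    55/sqrt(12) = 15.88 yr; with slope -0.05 uS/yr and a between-subject
    tonic SD of 1.55 uS the population correlation between age and tonic
    level is -0.794/sqrt(0.794^2 + 1.55^2) ~ -0.456.
    """

    age_scl_slope: float = -0.05  # uS per year of age
    age_midpoint_years: float = 47.5
    tonic_base: float = 8.0  # uS at the age midpoint
    tonic_between_subject_sd: float = 1.55  # uS

    scr_rise_s: float = 0.75
    scr_decay_s: float = 2.0
    #: SCR amplitude target per condition (uS); arousal-driven.
    scr_amplitude: dict = field(
        default_factory=lambda: {
            "neutral": 0.15,
            "HVHA": 0.35,
            "HVLA": 0.25,
            "LVHA": 0.35,
            "LVLA": 0.20,
        }
    )
    scr_amplitude_cv: float = 0.2  # per-event multiplicative jitter (truncated)

    gender_condition_gain: dict = field(default_factory=_default_gender_gain)

    #: EMG envelope targets during blocks (mV RMS); corrugator indexes
    #: negative valence (frowning), zygomaticus positive valence (smiling).
    corrugator_envelope: dict = field(
        default_factory=lambda: {
            "neutral": 0.008,
            "HVHA": 0.009,
            "HVLA": 0.008,
            "LVHA": 0.018,
            "LVLA": 0.014,
        }
    )
    zygomaticus_envelope: dict = field(
        default_factory=lambda: {
            "neutral": 0.008,
            "HVHA": 0.018,
            "HVLA": 0.014,
            "LVHA": 0.009,
            "LVLA": 0.008,
        }
    )
    emg_resting_sd: float = 0.005  # mV RMS during fixation
    powerline_amplitude: float = 0.010  # mV, 50 Hz interference

    #: Mean heart period per condition (ms); arousal shortens the period.
    heart_period_ms: dict = field(
        default_factory=lambda: {
            FIXATION: 858.0,
            "neutral": 850.0,
            "HVHA": 825.0,
            "HVLA": 840.0,
            "LVHA": 820.0,
            "LVLA": 848.0,
        }
    )
    #: Per-beat Gaussian jitter SD (ms); low arousal = higher vagal variability.
    heart_period_jitter_ms: dict = field(
        default_factory=lambda: {
            FIXATION: 35.0,
            "neutral": 35.0,
            "HVHA": 22.0,
            "HVLA": 40.0,
            "LVHA": 20.0,
            "LVLA": 45.0,
        }
    )

    scl_drift_amplitude: float = 0.10  # uS, slow sinusoidal drift
    scl_drift_period_s: float = 120.0
    noise_sd: dict = field(
        default_factory=lambda: {"scl": 0.02, "bvp": 0.02}
    )

    #: Log-SD of the per-subject multiplicative reactivity factor and of the
    #: per-block factor, applied to phasic responses (EMG envelope excursion,
    #: SCR amplitude).  Psychophysiological reactivity is strongly
    #: heterogeneous across people and trials; without these the synthetic
    #: conditions are implausibly separable.
    subject_reactivity_sd: float = 0.5
    block_reactivity_sd: float = 0.8

    #: Condition-independent background activity: per-interval jitter of the
    #: resting EMG tone (log-SD), spontaneous non-specific SCRs (Poisson rate
    #: per minute and their amplitude in uS), and slow per-interval drift of
    #: the mean heart period (SD in ms).  These set the noise floor against
    #: which affective reactivity must be detected.
    emg_resting_jitter_sd: float = 0.4
    nsscr_rate_per_min: float = 2.0
    nsscr_amplitude: float = 0.15
    heart_period_drift_sd_ms: float = 15.0


@dataclass(frozen=True)
class StudyDesign:
    """Cohort and session layout; defaults reproduce the study design.

    Five conditions x 2 blocks, 10 pictures of 2 s per block, a 20 s
    fixation cross before every block: a 400 s session of 100 pictures.
    """

    n_subjects: int = 100
    fraction_female: float = 0.64
    age_range: tuple[float, float] = (20.0, 75.0)
    seed: int = 0
    effect_params: EffectParams = field(default_factory=EffectParams)
    sampling_rates: dict = field(default_factory=lambda: dict(DEFAULT_SAMPLING_RATES))
    pictures_per_block: int = 10
    picture_duration: float = 2.0
    blocks_per_condition: int = 2
    fixation_duration: float = 20.0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not 0.0 <= self.fraction_female <= 1.0:
            raise ConfigurationError("fraction_female must be in [0, 1]")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range must satisfy min < max")
        for name, value in (
            ("pictures_per_block", self.pictures_per_block),
            ("picture_duration", self.picture_duration),
            ("blocks_per_condition", self.blocks_per_condition),
            ("fixation_duration", self.fixation_duration),
        ):
            if value <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {value!r}")
        for ch, fs in self.sampling_rates.items():
            if fs <= 0:
                raise ConfigurationError(f"sampling rate for {ch} must be > 0")

    @property
    def block_duration(self) -> float:
        return self.pictures_per_block * self.picture_duration

    @property
    def session_duration(self) -> float:
        n_blocks = len(CONDITIONS) * self.blocks_per_condition
        return n_blocks * (self.fixation_duration + self.block_duration)


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    age: float
    gender: str  # "female" | "male"
    extraversion: float
    neuroticism: float
    bis: float
    bas: float
    femininity: float
    masculinity: float

    TRAIT_FIELDS = ("extraversion", "neuroticism", "bis", "bas", "femininity", "masculinity")


@dataclass(frozen=True)
class EventTimeline:
    """Ordered, contiguous fixation/stimulation intervals."""

    intervals: tuple  # of (onset_s, offset_s, label)

    def validate(self) -> None:
        prev_off = 0.0
        prev_label = None
        for onset, offset, label in self.intervals:
            if onset != prev_off:
                raise ConfigurationError("timeline intervals must be contiguous")
            if offset <= onset:
                raise ConfigurationError("timeline intervals must have positive duration")
            if label not in CONDITIONS and label != FIXATION:
                raise ConfigurationError(f"unknown interval label {label!r}")
            if label != FIXATION and prev_label != FIXATION:
                raise ConfigurationError("every stimulation block must follow a fixation interval")
            prev_off = offset
            prev_label = label

    @property
    def blocks(self) -> list[tuple[float, float, str]]:
        """Stimulation intervals only, in presentation order."""
        return [iv for iv in self.intervals if iv[2] != FIXATION]

    @property
    def duration(self) -> float:
        return self.intervals[-1][1] if self.intervals else 0.0

    def preceding_fixation(self, block_onset: float) -> tuple[float, float, str] | None:
        for iv in self.intervals:
            if iv[2] == FIXATION and abs(iv[1] - block_onset) < 1e-9:
                return iv
        return None


@dataclass
class RawRecording:
    """Multichannel uniformly sampled recording for one subject.

    ``channels`` maps channel name to ``(samples, fs, units)``.
    """

    subject_id: str
    channels: dict

    def duration(self) -> float:
        durs = [len(s) / fs for s, fs, _ in self.channels.values()]
        return max(durs) if durs else 0.0


# ---------------------------------------------------------------------------
# generation


def _rng_for(design: StudyDesign, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(design.seed, spawn_key=spawn_key))


def generate_timeline(design: StudyDesign, rng: np.random.Generator | None = None) -> EventTimeline:
    """Random block order: a seeded permutation of conditions x blocks."""
    design.validate()
    if rng is None:
        rng = _rng_for(design, 0)
    blocks = [c for c in CONDITIONS for _ in range(design.blocks_per_condition)]
    order = rng.permutation(len(blocks))
    intervals = []
    t = 0.0
    for idx in order:
        intervals.append((t, t + design.fixation_duration, FIXATION))
        t += design.fixation_duration
        intervals.append((t, t + design.block_duration, blocks[idx]))
        t += design.block_duration
    timeline = EventTimeline(tuple(intervals))
    timeline.validate()
    return timeline


def _truncnorm(rng, lo, hi, mean, sd, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_profiles(design: StudyDesign, rng: np.random.Generator | None = None) -> list[SubjectProfile]:
    """Cohort demographics and trait scores.

    Gender counts are exact (``round(fraction_female * n)`` females) with a
    seeded random ordering; ages are uniform over ``age_range``; trait scores
    are truncated normals within each instrument's range, with BSRI
    femininity/masculinity means shifted by gender.
    """
    design.validate()
    if rng is None:
        rng = _rng_for(design, 1)
    n = design.n_subjects
    n_female = int(round(design.fraction_female * n))
    genders = np.array(["female"] * n_female + ["male"] * (n - n_female))
    rng.shuffle(genders)
    lo, hi = design.age_range
    ages = rng.uniform(lo, hi, size=n)

    trait_means = {
        "extraversion": 24.0,
        "neuroticism": 22.0,
        "bis": 18.0,
        "bas": 33.0,
    }
    trait_sds = {"extraversion": 7.0, "neuroticism": 7.0, "bis": 4.0, "bas": 6.0}

    traits = {
        name: _truncnorm(rng, *TRAIT_RANGES[name], trait_means[name], trait_sds[name], size=n)
        for name in ("extraversion", "neuroticism", "bis", "bas")
    }
    # BSRI gender-role means shifted by gender (own-role scores run higher).
    is_female = genders == "female"
    fem_mean = np.where(is_female, 5.0, 4.2)
    masc_mean = np.where(is_female, 4.2, 5.0)
    traits["femininity"] = _truncnorm(rng, 1.0, 7.0, fem_mean, 0.8, size=n)
    traits["masculinity"] = _truncnorm(rng, 1.0, 7.0, masc_mean, 0.8, size=n)

    return [
        SubjectProfile(
            subject_id=f"S{i:03d}",
            age=float(ages[i]),
            gender=str(genders[i]),
            **{name: float(traits[name][i]) for name in SubjectProfile.TRAIT_FIELDS},
        )
        for i in range(n)
    ]


def _scr_kernel(fs: float, rise: float, decay: float) -> np.ndarray:
    """Difference-of-exponentials SCR shape, normalised to unit peak."""
    t = np.arange(0.0, decay * 6, 1.0 / fs)
    h = np.exp(-t / decay) - np.exp(-t / rise)
    peak = h.max()
    return h / peak if peak > 0 else h


def _picture_onsets(timeline: EventTimeline, picture_duration: float) -> list[tuple[float, str]]:
    onsets = []
    for onset, offset, label in timeline.blocks:
        t = onset
        while t < offset - 1e-9:
            onsets.append((t, label))
            t += picture_duration
    return onsets


def _label_at(timeline: EventTimeline, t: float) -> str:
    for onset, offset, label in timeline.intervals:
        if onset <= t < offset:
            return label
    return FIXATION


def synthesize_recording(
    profile: SubjectProfile,
    timeline: EventTimeline,
    params: EffectParams | None = None,
    rng: np.random.Generator | None = None,
    *,
    sampling_rates: dict | None = None,
    picture_duration: float = 2.0,
    channels: tuple[str, ...] = CHANNELS,
) -> RawRecording:
    """Synthesise one subject's session; see the module docstring for the model."""
    timeline.validate()
    if params is None:
        params = EffectParams()
    if rng is None:
        rng = np.random.default_rng()
    rates = dict(DEFAULT_SAMPLING_RATES)
    if sampling_rates:
        rates.update(sampling_rates)
    duration = timeline.duration
    gain = params.gender_condition_gain[profile.gender]
    out: dict = {}

    # Fixed substream order so that restricting `channels` does not change
    # the samples of the channels that are generated.
    substreams = {name: np.random.default_rng(rng.integers(0, 2**63)) for name in CHANNELS}
    subject_reactivity = float(np.exp(params.subject_reactivity_sd * rng.normal()))

    def _block_factors(r: np.random.Generator) -> dict:
        """Per-block reactivity multiplier, keyed by block onset."""
        return {
            block[0]: subject_reactivity * np.exp(params.block_reactivity_sd * r.normal())
            for block in timeline.blocks
        }

    for site, env_table in (
        ("emg_corrugator", params.corrugator_envelope),
        ("emg_zygomaticus", params.zygomaticus_envelope),
    ):
        if site not in channels:
            continue
        r = substreams[site]
        fs = rates[site]
        n = int(round(duration * fs))
        t = np.arange(n) / fs
        sd = np.full(n, params.emg_resting_sd)
        factors = _block_factors(r)
        for onset, offset, label in timeline.intervals:
            rest = params.emg_resting_sd * np.exp(params.emg_resting_jitter_sd * r.normal())
            i0, i1 = int(round(onset * fs)), int(round(offset * fs))
            if label == FIXATION:
                sd[i0:i1] = rest
            else:
                delta = gain[label] * factors[onset] * (env_table[label] - params.emg_resting_sd)
                sd[i0:i1] = max(rest + delta, 0.2 * params.emg_resting_sd)
        samples = r.normal(0.0, 1.0, n) * sd
        samples += params.powerline_amplitude * np.sin(2 * np.pi * 50.0 * t + r.uniform(0, 2 * np.pi))
        out[site] = (samples, fs, CHANNEL_UNITS[site])

    if "scl" in channels:
        r = substreams["scl"]
        fs = rates["scl"]
        n = int(round(duration * fs))
        t = np.arange(n) / fs
        tonic = (
            params.tonic_base
            + params.age_scl_slope * (profile.age - params.age_midpoint_years)
            + r.normal(0.0, params.tonic_between_subject_sd)
        )
        impulses = np.zeros(n)
        factors = _block_factors(r)
        block_of = {o: o for o, _, _ in timeline.blocks}
        for onset, label in _picture_onsets(timeline, picture_duration):
            block_onset = max(b for b in block_of if b <= onset + 1e-9)
            amp = params.scr_amplitude[label] * gain[label] * factors[block_onset]
            if params.scr_amplitude_cv > 0:
                amp *= max(0.2, 1.0 + params.scr_amplitude_cv * r.normal())
            idx = int(round(onset * fs))
            if idx < n:
                impulses[idx] += amp
        # spontaneous (non-specific) SCRs throughout the session
        n_spont = r.poisson(params.nsscr_rate_per_min * duration / 60.0)
        for t_spont in np.sort(r.uniform(0.0, duration, n_spont)):
            idx = int(round(t_spont * fs))
            if idx < n:
                impulses[idx] += params.nsscr_amplitude * max(
                    0.2, 1.0 + params.scr_amplitude_cv * r.normal()
                )
        kernel = _scr_kernel(fs, params.scr_rise_s, params.scr_decay_s)
        phasic = sps.fftconvolve(impulses, kernel)[:n]
        drift = params.scl_drift_amplitude * np.sin(
            2 * np.pi * t / params.scl_drift_period_s + r.uniform(0, 2 * np.pi)
        )
        samples = tonic + phasic + drift + r.normal(0.0, params.noise_sd["scl"], n)
        out["scl"] = (np.maximum(samples, 0.01), fs, CHANNEL_UNITS["scl"])

    if "bvp" in channels:
        r = substreams["bvp"]
        fs = rates["bvp"]
        n = int(round(duration * fs))
        samples = r.normal(0.0, params.noise_sd["bvp"], n)
        beat_t = 0.2  # first beat shortly after recording start
        pulse_width = 0.25  # s, raised-cosine pulse
        w = int(round(pulse_width * fs))
        shape = 0.5 * (1 - np.cos(2 * np.pi * np.arange(w) / w))
        # slow autonomous drift of the mean heart period, one offset per interval
        drift = {
            iv[0]: params.heart_period_drift_sd_ms * r.normal() for iv in timeline.intervals
        }
        while beat_t < duration:
            label = _label_at(timeline, beat_t)
            offset = next(
                (drift[o] for o, e, _ in reversed(timeline.intervals) if o <= beat_t), 0.0
            )
            i0 = int(round(beat_t * fs))
            i1 = min(i0 + w, n)
            samples[i0:i1] += shape[: i1 - i0]
            period = (
                params.heart_period_ms[label]
                + offset
                + params.heart_period_jitter_ms[label] * r.normal()
            )
            beat_t += max(period, 300.0) / 1000.0
        out["bvp"] = (samples, fs, CHANNEL_UNITS["bvp"])

    return RawRecording(subject_id=profile.subject_id, channels=out)


def simulate_cohort(
    design: StudyDesign,
    *,
    channels: tuple[str, ...] = CHANNELS,
) -> tuple[list[SubjectProfile], EventTimeline, list[RawRecording]]:
    """Generate profiles, one shared timeline, and per-subject recordings.

    Per-subject noise streams are spawned from the design seed and the
    subject index, so the same (design, seed) is byte-reproducible.
    """
    design.validate()
    timeline = generate_timeline(design)
    profiles = generate_profiles(design)
    recordings = []
    for i, profile in enumerate(profiles):
        rng = _rng_for(design, 2, i)
        recordings.append(
            synthesize_recording(
                profile,
                timeline,
                design.effect_params,
                rng,
                sampling_rates=design.sampling_rates,
                picture_duration=design.picture_duration,
                channels=channels,
            )
        )
    return profiles, timeline, recordings


def scaled_design(**overrides) -> StudyDesign:
    """A shorter, lower-rate design for simulation studies.

    Same block structure and effect sizes as the default design, but 3
    pictures per block, 5 s fixation and reduced sampling rates, so that
    cohort-level resampling studies stay tractable.
    """
    base = dict(
        pictures_per_block=3,
        fixation_duration=5.0,
        sampling_rates={
            "emg_corrugator": 512.0,
            "emg_zygomaticus": 512.0,
            "scl": 32.0,
            "bvp": 64.0,
        },
    )
    base.update(overrides)
    return StudyDesign(**base)
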