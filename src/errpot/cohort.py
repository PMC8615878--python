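"""Synthetic multi-subject feedback-locked EEG cohorts.

Emulates the statistical structure of a motor-imagery BCI feedback
experiment: on each trial the subject imagines a limb movement, an online
classifier relays feedback (to the correct or an incorrect limb) 500 ms
after the feedback period starts, and incorrect feedback evokes an
error-related potential (ErrP) — a fronto-central negative deflection
roughly 250 ms after the feedback display, followed by a positive one.

Trials are 1/f (pink) Gaussian noise plus an 8-12 Hz motor-imagery
contaminant; the ErrP template is injected only into incorrect trials.
Per-subject covariate shifts (gain, DC offset, latency jitter, channel
mixing) emulate the cross-subject non-stationarity a domain-adaptation
step must correct.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CHANNELS_17",
    "TASKS",
    "FEEDBACK_LIMBS",
    "ERPTemplate",
    "SubjectShift",
    "CohortConfig",
    "RawEpochSet",
    "make_erp_template",
    "default_topography",
    "default_shifts",
    "apply_subject_shift",
    "generate_subject",
    "generate_cohort",
]

#: 10-20 montage subset used for recording (fronto-central to parietal).
CHANNELS_17 = (
    "Fz", "FC3", "FCz", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CPz", "CP4",
    "P3", "Pz", "P4",
)

TASKS = ("left_hand", "right_hand", "foot")
FEEDBACK_LIMBS = ("left_hand", "right_hand", "left_foot", "right_foot")

# Scalp gain of the ErrP template per channel: strongest over the
# fronto-central midline (anterior cingulate projection), falling off
# laterally and posteriorly.  Deliberately non-uniform so the surface
# Laplacian retains the deflection.
_DEFAULT_TOPO = {
    "FCz": 1.0, "Cz": 0.9, "CPz": 0.7,
    "Fz": 0.5, "C1": 0.45, "C2": 0.45, "FC3": 0.4, "FC4": 0.4,
    "CP3": 0.3, "CP4": 0.3, "Pz": 0.3, "C3": 0.3, "C4": 0.3,
    "C5": 0.15, "C6": 0.15, "P3": 0.15, "P4": 0.15,
}


def default_topography(channel_names=CHANNELS_17) -> np.ndarray:
    """Per-channel ErrP gains peaked over the fronto-central midline."""
    return np.array([_DEFAULT_TOPO[ch] for ch in channel_names])


@dataclass(frozen=True)
class ERPTemplate:
    """Two-lobed ErrP waveform: a negative then a positive Gaussian lobe.

    Latencies are expressed in seconds after the *feedback display*
    (i.e. after the 500 ms relay delay, not after feedback-period onset).
    """

    neg_latency: float
    neg_amp: float
    pos_latency: float
    pos_amp: float
    peak_width: float
    topography: np.ndarray

    def evaluate(self, times: np.ndarray, latency_shift: float = 0.0) -> np.ndarray:
        """Evaluate the template on a time axis (seconds after display).

        Returns an array of shape (n_channels, len(times)).
        ``latency_shift`` displaces both lobes (subject latency jitter).
        """
        t = np.asarray(times, dtype=float)
        w = self.peak_width
        lobe = (
            self.neg_amp * np.exp(-0.5 * ((t - self.neg_latency - latency_shift) / w) ** 2)
            + self.pos_amp * np.exp(-0.5 * ((t - self.pos_latency - latency_shift) / w) ** 2)
        )
        return np.asarray(self.topography)[:, None] * lobe[None, :]


def make_erp_template(
    neg_latency: float = 0.25,
    neg_amp: float = -6.0,
    pos_latency: float = 0.45,
    pos_amp: float = 5.0,
    peak_width: float = 0.05,
    topography: np.ndarray | None = None,
) -> ERPTemplate:
    """Build an ErrP template (defaults: negativity 250 ms after display).

    Parameters are in seconds and microvolts.  A null template
    (both amplitudes zero) is allowed and evaluates to zero everywhere.
    """
    if peak_width <= 0:
        raise ValueError("peak_width must be positive")
    if not (0 < neg_latency < pos_latency):
        raise ValueError("latencies must satisfy 0 < neg_latency < pos_latency")
    if not (neg_amp == pos_amp == 0.0) and not (neg_amp < 0 < pos_amp):
        raise ValueError("need neg_amp < 0 < pos_amp (or both zero for a null template)")
    if topography is None:
        topography = default_topography()
    return ERPTemplate(neg_latency, neg_amp, pos_latency, pos_amp, peak_width,
                       np.asarray(topography, dtype=float))


@dataclass(frozen=True)
class SubjectShift:
    """Affine covariate shift applied to one subject's raw epochs.

    data' = gain * (M(mixing_strength) @ data) + dc_offset, with
    M(s) = (1 - s) I + s * (1/C) 11^T  (uniform cross-channel leakage),
    and template latencies jittered by ``latency_jitter`` at generation.
    The identity shift is (1, 0, 0, 0).
    """

    gain: float = 1.0
    dc_offset: float = 0.0
    latency_jitter: float = 0.0
    mixing_strength: float = 0.0

    def __post_init__(self):
        if self.gain <= 0:
            raise ValueError("gain must be positive")
        if not 0.0 <= self.mixing_strength <= 1.0:
            raise ValueError("mixing_strength must lie in [0, 1]")

    @property
    def is_identity(self) -> bool:
        return (self.gain == 1.0 and self.dc_offset == 0.0
                and self.latency_jitter == 0.0 and self.mixing_strength == 0.0)


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level simulation parameters.

    Time 0 is feedback-period onset; feedback is displayed/stimulated at
    ``feedback_delay`` (the online decoder's 500 ms relay delay); the
    motor-imagery instruction ends at -2.0 s, so the 300 ms baseline
    window is [-2.3, -2.0] s and the default epoch span covers it.
    ``error_rate`` is the probability that a trial's feedback goes to the
    wrong limb (0.2568 reproduces the 74.32 % online accuracy of the
    somato-sensory feedback group; 0.34 the 66 % of the visual group).
    """

    n_subjects: int = 8
    n_trials: int = 96
    error_rate: float = 0.2568
    feedback_delay: float = 0.5
    fs: float = 256.0
    epoch_span: tuple[float, float] = (-2.3, 1.5)
    noise_sd: float = 1.5
    alpha_amp: float = 2.0
    seed: int = 0
    foot_merge: bool = True

    def __post_init__(self):
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must lie in [0, 1]")
        if self.epoch_span[0] >= self.epoch_span[1]:
            raise ValueError("epoch_span must be increasing")
        if self.epoch_span[1] < 1.5 or self.epoch_span[0] > -2.0:
            raise ValueError("epoch_span must cover the baseline window and [0, 1.5] s")
        if self.fs <= 24:  # 2 x highest synthesized frequency (12 Hz)
            raise ValueError("fs must exceed twice the highest synthesized frequency")

    def time_axis(self) -> np.ndarray:
        """Uniform sample grid anchored on integer multiples of 1/fs."""
        k0 = int(np.ceil(self.epoch_span[0] * self.fs - 1e-9))
        k1 = int(np.ceil(self.epoch_span[1] * self.fs - 1e-9))  # half-open end
        return np.arange(k0, k1) / self.fs


@dataclass
class RawEpochSet:
    """Feedback-locked multi-channel EEG trials with labels.

    data is (n_trials, n_channels, n_samples) in microvolts; times are
    seconds relative to feedback-period onset with uniform step 1/fs.
    """

    subject_id: str
    fs: float
    channel_names: tuple[str, ...]
    times: np.ndarray
    data: np.ndarray
    task_label: np.ndarray
    feedback_label: np.ndarray
    correctness: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel axis does not match channel_names")
        if self.data.shape[2] != len(self.times):
            raise ValueError("sample axis does not match times")
        steps = np.diff(self.times)
        if len(steps) and not np.allclose(steps, 1.0 / self.fs, rtol=0, atol=1e-9):
            raise ValueError("times must increase with step exactly 1/fs")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name) if isinstance(self.channel_names, list) \
                else list(self.channel_names).index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epoch set") from None


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    # counter-based derivation: master seed + stable hash of the subject id
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(subject_id.encode()),))
    )


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
                sd: float, fs: float) -> np.ndarray:
    """Gaussian 1/f noise, unit-variance shaped in the frequency domain."""
    white = rng.standard_normal(shape + (n_samples,))
    if sd == 0:
        return np.zeros_like(white)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = 1.0 / np.sqrt(f[nz])
    scale[0] = 0.0  # no DC drift
    pink = np.fft.irfft(spec * scale, n=n_samples, axis=-1)
    pink *= sd / pink.std(axis=-1, keepdims=True)
    return pink


def apply_subject_shift(epochs: RawEpochSet, shift: SubjectShift) -> RawEpochSet:
    """Apply gain/offset/channel-mixing to an epoch set (labels untouched).

    Latency jitter is a generation-time effect and is ignored here.
    The identity shift returns the input unchanged.
    """
    if shift.is_identity:
        return epochs
    data = epochs.data
    s = shift.mixing_strength
    if s > 0:
        mixed = (1.0 - s) * data + s * data.mean(axis=1, keepdims=True)
    else:
        mixed = data
    out = shift.gain * mixed + shift.dc_offset
    return replace(epochs, data=out)


def _draw_labels(rng: np.random.Generator, n_trials: int, error_rate: float):
    task = rng.choice(TASKS, size=n_trials)
    incorrect = rng.random(n_trials) < error_rate
    feedback = np.empty(n_trials, dtype=object)
    for i in range(n_trials):
        t = task[i]
        matching = [t] if t != "foot" else ["left_foot", "right_foot"]
        if incorrect[i]:
            pool = [fb for fb in FEEDBACK_LIMBS if fb not in matching]
        else:
            pool = matching
        feedback[i] = pool[rng.integers(len(pool))]
    correctness = np.where(incorrect, "incorrect", "correct")
    return task.astype(object), feedback, correctness.astype(object)


def generate_subject(config: CohortConfig, shift: SubjectShift,
                     template: ERPTemplate, subject_id: str) -> RawEpochSet:
    """Simulate one subject's feedback-locked epochs.

    Each trial is pink noise + an 8-12 Hz sinusoid (random frequency and
    phase per trial); incorrect trials additionally carry the ErrP
    template locked to the feedback display (onset + feedback_delay),
    with the subject's latency jitter.  The whole epoch set is then
    passed through the subject's affine shift.  Reproducible for a fixed
    (config.seed, subject_id) pair.
    """
    if len(template.topography) != len(CHANNELS_17):
        raise ValueError("template topography must cover the 17-channel montage")
    rng = _subject_rng(config.seed, subject_id)
    times = config.time_axis()
    n_t, n_c, n_s = config.n_trials, len(CHANNELS_17), len(times)

    task, feedback, correctness = _draw_labels(rng, n_t, config.error_rate)

    data = _pink_noise(rng, (n_t, n_c), n_s, config.noise_sd, config.fs)

    # motor-imagery contaminant: fixed amplitude, random freq/phase per trial
    freq = rng.uniform(8.0, 12.0, size=n_t)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=n_t)
    data += config.alpha_amp * np.sin(
        2.0 * np.pi * freq[:, None, None] * times[None, None, :] + phase[:, None, None]
    )

    erp = template.evaluate(times - config.feedback_delay,
                            latency_shift=shift.latency_jitter)
    data[correctness == "incorrect"] += erp[None, :, :]

    epochs = RawEpochSet(
        subject_id=subject_id, fs=config.fs, channel_names=tuple(CHANNELS_17),
        times=times, data=data, task_label=task, feedback_label=feedback,
        correctness=correctness,
    )
    return apply_subject_shift(epochs, replace(shift, latency_jitter=0.0))


def default_shifts(n_subjects: int, seed: int = 0,
                   gain_range: tuple[float, float] = (0.5, 2.0),
                   offset_sd: float = 1.5,
                   jitter_sd: float = 0.06,
                   mixing: float = 0.15) -> list[SubjectShift]:
    """Moderate per-subject covariate shifts.

    Gains are log-uniform over ``gain_range`` (up to 2x amplitude
    differences across heads), DC offsets Gaussian (microvolts), latency
    jitter Gaussian with a 60 ms scale (inter-subject variability of the
    error-potential peak latency, which spans tens of milliseconds), and
    a common channel-mixing strength standing in for electrode
    placement/impedance differences.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed),
                                                       spawn_key=(0xC0F0,)))
    lo, hi = np.log(gain_range[0]), np.log(gain_range[1])
    return [
        SubjectShift(
            gain=float(np.exp(rng.uniform(lo, hi))),
            dc_offset=float(rng.normal(0.0, offset_sd)),
            latency_jitter=float(rng.normal(0.0, jitter_sd)),
            mixing_strength=mixing,
        )
        for _ in range(n_subjects)
    ]


def generate_cohort(config: CohortConfig, shifts: list[SubjectShift],
                    template: ERPTemplate,
                    subject_ids: list[str] | None = None,
                    id_prefix: str = "S") -> list[RawEpochSet]:
    """Simulate ``config.n_subjects`` independent subjects.

    Deterministic given config.seed; subject ids default to
    ``{prefix}01`` ... and may be supplied explicitly.
    """
    if len(shifts) != config.n_subjects:
        raise ValueError("need one SubjectShift per subject")
    if subject_ids is None:
        subject_ids = [f"{id_prefix}{i + 1:02d}"
                       for i in range(config.n_subjects)]
    if len(subject_ids) != config.n_subjects:
        raise ValueError("need one subject id per subject")
    if len(set(subject_ids)) != len(subject_ids):
        raise ValueError("duplicate subject ids")
    return [generate_subject(config, sh, template, sid)
            for sid, sh in zip(subject_ids, shifts)]
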