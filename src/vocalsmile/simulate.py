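"""Synthetic study generator: template-matching observers, main-task
behavioral sessions, and envelope-modulated surface-EMG traces, with
ground truth stored alongside for recovery testing.

Observers are linear template matchers: on each reverse-correlation
trial the internal evidence is the dot product of the trial's band gains
with the observer's spectral template plus Gaussian decision noise; the
trial is classified as smiling when the evidence exceeds the bias. In the
main task the evidence is +/- filter_strength (Smiling-F/Unsmiling-F)
plus the same decision noise, mapped to a 4-level rating by a symmetric
intensity threshold.

EMG epochs are generated as band-limited (50-250 Hz) Gaussian carrier
noise multiplied by a microvolt envelope: a per-muscle baseline tonus,
a tonic task activation, condition-dependent increments (drawn once per
participant, Gaussian across participants), an optional linear
Processing-phase relaxation (the autistic-group pattern), and occasional
high-amplitude movement artifacts. This is an envelope-level model meant
to validate the analysis pipeline, not a motor-unit simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import fft as sfft
from scipy import optimize
from scipy import stats as sps

from .behavior import SMILE_C, SMILING_F, UNSMILE_C, UNSMILING_F
from .emg import MUSCLES, epoch_times
from .stimgen import EqualizerParams, FrequencyGrid, GainProfile, sample_perturbations

__all__ = [
    "ObserverModel",
    "SessionDesign",
    "EmgEffect",
    "EmgGenParams",
    "RevcorrSession",
    "ParticipantData",
    "Cohort",
    "noise_for_consistency",
    "choice_consistency",
    "canonical_template",
    "simulate_revcorr_session",
    "simulate_main_task",
    "simulate_emg_trial",
    "simulate_emg_epochs",
    "simulate_cohort",
    "band_limited_noise",
]

NT, ASD = "NT", "ASD"

# Table-style group covariate distributions (mean, SD)
AQ_DIST = {NT: (15.8, 7.0), ASD: (33.9, 7.0)}
EQ_DIST = {NT: (44.2, 9.0), ASD: (24.9, 15.0)}


@dataclass(frozen=True)
class ObserverModel:
    """Linear template-matching observer with Gaussian decision noise."""

    template: np.ndarray
    decision_noise: float
    bias: float = 0.0
    rating_threshold: float = 0.7

    def __post_init__(self) -> None:
        object.__setattr__(self, "template", np.asarray(self.template, float))
        if self.decision_noise < 0:
            raise ValueError("decision_noise must be >= 0")


@dataclass(frozen=True)
class SessionDesign:
    """Main-task session timing (ms) and trial counts."""

    n_sentences: int = 80
    n_speakers: int = 10
    tone_dur_ms: float = 300.0
    pre_sentence_gap_ms: float = 1000.0
    sentence_dur_ms: float = 1900.0
    post_silence_ms: float = 2000.0
    rating_window_ms: float = 5000.0

    def __post_init__(self) -> None:
        if self.n_sentences % 2:
            raise ValueError("n_sentences must be even (balanced filters)")
        for v in (self.tone_dur_ms, self.pre_sentence_gap_ms,
                  self.sentence_dur_ms, self.post_silence_ms,
                  self.rating_window_ms):
            if v <= 0:
                raise ValueError("durations must be positive")

    @property
    def trial_spacing_ms(self) -> float:
        return (self.tone_dur_ms + self.pre_sentence_gap_ms
                + self.sentence_dur_ms + self.post_silence_ms
                + self.rating_window_ms)


@dataclass(frozen=True)
class EmgEffect:
    """One envelope increment: applies to `muscle`, restricted to `group`
    (None = both) and optionally to trials matching a condition label
    (factor 'filter' or 'choice' at `level`); active inside `window_ms`
    with cosine on/off ramps. Amplitude is Gaussian across participants."""

    muscle: str
    window_ms: tuple[float, float]
    mean_uv: float
    sd_uv: float
    group: str | None = None
    factor: str | None = None
    level: str | None = None


def default_effects() -> list[EmgEffect]:
    """Defaults encode the qualitative group pattern: tonic task activation
    larger on CS than ZM in both groups; in NT only, a ZM increment for
    Smiling-F sentences and a CS increment for Unsmile-C choices in the
    late Processing phase (subject-level standardized effect ~0.9)."""
    return [
        EmgEffect("zm", (0.0, 4000.0), 0.8, 0.5),
        EmgEffect("cs", (0.0, 4000.0), 1.6, 0.8),
        EmgEffect("zm", (2400.0, 3900.0), 1.0, 1.0, group=NT,
                  factor="filter", level=SMILING_F),
        EmgEffect("cs", (2400.0, 3900.0), 1.2, 1.2, group=NT,
                  factor="choice", level=UNSMILE_C),
    ]


@dataclass(frozen=True)
class EmgGenParams:
    fs: float = 1024.0
    baseline_tonus: dict = field(default_factory=lambda: {"zm": 4.0, "cs": 6.0})
    carrier_band: tuple[float, float] = (50.0, 250.0)
    effects: list[EmgEffect] = field(default_factory=default_effects)
    asd_relaxation: tuple[float, float] = (0.15, 0.08)  # fraction (mean, sd)
    artifact_rate: float = 0.2
    artifact_amp: float = 150.0
    epoch_span_ms: tuple[float, float] = (-800.0, 4000.0)
    ramp_ms: float = 150.0

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.carrier_band[1]:
            raise ValueError("fs must exceed twice the carrier upper edge")
        if not (0.0 <= self.artifact_rate <= 1.0):
            raise ValueError("artifact_rate must be in [0, 1]")
        if any(v <= 0 for v in self.baseline_tonus.values()):
            raise ValueError("baseline_tonus must be positive")


@dataclass
class RevcorrSession:
    """Vectorized reverse-correlation session: gains (n_trials, n_bands),
    choices ('smile'/'unsmile'); iterable as (GainProfile, choice) pairs."""

    grid: FrequencyGrid
    gains: np.ndarray
    choices: np.ndarray

    def __iter__(self) -> Iterator[tuple[GainProfile, str]]:
        for i in range(len(self.choices)):
            yield GainProfile(self.grid, self.gains[i], i), str(self.choices[i])

    def to_frame(self) -> pd.DataFrame:
        n, b = self.gains.shape
        return pd.DataFrame({
            "trial_id": np.repeat(np.arange(n), b),
            "choice": np.repeat(self.choices, b),
            "band_hz": np.tile(self.grid.bands, n),
            "gain_db": self.gains.ravel(),
        })


def canonical_template(grid: FrequencyGrid) -> np.ndarray:
    """Smooth vocal-smile template on a frequency grid: positive weight on
    the mid-frequency (formant-raised) region ~500-2000 Hz, negative weight
    on the low flank, fading out above 5 kHz. Unit-norm."""
    log_f = np.log(grid.bands)
    bump = np.exp(-0.5 * ((log_f - np.log(1000.0)) / 0.55) ** 2)
    dip = -0.6 * np.exp(-0.5 * ((log_f - np.log(250.0)) / 0.4) ** 2)
    t = bump + dip
    return t / np.linalg.norm(t)


_HERMEGAUSS = np.polynomial.hermite_e.hermegauss(81)


def choice_consistency(signal_sd: float, noise_sd: float) -> float:
    """Probability a template observer repeats its choice on an identical
    stimulus: E[p^2 + (1-p)^2] with p = Phi(s/noise), s ~ N(0, signal_sd)."""
    if noise_sd == 0:
        return 1.0
    nodes, weights = _HERMEGAUSS
    p = sps.norm.cdf(signal_sd * nodes / noise_sd)
    vals = p**2 + (1 - p) ** 2
    return float(np.sum(weights * vals) / np.sqrt(2 * np.pi))


@lru_cache(maxsize=128)
def _noise_for_signal_sd(signal_sd: float, consistency: float) -> float:
    f = lambda s: choice_consistency(signal_sd, s) - consistency
    return float(optimize.brentq(f, 1e-9 * signal_sd, 1e4 * signal_sd))


def noise_for_consistency(template: np.ndarray, params: EqualizerParams,
                          consistency: float = 0.75) -> float:
    """Decision-noise SD giving the requested double-pass choice
    consistency for gains drawn under `params`."""
    if not (0.5 < consistency < 1.0):
        raise ValueError("consistency must be in (0.5, 1)")
    # per-band SD after hard clipping at c SDs
    c = params.clip_sd
    var_factor = (1 - 2 * c * sps.norm.pdf(c) - 2 * sps.norm.sf(c)
                  + 2 * c**2 * sps.norm.sf(c))
    signal_sd = params.sd_db * np.sqrt(var_factor) * np.linalg.norm(template)
    return _noise_for_signal_sd(round(signal_sd, 12), consistency)


def simulate_revcorr_session(observer: ObserverModel, params: EqualizerParams,
                             n_trials: int, rng: np.random.Generator) -> RevcorrSession:
    """Simulate template-observer choices over random equalizer trials."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    gains = sample_perturbations(params, n_trials, rng)
    evidence = gains @ observer.template
    if observer.decision_noise > 0:
        evidence = evidence + rng.normal(0.0, observer.decision_noise, n_trials)
    choices = np.where(evidence > observer.bias, "smile", "unsmile")
    return RevcorrSession(params.grid, gains, choices)


def simulate_main_task(observer: ObserverModel, design: SessionDesign,
                       filter_strength: float, rng: np.random.Generator) -> pd.DataFrame:
    """Simulate an 80-sentence rating session with balanced filters.

    Evidence e = +/- filter_strength + N(0, decision_noise); ratings
    1..4 from thresholds (-rating_threshold, 0, +rating_threshold); the
    binary choice is the rating sign and `correct` flags congruence with
    the filter.
    """
    n = design.n_sentences
    filters = np.array([SMILING_F, UNSMILING_F]).repeat(n // 2)
    rng.shuffle(filters)
    sign = np.where(filters == SMILING_F, 1.0, -1.0)
    e = sign * filter_strength
    if observer.decision_noise > 0:
        e = e + rng.normal(0.0, observer.decision_noise, n)
    thr = observer.rating_threshold
    rating = np.select([e < -thr, e < 0, e < thr], [1, 2, 3], default=4)
    choice = np.where(rating >= 3, SMILE_C, UNSMILE_C)
    speakers = rng.integers(0, design.n_speakers, n)
    return pd.DataFrame({
        "sentence_id": np.arange(n),
        "speaker": speakers,
        "filter": filters,
        "rating": rating,
        "choice": choice,
        "correct": (filters == SMILING_F) == (choice == SMILE_C),
    })


def random_responder_accuracies(n_sessions: int, rng: np.random.Generator,
                                design: SessionDesign = SessionDesign()
                                ) -> np.ndarray:
    """Session accuracies of a responder pressing each of the four rating
    keys uniformly at random on balanced 40/40 sessions (the chance-level
    reference for the accuracy measure)."""
    n = design.n_sentences
    filters_smiling = np.arange(n) < n // 2  # balanced; order irrelevant
    ratings = rng.integers(1, 5, size=(n_sessions, n))
    smile_choice = ratings >= 3
    correct = smile_choice == filters_smiling[None, :]
    return correct.mean(axis=1)


def band_limited_noise(n_samples: int, fs: float, band: tuple[float, float],
                       rng: np.random.Generator, shape: tuple = (),
                       dtype=np.float64) -> np.ndarray:
    """Unit-variance Gaussian noise with spectral support confined to `band`
    (frequency-domain synthesis; out-of-band power is exactly zero)."""
    n_freq = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    n_band = int(mask.sum())
    cdtype = np.complex64 if dtype == np.float32 else np.complex128
    coeff = np.zeros(shape + (n_freq,), dtype=cdtype)
    draws = rng.standard_normal(size=shape + (2, n_band), dtype=dtype)
    coeff[..., mask] = draws[..., 0, :] + 1j * draws[..., 1, :]
    x = sfft.irfft(coeff, n=n_samples)
    # irfft carries a 1/n factor; rescale to unit time-domain variance
    scale = n_samples / (2.0 * np.sqrt(n_band))
    x *= scale
    return x


def _cosine_window(times_ms: np.ndarray, window_ms: tuple[float, float],
                   ramp_ms: float) -> np.ndarray:
    """0->1->0 activation profile over `window_ms` with cosine ramps."""
    lo, hi = window_ms
    up = np.clip((times_ms - lo) / ramp_ms, 0.0, 1.0)
    down = np.clip((hi - times_ms) / ramp_ms, 0.0, 1.0)
    return 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down))


def draw_subject_effects(params: EmgGenParams, group: str,
                         rng: np.random.Generator) -> dict:
    """Per-participant realization of effect amplitudes and relaxation."""
    amps = [float(rng.normal(e.mean_uv, e.sd_uv)) for e in params.effects]
    relax = 0.0
    if group == ASD:
        relax = float(np.clip(rng.normal(*params.asd_relaxation), 0.0, 0.9))
    return {"effect_amps_uv": amps, "relaxation_fraction": relax}


def _trial_envelope(params: EmgGenParams, times_ms: np.ndarray, muscle: str,
                    group: str, filt: str, choice: str,
                    subject_effects: dict) -> np.ndarray:
    env = np.full(times_ms.shape, params.baseline_tonus[muscle])
    for amp, eff in zip(subject_effects["effect_amps_uv"], params.effects):
        if eff.muscle != muscle:
            continue
        if eff.group is not None and eff.group != group:
            continue
        if eff.factor == "filter" and filt != eff.level:
            continue
        if eff.factor == "choice" and choice != eff.level:
            continue
        env = env + amp * _cosine_window(times_ms, eff.window_ms, params.ramp_ms)
    relax = subject_effects["relaxation_fraction"]
    if relax > 0:
        t0, t1 = 1900.0, times_ms[-1]
        decline = 1.0 - relax * np.clip((times_ms - t0) / (t1 - t0), 0.0, 1.0)
        env = env * decline
    return np.maximum(env, 0.05 * min(params.baseline_tonus.values()))


def _artifact(times_ms: np.ndarray, fs: float, amp: float,
              rng: np.random.Generator) -> np.ndarray:
    """Movement artifact: a low-frequency sway plus a broadband burst at a
    random latency (the broadband part survives the 50 Hz high-pass)."""
    t0 = rng.uniform(times_ms[0] + 150, times_ms[-1] - 150)
    width = 250.0
    win = _cosine_window(times_ms, (t0 - width / 2, t0 + width / 2), width / 3)
    sway = amp * win * np.sin(2 * np.pi * 8.0 * (times_ms - t0) / 1000.0)
    burst = 0.5 * amp * win * rng.normal(size=times_ms.size)
    return sway + burst


def simulate_emg_trial(params: EmgGenParams, group: str, muscle: str,
                       filt: str, choice: str, rng: np.random.Generator,
                       subject_effects: dict | None = None) -> np.ndarray:
    """One epoch-spanning raw EMG trace (microvolts) for a labeled trial."""
    if group not in (NT, ASD) or muscle not in MUSCLES:
        raise ValueError("invalid group or muscle label")
    if subject_effects is None:
        subject_effects = {"effect_amps_uv": [e.mean_uv for e in params.effects],
                           "relaxation_fraction":
                               params.asd_relaxation[0] if group == ASD else 0.0}
    times = epoch_times(params.fs, *params.epoch_span_ms)
    env = _trial_envelope(params, times, muscle, group, filt, choice,
                          subject_effects)
    carrier = band_limited_noise(times.size, params.fs, params.carrier_band, rng)
    trace = env * carrier
    if params.artifact_rate > 0 and rng.random() < params.artifact_rate:
        trace = trace + _artifact(times, params.fs, params.artifact_amp, rng)
    return trace


def simulate_emg_epochs(params: EmgGenParams, behavior: pd.DataFrame,
                        group: str, rng: np.random.Generator,
                        subject_effects: dict, dtype=np.float32
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Epoch stack (n_trials, n_muscles, n_samples) for a whole session;
    artifacts hit both muscles of a trial at the same latency.

    Returns (data, artifact_hit) so the ground truth of which trials were
    contaminated is available for rejection-recovery tests."""
    times = epoch_times(params.fs, *params.epoch_span_ms)
    n_trials = len(behavior)
    n_samp = times.size
    carrier = band_limited_noise(n_samp, params.fs, params.carrier_band, rng,
                                 shape=(n_trials, len(MUSCLES)), dtype=dtype)
    data = np.empty_like(carrier)
    env_cache: dict[tuple, np.ndarray] = {}
    filters = behavior["filter"].to_numpy()
    choices = behavior["choice"].to_numpy()
    for j, muscle in enumerate(MUSCLES):
        for i in range(n_trials):
            key = (muscle, filters[i], choices[i])
            env = env_cache.get(key)
            if env is None:
                env = _trial_envelope(params, times, muscle, group,
                                      filters[i], choices[i], subject_effects)
                env_cache[key] = env
            data[i, j] = env * carrier[i, j]
    hit = np.zeros(n_trials, dtype=bool)
    if params.artifact_rate > 0:
        hit = rng.random(n_trials) < params.artifact_rate
        for i in np.nonzero(hit)[0]:
            art = _artifact(times, params.fs, params.artifact_amp, rng)
            data[i] += art  # same movement on both channels
    return data, hit


@dataclass
class ParticipantData:
    participant_id: str
    group: str
    aq: float
    eq: float
    revcorr: RevcorrSession | None
    behavior: pd.DataFrame
    emg: np.ndarray | None
    ground_truth: dict


@dataclass
class Cohort:
    participants: pd.DataFrame
    data: dict[str, ParticipantData]
    emg_params: EmgGenParams
    eq_params: EqualizerParams
    design: SessionDesign
    seed: int


def simulate_cohort(seed: int, n_nt: int = 21, n_asd: int = 20,
                    eq_params: EqualizerParams = EqualizerParams(),
                    design: SessionDesign = SessionDesign(),
                    emg_params: EmgGenParams = EmgGenParams(),
                    n_revcorr_trials: int = 600,
                    consistency: float = 0.75,
                    accuracy_target: float = 0.75,
                    template_jitter: float = 0.25,
                    include_revcorr: bool = True,
                    include_emg: bool = True,
                    null_effects: bool = False) -> Cohort:
    """Simulate a full two-group study cohort.

    Each participant gets group covariates (AQ/EQ), a template-matching
    observer (canonical vocal-smile template plus individual jitter,
    decision noise set for ~`consistency` double-pass choice consistency),
    one reverse-correlation session, one 80-sentence main-task session
    (filter strength set for ~`accuracy_target` expected accuracy), and
    EMG epochs for every sentence. Ground truth is stored per participant.

    Per-participant random substreams are derived from (seed, index), so
    enlarging the cohort leaves earlier participants bit-identical.
    `null_effects` zeroes all condition effects and the relaxation (for
    false-positive-rate studies) while keeping the tonic activations.
    """
    if n_nt < 2 or n_asd < 2:
        raise ValueError("need >= 2 participants per group")
    if null_effects:
        effects = [e for e in emg_params.effects if e.factor is None]
        emg_params = EmgGenParams(
            fs=emg_params.fs, baseline_tonus=emg_params.baseline_tonus,
            carrier_band=emg_params.carrier_band, effects=effects,
            asd_relaxation=(0.0, 0.0), artifact_rate=emg_params.artifact_rate,
            artifact_amp=emg_params.artifact_amp,
            epoch_span_ms=emg_params.epoch_span_ms, ramp_ms=emg_params.ramp_ms)

    grid = eq_params.grid
    base_template = canonical_template(grid)
    groups = [NT] * n_nt + [ASD] * n_asd
    rows, data = [], {}
    for idx, group in enumerate(groups):
        rng = np.random.default_rng([seed, idx])
        pid = f"{group.lower()}{idx:02d}"
        aq = float(rng.normal(*AQ_DIST[group]))
        eq = float(rng.normal(*EQ_DIST[group]))
        jitter = rng.normal(0.0, template_jitter, grid.n_bands)
        template = base_template + jitter * np.abs(base_template).mean()
        template /= np.linalg.norm(template)
        noise = noise_for_consistency(template, eq_params, consistency)
        observer = ObserverModel(template, noise,
                                 rating_threshold=0.7 * noise)
        filter_strength = float(sps.norm.ppf(accuracy_target) * noise)

        revc = (simulate_revcorr_session(observer, eq_params,
                                         n_revcorr_trials, rng)
                if include_revcorr else None)
        behav = simulate_main_task(observer, design, filter_strength, rng)
        subject_effects = draw_subject_effects(emg_params, group, rng)
        emg, artifact_hit = (
            simulate_emg_epochs(emg_params, behav, group, rng,
                                subject_effects)
            if include_emg else (None, None))
        truth = {
            "template": template.tolist(),
            "decision_noise": noise,
            "filter_strength": filter_strength,
            **subject_effects,
        }
        if artifact_hit is not None:
            truth["artifact_trials"] = np.nonzero(artifact_hit)[0].tolist()
        rows.append({"participant_id": pid, "group": group,
                     "aq": aq, "eq": eq})
        data[pid] = ParticipantData(pid, group, aq, eq, revc, behav, emg, truth)
    return Cohort(pd.DataFrame(rows), data, emg_params, eq_params, design, seed)
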