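"""Random spectral-equalizer stimuli and the parameterized smile filter.

The reverse-correlation stimuli are spectral perturbations of a base voiced
sound: a gain value (in dB) is drawn independently for each band of a
log-spaced frequency grid from a zero-mean Gaussian (default SD 5 dB,
hard-clipped at +/-2.5 SD) and interpolated linearly over log-frequency
to form a random equalizer curve.

The "smile filter" emulates the acoustic signature of smiled speech: an
upward shift of the spectral envelope in the first/second-formant region
plus an energy boost in the mid-frequency (F2-F4) region. The unsmiling
direction applies the inverse transform. Magnitudes are parameterized;
the transform operates on the signal's own smoothed spectral envelope so
that the two directions are (approximate) inverses of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrequencyGrid",
    "GainProfile",
    "EqualizerParams",
    "SmileFilterParams",
    "make_frequency_grid",
    "sample_perturbation",
    "sample_perturbations",
    "interpolate_gain",
    "gain_curve",
    "apply_equalizer",
    "apply_smile_filter",
    "harmonic_tone",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """Strictly ascending, log-spaced band center frequencies in Hz."""

    bands: np.ndarray

    def __post_init__(self) -> None:
        bands = np.asarray(self.bands, dtype=float)
        object.__setattr__(self, "bands", bands)
        if bands.ndim != 1 or bands.size < 2:
            raise ValueError("grid needs at least two bands")
        if np.any(np.diff(bands) <= 0) or bands[0] <= 0:
            raise ValueError("bands must be positive and strictly ascending")
        ratios = bands[1:] / bands[:-1]
        if not np.allclose(ratios, ratios[0], rtol=1e-9):
            raise ValueError("bands must be log-spaced (constant ratio)")

    @property
    def n_bands(self) -> int:
        return self.bands.size

    @property
    def f_min(self) -> float:
        return float(self.bands[0])

    @property
    def f_max(self) -> float:
        return float(self.bands[-1])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyGrid):
            return NotImplemented
        return self.bands.shape == other.bands.shape and np.allclose(
            self.bands, other.bands, rtol=1e-12
        )


@dataclass(frozen=True)
class GainProfile:
    """One trial's spectral perturbation: gain in dB at each grid band."""

    grid: FrequencyGrid
    gains: np.ndarray
    trial_id: int = 0

    def __post_init__(self) -> None:
        gains = np.asarray(self.gains, dtype=float)
        object.__setattr__(self, "gains", gains)
        if gains.shape != self.grid.bands.shape:
            raise ValueError("gains must have one value per grid band")


@dataclass(frozen=True)
class EqualizerParams:
    """Random-equalizer configuration (defaults: 25 bands 100-10000 Hz,
    SD 5 dB, clipped at +/-2.5 SD)."""

    n_bands: int = 25
    f_min: float = 100.0
    f_max: float = 10_000.0
    sd_db: float = 5.0
    clip_sd: float = 2.5

    def __post_init__(self) -> None:
        if self.n_bands < 2:
            raise ValueError("n_bands must be >= 2")
        if not (0 < self.f_min < self.f_max):
            raise ValueError("need 0 < f_min < f_max")
        if self.sd_db < 0 or self.clip_sd <= 0:
            raise ValueError("sd_db must be >= 0 and clip_sd > 0")

    @property
    def grid(self) -> FrequencyGrid:
        return make_frequency_grid(self.n_bands, self.f_min, self.f_max)

    @property
    def clip_db(self) -> float:
        return self.clip_sd * self.sd_db


@dataclass(frozen=True)
class SmileFilterParams:
    """Parameterized smile transform.

    formant_shift_ratio : multiplicative upward shift of the spectral
        envelope inside the F1/F2 region (smiling; unsmiling shifts down).
    band_energy_gain_db : dB boost of the F2-F4 energy region (smiling;
        unsmiling attenuates).
    """

    formant_shift_ratio: float = 1.05
    band_energy_gain_db: float = 2.0
    direction: str = "smiling"
    shift_region_hz: tuple[float, float] = (300.0, 2500.0)
    boost_region_hz: tuple[float, float] = (1000.0, 4500.0)

    def __post_init__(self) -> None:
        if self.formant_shift_ratio <= 0:
            raise ValueError("formant_shift_ratio must be > 0")
        if self.direction not in ("smiling", "unsmiling"):
            raise ValueError("direction must be 'smiling' or 'unsmiling'")


def make_frequency_grid(n_bands: int, f_min: float, f_max: float) -> FrequencyGrid:
    """Geometric progression of `n_bands` frequencies from f_min to f_max."""
    if n_bands < 2:
        raise ValueError("n_bands must be >= 2")
    if not (0 < f_min < f_max):
        raise ValueError("need 0 < f_min < f_max")
    return FrequencyGrid(np.geomspace(f_min, f_max, n_bands))


def sample_perturbations(
    params: EqualizerParams, n_trials: int, rng: np.random.Generator
) -> np.ndarray:
    """Matrix of `n_trials` independent gain profiles, shape (n_trials, n_bands).

    Per-band draws are N(0, sd_db**2) hard-clipped to +/-clip_sd*sd_db.
    """
    g = rng.normal(0.0, params.sd_db, size=(n_trials, params.n_bands))
    bound = params.clip_db
    np.clip(g, -bound, bound, out=g)
    return g


def sample_perturbation(params: EqualizerParams, rng: np.random.Generator,
                        trial_id: int = 0) -> GainProfile:
    gains = sample_perturbations(params, 1, rng)[0]
    return GainProfile(params.grid, gains, trial_id)


def interpolate_gain(profile: GainProfile, f) -> np.ndarray | float:
    """Gain in dB at frequency f, linear over log-frequency; exact at bands.

    Raises for frequencies outside [f_min, f_max].
    """
    f_arr = np.asarray(f, dtype=float)
    grid = profile.grid
    if np.any(f_arr < grid.f_min) or np.any(f_arr > grid.f_max):
        raise ValueError("frequency outside the equalizer grid")
    out = np.interp(np.log(f_arr), np.log(grid.bands), profile.gains)
    return float(out) if np.isscalar(f) or f_arr.ndim == 0 else out


def gain_curve(profile: GainProfile, freqs: np.ndarray) -> np.ndarray:
    """Gain in dB at arbitrary frequencies with flat extrapolation outside
    the grid (used when realizing the equalizer on a full spectrum)."""
    freqs = np.asarray(freqs, dtype=float)
    safe = np.maximum(freqs, 1e-12)  # log of the DC bin
    return np.interp(np.log(safe), np.log(profile.grid.bands), profile.gains)


def apply_equalizer(audio: np.ndarray, fs: float, profile: GainProfile) -> np.ndarray:
    """Apply a gain profile to a waveform via a single zero-phase FFT multiply."""
    audio = np.asarray(audio, dtype=float)
    if audio.size == 0:
        raise ValueError("audio must be non-empty")
    if fs <= 2 * profile.grid.f_max:
        raise ValueError("sampling rate must exceed twice the top band")
    spec = np.fft.rfft(audio)
    freqs = np.fft.rfftfreq(audio.size, d=1.0 / fs)
    spec *= 10.0 ** (gain_curve(profile, freqs) / 20.0)
    return np.fft.irfft(spec, n=audio.size)


def _raised_cosine_mask(log_f: np.ndarray, lo: float, hi: float,
                        skirt_oct: float = 0.5) -> np.ndarray:
    """Smooth 0->1->0 mask over [lo, hi] Hz with cosine skirts (log axis)."""
    s = skirt_oct * np.log(2.0)
    llo, lhi = np.log(lo), np.log(hi)
    up = np.clip((log_f - (llo - s)) / s, 0.0, 1.0)
    down = np.clip(((lhi + s) - log_f) / s, 0.0, 1.0)
    return 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down))


def _spectral_envelope_db(mag: np.ndarray, freqs: np.ndarray,
                          smooth_oct: float = 1.0 / 3.0) -> np.ndarray:
    """Smoothed log-magnitude envelope, computed on a dense log-f grid."""
    pos = freqs > 0
    log_f = np.log(freqs[pos])
    power_db = 10.0 * np.log10(np.maximum(mag[pos] ** 2, 1e-300))
    # uniform log-f grid at 1/48 octave, boxcar smoothing over smooth_oct
    step = np.log(2.0) / 48.0
    grid = np.arange(log_f[0], log_f[-1] + step / 2, step)
    on_grid = np.interp(grid, log_f, power_db)
    half = max(1, int(round(smooth_oct * np.log(2.0) / step / 2)))
    kernel = np.ones(2 * half + 1)
    counts = np.convolve(np.ones_like(on_grid), kernel, mode="same")
    smoothed = np.convolve(on_grid, kernel, mode="same") / counts
    env = np.empty_like(freqs)
    env[pos] = np.interp(log_f, grid, smoothed)
    env[~pos] = env[pos][0]
    return env / 2.0  # back to amplitude dB


def smile_gain_curve(audio: np.ndarray, fs: float,
                     params: SmileFilterParams) -> tuple[np.ndarray, np.ndarray]:
    """dB gain per rfft bin realizing the smile/unsmile transform for this
    signal, derived from its own spectral envelope. Returns (freqs, gain_db)."""
    spec = np.fft.rfft(np.asarray(audio, dtype=float))
    freqs = np.fft.rfftfreq(audio.size, d=1.0 / fs)
    env = _spectral_envelope_db(np.abs(spec), freqs)
    sign = 1.0 if params.direction == "smiling" else -1.0
    pos = freqs > 0
    log_f = np.log(np.maximum(freqs, freqs[pos][0]))
    shift_mask = _raised_cosine_mask(log_f, *params.shift_region_hz)
    boost_mask = _raised_cosine_mask(log_f, *params.boost_region_hz)
    # envelope value transported from the (un)shifted frequency
    src_log_f = log_f - sign * np.log(params.formant_shift_ratio) * shift_mask
    grid_log_f = log_f[pos]
    shifted_env = np.interp(src_log_f, grid_log_f, env[pos])
    gain_db = (shifted_env - env) + sign * params.band_energy_gain_db * boost_mask
    gain_db[~pos] = 0.0
    return freqs, gain_db


def apply_smile_filter(audio: np.ndarray, fs: float,
                       params: SmileFilterParams) -> np.ndarray:
    """Shift the F1/F2 spectral-envelope region and boost the F2-F4 energy
    region (smiling), or apply the inverse transform (unsmiling)."""
    audio = np.asarray(audio, dtype=float)
    if audio.size == 0:
        raise ValueError("audio must be non-empty")
    if params.formant_shift_ratio == 1.0 and params.band_energy_gain_db == 0.0:
        return audio.copy()
    spec = np.fft.rfft(audio)
    _, gain_db = smile_gain_curve(audio, fs, params)
    spec *= 10.0 ** (gain_db / 20.0)
    return np.fft.irfft(spec, n=audio.size)


def harmonic_tone(dur: float = 0.5, fs: float = 44_100.0, f0: float = 120.0,
                  n_harmonics: int = 60) -> np.ndarray:
    """Synthetic /a/-like voiced tone: constant-pitch harmonic series shaped
    by two broad resonances (700 and 1200 Hz), used as the base stimulus for
    equalizer demos. Peak-normalized to 0.9."""
    t = np.arange(int(round(dur * fs))) / fs
    out = np.zeros_like(t)
    for k in range(1, n_harmonics + 1):
        f = k * f0
        if f >= fs / 2:
            break
        res = sum(1.0 / (1.0 + ((f - fc) / bw) ** 2)
                  for fc, bw in ((700.0, 250.0), (1200.0, 350.0)))
        out += (res + 0.05) / k**0.3 * np.sin(2 * np.pi * f * t)
    # 10 ms cosine fade in/out
    n_fade = int(round(0.01 * fs))
    fade = 0.5 * (1 - np.cos(np.pi * np.arange(n_fade) / n_fade))
    out[:n_fade] *= fade
    out[-n_fade:] *= fade[::-1]
    return 0.9 * out / np.max(np.abs(out))
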