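"""Synthesis of behavioral acoustic stimuli and spectral verification utilities.

Vowel tokens are produced the way classic formant synthesizers do it: a
periodic click train (glottal-pulse surrogate) is passed through four
two-pole resonators in parallel, one per formant.  Broadband-noise maskers
and localization bursts are Gaussian noise, optionally low-pass filtered,
with raised-cosine on/off ramps.  All levels are software dB SPL referenced
to RMS 1.0 == ``SPL_REF_DB`` (no hardware calibration is modeled).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.io import wavfile

#: Default sample rate (Hz).  TDT-style hardware rate used for the
#: localization stimuli; vowel synthesis uses the same rate by default.
DEFAULT_FS_HZ = 48828.125

#: Software SPL reference: a waveform with RMS 1.0 sits at this level.
SPL_REF_DB = 94.0

#: Default formant bandwidths B1-B4 (Hz); typical speech-synthesis values.
DEFAULT_BANDWIDTHS_HZ = (60.0, 90.0, 150.0, 200.0)

#: Four-formant vowel table (F1-F4 in Hz) used in the discrimination task.
VOWEL_FORMANTS_HZ = {
    "u": (460.0, 1105.0, 2857.0, 4205.0),
    "e": (730.0, 2058.0, 2857.0, 4205.0),  # /ε/
    "a": (936.0, 1551.0, 2975.0, 4263.0),
    "i": (437.0, 2761.0, 2975.0, 4263.0),
}

DEFAULT_F0_HZ = 200.0
DEFAULT_TOKEN_MS = 250.0
DEFAULT_GAP_MS = 250.0
DEFAULT_RAMP_MS = 5.0


class StimulusParameterError(ValueError):
    """Raised when a stimulus parameter is outside its valid range."""


@dataclass(frozen=True)
class VowelSpec:
    """Specification of one synthetic vowel token."""

    label: str
    formants_hz: tuple[float, float, float, float]
    f0_hz: float = DEFAULT_F0_HZ
    duration_ms: float = DEFAULT_TOKEN_MS
    level_db: float = 70.0
    bandwidths_hz: tuple[float, float, float, float] = DEFAULT_BANDWIDTHS_HZ

    def __post_init__(self) -> None:
        if len(self.formants_hz) != 4:
            raise StimulusParameterError("exactly four formants required")
        if any(b <= a for a, b in zip(self.formants_hz, self.formants_hz[1:])):
            raise StimulusParameterError("formants must be strictly increasing")
        if self.f0_hz <= 0:
            raise StimulusParameterError("f0_hz must be positive")
        if self.duration_ms <= 0:
            raise StimulusParameterError("duration_ms must be positive")

    @classmethod
    def standard(cls, label: str, level_db: float = 70.0) -> "VowelSpec":
        """A vowel from the task's four-formant table."""
        return cls(label=label, formants_hz=VOWEL_FORMANTS_HZ[label], level_db=level_db)


@dataclass(frozen=True)
class MaskerConfig:
    """Noise-masker placement for one trial.

    ``mode`` is one of ``clean`` (no noise), ``colocated`` (noise on the same
    speaker(s) as the vowel) or ``separated`` (noise on the opposite speaker).
    Two-speaker presentation uses 70 dB SPL noise; single-speaker uses 67.
    """

    mode: str = "clean"
    noise_level_db: float = 70.0
    vowel_side: str = "both"

    def __post_init__(self) -> None:
        if self.mode not in ("clean", "colocated", "separated"):
            raise StimulusParameterError(f"unknown masker mode {self.mode!r}")
        if self.vowel_side not in ("left", "right", "both"):
            raise StimulusParameterError(f"unknown vowel side {self.vowel_side!r}")
        if self.mode == "separated" and self.vowel_side == "both":
            raise StimulusParameterError("separated masker needs a single vowel side")


@dataclass
class StimulusTimeline:
    """Multi-channel trial stimulus plus a named event list (times in ms)."""

    fs_hz: float
    channels: dict[str, np.ndarray]
    events: list[tuple[str, float, float]] = field(default_factory=list)

    @property
    def duration_ms(self) -> float:
        n = max(len(v) for v in self.channels.values())
        return 1000.0 * n / self.fs_hz

    def manifest(self) -> dict:
        return {
            "fs_hz": self.fs_hz,
            "channels": sorted(self.channels),
            "events": [
                {"name": n, "onset_ms": a, "offset_ms": b} for n, a, b in self.events
            ],
        }

    def save(self, directory, prefix: str = "stimulus") -> None:
        """Write one float32 WAV per channel plus a JSON event manifest."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, buf in self.channels.items():
            wavfile.write(
                directory / f"{prefix}_{name}.wav",
                int(round(self.fs_hz)),
                buf.astype(np.float32),
            )
        (directory / f"{prefix}.json").write_text(json.dumps(self.manifest(), indent=2))


def db_to_rms(level_db: float) -> float:
    """Target RMS amplitude for a software SPL level."""
    return 10.0 ** ((level_db - SPL_REF_DB) / 20.0)


def make_click_train(
    f0_hz: float, duration_ms: float, fs_hz: float = DEFAULT_FS_HZ
) -> np.ndarray:
    """Unit-amplitude impulse train at the fundamental period, first click at 0.

    The period ``fs/f0`` need not be integer; click positions are rounded to
    the nearest sample so the long-run rate stays exact.
    """
    if f0_hz <= 0:
        raise StimulusParameterError("f0_hz must be positive")
    if duration_ms < 0:
        raise StimulusParameterError("duration_ms must be non-negative")
    n = int(round(duration_ms * fs_hz / 1000.0))
    out = np.zeros(n)
    if n == 0:
        return out
    period = fs_hz / f0_hz
    idx = np.round(np.arange(0, n, period)).astype(int)
    out[idx[idx < n]] = 1.0
    return out


def resonator_coefficients(
    fc_hz: float, bandwidth_hz: float, fs_hz: float = DEFAULT_FS_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Two-pole resonator (biquad) with unit gain at its center frequency.

    Poles at radius ``exp(-pi*bw/fs)`` and angle ``2*pi*fc/fs``; the scalar
    numerator is scaled so the transfer function has 0 dB gain at ``fc``.
    Returns ``(b, a)`` suitable for :func:`scipy.signal.lfilter`.
    """
    if not 0 < fc_hz < fs_hz / 2:
        raise StimulusParameterError("fc_hz must lie in (0, Nyquist)")
    if bandwidth_hz <= 0:
        raise StimulusParameterError("bandwidth_hz must be positive")
    r = np.exp(-np.pi * bandwidth_hz / fs_hz)
    theta = 2 * np.pi * fc_hz / fs_hz
    a = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
    # scale the scalar numerator for unit gain at fc
    _, h = signal.freqz([1.0], a, worN=np.array([theta]))
    b = np.array([1.0 / abs(h[0])])
    return b, a


def raised_cosine_ramp(
    waveform: np.ndarray, fs_hz: float, ramp_ms: float = DEFAULT_RAMP_MS
) -> np.ndarray:
    """Apply raised-cosine on/off ramps in place-free fashion.

    The ramp follows ``sin^2`` so the first sample is exactly zero.
    """
    n_ramp = int(round(ramp_ms * fs_hz / 1000.0))
    out = waveform.copy()
    if n_ramp == 0 or len(out) < 2 * n_ramp:
        return out
    t = np.arange(n_ramp) / n_ramp
    ramp = np.sin(0.5 * np.pi * t) ** 2
    out[:n_ramp] *= ramp
    out[-n_ramp:] *= ramp[::-1]
    return out


def _scale_to_level(waveform: np.ndarray, level_db: float) -> np.ndarray:
    rms = np.sqrt(np.mean(waveform**2))
    if rms == 0:
        raise StimulusParameterError("cannot level-scale a silent waveform")
    return waveform * (db_to_rms(level_db) / rms)


def synthesize_vowel(spec: VowelSpec, fs_hz: float = DEFAULT_FS_HZ) -> np.ndarray:
    """Synthesize one vowel token: click train through parallel resonators.

    The four resonator outputs are summed with equal weights, ramped with
    5 ms raised cosines, and RMS-scaled to ``spec.level_db``.
    """
    if max(spec.formants_hz) >= fs_hz / 2:
        raise StimulusParameterError("formant at or above Nyquist")
    clicks = make_click_train(spec.f0_hz, spec.duration_ms, fs_hz)
    out = np.zeros_like(clicks)
    for fc, bw in zip(spec.formants_hz, spec.bandwidths_hz):
        b, a = resonator_coefficients(fc, bw, fs_hz)
        out += signal.lfilter(b, a, clicks)
    out = raised_cosine_ramp(out, fs_hz)
    return _scale_to_level(out, spec.level_db)


def make_noise(
    duration_ms: float,
    fs_hz: float = DEFAULT_FS_HZ,
    seed: int | np.random.Generator = 0,
    level_db: float = 70.0,
    lowpass_hz: float | None = None,
    ramp_ms: float = DEFAULT_RAMP_MS,
) -> np.ndarray:
    """Gaussian broadband noise burst, fresh from ``seed``, ramped and leveled.

    ``lowpass_hz`` applies a linear-phase FIR low-pass (Kaiser design, >=70 dB
    stopband 200 Hz above the cutoff) as used for the localization bursts.
    """
    if duration_ms <= 0:
        raise StimulusParameterError("duration_ms must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(duration_ms * fs_hz / 1000.0))
    x = rng.standard_normal(n)
    if lowpass_hz is not None:
        if not 0 < lowpass_hz < fs_hz / 2:
            raise StimulusParameterError("lowpass_hz must lie in (0, Nyquist)")
        trans_hz = 200.0
        numtaps, beta = signal.kaiserord(75.0, 2.0 * trans_hz / fs_hz)
        numtaps |= 1  # odd length, type-I linear phase
        taps = signal.firwin(
            numtaps, lowpass_hz + trans_hz / 2, window=("kaiser", beta), fs=fs_hz
        )
        x = signal.lfilter(taps, [1.0], x)
    x = raised_cosine_ramp(x, fs_hz, ramp_ms)
    return _scale_to_level(x, level_db)


def lowpass_taps(lowpass_hz: float, fs_hz: float = DEFAULT_FS_HZ) -> np.ndarray:
    """The FIR taps :func:`make_noise` uses, exposed for response checks."""
    trans_hz = 200.0
    numtaps, beta = signal.kaiserord(75.0, 2.0 * trans_hz / fs_hz)
    numtaps |= 1
    return signal.firwin(
        numtaps, lowpass_hz + trans_hz / 2, window=("kaiser", beta), fs=fs_hz
    )


def build_trial_stimulus(
    spec: VowelSpec,
    masker: MaskerConfig,
    snr_db: float,
    fs_hz: float = DEFAULT_FS_HZ,
    gap_ms: float = DEFAULT_GAP_MS,
    seed: int = 0,
) -> StimulusTimeline:
    """Two-token vowel trial with an optional noise masker.

    Two identical vowel tokens separated by a silent gap; when a masker is
    present it spans exactly token-1 onset to token-2 offset (750 ms for the
    standard 250/250/250 ms configuration).  The masker level is set to
    ``spec.level_db - snr_db`` so the recorded SNR is vowel minus noise.
    Channel routing follows the masker mode: ``colocated`` places noise on
    the vowel speaker(s), ``separated`` on the opposite speaker.
    """
    token = synthesize_vowel(spec, fs_hz)
    n_tok = len(token)
    n_gap = int(round(gap_ms * fs_hz / 1000.0))
    n_total = 2 * n_tok + n_gap
    vowel_buf = np.zeros(n_total)
    vowel_buf[:n_tok] = token
    vowel_buf[n_tok + n_gap:] = token

    tok_ms = 1000.0 * n_tok / fs_hz
    gap_ms_actual = 1000.0 * n_gap / fs_hz
    events = [
        ("vowel_token_1", 0.0, tok_ms),
        ("gap", tok_ms, tok_ms + gap_ms_actual),
        ("vowel_token_2", tok_ms + gap_ms_actual, 2 * tok_ms + gap_ms_actual),
    ]

    sides = ("left", "right") if masker.vowel_side == "both" else (masker.vowel_side,)
    channels = {s: vowel_buf.copy() for s in sides}
    for s in ("left", "right"):
        channels.setdefault(s, np.zeros(n_total))

    if masker.mode != "clean":
        noise_level = spec.level_db - snr_db
        noise = make_noise(
            1000.0 * n_total / fs_hz, fs_hz, seed=seed, level_db=noise_level
        )
        if masker.mode == "colocated":
            noise_sides = sides
        else:  # separated
            noise_sides = ("right",) if masker.vowel_side == "left" else ("left",)
        for s in noise_sides:
            channels[s] = channels[s] + noise
        events.append(("noise", 0.0, 1000.0 * n_total / fs_hz))

    return StimulusTimeline(fs_hz=fs_hz, channels=channels, events=events)


def _harmonic_levels(
    waveform: np.ndarray, fs_hz: float, f0_hz: float
) -> tuple[np.ndarray, np.ndarray]:
    """Envelope samples (dB) at harmonics of ``f0_hz`` from a windowed FFT."""
    n_skip = int(round(DEFAULT_RAMP_MS * fs_hz / 1000.0))
    x = waveform[n_skip: len(waveform) - n_skip]
    spec = np.abs(np.fft.rfft(x * np.hanning(len(x))))
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs_hz)
    ks = np.arange(1, int((fs_hz / 2 - f0_hz) / f0_hz) + 1)
    amps = np.empty(len(ks))
    for j, k in enumerate(ks):
        i = int(np.argmin(np.abs(freqs - k * f0_hz)))
        lo = max(0, i - 3)
        amps[j] = spec[lo: i + 4].max()
    return ks * f0_hz, 20 * np.log10(amps + 1e-15)


def _resonator_sum_db(freqs_hz: np.ndarray, params: np.ndarray, fs_hz: float) -> np.ndarray:
    """dB magnitude of a weighted complex sum of unit-gain digital resonators.

    ``params`` is a flat ``(fc, bw, gain)`` triple per resonator; gains are
    signed so the model can reproduce the interference nulls that parallel
    formant summation creates between resonances.
    """
    w = 2 * np.pi * freqs_hz / fs_hz
    z1 = np.exp(-1j * w)
    total = np.zeros(len(freqs_hz), dtype=complex)
    for i in range(len(params) // 3):
        fc, bw, g = params[3 * i: 3 * i + 3]
        r = np.exp(-np.pi * abs(bw) / fs_hz)
        theta = 2 * np.pi * abs(fc) / fs_hz
        a1, a2 = -2 * r * np.cos(theta), r * r
        b0 = abs(1.0 + a1 * np.exp(-1j * theta) + a2 * np.exp(-2j * theta))
        total += g * b0 / (1.0 + a1 * z1 + a2 * z1 * z1)
    return 20 * np.log10(np.abs(total) + 1e-15)


def _aperiodic_peaks(waveform: np.ndarray, fs_hz: float, n_peaks: int) -> list[float]:
    """Peaks of a Welch spectrum with parabolic refinement (ascending Hz)."""
    nperseg = min(len(waveform), 4096)
    freqs, pxx = signal.welch(waveform, fs=fs_hz, nperseg=nperseg)
    pdb = 10 * np.log10(pxx + 1e-30)
    idx, props = signal.find_peaks(pdb, prominence=6.0)
    if len(idx) == 0:
        return []
    order = np.argsort(props["prominences"])[::-1][:n_peaks]
    out = []
    for i in sorted(idx[order]):
        if 0 < i < len(pdb) - 1:
            y0, y1, y2 = pdb[i - 1], pdb[i], pdb[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
        else:
            delta = 0.0
        out.append(float(freqs[i] + delta * (freqs[1] - freqs[0])))
    return out


def spectral_envelope_peaks(
    waveform: np.ndarray,
    fs_hz: float = DEFAULT_FS_HZ,
    n_peaks: int = 4,
) -> list[float]:
    """Peak frequencies (Hz, ascending) of the spectral envelope.

    For harmonic signals (voiced vowels) the line spectrum undersamples the
    envelope, so peak positions are recovered by fitting a sum-of-resonators
    envelope model to the harmonic amplitudes (analysis by synthesis); the
    returned peaks are the maxima of the fitted envelope.  Aperiodic signals
    fall back to peaks of a Welch spectrum.
    """
    from scipy import optimize

    if len(waveform) < 1024:
        raise StimulusParameterError("waveform too short for envelope analysis")
    if not np.any(waveform):
        return []
    try:
        f0 = autocorrelation_f0(waveform, fs_hz, fmin_hz=50.0, fmax_hz=fs_hz / 8)
    except StimulusParameterError:
        return _aperiodic_peaks(waveform, fs_hz, n_peaks)
    freqs_h, levels_db = _harmonic_levels(waveform, fs_hz, f0)
    if len(freqs_h) < 5:
        return _aperiodic_peaks(waveform, fs_hz, n_peaks)
    pk, _ = signal.find_peaks(levels_db)
    if len(pk) == 0:
        return _aperiodic_peaks(waveform, fs_hz, n_peaks)
    pk = np.sort(pk[np.argsort(levels_db[pk])[::-1][:n_peaks]])
    f_hi = freqs_h[pk].max() * 1.25 + 3 * f0
    sel = freqs_h <= f_hi
    fsel, ysel = freqs_h[sel], levels_db[sel]

    scale_db = 20 * np.log10(10 ** (ysel / 20).max())
    y_db = ysel - scale_db
    y_lin = 10 ** (y_db / 20)

    m = len(pk)
    x0 = np.empty(3 * m)
    lb, ub = np.empty(3 * m), np.empty(3 * m)
    for j, p in enumerate(pk):
        x0[3 * j: 3 * j + 3] = (freqs_h[p], 100.0, 10 ** (y_db[p] / 20))
        lb[3 * j: 3 * j + 3] = (max(freqs_h[p] - f0, 30.0), 15.0, -np.inf)
        ub[3 * j: 3 * j + 3] = (freqs_h[p] + f0, 600.0, np.inf)

    def rms_db(params: np.ndarray) -> float:
        return float(
            np.sqrt(np.mean((_resonator_sum_db(fsel, params, fs_hz) - y_db) ** 2))
        )

    # Parallel summation interleaves unknown relative signs between
    # resonances, so restart over sign patterns; dB-domain fits resolve
    # shallow resonances while linear-amplitude fits are robust to the deep
    # interference nulls, so both objectives are tried and all candidates
    # are scored on a common dB-RMS metric.
    best_params, best_rms = None, np.inf
    for pattern in range(2 ** max(m - 1, 0)):
        signs = np.ones(m)
        for j in range(1, m):
            if (pattern >> (j - 1)) & 1:
                signs[j] = -1.0
        start = x0.copy()
        start[2::3] *= signs
        for objective in (
            lambda th: 10 ** (_resonator_sum_db(fsel, th, fs_hz) / 20) - y_lin,
            lambda th: _resonator_sum_db(fsel, th, fs_hz) - y_db,
        ):
            res = optimize.least_squares(objective, start, bounds=(lb, ub))
            r = rms_db(res.x)
            if r < best_rms:
                best_params, best_rms = res.x, r
        if best_rms < 0.1:
            break

    grid = np.linspace(30.0, f_hi, 8000)
    env = _resonator_sum_db(grid, best_params, fs_hz)
    idx, _ = signal.find_peaks(env)
    return [float(grid[i]) for i in idx[:n_peaks]]


def autocorrelation_f0(
    waveform: np.ndarray,
    fs_hz: float = DEFAULT_FS_HZ,
    fmin_hz: float = 50.0,
    fmax_hz: float = 500.0,
    exclude_ramp_ms: float = DEFAULT_RAMP_MS,
) -> float:
    """Fundamental frequency from the first autocorrelation peak.

    Analyzes the steady-state portion (ramps excluded), finds the lag of the
    autocorrelation maximum in the ``[fs/fmax, fs/fmin]`` range and refines
    it by parabolic interpolation.
    """
    n_skip = int(round(exclude_ramp_ms * fs_hz / 1000.0))
    x = waveform[n_skip: len(waveform) - n_skip]
    x = x - np.mean(x)
    ac = np.correlate(x, x, mode="full")[len(x) - 1:]
    lag_min = int(np.floor(fs_hz / fmax_hz))
    lag_max = int(np.ceil(fs_hz / fmin_hz))
    lag_max = min(lag_max, len(ac) - 2)
    if lag_max <= lag_min:
        raise StimulusParameterError("waveform too short for pitch analysis")
    seg = ac[lag_min: lag_max + 1]
    k = int(np.argmax(seg)) + lag_min
    # parabolic refinement around the peak
    y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
    denom = y0 - 2 * y1 + y2
    delta = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return float(fs_hz / (k + delta))
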