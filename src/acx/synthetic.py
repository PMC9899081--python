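"""Synthetic behavioral and electrophysiological datasets with known ground truth.

The generators emulate the statistical structure of a two-alternative vowel
discrimination task and a seven-speaker localization task under reversible
cortical inactivation (cooling or optogenetics), and of anesthetized
Neuropixels recordings with laser-driven suppression.  Every generator is
driven by one explicit seed through per-subject substreams, returns tidy
pandas tables, and ships the generative parameters back as a ground-truth
object so downstream estimators can be tested by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from scipy.special import expit

TREATMENT_ARMS = (
    "control",
    "cooled_bilateral",
    "cooled_left",
    "cooled_right",
    "laser_on",
    "laser_off",
)

SPEAKER_ANGLES_DEG = (-90, -60, -30, 0, 30, 60, 90)
LOCALIZATION_LEVELS_DB = (57.0, 61.5, 66.0)

CONTROL_TEMP_C = 37.0
COOLED_TEMP_RANGE_C = (8.0, 20.0)


class GeneratorConfigError(ValueError):
    """Raised when a generator configuration is inconsistent."""


def _spawn(seed: int, *key: int) -> np.random.Generator:
    """Independent substream derived from one root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *key]))


# ---------------------------------------------------------------------------
# behavioral generator: vowel discrimination
# ---------------------------------------------------------------------------

@dataclass
class BehaviorGenConfig:
    """Generative settings for the two-choice vowel-in-noise task.

    The per-trial success probability is a logistic model
    ``P(correct) = sigmoid(b0 + b_level*z(level) + b_noise*noise
    + b_treat*treat + b_interaction*treat*noise + u_ferret)`` where ``noise``
    and ``treat`` are 0/1 indicators and ``u_ferret`` is a Gaussian random
    intercept.  Defaults are calibrated so that inactivation costs roughly
    ten percentage points in co-located noise and nothing in clean
    conditions, matching the size of deficits the task is designed to probe.
    """

    ferret_ids: tuple[str, ...] = ("F01", "F02")
    task: str = "vowel_2AC"
    vowel_pair: tuple[str, str] = ("u", "e")
    levels_db: tuple[float, ...] = (50.0, 60.0, 70.0)
    snrs_db: tuple[float, ...] = (-10.0, 0.0, 10.0)
    masker_modes: tuple[str, ...] = ("clean", "colocated")
    treatment_arms: tuple[str, ...] = ("control", "cooled_bilateral")
    intercept: float = 1.7
    beta_level: float = 0.3
    beta_noise: float = -0.6
    beta_treatment: float = 0.05
    beta_interaction: float = -0.50
    ferret_intercept_sd: float = 0.3
    center_reward_prob: float = 0.10
    omission_prob: float = 0.02
    n_sessions: int = 10
    trials_per_session: int = 100
    seed: int = 0

    def validate(self) -> None:
        for p in (self.center_reward_prob, self.omission_prob):
            if not 0 <= p <= 1:
                raise GeneratorConfigError("probabilities must lie in [0, 1]")
        if not self.ferret_ids:
            raise GeneratorConfigError("at least one ferret required")
        if not (self.levels_db and self.snrs_db and self.masker_modes):
            raise GeneratorConfigError("empty condition grid")
        for arm in self.treatment_arms:
            if arm not in TREATMENT_ARMS:
                raise GeneratorConfigError(f"unknown treatment arm {arm!r}")
        coefs = (
            self.intercept, self.beta_level, self.beta_noise,
            self.beta_treatment, self.beta_interaction, self.ferret_intercept_sd,
        )
        if not all(np.isfinite(coefs)):
            raise GeneratorConfigError("coefficients must be finite")


@dataclass
class GroundTruth:
    """Generative parameters aligned with a generated dataset."""

    coefficients: dict = field(default_factory=dict)
    ferret_intercepts: dict = field(default_factory=dict)
    p_correct: np.ndarray | None = None
    unit_class: pd.DataFrame | None = None
    latency_ms: float | None = None

    def to_dict(self) -> dict:
        out = {"coefficients": self.coefficients,
               "ferret_intercepts": self.ferret_intercepts}
        if self.latency_ms is not None:
            out["latency_ms"] = self.latency_ms
        return out


def _draw_temperatures(rng: np.random.Generator, arm: str, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial loop temperatures for left/right thermocouples."""
    lo, hi = COOLED_TEMP_RANGE_C
    left = np.full(n, CONTROL_TEMP_C) + rng.normal(0, 0.3, n)
    right = np.full(n, CONTROL_TEMP_C) + rng.normal(0, 0.3, n)
    if arm == "cooled_bilateral":
        left = rng.uniform(lo, hi, n)
        right = rng.uniform(lo, hi, n)
    elif arm == "cooled_left":
        left = rng.uniform(lo, hi, n)
    elif arm == "cooled_right":
        right = rng.uniform(lo, hi, n)
    return left, right


def gen_vowel_behavior(config: BehaviorGenConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a vowel-discrimination trial table with correction dynamics.

    Standard trials are drawn independently from the logistic model; each
    incorrect, non-omitted standard trial is followed by a chain of
    correction trials repeating the identical stimulus until a correct
    response occurs.  Cooled-arm trials carry loop temperatures in the
    8-20 degC band, control trials sit near body temperature.
    """
    config.validate()
    level_arr = np.asarray(config.levels_db, dtype=float)
    level_mu, level_sd = level_arr.mean(), level_arr.std() or 1.0

    ferret_effects = {
        f: _spawn(config.seed, 1, i).normal(0, config.ferret_intercept_sd)
        for i, f in enumerate(config.ferret_ids)
    }

    frames = []
    p_list = []
    for i, ferret in enumerate(config.ferret_ids):
        rng = _spawn(config.seed, 2, i)
        u = ferret_effects[ferret]
        for sess in range(config.n_sessions):
            arm = config.treatment_arms[sess % len(config.treatment_arms)]
            n = config.trials_per_session
            levels = rng.choice(level_arr, n)
            masker = rng.choice(config.masker_modes, n)
            snrs = np.where(
                masker == "clean", np.nan, rng.choice(config.snrs_db, n)
            )
            vowels = rng.choice(config.vowel_pair, n)
            sides = rng.choice(["left", "right"], n)
            noise_ind = (masker != "clean").astype(float)
            treat_ind = float(arm != "control" and arm != "laser_off")
            z_level = (levels - level_mu) / level_sd
            eta = (
                config.intercept
                + config.beta_level * z_level
                + config.beta_noise * noise_ind
                + config.beta_treatment * treat_ind
                + config.beta_interaction * treat_ind * noise_ind
                + u
            )
            p = expit(eta)
            correct = rng.random(n) < p
            responded = rng.random(n) >= config.omission_prob
            center = rng.random(n) < config.center_reward_prob
            t_left, t_right = _draw_temperatures(rng, arm, n)

            rows = {
                "ferret": ferret,
                "session_id": f"{ferret}_s{sess:03d}",
                "trial_index": np.arange(n),
                "task": config.task,
                "vowel_label": vowels,
                "vowel_side": sides,
                "masker_mode": masker,
                "level_db": levels,
                "snr_db": snrs,
                "treatment": arm,
                "loop_temp_left_c": t_left,
                "loop_temp_right_c": t_right,
                "is_correction": False,
                "center_rewarded": center,
                "responded": responded,
                "correct": correct & responded,
            }
            df = pd.DataFrame(rows)
            p_list.append(p)

            # correction chains: repeat failed stimuli until a correct
            # response; chain length is geometric with the same success
            # probability as the triggering trial
            failed = df.index[responded & ~correct]
            if len(failed):
                n_rep = rng.geometric(np.clip(p[failed], 1e-6, 1.0))
                chain = df.loc[np.repeat(failed, n_rep)].copy()
                chain["is_correction"] = True
                within = np.concatenate([np.arange(k) for k in n_rep])
                last = np.concatenate([np.arange(k) == k - 1 for k in n_rep])
                chain["correct"] = last
                chain["trial_index"] = (
                    chain["trial_index"].to_numpy() + (within + 1) / 100.0
                )
                chain["center_rewarded"] = False
                df = (
                    pd.concat([df, chain])
                    .sort_values("trial_index", kind="stable")
                    .reset_index(drop=True)
                )
            frames.append(df)

    trials = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        coefficients={
            "intercept": config.intercept,
            "level": config.beta_level,
            "noise": config.beta_noise,
            "treatment": config.beta_treatment,
            "treatment:noise": config.beta_interaction,
        },
        ferret_intercepts=ferret_effects,
        p_correct=np.concatenate(p_list),
    )
    return trials, truth


# ---------------------------------------------------------------------------
# behavioral generator: sound localization
# ---------------------------------------------------------------------------

@dataclass
class LocalizationGenConfig:
    """Generative settings for the approach-to-target localization task.

    Responses are drawn from a wrapped-Gaussian confusion kernel over the
    speaker ring, centered on the target.  Cooling broadens the kernel:
    bilaterally for both hemifields, unilaterally mostly for speakers
    contralateral to the cooled hemisphere, growing with eccentricity.
    """

    ferret_ids: tuple[str, ...] = ("F01", "F02")
    speaker_angles_deg: tuple[int, ...] = SPEAKER_ANGLES_DEG
    levels_db: tuple[float, ...] = LOCALIZATION_LEVELS_DB
    durations_ms: tuple[float, ...] = (250.0,)
    treatment_arms: tuple[str, ...] = ("control", "cooled_bilateral")
    kernel_sd_deg: float = 27.0
    cooling_broadening: float = 0.45
    contra_weighting: float = 1.0
    ipsi_weighting: float = 0.15
    center_reward_prob: float = 0.10
    omission_prob: float = 0.02
    n_sessions: int = 10
    trials_per_session: int = 100
    seed: int = 0

    def validate(self) -> None:
        valid = set(SPEAKER_ANGLES_DEG)
        if not set(self.speaker_angles_deg) <= valid:
            raise GeneratorConfigError(
                f"speakers must be a subset of {sorted(valid)}"
            )
        if not self.speaker_angles_deg:
            raise GeneratorConfigError("at least one speaker required")
        for arm in self.treatment_arms:
            if arm not in TREATMENT_ARMS:
                raise GeneratorConfigError(f"unknown treatment arm {arm!r}")


def _confusion_kernel(
    target: float, speakers: np.ndarray, sd_deg: float
) -> np.ndarray:
    w = np.exp(-0.5 * ((speakers - target) / sd_deg) ** 2)
    return w / w.sum()


def localization_kernel_sd(
    config: LocalizationGenConfig, arm: str, target_deg: float
) -> float:
    """Effective confusion-kernel SD for one speaker under one treatment arm."""
    sd = config.kernel_sd_deg
    if arm == "control" or arm == "laser_off":
        return sd
    ecc = abs(target_deg) / 90.0
    if arm == "cooled_bilateral":
        factor = config.cooling_broadening
    elif arm == "cooled_left":
        w = config.contra_weighting if target_deg > 0 else config.ipsi_weighting
        factor = config.cooling_broadening * w * (0.5 + ecc)
    elif arm == "cooled_right":
        w = config.contra_weighting if target_deg < 0 else config.ipsi_weighting
        factor = config.cooling_broadening * w * (0.5 + ecc)
    else:
        factor = config.cooling_broadening
    return sd * (1.0 + factor)


def gen_localization_behavior(
    config: LocalizationGenConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a localization trial table with hemifield-specific deficits."""
    config.validate()
    speakers = np.asarray(config.speaker_angles_deg, dtype=float)

    frames = []
    for i, ferret in enumerate(config.ferret_ids):
        rng = _spawn(config.seed, 3, i)
        for sess in range(config.n_sessions):
            arm = config.treatment_arms[sess % len(config.treatment_arms)]
            n = config.trials_per_session
            targets = rng.choice(speakers, n)
            levels = rng.choice(config.levels_db, n)
            durations = rng.choice(config.durations_ms, n)
            responses = np.empty(n)
            for j, tgt in enumerate(targets):
                sd = localization_kernel_sd(config, arm, tgt)
                responses[j] = rng.choice(
                    speakers, p=_confusion_kernel(tgt, speakers, sd)
                )
            responded = rng.random(n) >= config.omission_prob
            center = rng.random(n) < config.center_reward_prob
            t_left, t_right = _draw_temperatures(rng, arm, n)
            correct = (responses == targets) & responded
            df = pd.DataFrame(
                {
                    "ferret": ferret,
                    "session_id": f"{ferret}_s{sess:03d}",
                    "trial_index": np.arange(n),
                    "task": "localization",
                    "speaker_angle_deg": targets,
                    "level_db": levels,
                    "duration_ms": durations,
                    "treatment": arm,
                    "loop_temp_left_c": t_left,
                    "loop_temp_right_c": t_right,
                    "is_correction": False,
                    "center_rewarded": center,
                    "responded": responded,
                    "response_angle_deg": responses,
                    "correct": correct,
                }
            )
            # correction chains, as in the vowel task
            failed = df.index[responded & ~correct]
            if len(failed):
                reps = []
                for f_idx in failed:
                    tgt = targets[f_idx]
                    sd = localization_kernel_sd(config, arm, tgt)
                    p_vec = _confusion_kernel(tgt, speakers, sd)
                    k = 0
                    while True:
                        k += 1
                        resp = rng.choice(speakers, p=p_vec)
                        row = df.loc[f_idx].copy()
                        row["is_correction"] = True
                        row["response_angle_deg"] = resp
                        row["correct"] = resp == tgt
                        row["center_rewarded"] = False
                        row["trial_index"] = df.loc[f_idx, "trial_index"] + k / 100.0
                        reps.append(row)
                        if resp == tgt:
                            break
                df = (
                    pd.concat([df, pd.DataFrame(reps)])
                    .sort_values("trial_index", kind="stable")
                    .reset_index(drop=True)
                )
            frames.append(df)

    trials = pd.concat(frames, ignore_index=True)
    truth = GroundTruth(
        coefficients={
            "kernel_sd_deg": config.kernel_sd_deg,
            "cooling_broadening": config.cooling_broadening,
            "contra_weighting": config.contra_weighting,
            "ipsi_weighting": config.ipsi_weighting,
        }
    )
    return trials, truth


# ---------------------------------------------------------------------------
# electrophysiology generator
# ---------------------------------------------------------------------------

@dataclass
class EphysGenConfig:
    """Generative settings for laser-modulated Poisson spiking units.

    Units are inhomogeneous-Poisson: a baseline rate, an additive evoked
    step during the sound, and a laser effect that switches on at
    ``laser onset + latency``.  Suppressed units scale their rate by a
    per-unit factor; driven units add a small rate increment.  The
    probability of being suppressed decays with cortical depth.  Rates are
    drawn from a lognormal mixture: a low-rate majority plus a high-rate
    (multi-unit / fast-spiking) minority, which is what gives the
    population a spikes-per-second median change near 1.3 while still
    containing units fast enough to carry millisecond latency information.
    """

    n_units: int = 400
    depth_range_mm: tuple[float, float] = (0.0, 2.6)
    suppressed_fraction_target: float = 0.60
    depth_decay_mm: float = 0.9
    baseline_rate_median_hz: float = 0.55
    baseline_rate_sigma: float = 0.7
    evoked_rate_median_hz: float = 0.8
    evoked_rate_sigma: float = 0.8
    high_rate_fraction: float = 0.15
    high_rate_median_hz: float = 45.0
    high_rate_baseline_hz: float = 64.0
    high_rate_sigma: float = 0.4
    suppression_factor_range: tuple[float, float] = (0.05, 0.35)
    high_rate_suppression_range: tuple[float, float] = (0.02, 0.15)
    drive_magnitude_hz: float = 0.05
    laser_latency_ms: float = 2.5
    levels_db: tuple[float, ...] = (40.0, 50.0, 60.0, 70.0)
    durations_ms: tuple[float, ...] = (50.0, 100.0, 250.0)
    n_repeats: int = 20
    laser_protocol: str = "10Hz_50duty"
    laser_lead_ms: float = 100.0
    single_unit_fraction: float = 0.4
    waveform_fs_hz: float = 30000.0
    broad_trough_to_peak_ms: float = 0.402
    narrow_trough_to_peak_ms: float = 0.338
    seed: int = 0

    def validate(self) -> None:
        if self.n_units < 1:
            raise GeneratorConfigError("n_units must be positive")
        if self.laser_latency_ms < 0:
            raise GeneratorConfigError("latency must be non-negative")
        if not (self.levels_db and self.durations_ms):
            raise GeneratorConfigError("levels and durations must be non-empty")
        for r in (
            self.baseline_rate_median_hz, self.evoked_rate_median_hz,
            self.high_rate_median_hz, self.drive_magnitude_hz,
        ):
            if r < 0:
                raise GeneratorConfigError("rates must be non-negative")


def make_waveform_template(
    trough_to_peak_ms: float, fs_hz: float = 30000.0, span_ms: float = 2.4
) -> np.ndarray:
    """Biphasic spike-waveform template: Gaussian trough then Gaussian peak.

    The overlap of the two Gaussians shifts the extrema, so the peak offset
    is calibrated by bisection until the measured trough-to-peak latency of
    the rendered template equals the requested value.
    """
    t = np.arange(int(round(span_ms * fs_hz / 1000.0))) / fs_hz * 1000.0
    t_trough = span_ms / 3.0

    def render(offset_ms: float) -> np.ndarray:
        w = -np.exp(-0.5 * ((t - t_trough) / 0.12) ** 2)
        return w + 0.55 * np.exp(-0.5 * ((t - t_trough - offset_ms) / 0.22) ** 2)

    def measured(offset_ms: float) -> float:
        w = render(offset_ms)
        trough = int(np.argmin(w))
        peak = trough + int(np.argmax(w[trough:]))

        def refine(i):
            y0, y1, y2 = w[i - 1], w[i], w[i + 1]
            d = y0 - 2 * y1 + y2
            return i + (0.5 * (y0 - y2) / d if d else 0.0)

        return (refine(peak) - refine(trough)) / fs_hz * 1000.0

    lo, hi = 0.5 * trough_to_peak_ms, 2.0 * trough_to_peak_ms
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if measured(mid) < trough_to_peak_ms:
            lo = mid
        else:
            hi = mid
    return render(0.5 * (lo + hi))


def suppressed_probability(depth_mm: np.ndarray, config: EphysGenConfig) -> np.ndarray:
    """Monotone-decreasing probability of the suppressed class with depth.

    The exponential depth profile is scaled (with a bisection that accounts
    for clipping at 1) so the expected suppressed fraction over a uniform
    depth distribution equals ``suppressed_fraction_target``.
    """
    grid = np.linspace(*config.depth_range_mm, 512)
    shape = np.exp(-grid / config.depth_decay_mm)
    lo, hi = 0.0, 1e3
    for _ in range(60):
        c = 0.5 * (lo + hi)
        if np.mean(np.clip(c * shape, 0, 1)) < config.suppressed_fraction_target:
            lo = c
        else:
            hi = c
    return np.clip(c * np.exp(-np.asarray(depth_mm) / config.depth_decay_mm), 0.0, 1.0)


def _piecewise_poisson(
    rng: np.random.Generator,
    edges_ms: np.ndarray,
    rates_hz: np.ndarray,
) -> np.ndarray:
    """Spike times (ms) of a piecewise-constant-rate Poisson process."""
    times = []
    for (t0, t1), r in zip(zip(edges_ms[:-1], edges_ms[1:]), rates_hz):
        if r <= 0 or t1 <= t0:
            continue
        n = rng.poisson(r * (t1 - t0) / 1000.0)
        if n:
            times.append(rng.uniform(t0, t1, n))
    if not times:
        return np.empty(0)
    return np.sort(np.concatenate(times))


def gen_ephys_dataset(
    config: EphysGenConfig,
) -> tuple[list[dict], pd.DataFrame, GroundTruth]:
    """Generate per-unit spike trains, a trial-condition table and truth.

    Returns ``(units, trial_table, truth)`` where ``units`` is a list of
    dicts with keys ``unit_id``, ``spikes`` (list of per-trial spike-time
    arrays, ms relative to sound onset), ``waveform``, ``waveform_fs_hz``,
    ``depth_mm`` and ``isolation``.  Trial rows carry sound level, duration,
    laser state and laser onset (-100 ms relative to sound onset on laser
    trials).
    """
    config.validate()
    rng = _spawn(config.seed, 4)

    # trial grid: level x duration x laser x repeat, shared by all units
    rows = []
    for level in config.levels_db:
        for dur in config.durations_ms:
            for laser in (False, True):
                for rep in range(config.n_repeats):
                    rows.append(
                        {
                            "level_db": level,
                            "duration_ms": dur,
                            "laser": laser,
                            "laser_onset_ms": -config.laser_lead_ms if laser else np.nan,
                            "laser_offset_ms": dur + config.laser_lead_ms if laser else np.nan,
                            "laser_protocol": config.laser_protocol if laser else "",
                            "repeat": rep,
                        }
                    )
    trial_table = pd.DataFrame(rows)
    trial_table.insert(0, "trial_index", np.arange(len(trial_table)))

    depths = rng.uniform(*config.depth_range_mm, config.n_units)
    p_sup = suppressed_probability(depths, config)
    is_sup = rng.random(config.n_units) < p_sup

    high = rng.random(config.n_units) < config.high_rate_fraction
    base = np.where(
        high,
        rng.lognormal(np.log(config.high_rate_baseline_hz), config.high_rate_sigma, config.n_units),
        rng.lognormal(np.log(config.baseline_rate_median_hz), config.baseline_rate_sigma, config.n_units),
    )
    evoked = np.where(
        high,
        rng.lognormal(np.log(config.high_rate_median_hz), config.high_rate_sigma, config.n_units),
        rng.lognormal(np.log(config.evoked_rate_median_hz), config.evoked_rate_sigma, config.n_units),
    )
    # strongly active (fast-spiking / multi-unit) sites are silenced almost
    # completely by the driven inhibition; sparse units are suppressed more
    # variably
    sup_factor = np.where(
        high,
        rng.uniform(*config.high_rate_suppression_range, config.n_units),
        rng.uniform(*config.suppression_factor_range, config.n_units),
    )
    drive = rng.lognormal(np.log(config.drive_magnitude_hz), 0.6, config.n_units)
    single = rng.random(config.n_units) < config.single_unit_fraction

    broad = make_waveform_template(config.broad_trough_to_peak_ms, config.waveform_fs_hz)
    narrow = make_waveform_template(config.narrow_trough_to_peak_ms, config.waveform_fs_hz)

    pre_ms, post_ms = 150.0, 100.0  # analysis margins around the sound
    units = []
    for u in range(config.n_units):
        urng = _spawn(config.seed, 5, u)
        spikes = []
        for tr in trial_table.itertuples():
            dur = tr.duration_ms
            t_start, t_end = -pre_ms, dur + post_ms
            edges = [t_start, 0.0, dur, t_end]
            rates = [base[u], base[u] + evoked[u], base[u]]
            if tr.laser:
                t_eff = tr.laser_onset_ms + config.laser_latency_ms
                t_off = tr.laser_offset_ms
                edges_new = sorted(set(edges) | {t_eff, t_off})
                rates_new = []
                for a, b in zip(edges_new[:-1], edges_new[1:]):
                    mid = 0.5 * (a + b)
                    r = base[u] + (evoked[u] if 0 <= mid < dur else 0.0)
                    if t_eff <= mid < t_off:
                        r = r * sup_factor[u] if is_sup[u] else r + drive[u]
                    rates_new.append(r)
                edges, rates = edges_new, rates_new
            spikes.append(
                _piecewise_poisson(urng, np.asarray(edges, float), np.asarray(rates, float))
            )
        template = broad if is_sup[u] else narrow
        waveform = template + urng.normal(0, 0.01, len(template))
        units.append(
            {
                "unit_id": f"u{u:04d}",
                "spikes": spikes,
                "waveform": waveform,
                "waveform_fs_hz": config.waveform_fs_hz,
                "depth_mm": float(depths[u]),
                "isolation": "single" if single[u] else "multi",
            }
        )

    truth = GroundTruth(
        unit_class=pd.DataFrame(
            {
                "unit_id": [f"u{u:04d}" for u in range(config.n_units)],
                "true_class": np.where(is_sup, "suppressed", "driven"),
                "depth_mm": depths,
                "baseline_hz": base,
                "evoked_extra_hz": evoked,
                "suppression_factor": sup_factor,
                "drive_hz": drive,
            }
        ),
        latency_ms=config.laser_latency_ms,
    )
    return units, trial_table, truth


# ---------------------------------------------------------------------------
# plain-text export
# ---------------------------------------------------------------------------

def save_trial_table(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def load_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_ephys_dataset(units: list[dict], trial_table: pd.DataFrame, out_dir) -> None:
    """One spike CSV per unit (trial_index, spike_time_ms) plus manifests."""
    out = Path(out_dir)
    (out / "spikes").mkdir(parents=True, exist_ok=True)
    trial_table.to_csv(out / "trials.csv", index=False)
    manifest = []
    for unit in units:
        uid = unit["unit_id"]
        rows = [
            (i, t)
            for i, times in enumerate(unit["spikes"])
            for t in times
        ]
        pd.DataFrame(rows, columns=["trial_index", "spike_time_ms"]).to_csv(
            out / "spikes" / f"{uid}.csv", index=False
        )
        np.savetxt(out / "spikes" / f"{uid}_waveform.csv", unit["waveform"], delimiter=",")
        manifest.append(
            {
                "unit_id": uid,
                "depth_mm": unit["depth_mm"],
                "isolation": unit["isolation"],
                "waveform_fs_hz": unit["waveform_fs_hz"],
                "spike_file": f"spikes/{uid}.csv",
                "waveform_file": f"spikes/{uid}_waveform.csv",
            }
        )
    pd.DataFrame(manifest).to_csv(out / "units.csv", index=False)


def load_ephys_dataset(in_dir) -> tuple[list[dict], pd.DataFrame]:
    src = Path(in_dir)
    trial_table = pd.read_csv(src / "trials.csv")
    if "laser_protocol" in trial_table.columns:
        trial_table["laser_protocol"] = (
            trial_table["laser_protocol"].astype("object").fillna("")
        )
    n_trials = len(trial_table)
    manifest = pd.read_csv(src / "units.csv")
    units = []
    for row in manifest.itertuples():
        sp = pd.read_csv(src / row.spike_file)
        spikes = [np.empty(0)] * n_trials
        for idx, grp in sp.groupby("trial_index"):
            spikes[int(idx)] = np.sort(grp["spike_time_ms"].to_numpy())
        units.append(
            {
                "unit_id": row.unit_id,
                "spikes": spikes,
                "waveform": np.loadtxt(src / row.waveform_file, delimiter=","),
                "waveform_fs_hz": row.waveform_fs_hz,
                "depth_mm": row.depth_mm,
                "isolation": row.isolation,
            }
        )
    return units, trial_table
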