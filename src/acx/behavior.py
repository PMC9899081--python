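"""Behavioral statistics: trial filtering, balanced bootstrap, contrasts.

Implements the psychophysics summary layer: exclusion of correction and
no-response trials, temperature-based definition of "cooled", minimum
trial/session requirements per stimulus value, the stratified balanced
bootstrap of percent correct (equal draws per stratum, median-size rule),
inactivation contrasts, and localization confusion matrices with hemifield
breakdowns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SchemaError(KeyError):
    """Raised when a trial table lacks a required column."""


class EmptyStratumError(ValueError):
    """Raised when a bootstrap stratum has no trials."""


COOLED_ARMS = ("cooled_bilateral", "cooled_left", "cooled_right")
TEST_ARMS = COOLED_ARMS + ("laser_on",)


@dataclass
class FilterPolicy:
    """Trial-inclusion rules applied before any behavioral statistic.

    ``cooled_scope`` selects which thermocouple defines "cooled":
    ``bilateral_mean`` (mean of left and right loops), ``left_loop`` or
    ``right_loop``.  ``min_count_col`` names the stimulus column (sound
    level or SNR) whose values must reach ``min_trials_per_value`` trials
    and ``min_sessions_per_value`` sessions in both treatment arms; values
    failing in either arm are dropped from both.
    """

    exclude_corrections: bool = True
    exclude_omissions: bool = True
    cooled_temp_max_c: float = 20.0
    cooled_scope: str = "bilateral_mean"
    min_trials_per_value: int = 10
    min_sessions_per_value: int = 3
    min_count_col: str | None = "snr_db"
    level_floor_db: float | None = None

    def __post_init__(self) -> None:
        if self.cooled_scope not in ("bilateral_mean", "left_loop", "right_loop"):
            raise ValueError(f"unknown cooled_scope {self.cooled_scope!r}")
        if self.cooled_temp_max_c <= 0:
            raise ValueError("cooled_temp_max_c must be positive")


def _require(trials: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in trials.columns]
    if missing:
        raise SchemaError(f"trial table missing columns: {missing}")


def _scoped_temperature(trials: pd.DataFrame, scope: str) -> pd.Series:
    if scope == "left_loop":
        return trials["loop_temp_left_c"]
    if scope == "right_loop":
        return trials["loop_temp_right_c"]
    return 0.5 * (trials["loop_temp_left_c"] + trials["loop_temp_right_c"])


def filter_trials(
    trials: pd.DataFrame, policy: FilterPolicy | None = None
) -> pd.DataFrame:
    """Apply the inclusion policy; the exclusion tally lands in ``.attrs``.

    Cooled-arm trials are kept only while the scoped loop temperature is at
    or below the cooling threshold; control trials are never filtered on
    temperature.  Stimulus values (level or SNR) with fewer than the minimum
    trials or sessions in either arm are removed from both arms so that the
    two arms stay comparable.
    """
    policy = policy or FilterPolicy()
    log: dict[str, int] = {"input": len(trials)}
    out = trials
    if len(out) == 0:
        out = out.copy()
        out.attrs["filter_log"] = log
        return out
    _require(out, ["treatment", "correct"])

    if policy.exclude_corrections:
        _require(out, ["is_correction"])
        n = len(out)
        out = out[~out["is_correction"].astype(bool)]
        log["correction_trials"] = n - len(out)
    if policy.exclude_omissions:
        _require(out, ["responded"])
        n = len(out)
        out = out[out["responded"].astype(bool)]
        log["omitted_trials"] = n - len(out)

    cooled = out["treatment"].isin(COOLED_ARMS)
    if cooled.any():
        _require(out, ["loop_temp_left_c", "loop_temp_right_c"])
        temp = _scoped_temperature(out, policy.cooled_scope)
        warm = cooled & (temp > policy.cooled_temp_max_c)
        log["warm_cooled_trials"] = int(warm.sum())
        out = out[~warm]

    if policy.level_floor_db is not None:
        _require(out, ["level_db"])
        n = len(out)
        out = out[out["level_db"] >= policy.level_floor_db]
        log["below_level_floor"] = n - len(out)

    col = policy.min_count_col
    if col is not None and col in out.columns:
        _require(out, ["session_id"])
        is_test = out["treatment"].isin(TEST_ARMS)
        arm = np.where(is_test, "test", "control")
        values = out[col]
        keep_values = []
        for v, grp in out.groupby(values, dropna=False):
            sub_arm = pd.Series(arm[out.index.get_indexer(grp.index)])
            ok = True
            for a in ("test", "control"):
                g = grp[(sub_arm == a).to_numpy()]
                if (
                    len(g) < policy.min_trials_per_value
                    or g["session_id"].nunique() < policy.min_sessions_per_value
                ):
                    ok = False
            if ok:
                keep_values.append(v)
        n = len(out)
        if keep_values:
            mask = values.isin(keep_values)
            if any(pd.isna(v) for v in keep_values):
                mask |= values.isna()
        else:
            mask = pd.Series(False, index=out.index)
        out = out[mask]
        log["undersampled_values"] = n - len(out)

    out = out.copy()
    log["output"] = len(out)
    out.attrs["filter_log"] = log
    return out


@dataclass
class BootstrapSummary:
    """Distribution of balanced-resample percent correct for one condition."""

    condition: dict
    strata: list[str]
    n_per_stratum: int
    stratum_sizes: dict
    values: np.ndarray = field(repr=False)

    @property
    def n_iter(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "strata": self.strata,
            "n_per_stratum": self.n_per_stratum,
            "stratum_sizes": {str(k): int(v) for k, v in self.stratum_sizes.items()},
            "n_iter": self.n_iter,
            "mean_percent_correct": self.mean,
        }


def median_stratum_size(sizes) -> int:
    """Median of the stratum sizes, rounded half-up to an integer."""
    return int(np.floor(np.median(list(sizes)) + 0.5))


def balanced_bootstrap(
    trials: pd.DataFrame,
    strata: list[str],
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
    n_per_stratum: int | None = None,
    condition: dict | None = None,
) -> BootstrapSummary:
    """Stratified balanced bootstrap of percent correct.

    On every iteration the same number ``m`` of trials is drawn with
    replacement from each stratum (joint combination of the ``strata``
    columns) and percent correct is computed over the pooled draw.  ``m``
    defaults to the median of the stratum sizes; pass ``n_per_stratum`` to
    fix it (the per-location rule of the localization analysis).
    """
    _require(trials, strata + ["correct"])
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    groups = {
        (k[0] if isinstance(k, tuple) and len(k) == 1 else k): g["correct"].to_numpy(dtype=float)
        for k, g in trials.groupby(strata, dropna=False)
    }
    if not groups:
        raise EmptyStratumError("no strata present in input")
    for k, g in groups.items():
        if len(g) == 0:
            raise EmptyStratumError(f"stratum {k!r} is empty")
    sizes = {k: len(g) for k, g in groups.items()}
    m = n_per_stratum if n_per_stratum is not None else median_stratum_size(sizes.values())
    if m < 1:
        raise EmptyStratumError("median stratum size is zero")

    total = np.zeros(n_iter)
    for g in groups.values():
        draws = rng.integers(0, len(g), size=(n_iter, m))
        total += g[draws].sum(axis=1)
    values = 100.0 * total / (m * len(groups))
    return BootstrapSummary(
        condition=condition or {},
        strata=list(strata),
        n_per_stratum=m,
        stratum_sizes=sizes,
        values=values,
    )


def performance_change(
    test: BootstrapSummary, control: BootstrapSummary
) -> tuple[np.ndarray, float]:
    """Inactivation contrast, paired by bootstrap iteration (test - control).

    Returns the per-iteration difference distribution and its mean — the
    headline "cooled minus control" change in percent correct.
    """
    if test.n_iter != control.n_iter:
        raise ValueError("bootstrap summaries have different n_iter")
    delta = test.values - control.values
    return delta, float(delta.mean())


@dataclass
class ConfusionMatrix:
    """Speaker-by-response counts for the localization task."""

    table: pd.DataFrame

    @property
    def per_speaker_percent_correct(self) -> pd.Series:
        diag = pd.Series(
            {a: self.table.loc[a, a] if a in self.table.columns else 0 for a in self.table.index}
        )
        return 100.0 * diag / self.table.sum(axis=1)

    @property
    def trial_totals(self) -> pd.Series:
        return self.table.sum(axis=1)


def localization_summary(
    trials: pd.DataFrame,
    per_location_n: int | None = None,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
    balance_duration: bool = False,
) -> tuple[ConfusionMatrix, BootstrapSummary]:
    """Confusion matrix plus location-balanced bootstrap percent correct.

    ``per_location_n`` fixes the number of draws per speaker; when mixed
    sound durations are analyzed, ``balance_duration`` adds duration as a
    second balancing stratum.
    """
    _require(trials, ["speaker_angle_deg", "response_angle_deg", "correct"])
    known = set(np.unique(trials["speaker_angle_deg"]))
    if not known <= set(float(a) for a in range(-90, 91, 30)):
        raise ValueError(f"unknown speaker angles: {sorted(known)}")
    cm = ConfusionMatrix(
        pd.crosstab(trials["speaker_angle_deg"], trials["response_angle_deg"])
    )
    strata = ["speaker_angle_deg"] + (["duration_ms"] if balance_duration else [])
    summary = balanced_bootstrap(
        trials, strata, n_iter=n_iter, seed=seed, n_per_stratum=per_location_n
    )
    return cm, summary


def hemifield_contrast(
    trials: pd.DataFrame,
    cooled_arm: str,
    n_iter: int = 1000,
    seed: int = 0,
) -> dict:
    """Cooled-minus-control percent-correct change per hemifield and |angle|.

    Midline (0 degree) speakers belong to no hemifield and are excluded;
    the contrast is computed from location-balanced bootstraps within each
    hemifield, and per eccentricity bin (30/60/90 degrees) without
    bootstrap balancing (single-speaker bins).
    """
    _require(trials, ["speaker_angle_deg", "treatment", "correct"])
    trials = trials[trials["treatment"].isin([cooled_arm, "control"])]
    lateral = trials[trials["speaker_angle_deg"] != 0]
    if len(lateral) == 0:
        raise ValueError("only midline speakers present: hemifield undefined")
    rng = np.random.default_rng(seed)
    out: dict = {"cooled_arm": cooled_arm, "hemifield": {}, "eccentricity": {}}
    for name, mask in (
        ("left", lateral["speaker_angle_deg"] < 0),
        ("right", lateral["speaker_angle_deg"] > 0),
    ):
        sub = lateral[mask]
        boots = {}
        for arm in (cooled_arm, "control"):
            boots[arm] = balanced_bootstrap(
                sub[sub["treatment"] == arm],
                ["speaker_angle_deg"],
                n_iter=n_iter,
                seed=rng,
            )
        _, delta = performance_change(boots[cooled_arm], boots["control"])
        out["hemifield"][name] = delta
    for ecc, grp in lateral.groupby(lateral["speaker_angle_deg"].abs()):
        pc = grp.groupby(grp["treatment"] == cooled_arm)["correct"].mean() * 100
        if True in pc.index and False in pc.index:
            out["eccentricity"][int(ecc)] = float(pc[True] - pc[False])
    return out
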