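"""Optogenetic spike-train analysis.

Quality control of sorted units, evoked-response detection, laser-modulation
profiling, cosine (spherical) K-means clustering with knee-point model
selection, cortical-depth statistics, cluster-based permutation latency
estimation on peri-stimulus time histograms, and spike-waveform
(trough-to-peak) statistics with label-permutation inference.

Sign convention throughout: ``change = laser OFF - laser ON``, so positive
changes are suppression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

LASER_TEST_WINDOW_MS = (50.0, 150.0)  # from laser onset
SPONTANEOUS_WINDOW_MS = 100.0  # before sound onset
LATENCY_WINDOW_MS = 100.0  # after laser onset
DEFAULT_PSTH_BIN_MS = 0.5


# ---------------------------------------------------------------------------
# unit quality control
# ---------------------------------------------------------------------------

def isi_violation_fraction(unit: dict, threshold_ms: float = 2.0) -> float:
    """Fraction of inter-spike intervals shorter than ``threshold_ms``."""
    n_viol = n_isi = 0
    for times in unit["spikes"]:
        if len(times) > 1:
            d = np.diff(times)
            n_viol += int((d < threshold_ms).sum())
            n_isi += len(d)
    return n_viol / n_isi if n_isi else 0.0


def is_artifact_waveform(waveform: np.ndarray, noise_k: float = 3.0) -> bool:
    """Monophasic-positive waveform screen (laser artifact heuristic).

    A physiological spike is biphasic: a trough precedes the main positive
    deflection.  A waveform whose samples never drop below ``-k`` times the
    baseline noise SD before its global maximum is flagged as an artifact.
    """
    w = np.asarray(waveform, float)
    noise_sd = np.std(w[: max(len(w) // 8, 2)]) or 1e-9
    peak = int(np.argmax(w))
    return not np.any(w[:peak] < -noise_k * noise_sd)


def qc_units(units: list[dict], isi_threshold: float = 0.02) -> pd.DataFrame:
    """Per-unit QC flags: single-unit criterion, artifact screen, analyzability.

    Single-unit status requires an ISI-violation fraction (< 2 ms) at or
    below ``isi_threshold``; monophasic-positive mean waveforms are flagged
    for exclusion; units with no spikes at all are kept but marked
    unanalyzable.
    """
    rows = []
    for unit in units:
        viol = isi_violation_fraction(unit)
        n_spikes = sum(len(s) for s in unit["spikes"])
        rows.append(
            {
                "unit_id": unit["unit_id"],
                "isolation": unit.get("isolation", "multi"),
                "isi_violation_fraction": viol,
                "passes_single_unit": viol <= isi_threshold,
                "is_artifact": is_artifact_waveform(unit["waveform"]),
                "analyzable": n_spikes > 0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# firing rates and modulation profiles
# ---------------------------------------------------------------------------

def _window_rates(
    spikes: list[np.ndarray],
    idx: np.ndarray,
    t0: np.ndarray,
    t1: np.ndarray,
) -> np.ndarray:
    """Per-trial firing rate (spikes/s) in [t0, t1) ms for selected trials."""
    out = np.empty(len(idx))
    for j, (i, a, b) in enumerate(zip(idx, t0, t1)):
        sp = spikes[i]
        out[j] = np.count_nonzero((sp >= a) & (sp < b)) / ((b - a) / 1000.0)
    return out


def firing_rates(unit: dict, trials: pd.DataFrame) -> dict:
    """Mean evoked and spontaneous rates per laser condition for one unit.

    Evoked: sound onset to offset (window length equals the trial's sound
    duration).  Spontaneous: the 100 ms before sound onset.  Rates are
    pooled over all conditions within each laser state; a state with no
    trials yields NaN.
    """
    idx = trials["trial_index"].to_numpy()
    dur = trials["duration_ms"].to_numpy(float)
    laser = trials["laser"].to_numpy(bool)
    evoked = _window_rates(unit["spikes"], idx, np.zeros(len(idx)), dur)
    spont = _window_rates(
        unit["spikes"], idx, np.full(len(idx), -SPONTANEOUS_WINDOW_MS), np.zeros(len(idx))
    )
    def _mean(x):
        return float(np.mean(x)) if len(x) else np.nan
    return {
        "unit_id": unit["unit_id"],
        "evoked_off_hz": _mean(evoked[~laser]),
        "evoked_on_hz": _mean(evoked[laser]),
        "spont_off_hz": _mean(spont[~laser]),
        "spont_on_hz": _mean(spont[laser]),
        "evoked_change_hz": _mean(evoked[~laser]) - _mean(evoked[laser]),
        "spont_change_hz": _mean(spont[~laser]) - _mean(spont[laser]),
        "depth_mm": unit.get("depth_mm", np.nan),
    }


def modulation_profiles(units: list[dict], trials: pd.DataFrame) -> pd.DataFrame:
    """Stack :func:`firing_rates` over units into one profile table."""
    return pd.DataFrame([firing_rates(u, trials) for u in units])


def detect_evoked(
    unit: dict, trials: pd.DataFrame, alpha: float = 0.05, min_trials: int = 5
) -> bool:
    """Sound-evoked flag via per-condition signed-rank tests, Bonferroni.

    For every level-by-duration cell, per-trial rates during the sound are
    compared against a pre-onset window of matched duration (paired
    Wilcoxon signed-rank); the unit is evoked if any cell survives
    Bonferroni correction over the number of cells.  Tie-degenerate cells
    (all paired differences zero) are skipped.
    """
    off = trials[~trials["laser"].astype(bool)]
    cells = list(off.groupby(["level_db", "duration_ms"]))
    n_cells = len(cells)
    for (_, dur), cell in cells:
        if len(cell) < min_trials:
            continue
        idx = cell["trial_index"].to_numpy()
        d = np.full(len(idx), float(dur))
        during = _window_rates(unit["spikes"], idx, np.zeros(len(idx)), d)
        before = _window_rates(unit["spikes"], idx, -d, np.zeros(len(idx)))
        if np.all(during == before):
            continue
        p = stats.wilcoxon(during, before, zero_method="wilcox").pvalue
        if p * n_cells < alpha:
            return True
    return False


def per_unit_laser_test(
    unit: dict, trials: pd.DataFrame, alpha: float = 0.05, min_trials: int = 5
) -> tuple[float, str]:
    """Laser-modulation test in the 50-150 ms-from-laser-onset window.

    Rates in a window spanning the last 50 ms of baseline and the first
    50 ms of sound-evoked activity are compared between laser-on and
    laser-off trials (two-tailed rank-sum on per-trial rates).  Returns
    ``(p, direction)`` with direction ``"suppressed"``/``"driven"`` by the
    sign of off-minus-on (``"none"`` if not significant at ``alpha``).
    """
    laser = trials["laser"].to_numpy(bool)
    lead = -np.nanmedian(trials.loc[laser, "laser_onset_ms"].to_numpy(float)) if laser.any() else 100.0
    w0, w1 = LASER_TEST_WINDOW_MS[0] - lead, LASER_TEST_WINDOW_MS[1] - lead
    idx = trials["trial_index"].to_numpy()
    r = _window_rates(unit["spikes"], idx, np.full(len(idx), w0), np.full(len(idx), w1))
    r_on, r_off = r[laser], r[~laser]
    if len(r_on) < min_trials or len(r_off) < min_trials:
        return np.nan, "none"
    if np.all(r_on == r_on[0]) and np.all(r_off == r_off[0]) and r_on[0] == r_off[0]:
        return 1.0, "none"
    p = float(stats.mannwhitneyu(r_off, r_on, alternative="two-sided").pvalue)
    if p >= alpha:
        return p, "none"
    return p, "suppressed" if r_off.mean() > r_on.mean() else "driven"


# ---------------------------------------------------------------------------
# cosine K-means with knee-point model selection
# ---------------------------------------------------------------------------

def knee_point(curve: np.ndarray) -> int:
    """Index (1-based K) of the knee of a decreasing cost curve.

    The knee is the point with maximal perpendicular distance to the chord
    joining the first and last points of the curve.
    """
    y = np.asarray(curve, float)
    x = np.arange(1, len(y) + 1, dtype=float)
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        return 1
    d = np.abs(chord[0] * (p0[1] - y) - (p0[0] - x) * chord[1]) / norm
    return int(np.argmax(d)) + 1


@dataclass
class ClusterAssignment:
    """Cosine K-means result over unit modulation features."""

    knee_k: int
    labels: np.ndarray
    distance_curve: np.ndarray
    unit_ids: list[str]
    excluded: list[str] = field(default_factory=list)

    def label_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.unit_ids, name="cluster")


def cluster_modulation(
    profiles: pd.DataFrame,
    k_range: range = range(1, 11),
    n_restarts: int = 20,
    seed: int = 0,
) -> ClusterAssignment:
    """Cluster units on cosine distance between laser-off/on evoked rates.

    Feature per unit: ``[mean evoked rate laser-off, mean evoked rate
    laser-on]``.  Rows are L2-normalized so Lloyd's algorithm operates on
    the cosine geometry (spherical K-means); model order is the knee of the
    sum of point-to-centroid distances for K in ``k_range``; final labels
    at the knee are ordered so cluster 1 has the larger median off-minus-on
    change (the suppressed group).
    """
    feats = profiles[["evoked_off_hz", "evoked_on_hz"]].to_numpy(float)
    ids = list(profiles["unit_id"])
    norms = np.linalg.norm(feats, axis=1)
    ok = np.isfinite(feats).all(axis=1) & (norms > 0)
    excluded = [i for i, good in zip(ids, ok) if not good]
    X = feats[ok] / norms[ok, None]
    if len(X) < max(k_range):
        raise ValueError("need at least max(K) units with finite features")

    curve = np.empty(len(k_range))
    fits = []
    for j, k in enumerate(k_range):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(X)
        # sum of point-to-centroid (Euclidean on the sphere) distances
        d = np.linalg.norm(X - km.cluster_centers_[km.labels_], axis=1)
        curve[j] = d.sum()
        fits.append(km)
    knee_k = list(k_range)[knee_point(curve) - 1]
    km = fits[list(k_range).index(knee_k)]

    change = feats[ok, 0] - feats[ok, 1]
    medians = [np.median(change[km.labels_ == c]) for c in range(knee_k)]
    order = np.argsort(medians)[::-1]  # cluster 1 = most suppressed
    relabel = np.empty(knee_k, int)
    relabel[order] = np.arange(1, knee_k + 1)
    labels = relabel[km.labels_]
    return ClusterAssignment(
        knee_k=knee_k,
        labels=labels,
        distance_curve=curve,
        unit_ids=[i for i, good in zip(ids, ok) if good],
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# depth statistics
# ---------------------------------------------------------------------------

def depth_profile(
    profiles: pd.DataFrame,
    evoked_flags: pd.Series,
    significant_suppressed: pd.Series,
    cluster_labels: pd.Series | None = None,
    min_group: int = 3,
) -> dict:
    """Depth percentiles of evoked and significantly inactivated units.

    Returns the 95th percentile of evoked-unit depths (functional extent of
    the responsive cortex), the 90th percentile of significantly suppressed
    units (inactivation extent), and, when cluster labels are supplied, a
    rank-sum comparison of cluster-1 versus cluster-2 depths.
    """
    depths = profiles.set_index("unit_id")["depth_mm"]
    out: dict = {}
    ev = depths[evoked_flags.reindex(depths.index, fill_value=False)]
    if len(ev) >= min_group:
        out["evoked_depth_p95_mm"] = float(np.percentile(ev, 95))
    sup = depths[significant_suppressed.reindex(depths.index, fill_value=False)]
    if len(sup) >= min_group:
        out["inactivated_depth_p90_mm"] = float(np.percentile(sup, 90))
    if cluster_labels is not None:
        d1 = depths[cluster_labels.reindex(depths.index) == 1].dropna()
        d2 = depths[cluster_labels.reindex(depths.index) == 2].dropna()
        if len(d1) >= min_group and len(d2) >= min_group:
            res = stats.mannwhitneyu(d1, d2, alternative="two-sided")
            out["cluster_depth_ranksum_p"] = float(res.pvalue)
            out["cluster1_median_depth_mm"] = float(np.median(d1))
            out["cluster2_median_depth_mm"] = float(np.median(d2))
    return out


# ---------------------------------------------------------------------------
# PSTH and cluster-based permutation latency
# ---------------------------------------------------------------------------

def psth(
    unit: dict,
    trials: pd.DataFrame,
    bin_ms: float = DEFAULT_PSTH_BIN_MS,
    window_ms: tuple[float, float] = (0.0, LATENCY_WINDOW_MS),
    align: str = "laser",
) -> tuple[np.ndarray, np.ndarray]:
    """Trials-by-bins firing-rate matrix (spikes/s) plus bin left edges (ms).

    ``align='laser'`` re-references spike times to the laser onset (using
    the laser-on lead time for laser-off trials as well, so the two
    conditions share a time base); ``align='sound'`` keeps sound onset.
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    t0, t1 = window_ms
    edges = np.arange(t0, t1 + bin_ms / 2, bin_ms)
    laser = trials["laser"].to_numpy(bool)
    if align == "laser":
        lead = (
            -np.nanmedian(trials.loc[laser, "laser_onset_ms"].to_numpy(float))
            if laser.any()
            else 100.0
        )
    else:
        lead = 0.0
    idx = trials["trial_index"].to_numpy()
    mat = np.empty((len(idx), len(edges) - 1))
    for j, i in enumerate(idx):
        sp = unit["spikes"][i] + lead  # now relative to laser onset
        mat[j] = np.histogram(sp, bins=edges)[0]
    return mat / (bin_ms / 1000.0), edges[:-1]


def _ranksum_z(counts: np.ndarray, group_a: np.ndarray) -> np.ndarray:
    """Vectorized per-bin Mann-Whitney z for group_a vs rest (columns=bins)."""
    n, n_bins = counts.shape
    n_a = int(group_a.sum())
    n_b = n - n_a
    ranks = stats.rankdata(counts, axis=0)
    ra = ranks[group_a].sum(axis=0)
    mu = n_a * (n + 1) / 2.0
    # tie correction per column
    tie_term = np.zeros(n_bins)
    for j in range(n_bins):
        _, cnt = np.unique(counts[:, j], return_counts=True)
        tie_term[j] = np.sum(cnt**3 - cnt)
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    var = np.maximum(var, 1e-12)
    return (ra - mu) / np.sqrt(var)


def _cluster_masses(z: np.ndarray, z_thresh: float) -> list[tuple[int, int, float]]:
    """Contiguous same-sign supra-threshold runs: (start, end, mass)."""
    sig = np.where(z > z_thresh, 1, np.where(z < -z_thresh, -1, 0))
    clusters = []
    start = None
    for i in range(len(sig) + 1):
        s = sig[i] if i < len(sig) else 0
        if start is None:
            if s != 0:
                start, sign = i, s
        elif s != sign:
            clusters.append((start, i, float(np.abs(z[start:i]).sum())))
            start = None if s == 0 else i
            sign = s
    return clusters


def cluster_permutation_latency(
    psth_on: np.ndarray,
    psth_off: np.ndarray,
    bin_edges_ms: np.ndarray,
    n_perm: int = 1000,
    alpha_cluster: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Latency of laser-driven rate change via cluster-based permutation.

    Per-bin rank-sum statistics (laser-on vs laser-off across trials) are
    thresholded at the cluster-forming ``alpha_cluster``; contiguous
    same-sign supra-threshold runs are scored by the sum of |z|, and the
    family-wise null is the maximum cluster mass over ``n_perm`` random
    relabelings of trials.  The latency is the left edge of the earliest
    bin belonging to any cluster with permutation p < ``alpha``; when no
    cluster survives the latency is NaN.
    """
    rng = np.random.default_rng(seed)
    counts = np.vstack([psth_on, psth_off])
    is_on = np.zeros(len(counts), bool)
    is_on[: len(psth_on)] = True
    z_thresh = stats.norm.isf(alpha_cluster / 2)
    z_obs = _ranksum_z(counts, is_on)
    clusters = _cluster_masses(z_obs, z_thresh)
    result = {"latency_ms": np.nan, "clusters": [], "z": z_obs}
    if not clusters:
        return result

    # permutation null of the maximum cluster mass; ranks are recomputed
    # implicitly by permuting group membership over fixed per-bin ranks
    n = len(counts)
    ranks = stats.rankdata(counts, axis=0)
    perm_members = np.zeros((n_perm, n))
    for s in range(n_perm):
        perm_members[s, rng.permutation(n)[: is_on.sum()]] = 1.0
    ra = perm_members @ ranks  # n_perm x n_bins rank sums for "on" group
    n_a = is_on.sum()
    n_b = n - n_a
    mu = n_a * (n + 1) / 2.0
    tie_term = np.array([
        np.sum(cnt**3 - cnt)
        for cnt in (np.unique(counts[:, j], return_counts=True)[1] for j in range(counts.shape[1]))
    ])
    var = np.maximum(n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1))), 1e-12)
    z_perm = (ra - mu) / np.sqrt(var)
    null_max = np.zeros(n_perm)
    for s in range(n_perm):
        cl = _cluster_masses(z_perm[s], z_thresh)
        if cl:
            null_max[s] = max(c[2] for c in cl)

    sig_bins = []
    for start, end, mass in clusters:
        p = (1 + np.sum(null_max >= mass)) / (n_perm + 1)
        result["clusters"].append(
            {"start_ms": float(bin_edges_ms[start]),
             "end_ms": float(bin_edges_ms[end - 1]),
             "mass": mass, "p": float(p)}
        )
        if p < alpha:
            sig_bins.append(start)
    if sig_bins:
        result["latency_ms"] = float(bin_edges_ms[min(sig_bins)])
    return result


def unit_latency(
    unit: dict,
    trials: pd.DataFrame,
    bin_ms: float = DEFAULT_PSTH_BIN_MS,
    n_perm: int = 1000,
    seed: int = 0,
    per_condition: bool = False,
) -> float:
    """Per-unit laser-modulation latency (ms from laser onset).

    By default all laser-on conditions are pooled against all laser-off
    trials to maximize trial counts; ``per_condition=True`` instead runs
    the cluster test within each level-by-duration condition and averages
    the per-condition latencies, skipping conditions with no significant
    cluster.
    """
    laser = trials["laser"].astype(bool)
    if per_condition:
        lats = []
        for (lev, dur), cell in trials.groupby(["level_db", "duration_ms"]):
            on, off = cell[cell["laser"]], cell[~cell["laser"]]
            if len(on) < 5 or len(off) < 5:
                continue
            m_on, edges = psth(unit, on, bin_ms)
            m_off, _ = psth(unit, off, bin_ms)
            res = cluster_permutation_latency(m_on, m_off, edges, n_perm=n_perm, seed=seed)
            if np.isfinite(res["latency_ms"]):
                lats.append(res["latency_ms"])
        return float(np.mean(lats)) if lats else np.nan
    m_on, edges = psth(unit, trials[laser], bin_ms)
    m_off, _ = psth(unit, trials[~laser], bin_ms)
    res = cluster_permutation_latency(m_on, m_off, edges, n_perm=n_perm, seed=seed)
    return res["latency_ms"]


# ---------------------------------------------------------------------------
# waveform statistics
# ---------------------------------------------------------------------------

def trough_to_peak(waveform: np.ndarray, fs_hz: float) -> float:
    """Trough-to-peak latency (ms) with parabolic sub-sample refinement.

    Time from the global minimum to the following maximum; raises if the
    waveform has no post-trough peak (e.g. inverted/artifact shapes).
    """
    w = np.asarray(waveform, float)
    trough = int(np.argmin(w))
    if trough >= len(w) - 1:
        raise ValueError("no samples after the trough")
    if w[trough] >= 0 or np.max(w[trough:]) <= w[trough]:
        raise ValueError("waveform lacks a biphasic trough-peak structure")
    if np.max(w) > abs(w[trough]):
        # dominant positive deflection: inverted or artifact-like shape
        raise ValueError("main deflection is positive-going, not a spike trough")
    peak = trough + int(np.argmax(w[trough:]))

    def refine(i):
        if 0 < i < len(w) - 1:
            y0, y1, y2 = w[i - 1], w[i], w[i + 1]
            denom = y0 - 2 * y1 + y2
            if denom != 0:
                return i + 0.5 * (y0 - y2) / denom
        return float(i)

    return (refine(peak) - refine(trough)) / fs_hz * 1000.0


def waveform_permutation_test(
    latencies: np.ndarray,
    cluster_labels: np.ndarray,
    n_iter: int = 1000,
    seed: int = 0,
) -> dict:
    """Label-shuffling test of the cluster-1 minus cluster-2 latency gap.

    Observed statistic: difference of mean trough-to-peak latency between
    the two clusters.  Null: the statistic under ``n_iter`` random
    permutations of cluster labels; two-sided p with add-one smoothing.
    """
    lat = np.asarray(latencies, float)
    lab = np.asarray(cluster_labels)
    groups = np.unique(lab)
    if len(groups) != 2:
        raise ValueError("exactly two clusters required")
    if min((lab == g).sum() for g in groups) < 3:
        raise ValueError("each cluster needs at least 3 units")
    rng = np.random.default_rng(seed)
    g1 = lab == groups[0]
    obs = float(lat[g1].mean() - lat[~g1].mean())
    null = np.empty(n_iter)
    for i in range(n_iter):
        perm = rng.permutation(lab) == groups[0]
        null[i] = lat[perm].mean() - lat[~perm].mean()
    p = (1 + np.sum(np.abs(null) >= abs(obs))) / (n_iter + 1)
    return {"observed_diff_ms": obs, "null": null, "p": float(p)}


# ---------------------------------------------------------------------------
# cluster-by-isolation bookkeeping
# ---------------------------------------------------------------------------

def modulation_table(
    qc: pd.DataFrame,
    cluster_labels: pd.Series,
    significant: pd.Series,
) -> pd.DataFrame:
    """Counts of significantly modulated units per cluster and isolation.

    Rows are clusters plus a total row; columns hold ``significant/total``
    counts for single units, multi-units and all units.
    """
    df = qc.set_index("unit_id").copy()
    df["cluster"] = cluster_labels.reindex(df.index)
    df["significant"] = significant.reindex(df.index, fill_value=False)
    df = df.dropna(subset=["cluster"])
    rows = []
    clusters = sorted(df["cluster"].unique())
    for c in clusters + ["total"]:
        sub = df if c == "total" else df[df["cluster"] == c]
        row = {"cluster": c}
        for iso in ("single", "multi", "total"):
            g = sub if iso == "total" else sub[sub["isolation"] == iso]
            row[f"{iso}_significant"] = int(g["significant"].sum())
            row[f"{iso}_total"] = len(g)
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster")


def significant_percentages(table: pd.DataFrame) -> pd.DataFrame:
    """Percent significantly modulated per cluster/isolation from the counts."""
    out = {}
    for iso in ("single", "multi", "total"):
        out[iso] = 100.0 * table[f"{iso}_significant"] / table[f"{iso}_total"]
    return pd.DataFrame(out)
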