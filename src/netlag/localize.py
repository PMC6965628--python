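"""Functional localization of task-responsive electrodes.

Target (mountain) trials are contrasted against matched baseline (correct
city) trials with a nonparametric cluster-based permutation test on the
smoothed HFB envelope: per-timepoint two-sample t tests in 0..+1500 ms,
suprathreshold samples grouped into sign-consistent temporal clusters,
cluster mass = sum of t values, and the maximum |mass| compared against a
Monte-Carlo distribution obtained by relabeling trials.  Electrodes are
then screened by network identity: dorsal-attention (DAN) and salience (SN)
sites must respond with an HFB increase, default-mode (DMN) sites with a
decrease, with Bonferroni correction over the electrodes of each network
within each subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import TrialTable
from .synth import MOUNTAIN, CITY

__all__ = [
    "TrialSelection", "EpochSet", "Cluster", "ClusterResult",
    "select_trials", "epoch", "cluster_permutation_test", "screen_network",
]

EXPECTED_SIGN = {"DAN": +1, "SN": +1, "DMN": -1}


@dataclass
class TrialSelection:
    """Trial indices entering the localization contrast."""

    targets: np.ndarray            # correct-omission mountains, no mountain before
    targets_error: np.ndarray      # commission-error mountains, no mountain before
    baselines: np.ndarray          # subsampled flanked correct-commission cities
    baselines_all: np.ndarray      # eligible baselines before subsampling


@dataclass
class EpochSet:
    """Trials x time matrix for one channel, time-locked to trial onsets."""

    data: np.ndarray               # (n_trials, n_times)
    times_ms: np.ndarray           # relative to onset
    fs: float
    label: str = ""
    channel: str = ""
    dropped_trials: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class Cluster:
    start_ms: float
    end_ms: float
    mass: float


@dataclass
class ClusterResult:
    """Permutation-test outcome for one channel."""

    channel: str
    clusters: list[Cluster]
    max_mass: float                # signed mass of the winning cluster (0 if none)
    p: float
    responsive: bool
    sign: int                      # sign of the winning cluster, 0 if none


# ---------------------------------------------------------------------------


def select_trials(table: TrialTable, seed: int = 0) -> TrialSelection:
    """Apply the target/baseline eligibility rules and subsample baselines.

    Targets: correct-omission mountains not preceded by another mountain
    (commission-error mountains meeting the same adjacency rule are returned
    separately).  Baselines: correct-commission cities whose two neighbors
    are both cities with correct responses; a seeded random subset matching
    the target count is drawn.
    """
    cats = np.asarray(table.categories)
    out = np.asarray(table.outcomes)
    n = len(cats)
    prev_mountain = np.zeros(n, dtype=bool)
    prev_mountain[1:] = cats[:-1] == MOUNTAIN
    targets = np.nonzero((out == "correct_omission") & ~prev_mountain)[0]
    targets_err = np.nonzero((out == "commission_error") & ~prev_mountain)[0]
    if len(targets) == 0:
        raise ValueError("no eligible target trials in this run")

    eligible = np.zeros(n, dtype=bool)
    for k in range(1, n - 1):
        if out[k] != "correct_commission":
            continue
        if out[k - 1] == "correct_commission" and out[k + 1] == "correct_commission":
            eligible[k] = True
    baselines_all = np.nonzero(eligible)[0]
    n_take = min(len(targets), len(baselines_all))
    rng = np.random.default_rng(seed)
    baselines = np.sort(rng.choice(baselines_all, size=n_take, replace=False))
    return TrialSelection(targets=targets, targets_error=targets_err,
                          baselines=baselines, baselines_all=baselines_all)


def epoch(env: np.ndarray, fs: float, onsets: np.ndarray,
          window_ms: tuple[float, float] = (-800.0, 1600.0),
          t0: float = 0.0, valid: np.ndarray | None = None,
          label: str = "", channel: str = "") -> EpochSet:
    """Extract time-locked epochs from a 1-D envelope.

    ``env`` is a single channel's envelope sampled at ``fs``; sample ``i``
    corresponds to time ``t0 + i/fs`` on the clock of ``onsets``.  Trials
    whose window leaves the record, or touches edge-flagged (``valid is
    False``) samples, are dropped and reported in ``dropped_trials``.
    """
    env = np.asarray(env)
    if env.ndim != 1:
        raise ValueError("epoch() expects a single-channel envelope")
    w0, w1 = (w / 1000.0 for w in window_ms)
    n_samp = int(round((w1 - w0) * fs))
    times_ms = (w0 + np.arange(n_samp) / fs) * 1000.0
    rows, dropped = [], []
    for k, onset in enumerate(np.asarray(onsets, dtype=float)):
        i0 = int(round((onset + w0 - t0) * fs))
        i1 = i0 + n_samp
        if i0 < 0 or i1 > len(env) or (
                valid is not None and not valid[i0:i1].all()):
            dropped.append(k)
            continue
        rows.append(env[i0:i1])
    data = np.asarray(rows) if rows else np.empty((0, n_samp))
    return EpochSet(data=data, times_ms=times_ms, fs=fs, label=label,
                    channel=channel,
                    dropped_trials=np.asarray(dropped, dtype=int))


# ---------------------------------------------------------------------------


def _t_per_timepoint(x: np.ndarray, y: np.ndarray, welch: bool) -> np.ndarray:
    n1, n2 = x.shape[0], y.shape[0]
    m1, m2 = x.mean(axis=0), y.mean(axis=0)
    v1, v2 = x.var(axis=0, ddof=1), y.var(axis=0, ddof=1)
    if welch:
        denom = np.sqrt(v1 / n1 + v2 / n2)
    else:
        sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        denom = np.sqrt(sp * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / denom
    return np.where(np.isfinite(t), t, 0.0)


def _max_cluster_mass_rows(tmat: np.ndarray, thr: float) -> np.ndarray:
    """Per row of ``tmat``: max |sum of t| over sign-consistent
    suprathreshold runs (0.0 when a row has no suprathreshold sample)."""
    r, t = tmat.shape
    lab = np.zeros((r, t + 1), dtype=np.int8)
    lab[:, :t][tmat > thr] = 1
    lab[:, :t][tmat < -thr] = -1
    vals = np.zeros((r, t + 1))
    vals[:, :t] = tmat
    flat_lab = lab.ravel()
    flat_val = vals.ravel()
    prev = np.empty_like(flat_lab)
    prev[0] = 0
    prev[1:] = flat_lab[:-1]
    starts = np.nonzero(flat_lab != prev)[0]
    out = np.zeros(r)
    if len(starts) == 0:
        return out
    seg_sums = np.add.reduceat(flat_val, starts)
    seg_lab = flat_lab[starts]
    keep = seg_lab != 0
    seg_sums = np.abs(seg_sums[keep])
    rows = starts[keep] // (t + 1)
    np.maximum.at(out, rows, seg_sums)
    return out


def _observed_clusters(tvals: np.ndarray, times_ms: np.ndarray,
                       thr: float) -> list[Cluster]:
    lab = np.zeros(len(tvals), dtype=np.int8)
    lab[tvals > thr] = 1
    lab[tvals < -thr] = -1
    clusters = []
    i = 0
    while i < len(lab):
        if lab[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < len(lab) and lab[j + 1] == lab[i]:
            j += 1
        clusters.append(Cluster(start_ms=float(times_ms[i]),
                                end_ms=float(times_ms[j]),
                                mass=float(tvals[i:j + 1].sum())))
        i = j + 1
    return clusters


def cluster_permutation_test(targets: EpochSet, baselines: EpochSet,
                             test_window_ms: tuple[float, float] = (0.0, 1500.0),
                             alpha_sample: float = 0.05,
                             n_perm: int = 1000, seed: int = 0,
                             alpha: float = 0.05,
                             welch: bool = False) -> ClusterResult:
    """Cluster-based permutation test of target vs baseline epochs.

    Per-timepoint two-sample t tests (Student pooled-variance by default)
    inside ``test_window_ms``; samples beyond the two-tailed
    ``alpha_sample`` threshold form sign-consistent temporal clusters whose
    mass is the summed t value.  The max |mass| is compared to its
    Monte-Carlo null from ``n_perm`` random relabelings;
    p = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n1, n2 = targets.n_trials, baselines.n_trials
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 trials per condition")
    sel = (targets.times_ms >= test_window_ms[0]) & \
          (targets.times_ms <= test_window_ms[1])
    x = targets.data[:, sel]
    y = baselines.data[:, sel]
    times = targets.times_ms[sel]
    df = n1 + n2 - 2
    thr = stats.t.ppf(1.0 - alpha_sample / 2.0, df)

    tvals = _t_per_timepoint(x, y, welch)
    clusters = _observed_clusters(tvals, times, thr)
    if not clusters:
        return ClusterResult(channel=targets.channel, clusters=[],
                             max_mass=0.0, p=1.0, responsive=False, sign=0)
    masses = np.array([c.mass for c in clusters])
    win = int(np.argmax(np.abs(masses)))
    obs = abs(masses[win])

    z = np.vstack([x, y])
    n = n1 + n2
    rng = np.random.default_rng(seed)
    # all permutations' group-1 membership as a (n_perm, n) 0/1 matrix
    perm_max = np.empty(n_perm)
    batch = max(1, min(n_perm, int(2e7 // max(z.shape[1], 1))))
    z2 = z ** 2
    tot = z.sum(axis=0)
    tot2 = z2.sum(axis=0)
    for b0 in range(0, n_perm, batch):
        b = min(batch, n_perm - b0)
        sel1 = np.zeros((b, n), dtype=float)
        for i in range(b):
            idx = rng.permutation(n)[:n1]
            sel1[i, idx] = 1.0
        s1 = sel1 @ z
        ss1 = sel1 @ z2
        m1 = s1 / n1
        m2 = (tot[None, :] - s1) / n2
        v1 = (ss1 - n1 * m1 ** 2) / (n1 - 1)
        v2 = ((tot2[None, :] - ss1) - n2 * m2 ** 2) / (n2 - 1)
        v1 = np.maximum(v1, 0.0)
        v2 = np.maximum(v2, 0.0)
        if welch:
            denom = np.sqrt(v1 / n1 + v2 / n2)
        else:
            sp = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            denom = np.sqrt(sp * (1 / n1 + 1 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            tmat = (m1 - m2) / denom
        tmat = np.where(np.isfinite(tmat), tmat, 0.0)
        perm_max[b0:b0 + b] = _max_cluster_mass_rows(tmat, thr)

    p = (1.0 + np.sum(perm_max >= obs)) / (1.0 + n_perm)
    return ClusterResult(channel=targets.channel, clusters=clusters,
                         max_mass=float(masses[win]), p=float(p),
                         responsive=bool(p < alpha),
                         sign=int(np.sign(masses[win])))


# ---------------------------------------------------------------------------


def screen_network(results: list[ClusterResult], channel_table: pd.DataFrame,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Screen per-channel permutation results by network identity.

    ``channel_table`` needs columns ``channel``, ``subject``, ``network``.
    The Monte-Carlo p is Bonferroni-corrected by the number of electrodes in
    the same subject x network cell.  DAN/SN electrodes are retained when
    significantly *increased* (sign +1), DMN when significantly *decreased*
    (sign -1); significant responses of the opposite sign are tallied in
    ``opposite_sign``.  Channels without a recognized network label are
    excluded.  Note: Bonferroni over k electrodes needs Monte-Carlo
    resolution below alpha/k, so raise ``n_perm`` accordingly upstream.
    """
    info = channel_table.set_index("channel")
    rows = []
    for res in results:
        if res.channel not in info.index:
            continue
        net = info.loc[res.channel, "network"]
        if net not in EXPECTED_SIGN:
            continue
        subject = info.loc[res.channel, "subject"]
        n_in_cell = int(np.sum((channel_table["subject"] == subject) &
                               (channel_table["network"] == net)))
        p_corr = min(1.0, res.p * n_in_cell)
        significant = p_corr < alpha
        expected = EXPECTED_SIGN[net]
        rows.append({
            "channel": res.channel,
            "subject": subject,
            "network": net,
            "p": res.p,
            "p_corrected": p_corr,
            "sign": res.sign,
            "retained": bool(significant and res.sign == expected),
            "opposite_sign": bool(significant and res.sign == -expected),
        })
    return pd.DataFrame(rows, columns=["channel", "subject", "network", "p",
                                       "p_corrected", "sign", "retained",
                                       "opposite_sign"])
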