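"""GradCPT behavioral scoring: press assignment, error rates, d-prime.

The gradual-onset CPT overlaps stimuli across adjacent trials (each scene
cross-fades over 800 ms, reaching full coherence at the 400 ms midpoint), so
a key press cannot always be attributed to a unique trial.  Presses with
reaction times inside the *normal* response window — from 70% coherence of
the current trial to 40% coherence of the following one, i.e. RT in
[0.7*rise, transition + 0.4*rise] = [280, 960] ms for the standard 800 ms
transition — are assigned to that trial directly.  Deviant presses (those
falling in the 120 ms gap between adjacent normal windows) are resolved by
an iterative rule set:

1. if exactly one of the two adjacent trials has no response yet, the press
   goes to that trial;
2. if neither has a response, the press goes to the trial closest in time
   (distance to the nearest edge of each trial's normal window; ties to the
   earlier trial), excluding mountain (target) trials;
3. when several presses compete for one trial, the fastest RT wins and the
   losers are re-evaluated.

Rules are iterated to a fixed point; presses that remain unassignable are
dropped (and counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .synth import CITY, MOUNTAIN, StimulusSequence

__all__ = ["TrialTable", "RunScore", "assign_presses", "score_run", "dprime"]

#: fraction of the fade-in at which the normal window opens (70% coherence)
_WINDOW_OPEN_FRAC = 0.7
#: fraction of the fade-in past the next onset at which it closes (40% coherence)
_WINDOW_CLOSE_FRAC = 0.4

OMISSION_MAX = 0.15     # run-inclusion thresholds on error rates
COMMISSION_MAX = 0.60


@dataclass
class TrialTable:
    """Per-trial behavioral outcome of one GradCPT run."""

    onsets: np.ndarray
    categories: np.ndarray
    rts: np.ndarray                # seconds from trial onset, NaN if no press
    outcomes: np.ndarray           # correct_commission | omission_error |
                                   # correct_omission | commission_error
    dropped_presses: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "onset_s": self.onsets,
            "category": self.categories,
            "rt_s": self.rts,
            "outcome": self.outcomes,
        })


@dataclass(frozen=True)
class RunScore:
    """Run-level behavioral summary with inclusion flag."""

    omission_rate: float
    commission_rate: float
    hit_rate: float
    fa_rate: float
    d_prime: float
    include_flag: bool
    n_city: int
    n_mountain: int


def _windows(seq: StimulusSequence):
    """Normal-window bounds (relative to onset) and the fade rise time."""
    transition = seq.transition_ms / 1000.0
    rise = transition / 2.0
    lo = _WINDOW_OPEN_FRAC * rise
    hi = transition + _WINDOW_CLOSE_FRAC * rise
    return transition, lo, hi


def assign_presses(seq: StimulusSequence, presses: np.ndarray) -> TrialTable:
    """Assign key presses to trials and label every trial's outcome.

    ``presses`` must be sorted ascending (seconds, same clock as the
    sequence onsets).  Returns a :class:`TrialTable`; presses that cannot be
    assigned are recorded in ``dropped_presses`` so that
    ``n_assigned + n_dropped == n_presses``.
    """
    presses = np.asarray(presses, dtype=float)
    if presses.ndim != 1:
        raise ValueError("presses must be a 1-D array of times")
    if len(presses) > 1 and np.any(np.diff(presses) < 0):
        raise ValueError("presses must be sorted ascending")
    n = seq.n_trials
    transition, lo, hi = _windows(seq)
    onsets = seq.onsets
    cats = seq.categories

    assigned_rt: dict[int, float] = {}
    dropped: list[float] = []
    deviant: list[tuple[float, int | None, int | None]] = []  # (p, prev, curr)

    # --- pass 1: unambiguous (normal-window) presses -----------------------
    # Period j covers [onset_0 + j*T, onset_0 + (j+1)*T).  Within it, the
    # first 20% belongs to trial j-1's normal window, (20%, 35%) is the
    # deviant gap between trials j-1 and j, and from 35% on it is trial j's
    # normal window (which extends into the next period).
    normal_claims: dict[int, list[float]] = {}
    for p in presses:
        j = int(np.floor((p - onsets[0]) / transition))
        prev_t = j - 1 if 0 <= j - 1 < n else None
        curr_t = j if 0 <= j < n else None
        if prev_t is not None and onsets[prev_t] + lo <= p <= onsets[prev_t] + hi:
            normal_claims.setdefault(prev_t, []).append(p)
        elif curr_t is not None and onsets[curr_t] + lo <= p <= onsets[curr_t] + hi:
            normal_claims.setdefault(curr_t, []).append(p)
        else:
            gap_lo = onsets[0] + j * transition + (hi - transition)
            gap_hi = onsets[0] + j * transition + lo
            if (prev_t is not None or curr_t is not None) and gap_lo < p < gap_hi:
                deviant.append((p, prev_t, curr_t))
            else:
                dropped.append(p)

    for trial, plist in normal_claims.items():
        rts = sorted(p - onsets[trial] for p in plist)
        assigned_rt[trial] = rts[0]           # rule 3: fastest RT
        dropped.extend(onsets[trial] + r for r in rts[1:])

    # --- pass 2: deviant presses, iterated to a fixed point ----------------
    pending = list(deviant)   # keep temporal order (presses were sorted)
    while pending:
        proposals: dict[int, list[tuple[float, int]]] = {}
        undecided: list[int] = []
        for idx, (p, a, b) in enumerate(pending):
            has_a = a is None or a in assigned_rt
            has_b = b is None or b in assigned_rt
            target = None
            if has_a and not has_b:
                target = b                    # rule 1
            elif has_b and not has_a:
                target = a                    # rule 1
            elif not has_a and not has_b:
                # rule 2: closest in time, excluding mountains
                cand = [c for c in (a, b) if cats[c] != MOUNTAIN]
                if len(cand) == 1:
                    target = cand[0]
                elif len(cand) == 2:
                    d_a = p - (onsets[a] + hi)      # distance past a's window
                    d_b = (onsets[b] + lo) - p      # distance before b's window
                    target = a if d_a <= d_b else b  # tie -> earlier trial
                # both mountains: unassignable for now
            # both have responses: unassignable for now (rule 3 competition
            # may still free nothing, but state only grows)
            if target is not None:
                proposals.setdefault(target, []).append((p, idx))
            else:
                undecided.append(idx)

        progressed = False
        leftover: set[int] = set(undecided)
        for trial, plist in proposals.items():
            plist.sort(key=lambda pi: pi[0] - onsets[trial])   # fastest RT
            winner_p, winner_idx = plist[0]
            assigned_rt[trial] = winner_p - onsets[trial]
            progressed = True
            for _, i2 in plist[1:]:
                leftover.add(i2)
        if not progressed:
            dropped.extend(p for p, _, _ in pending)
            break
        pending = [pending[i] for i in sorted(leftover)]

    rts_out = np.full(n, np.nan)
    outcomes = np.empty(n, dtype=object)
    for k in range(n):
        has = k in assigned_rt
        if has:
            rts_out[k] = assigned_rt[k]
        if cats[k] == CITY:
            outcomes[k] = "correct_commission" if has else "omission_error"
        else:
            outcomes[k] = "commission_error" if has else "correct_omission"
    return TrialTable(onsets=onsets.copy(), categories=cats.copy(),
                      rts=rts_out, outcomes=outcomes,
                      dropped_presses=np.asarray(sorted(dropped)))


def score_run(table: TrialTable) -> RunScore:
    """Compute omission/commission rates, d', and the run-inclusion flag.

    Convention: a *hit* is a correct commission (press to a city), a *false
    alarm* a commission error (press to a mountain).  Extreme rates are
    corrected by the 1/(2N) rule before the inverse-normal transform.
    Runs are included when omission rate < 15% and commission rate < 60%.
    """
    cats = np.asarray(table.categories)
    n_city = int(np.sum(cats == CITY))
    n_mtn = int(np.sum(cats == MOUNTAIN))
    if n_city == 0 or n_mtn == 0:
        raise ValueError("both categories must be present to score a run")
    has_press = ~np.isnan(table.rts)
    omission = float(np.sum((cats == CITY) & ~has_press)) / n_city
    commission = float(np.sum((cats == MOUNTAIN) & has_press)) / n_mtn
    hit = _correct_extreme(1.0 - omission, n_city)
    fa = _correct_extreme(commission, n_mtn)
    return RunScore(
        omission_rate=omission,
        commission_rate=commission,
        hit_rate=hit,
        fa_rate=fa,
        d_prime=dprime(hit, fa),
        include_flag=(omission < OMISSION_MAX and commission < COMMISSION_MAX),
        n_city=n_city,
        n_mountain=n_mtn,
    )


def _correct_extreme(rate: float, n: int) -> float:
    """1/(2N) correction for rates of exactly 0 or 1."""
    if rate <= 0.0:
        return 1.0 / (2 * n)
    if rate >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return rate


def dprime(hit_rate: float, fa_rate: float) -> float:
    """Sensitivity d' = Z(hit rate) - Z(false-alarm rate).

    ``Z`` is the inverse Gaussian CDF.  Rates must lie strictly inside
    (0, 1); apply an extreme-rate correction (e.g. 1/(2N)) first.
    """
    if not (0.0 < hit_rate < 1.0 and 0.0 < fa_rate < 1.0):
        raise ValueError(
            "rates must lie strictly in (0, 1); apply an extreme-rate "
            "correction such as 1/(2N) before computing d'")
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))
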