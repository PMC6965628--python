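"""Independent brute-force oracles used to validate the fast implementations."""

from __future__ import annotations

import numpy as np


def assign_presses_bruteforce(onsets, categories, transition, presses):
    """Naive reference implementation of GradCPT press assignment.

    Re-derives every press's status from scratch on each sweep by scanning
    all trials, applying the written rules literally:

    * a press inside a trial's normal window [onset + 0.35*T, onset + 1.2*T]
      belongs to that trial; if several normal presses claim one trial the
      fastest RT stays, the rest are dropped;
    * a press in the deviant gap between two adjacent normal windows is
      assigned by: (1) to whichever adjacent trial lacks a response, if
      exactly one does; (2) if neither has a response, to the closest trial
      (distance to the nearest normal-window edge, ties to the earlier
      trial), mountains excluded; (3) competing presses for one trial are
      resolved in favor of the fastest RT, the losers re-evaluated;
    * sweeps repeat until nothing changes; leftovers are dropped.

    Returns (rt_by_trial: dict, dropped: sorted list of press times).
    """
    onsets = list(map(float, onsets))
    categories = list(categories)
    n = len(onsets)
    T = float(transition)
    lo, hi = 0.7 * (T / 2.0), T + 0.4 * (T / 2.0)

    def in_window(p, k):
        return onsets[k] + lo <= p <= onsets[k] + hi

    def gap_candidates(p):
        """Adjacent (prev, curr) trials if p sits in a deviant gap, else None."""
        # gap before trial k's window: (onsets[k] - T + hi, onsets[k] + lo)
        for k in range(n + 1):
            onset_k = onsets[0] + k * T
            if onset_k - T + hi < p < onset_k + lo:
                prev = k - 1 if 0 <= k - 1 < n else None
                curr = k if k < n else None
                if prev is None and curr is None:
                    return None
                return (prev, curr)
        return None

    assigned = {}          # trial -> press time
    dropped = []
    deviants = []

    # normal-window presses first
    claims = {}
    for p in presses:
        owners = [k for k in range(n) if in_window(p, k)]
        assert len(owners) <= 1
        if owners:
            claims.setdefault(owners[0], []).append(p)
        else:
            cand = gap_candidates(p)
            if cand is None:
                dropped.append(p)
            else:
                deviants.append((p, cand))
    for k, ps in claims.items():
        ps = sorted(ps, key=lambda q: q - onsets[k])
        assigned[k] = ps[0]
        dropped.extend(ps[1:])

    # deviant presses: sweep to fixed point
    remaining = list(deviants)
    while True:
        wants = {}
        stuck = []
        for item in remaining:
            p, (a, b) = item
            free = [c for c in (a, b) if c is not None and c not in assigned]
            target = None
            if len(free) == 1:
                target = free[0]
            elif len(free) == 2:
                non_mtn = [c for c in free if categories[c] != "mountain"]
                if len(non_mtn) == 1:
                    target = non_mtn[0]
                elif len(non_mtn) == 2:
                    da = p - (onsets[a] + hi)
                    db = (onsets[b] + lo) - p
                    target = a if da <= db else b
            if target is None:
                stuck.append(item)
            else:
                wants.setdefault(target, []).append(item)
        if not wants:
            dropped.extend(p for p, _ in remaining)
            break
        next_remaining = list(stuck)
        for k, items in wants.items():
            items = sorted(items, key=lambda it: it[0] - onsets[k])
            assigned[k] = items[0][0]
            next_remaining.extend(items[1:])
        remaining = sorted(next_remaining, key=lambda it: it[0])
        if not remaining:
            break

    rt_by_trial = {k: assigned[k] - onsets[k] for k in assigned}
    return rt_by_trial, sorted(dropped)
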