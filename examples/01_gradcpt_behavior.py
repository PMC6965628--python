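"""Score a simulated GradCPT run: press assignment, error rates, d'.

Generates a 300-trial city/mountain stream (10% mountains, 800 ms
transitions), simulates a subject with a 25% lapse rate on mountains and
3% omissions on cities, assigns the key presses to trials with the
iterative deviant-press rules, and prints the run score.
"""

from netlag.behavior import assign_presses, score_run
from netlag.synth import make_stimulus_sequence, simulate_behavior

seq = make_stimulus_sequence(n_trials=300, mountain_rate=0.1,
                             transition_ms=800.0, seed=7)
presses, truth = simulate_behavior(seq, lapse_rate=0.25, omission_rate=0.03,
                                   seed=7)
table = assign_presses(seq, presses)
score = score_run(table)

print(f"trials: {seq.n_trials} ({score.n_mountain} mountains)")
print(f"presses: {len(presses)} ({len(table.dropped_presses)} unassignable)")
print(f"omission error rate:   {score.omission_rate:6.1%}  "
      "(withheld presses to cities)")
print(f"commission error rate: {score.commission_rate:6.1%}  "
      "(presses to mountain targets)")
print(f"d' = {score.d_prime:.2f}   include run: {score.include_flag}")
# The commission rate tracks the injected 25% lapse probability and d'
# summarizes sensitivity: higher means better sustained attention.
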