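"""Zero-lag vs lag-minimum coupling of slow HFB envelope fluctuations.

Generates an electrode pair whose 0.1-1 Hz envelopes are anticorrelated at
r = -0.8 with a 400 ms delay, and shows that the lag-minimum correlation
captures the antagonism the zero-lag measure misses.
"""

from netlag.coupling import run_coupling
from netlag.synth import simulate_envelope_pair

x, y = simulate_envelope_pair(duration=380.0, fs_env=1000.0, r_target=-0.8,
                              lag_s=0.4, seed=11)
res = run_coupling(x, y, fs=1000.0, ch_i="dPPC", ch_j="PMC")

print(f"zero-lag correlation:    r = {res.zero_lag_r:+.3f} "
      f"(z = {res.zero_lag_z:+.3f})")
print(f"lag-minimum correlation: r = {res.lag_min_r:+.3f} "
      f"(z = {res.lag_min_z:+.3f}) at lag {res.lag_at_min_s:+.2f} s")
print(f"coupling envelope rate: {res.fs_env:g} Hz "
      f"(lag resolution {1 / res.fs_env:.2f} s)")
# The generative lag (0.4 s) is recovered by the argmin, the lag-minimum r
# approaches the generative -0.8, and the zero-lag r stays near zero: the
# delayed antagonism is invisible without the lag scan.
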