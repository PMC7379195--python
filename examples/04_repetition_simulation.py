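"""Why control sequences enforce the no-repetition rule explicitly.

If the 8 control tones (180 presentations each) were ordered completely
at random, adjacent repetitions would occur on ~12.4% of consecutive-tone
pairs — the Monte-Carlo mean matches the closed form
m*r*(r-1)/(N*(N-1)). Because repetition rates below ~15% let the
auditory system extract a no-repetition regularity (so chance
repetitions would evoke their own MMN inside the control condition),
full randomization is an inadequate control and the rule is enforced.
"""

from mmnlab import RepSimSpec, simulate_repetition_pct

res = simulate_repetition_pct(RepSimSpec(n_tone_types=8, reps_per_tone=180,
                                         k_sims=10_000, seed=1))
print(f"simulated mean repetition rate: {res.mean_pct:.2f}% "
      f"(SD across simulations {res.sd_pct:.2f}%)")
print(f"closed-form expectation:        {res.analytic_pct:.2f}%")
print(f"difference in simulation SEs:   "
      f"{abs(res.mean_pct - res.analytic_pct) / res.se_pct:.2f}")
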