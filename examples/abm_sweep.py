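"""Conformity x migration sweep of the agent-based simulator (reduced scale).

Each run burns in the demography, fixes every group on its own variant
(CFST = 1), then lets birth/death, migration, innovation, and
frequency-dependent learning act for 300 years. Reported values are mean
CFST over the final 200 years.
"""

from cultrans import mini_sweep_params, migration_contrast, sweep_grid

params = mini_sweep_params()
table = sweep_grid(
    theta_values=[0.5, 1.0, 1.4, 2.0],
    m_values=[0.0, 0.2],
    n_replicates=3,
    params=params,
    seed=1,
)
print("mean terminal CFST by (theta, m):")
print(table.groupby(["theta", "m"])["mean_cfst"].mean().round(3).to_string())
print(
    "\nConformity (theta > 1) preserves between-group diversity without"
    "\nmigration; unbiased (theta = 1) and anticonformist (theta = 0.5)"
    "\ntransmission lose it. Migration erodes diversity everywhere at this"
    "\nreduced scale."
)

diffs = migration_contrast(2.0, 0.1, 0.2, mini_sweep_params(theta=2.0), 5, seed=2)
print(
    f"\ncausal effect of migration 0.1 -> 0.2 at theta=2: "
    f"mean CFST change {diffs.mean():+.3f} over 5 matched replicate pairs"
)
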