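"""Run a configured sweep experiment through the library (the same entry
point the `clocktradeoff` CLI wraps) and read its headline summary.

The internal_scan compares simulated population precision against the
closed-form variance predictions of the entrainment theory.
"""

from clocktradeoff import SweepConfig, run_experiment

config = SweepConfig(
    experiment_tag="internal_scan",
    geometry_grid=[0.0, 0.05, 0.1, 0.2, 0.4],  # 0 -> point attractor
    eps_int_grid=[0.05],
    n_members=150,
    n_days=20,
    replicates=1,
    seed=7,
)
result = run_experiment(config, out_dir="scratch/internal_scan_demo")

cols = ["L_over_R", "eps_int", "MI_bits", "circ_var", "theory_sigma2"]
print(result.table[cols].to_string(index=False,
                                   float_format=lambda v: f"{v:.4f}"))
print("\nsummary:", result.summary)
print("\nMI rises with L/R under internal noise: stronger driving squeezes")
print("out phase diffusion at every dusk and dawn (theory_sigma2 is the")
print("closed-form eps^2 T / (s^2 - 1); the point attractor row uses")
print("eps^2 tau_relax).  Outputs written to scratch/internal_scan_demo/.")
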