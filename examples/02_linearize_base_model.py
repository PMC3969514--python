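"""Linearize a fitted base model and verify the OFV identity.

The linearized model replaces the structural PK model by its first-order
expansion at each subject's empirical Bayes estimates. If the
linearization is faithful, re-estimating the random effects on it
reproduces the nonlinear FOCE-I objective function value. For
proportional-error models the inner eta* search can fall into local
minima when started at zero — the MCETA multi-start repairs that, which
this script demonstrates.
"""

from focelin import foce, linearize, simulate

design = simulate.adversarial_proportional(seed=1)
data = simulate.simulate_dataset(design)

base = foce.ofv(design.true_model, data,
                foce.EstimationOptions(mceta=100, seed=7))
lin = linearize.linearize(design.true_model, base, data)
print(f"linearization table: {len(lin.table)} rows x "
      f"{lin.table.shape[1]} columns (predictions and derivatives at Q0)")

for mceta in (0, 10, 100):
    res = linearize.evaluate_linearized(
        lin, foce.EstimationOptions(mceta=mceta, seed=7)
    )
    n_stuck = sum(
        1 for sid in res.iofv if res.iofv[sid] - base.iofv[sid] > 1.0
    )
    print(f"mceta={mceta:>3}: linearized OFV {res.ofv:10.3f} "
          f"(nonlinear {base.ofv:.3f}, difference {res.ofv - base.ofv:+9.3f}, "
          f"subjects stuck in local minima: {n_stuck})")

print("\nAt mceta=0 the difference is large because a few subjects' inner "
      "searches terminate in spurious minima created by the eps-eta "
      "interaction term; with enough random initial eta vectors the "
      "linearized OFV matches the nonlinear one.")
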