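"""Rank all 40 model parameters by their DGSM influence index.

Derivative-based global sensitivity: relative output sensitivities are
averaged (squared) over a Sobol sample of the parameter box, square-rooted
and normalised to sum to one.  Parameters with a tiny index can be fixed at
defaults ("factor fixing") before estimation.
"""

from asmcal import dgsm_indices, load_model
from asmcal.fixtures import FixtureSpec, make_dataset, make_sbr_context
from asmcal.sensitivity import SensitivityConfig

model = load_model()
dataset, _ = make_dataset(FixtureSpec(seed=1), model)
ctx = make_sbr_context(dataset, model=model)

report = dgsm_indices(ctx.simulate_stacked, ctx.lower, ctx.upper,
                      SensitivityConfig(n_samples=8, seed=1), names=ctx.names)

print(f"{report.n_samples} Sobol points, "
      f"convergence diagnostic {report.convergence:.3f}\n")
print(report.to_frame().head(12).to_string(index=False))
print("\nIndices sum to 1; a value of 0.01 or higher marks a parameter that")
print("materially shapes the COD/NH4/NO2/NO3 trajectories of this scenario.")
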