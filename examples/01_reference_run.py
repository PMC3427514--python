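"""Simulate the reference (physiological) parameter set on a coarse grid.

Runs the five-species neurogenesis model for 100 days at grid spacing
h = 0.1, prints the SVZ stem/progenitor pool means against their
algebraic steady states, and the OB signal (the bioluminescence proxy:
OB-integrated neuroblast + neuron density) with its onset time.
"""

import numpy as np

import svzsim as sv

spec = sv.coarse_spec(h=0.1)
params = sv.reference_parameters()
config = sv.NumericsConfig(t_final=100.0, save_every=1.0)

result = sv.run_simulation(params, spec, config)
report = sv.classify_solution(result, params)

nB = result.readouts["svz_mean_nB"]
nC = result.readouts["svz_mean_nC"]
sig = result.readouts["ob_signal"]
onset = sig.times[np.argmax(sig.values >= 0.05 * sig.final)]

print(f"classification:        {report.category}")
print(f"SVZ mean n_B at t=100: {nB.final:.4f}  (steady state "
      f"{sv.steady_state_nB(params):.4f})")
print(f"SVZ mean n_C at t=100: {nC.final:.4f}  (steady state "
      f"{sv.steady_state_nC(params):.4f})")
print(f"final OB signal:       {sig.final:.4f}")
print(f"OB signal onset (5% of final): day {onset:.0f}")
print()
print("The SVZ pools equilibrate to the algebraic steady states within "
      "days, while the OB signal rises after a migration delay of a few "
      "weeks and saturates — the behaviour seen in vivo by "
      "bioluminescent imaging.")
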