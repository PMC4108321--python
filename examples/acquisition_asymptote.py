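"""Delay conditioning with a single CS: the real-time acquisition asymptote.

A 10 s tone is paired with a one-step US at its offset, 400 trials.  At
asymptote the clamped US prediction k steps before the US onset settles on
gamma**k * lambda: the model times the US within the trial, responding
hardest just before delivery.
"""

import numpy as np

from cctd import (
    ExperimentDesign, GroupSpec, ITISpec, ModelParameters, PhaseSpec, Placement,
    StimulusSpec, TrialTemplate, run_experiment,
)

params = ModelParameters()  # rho = gamma = 0.97, beta+ = 0.5, 1 s timesteps
design = ExperimentDesign(
    name="acquisition",
    stimuli={"tone": StimulusSpec("tone", alpha=0.1, duration_s=10)},
    templates={"tone+": TrialTemplate("tone+", [Placement("tone")], reinforced=True)},
    groups=[GroupSpec("G", [PhaseSpec([("tone+", 400)], ITISpec(fixed_s=150))])],
    params=params,
)

result = run_experiment(design, seed=1)["G"]
last = result.trials[-1]
prediction = result.strength[last.start:last.start + 10]
ladder = params.lambda_us * params.gamma ** np.arange(9, -1, -1)

print("step before US onset   prediction   gamma^k * lambda")
for k in range(9, -1, -1):
    print(f"{k:>18}   {prediction[9 - k]:>10.4f}   {ladder[9 - k]:>16.4f}")
print(f"\nlargest deviation from the discounted asymptote: "
      f"{np.max(np.abs(prediction - ladder)):.2e}")
# The prediction ramps exponentially toward lambda over the CS: the signature
# real-time property that a trial-level delta rule cannot produce.
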