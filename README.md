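# cctd — configural-cue temporal-difference learning for classical conditioning

`cctd` is a real-time simulator of Pavlovian (classical) conditioning built on
temporal-difference (TD) learning with a *configural-cue compound* stimulus
representation.  It is written for associative-learning researchers who want
to simulate conditioning experiments — acquisition, blocking, patterning,
renewal, occasion setting, serial-order discriminations — from a declarative
description of the design, and read out simulated response rates.

## The model

Every stimulus *i* (nominal cue, context, common element, configural cue) is a
**complete serial compound** (CSC): a chain of one-timestep components
*x*<sub>*i,j*</sub>(*t*) ∈ {0, 1}, each with its own associative weight
*V*<sub>*i,j*</sub> and eligibility trace *e*<sub>*i,j*</sub>.  On every
timestep the aggregate US prediction is

&nbsp;&nbsp;*Y*(*t*) = Σ<sub>*i,j*</sub> *V*<sub>*i,j*</sub> · *x*<sub>*i,j*</sub>(*t*),

and learning is driven by the TD error

&nbsp;&nbsp;δ(*t*) = λ(*t*) + γ·⌊*Y*(*t*)⌋₀ − ⌊*Y*(*t*−1)⌋₀,

where λ(*t*) is the US level (λ on US-active steps, else 0), γ the per-step
discount, and ⌊·⌋₀ clamps negative aggregates to zero.  Weights update as

&nbsp;&nbsp;Δ*V*<sub>*i,j*</sub> = β·α<sub>*i*</sub>·δ(*t*)·*e*<sub>*i,j*</sub>,

with β = β⁺ on US-present steps, β⁻ otherwise, and a replacing trace
*e*(*t*) = min(1, ργ·*e*(*t*−1) + *x*(*t*)).

On top of this elemental machinery sit **configurations**:

* **Simultaneous** — whenever two or more eligible stimuli co-occur, the
  maximal co-present set forms a configuration and an emergent **configural
  cue** *q*, unique to that combination, turns on for exactly the overlap.
  The cue is an ordinary stimulus (own components, traces, weights,
  learning rate = product of the two largest constituent α's), so compounds
  can deviate from pure summation — e.g. the cue turns *inhibitory* under
  negative patterning (A+, B+, AB−).
* **Serial** — when a stimulus is active while the decaying traces of earlier
  stimuli are still present (trace above a threshold θ), a pre-declared
  *ordered* configuration forms, with a cue specific to that order
  (A→B ≠ B→A).  This supports serial feature-negative discriminations and
  pure serial-order (structural) discriminations.
* **Context** — a background stimulus spanning the trial and repeating
  (component index mod its duration) through the inter-trial interval, so it
  extinguishes during unreinforced stretches; it can join configurations
  (e.g. the context+CS compound that carries ABA renewal).

Responding is generated from the clamped prediction by a threshold rule: per
minute of a readout window, draw `rpm_cap` thresholds *b* ~ U(0, *B*) and
count threshold crossings, so E[rpm] = cap·min(1, *s*/*B*), capped at
100 rpm.  Derived measures: elevation scores (CS − preCS rate) and
suppression ratios (cap − CR)/((cap − CR) + cap) ∈ [0, 0.5].

## Worked example

```python
from cctd import (ExperimentDesign, GroupSpec, ITISpec, ModelParameters,
                  PhaseSpec, Placement, StimulusSpec, TrialTemplate,
                  run_experiment)
import numpy as np

params = ModelParameters()          # rho = gamma = 0.97, 1 s timesteps
design = ExperimentDesign(
    name="acquisition",
    stimuli={"tone": StimulusSpec("tone", alpha=0.1, duration_s=10)},
    templates={"tone+": TrialTemplate("tone+", [Placement("tone")], reinforced=True)},
    groups=[GroupSpec("G", [PhaseSpec([("tone+", 400)], ITISpec(fixed_s=150))])],
    params=params,
)
result = run_experiment(design, seed=1)["G"]
last = result.trials[-1]
print(np.round(result.strength[last.start:last.start + 10], 4))
```

prints the asymptotic US prediction across the ten CS steps of the final
trial:

```
[0.7603 0.7838 0.808  0.833  0.8588 0.8854 0.9127 0.941  0.9701 1.0001]
```

— an exponential ramp γ⁹λ … γ⁰λ toward the US: the model has learned not
just *that* the US follows the tone but *when* (largest deviation from the
discounted asymptote here: 7.4·10⁻⁵).

Nine classic experiment designs ship as fixtures
(`cctd.fixture_catalog()`): second-order conditioning, blocking, fixed- vs
variable-duration timing, stimulus generalization, ABA renewal, positive /
negative / biconditional patterning, compound summation, simultaneous vs
serial negative occasion setting, and serial structural discrimination.
`cctd.validate_fixture(name)` runs a 5-seed battery and checks each
experiment's published response pattern directionally.  The `examples/`
scripts walk one capability each; a thin CLI mirrors the library:

```bash
cctd list-fixtures
cctd run renewal --seed 1 --scale 0.1 --out runs/
cctd validate generalization
cctd export-design blocking
```

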