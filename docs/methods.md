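# Methods

This note documents the model as implemented: the update rules and their
fixed ordering, the configuration logic, the behavioural readout, the
choices made where the procedure was genuinely open, and what the shipped
experiment fixtures do and do not establish.

## Learning rule and update order

Time is discrete, 0-based, with half-open presentation intervals: a stimulus
with onset *o* and duration *d* (in steps) is present on steps [*o*, *o*+*d*).
Each present stimulus activates exactly one CSC component per step (component
*j* = steps since onset).  On every step the engine executes, in this order:

1. advance presence of all scheduled stimuli and the context;
2. form configurations (simultaneous, then the declared serial ones) and
   activate their configural cues;
3. compute the aggregate prediction *Y*(*t*) over all active components;
4. form the TD error δ(*t*) = λ(*t*) + γ⌊*Y*(*t*)⌋₀ − ⌊*Y*(*t*−1)⌋₀;
5. update all weights *V* += β α<sub>i</sub> δ *e*, using the eligibility
   traces **as they stood at the end of step t−1** (a component therefore
   never learns from the δ of its own first step);
6. update traces *e*(*t*) = min(1, ργ·*e*(*t*−1) + *x*(*t*)), flushing values
   below 10⁻¹² to zero.

Negative aggregate predictions are clamped to zero inside the error and the
response rule; raw signed weights are retained so inhibition is observable.
β⁺ applies on US-active steps, β⁻ elsewhere.  Traces persist across trials
and the inter-trial interval (ITI) with no reset; ITIs in the shipped
designs are long enough that traces decay to irrelevance naturally.

Under this scheme the fixed point of single-CS delay conditioning (CS on
steps [0, d), one-step US at step d) places the clamped prediction at
γᵏλ on the CS step *k* steps separated from the US onset — λ on the final
CS step, γλ one step earlier, and so on.  The acceptance suite asserts this
ladder to ±0.01.  With one-step stimuli, the US on the following step and
γ = 0, each trial collapses to exactly one effective update and the engine
reproduces the trial-level delta rule (Rescorla–Wagner) to machine
precision; the suite checks this against an independent trial-level oracle.

## Configurations

**Simultaneous.**  Eligible stimuli are all co-present non-context stimuli
(the context joins only when `context_in_configs` is set, as in the renewal
design; the common element can be excluded via `common_in_configs`, as in
the timing design).  Each step, the *maximal* co-present eligible set (≥ 2
stimuli) is the one configuration present — presence of any proper subset is
rejected (the subtractive exclusivity term: a configuration AB is not
present when A, B and C are all active; ABC forms instead).  The cue exists
exactly while the overlap lasts; its component chain restarts whenever
presence breaks (first component on each 0→1 transition, component *n*
contingent on *n*−1 having been present the step before).  Cue learning
rate: the product of the two largest constituent α's.

**Serial.**  Serial configurations must be declared in the design (which
set of stimuli forms a sequence is given by the experimental procedure).
A declared order (s₁, …, s_z) is present at *t* iff the final constituent
s_z has an active component; every earlier constituent is *trace-present*
(all components off, eligibility above θ); the constituents' most recent
onsets respect the declared order; and no other eligible stimulus is active
or trace-present (otherwise the larger sequence forms instead).
Configurations are never formed from traces alone.  Trace presence uses the
closed form decayᵏ > θ (the strongest trace of an ended stimulus is its most
recent component's, capped at 1 while active), with θ = 0.1 by default —
at ργ = 0.9409 a trace counts as present for 37 steps, which bridges the
1 s gaps and 60 s serial compounds of the shipped designs and expires over
any of their ITIs.  Serial cue rate: the simultaneous product rule times
u/s (u = CSs unique to the configuration, s = configurations sharing a CS
with it, both floored at 1), the stated correction for memory interference
between overlapping sequences.

The common element is ignored for serial formation and exactness, like the
context: it accompanies every nominal CS, so it would otherwise veto every
declared sequence.  Its strength (like the context's) still feeds the
aggregate prediction during the sequence.

**Context.**  One context stimulus per phase, present on every step of
trial + ITI, component index *t* mod *d* with *d* = the span from trial
onset to the latest stimulus/US offset.  Repetition without reinforcement
makes the context lose strength across the ITI (verified by test).

**Configuration strength accessors.**  Summed-strength accessors are
provided for both kinds (`simultaneous_configuration_strength`: active
constituents + cue; `serial_configuration_strength`: active constituents +
the most recent component of each traced constituent + cue + context),
together with the within-trial hold clause (`ConfigurationStrength`: after
presence ceases the last value is held until trial end).  The fixture
battery reads behaviour from the clamped aggregate prediction (below),
which equals the simultaneous configuration sum whenever that configuration
is what is present; for serial configurations it omits the traced-
constituent term — a contribution common to reinforced and non-reinforced
sequences in the order-discrimination designs, so directions are
unaffected.

## Behavioural readout

Responding is generated from the clamped prediction over a readout window
(a stimulus's presentation, or the compound's span).  Per (possibly
partial) minute of the window, `rpm_cap` = 100 thresholds *b* ~ U(0, *B*)
are drawn (B = 0.985) and crossings counted, capping rates at 100 rpm with
E[rpm] = cap·min(1, s̄/B); the Monte-Carlo calibration of this rule against
the uniform CDF is part of the acceptance suite.  The validation battery
uses the deterministic expectation instead of draws, so seed variation
reflects only trial scheduling (orders, ITIs, sampled durations).
Elevation score = CS-window rate − preCS-window rate (equal-length window
immediately before onset).  Suppression ratio = (cap − CR)/((cap − CR) + cap),
reconstructed from its stated endpoints (0.5 = no conditioning, 0 =
maximal); it replaces observed baseline responding with the simulated rate
ceiling.  The optional weighted-mean decision rule for serial compounds is
deliberately not implemented; responding during the last element of a
sequence is read out like any other window.

## Design language and sampling

Designs are declarative: stimuli (α, context/common flags, default
durations), trial templates (placements, US onset/duration, reinforcement),
groups of phases (trial multisets, ITI distribution, ordering policy,
context).  Expansion to a timestep schedule is seeded and reproducible;
random orders are permutations of the declared multiset; fixed sequences
(the occasion-setting test day: N, LN, LN, N, LN, N, N, LN) are preserved
verbatim.  Conventions chosen once:

* "variable ITI, mean m" → uniform on [0.5 m, 1.5 m]; "m ± r" → uniform on
  [m − r, m + r]; a fixed-plus-variable ITI adds the two parts.
* exponential CS durations are rounded to the nearest step, minimum 1;
  the independently sampled common element never moves the US, which tracks
  the latest *nominal* CS offset.
* a reinforced template without an explicit US onset is delay conditioning:
  one-step US at the latest nominal CS offset.
* unpaired control phases ("84 L; 84+") randomly interleave CS-alone and
  US-alone trials, the latter carrying only context + US.
* reduced fixtures scale trial counts by max(min(n, 4), ⌊n·scale⌋): a tenth
  of the trials but never fewer than 4 (counts already below 4 are kept).

## Fixtures: what they emulate, and limits

The nine shipped designs reproduce the corresponding experimental
procedures' trial structure, timing and learning-rate assignments,
including the per-design overrides (0.05 s timesteps for eye-blink
blocking; ρ = γ = 0.989 for timing; ρ = γ = 0.995 for occasion setting; a
shared common element X wherever two or more nominal CSs occur).  They are
synthetic schedules, not data: physical stimulus identities are not
counterbalanced, sessions are flattened into trial counts, and behaviour
is a deterministic transform of model strength plus scheduling noise — so
passing the battery shows the *model* produces the published response
patterns under these procedures, not that it fits any animal's data
quantitatively.

The validation battery runs 5 seeds (default seeds 1–5) and asserts
directions on seed-averaged rates.  Most fixtures run at scale 0.1.  Two
discriminations only exist after prolonged training and therefore validate
at full trial counts: the serial structural discrimination (weak, late
emerging — the early-training difference is asserted to be near zero) and
patterning (negative patterning is the slowest discrimination; at a tenth
of the trials the compound cue is already inhibitory but CD− responding has
not yet fallen below C+/D+).  Renewal at reduced scale leaves extinction
visibly incomplete; the battery therefore asserts the renewal *signature* —
more test responding in ABA than AAA or Control, and recovery at the
context switch only in ABA — rather than the full-scale equivalence of AAA
and Control.  The equivalence-style checks (e.g. "blocking ≈ naïve
reacquisition") are operationalised as "the control difference is smaller
than the experimental effect".

## Numerical notes

* All weights/traces live in flat float64 arrays (one slot per
  (entity, component), allocated lazily), so a step is a handful of
  vectorised operations; the full nine-experiment battery runs in about two
  minutes on one CPU.
* Traces below 10⁻¹² are flushed to zero to keep the decayed tail out of
  denormal arithmetic; at ργ ≈ 0.94 this is ~450 steps after offset, far
  beyond the trace-presence threshold.
* Determinism: a run is a pure function of (design, parameters, seed);
  response tables for equal seeds are byte-identical (tested).
* γ = 0 is admitted (trial-level limit); ρ·γ < 1 is enforced.

## Known limitations

* Configuration formation is greedy-maximal per step; nested or
  overlapping simultaneous configurations (AB and ABC simultaneously) are
  intentionally exclusive, which matches the exactness rule but means a
  subset compound never accrues its own cue while a superset is present.
* Serial configurations of partially overlapping stimuli only form once
  the earlier stimulus has fully ended; fully simultaneous onsets never
  form a serial configuration.
* The response rule is memoryless across windows; no habituation,
  motivation or baseline-drift processes are modelled.
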