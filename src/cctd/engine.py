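"""The per-timestep simulation loop.

Orchestrates, in a fixed order on every timestep: presence advance ->
configuration formation -> aggregate prediction -> TD error -> weight
update (with the traces as of the previous step) -> trace update.  The run
is fully deterministic given (design, parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import configs as cfg
from .core import ComponentStore, td_error
from .design import ExperimentDesign, TrialInstance, assign_configural_alphas, expand_design
from .params import ModelParameters


@dataclass
class TrialRecord:
    """Where a trial landed on the global step axis (for window extraction)."""

    index: int
    label: str
    phase: int
    start: int  # global step of trial onset
    span: int
    iti_steps: int
    placements: list[tuple[str, int, int]]  # (stimulus, global onset, duration)
    us_onset: int | None  # global step


@dataclass
class RunResult:
    """Outcome of simulating one group: prediction trace, trials, weights."""

    design_name: str
    group: str
    params: ModelParameters
    seed: int
    scale: float
    strength: np.ndarray  # clamped aggregate prediction per global step
    us: np.ndarray  # US level per global step
    trials: list[TrialRecord]
    weights: dict[str, np.ndarray]
    alphas: dict[str, float]

    def trials_matching(self, phase: int | None = None, labels=None) -> list[TrialRecord]:
        sel = self.trials
        if phase is not None:
            sel = [t for t in sel if t.phase == phase]
        if labels is not None:
            labels = {labels} if isinstance(labels, str) else set(labels)
            sel = [t for t in sel if t.label in labels]
        return sel


class Simulator:
    """Runs one group's trial schedule through the learning rule."""

    def __init__(self, design: ExperimentDesign, params: ModelParameters | None = None):
        self.design = design
        self.params = params or design.params
        self.store = ComponentStore()
        for name, s in design.stimuli.items():
            self.store.register_entity(name, s.alpha)
        self._serial_alphas = assign_configural_alphas(design)
        self._serial_specs = [
            cfg.ConfigurationSpec(kind="serial", constituents=tuple(o))
            for o in design.serial_configs
        ]
        self._serial_seq = {s.cue_id: cfg.ComponentSequencer() for s in self._serial_specs}
        self._sim_seq: dict[frozenset, cfg.ComponentSequencer] = {}
        self._sim_alpha_known: set[str] = set()
        self._last_active: dict[str, int] = {}
        self._last_onset: dict[str, int] = {}
        self._prev_active: set[str] = set()
        self._prev_sim_key: frozenset | None = None

    # -- helpers ------------------------------------------------------------
    def _sim_eligible(self, name: str) -> bool:
        s = self.design.stimuli[name]
        if s.is_context:
            return self.design.context_in_configs
        if s.is_common:
            return self.design.common_in_configs
        return True

    def _serial_eligible(self, name: str) -> bool:
        s = self.design.stimuli[name]
        return not s.is_context and not s.is_common

    def run(self, trials: list[TrialInstance], seed: int = 0, scale: float = 1.0,
            group: str = "") -> RunResult:
        p = self.params
        store = self.store
        design = self.design
        decay = p.trace_decay
        theta = p.trace_presence_threshold
        total = sum(t.total_steps for t in trials)
        strength = np.zeros(total)
        us_track = np.zeros(total)
        records: list[TrialRecord] = []

        serial_names = {s.cue_id: s for s in self._serial_specs}
        all_stimuli = list(design.stimuli)
        y_prev_clamped = 0.0
        t_global = 0

        for ti, tr in enumerate(trials):
            records.append(
                TrialRecord(
                    index=ti, label=tr.label, phase=tr.phase, start=t_global,
                    span=tr.span, iti_steps=tr.iti_steps,
                    placements=[(s, t_global + o, d) for (s, o, d) in tr.placements],
                    us_onset=None if tr.us_onset is None else t_global + tr.us_onset,
                )
            )
            ctx = tr.context
            d_ctx = tr.context_period
            for tau in range(tr.total_steps):
                # 1. presence of primitive stimuli
                active: dict[str, int] = {}
                for stim, onset, dur in tr.placements:
                    if onset <= tau < onset + dur:
                        active[stim] = tau - onset
                if ctx is not None:
                    active[ctx] = cfg.context_component(tau, d_ctx)

                # onset bookkeeping (for serial order checks)
                for stim in active:
                    if stim not in self._prev_active:
                        self._last_onset[stim] = t_global

                active_idx: list[int] = [store.idx(s, c) for s, c in active.items()]

                # 2a. simultaneous configuration: maximal co-present eligible set
                sim_key = None
                if design.form_simultaneous:
                    elig = [s for s in active if self._sim_eligible(s)]
                    if len(elig) >= 2:
                        sim_key = frozenset(elig)
                if sim_key != self._prev_sim_key and self._prev_sim_key is not None:
                    self._sim_seq[self._prev_sim_key].reset()
                if sim_key is not None:
                    seq = self._sim_seq.get(sim_key)
                    if seq is None:
                        seq = self._sim_seq[sim_key] = cfg.ComponentSequencer()
                    comp = seq.advance(True)
                    spec = cfg.ConfigurationSpec(kind="simultaneous", constituents=tuple(sorted(sim_key)))
                    cue = spec.cue_id
                    if cue not in self._sim_alpha_known:
                        store.register_entity(
                            cue, cfg.simultaneous_cue_alpha([design.stimuli[s].alpha for s in sim_key])
                        )
                        self._sim_alpha_known.add(cue)
                    active_idx.append(store.idx(cue, comp))
                self._prev_sim_key = sim_key

                # 2b. serial configurations (pre-declared)
                if self._serial_specs:
                    ser_active = {s: c for s, c in active.items() if self._serial_eligible(s)}
                    traced = set()
                    for s in all_stimuli:
                        if s in active or not self._serial_eligible(s):
                            continue
                        last = self._last_active.get(s)
                        since = None if last is None else (t_global - 1 - last)
                        if cfg.trace_present(since, decay, theta):
                            traced.add(s)
                    for spec in self._serial_specs:
                        present = cfg.serial_presence(
                            ser_active, traced, spec.constituents, self._last_onset
                        )
                        comp = self._serial_seq[spec.cue_id].advance(bool(present))
                        if present:
                            cue = spec.cue_id
                            if cue not in self._sim_alpha_known:
                                store.register_entity(cue, self._serial_alphas[cue])
                                self._sim_alpha_known.add(cue)
                            active_idx.append(store.idx(cue, comp))

                # 3. prediction and TD error
                us_on = tr.us_onset is not None and tr.us_onset <= tau < tr.us_onset + tr.us_duration
                us_level = p.lambda_us if us_on else 0.0
                y_now = store.prediction(active_idx)
                y_now_clamped = max(0.0, y_now)
                delta = us_level + p.gamma * y_now_clamped - y_prev_clamped

                # 4. weights (traces as of t-1), then 5. traces
                store.update_weights(delta, us_on, p)
                store.update_traces(active_idx, p)

                strength[t_global] = y_now_clamped
                us_track[t_global] = us_level
                for stim in active:
                    self._last_active[stim] = t_global
                self._prev_active = set(active)
                y_prev_clamped = y_now_clamped
                t_global += 1

        return RunResult(
            design_name=design.name, group=group, params=p, seed=seed, scale=scale,
            strength=strength, us=us_track, trials=records,
            weights=store.weight_table(),
            alphas={e: store.alpha_of(e) for e in store.entities},
        )


def run_experiment(
    design: ExperimentDesign, seed: int, scale: float = 1.0
) -> dict[str, RunResult]:
    """Expand and simulate every group of a design. Deterministic per seed."""
    schedule = expand_design(design, seed=seed, scale=scale)
    out: dict[str, RunResult] = {}
    for group, trials in schedule.items():
        sim = Simulator(design)
        out[group] = sim.run(trials, seed=seed, scale=scale, group=group)
    return out
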