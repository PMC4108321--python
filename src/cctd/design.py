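"""Declarative experiment designs and their expansion into trial schedules.

A design describes *what happens when*: stimuli with learning rates,
trial templates with per-stimulus onset/duration placements and US timing,
groups of phases with trial counts, ITI distributions and ordering
policies.  :func:`expand_design` turns a design into a concrete, seeded,
timestep-resolved trial list per group; the simulator consumes that list.

Conventions
-----------
* Time within a design is in seconds; expansion converts to timesteps.
* A stimulus with onset ``o`` and duration ``d`` occupies steps
  ``[o, o+d)`` (half-open, 0-based).
* A reinforced template with no explicit US onset places the US at the
  latest CS offset (delay conditioning).
* "Variable" intervals with a stated mean ``m`` are sampled uniformly on
  ``[0.5m, 1.5m]``; ``m ± r`` means uniform on ``[m-r, m+r]``.
* Exponentially distributed stimulus durations are rounded to the nearest
  whole timestep, minimum 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .configs import ConfigurationSpec, serial_cue_alpha
from .params import ModelParameters


class DesignError(ValueError):
    """Raised when a design fails validation."""


# ---------------------------------------------------------------------------
# declarative types
# ---------------------------------------------------------------------------

@dataclass
class StimulusSpec:
    name: str
    alpha: float
    is_context: bool = False
    is_common: bool = False
    duration_s: float | None = None  # default placement duration

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise DesignError(f"alpha of {self.name!r} must be in (0, 1]")


@dataclass
class Placement:
    """One stimulus presentation within a trial.

    Exactly one of ``duration_s`` / ``exp_mean_s`` / the stimulus default
    determines the duration; ``exp_mean_s`` samples an exponential duration
    with that mean independently on every trial.
    """

    stimulus: str
    onset_s: float = 0.0
    duration_s: float | None = None
    exp_mean_s: float | None = None

    def __post_init__(self):
        if self.onset_s < 0:
            raise DesignError("placement onset must be >= 0")


@dataclass
class USSpec:
    onset_s: float | None = None  # None -> latest CS offset
    duration_s: float | None = None  # None -> one timestep


@dataclass
class TrialTemplate:
    label: str
    placements: list[Placement] = field(default_factory=list)
    reinforced: bool = False
    us: USSpec = field(default_factory=USSpec)


@dataclass
class ITISpec:
    fixed_s: float = 0.0
    var_mean_s: float = 0.0
    var_halfrange_s: float | None = None  # None -> var_mean / 2

    def sample_s(self, rng: np.random.Generator) -> float:
        iti = self.fixed_s
        if self.var_mean_s > 0:
            hr = self.var_halfrange_s
            if hr is None:
                hr = 0.5 * self.var_mean_s
            iti += rng.uniform(self.var_mean_s - hr, self.var_mean_s + hr)
        return iti

    def bounds_s(self) -> tuple[float, float]:
        hr = self.var_halfrange_s
        if hr is None:
            hr = 0.5 * self.var_mean_s
        lo = self.fixed_s + (self.var_mean_s - hr if self.var_mean_s > 0 else 0.0)
        hi = self.fixed_s + (self.var_mean_s + hr if self.var_mean_s > 0 else 0.0)
        return lo, hi


@dataclass
class PhaseSpec:
    trials: list[tuple[str, int]] = field(default_factory=list)
    iti: ITISpec = field(default_factory=ITISpec)
    context: str | None = None
    ordering: str = "random"  # random | sequence | random_tests_last
    sequence: list[str] | None = None  # verbatim order for "sequence"
    test_labels: tuple[str, ...] = ()  # confined to the 2nd half under random_tests_last


@dataclass
class GroupSpec:
    name: str
    phases: list[PhaseSpec] = field(default_factory=list)


@dataclass
class ExperimentDesign:
    name: str
    stimuli: dict[str, StimulusSpec]
    templates: dict[str, TrialTemplate]
    groups: list[GroupSpec]
    params: ModelParameters = field(default_factory=ModelParameters)
    serial_configs: list[tuple[str, ...]] = field(default_factory=list)
    form_simultaneous: bool = True
    common_in_configs: bool = True
    context_in_configs: bool = False
    notes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for label, tpl in self.templates.items():
            for p in tpl.placements:
                if p.stimulus not in self.stimuli:
                    raise DesignError(f"template {label!r} uses unknown stimulus {p.stimulus!r}")
        for g in self.groups:
            for ph in g.phases:
                for label, count in ph.trials:
                    if label not in self.templates:
                        raise DesignError(f"group {g.name!r} uses unknown template {label!r}")
                    if count < 0:
                        raise DesignError("trial counts must be >= 0")
                if ph.ordering == "sequence":
                    for label in ph.sequence or []:
                        if label not in self.templates:
                            raise DesignError(f"sequence uses unknown template {label!r}")
                if ph.context is not None and ph.context not in self.stimuli:
                    raise DesignError(f"unknown context {ph.context!r}")
        for order in self.serial_configs:
            if len(order) < 2:
                raise DesignError("serial configuration needs >= 2 constituents")
            for s in order:
                if s not in self.stimuli:
                    raise DesignError(f"serial configuration uses unknown stimulus {s!r}")

    @property
    def common_element(self) -> str | None:
        for name, s in self.stimuli.items():
            if s.is_common:
                return name
        return None


# ---------------------------------------------------------------------------
# expansion
# ---------------------------------------------------------------------------

@dataclass
class TrialInstance:
    """A fully resolved trial: everything in integer timesteps."""

    label: str
    phase: int
    placements: list[tuple[str, int, int]]  # (stimulus, onset, duration)
    us_onset: int | None
    us_duration: int
    iti_steps: int
    context: str | None
    context_period: int
    span: int  # steps from trial start to the latest stimulus/US offset

    @property
    def total_steps(self) -> int:
        return self.span + self.iti_steps


def scaled_count(n: int, scale: float) -> int:
    """Reduced-fixture trial count: divide by ``1/scale`` but never drop
    below 4 trials (unless the original count was already below 4)."""
    if scale >= 1.0:
        return n
    return max(min(n, 4), int(math.floor(n * scale)))


def _steps(seconds: float, dt: float) -> int:
    return int(round(seconds / dt))


def _resolve_duration(p: Placement, stim: StimulusSpec, dt: float, rng: np.random.Generator) -> int:
    if p.exp_mean_s is not None:
        d = rng.exponential(p.exp_mean_s)
        return max(1, int(round(d / dt)))
    dur_s = p.duration_s if p.duration_s is not None else stim.duration_s
    if dur_s is None:
        raise DesignError(f"no duration for stimulus {p.stimulus!r}")
    steps = _steps(dur_s, dt)
    if steps < 1:
        raise DesignError(f"duration of {p.stimulus!r} rounds to < 1 timestep")
    return steps


def _phase_order(ph: PhaseSpec, scale: float, rng: np.random.Generator) -> list[str]:
    if ph.ordering == "sequence":
        return list(ph.sequence or [])
    labels: list[str] = []
    for label, count in ph.trials:
        labels.extend([label] * scaled_count(count, scale))
    if ph.ordering == "random":
        return [labels[i] for i in rng.permutation(len(labels))]
    if ph.ordering == "random_tests_last":
        main = [l for l in labels if l not in ph.test_labels]
        tests = [l for l in labels if l in ph.test_labels]
        main = [main[i] for i in rng.permutation(len(main))]
        half = len(main) // 2
        tail = main[half:] + tests
        tail = [tail[i] for i in rng.permutation(len(tail))]
        return main[:half] + tail
    raise DesignError(f"unknown ordering {ph.ordering!r}")


def expand_design(
    design: ExperimentDesign, seed: int, scale: float = 1.0
) -> dict[str, list[TrialInstance]]:
    """Expand every group of a design into a seeded trial schedule.

    The result is reproducible given ``(design, seed, scale)``; each group
    draws from an independent stream derived from the seed and the group's
    position in the design.
    """
    dt = design.params.timestep_s
    out: dict[str, list[TrialInstance]] = {}
    for gi, group in enumerate(design.groups):
        rng = np.random.default_rng([int(seed) % (2**31), gi])
        trials: list[TrialInstance] = []
        for pi, ph in enumerate(group.phases):
            for label in _phase_order(ph, scale, rng):
                tpl = design.templates[label]
                placements = []
                for p in tpl.placements:
                    onset = _steps(p.onset_s, dt)
                    dur = _resolve_duration(p, design.stimuli[p.stimulus], dt, rng)
                    placements.append((p.stimulus, onset, dur))
                offsets = [o + d for (_, o, d) in placements]
                # the default (delay-conditioning) US onset tracks the nominal
                # CSs; an independently sampled common element must not move it
                cs_offsets = [
                    o + d for (s, o, d) in placements if not design.stimuli[s].is_common
                ]
                if tpl.reinforced:
                    if tpl.us.onset_s is not None:
                        us_on = _steps(tpl.us.onset_s, dt)
                    elif cs_offsets:
                        us_on = max(cs_offsets)
                    else:
                        raise DesignError(f"template {label!r}: US onset underdetermined")
                    us_dur = 1 if tpl.us.duration_s is None else max(1, _steps(tpl.us.duration_s, dt))
                    offsets.append(us_on + us_dur)
                else:
                    us_on, us_dur = None, 0
                span = max(offsets, default=1)
                iti = max(1, _steps(ph.iti.sample_s(rng), dt))
                trials.append(
                    TrialInstance(
                        label=label,
                        phase=pi,
                        placements=placements,
                        us_onset=us_on,
                        us_duration=us_dur,
                        iti_steps=iti,
                        context=ph.context,
                        context_period=span,
                        span=span,
                    )
                )
        out[group.name] = trials
    return out


# ---------------------------------------------------------------------------
# common-element augmentation and configural learning rates
# ---------------------------------------------------------------------------

def add_common_elements(design: ExperimentDesign, alpha: float, name: str = "X") -> ExperimentDesign:
    """Accompany every nominal CS presentation with a shared element.

    Each non-context placement in every template gains a co-extensive
    placement of the common element; where the nominal duration is sampled,
    the common element samples its own duration independently from the same
    distribution.  Designs with fewer than two nominal stimuli are returned
    unchanged.
    """
    nominal = [s for s in design.stimuli.values() if not s.is_context and not s.is_common]
    if len(nominal) < 2:
        return design
    if design.common_element is not None:
        raise DesignError("design already has a common element")
    stimuli = dict(design.stimuli)
    stimuli[name] = StimulusSpec(name=name, alpha=alpha, is_common=True)
    templates: dict[str, TrialTemplate] = {}
    for label, tpl in design.templates.items():
        placements = list(tpl.placements)
        seen: set[tuple] = set()
        extra: list[Placement] = []
        for p in tpl.placements:
            key = (p.onset_s, p.duration_s, p.exp_mean_s)
            if key in seen:
                continue
            seen.add(key)
            dur = p.duration_s
            if dur is None and p.exp_mean_s is None:
                dur = design.stimuli[p.stimulus].duration_s
            extra.append(
                Placement(stimulus=name, onset_s=p.onset_s, duration_s=dur, exp_mean_s=p.exp_mean_s)
            )
        templates[label] = TrialTemplate(
            label=label, placements=placements + extra, reinforced=tpl.reinforced, us=tpl.us
        )
    return ExperimentDesign(
        name=design.name,
        stimuli=stimuli,
        templates=templates,
        groups=design.groups,
        params=design.params,
        serial_configs=design.serial_configs,
        form_simultaneous=design.form_simultaneous,
        common_in_configs=design.common_in_configs,
        context_in_configs=design.context_in_configs,
        notes=design.notes,
    )


def assign_configural_alphas(design: ExperimentDesign) -> dict[str, float]:
    """Learning rates for the declared serial configural cues.

    The simultaneous product-of-two-largest rule, adjusted per configuration
    by ``u/s``: ``u`` = CSs unique to the configuration (floor 1), ``s`` =
    configurations sharing at least one CS with it (floor 1).
    """
    out: dict[str, float] = {}
    orders = [tuple(o) for o in design.serial_configs]
    for order in orders:
        spec = ConfigurationSpec(kind="serial", constituents=order)
        alphas = [design.stimuli[s].alpha for s in order]
        others = [o for o in orders if o != order]
        sharing = sum(1 for o in others if set(o) & set(order))
        unique = sum(1 for s in order if not any(s in set(o) for o in others))
        out[spec.cue_id] = serial_cue_alpha(alphas, unique, sharing)
    return out


# ---------------------------------------------------------------------------
# serialization (YAML round trip)
# ---------------------------------------------------------------------------

def design_to_dict(design: ExperimentDesign) -> dict:
    return {
        "name": design.name,
        "params": design.params.to_dict(),
        "stimuli": {k: asdict(v) for k, v in design.stimuli.items()},
        "templates": {k: asdict(v) for k, v in design.templates.items()},
        "groups": [asdict(g) for g in design.groups],
        "serial_configs": [list(o) for o in design.serial_configs],
        "form_simultaneous": design.form_simultaneous,
        "common_in_configs": design.common_in_configs,
        "context_in_configs": design.context_in_configs,
        "notes": design.notes,
    }


def design_from_dict(d: dict) -> ExperimentDesign:
    groups = []
    for g in d["groups"]:
        phases = []
        for ph in g["phases"]:
            phases.append(
                PhaseSpec(
                    trials=[(l, c) for l, c in ph["trials"]],
                    iti=ITISpec(**ph["iti"]),
                    context=ph.get("context"),
                    ordering=ph.get("ordering", "random"),
                    sequence=ph.get("sequence"),
                    test_labels=tuple(ph.get("test_labels", ())),
                )
            )
        groups.append(GroupSpec(name=g["name"], phases=phases))
    templates = {}
    for label, t in d["templates"].items():
        templates[label] = TrialTemplate(
            label=t["label"],
            placements=[Placement(**p) for p in t["placements"]],
            reinforced=t["reinforced"],
            us=USSpec(**t["us"]),
        )
    return ExperimentDesign(
        name=d["name"],
        stimuli={k: StimulusSpec(**v) for k, v in d["stimuli"].items()},
        templates=templates,
        groups=groups,
        params=ModelParameters.from_dict(d["params"]),
        serial_configs=[tuple(o) for o in d.get("serial_configs", [])],
        form_simultaneous=d.get("form_simultaneous", True),
        common_in_configs=d.get("common_in_configs", True),
        context_in_configs=d.get("context_in_configs", False),
        notes=d.get("notes", {}),
    )


def design_to_yaml(design: ExperimentDesign) -> str:
    return yaml.safe_dump(design_to_dict(design), sort_keys=False)


def design_from_yaml(text: str) -> ExperimentDesign:
    return design_from_dict(yaml.safe_load(text))


def schedule_table(schedule: dict[str, list[TrialInstance]]):
    """Expanded schedule as a tidy table (one row per stimulus placement)."""
    import pandas as pd

    rows = []
    for group, trials in schedule.items():
        step = 0
        for ti, tr in enumerate(trials):
            for stim, onset, dur in tr.placements:
                rows.append(
                    dict(group=group, trial=ti, phase=tr.phase, label=tr.label,
                         stimulus=stim, onset=step + onset, duration=dur)
                )
            if tr.us_onset is not None:
                rows.append(
                    dict(group=group, trial=ti, phase=tr.phase, label=tr.label,
                         stimulus="US", onset=step + tr.us_onset, duration=tr.us_duration)
                )
            step += tr.total_steps
    return pd.DataFrame(
        rows, columns=["group", "trial", "phase", "label", "stimulus", "onset", "duration"]
    )
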