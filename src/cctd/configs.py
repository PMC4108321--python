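"""Simultaneous and serial stimulus configurations and configural cues.

A *configuration* is a compound of co-occurring (simultaneous) or
trace-overlapping (serial) stimuli plus an emergent *configural cue* that is
unique to that combination (and, for serial compounds, to the order of
presentation).  The cue is an ordinary stimulus: it has its own CSC
components, eligibility traces and weights, and competes for associative
strength like any other cue.

Presence logic
--------------
* A simultaneous configuration is present at ``t`` iff every constituent has
  an active component at ``t`` and no other (policy-eligible) stimulus does:
  the product-of-sums term minus ``min(1, sum of other presences)``.
* A serial configuration is present iff its final constituent is active,
  every earlier constituent is represented by a present memory trace (the
  component is off but its eligibility exceeds the trace-presence
  threshold), the constituents' onsets occurred in the declared order, and
  no other eligible stimulus is active or trace-present.  Configurations are
  never formed from traces alone, and the context never participates in
  formation (though its strength contributes to the aggregate prediction).

Component bookkeeping follows the CSC recursion: the first configuration
component starts on the step where presence transitions 0 -> 1, and
component ``n`` is present at ``t`` only if component ``n-1`` was present at
``t-1`` and the configuration is still present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Collection, Iterable, Mapping, Sequence


@dataclass(frozen=True)
class ConfigurationSpec:
    """Identity of a configuration: its constituents and configural cue.

    ``constituents`` is order-significant for serial configurations
    (``A -> B`` and ``B -> A`` are different configurations with distinct
    cues); for simultaneous configurations it is treated as a set.
    """

    kind: str  # "simultaneous" | "serial"
    constituents: tuple[str, ...]
    alpha_q: float | None = None  # learning rate of the cue; None = derive

    def __post_init__(self):
        if self.kind not in ("simultaneous", "serial"):
            raise ValueError(f"unknown configuration kind {self.kind!r}")
        if len(self.constituents) < 2:
            raise ValueError("a configuration needs at least 2 constituents")
        if len(set(self.constituents)) != len(self.constituents):
            raise ValueError("duplicate constituent in configuration")

    @property
    def cue_id(self) -> str:
        if self.kind == "simultaneous":
            return "q(" + "+".join(sorted(self.constituents)) + ")"
        return "q(" + ">".join(self.constituents) + ")"


def simultaneous_presence(
    active: Mapping[str, int],
    constituents: Iterable[str],
    exclude: Collection[str] = (),
) -> int:
    """Presence of a simultaneous configuration at one timestep.

    Parameters
    ----------
    active:
        Map of stimulus -> active component index at this timestep (only
        stimuli with an active component appear).
    constituents:
        The configuration's primitive constituents.
    exclude:
        Stimuli ignored by the exclusivity clause (the context by default
        policy, plus configural cues), i.e. their presence neither helps nor
        blocks the configuration.
    """
    cons = set(constituents)
    if not all(s in active for s in cons):
        return 0
    others = sum(1 for s in active if s not in cons and s not in exclude)
    return 1 if min(1, others) == 0 else 0


def serial_presence(
    active: Mapping[str, int],
    traced: Collection[str],
    order: Sequence[str],
    last_onset: Mapping[str, int],
    exclude: Collection[str] = (),
) -> int:
    """Presence of a serial configuration at one timestep.

    ``traced`` holds the stimuli whose components are all off but whose
    eligibility trace is above the presence threshold.  ``last_onset`` maps
    each stimulus to the step of its most recent onset and is used to verify
    that the constituents occurred in the declared order.
    """
    *earlier, final = order
    if final not in active:
        return 0  # never formed by traces only; the last element must be live
    for s in earlier:
        if s in active or s not in traced:
            return 0
    onsets = [last_onset.get(s) for s in order]
    if any(o is None for o in onsets):
        return 0
    if any(a >= b for a, b in zip(onsets, onsets[1:])):
        return 0  # order violated
    cons = set(order)
    for s in active:
        if s not in cons and s not in exclude:
            return 0  # a larger configuration forms instead
    for s in traced:
        if s not in cons and s not in exclude:
            return 0
    return 1


class ComponentSequencer:
    """CSC component recursion for a configuration's presence track.

    ``advance(present)`` must be called exactly once per timestep; it
    returns the active component index (0-based) or ``None`` when the
    configuration is absent.  Presence restarts the chain at component 0
    after any gap.
    """

    def __init__(self):
        self._comp: int | None = None

    def advance(self, present: bool) -> int | None:
        if not present:
            self._comp = None
        elif self._comp is None:
            self._comp = 0
        else:
            self._comp += 1
        return self._comp

    def reset(self) -> None:
        self._comp = None


def component_sequence(presence: Sequence[int]) -> list[int | None]:
    """Component indices for a whole presence track (convenience/oracle)."""
    seq = ComponentSequencer()
    return [seq.advance(bool(p)) for p in presence]


# ---------------------------------------------------------------------------
# configuration strength (summed constituent strength, with within-trial hold)
# ---------------------------------------------------------------------------

class ConfigurationStrength:
    """Summed strength of a configuration with the within-trial hold clause.

    While the configuration is present its strength is exactly the sum of
    the active components' weights over constituents-plus-cue (for serial
    configurations, the traced constituents contribute the weight of their
    most recently active component, and the context's active component is
    added even though it cannot trigger formation).  When presence ceases
    within a trial the last value is held; the hold resets at trial end.
    """

    def __init__(self):
        self._held = 0.0

    def update(self, present: bool, summed: float) -> float:
        if present:
            self._held = summed
            return summed
        return self._held

    def reset(self) -> None:
        self._held = 0.0


def simultaneous_configuration_strength(
    weight_of, constituent_comps: Mapping[str, int], cue: tuple[str, int] | None
) -> float:
    """Strength of a present simultaneous configuration: the sum of its
    constituents' active-component weights plus the configural cue's.

    ``weight_of(entity, comp)`` supplies component weights (e.g.
    :meth:`cctd.core.ComponentStore.weight`).
    """
    total = sum(weight_of(s, c) for s, c in constituent_comps.items())
    if cue is not None:
        total += weight_of(*cue)
    return total


def serial_configuration_strength(
    weight_of,
    active_comps: Mapping[str, int],
    traced_comps: Mapping[str, int],
    cue: tuple[str, int] | None,
    context_comp: tuple[str, int] | None = None,
) -> float:
    """Strength of a present serial configuration.

    Sums (a) the active components of the currently present constituents,
    (b) the most recently active component of each traced constituent,
    (c) the serial cue, and (d) the context's active component — the context
    contributes value even though it cannot trigger formation.
    """
    total = sum(weight_of(s, c) for s, c in active_comps.items())
    total += sum(weight_of(s, c) for s, c in traced_comps.items())
    if cue is not None:
        total += weight_of(*cue)
    if context_comp is not None:
        total += weight_of(*context_comp)
    return total


# ---------------------------------------------------------------------------
# context stimulus
# ---------------------------------------------------------------------------

def context_duration(offsets: Iterable[int]) -> int:
    """Repetition period of the context: span from step 0 to the latest
    stimulus/US offset within the trial (offsets are exclusive ends)."""
    d = max(offsets, default=0)
    if d < 1:
        raise ValueError("context duration must be at least 1 timestep")
    return d


def context_component(t_in_trial: int, d: int) -> int:
    """Active context component at trial-relative step ``t`` (repeats mod d,
    throughout the trial and the following inter-trial interval)."""
    return t_in_trial % d


def trace_present(steps_since_active: int | None, decay: float, threshold: float) -> bool:
    """Stimulus-level trace presence.

    After a stimulus's last active step its strongest component trace equals
    ``decay**k`` after ``k`` further steps (it was capped at 1 while
    active), so presence reduces to a step-count comparison.
    """
    if steps_since_active is None or steps_since_active < 0:
        return False
    return decay**steps_since_active > threshold


def simultaneous_cue_alpha(alphas: Sequence[float]) -> float:
    """Learning rate of a simultaneous configural cue: the product of the
    two largest constituent learning rates."""
    if len(alphas) < 2:
        raise ValueError("need at least two constituents")
    top = sorted(alphas, reverse=True)[:2]
    return top[0] * top[1]


def serial_cue_alpha(
    alphas: Sequence[float],
    n_unique_css: int,
    n_sharing_configs: int,
) -> float:
    """Learning rate of a serial configural cue.

    The simultaneous product rule adjusted for memory interference by the
    factor ``u / s`` where ``u`` is the number of CSs unique to this
    configuration and ``s`` the number of configurations sharing at least
    one CS with it (both floored at 1).
    """
    u = max(1, n_unique_css)
    s = max(1, n_sharing_configs)
    return min(1.0, simultaneous_cue_alpha(alphas) * u / s)
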