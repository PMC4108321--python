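"""Global learning constants of the configural-cue TD model.

All temporal quantities are expressed in timesteps of ``timestep_s`` seconds.
The eligibility trace of a stimulus component decays by a factor ``rho*gamma``
on every step on which the component is inactive; ``gamma`` additionally
discounts the one-step-ahead prediction inside the TD error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class ModelParameters:
    """Learning constants shared by every stimulus in a simulation.

    Parameters
    ----------
    lambda_us:
        Asymptote of the US representation; the reinforcement signal takes
        this value on every US-active timestep and 0 elsewhere.
    rho:
        Eligibility-trace decay per timestep (activation memory).
    gamma:
        Discount factor per timestep. ``gamma=0`` reduces the model to a
        trial-level delta rule when stimuli last a single step.
    beta_plus, beta_minus:
        US-dependent learning rates, applied on US-present and US-absent
        timesteps respectively.
    timestep_s:
        Real-time length of one timestep, in seconds.
    rpm_cap:
        Maximum simulated response rate (responses per minute); also the
        number of threshold draws used by the response decision rule.
    decision_B:
        Upper bound of the uniform response threshold ``b ~ U(0, B)``.
    trace_presence_threshold:
        Eligibility level above which an inactive stimulus still counts as
        "present in memory" for serial-configuration formation.
    """

    lambda_us: float = 1.0
    rho: float = 0.97
    gamma: float = 0.97
    beta_plus: float = 0.5
    beta_minus: float = 0.495
    timestep_s: float = 1.0
    rpm_cap: float = 100.0
    decision_B: float = 0.985
    trace_presence_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.rho <= 1.0):
            raise ValueError(f"rho must be in (0, 1], got {self.rho}")
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError(f"gamma must be in [0, 1), got {self.gamma}")
        if self.rho * self.gamma >= 1.0:
            raise ValueError("rho * gamma must be < 1")
        for name in ("beta_plus", "beta_minus", "decision_B"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.timestep_s <= 0:
            raise ValueError("timestep_s must be positive")
        if self.rpm_cap <= 0:
            raise ValueError("rpm_cap must be positive")
        if not (0.0 < self.trace_presence_threshold < 1.0):
            raise ValueError("trace_presence_threshold must be in (0, 1)")

    @property
    def trace_decay(self) -> float:
        """Per-step decay factor of an inactive component's trace."""
        return self.rho * self.gamma

    def replace(self, **kwargs) -> "ModelParameters":
        d = asdict(self)
        d.update(kwargs)
        return ModelParameters(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        return cls(**d)
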