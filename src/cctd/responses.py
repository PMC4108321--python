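"""From associative strength to simulated behaviour.

The response decision rule draws, for every minute of a readout window,
``rpm_cap`` independent thresholds ``b ~ Uniform(0, B)`` and counts how
often the (clamped) strength exceeds them, so the simulated rate is capped
at ``rpm_cap`` responses per minute and proportional to strength in
expectation: ``E[rpm] = rpm_cap * min(1, s / B)``.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParameters


def _window_means(strengths: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Mean clamped strength per (possibly partial) minute of the window."""
    s = np.clip(np.asarray(strengths, dtype=float), 0.0, None)
    if s.size == 0:
        raise ValueError("empty readout window")
    per_min = max(1, int(round(60.0 / params.timestep_s)))
    n_chunks = int(np.ceil(s.size / per_min))
    return np.array([s[i * per_min:(i + 1) * per_min].mean() for i in range(n_chunks)])


def decide_responses(
    strengths: np.ndarray, params: ModelParameters, rng: np.random.Generator
) -> float:
    """Simulated responses per minute for one readout window (stochastic)."""
    n_iter = int(round(params.rpm_cap))
    counts = []
    for s_bar in _window_means(strengths, params):
        b = rng.uniform(0.0, params.decision_B, n_iter)
        counts.append(float(np.sum(s_bar > b)))
    return float(np.mean(counts))


def expected_rate(strengths: np.ndarray, params: ModelParameters) -> float:
    """Expectation of the decision rule: ``cap * min(1, s_bar / B)``."""
    rates = [
        params.rpm_cap * min(1.0, s_bar / params.decision_B)
        for s_bar in _window_means(strengths, params)
    ]
    return float(np.mean(rates))


def elevation_score(cs_rate: float, pre_cs_rate: float) -> float:
    """CS-period rate minus the immediately preceding preCS-period rate."""
    return cs_rate - pre_cs_rate


def suppression_ratio(cr_rpm: float, params: ModelParameters) -> float:
    """Conditioned-suppression ratio built on the simulated rate ceiling.

    ``SR = (cap - CR) / ((cap - CR) + cap)``: 0.5 means no conditioning
    (no suppression of the baseline), 0 means maximal conditioning.
    """
    cap = params.rpm_cap
    if not (0.0 <= cr_rpm <= cap):
        raise ValueError(f"conditioned response rate {cr_rpm} outside [0, {cap}]")
    return (cap - cr_rpm) / ((cap - cr_rpm) + cap)


def smooth_running_mean(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered running mean; edges are truncated to the available points."""
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise ValueError("series must have length >= 1")
    if window < 1:
        raise ValueError("window must be >= 1")
    half = (window - 1) // 2
    out = np.empty_like(s)
    for i in range(s.size):
        lo = max(0, i - half)
        hi = min(s.size, i + window - half)
        out[i] = s[lo:hi].mean()
    return out
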