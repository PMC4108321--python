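"""Component-level real-time TD learning kernels.

Every stimulus (nominal cue, common element, context, configural cue) is
represented as a complete serial compound (CSC): a chain of one-timestep
components, each carrying its own associative weight ``V`` and eligibility
trace ``e``.  The :class:`ComponentStore` keeps all components of all
stimuli in flat numpy arrays so the per-step update is a handful of
vectorised operations regardless of how many entities exist.

Update order within a timestep (fixed, see :mod:`cctd.engine`):

1. presence is advanced and configurations are formed;
2. the aggregate prediction ``Y(t) = sum_ij V_ij x_ij(t)`` is computed;
3. the TD error ``delta(t) = us(t) + gamma*max(0, Y(t)) - max(0, Y(t-1))``
   is formed;
4. weights are updated, ``V_ij += beta * alpha_i * delta * e_ij``, using the
   traces as they stood at the end of step ``t-1``;
5. traces are updated, ``e(t) = min(1, rho*gamma*e(t-1) + x(t))`` (a
   replacing trace: accumulating but bounded at 1).
"""

from __future__ import annotations

import numpy as np

from .params import ModelParameters

#: traces below this value are flushed to exactly zero (keeps the decayed
#: tail out of denormal-float territory; far below any behavioural effect)
TRACE_FLOOR = 1e-12


def td_error(y_now: float, y_prev: float, us_level: float, params: ModelParameters) -> float:
    """Temporal-difference error for one timestep.

    Negative aggregate predictions are clamped to zero inside the error
    (the raw signed weights are retained elsewhere for inhibition tests).
    """
    return us_level + params.gamma * max(0.0, y_now) - max(0.0, y_prev)


class ComponentStore:
    """Flat weight/trace storage for every (entity, component) pair.

    Entities are registered by name with a per-entity learning rate
    ``alpha``; components are allocated lazily the first time they become
    active.  ``V``, ``E`` and ``A`` (the per-component alpha) share a common
    index space.
    """

    def __init__(self, initial_capacity: int = 256):
        self._cap = int(initial_capacity)
        self.n = 0
        self.V = np.zeros(self._cap)
        self.E = np.zeros(self._cap)
        self.A = np.zeros(self._cap)
        self._index: dict[tuple[str, int], int] = {}
        self._alpha: dict[str, float] = {}

    # -- registry -----------------------------------------------------------
    def register_entity(self, name: str, alpha: float) -> None:
        if name in self._alpha:
            if self._alpha[name] != alpha:
                raise ValueError(f"entity {name!r} re-registered with a different alpha")
            return
        if not (0.0 < alpha <= 1.0):
            raise ValueError(f"alpha for {name!r} must be in (0, 1], got {alpha}")
        self._alpha[name] = alpha

    @property
    def entities(self) -> list[str]:
        return list(self._alpha)

    def alpha_of(self, name: str) -> float:
        return self._alpha[name]

    def _grow(self) -> None:
        self._cap *= 2
        for attr in ("V", "E", "A"):
            arr = getattr(self, attr)
            new = np.zeros(self._cap)
            new[: self.n] = arr[: self.n]
            setattr(self, attr, new)

    def idx(self, entity: str, comp: int) -> int:
        """Flat index of a component, allocating it on first use."""
        key = (entity, comp)
        i = self._index.get(key)
        if i is None:
            if entity not in self._alpha:
                raise KeyError(f"unknown entity {entity!r}; register it with an alpha first")
            if self.n == self._cap:
                self._grow()
            i = self.n
            self.n += 1
            self._index[key] = i
            self.A[i] = self._alpha[entity]
        return i

    # -- TD kernels ---------------------------------------------------------
    def prediction(self, active: list[int]) -> float:
        """Aggregate prediction ``Y(t)``: summed V of all active components."""
        V = self.V
        return float(sum(V[i] for i in active))

    def update_weights(self, delta: float, us_active: bool, params: ModelParameters) -> None:
        """Apply the delta rule to every component, gated by its trace."""
        if delta == 0.0:
            return
        beta = params.beta_plus if us_active else params.beta_minus
        n = self.n
        # V += beta * delta * alpha * e   (componentwise)
        self.V[:n] += (beta * delta) * (self.A[:n] * self.E[:n])

    def update_traces(self, active: list[int], params: ModelParameters) -> None:
        """Decay-then-add replacing trace, capped at 1."""
        n = self.n
        E = self.E
        E[:n] *= params.trace_decay
        E[:n][E[:n] < TRACE_FLOOR] = 0.0
        for i in active:
            e = E[i] + 1.0
            E[i] = 1.0 if e > 1.0 else e

    # -- inspection ---------------------------------------------------------
    def weight(self, entity: str, comp: int) -> float:
        i = self._index.get((entity, comp))
        return 0.0 if i is None else float(self.V[i])

    def trace(self, entity: str, comp: int) -> float:
        i = self._index.get((entity, comp))
        return 0.0 if i is None else float(self.E[i])

    def weights_of(self, entity: str) -> np.ndarray:
        """Weight vector of one entity, indexed by component."""
        comps = [c for (e, c) in self._index if e == entity]
        if not comps:
            return np.zeros(0)
        out = np.zeros(max(comps) + 1)
        for c in comps:
            out[c] = self.V[self._index[(entity, c)]]
        return out

    def weight_table(self) -> dict[str, np.ndarray]:
        return {e: self.weights_of(e) for e in self._alpha}
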