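"""State space and parameter layout for the five-state health/work process.

Living states follow the conventional coding:

    1  healthy and working
    2  healthy and not working
    3  not healthy and working
    4  not healthy and not working

plus an absorbing dead state.  Two sentinel codes mark incomplete panel
observations: ``-1`` (interviewed, alive, but health/work state unknown) and
``-2`` (wave not participated in; vital status unknown at that time).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

HEALTHY_WORKING = 1
HEALTHY_NOT_WORKING = 2
UNHEALTHY_WORKING = 3
UNHEALTHY_NOT_WORKING = 4
DEAD = 5
UNKNOWN_STATE = -1
UNKNOWN_VITAL = -2

LIVING_STATES = (1, 2, 3, 4)

STATE_LABELS = {
    1: "healthy, working",
    2: "healthy, not working",
    3: "not healthy, working",
    4: "not healthy, not working",
    DEAD: "dead",
}


@dataclass(frozen=True)
class TransitionStructure:
    """Permitted-transition graph over the living states plus the dead state.

    The default structure permits every ordered pair of distinct living states
    (12 logits) and death from each living state (4 logits): 16 modelled
    transitions.  The self-transition of each living row is the multinomial
    reference category; the dead row is absorbing.
    """

    living_states: tuple[int, ...] = LIVING_STATES
    permitted: tuple[tuple[int, int], ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.permitted is None:
            pairs = [
                (i, j)
                for i in self.living_states
                for j in self.living_states
                if i != j
            ]
            pairs += [(i, DEAD) for i in self.living_states]
            object.__setattr__(self, "permitted", tuple(pairs))
        for i, j in self.permitted:
            if i == DEAD:
                raise ValueError("no transitions out of the dead state")
            if i == j:
                raise ValueError("self-transitions are the reference category, not modelled")
            if i not in self.living_states:
                raise ValueError(f"unknown origin state {i}")
            if j != DEAD and j not in self.living_states:
                raise ValueError(f"unknown destination state {j}")

    @property
    def n_living(self) -> int:
        return len(self.living_states)

    @property
    def n_states(self) -> int:
        """Living states plus the absorbing dead state."""
        return self.n_living + 1

    @property
    def n_transitions(self) -> int:
        return len(self.permitted)

    def state_index(self, state: int) -> int:
        """Matrix row/column index of a state (dead occupies the last index)."""
        if state == DEAD:
            return self.n_living
        return self.living_states.index(state)

    def transition_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) matrix indices of each permitted transition, in layout order."""
        rows = np.array([self.state_index(i) for i, _ in self.permitted], dtype=int)
        cols = np.array([self.state_index(j) for _, j in self.permitted], dtype=int)
        return rows, cols


@dataclass
class ParameterVector:
    """Coefficients of the multinomial-logit step-transition model.

    For each permitted transition (i, j) the log-odds relative to staying in
    state i over one interpolation step are

        eta_ij = intercept_ij + age_slope_ij * (age - reference_age)
                 + sum_c covariate_effects[c]_ij * x_c

    ``reference_age`` only shifts where the intercept is read (the model is
    identical for any choice); intercepts on the raw-age scale are
    ``intercept - reference_age * age_slope``.

    Flat-array layout (used by the optimizer and the serialized form):
    all intercepts in ``structure.permitted`` order, then all age slopes,
    then each covariate's effects in ``covariate_names`` order.
    """

    structure: TransitionStructure
    intercept: np.ndarray
    age_slope: np.ndarray
    covariate_effects: dict[str, np.ndarray] = field(default_factory=dict)
    reference_age: float = 50.0

    def __post_init__(self):
        n = self.structure.n_transitions
        self.intercept = np.asarray(self.intercept, dtype=float)
        self.age_slope = np.asarray(self.age_slope, dtype=float)
        if self.intercept.shape != (n,) or self.age_slope.shape != (n,):
            raise ValueError(f"intercept/age_slope must have shape ({n},)")
        self.covariate_effects = {
            k: np.asarray(v, dtype=float) for k, v in self.covariate_effects.items()
        }
        for k, v in self.covariate_effects.items():
            if v.shape != (n,):
                raise ValueError(f"covariate effect {k!r} must have shape ({n},)")
        for arr in (self.intercept, self.age_slope, *self.covariate_effects.values()):
            if not np.all(np.isfinite(arr)):
                raise ValueError("parameters must be finite")

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariate_effects)

    def to_array(self) -> np.ndarray:
        parts = [self.intercept, self.age_slope]
        parts += [self.covariate_effects[k] for k in self.covariate_names]
        return np.concatenate(parts)

    @classmethod
    def from_array(
        cls,
        arr: np.ndarray,
        structure: TransitionStructure,
        covariate_names: list[str] | None = None,
        reference_age: float = 50.0,
    ) -> "ParameterVector":
        covariate_names = covariate_names or []
        n = structure.n_transitions
        arr = np.asarray(arr, dtype=float)
        expected = n * (2 + len(covariate_names))
        if arr.shape != (expected,):
            raise ValueError(f"expected flat array of length {expected}, got {arr.shape}")
        cov = {
            name: arr[(2 + c) * n : (3 + c) * n]
            for c, name in enumerate(covariate_names)
        }
        return cls(
            structure=structure,
            intercept=arr[:n].copy(),
            age_slope=arr[n : 2 * n].copy(),
            covariate_effects=cov,
            reference_age=reference_age,
        )

    def copy(self) -> "ParameterVector":
        return ParameterVector.from_array(
            self.to_array(), self.structure, self.covariate_names, self.reference_age
        )
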