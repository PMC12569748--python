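"""State-space specifications for the two chronic GvHD multistate models.

Both models describe the course of a patient after stem cell transplantation,
with chronic graft-versus-host disease (cGvHD) as a recurrent complication and
death/relapse as the absorbing endpoint.

``PROG6`` is the progressive six-state model: state 0 is "alive, in remission,
never had cGvHD", states 1 and 3 are the first and second cGvHD episodes,
states 2 and 4 are "recovered from the first/second episode", and state 5 is
death or relapse.  The chain is strictly progressive, so each patient visits
every transient state at most once.

``IDM3`` is the illness-death model with recovery: state 0 is "alive without
current cGvHD", state 1 "alive with cGvHD" (any episode), state 2 death or
relapse.  Back-transitions 1 -> 0 make cGvHD a genuinely recurrent event.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ModelSpec:
    """A finite state space with a set of allowed direct transitions.

    Parameters
    ----------
    name :
        Short label, e.g. ``"prog6"``.
    n_states :
        Number of states; states are the integers ``0 .. n_states - 1``.
    transitions :
        Allowed ordered state pairs ``(g, h)``, ``g != h``.
    absorbing :
        States with no outgoing transitions.
    initial_state :
        Common starting state of every individual (default 0).
    """

    name: str
    n_states: int
    transitions: frozenset[tuple[int, int]]
    absorbing: frozenset[int] = field(default_factory=frozenset)
    initial_state: int = 0

    def __post_init__(self) -> None:
        states = self.states
        for g, h in self.transitions:
            if g not in states or h not in states:
                raise ValueError(f"transition {g}->{h} outside state space")
            if g == h:
                raise ValueError(f"self-loop {g}->{g} not allowed")
            if g in self.absorbing:
                raise ValueError(f"transition {g}->{h} leaves absorbing state")
        if self.initial_state not in states:
            raise ValueError("initial state outside state space")

    @property
    def states(self) -> frozenset[int]:
        return frozenset(range(self.n_states))

    def allows(self, g: int, h: int) -> bool:
        return (g, h) in self.transitions


PROG6 = ModelSpec(
    name="prog6",
    n_states=6,
    transitions=frozenset(
        [(0, 1), (1, 2), (2, 3), (3, 4), (0, 5), (1, 5), (2, 5), (3, 5), (4, 5)]
    ),
    absorbing=frozenset([5]),
)

IDM3 = ModelSpec(
    name="idm3",
    n_states=3,
    transitions=frozenset([(0, 1), (1, 0), (0, 2), (1, 2)]),
    absorbing=frozenset([2]),
)

#: prog6 state -> idm3 state: {0,2,4} are "alive without current cGvHD",
#: {1,3} "alive with cGvHD", 5 death/relapse.
PROG6_TO_IDM3 = (0, 1, 0, 1, 0, 2)

MODELS = {"prog6": PROG6, "idm3": IDM3}


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; expected one of {sorted(MODELS)}"
        ) from None
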