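"""Nonparametric estimators of chronic GvHD- and relapse-free survival.

Three estimators are provided for CGRFS, the probability of being alive, in
remission and free of chronic GvHD at time t:

* the linear combination of five Kaplan-Meier estimators in the progressive
  six-state model, ``CGRFS^ = S^1 + S^2 - S^3 + S^4 - S^5``, which is free of
  any Markov assumption but may leave the unit interval;
* the Aalen-Johansen estimator in the progressive six-state model,
  ``P^00 + P^02 + P^04``;
* the Aalen-Johansen estimator in the illness-death model with recovery,
  ``P^00``.

Both Aalen-Johansen variants are product integrals of the Nelson-Aalen
cumulative transition-rate matrix and are consistent for state occupation
probabilities under random censoring even when the process is non-Markov.

The estimators are exposed as scikit-learn style classes
(:class:`KaplanMeierCombination`, :class:`AalenJohansenCGRFS`) with thin
functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .counting import CountingSystem, build_counting
from .data import MultistateDataset, map_prog6_to_idm3
from .model import ModelSpec, get_model
from .stepfun import MatrixStepFunction, StepFunction

#: signs of the five Kaplan-Meier components in the CGRFS combination
KM_SIGNS = (1.0, 1.0, -1.0, 1.0, -1.0)

#: states whose occupation probabilities sum to CGRFS, per model
CGRFS_STATES = {"prog6": (0, 2, 4), "idm3": (0,)}


# -- Nelson-Aalen and Aalen-Johansen ----------------------------------------


def _na_increments(counting: CountingSystem) -> np.ndarray:
    """Nelson-Aalen increments dA^(t) on the event grid, shape (m, K, K).

    Off-diagonal increment at grid time t is dN_gh(t) / Y_g(t-) when
    Y_g(t-) > 0 (else 0); diagonals make row sums zero.
    """
    m, k = len(counting.times), counting.n_states
    da = np.zeros((m, k, k))
    yv = counting.Y[counting.jump_from, counting.jump_time_idx].astype(np.float64)
    w = np.where(yv > 0, 1.0 / np.maximum(yv, 1.0), 0.0)
    np.add.at(da, (counting.jump_time_idx, counting.jump_from, counting.jump_to), w)
    diag = np.arange(k)
    da[:, diag, diag] -= da.sum(axis=2)
    return da


def nelson_aalen(counting: CountingSystem) -> MatrixStepFunction:
    """Nelson-Aalen estimator of the cumulative transition-rate matrix."""
    da = _na_increments(counting)
    return MatrixStepFunction(counting.times, np.cumsum(da, axis=0))


def aalen_johansen(cumhaz: MatrixStepFunction) -> MatrixStepFunction:
    """Aalen-Johansen transition-probability matrix ``P^(0, t)``.

    The product integral over the jumps of the cumulative hazard:
    ``P^(0,t) = prod_{s<=t} (I + dA^(s))``; rows sum to one.
    """
    inc = cumhaz.increments
    k = cumhaz.n_states
    off = inc.copy()
    diag = np.arange(k)
    off[:, diag, diag] = 0.0
    if np.any(off > 1.0 + 1e-9):
        raise ValueError("cumulative-hazard increment above one")
    eye = np.eye(k)
    p = eye.copy()
    out = np.empty_like(inc)
    for i in range(len(inc)):
        p = p @ (eye + inc[i])
        out[i] = p
    return MatrixStepFunction(cumhaz.x, out, v0=eye)


def _aj_row0(da: np.ndarray) -> np.ndarray:
    """Initial-state row of the product integral, shape (m, K)."""
    m, k = da.shape[0], da.shape[1]
    p = np.zeros(k)
    p[0] = 1.0
    out = np.empty((m, k))
    for i in range(m):
        p = p + p @ da[i]
        out[i] = p
    return out


# -- Kaplan-Meier components -------------------------------------------------


@dataclass(frozen=True)
class KMComponentSpec:
    """Risk-state set, composite event transitions and bilinear weights of one
    Kaplan-Meier component.

    The row weight ``u_j(t)`` puts mass ``Y_g(t-) / sum_{g' in R_j} Y_g'(t-)``
    on each risk state; ``v_j`` is the 0/1 indicator of the event target
    states.  Because all excluded hazards vanish identically in the
    progressive six-state model, ``f_j(A^)(t) = u_j(t)^T A^(t) v_j(t)``
    reproduces the component's cumulative hazard.
    """

    index: int
    risk_states: tuple[int, ...]
    event_transitions: tuple[tuple[int, int], ...]

    @property
    def target_states(self) -> tuple[int, ...]:
        return tuple(sorted({h for _, h in self.event_transitions}))

    def u(self, counting: CountingSystem) -> np.ndarray:
        """Row-weight vectors on the event grid, shape (m, K)."""
        m, k = len(counting.times), counting.n_states
        u = np.zeros((m, k))
        yr = counting.Y[list(self.risk_states)].sum(axis=0).astype(np.float64)
        pos = yr > 0
        for g in self.risk_states:
            u[pos, g] = counting.Y[g, pos] / yr[pos]
        return u

    def v(self, n_states: int) -> np.ndarray:
        v = np.zeros(n_states)
        v[list(self.target_states)] = 1.0
        return v


#: the five components of the CGRFS combination, in combination order.
#: S1: first cGvHD onset or prior death/relapse; S2: second onset or prior
#: death/relapse; S3: recovery from the first episode or prior death/relapse;
#: S4: relapse-free survival; S5: recovery from the second episode or prior
#: death/relapse.
KM_COMPONENTS = (
    KMComponentSpec(1, (0,), ((0, 1), (0, 5))),
    KMComponentSpec(2, (0, 1, 2), ((2, 3), (0, 5), (1, 5), (2, 5))),
    KMComponentSpec(3, (0, 1), ((1, 2), (0, 5), (1, 5))),
    KMComponentSpec(4, (0, 1, 2, 3, 4), ((0, 5), (1, 5), (2, 5), (3, 5), (4, 5))),
    KMComponentSpec(5, (0, 1, 2, 3), ((3, 4), (0, 5), (1, 5), (2, 5), (3, 5))),
)


def _km_curves(counting: CountingSystem) -> np.ndarray:
    """All five Kaplan-Meier component curves on the event grid, shape (5, m)."""
    m, k = len(counting.times), counting.n_states
    out = np.empty((5, m))
    for j, spec in enumerate(KM_COMPONENTS):
        lut = np.zeros((k, k), dtype=bool)
        for g, h in spec.event_transitions:
            lut[g, h] = True
        ev = lut[counting.jump_from, counting.jump_to]
        d = np.bincount(counting.jump_time_idx[ev], minlength=m).astype(np.float64)
        yr = counting.Y[list(spec.risk_states)].sum(axis=0).astype(np.float64)
        factors = np.where(yr > 0, 1.0 - d / np.maximum(yr, 1.0), 1.0)
        out[j] = np.cumprod(factors)
    return out


def km_component(counting: CountingSystem, spec: KMComponentSpec) -> StepFunction:
    """Kaplan-Meier estimator over the composite event process of ``spec``.

    At each event time the curve is multiplied by ``1 - d_j(t) / Y_Rj(t-)``
    where ``d_j`` aggregates all event transitions of the component and
    ``Y_Rj`` sums the at-risk left limits over its risk states; when the risk
    set is empty the factor is one.  Individuals leaving the risk set other
    than through an event transition drop out without contributing an event.
    """
    return StepFunction(counting.times, _km_curves(counting)[spec.index - 1])


# -- scikit-learn style estimators -------------------------------------------


def _as_dataset(X, model: ModelSpec) -> MultistateDataset:
    if isinstance(X, MultistateDataset):
        return X
    if isinstance(X, pd.DataFrame):
        return MultistateDataset(model, X)
    raise TypeError("X must be a MultistateDataset or a long-format DataFrame")


class KaplanMeierCombination(BaseEstimator):
    """CGRFS via the signed combination of five Kaplan-Meier estimators.

    ``CGRFS^(t) = S^1(t) + S^2(t) - S^3(t) + S^4(t) - S^5(t)`` in the
    progressive six-state model.  The combination is Markov-free but can
    leave [0, 1]; set ``clip=True`` to truncate the reported curve to the
    unit interval (the raw curve stays available as
    ``survival_function_raw_``).

    Attributes (after ``fit``)
    --------------------------
    n_ : number of individuals.
    counting_ : the fitted :class:`~cgrfs.counting.CountingSystem`.
    components_ : the five component :class:`~cgrfs.stepfun.StepFunction` s.
    survival_function_raw_ : the unclipped combination.
    survival_function_ : the reported curve (clipped iff ``clip=True``).
    """

    def __init__(self, clip: bool = False):
        self.clip = clip

    def fit(self, X, y=None):
        from .model import PROG6

        ds = _as_dataset(X, PROG6)
        if ds.model.name != "prog6":
            raise ValueError("the Kaplan-Meier combination requires prog6 data")
        counting = build_counting(ds)
        curves = _km_curves(counting)
        raw = np.asarray(KM_SIGNS) @ curves
        self.n_ = counting.n
        self.counting_ = counting
        self.components_ = [
            StepFunction(counting.times, curves[j]) for j in range(5)
        ]
        self.survival_function_raw_ = StepFunction(counting.times, raw)
        self.survival_function_ = (
            self.survival_function_raw_.clip() if self.clip
            else self.survival_function_raw_
        )
        return self

    def predict(self, times):
        """Evaluate the fitted CGRFS curve at ``times``."""
        return self.survival_function_(times)


class AalenJohansenCGRFS(BaseEstimator):
    """CGRFS via the Aalen-Johansen estimator.

    In the progressive six-state model CGRFS is ``P^00 + P^02 + P^04``; in
    the illness-death model with recovery it is the occupation probability
    ``P^00`` of the healthy state.  With ``model="idm3"`` a prog6 dataset is
    collapsed onto the illness-death model first.

    Attributes (after ``fit``)
    --------------------------
    n_ : number of individuals.
    counting_ : fitted counting system (in the requested model).
    cumulative_hazard_ : Nelson-Aalen :class:`~cgrfs.stepfun.MatrixStepFunction`.
    transition_probabilities_ : Aalen-Johansen matrix ``P^(0, .)``.
    survival_function_ : the CGRFS curve (always within [0, 1]).
    """

    def __init__(self, model: str = "prog6"):
        self.model = model

    def fit(self, X, y=None):
        spec = get_model(self.model)
        ds = _as_dataset(X, spec)
        if ds.model.name != spec.name:
            if spec.name == "idm3" and ds.model.name == "prog6":
                ds = map_prog6_to_idm3(ds)
            else:
                raise ValueError(
                    f"dataset is under {ds.model.name!r}, estimator expects "
                    f"{spec.name!r}"
                )
        counting = build_counting(ds)
        cumhaz = nelson_aalen(counting)
        probs = aalen_johansen(cumhaz)
        targets = list(CGRFS_STATES[spec.name])
        values = probs.values[:, 0, targets].sum(axis=1)
        self.n_ = counting.n
        self.counting_ = counting
        self.cumulative_hazard_ = cumhaz
        self.transition_probabilities_ = probs
        self.survival_function_ = StepFunction(counting.times, values)
        return self

    def predict(self, times):
        """Evaluate the fitted CGRFS curve at ``times``."""
        return self.survival_function_(times)


# -- functional wrappers ------------------------------------------------------


def cgrfs_km(dataset: MultistateDataset, clip: bool = False) -> StepFunction:
    """CGRFS by the five-Kaplan-Meier combination (unclipped by default)."""
    return KaplanMeierCombination(clip=clip).fit(dataset).survival_function_


def cgrfs_aje(dataset: MultistateDataset, model: ModelSpec | str | None = None) -> StepFunction:
    """CGRFS by the Aalen-Johansen estimator under the named model."""
    if model is None:
        name = dataset.model.name
    else:
        name = model if isinstance(model, str) else model.name
    if name not in CGRFS_STATES:
        raise ValueError(f"unsupported model {name!r}")
    return AalenJohansenCGRFS(model=name).fit(dataset).survival_function_


def clip_unit(f: StepFunction) -> StepFunction:
    """Pointwise truncation of a curve to the unit interval (idempotent)."""
    return f.clip(0.0, 1.0)
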