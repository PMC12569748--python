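"""Wild and Efron bootstrap for the CGRFS estimators.

The wild bootstrap keeps the data fixed and perturbs the counting-process
increments: every observed individual transition receives an independent
standard-normal multiplier ``G_i;gh``.  The multiplier process

    xi_gh(t) = sqrt(n) * sum_i int_0^t G_i;gh 1{Y_g > 0} dN_i;gh / Y_g

shares the limit distribution of ``sqrt(n) (A^ - A)`` and is pushed through
the functional (Hadamard) derivative of the estimator: for the Kaplan-Meier
combination each component contributes ``-S^j(t) int_0^t u_j^T dxi v_j`` with
the combination signs, and for the Aalen-Johansen estimator the derivative of
the product integral gives ``D(t) = sum_{s<=t} P^(0,s-) dxi(s) P^(s,t)``.

Efron's bootstrap instead redraws whole individuals with replacement and
re-estimates; its realizations are centered at the original estimate and
scaled by sqrt(n) so both methods live on the same scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counting import CountingSystem, RecordArrays, counting_from_records, record_arrays
from .data import MultistateDataset
from .estimators import (
    CGRFS_STATES,
    KM_COMPONENTS,
    KM_SIGNS,
    _aj_row0,
    _km_curves,
    _na_increments,
)
from .stepfun import MatrixStepFunction, StepFunction

ESTIMATORS = ("km_comb", "aje_prog6", "aje_idm3")
METHODS = ("wild", "efron")


# -- multipliers and the xi process ------------------------------------------


@dataclass
class WildMultipliers:
    """One standard-normal draw per observed individual transition.

    ``values`` is aligned with the counting system's time-ordered jump
    registry, so a recurrent transition of one individual (possible in the
    illness-death model with recovery) receives an independent draw per
    episode.
    """

    values: np.ndarray
    seed: int | None = None


def draw_multipliers(counting: CountingSystem, seed) -> WildMultipliers:
    """Draw independent N(0, 1) multipliers, one per individual jump."""
    rng = np.random.default_rng(seed)
    return WildMultipliers(
        values=rng.standard_normal(counting.n_jumps),
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def xi_process(counting: CountingSystem, multipliers: WildMultipliers) -> MatrixStepFunction:
    """The multiplier analogue of the Nelson-Aalen deviation process.

    Off-diagonal entries jump by ``sqrt(n) * G / Y_g(t-)`` at each individual
    g -> h transition; diagonals keep row sums at zero; ``xi(0) = 0``.
    """
    g = np.asarray(multipliers.values, dtype=np.float64)
    if g.shape != (counting.n_jumps,):
        raise ValueError("multipliers do not match the jump registry")
    m, k = len(counting.times), counting.n_states
    dxi = np.zeros((m, k, k))
    yv = counting.Y[counting.jump_from, counting.jump_time_idx].astype(np.float64)
    w = np.where(yv > 0, np.sqrt(counting.n) * g / np.maximum(yv, 1.0), 0.0)
    np.add.at(dxi, (counting.jump_time_idx, counting.jump_from, counting.jump_to), w)
    diag = np.arange(k)
    dxi[:, diag, diag] -= dxi.sum(axis=2)
    return MatrixStepFunction(counting.times, np.cumsum(dxi, axis=0))


# -- single wild realizations (reference implementations) --------------------


def wild_km_realization(
    counting: CountingSystem,
    components,
    xi: MatrixStepFunction,
    specs=KM_COMPONENTS,
) -> StepFunction:
    """One wild-bootstrap realization of the centered, sqrt(n)-scaled
    Kaplan-Meier combination.

    ``B^(t) = -S^1 I_1 - S^2 I_2 + S^3 I_3 - S^4 I_4 + S^5 I_5`` with
    ``I_j(t) = sum_{s<=t} u_j(s)^T dxi(s) v_j(s)`` and ``u_j`` evaluated at
    the at-risk left limits.

    Parameters
    ----------
    components :
        The five fitted component curves on the counting grid (e.g. from
        :class:`~cgrfs.estimators.KaplanMeierCombination`); pass ``None`` to
        recompute them.
    """
    if not np.array_equal(xi.x, counting.times):
        raise ValueError("xi was not built from this counting system")
    if components is None:
        curves = _km_curves(counting)
    else:
        curves = np.vstack([np.asarray(c.values) for c in components])
    dxi = xi.increments
    total = np.zeros(len(counting.times))
    for j, spec in enumerate(specs):
        u = spec.u(counting)
        v = spec.v(counting.n_states)
        di = np.einsum("mk,mkl,l->m", u, dxi, v)
        total += -KM_SIGNS[j] * curves[j] * np.cumsum(di)
    return StepFunction(counting.times, total, y0=0.0)


def wild_aje_realization(
    counting: CountingSystem,
    probs: MatrixStepFunction,
    xi: MatrixStepFunction,
    functional,
) -> StepFunction:
    """One wild-bootstrap realization of the centered, sqrt(n)-scaled
    Aalen-Johansen functional ``sum_{h in functional} P^0h(0, t)``.

    Uses the forward recursion
    ``D(t_k) = D(t_{k-1})(I + dA(t_k)) + P^(0, t_{k-1}) dxi(t_k)``,
    equivalent to ``D(t) = sum_{s<=t} P^(0,s-) dxi(s) P^(s,t)``.
    """
    functional = list(functional)
    k = counting.n_states
    if any(h < 0 or h >= k for h in functional):
        raise ValueError("functional states outside the state space")
    if not np.array_equal(xi.x, counting.times):
        raise ValueError("xi was not built from this counting system")
    da = _na_increments(counting)
    dxi = xi.increments
    eye = np.eye(k)
    p_prev = eye
    d = np.zeros((k, k))
    out = np.empty(len(counting.times))
    for i in range(len(counting.times)):
        d = d @ (eye + da[i]) + p_prev @ dxi[i]
        p_prev = probs.values[i]
        out[i] = d[0, functional].sum()
    return StepFunction(counting.times, out, y0=0.0)


# -- Efron resampling --------------------------------------------------------


def efron_resample(dataset: MultistateDataset, seed) -> MultistateDataset:
    """Draw n whole paths i.i.d. uniformly with replacement (fresh ids 0..n-1)."""
    rec = record_arrays(dataset)
    if rec.n == 0:
        raise ValueError("cannot resample an empty dataset")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, rec.n, rec.n)
    r2 = rec.resample(idx)
    frame = pd.DataFrame(
        {"id": r2.indiv, "from": r2.from_, "to": r2.to, "time": r2.time}
    )
    return MultistateDataset(dataset.model, frame, validate=False)


# -- vectorized ensembles -----------------------------------------------------


def _wild_km_realizations(counting: CountingSystem, curves: np.ndarray,
                          G: np.ndarray) -> np.ndarray:
    """All B wild realizations of the KM combination at once, shape (B, m).

    The realization is linear in the multipliers: a g -> h jump at time s
    contributes ``sqrt(n) * G / Y_Rj(s-)`` to ``I_j`` whenever (g, h) is an
    event transition of component j.
    """
    m = len(counting.times)
    B = G.shape[0]
    out = np.zeros((B, m))
    if m == 0:
        return out
    sqn = np.sqrt(counting.n)
    # last jump index (exclusive) at or before each grid point
    last = np.searchsorted(counting.jump_time_idx, np.arange(m), side="right")
    for j, spec in enumerate(KM_COMPONENTS):
        k = counting.n_states
        lut = np.zeros((k, k), dtype=bool)
        for g, h in spec.event_transitions:
            lut[g, h] = True
        ev = lut[counting.jump_from, counting.jump_to]
        yr = counting.Y[list(spec.risk_states)].sum(axis=0).astype(np.float64)
        yr_jump = yr[counting.jump_time_idx]
        coef = np.where(ev & (yr_jump > 0), sqn / np.maximum(yr_jump, 1.0), 0.0)
        cum = np.cumsum(G * coef[None, :], axis=1)
        I = np.where(last[None, :] > 0, cum[:, np.maximum(last - 1, 0)], 0.0)
        out += -KM_SIGNS[j] * curves[j][None, :] * I
    return out


def _wild_aje_realizations(counting: CountingSystem, targets,
                           G: np.ndarray) -> np.ndarray:
    """All B wild realizations of an Aalen-Johansen functional, shape (B, m).

    Tracks only the initial-state row of ``D`` through the forward recursion,
    vectorized across replicates.
    """
    m, k = len(counting.times), counting.n_states
    B = G.shape[0]
    out = np.empty((B, m))
    if m == 0:
        return out
    da = _na_increments(counting)
    rows = _aj_row0(da)
    rows_prev = np.vstack([np.eye(k)[0], rows[:-1]])  # P^(0, t_{k-1}) row 0
    yv = counting.Y[counting.jump_from, counting.jump_time_idx].astype(np.float64)
    w = np.where(
        yv > 0,
        np.sqrt(counting.n)
        * rows_prev[counting.jump_time_idx, counting.jump_from]
        / np.maximum(yv, 1.0),
        0.0,
    )
    bounds = np.searchsorted(counting.jump_time_idx, np.arange(m + 1))
    eye = np.eye(k)
    d = np.zeros((B, k))
    targets = list(targets)
    for i in range(m):
        d = d @ (eye + da[i])
        for e in range(bounds[i], bounds[i + 1]):
            col = w[e] * G[:, e]
            d[:, counting.jump_to[e]] += col
            d[:, counting.jump_from[e]] -= col
        out[:, i] = d[:, targets].sum(axis=1)
    return out


def _step_eval(times: np.ndarray, values: np.ndarray, at: np.ndarray,
               y0: float = 1.0) -> np.ndarray:
    if len(values) == 0:
        return np.full(len(at), y0)
    idx = np.searchsorted(times, at, side="right") - 1
    return np.where(idx >= 0, values[np.clip(idx, 0, None)], y0)


def _efron_realizations(rec: RecordArrays, estimator: str, grid: np.ndarray,
                        base: np.ndarray, B: int, rng,
                        map_idm3: bool = False) -> np.ndarray:
    """All B Efron realizations on the original grid, shape (B, len(grid)).

    Each resample re-derives risk sets from scratch; for the Kaplan-Meier
    combination both the resampled and the original estimate are clipped to
    [0, 1] before centering.  ``rec`` is in the dataset's own model;
    ``map_idm3`` collapses each resample onto the illness-death model.
    """
    n = rec.n
    sqn = np.sqrt(n)
    targets = CGRFS_STATES["idm3" if estimator == "aje_idm3" else "prog6"]
    out = np.empty((B, len(grid)))
    for b in range(B):
        idx = rng.integers(0, n, n)
        r2 = rec.resample(idx)
        if map_idm3:
            r2 = r2.to_idm3()
        c2 = counting_from_records(r2)
        if estimator == "km_comb":
            vals = np.asarray(KM_SIGNS) @ _km_curves(c2)
            vals = np.clip(vals, 0.0, 1.0)
        else:
            rows = _aj_row0(_na_increments(c2))
            vals = rows[:, list(targets)].sum(axis=1)
        out[b] = sqn * (_step_eval(c2.times, vals, grid) - base)
    return out


# -- ensemble assembly --------------------------------------------------------


@dataclass
class BootstrapEnsemble:
    """Per-replicate realizations of the centered CGRFS process.

    Realizations are stored on the sqrt(n)-difference scale for both methods:
    wild realizations are ``B^(t)`` directly, Efron realizations are
    ``sqrt(n) {CGRFS^*(t) - CGRFS^(t)}`` on the original estimate's grid.
    """

    method: str
    estimator: str
    grid: np.ndarray
    realizations: np.ndarray  # (B, len(grid))
    n: int
    B: int
    seed: object = None

    def at(self, t: float) -> np.ndarray:
        """Realization values at time t (right-continuous), shape (B,)."""
        idx = int(np.searchsorted(self.grid, t, side="right")) - 1
        if idx < 0:
            return np.zeros(self.B)
        return self.realizations[:, idx]


def bootstrap_ensemble(
    dataset: MultistateDataset,
    estimator: str,
    method: str,
    B: int,
    seed,
    multipliers: np.ndarray | None = None,
) -> BootstrapEnsemble:
    """Assemble B bootstrap realizations for one estimator.

    Parameters
    ----------
    estimator :
        ``"km_comb"``, ``"aje_prog6"`` or ``"aje_idm3"``.
    method :
        ``"wild"`` or ``"efron"``.
    multipliers :
        Optional (B, n_jumps) array of wild multipliers to inject (testing
        hook); ignored for Efron's bootstrap.
    """
    if estimator not in ESTIMATORS:
        raise ValueError(f"unknown estimator {estimator!r}")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if B < 1:
        raise ValueError("B must be at least 1")
    if estimator in ("km_comb", "aje_prog6") and dataset.model.name != "prog6":
        raise ValueError(f"{estimator} requires prog6 data")
    rec = record_arrays(dataset)
    if estimator == "aje_idm3" and dataset.model.name == "prog6":
        work = rec.to_idm3()
    else:
        work = rec
    counting = counting_from_records(work)
    rng = np.random.default_rng(seed)
    if method == "wild":
        if multipliers is None:
            G = rng.standard_normal((B, counting.n_jumps))
        else:
            G = np.asarray(multipliers, dtype=np.float64)
            if G.shape != (B, counting.n_jumps):
                raise ValueError("injected multipliers have wrong shape")
        if estimator == "km_comb":
            real = _wild_km_realizations(counting, _km_curves(counting), G)
        else:
            targets = CGRFS_STATES["prog6" if estimator == "aje_prog6" else "idm3"]
            real = _wild_aje_realizations(counting, targets, G)
    else:
        if estimator == "km_comb":
            base = np.clip(np.asarray(KM_SIGNS) @ _km_curves(counting), 0.0, 1.0)
        else:
            targets = CGRFS_STATES["prog6" if estimator == "aje_prog6" else "idm3"]
            rows = _aj_row0(_na_increments(counting))
            base = rows[:, list(targets)].sum(axis=1)
        map_idm3 = estimator == "aje_idm3" and dataset.model.name == "prog6"
        real = _efron_realizations(
            rec, estimator, counting.times, base, B, rng, map_idm3=map_idm3
        )
    return BootstrapEnsemble(
        method=method,
        estimator=estimator,
        grid=counting.times,
        realizations=real,
        n=counting.n,
        B=B,
        seed=seed,
    )
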