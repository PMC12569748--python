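"""Non-Markov frailty simulator and the coverage-probability experiment.

Data are generated from the progressive six-state model with constant
per-day transition hazards that are multiplied, per individual, by a gamma
frailty Z ~ Gamma(shape 2, scale 1) (mean 2, variance 2).  Conditional on Z
the process is Markov with exponential sojourns; marginally the frailty
mixture makes it non-Markov: e.g. the marginal probability of still occupying
the initial state is the gamma Laplace transform
``(1 + scale * (a01 + a05) * t)^(-shape)``, whose hazard decreases in t.
Right-censoring is independent of the process and exponential.

The coverage experiment repeatedly simulates datasets, builds bootstrap
confidence intervals and simultaneous confidence bands for CGRFS with the
three estimators and both bootstrap methods, and reports the proportion of
replicates whose interval/band contains the true curve, approximated once
from a large uncensored simulation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counting import RecordArrays, counting_from_records
from .data import CENSORED, MultistateDataset
from .estimators import CGRFS_STATES, KM_SIGNS, _aj_row0, _km_curves, _na_increments
from .inference import (
    ConfidenceSpec,
    band_quantile,
    bootstrap_variance,
    loglog_band,
    loglog_ci,
)
from .model import PROG6
from .resampling import (
    BootstrapEnsemble,
    _efron_realizations,
    _wild_aje_realizations,
    _wild_km_realizations,
)
from .stepfun import StepFunction

#: per-day baseline hazards of the progressive six-state model
DEFAULT_HAZARDS = {
    (0, 1): 0.0009,
    (1, 2): 0.0008,
    (2, 3): 0.001,
    (3, 4): 0.00065,
    (0, 5): 0.00075,
    (1, 5): 0.0006,
    (2, 5): 0.0006,
    (3, 5): 0.0006,
    (4, 5): 0.0006,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the frailty simulation.

    All hazards are per day.  ``censoring`` toggles right-censoring as an
    explicit flag (a zero censoring rate is rejected rather than used to
    emulate "no censoring").
    """

    n: int = 200
    hazards: dict = field(default_factory=lambda: dict(DEFAULT_HAZARDS))
    frailty_shape: float = 2.0
    frailty_scale: float = 1.0
    censoring_rate: float = 0.00095
    censoring: bool = True
    horizon: float | None = None

    def __post_init__(self) -> None:
        for (g, h), rate in self.hazards.items():
            if rate <= 0:
                raise ValueError(f"hazard {g}->{h} must be positive")
            if (g, h) not in PROG6.transitions:
                raise ValueError(f"hazard for disallowed transition {g}->{h}")
        if set(self.hazards) != PROG6.transitions:
            missing = PROG6.transitions - set(self.hazards)
            raise ValueError(f"missing hazards for {sorted(missing)}")
        if self.frailty_shape <= 0 or self.frailty_scale <= 0:
            raise ValueError("frailty parameters must be positive")
        if self.censoring_rate <= 0:
            raise ValueError(
                "censoring rate must be positive; disable censoring via the "
                "'censoring' flag"
            )
        if self.n < 0:
            raise ValueError("n must be nonnegative")

    def digest(self) -> str:
        """Stable hash of the study conditions (used for truth caching)."""
        parts = [f"{g}>{h}:{self.hazards[g, h]!r}" for g, h in sorted(self.hazards)]
        parts += [
            repr(self.frailty_shape),
            repr(self.frailty_scale),
            repr(self.censoring_rate),
            repr(self.censoring),
            repr(self.horizon),
        ]
        return hashlib.sha256("|".join(parts).encode()).hexdigest()[:16]


def _rates(config: SimulationConfig):
    hz = config.hazards
    prog = np.array([hz[0, 1], hz[1, 2], hz[2, 3], hz[3, 4], 0.0])
    death = np.array([hz[0, 5], hz[1, 5], hz[2, 5], hz[3, 5], hz[4, 5]])
    return prog, death


def _simulate_records(
    config: SimulationConfig,
    n: int,
    rng: np.random.Generator,
    censoring: bool | None = None,
    frailty: np.ndarray | None = None,
) -> RecordArrays:
    """Simulate n paths and return them as compact record arrays.

    After k forward transitions an individual occupies state k, so the
    progressive chain absorbs in at most five steps: from each transient
    state g the sojourn is Exp(Z * (a_{g,g+1} + a_{g5})) and the destination
    is death/relapse with probability a_{g5} / (a_{g,g+1} + a_{g5}).
    """
    if censoring is None:
        censoring = config.censoring
    prog, death = _rates(config)
    if frailty is None:
        z = rng.gamma(config.frailty_shape, scale=config.frailty_scale, size=n)
    else:
        z = np.asarray(frailty, dtype=np.float64)
        if z.shape != (n,):
            raise ValueError("injected frailty must have shape (n,)")
    to_mat = np.full((n, 5), -9, dtype=np.int64)
    time_mat = np.full((n, 5), np.inf)
    t = np.zeros(n)
    alive = np.ones(n, dtype=bool)
    for g in range(5):
        idx = np.flatnonzero(alive)
        if len(idx) == 0:
            break
        total = z[idx] * (prog[g] + death[g])
        t[idx] = t[idx] + rng.exponential(1.0, len(idx)) / total
        die = rng.random(len(idx)) < death[g] / (prog[g] + death[g])
        to_mat[idx, g] = np.where(die, 5, g + 1)
        time_mat[idx, g] = t[idx]
        alive[idx[die]] = False
    if censoring:
        cens = rng.exponential(1.0 / config.censoring_rate, n)
    else:
        cens = np.full(n, np.inf)
    if config.horizon is not None:
        cens = np.minimum(cens, config.horizon)
    valid = to_mat != -9
    keep = valid & (time_mat <= cens[:, None])
    # an individual is censored iff its death/relapse record is not observed
    censored = ~np.any(keep & (to_mat == 5), axis=1)
    ri, rg = np.nonzero(keep)  # row-major: per individual, in time order
    rec_i = ri
    rec_f = rg.astype(np.int64)
    rec_to = to_mat[ri, rg]
    rec_t = time_mat[ri, rg]
    ci = np.flatnonzero(censored)
    state_at_c = keep[ci].sum(axis=1)  # state after k observed transitions
    rec_i = np.concatenate([rec_i, ci])
    rec_f = np.concatenate([rec_f, state_at_c])
    rec_to = np.concatenate([rec_to, np.full(len(ci), CENSORED, dtype=np.int64)])
    rec_t = np.concatenate([rec_t, cens[ci]])
    order = np.lexsort((rec_t, rec_i))
    rec_i, rec_f, rec_to, rec_t = (
        rec_i[order],
        rec_f[order],
        rec_to[order],
        rec_t[order],
    )
    counts = np.bincount(rec_i, minlength=n)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return RecordArrays(
        indiv=rec_i.astype(np.int64),
        from_=rec_f,
        to=rec_to,
        time=rec_t,
        indptr=indptr,
        n=n,
        n_states=6,
    )


def simulate_prog6(
    config: SimulationConfig,
    seed,
    frailty: np.ndarray | None = None,
) -> MultistateDataset:
    """Simulate a right-censored dataset from the frailty model.

    ``frailty`` optionally injects the individual frailties (testing hook).
    """
    rng = np.random.default_rng(seed)
    rec = _simulate_records(config, config.n, rng, frailty=frailty)
    frame = pd.DataFrame(
        {"id": rec.indiv, "from": rec.from_, "to": rec.to, "time": rec.time}
    )
    return MultistateDataset(PROG6, frame, validate=False)


# -- truth approximation ------------------------------------------------------


def _occupation_024(rec: RecordArrays) -> StepFunction:
    """Empirical proportion of individuals in states {0, 2, 4} over time
    (uncensored data; right-continuous)."""
    in_set = np.array([True, False, True, False, True, False])
    trans = rec.to != CENSORED
    f, h, t = rec.from_[trans], rec.to[trans], rec.time[trans]
    exit_ = in_set[f] & ~in_set[np.clip(h, 0, 5)]
    entry = ~in_set[f] & in_set[np.clip(h, 0, 5)]
    times = np.concatenate([t[exit_], t[entry]])
    delta = np.concatenate([-np.ones(exit_.sum()), np.ones(entry.sum())])
    order = np.argsort(times, kind="stable")
    times = times[order]
    vals = 1.0 + np.cumsum(delta[order]) / rec.n
    return StepFunction(times, vals, y0=1.0)


def approximate_truth(
    config: SimulationConfig,
    n_truth: int = 200_000,
    seed=0,
    cache_dir=None,
) -> StepFunction:
    """True CGRFS curve, approximated from a large uncensored simulation.

    On uncensored data all three estimators coincide with the empirical
    proportion of individuals in states {0, 2, 4}, which is what this
    computes.  With ``cache_dir`` the curve is cached as CSV keyed by the
    config digest, ``n_truth`` and ``seed``.
    """
    if n_truth < 10_000:
        raise ValueError("n_truth must be at least 10,000")
    cache = None
    if cache_dir is not None:
        import os

        os.makedirs(cache_dir, exist_ok=True)
        cache = os.path.join(
            cache_dir, f"truth_{config.digest()}_{n_truth}_{seed}.csv"
        )
        if os.path.exists(cache):
            t = pd.read_csv(cache)
            return StepFunction(t["time"].to_numpy(), t["value"].to_numpy(), y0=1.0)
    rng = np.random.default_rng(seed)
    rec = _simulate_records(config, n_truth, rng, censoring=False)
    truth = _occupation_024(rec)
    if cache is not None:
        pd.DataFrame({"time": truth.x, "value": truth.y}).to_csv(cache, index=False)
    return truth


# -- out-of-bounds accounting -------------------------------------------------


def out_of_bounds_counts(
    config: SimulationConfig, reps: int, seed
) -> tuple[int, int]:
    """Count simulated datasets whose unclipped Kaplan-Meier combination is
    ever strictly negative, respectively strictly above one.

    A dataset counts once however many time points are out of bounds.
    """
    children = np.random.SeedSequence(seed).spawn(reps)
    n_neg = n_pos = 0
    signs = np.asarray(KM_SIGNS)
    for r in range(reps):
        rng = np.random.default_rng(children[r])
        rec = _simulate_records(config, config.n, rng)
        counting = counting_from_records(rec)
        raw = signs @ _km_curves(counting)
        if raw.size:
            if raw.min() < 0.0:
                n_neg += 1
            if raw.max() > 1.0:
                n_pos += 1
    return n_neg, n_pos


# -- coverage experiment ------------------------------------------------------


@dataclass
class CoverageTable:
    """Coverage proportions per (estimator, method, target), plus counts of
    out-of-bounds Kaplan-Meier combination datasets."""

    table: pd.DataFrame
    n_negative: int
    n_above_one: int
    reps: int
    B: int
    n: int

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _estimator_inputs(rec: RecordArrays):
    """Fitted curves and counting systems shared by all bootstrap tasks."""
    c6 = counting_from_records(rec)
    c3 = counting_from_records(rec.to_idm3())
    curves = _km_curves(c6)
    km_raw = np.asarray(KM_SIGNS) @ curves
    rows6 = _aj_row0(_na_increments(c6))
    rows3 = _aj_row0(_na_increments(c3))
    estimates = {
        "km_comb": StepFunction(c6.times, km_raw),
        "aje_prog6": StepFunction(c6.times, rows6[:, [0, 2, 4]].sum(axis=1)),
        "aje_idm3": StepFunction(c3.times, rows3[:, 0]),
    }
    return c6, c3, curves, km_raw, estimates


def _make_ensemble(
    est_name: str,
    method: str,
    rec: RecordArrays,
    c6,
    c3,
    curves,
    estimates,
    B: int,
    rng,
) -> BootstrapEnsemble:
    counting = c3 if est_name == "aje_idm3" else c6
    if method == "wild":
        G = rng.standard_normal((B, counting.n_jumps))
        if est_name == "km_comb":
            real = _wild_km_realizations(counting, curves, G)
        else:
            targets = CGRFS_STATES["prog6" if est_name == "aje_prog6" else "idm3"]
            real = _wild_aje_realizations(counting, targets, G)
    else:
        if est_name == "km_comb":
            base = np.clip(estimates["km_comb"].values, 0.0, 1.0)
        else:
            base = estimates[est_name].values
        real = _efron_realizations(
            rec,
            est_name,
            counting.times,
            base,
            B,
            rng,
            map_idm3=(est_name == "aje_idm3"),
        )
    return BootstrapEnsemble(
        method=method,
        estimator=est_name,
        grid=counting.times,
        realizations=real,
        n=counting.n,
        B=B,
    )


def coverage_experiment(
    config: SimulationConfig,
    reps: int,
    B: int,
    times,
    intervals,
    estimators=("aje_idm3", "aje_prog6", "km_comb"),
    methods=("efron", "wild"),
    alpha: float = 0.05,
    seed=0,
    truth: StepFunction | None = None,
    n_truth: int = 200_000,
    pairs=None,
) -> CoverageTable:
    """Empirical coverage of 95% (by default) CIs and confidence bands.

    For each replicate a dataset is simulated, the three CGRFS estimates are
    computed (the Kaplan-Meier combination clipped to [0, 1] for the
    transformation; out-of-bounds occurrence recorded before clipping), an
    ensemble of B bootstrap realizations is built per (estimator, method)
    task, and log-log CIs at ``times`` and bands over ``intervals`` are
    checked against the truth curve.  Coverage is the proportion of
    replicates whose interval/band contains the truth at the requested time
    (at every evaluated grid point, for bands); degenerate time points
    collapse to the clipped estimate and count as covered only if the truth
    equals that value.

    ``pairs`` restricts the (estimator, method) tasks explicitly; by default
    the full cross product of ``estimators`` and ``methods`` is run.  All
    randomness derives from ``seed`` through per-replicate substreams.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    if pairs is None:
        pairs = [(e, m) for e in estimators for m in methods]
    times = list(times)
    intervals = [tuple(iv) for iv in intervals]
    if truth is None:
        truth = approximate_truth(
            config, n_truth=n_truth, seed=np.random.SeedSequence([seed, 824_063]).spawn(1)[0]
        )
    truth_at = {t: float(truth(t)) for t in times}
    children = np.random.SeedSequence(seed).spawn(reps)
    covered = {
        (e, m, kind, tgt): 0
        for (e, m) in pairs
        for kind, tgt in [("ci", t) for t in times] + [("band", iv) for iv in intervals]
    }
    n_neg = n_pos = 0
    for r in range(reps):
        rng = np.random.default_rng(children[r])
        rec = _simulate_records(config, config.n, rng)
        c6, c3, curves, km_raw, estimates = _estimator_inputs(rec)
        if km_raw.size and km_raw.min() < 0.0:
            n_neg += 1
        if km_raw.size and km_raw.max() > 1.0:
            n_pos += 1
        for est_name, method in pairs:
            ens = _make_ensemble(
                est_name, method, rec, c6, c3, curves, estimates, B, rng
            )
            est = estimates[est_name]
            var = bootstrap_variance(ens)
            for t in times:
                spec = ConfidenceSpec(alpha=alpha, time=t)
                ci = loglog_ci(float(est(t)), ens, spec, t)
                if ci.lower[0] <= truth_at[t] <= ci.upper[0]:
                    covered[est_name, method, "ci", t] += 1
            for iv in intervals:
                spec = ConfidenceSpec(alpha=alpha, interval=iv)
                q = band_quantile(ens, est, var, spec)
                band = loglog_band(est, var, q, ens.n, spec)
                tr = truth(band.times)
                if np.all((band.lower <= tr) & (tr <= band.upper)):
                    covered[est_name, method, "band", iv] += 1
    rows = [
        {
            "n": config.n,
            "estimator": e,
            "method": m,
            "kind": kind,
            "target": f"t={tgt}" if kind == "ci" else f"[{tgt[0]},{tgt[1]}]",
            "coverage": covered[e, m, kind, tgt] / reps,
            "covered": covered[e, m, kind, tgt],
            "reps": reps,
            "B": B,
        }
        for (e, m, kind, tgt) in covered
    ]
    return CoverageTable(
        table=pd.DataFrame(rows),
        n_negative=n_neg,
        n_above_one=n_pos,
        reps=reps,
        B=B,
        n=config.n,
    )
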