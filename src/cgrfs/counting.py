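"""Counting processes and at-risk sets derived from event-history data.

For every allowed transition g -> h, ``N_gh`` counts observed jumps; for every
state g, ``Y_g(t-)`` is the number of individuals occupying g just before t
and still uncensored at t.  An individual leaving g at time t (by transition
or censoring) is still counted in ``Y_g(t-)``.

The per-individual jump registry is retained because the wild bootstrap draws
one multiplier per individual jump.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CENSORED, MultistateDataset
from .model import PROG6_TO_IDM3, ModelSpec


@dataclass
class RecordArrays:
    """Compact array view of a dataset: records sorted by (individual, time).

    ``indiv`` holds dense individual codes ``0 .. n-1``; ``indptr`` delimits
    each individual's block (CSR style).  ``to == CENSORED`` marks censoring.
    """

    indiv: np.ndarray
    from_: np.ndarray
    to: np.ndarray
    time: np.ndarray
    indptr: np.ndarray
    n: int
    n_states: int

    def resample(self, idx: np.ndarray) -> "RecordArrays":
        """Gather whole paths for the individual indices ``idx`` (with fresh
        dense codes 0..len(idx)-1)."""
        counts = self.indptr[idx + 1] - self.indptr[idx]
        total = int(counts.sum())
        new_indiv = np.repeat(np.arange(len(idx)), counts)
        # positions within each block
        block_start = np.concatenate([[0], np.cumsum(counts)[:-1]])
        within = np.arange(total) - np.repeat(block_start, counts)
        gather = np.repeat(self.indptr[idx], counts) + within
        new_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        return RecordArrays(
            indiv=new_indiv,
            from_=self.from_[gather],
            to=self.to[gather],
            time=self.time[gather],
            indptr=new_ptr,
            n=len(idx),
            n_states=self.n_states,
        )

    def map_states(self, mapping, n_states: int) -> "RecordArrays":
        mapping = np.asarray(mapping, dtype=np.int64)
        to = self.to
        new_to = np.where(to == CENSORED, CENSORED, mapping[np.clip(to, 0, None)])
        return RecordArrays(
            indiv=self.indiv,
            from_=mapping[self.from_],
            to=new_to,
            time=self.time,
            indptr=self.indptr,
            n=self.n,
            n_states=n_states,
        )

    def to_idm3(self) -> "RecordArrays":
        return self.map_states(PROG6_TO_IDM3, 3)


def record_arrays(dataset: MultistateDataset) -> RecordArrays:
    """Extract the compact array representation of a validated dataset."""
    f = dataset.frame
    codes, _ = pd.factorize(f["id"], sort=False)
    indiv = codes.astype(np.int64)
    n = int(indiv.max()) + 1 if len(indiv) else 0
    counts = np.bincount(indiv, minlength=n)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return RecordArrays(
        indiv=indiv,
        from_=f["from"].to_numpy(np.int64),
        to=f["to"].to_numpy(np.int64),
        time=f["time"].to_numpy(np.float64),
        indptr=indptr,
        n=n,
        n_states=dataset.model.n_states,
    )


@dataclass
class CountingSystem:
    """Jump registry, event grid and at-risk left limits of a dataset.

    Attributes
    ----------
    n, n_states :
        Number of individuals and states.
    times :
        Sorted distinct observed transition times (the event grid).
    jump_time_idx, jump_from, jump_to, jump_indiv :
        One entry per observed individual transition, sorted by time;
        ``jump_time_idx`` indexes into ``times``.
    Y :
        Array of shape ``(K, m)``; ``Y[g, k] = Y_g(times[k]-)``.
    """

    n: int
    n_states: int
    times: np.ndarray
    jump_time_idx: np.ndarray
    jump_from: np.ndarray
    jump_to: np.ndarray
    jump_indiv: np.ndarray
    Y: np.ndarray
    _starts: list
    _stops: list

    @property
    def n_jumps(self) -> int:
        return len(self.jump_time_idx)

    def at_risk(self, g: int, t):
        """``Y_g(t-)`` for arbitrary times ``t`` (vectorized)."""
        t = np.asarray(t, dtype=np.float64)
        out = np.searchsorted(self._starts[g], t, side="left") - np.searchsorted(
            self._stops[g], t, side="left"
        )
        return out if out.ndim else int(out)

    def transition_counts(self) -> np.ndarray:
        """``dN`` array of shape ``(m, K, K)`` with the number of g -> h jumps
        at each grid time."""
        m, k = len(self.times), self.n_states
        dn = np.zeros((m, k, k))
        np.add.at(dn, (self.jump_time_idx, self.jump_from, self.jump_to), 1.0)
        return dn


def counting_from_records(rec: RecordArrays) -> CountingSystem:
    """Build the counting system from a compact record-array view."""
    k = rec.n_states
    # occupation interval of each record's origin state: (prev_time, time]
    prev = np.empty_like(rec.time)
    if len(rec.time):
        prev[1:] = rec.time[:-1]
        prev[rec.indptr[:-1]] = 0.0
    is_jump = rec.to != CENSORED
    jt = rec.time[is_jump]
    order = np.argsort(jt, kind="stable")
    jt = jt[order]
    jf = rec.from_[is_jump][order]
    jh = rec.to[is_jump][order]
    ji = rec.indiv[is_jump][order]
    times, jump_time_idx = np.unique(jt, return_inverse=True)
    m = len(times)
    Y = np.zeros((k, m), dtype=np.int64)
    starts, stops = [], []
    for g in range(k):
        in_g = rec.from_ == g
        sg = np.sort(prev[in_g])
        eg = np.sort(rec.time[in_g])
        starts.append(sg)
        stops.append(eg)
        if m:
            Y[g] = np.searchsorted(sg, times, side="left") - np.searchsorted(
                eg, times, side="left"
            )
    return CountingSystem(
        n=rec.n,
        n_states=k,
        times=times,
        jump_time_idx=jump_time_idx.astype(np.int64),
        jump_from=jf,
        jump_to=jh,
        jump_indiv=ji,
        Y=Y,
        _starts=starts,
        _stops=stops,
    )


def build_counting(dataset: MultistateDataset) -> CountingSystem:
    """Counting processes ``N_gh`` and at-risk left limits ``Y_g(t-)`` of a
    validated dataset."""
    return counting_from_records(record_arrays(dataset))
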