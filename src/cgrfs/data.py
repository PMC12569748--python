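"""Event-history data model and long-format CSV I/O.

A dataset is a collection of right-censored sample paths of a multistate
process, stored in long format: one row per observed direct transition, plus
(at most) one terminal censoring row per individual.  Censoring is marked by
the token ``cens`` in the ``to`` column, encoded internally as ``-1``.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import IDM3, PROG6, PROG6_TO_IDM3, ModelSpec

#: internal integer code for a censoring record in the ``to`` column
CENSORED = -1

#: token written to / accepted in CSV files (also accepted with the
#: typographic quotes used in print, case-insensitively)
CENS_TOKEN = "cens"

_COLUMNS = ["id", "from", "to", "time"]


class DataError(ValueError):
    """Raised when an event table violates the multistate data contract."""


def _parse_to(value) -> int:
    """Parse a ``to`` entry: an integer state or a censoring token."""
    if isinstance(value, (int, np.integer)):
        return int(value)
    if isinstance(value, float) and float(value).is_integer():
        return int(value)
    text = str(value).strip().strip('"').strip("“”‘’'")
    if text.lower() == CENS_TOKEN:
        return CENSORED
    try:
        return int(text)
    except ValueError:
        raise DataError(f"malformed 'to' entry: {value!r}") from None


@dataclass(frozen=True)
class EventRecord:
    """One observed transition (or terminal censoring) of one individual."""

    id: object
    from_state: int
    to_state: int  # CENSORED (-1) marks censoring
    time: float

    @property
    def is_censoring(self) -> bool:
        return self.to_state == CENSORED


class MultistateDataset:
    """Validated per-individual transition paths in a declared state space.

    Parameters
    ----------
    model :
        The :class:`~cgrfs.model.ModelSpec` the paths must respect.
    frame :
        Long-format table with columns ``id, from, to, time``; ``to`` is an
        integer state or ``CENSORED``.  Row order is irrelevant; the table is
        sorted by ``(id, time)`` on construction.

    Every individual's path must start in the model's initial state, have
    strictly increasing positive times, be connected (each ``from`` equals the
    previous ``to``), use only allowed transitions, and end either with a
    single censoring record or by entering an absorbing state.
    """

    def __init__(self, model: ModelSpec, frame: pd.DataFrame, validate: bool = True):
        frame = frame.loc[:, _COLUMNS].copy()
        frame["from"] = frame["from"].astype(np.int64)
        frame["to"] = frame["to"].astype(np.int64)
        frame["time"] = frame["time"].astype(np.float64)
        # stable sort keeps input order among (pathological) ties
        frame = frame.sort_values(["id", "time"], kind="stable").reset_index(drop=True)
        self.model = model
        self.frame = frame
        if validate:
            self._validate()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(cls, model: ModelSpec, records, validate: bool = True):
        rows = [
            (r.id, r.from_state, r.to_state, r.time) if isinstance(r, EventRecord) else tuple(r)
            for r in records
        ]
        frame = pd.DataFrame(rows, columns=_COLUMNS)
        if len(rows) == 0:
            frame = _empty_frame()
        return cls(model, frame, validate=validate)

    # -- basic accessors ----------------------------------------------------

    @property
    def ids(self) -> np.ndarray:
        return self.frame["id"].unique()

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    def records_of(self, individual) -> pd.DataFrame:
        return self.frame[self.frame["id"] == individual]

    def n_transitions(self) -> int:
        return int((self.frame["to"] != CENSORED).sum())

    def __eq__(self, other) -> bool:
        if not isinstance(other, MultistateDataset):
            return NotImplemented
        if self.model.name != other.model.name:
            return False
        a = self.frame.astype({"id": str})
        b = other.frame.astype({"id": str})
        return a.equals(b)

    def __repr__(self) -> str:
        return (
            f"MultistateDataset(model={self.model.name!r}, "
            f"n={self.n_individuals}, transitions={self.n_transitions()})"
        )

    # -- validation ---------------------------------------------------------

    def _validate(self) -> None:
        m = self.model
        f = self.frame
        if (f["time"] <= 0).any():
            raise DataError("event times must be strictly positive")
        bad = (f["to"] != CENSORED) & (f["from"] == f["to"])
        if bad.any():
            raise DataError("self-loop record (from == to)")
        for g, h in zip(f["from"], f["to"]):
            if h != CENSORED and not m.allows(int(g), int(h)):
                raise DataError(f"transition {g}->{h} not allowed under {m.name}")
        for ind, grp in f.groupby("id", sort=False):
            times = grp["time"].to_numpy()
            if np.any(np.diff(times) <= 0):
                raise DataError(f"individual {ind!r}: times not strictly increasing")
            froms = grp["from"].to_numpy()
            tos = grp["to"].to_numpy()
            if froms[0] != m.initial_state:
                raise DataError(f"individual {ind!r}: path does not start in state "
                                f"{m.initial_state}")
            if np.any(tos[:-1] == CENSORED):
                raise DataError(f"individual {ind!r}: record after censoring")
            if np.any(froms[1:] != tos[:-1]):
                raise DataError(f"individual {ind!r}: path discontinuity")
            for g in tos[:-1]:
                if int(g) in m.absorbing:
                    raise DataError(f"individual {ind!r}: record after absorption")
            last = int(tos[-1])
            if last != CENSORED and last not in m.absorbing:
                raise DataError(
                    f"individual {ind!r}: path must end in censoring or an "
                    f"absorbing state"
                )


def _empty_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": pd.Series([], dtype=object),
            "from": pd.Series([], dtype=np.int64),
            "to": pd.Series([], dtype=np.int64),
            "time": pd.Series([], dtype=np.float64),
        }
    )


# -- CSV I/O ----------------------------------------------------------------


def read_events(path, model: ModelSpec) -> MultistateDataset:
    """Read a long-format event CSV (columns ``id,from,to,time``).

    The ``to`` column holds integer states or the censoring token ``cens``
    (case-insensitive, typographic quotes tolerated).  Rows need not be
    sorted.
    """
    raw = pd.read_csv(path, dtype={"to": object}, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in raw.columns]
    if missing:
        raise DataError(f"missing columns {missing} in {path}")
    if len(raw) == 0:
        return MultistateDataset(model, _empty_frame())
    frame = raw.loc[:, _COLUMNS].copy()
    frame["to"] = [_parse_to(v) for v in frame["to"]]
    return MultistateDataset(model, frame)


def write_events(dataset: MultistateDataset, path) -> None:
    """Write a dataset back to long-format CSV; round-trips through
    :func:`read_events`."""
    out = dataset.frame.copy()
    out["to"] = out["to"].map(lambda h: CENS_TOKEN if h == CENSORED else int(h))
    out.to_csv(path, index=False)


# -- built-in three-individual example --------------------------------------

_TOY_CSV = """\
id,from,to,time
1,0,cens,2
2,0,1,1
2,1,2,3
2,2,3,6
2,3,5,7
3,0,1,4
3,1,cens,5
"""


def toy_table1() -> MultistateDataset:
    """The built-in three-individual example dataset.

    Individual 1 is censored in the initial state at day 2; individual 2 has
    two cGvHD episodes and dies before recovering from the second; individual
    3 has one episode and is censored during it.
    """
    return read_events(io.StringIO(_TOY_CSV), PROG6)


# -- model mapping -----------------------------------------------------------


def map_prog6_to_idm3(dataset: MultistateDataset) -> MultistateDataset:
    """Collapse a progressive six-state dataset onto the illness-death model
    with recovery.

    States {0, 2, 4} map to "alive without current cGvHD" (0), {1, 3} to
    "alive with cGvHD" (1) and 5 to death/relapse (2).  Event times and
    censoring are preserved exactly; no allowed prog6 transition maps to a
    self-loop.
    """
    if dataset.model.name != "prog6":
        raise DataError("map_prog6_to_idm3 requires a prog6 dataset")
    mapping = np.asarray(PROG6_TO_IDM3, dtype=np.int64)
    frame = dataset.frame.copy()
    frame["from"] = mapping[frame["from"].to_numpy()]
    to = frame["to"].to_numpy()
    mapped = np.where(to == CENSORED, CENSORED, mapping[np.clip(to, 0, 5)])
    frame["to"] = mapped
    return MultistateDataset(IDM3, frame)


def ensure_path(path) -> None:
    d = os.path.dirname(os.fspath(path))
    if d:
        os.makedirs(d, exist_ok=True)
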