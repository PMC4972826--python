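"""Core data containers for agonistic-interaction and census records.

The raw material of a colony study is two logs: an event log of dyadic
agonistic interactions (who won, who lost, where and when) and a census log
of sightings (who was visible in which vivarium at each census time point).
Everything downstream — sociomatrices, hierarchy statistics, network metrics,
association indices — is derived from these two containers.

Matrices are represented as :class:`pandas.DataFrame` objects whose index and
columns are the roster (winner rows, loser columns), so a permutation of
individuals can never silently change the meaning of an entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_COLUMNS",
    "CENSUS_COLUMNS",
    "DEFAULT_ETHOGRAM",
    "ValidationError",
    "EventLog",
    "CensusLog",
    "build_frequency_matrix",
    "binarize",
    "symmetrize",
    "as_matrix",
]

EVENT_COLUMNS = ["day", "winner", "loser", "behavior", "vivarium", "zone"]
CENSUS_COLUMNS = ["day", "timepoint", "vivarium", "id"]

#: Ethogram of agonistic behaviors with an identifiable winner/loser role.
DEFAULT_ETHOGRAM = (
    "fighting",
    "chasing",
    "mounting",
    "subordinate posture",
    "induced-flee",
)


class ValidationError(ValueError):
    """A log or matrix violates a structural invariant."""


def _normalize_roster(ids: Iterable[str]) -> list[str]:
    roster = sorted({str(i) for i in ids})
    if len(roster) < 2:
        raise ValidationError("roster must contain at least 2 individuals")
    return roster


@dataclass
class EventLog:
    """Ordered log of agonistic events among a fixed roster.

    Parameters
    ----------
    roster
        Unique individual ids. If ``None``, inferred as the sorted union of
        winner and loser ids (lexicographic order is the canonical roster
        order throughout the package).
    events
        DataFrame with columns ``day, winner, loser, behavior, vivarium,
        zone``; row order is preserved.
    vivaria
        Catalogue of vivarium indices; defaults to those observed.
    """

    events: pd.DataFrame
    roster: Sequence[str] | None = None
    vivaria: Sequence[int] | None = None

    def __post_init__(self) -> None:
        ev = pd.DataFrame(self.events).copy()
        missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
        if missing:
            raise ValidationError(f"event log missing columns: {missing}")
        ev = ev[EVENT_COLUMNS]
        ev["winner"] = ev["winner"].astype(str)
        ev["loser"] = ev["loser"].astype(str)
        ev["day"] = ev["day"].astype(int)
        ev["vivarium"] = ev["vivarium"].astype(int)
        if (ev["day"] < 1).any():
            raise ValidationError("event days must be positive integers")
        self_fight = ev["winner"] == ev["loser"]
        if self_fight.any():
            row = int(np.flatnonzero(self_fight.to_numpy())[0])
            raise ValidationError(
                f"event row {row}: winner equals loser ({ev['winner'].iloc[row]!r})"
            )
        if self.roster is None:
            self.roster = _normalize_roster(
                pd.concat([ev["winner"], ev["loser"]])
            )
        else:
            self.roster = [str(i) for i in self.roster]
            if len(set(self.roster)) != len(self.roster):
                raise ValidationError("roster ids must be unique")
            known = set(self.roster)
            unknown = set(ev["winner"]).union(ev["loser"]) - known
            if unknown:
                raise ValidationError(f"events reference unknown ids: {sorted(unknown)}")
            if len(self.roster) < 2:
                raise ValidationError("roster must contain at least 2 individuals")
        if self.vivaria is None:
            self.vivaria = sorted(ev["vivarium"].unique().tolist()) or [1]
        else:
            self.vivaria = sorted(int(v) for v in self.vivaria)
        self.events = ev.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.roster)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def filter_behaviors(self, behaviors: Iterable[str]) -> "EventLog":
        """Restrict the log to a subset of ethogram behaviors."""
        keep = self.events["behavior"].isin(set(behaviors))
        return EventLog(self.events.loc[keep], roster=self.roster, vivaria=self.vivaria)


@dataclass
class CensusLog:
    """Sightings of individuals at daily census time points.

    A census *period* is one (day, timepoint) pair; an individual appears at
    most once per period. Duplicate sightings are collapsed with a warning.
    """

    sightings: pd.DataFrame
    roster: Sequence[str]
    timepoints: Sequence[str] = field(default_factory=lambda: ["T1", "T2", "T3"])
    vivaria: Sequence[int] | None = None

    def __post_init__(self) -> None:
        cs = pd.DataFrame(self.sightings).copy()
        missing = [c for c in CENSUS_COLUMNS if c not in cs.columns]
        if missing:
            raise ValidationError(f"census log missing columns: {missing}")
        cs = cs[CENSUS_COLUMNS]
        cs["id"] = cs["id"].astype(str)
        cs["day"] = cs["day"].astype(int)
        cs["vivarium"] = cs["vivarium"].astype(int)
        cs["timepoint"] = cs["timepoint"].astype(str)
        self.roster = [str(i) for i in self.roster]
        unknown = set(cs["id"]) - set(self.roster)
        if unknown:
            raise ValidationError(f"census references unknown ids: {sorted(unknown)}")
        dup = cs.duplicated(subset=["day", "timepoint", "id"])
        if dup.any():
            warnings.warn(
                f"census log: collapsed {int(dup.sum())} duplicate "
                "(day, timepoint, id) sightings",
                stacklevel=2,
            )
            cs = cs.loc[~dup]
        if self.vivaria is None:
            self.vivaria = sorted(cs["vivarium"].unique().tolist()) or [1]
        else:
            self.vivaria = sorted(int(v) for v in self.vivaria)
        self.sightings = cs.reset_index(drop=True)

    @property
    def periods(self) -> list[tuple[int, str]]:
        """All observed census periods in (day, timepoint) order."""
        seen = self.sightings[["day", "timepoint"]].drop_duplicates()
        return sorted(map(tuple, seen.to_numpy().tolist()))

    @property
    def n_periods(self) -> int:
        return len(self.periods)


# ---------------------------------------------------------------------------
# Sociomatrices


def as_matrix(m: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Return (ndarray, roster) for a labelled or plain square matrix."""
    if isinstance(m, pd.DataFrame):
        if list(m.index) != list(m.columns):
            raise ValidationError("matrix index and columns must both be the roster")
        return m.to_numpy(dtype=float), [str(i) for i in m.index]
    a = np.asarray(m, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("matrix must be square")
    return a, [str(i) for i in range(a.shape[0])]


def build_frequency_matrix(log: EventLog) -> pd.DataFrame:
    """Winner-by-loser sociomatrix of win counts.

    ``M[i, j]`` counts events in which ``i`` defeated ``j``; the diagonal is
    structurally zero and the entries sum to the number of events.
    """
    roster = list(log.roster)
    idx = {r: k for k, r in enumerate(roster)}
    mat = np.zeros((len(roster), len(roster)), dtype=int)
    wi = log.events["winner"].map(idx).to_numpy()
    li = log.events["loser"].map(idx).to_numpy()
    np.add.at(mat, (wi, li), 1)
    return pd.DataFrame(mat, index=roster, columns=roster)


def binarize(freq: pd.DataFrame) -> pd.DataFrame:
    """Binary dominance matrix under the Appleby tie rule.

    ``B[i, j] = 1`` iff *i* won strictly more contests against *j* than it
    lost; tied dyads — including dyads that never interacted — get 0 in both
    directions.
    """
    m, roster = as_matrix(freq)
    b = (m > m.T).astype(int)
    np.fill_diagonal(b, 0)
    return pd.DataFrame(b, index=roster, columns=roster)


def symmetrize(freq: pd.DataFrame) -> pd.DataFrame:
    """Total-interaction matrix ``S = M + M.T`` (undirected tie strengths)."""
    m, roster = as_matrix(freq)
    s = m + m.T
    np.fill_diagonal(s, 0)
    return pd.DataFrame(s.astype(int), index=roster, columns=roster)


def unknown_dyads(freq: pd.DataFrame) -> int:
    """Number of dyads that never interacted ("unknown relationships")."""
    m, _ = as_matrix(freq)
    tot = m + m.T
    iu = np.triu_indices(m.shape[0], 1)
    return int((tot[iu] == 0).sum())
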