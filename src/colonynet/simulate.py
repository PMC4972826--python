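"""Synthetic colony generator.

Emulates the data-generating regime the analyses assume: a group of ~30 male
mice with a steep, near-linear dominance hierarchy, two spatially segregated
communities of unequal size plus a few "floaters", despotic concentration of
wins among top-ranked individuals, and census sightings correlated with
community territory.

The generative model is deliberately simple:

* each individual *i* carries a latent dominance score ``d_i`` (evenly spaced,
  spacing ``sigma_d``, higher = more dominant);
* a contest between *i* and *j* is won by *i* with Bradley–Terry probability
  ``1 / (1 + exp(-beta * (d_i - d_j)))``;
* dyads are drawn with weight ``w`` if the two belong to the same community
  and weight 1 otherwise;
* community A holds territory vivaria {1, 2}, community B holds {3, 4};
  an event is located in the interacting pair's home territory with
  probability ``phi`` (location fidelity) and in the other territory
  otherwise; floaters have no home and split evenly;
* censuses sight each individual independently (probability ``p_sight``) and
  place it in its home territory with probability ``phi``.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import DEFAULT_ETHOGRAM, CensusLog, EventLog, ValidationError

__all__ = ["SimConfig", "SyntheticDataset", "simulate_colony", "null_colony"]

_TERRITORIES = {"A": (1, 2), "B": (3, 4)}
_ZONES = ("shelf", "nestbox", "floor")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic colony.

    Defaults target a 30-mouse colony observed over 19 days with 1230
    agonistic interactions, split into communities of 19 and 8 plus 3
    floaters.
    """

    n: int = 30
    community_sizes: Sequence[int] = (19, 8, 3)
    sigma_d: float = 1.0  # latent-score spacing between adjacent ranks
    beta: float = 3.0  # contest steepness (logistic scale)
    w: float = 5.0  # within-community dyad weight (>= 1)
    phi: float = 0.9  # location fidelity in [0.5, 1]
    p_sight: float = 0.8  # per-census detectability
    n_events: int = 1230
    n_days: int = 19
    censuses_per_day: int = 3
    behavior_probs: Sequence[float] = (0.45, 0.35, 0.08, 0.07, 0.05)
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2:
            raise ValidationError("n must be >= 2")
        if sum(self.community_sizes) != self.n:
            raise ValidationError("community sizes must sum to n")
        if len(self.community_sizes) not in (2, 3):
            raise ValidationError("expected 2 communities (+ optional floaters)")
        if self.beta < 0 or self.w < 1:
            raise ValidationError("beta >= 0 and w >= 1 required")
        if not 0.5 <= self.phi <= 1.0:
            raise ValidationError("phi must lie in [0.5, 1]")
        if not 0.0 < self.p_sight <= 1.0:
            raise ValidationError("p_sight must lie in (0, 1]")
        if self.n_events < 1 or self.n_days < 1 or self.censuses_per_day < 1:
            raise ValidationError("n_events, n_days, censuses_per_day must be >= 1")
        if abs(sum(self.behavior_probs) - 1.0) > 1e-9 or len(
            self.behavior_probs
        ) != len(DEFAULT_ETHOGRAM):
            raise ValidationError("behavior_probs must sum to 1 over the ethogram")


@dataclass
class SyntheticDataset:
    """Simulated logs plus the planted ground truth."""

    events: EventLog
    census: CensusLog
    true_communities: dict[str, str]  # id -> "A" | "B" | "floater"
    true_order: list[str]  # ids from most to least dominant
    config: SimConfig = field(repr=False, default=None)


def _roster(n: int) -> list[str]:
    return [f"M{k:02d}" for k in range(1, n + 1)]


def _labels(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    names = ["A", "B", "floater"][: len(config.community_sizes)]
    lab = np.repeat(names, list(config.community_sizes))
    rng.shuffle(lab)  # community membership independent of dominance rank
    return lab


def _pair_territory(
    lab_i: str, lab_j: str, rng: np.random.Generator
) -> tuple[int, int]:
    homes = [_TERRITORIES[l] for l in (lab_i, lab_j) if l in _TERRITORIES]
    if not homes:  # two floaters
        return _TERRITORIES["A" if rng.random() < 0.5 else "B"]
    if len(homes) == 2 and homes[0] != homes[1]:  # cross-community pair
        return homes[rng.integers(2)]
    return homes[0]


def simulate_colony(config: SimConfig | None = None, **overrides) -> SyntheticDataset:
    """Draw a synthetic colony dataset under `config` (seed-deterministic)."""
    config = replace(config or SimConfig(), **overrides)
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n
    roster = _roster(n)
    labels = _labels(config, rng)
    # latent scores: evenly spaced, decreasing with roster index, then the
    # planted order is the roster order itself (M01 most dominant).
    scores = config.sigma_d * np.arange(n - 1, -1, -1, dtype=float)

    # --- dyad sampling weights
    iu, ju = np.triu_indices(n, 1)
    same = (labels[iu] == labels[ju]) & (labels[iu] != "floater")
    weights = np.where(same, config.w, 1.0)
    weights = weights / weights.sum()

    dyads = rng.choice(len(iu), size=config.n_events, p=weights)
    a, b = iu[dyads], ju[dyads]
    p_win = 1.0 / (1.0 + np.exp(-config.beta * (scores[a] - scores[b])))
    a_wins = rng.random(config.n_events) < p_win
    win = np.where(a_wins, a, b)
    lose = np.where(a_wins, b, a)

    days = np.sort(rng.integers(1, config.n_days + 1, size=config.n_events))
    behaviors = rng.choice(
        DEFAULT_ETHOGRAM, size=config.n_events, p=list(config.behavior_probs)
    )
    vivs = np.empty(config.n_events, dtype=int)
    for k in range(config.n_events):
        terr = _pair_territory(labels[a[k]], labels[b[k]], rng)
        if rng.random() >= config.phi:
            terr = _TERRITORIES["B"] if terr == _TERRITORIES["A"] else _TERRITORIES["A"]
        vivs[k] = terr[rng.integers(2)]
    zones = rng.choice(_ZONES, size=config.n_events)

    events = EventLog(
        pd.DataFrame(
            {
                "day": days,
                "winner": np.array(roster)[win],
                "loser": np.array(roster)[lose],
                "behavior": behaviors,
                "vivarium": vivs,
                "zone": zones,
            }
        ),
        roster=roster,
        vivaria=[1, 2, 3, 4],
    )

    # --- censuses
    timepoints = [f"T{t}" for t in range(1, config.censuses_per_day + 1)]
    rows = []
    for day in range(1, config.n_days + 1):
        for tp in timepoints:
            seen = rng.random(n) < config.p_sight
            for i in np.flatnonzero(seen):
                if labels[i] == "floater":
                    home = _TERRITORIES["A" if rng.random() < 0.5 else "B"]
                else:
                    home = _TERRITORIES[labels[i]]
                terr = home
                if rng.random() >= config.phi:
                    terr = (
                        _TERRITORIES["B"] if terr == _TERRITORIES["A"] else _TERRITORIES["A"]
                    )
                rows.append((day, tp, terr[rng.integers(2)], roster[i]))
    census = CensusLog(
        pd.DataFrame(rows, columns=["day", "timepoint", "vivarium", "id"]),
        roster=roster,
        timepoints=timepoints,
        vivaria=[1, 2, 3, 4],
    )

    return SyntheticDataset(
        events=events,
        census=census,
        true_communities=dict(zip(roster, labels)),
        true_order=list(roster),
        config=config,
    )


def null_colony(
    n: int = 30, n_events: int = 1230, seed: int = 0, n_days: int = 19,
    censuses_per_day: int = 3, p_sight: float = 0.8,
) -> SyntheticDataset:
    """Structureless colony: uniform dyads, fair-coin winners, uniform locations.

    Calibration input for every randomization test — no hierarchy, no
    communities, no territoriality.
    """
    if n < 3:
        raise ValidationError("null_colony requires n >= 3")
    rng = np.random.default_rng(seed)
    roster = _roster(n)
    iu, ju = np.triu_indices(n, 1)
    dyads = rng.integers(0, len(iu), size=n_events)
    a, b = iu[dyads], ju[dyads]
    a_wins = rng.random(n_events) < 0.5
    win = np.where(a_wins, a, b)
    lose = np.where(a_wins, b, a)
    events = EventLog(
        pd.DataFrame(
            {
                "day": np.sort(rng.integers(1, n_days + 1, size=n_events)),
                "winner": np.array(roster)[win],
                "loser": np.array(roster)[lose],
                "behavior": rng.choice(DEFAULT_ETHOGRAM, size=n_events),
                "vivarium": rng.integers(1, 5, size=n_events),
                "zone": rng.choice(_ZONES, size=n_events),
            }
        ),
        roster=roster,
        vivaria=[1, 2, 3, 4],
    )
    timepoints = [f"T{t}" for t in range(1, censuses_per_day + 1)]
    rows = []
    for day in range(1, n_days + 1):
        for tp in timepoints:
            for i in np.flatnonzero(rng.random(n) < p_sight):
                rows.append((day, tp, int(rng.integers(1, 5)), roster[i]))
    census = CensusLog(
        pd.DataFrame(rows, columns=["day", "timepoint", "vivarium", "id"]),
        roster=roster,
        timepoints=timepoints,
        vivaria=[1, 2, 3, 4],
    )
    labels = {r: "none" for r in roster}
    return SyntheticDataset(events, census, labels, list(roster), None)
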