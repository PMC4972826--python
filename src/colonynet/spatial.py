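"""Spatial distribution of agonistic behavior.

Per-individual, per-vivarium counts of aggression given (wins) and received
(losses), Shannon's evenness of those distributions with a multinomial-
uniform unevenness test, Bray–Curtis / Euclidean distances between
individuals' space-usage profiles, and a non-metric multidimensional scaling
(nMDS) ordination of the usage table.

The per-individual unevenness test is this package's operationalization: the
null draws the same total count from a uniform multinomial over vivaria and
asks how often the null evenness is as low as observed (one-sided toward
unevenness).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import smacof

from .datamodel import EventLog, ValidationError

__all__ = [
    "LocationUsage",
    "location_usage",
    "shannon_evenness",
    "evenness_significance",
    "usage_distance",
    "OrdinationResult",
    "nmds",
]


@dataclass
class LocationUsage:
    """Counts of aggression given/received per individual per vivarium."""

    given: pd.DataFrame  # individuals x vivaria
    received: pd.DataFrame

    @property
    def total(self) -> pd.DataFrame:
        return self.given + self.received


def location_usage(log: EventLog, on_missing: str = "drop") -> LocationUsage:
    """Tabulate wins and losses by vivarium.

    ``given[i, v]`` counts wins by *i* in vivarium *v*; ``received`` the
    losses. Events with a missing location are dropped with a warning
    (``on_missing="drop"``) or rejected (``"error"``).
    """
    ev = log.events
    missing = ev["vivarium"].isna()
    if missing.any():
        if on_missing == "error":
            raise ValidationError(f"{int(missing.sum())} events lack a location")
        warnings.warn(f"dropping {int(missing.sum())} events without location",
                      stacklevel=2)
        ev = ev.loc[~missing]
    vivaria = list(log.vivaria)
    roster = list(log.roster)

    def tab(col: str) -> pd.DataFrame:
        t = (
            ev.groupby([col, "vivarium"], sort=False).size().unstack(fill_value=0)
        )
        return t.reindex(index=roster, columns=vivaria, fill_value=0).astype(int)

    return LocationUsage(given=tab("winner"), received=tab("loser"))


def shannon_evenness(counts) -> float:
    """Shannon's evenness J = H / ln K of a count vector over K locations.

    Returns NaN when the total count is zero (undefined).
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1 or c.size < 2:
        raise ValidationError("evenness needs >= 2 locations")
    if (c < 0).any():
        raise ValidationError("negative counts")
    total = c.sum()
    if total == 0:
        return float("nan")
    p = c / total
    p = p[p > 0]
    h = float(-(p * np.log(p)).sum())
    return h / np.log(c.size)


def evenness_significance(
    counts, n_rand: int = 10000, seed: int | None = None
) -> float:
    """One-sided multinomial test for spatial unevenness.

    Null: the same total count thrown uniformly over the locations;
    ``p = (1 + #{J_null <= J_obs}) / (1 + n_rand)``. Small p = the individual
    concentrates its activity in fewer locations than chance allows.
    """
    c = np.asarray(counts, dtype=float)
    obs = shannon_evenness(c)
    if not np.isfinite(obs):
        raise ValidationError("evenness significance undefined for zero total")
    k = c.size
    total = int(c.sum())
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(total, np.full(k, 1.0 / k), size=n_rand)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = draws / total
        logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), 0.0)
        j_null = -(p * logp).sum(axis=1) / np.log(k)
    return float((1 + np.sum(j_null <= obs + 1e-12)) / (1 + n_rand))


def usage_distance(
    usage: LocationUsage, metric: str = "braycurtis"
) -> pd.DataFrame:
    """Pairwise distances between per-vivarium total-activity profiles.

    Individuals with an all-zero profile are excluded with a warning (their
    composition is undefined under Bray–Curtis).
    """
    metric = {"bray-curtis": "braycurtis"}.get(metric, metric)
    if metric not in ("braycurtis", "euclidean"):
        raise ValidationError("metric must be 'braycurtis' or 'euclidean'")
    tot = usage.total
    zero = tot.sum(axis=1) == 0
    if zero.any():
        warnings.warn(
            f"excluding {int(zero.sum())} individuals with no located activity",
            stacklevel=2,
        )
        tot = tot.loc[~zero]
    if len(tot) < 2:
        raise ValidationError("usage distance needs >= 2 active individuals")
    d = squareform(pdist(tot.to_numpy(dtype=float), metric=metric))
    return pd.DataFrame(d, index=tot.index, columns=tot.index)


@dataclass
class OrdinationResult:
    coords: pd.DataFrame  # items x k, centered at origin
    stress: float  # Kruskal stress-1
    n_iter: int
    converged: bool


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    bmat = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(bmat)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0, None)
    return vecs[:, order] * np.sqrt(lam)


def nmds(
    d,
    k: int = 2,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int | None = None,
) -> OrdinationResult:
    """Non-metric MDS minimizing Kruskal stress-1.

    Nonmetric SMACOF (iterative majorization with isotonic regression of the
    configuration distances on the dissimilarity ranks), initialized from
    classical metric scaling plus ``n_starts`` random restarts; the best
    configuration is returned, centered at the origin.
    """
    if isinstance(d, pd.DataFrame):
        labels = [str(i) for i in d.index]
        dm = d.to_numpy(dtype=float)
    else:
        dm = np.asarray(d, dtype=float)
        labels = [str(i) for i in range(dm.shape[0])]
    if dm.shape[0] < 3:
        raise ValidationError("nMDS needs >= 3 items")
    if not np.allclose(dm, dm.T) or not np.allclose(np.diag(dm), 0):
        raise ValidationError("nMDS needs a symmetric zero-diagonal matrix")

    rng = np.random.default_rng(seed)
    best = None
    inits = [_classical_mds(dm, k)] + [None] * max(0, n_starts)
    for init in inits:
        coords, stress, it = smacof(
            dm,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            random_state=int(rng.integers(2**31 - 1)),
            normalized_stress=True,
            return_n_iter=True,
        )
        if best is None or stress < best[1]:
            best = (coords, float(stress), int(it))
    coords, stress, it = best
    coords = coords - coords.mean(axis=0, keepdims=True)
    return OrdinationResult(
        coords=pd.DataFrame(
            coords, index=labels, columns=[f"dim{i+1}" for i in range(k)]
        ),
        stress=stress,
        n_iter=it,
        converged=it < max_iter,
    )
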