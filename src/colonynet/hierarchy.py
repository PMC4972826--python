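"""Dominance-hierarchy statistics and their randomization tests.

All statistics operate on the winner-by-loser frequency sociomatrix (or its
Appleby-binarized form) and come with Monte-Carlo significance tests:

* **directional consistency (DC)** — the excess of interactions flowing in
  each dyad's majority direction, ``sum(H - L) / sum(H + L)``;
* **Landau/de Vries linearity** — Landau's ``h`` with de Vries' modification
  ``h'`` that handles unknown and tied relationships, and the de Vries (1995)
  two-step randomization test;
* **David's scores and steepness** — dyadic-proportion dominance success and
  the absolute OLS slope of normalized David's scores against rank;
* **triangle transitivity** — the proportion ``Pt`` of complete triads that
  are transitive and its rescaling ``t.tri = 4 (Pt - 0.75)``;
* **I&SI ranking** — the order minimizing (number, strength) of dyads
  inconsistent with it.

Monte-Carlo p-values use the add-one convention
``p = (1 + #{null >= obs}) / (1 + n_rand)`` so that p is never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import ValidationError, as_matrix

__all__ = [
    "TransitivityResult",
    "DavidScores",
    "RankingResult",
    "HierarchySummary",
    "directional_consistency",
    "landau_h",
    "landau_h_prime",
    "david_scores",
    "steepness",
    "triangle_transitivity",
    "scale_transitivity",
    "isi_rank",
    "isi_score",
    "hierarchy_summary",
]


def mc_pvalue(null: np.ndarray, observed: float) -> float:
    """Add-one Monte-Carlo p-value for an upper-tail test."""
    null = np.asarray(null, dtype=float)
    return float((1 + np.sum(null >= observed)) / (1 + null.size))


def _dyad_counts(freq) -> tuple[np.ndarray, np.ndarray, int]:
    """Upper/lower triangle win counts per unordered dyad."""
    m, _ = as_matrix(freq)
    iu = np.triu_indices(m.shape[0], 1)
    return m[iu], m.T[iu], m.shape[0]


# ---------------------------------------------------------------------------
# Directional consistency


def directional_consistency(
    freq, n_rand: int = 10000, seed: int | None = None
) -> tuple[float, float]:
    """DC index and its direction-flip randomization p-value.

    The null flips each individual interaction's direction with a fair coin,
    which per dyad makes the win split Binomial(n_dyad, 1/2).
    """
    up, lo, _ = _dyad_counts(freq)
    tot = up + lo
    if tot.sum() == 0:
        raise ValidationError("directional consistency undefined: no interactions")
    dc = float(np.abs(up - lo).sum() / tot.sum())
    rng = np.random.default_rng(seed)
    nz = tot[tot > 0].astype(int)
    wins = rng.binomial(nz, 0.5, size=(n_rand, nz.size))
    dc_null = np.abs(2 * wins - nz).sum(axis=1) / nz.sum()
    return dc, mc_pvalue(dc_null, dc)


# ---------------------------------------------------------------------------
# Landau / de Vries linearity


def _h_from_v(v: np.ndarray, n: int) -> np.ndarray:
    """Landau's h from row dominance counts V_i (vectorized over leading axes)."""
    c = 12.0 / (n**3 - n)
    return c * np.square(v - (n - 1) / 2.0).sum(axis=-1)


def landau_h(binary) -> float:
    """Plain Landau h of a binary dominance matrix (ties/unknowns count 0)."""
    b, _ = as_matrix(binary)
    n = b.shape[0]
    if n < 3:
        raise ValidationError("Landau's h requires N >= 3")
    return float(_h_from_v(b.sum(axis=1), n))


def landau_h_prime(
    freq,
    n_rand: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """de Vries' modified linearity index h' with its two-step randomization p.

    Dyads without a strict winner — never-interacting pairs and pairs tied on
    wins (which the Appleby rule also leaves undirected) — carry no direction
    information and are conceptually imputed with a fair coin. The reported
    h' is the exact mean of Landau's h over all such imputations, which
    reduces to h on the 0.5-filled matrix plus the correction
    ``6u / (N^3 - N)`` for ``u`` undirected dyads.

    The p-value follows the two-step procedure: in each trial the undirected
    dyads are imputed at random (trial h'), a full random tournament of the
    same size is generated (null h), and p is the add-one proportion of trials
    whose null h reaches the trial h'.
    """
    m, _ = as_matrix(freq)
    n = m.shape[0]
    if n < 3:
        raise ValidationError("h' requires N >= 3")
    iu, ju = np.triu_indices(n, 1)
    up, lo = m[iu, ju], m[ju, iu]
    undirected = up == lo  # ties on wins, including never-interacting pairs
    u = int(undirected.sum())

    # base V: strict wins count 1; undirected dyads held at expectation 0.5
    v0 = np.zeros(n)
    np.add.at(v0, iu[up > lo], 1.0)
    np.add.at(v0, ju[lo > up], 1.0)
    v_exp = v0 + 0.5 * undirected @ _incidence(n, iu, ju)
    h_prime = float(_h_from_v(v_exp, n) + 6.0 * u / (n**3 - n))

    # two-step randomization
    rng = np.random.default_rng(seed)
    if u > 0:
        bits = rng.random((n_rand, u)) < 0.5
        inc_i = _onehot(iu[undirected], n)
        inc_j = _onehot(ju[undirected], n)
        v_obs = v0 + bits @ inc_i + (~bits) @ inc_j
    else:
        v_obs = np.broadcast_to(v0, (n_rand, n))
    h_obs = _h_from_v(v_obs, n)

    d = iu.size
    bits_r = rng.random((n_rand, d)) < 0.5
    v_rand = bits_r @ _onehot(iu, n) + (~bits_r) @ _onehot(ju, n)
    h_rand = _h_from_v(v_rand, n)
    p = float((1 + np.sum(h_rand >= h_obs)) / (1 + n_rand))
    return h_prime, p


def _onehot(idx: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((idx.size, n))
    out[np.arange(idx.size), idx] = 1.0
    return out


def _incidence(n: int, iu: np.ndarray, ju: np.ndarray) -> np.ndarray:
    inc = np.zeros((iu.size, n))
    inc[np.arange(iu.size), iu] = 1.0
    inc[np.arange(ju.size), ju] = 1.0
    return inc


# ---------------------------------------------------------------------------
# David's scores and steepness


@dataclass
class DavidScores:
    """Per-individual David's scores and the dyadic proportion matrix."""

    table: pd.DataFrame  # columns w, w2, l, l2, DS, NormDS
    P: pd.DataFrame
    dyadic: str = "Pij"

    @property
    def norm_ds(self) -> pd.Series:
        return self.table["NormDS"]


def _p_matrix(m: np.ndarray, dyadic: str) -> np.ndarray:
    tot = m + m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, m / np.where(tot > 0, tot, 1), 0.0)
    if dyadic == "Dij":
        # chance-corrected variant: shrink toward 0.5 by 1/(n_ij + 1)
        p = np.where(tot > 0, p - (p - 0.5) / (tot + 1), 0.0)
    elif dyadic != "Pij":
        raise ValidationError("dyadic must be 'Pij' or 'Dij'")
    np.fill_diagonal(p, 0.0)
    return p


def _ds_from_p(p: np.ndarray) -> dict[str, np.ndarray]:
    w = p.sum(axis=-1)
    l = p.sum(axis=-2)
    w2 = np.einsum("...ij,...j->...i", p, w)
    l2 = np.einsum("...ji,...j->...i", p, l)
    ds = w + w2 - l - l2
    return {"w": w, "w2": w2, "l": l, "l2": l2, "DS": ds}


def david_scores(freq, dyadic: str = "Pij") -> DavidScores:
    """David's scores from dyadic win proportions.

    ``DS = w + w2 - l - l2`` where ``w``/``l`` are summed win/loss proportions
    and ``w2``/``l2`` their success-weighted second-order forms;
    ``NormDS = (DS + N(N-1)/2) / N``.
    """
    m, roster = as_matrix(freq)
    n = m.shape[0]
    p = _p_matrix(m, dyadic)
    parts = _ds_from_p(p)
    parts["NormDS"] = (parts["DS"] + n * (n - 1) / 2.0) / n
    table = pd.DataFrame(parts, index=roster)
    return DavidScores(table=table, P=pd.DataFrame(p, index=roster, columns=roster),
                       dyadic=dyadic)


def _steepness_from_normds(normds: np.ndarray) -> np.ndarray:
    """|OLS slope| of descending-sorted NormDS against rank 1..N."""
    y = -np.sort(-normds, axis=-1)
    n = y.shape[-1]
    x = np.arange(1, n + 1, dtype=float)
    xc = x - x.mean()
    slope = (y * xc).sum(axis=-1) / (xc**2).sum()
    return np.abs(slope)


def steepness(
    freq, n_rand: int = 10000, seed: int | None = None, dyadic: str = "Pij"
) -> tuple[float, float]:
    """Hierarchy steepness with a direction-flip randomization p-value."""
    m, _ = as_matrix(freq)
    n = m.shape[0]
    if n < 3:
        raise ValidationError("steepness requires N >= 3")
    obs = float(_steepness_from_normds(david_scores(freq, dyadic).norm_ds.to_numpy()))
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, 1)
    tot = (m + m.T)[iu, ju].astype(int)
    wins = rng.binomial(tot, 0.5, size=(n_rand, tot.size))
    mats = np.zeros((n_rand, n, n))
    mats[:, iu, ju] = wins
    mats[:, ju, iu] = tot - wins
    p_null = np.stack([_p_matrix(mm, dyadic) for mm in mats])
    normds = (_ds_from_p(p_null)["DS"] + n * (n - 1) / 2.0) / n
    null = _steepness_from_normds(normds)
    return obs, mc_pvalue(null, obs)


# ---------------------------------------------------------------------------
# Triangle transitivity


@dataclass
class TransitivityResult:
    pt: float
    t_tri: float
    p: float
    n_random: int
    n_complete_triads: int


def scale_transitivity(pt: float) -> float:
    """Rescale a transitive-triad proportion: 0.75 (random) -> 0, 1 -> 1."""
    return 4.0 * (pt - 0.75)


def _triad_counts(b: np.ndarray) -> tuple[int, int]:
    rel = ((b + b.T) > 0).astype(float)
    complete = int(round(np.trace(rel @ rel @ rel) / 6.0))
    cyclic = int(round(np.trace(b @ b @ b) / 3.0))
    return complete, cyclic


def triangle_transitivity(
    binary, n_rand: int = 1000, seed: int | None = None
) -> TransitivityResult:
    """Proportion of transitive complete triads, scaled, with Monte-Carlo p.

    The null preserves which dyads have a dominance relation and randomizes
    each relation's orientation with a fair coin.
    """
    b, _ = as_matrix(binary)
    b = (b > 0).astype(float)
    n = b.shape[0]
    complete, cyclic = _triad_counts(b)
    if complete == 0:
        raise ValidationError("no complete triads: triangle transitivity undefined")
    pt = 1.0 - cyclic / complete
    t_obs = scale_transitivity(pt)

    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, 1)
    related = (b + b.T)[iu, ju] > 0
    ri, rj = iu[related], ju[related]
    bits = rng.random((n_rand, ri.size)) < 0.5
    mats = np.zeros((n_rand, n, n))
    mats[:, ri, rj] = bits
    mats[:, rj, ri] = ~bits
    cyc_null = np.einsum("rij,rjk,rki->r", mats, mats, mats) / 3.0
    t_null = scale_transitivity(1.0 - cyc_null / complete)
    return TransitivityResult(
        pt=float(pt),
        t_tri=float(t_obs),
        p=mc_pvalue(t_null, t_obs),
        n_random=n_rand,
        n_complete_triads=complete,
    )


# ---------------------------------------------------------------------------
# I&SI ranking


@dataclass
class RankingResult:
    ordering: list[str]  # ids from top to bottom rank
    inconsistencies: int  # I
    strength: int  # SI
    converged: bool
    restarts_used: int
    note: str = ""

    @property
    def ranks(self) -> dict[str, int]:
        """1-based rank per id (1 = most dominant)."""
        return {ind: k + 1 for k, ind in enumerate(self.ordering)}


def isi_score(binary, order: np.ndarray) -> tuple[int, int]:
    """(I, SI) of an ordering: inconsistent dyads and their rank distances."""
    b, _ = as_matrix(binary)
    bp = b[np.ix_(order, order)]
    low = np.tril(bp, -1)  # winner ranked below loser
    r, c = np.nonzero(low)
    return int(low.sum()), int((r - c).sum())


def isi_rank(
    binary,
    n_restarts: int = 20,
    max_sweeps: int = 1000,
    seed: int | None = None,
) -> RankingResult:
    """I&SI ranking by pairwise-swap descent from the David's-score order.

    Minimizes the pair ``(I, SI)`` lexicographically: sweeps over all position
    pairs, accepting any swap that strictly improves, with random restarts.
    The result can never be worse than the David's-score starting order.
    """
    b, roster = as_matrix(binary)
    b = (b > 0).astype(float)
    n = b.shape[0]
    if n < 2:
        raise ValidationError("isi_rank requires N >= 2")
    note = "" if b.sum() > 0 else "no relations"
    rng = np.random.default_rng(seed)

    ds = _ds_from_p(_p_matrix(b, "Pij"))["DS"]
    start = np.lexsort((np.arange(n), -ds))  # DS descending, roster tie-break

    dist = np.tril(np.subtract.outer(np.arange(n), np.arange(n)), -1)

    def evaluate(order: np.ndarray) -> tuple[int, int]:
        bp = b[np.ix_(order, order)]
        low = np.tril(bp, -1)
        return int(low.sum()), int((low * dist).sum())

    best_order, best = start.copy(), evaluate(start)
    converged = False
    restarts_used = 0
    for restart in range(max(1, n_restarts)):
        restarts_used = restart + 1
        order = start.copy() if restart == 0 else rng.permutation(n)
        score = evaluate(order)
        for _ in range(max_sweeps):
            improved = False
            for p in range(n - 1):
                for q in range(p + 1, n):
                    order[p], order[q] = order[q], order[p]
                    cand = evaluate(order)
                    if cand < score:
                        score = cand
                        improved = True
                    else:
                        order[p], order[q] = order[q], order[p]
            if not improved:
                converged = True
                break
        if score < best:
            best, best_order = score, order.copy()
        if best == (0, 0):
            break
    return RankingResult(
        ordering=[roster[i] for i in best_order],
        inconsistencies=best[0],
        strength=best[1],
        converged=converged,
        restarts_used=restarts_used,
        note=note,
    )


# ---------------------------------------------------------------------------
# Convenience summary


@dataclass
class HierarchySummary:
    h_prime: float
    h_prime_p: float
    steepness: float
    steepness_p: float
    dc: float
    dc_p: float
    n_rand: int


def hierarchy_summary(
    freq, n_rand: int = 10000, seed: int | None = None
) -> HierarchySummary:
    """h', steepness and DC with randomization p-values in one call."""
    s1, s2, s3 = np.random.default_rng(seed).spawn(3)
    hp, hp_p = landau_h_prime(freq, n_rand=n_rand, seed=s1)
    st, st_p = steepness(freq, n_rand=n_rand, seed=s2)
    dc, dc_p = directional_consistency(freq, n_rand=n_rand, seed=s3)
    return HierarchySummary(hp, hp_p, st, st_p, dc, dc_p, n_rand)
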