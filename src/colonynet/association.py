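"""Half-weight association indices and matrix-level association tests.

Census sightings give, for each pair (A, B) over all census periods, the
counts x (both seen, same vivarium), yAB (both seen, different vivaria), and
yA / yB (only one seen). The half-weight index

    HWI = x / (x + yAB + 0.5 (yA + yB))

corrects for partial observability and ranges from 0 (never associated) to 1
(always associated). Mice unseen in a period contribute to no count for that
period.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .community import CommunityResult
from .datamodel import CensusLog, ValidationError, as_matrix

__all__ = [
    "pair_association_counts",
    "hwi_matrix",
    "mantel_test",
    "within_between_test",
]


def _presence(census: CensusLog) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """(seen, vivarium) arrays of shape (periods, N)."""
    roster = list(census.roster)
    idx = {r: k for k, r in enumerate(roster)}
    periods = census.periods
    pidx = {p: k for k, p in enumerate(periods)}
    seen = np.zeros((len(periods), len(roster)), dtype=bool)
    viv = np.zeros((len(periods), len(roster)), dtype=int)
    for day, tp, v, ind in census.sightings[
        ["day", "timepoint", "vivarium", "id"]
    ].itertuples(index=False):
        p = pidx[(day, tp)]
        seen[p, idx[ind]] = True
        viv[p, idx[ind]] = v
    return seen, viv, roster


def pair_association_counts(census: CensusLog) -> dict[str, pd.DataFrame]:
    """Dyadic x, yAB, yA, yB count matrices over all census periods."""
    seen, viv, roster = _presence(census)
    both = seen[:, :, None] & seen[:, None, :]
    same = viv[:, :, None] == viv[:, None, :]
    x = (both & same).sum(axis=0).astype(float)
    y_ab = (both & ~same).sum(axis=0).astype(float)
    only_a = (seen[:, :, None] & ~seen[:, None, :]).sum(axis=0).astype(float)
    out = {
        "x": x,
        "yAB": y_ab,
        "yA": only_a,
        "yB": only_a.T,
    }
    return {
        k: pd.DataFrame(v, index=roster, columns=roster) for k, v in out.items()
    }


def hwi_matrix(census: CensusLog) -> pd.DataFrame:
    """Symmetric half-weight association index matrix.

    Dyads whose denominator is zero (neither ever seen) are NaN; the diagonal
    is NaN (self-association undefined).
    """
    if census.n_periods < 1:
        raise ValidationError("HWI requires at least one census period")
    counts = pair_association_counts(census)
    x = counts["x"].to_numpy()
    denom = x + counts["yAB"].to_numpy() + 0.5 * (
        counts["yA"].to_numpy() + counts["yB"].to_numpy()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        hwi = np.where(denom > 0, x / np.where(denom > 0, denom, 1.0), np.nan)
    np.fill_diagonal(hwi, np.nan)
    roster = list(census.roster)
    return pd.DataFrame(hwi, index=roster, columns=roster)


def _upper(m: np.ndarray) -> np.ndarray:
    return m[np.triu_indices(m.shape[0], 1)]


def mantel_test(
    m1,
    m2,
    n_perm: int = 1000,
    seed: int | None = None,
    method: str = "pearson",
) -> tuple[float, float]:
    """Mantel test between two symmetric matrices on the same roster.

    Correlates the off-diagonal upper triangles (Pearson by default, Spearman
    behind the flag); significance by jointly permuting rows and columns of
    the second matrix; two-sided add-one p on |r|. NaN entries (e.g. undefined
    dyads) are excluded pairwise.
    """
    a, ra = as_matrix(m1)
    b, rb = as_matrix(m2)
    if a.shape != b.shape or ra != rb:
        raise ValidationError("Mantel test requires matching rosters")

    def corr(x, y):
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if x.size < 3 or x.std() == 0 or y.std() == 0:
            raise ValidationError("Mantel test undefined: constant matrix")
        if method == "spearman":
            x = pd.Series(x).rank().to_numpy()
            y = pd.Series(y).rank().to_numpy()
        return float(np.corrcoef(x, y)[0, 1])

    ua = _upper(a)
    r_obs = corr(ua, _upper(b))
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(ua, _upper(b[np.ix_(perm, perm)]))
        if abs(r_p) >= abs(r_obs):
            count += 1
    return r_obs, float((1 + count) / (1 + n_perm))


def within_between_test(
    hwi,
    communities: CommunityResult,
    n_rand: int = 10000,
    seed: int | None = None,
) -> dict[str, float]:
    """Median within- minus between-community association, with label-
    permutation significance.

    Unassigned individuals are excluded. The null permutes community labels
    over the assigned individuals; p is the add-one proportion of null
    differences at least as large as observed.
    """
    h, roster = as_matrix(hwi)
    lab = np.array([communities.membership.get(r, "unassigned") for r in roster])
    keep = lab != "unassigned"
    names, counts = np.unique(lab[keep], return_counts=True)
    if len(names) < 2 or (counts < 2).any():
        raise ValidationError(
            "within/between test needs >= 2 communities with >= 2 members"
        )
    h = h[np.ix_(keep, keep)]
    lab = lab[keep]
    iu = np.triu_indices(h.shape[0], 1)
    vals = h[iu]
    same = (lab[iu[0]] == lab[iu[1]])
    ok = np.isfinite(vals)

    def stat(same_mask):
        w = vals[same_mask & ok]
        b = vals[~same_mask & ok]
        return np.median(w) - np.median(b)

    obs = stat(same)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_rand):
        perm = rng.permutation(lab)
        if stat(perm[iu[0]] == perm[iu[1]]) >= obs:
            count += 1
    out = {
        "difference": float(obs),
        "p": float((1 + count) / (1 + n_rand)),
        "median_between": float(np.median(vals[~same & ok])),
        "n_rand": n_rand,
    }
    for name in names:
        within_c = same & (lab[iu[0]] == name)
        out[f"median_within_{name}"] = float(np.median(vals[within_c & ok]))
    return out
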