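"""Directed-network structure and node-position metrics.

The dominance network is the Appleby-binarized sociomatrix viewed as a
directed graph (an edge i -> j means i dominates j). Network-level metrics
(density, average path length, Freeman centralizations, degree
assortativity, extreme-degree tests) describe how concentrated power is;
node-level metrics (degrees, closenesses, hub score) locate each individual.

Unreachable-pair conventions differ on purpose between the two statistics
that need one: closeness assigns unreachable targets a distance of N
(the convention of the classical sna software family), while average path
length substitutes the maximum finite geodesic (the network diameter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .datamodel import ValidationError, as_matrix
from .hierarchy import mc_pvalue

__all__ = [
    "density",
    "average_path_length",
    "degree_centralization",
    "closeness_centralization",
    "node_metrics",
    "hub_scores",
    "degree_assortativity",
    "extreme_degree_test",
    "correlate_node_measures",
    "holm_adjust",
    "NetworkSummary",
    "network_summary",
]


def _binary(binary) -> tuple[np.ndarray, list[str]]:
    b, roster = as_matrix(binary)
    return (b > 0).astype(float), roster


def density(binary) -> float:
    """Proportion of the N(N-1) possible directed ties that exist."""
    b, _ = _binary(binary)
    n = b.shape[0]
    if n < 2:
        raise ValidationError("density requires N >= 2")
    return float(b.sum() / (n * (n - 1)))


def _geodesics(b: np.ndarray) -> np.ndarray:
    return shortest_path(b, method="D", directed=True, unweighted=True)


def average_path_length(binary) -> float:
    """Mean directed geodesic over ordered pairs.

    Unreachable pairs are given the maximum finite geodesic (the diameter).
    """
    b, _ = _binary(binary)
    if b.sum() == 0:
        raise ValidationError("average path length undefined: no edges")
    d = _geodesics(b)
    n = b.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    diam = d[finite].max()
    d = np.where(np.isfinite(d), d, diam)
    return float(d[off].mean())


def _closeness(b: np.ndarray, mode: str) -> np.ndarray:
    """(N-1)/sum of distances; unreachable targets count distance N."""
    n = b.shape[0]
    d = _geodesics(b if mode == "out" else b.T)
    d = np.where(np.isfinite(d), d, float(n))
    np.fill_diagonal(d, 0.0)
    return (n - 1) / d.sum(axis=1)


def degree_centralization(binary, mode: str = "out") -> float:
    """Freeman degree centralization, normalized by the directed-star maximum
    (N-1)^2."""
    b, _ = _binary(binary)
    n = b.shape[0]
    if n < 3:
        raise ValidationError("centralization requires N >= 3")
    deg = b.sum(axis=1) if mode == "out" else b.sum(axis=0)
    return float((deg.max() - deg).sum() / (n - 1) ** 2)


def closeness_centralization(binary, mode: str = "out") -> float:
    """Freeman closeness centralization.

    Normalized by the same sum evaluated on a directed star with identical
    unreachable-handling: the star centre has closeness 1 and each leaf
    (N-1)/((N-1)N), giving a maximum of (N-1)^2/N.
    """
    b, _ = _binary(binary)
    n = b.shape[0]
    if n < 3:
        raise ValidationError("centralization requires N >= 3")
    c = _closeness(b, mode)
    star_max = (n - 1) ** 2 / n
    return float((c.max() - c).sum() / star_max)


def hub_scores(
    binary, max_iter: int = 1000, tol: float = 1e-12
) -> np.ndarray:
    """Kleinberg hub scores: principal eigenvector of A A^T, scaled to max 1.

    Computed by power iteration from a uniform start; if the leading
    eigenvalue is degenerate the iteration settles on the projection of the
    uniform vector onto the leading eigenspace (the HITS limit). Raises on
    non-convergence.
    """
    b, _ = _binary(binary)
    n = b.shape[0]
    m = b @ b.T
    x = np.full(n, 1.0 / np.sqrt(n))
    for it in range(max_iter):
        y = m @ x
        norm = np.linalg.norm(y)
        if norm == 0:
            raise ValidationError("hub scores undefined: A A^T annihilates all vectors")
        y /= norm
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    else:
        raise ValidationError(
            f"hub-score power iteration did not converge in {max_iter} steps"
        )
    x = np.abs(x)
    return x / x.max()


def node_metrics(binary, isi_order: list[str] | None = None) -> pd.DataFrame:
    """Per-individual degrees, closenesses and hub score (plus I&SI rank).

    Columns: ``out_degree, in_degree, out_closeness, in_closeness, hub_score``
    and, when an I&SI ordering is supplied, ``isi_rank``.
    """
    b, roster = _binary(binary)
    df = pd.DataFrame(
        {
            "out_degree": b.sum(axis=1).astype(int),
            "in_degree": b.sum(axis=0).astype(int),
            "out_closeness": _closeness(b, "out"),
            "in_closeness": _closeness(b, "in"),
            "hub_score": hub_scores(b),
        },
        index=roster,
    )
    if isi_order is not None:
        df["isi_rank"] = pd.Series(
            {ind: k + 1 for k, ind in enumerate(isi_order)}
        ).reindex(roster)
    return df


# ---------------------------------------------------------------------------
# Assortativity


def _edge_degree_corr(b: np.ndarray, mode: str) -> float:
    deg = b.sum(axis=1) if mode == "out" else b.sum(axis=0)
    src, dst = np.nonzero(b)
    x, y = deg[src], deg[dst]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def _random_gnm_directed(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    pairs = rng.choice(n * (n - 1), size=m, replace=False)
    src, off = divmod(pairs, n - 1)
    dst = off + (off >= src)
    b = np.zeros((n, n))
    b[src, dst] = 1.0
    return b


def degree_assortativity(
    binary,
    mode: str = "out",
    n_rand: int = 10000,
    seed: int | None = None,
    null: str = "rewire",
) -> tuple[float, float]:
    """Newman edge-wise degree assortativity with a randomization p-value.

    ``r`` correlates the chosen-mode degree of each edge's source and target.
    The default null redraws the same number of edges uniformly at random
    (fixed N and edge count); ``null="permute"`` instead permutes the degree
    labels over nodes while keeping the edge list.

    Returns ``(nan, nan)`` when endpoint degrees have zero variance
    (assortativity undefined).
    """
    b, _ = _binary(binary)
    n = b.shape[0]
    r_obs = _edge_degree_corr(b, mode)
    if np.isnan(r_obs):
        return np.nan, np.nan
    rng = np.random.default_rng(seed)
    m = int(b.sum())
    null_r = np.empty(n_rand)
    if null == "rewire":
        for k in range(n_rand):
            null_r[k] = _edge_degree_corr(_random_gnm_directed(n, m, rng), mode)
    elif null == "permute":
        deg = b.sum(axis=1) if mode == "out" else b.sum(axis=0)
        src, dst = np.nonzero(b)
        for k in range(n_rand):
            perm = rng.permutation(n)
            x, y = deg[perm[src]], deg[perm[dst]]
            null_r[k] = (
                np.nan if x.std() == 0 or y.std() == 0 else np.corrcoef(x, y)[0, 1]
            )
    else:
        raise ValidationError("null must be 'rewire' or 'permute'")
    null_r = null_r[~np.isnan(null_r)]
    return r_obs, mc_pvalue(null_r, r_obs)


# ---------------------------------------------------------------------------
# Extreme-degree Bernoulli-graph test


def extreme_degree_test(
    binary,
    n_random: int = 5000,
    replicates: int = 20,
    seed: int | None = None,
) -> dict[str, float]:
    """Are the maximum out-degree and minimum in-degree extreme for a
    Bernoulli graph of the same size and density?

    Per replicate, ``n_random`` directed Bernoulli graphs are drawn with the
    observed density; ``p_max`` is the (add-one) proportion whose maximum
    out-degree reaches the observed maximum, ``p_min`` the proportion whose
    minimum in-degree falls to the observed minimum. Mean and SD over
    replicates are reported.
    """
    b, _ = _binary(binary)
    n = b.shape[0]
    if n < 3:
        raise ValidationError("extreme-degree test requires N >= 3")
    p_edge = b.sum() / (n * (n - 1))
    obs_max_out = b.sum(axis=1).max()
    obs_min_in = b.sum(axis=0).min()
    rng = np.random.default_rng(seed)
    p_max = np.empty(replicates)
    p_min = np.empty(replicates)
    offdiag = ~np.eye(n, dtype=bool)
    for r in range(replicates):
        g = (rng.random((n_random, n, n)) < p_edge) & offdiag
        max_out = g.sum(axis=2).max(axis=1)
        min_in = g.sum(axis=1).min(axis=1)
        p_max[r] = (1 + np.sum(max_out >= obs_max_out)) / (1 + n_random)
        p_min[r] = (1 + np.sum(min_in <= obs_min_in)) / (1 + n_random)
    return {
        "p_max_out_mean": float(p_max.mean()),
        "p_max_out_sd": float(p_max.std(ddof=1)) if replicates > 1 else 0.0,
        "p_min_in_mean": float(p_min.mean()),
        "p_min_in_sd": float(p_min.std(ddof=1)) if replicates > 1 else 0.0,
        "n_random": n_random,
        "replicates": replicates,
    }


# ---------------------------------------------------------------------------
# Spearman correlations with Holm adjustment


def holm_adjust(pvals) -> np.ndarray:
    """Holm step-down adjustment of a vector of p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="holm")[1]


def correlate_node_measures(
    metrics: pd.DataFrame, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """All pairwise Spearman correlations among node measures (and optional
    per-individual covariates such as body mass or relative gene expression),
    with Holm-adjusted p-values.

    Constant columns are flagged and excluded. Returns a tidy frame with
    columns ``var1, var2, rho, p, p_holm``.
    """
    table = metrics.copy()
    if covariates is not None:
        table = table.join(covariates, how="left")
    if len(table) < 4:
        raise ValidationError("correlations require >= 4 individuals")
    dropped = [c for c in table.columns if table[c].nunique(dropna=True) <= 1]
    table = table.drop(columns=dropped)
    cols = list(table.columns)
    rows = []
    for a in range(len(cols)):
        for b_ in range(a + 1, len(cols)):
            sub = table[[cols[a], cols[b_]]].dropna()
            rho, p = spearmanr(sub[cols[a]], sub[cols[b_]])
            rows.append((cols[a], cols[b_], rho, p))
    out = pd.DataFrame(rows, columns=["var1", "var2", "rho", "p"])
    out["p_holm"] = holm_adjust(out["p"].to_numpy())
    out.attrs["excluded_constant"] = dropped
    return out


# ---------------------------------------------------------------------------
# Summary


@dataclass
class NetworkSummary:
    density: float
    average_path_length: float
    out_degree_centralization: float
    out_closeness_centralization: float
    r_out: float
    r_out_p: float
    r_in: float
    r_in_p: float
    extreme_degree: dict


def network_summary(
    binary, n_rand: int = 10000, n_random_graphs: int = 5000,
    replicates: int = 20, seed: int | None = None,
) -> NetworkSummary:
    """All network-level hierarchy diagnostics in one call."""
    rngs = np.random.default_rng(seed).spawn(3)
    r_out, p_out = degree_assortativity(binary, "out", n_rand, rngs[0])
    r_in, p_in = degree_assortativity(binary, "in", n_rand, rngs[1])
    return NetworkSummary(
        density=density(binary),
        average_path_length=average_path_length(binary),
        out_degree_centralization=degree_centralization(binary, "out"),
        out_closeness_centralization=closeness_centralization(binary, "out"),
        r_out=r_out,
        r_out_p=p_out,
        r_in=r_in,
        r_in_p=p_in,
        extreme_degree=extreme_degree_test(
            binary, n_random_graphs, replicates, rngs[2]
        ),
    )
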