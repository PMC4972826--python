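"""Girvan–Newman community structure with bootstrap comembership consensus.

The agonistic network is symmetrized (wins + losses per pair) and communities
are found by iteratively removing the edge with the highest betweenness,
evaluating weighted modularity Q at every stage of the removal sequence and
keeping the partition that maximizes Q. The default edge score is shortest-
path betweenness divided by edge weight, so weak ties carrying much traffic
— the community boundaries — are removed first.

Confidence in membership comes from bootstrap resampling of the raw events:
each replicate resamples events with replacement, re-detects communities, and
the proportion of replicates in which two individuals co-occur in a community
forms the comembership matrix. Consensus communities are the Girvan–Newman
partition of that matrix, with weakly attached individuals left unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd

from .datamodel import EventLog, ValidationError, as_matrix

__all__ = [
    "CommunityResult",
    "modularity",
    "girvan_newman",
    "bootstrap_comembership",
    "consensus_communities",
]


@dataclass
class CommunityResult:
    """Partition of the roster with its modularity and removal dendrogram."""

    membership: dict[str, str]  # id -> community label or "unassigned"
    q_max: float
    dendrogram: list[tuple[str, str]] = field(repr=False)  # edge-removal order
    sizes: dict[str, int] = field(default_factory=dict)

    def labels(self, roster: list[str]) -> np.ndarray:
        return np.array([self.membership[r] for r in roster])

    @property
    def communities(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for ind, lab in self.membership.items():
            out.setdefault(lab, []).append(ind)
        return out


def modularity(weights, partition: np.ndarray) -> float:
    """Weighted Newman modularity Q of a labelled partition.

    ``Q = (1/2m) sum_ij [A_ij - k_i k_j / 2m] delta(c_i, c_j)``.
    """
    a, _ = as_matrix(weights)
    k = a.sum(axis=1)
    two_m = a.sum()
    if two_m == 0:
        raise ValidationError("modularity undefined on an empty graph")
    same = np.equal.outer(partition, partition)
    return float(((a - np.outer(k, k) / two_m) * same).sum() / two_m)


def _components_labels(g: ig.Graph) -> np.ndarray:
    return np.asarray(g.connected_components().membership)


def girvan_newman(s, betweenness: str = "newman") -> CommunityResult:
    """Girvan–Newman partition of a symmetric interaction matrix.

    Removes the highest-scoring edge (ties broken toward the smallest
    (row, column) pair), re-evaluating after each removal, and returns the
    stage of maximum weighted modularity. Edge scores:

    * ``"newman"`` (default) — shortest-path edge betweenness divided by the
      edge weight, the canonical weighted Girvan–Newman rule: weak ties that
      carry much traffic are the community boundaries;
    * ``"length"`` — betweenness computed with 1/weight as edge length;
    * ``"unweighted"`` — plain edge betweenness.
    """
    a, roster = as_matrix(s)
    if not np.allclose(a, a.T):
        raise ValidationError("girvan_newman expects a symmetric matrix")
    if (a < 0).any():
        raise ValidationError("negative interaction weights")
    if betweenness not in ("newman", "length", "unweighted"):
        raise ValidationError("betweenness must be newman|length|unweighted")
    n = a.shape[0]
    iu, ju = np.nonzero(np.triu(a, 1))
    if iu.size == 0:
        raise ValidationError("girvan_newman: empty graph")
    g = ig.Graph(n=n, edges=list(zip(iu.tolist(), ju.tolist())))
    g.es["weight"] = a[iu, ju].tolist()
    g.es["length"] = (1.0 / a[iu, ju]).tolist()

    best_part = _components_labels(g)
    best_q = modularity(a, best_part)
    removal: list[tuple[str, str]] = []
    while g.ecount() > 0:
        if betweenness == "newman":
            eb = np.asarray(g.edge_betweenness()) / np.asarray(g.es["weight"])
        elif betweenness == "length":
            eb = np.asarray(g.edge_betweenness(weights="length"))
        else:
            eb = np.asarray(g.edge_betweenness())
        cand = np.flatnonzero(eb >= eb.max() - 1e-12)
        ends = [tuple(sorted(g.es[int(e)].tuple)) for e in cand]
        pick = int(cand[int(np.argmin([e[0] * n + e[1] for e in ends]))])
        u, v = sorted(g.es[pick].tuple)
        removal.append((roster[u], roster[v]))
        g.delete_edges(pick)
        part = _components_labels(g)
        q = modularity(a, part)
        if q > best_q + 1e-12:
            best_q, best_part = q, part
    return _as_result(best_part, best_q, roster, removal)


def _as_result(
    part: np.ndarray, q: float, roster: list[str], removal: list
) -> CommunityResult:
    # label communities A, B, C... by decreasing size (roster order tie-break)
    labels_ids: dict[int, list[str]] = {}
    for idx, c in enumerate(part):
        labels_ids.setdefault(int(c), []).append(roster[idx])
    ordered = sorted(labels_ids.values(), key=lambda ids: (-len(ids), ids[0]))
    membership: dict[str, str] = {}
    for k, ids in enumerate(ordered):
        name = chr(ord("A") + k) if k < 26 else f"C{k}"
        for ind in ids:
            membership[ind] = name
    sizes = {name: len(ids) for name, ids in
             zip([membership[ids[0]] for ids in ordered], ordered)}
    return CommunityResult(membership=membership, q_max=float(q),
                           dendrogram=removal, sizes=sizes)


def bootstrap_comembership(
    log: EventLog, n_boot: int = 1000, seed: int | None = None
) -> pd.DataFrame:
    """Proportion of bootstrap replicates placing each pair in one community.

    Each replicate resamples the raw agonistic events with replacement to the
    original count, rebuilds the symmetrized matrix and reruns Girvan–Newman.
    Individuals isolated in a replicate sit in singleton components and hence
    co-occur with nobody. Diagonal is 1 by construction.
    """
    if log.n_events == 0:
        raise ValidationError("bootstrap requires at least one event")
    rng = np.random.default_rng(seed)
    roster = list(log.roster)
    n = len(roster)
    counts = np.zeros((n, n), dtype=float)
    idx_of = {r: k for k, r in enumerate(roster)}
    wi = log.events["winner"].map(idx_of).to_numpy()
    li = log.events["loser"].map(idx_of).to_numpy()
    n_ev = len(wi)
    for _ in range(n_boot):
        take = rng.integers(0, n_ev, size=n_ev)
        freq = np.zeros((n, n))
        np.add.at(freq, (wi[take], li[take]), 1.0)
        s = pd.DataFrame(freq + freq.T, index=roster, columns=roster)
        part = girvan_newman(s)
        lab = part.labels(roster)
        counts += np.equal.outer(lab, lab)
    com = counts / n_boot
    np.fill_diagonal(com, 1.0)
    return pd.DataFrame(com, index=roster, columns=roster)


def consensus_communities(
    comembership: pd.DataFrame, assign_threshold: float = 0.5
) -> CommunityResult:
    """Girvan–Newman on the comembership matrix, with an unassigned set.

    An individual is unassigned when its mean comembership with the members
    of every detected community falls below ``assign_threshold``.
    """
    c, roster = as_matrix(comembership)
    work = c.copy()
    np.fill_diagonal(work, 0.0)
    result = girvan_newman(pd.DataFrame(work, index=roster, columns=roster))
    lab = result.labels(roster)
    unassigned = []
    for i, ind in enumerate(roster):
        attachments = []
        for name in set(lab):
            members = [j for j in range(len(roster)) if lab[j] == name and j != i]
            if members:
                attachments.append(work[i, members].mean())
        if attachments and max(attachments) < assign_threshold:
            unassigned.append(ind)
    membership = dict(result.membership)
    for ind in unassigned:
        membership[ind] = "unassigned"
    # relabel remaining communities by decreasing size
    part = np.array(
        [membership[r] for r in roster], dtype=object
    )
    keep = part != "unassigned"
    labels_ids: dict[str, list[str]] = {}
    for r, l in zip(np.array(roster)[keep], part[keep]):
        labels_ids.setdefault(l, []).append(r)
    ordered = sorted(labels_ids.values(), key=lambda ids: (-len(ids), ids[0]))
    final: dict[str, str] = {r: "unassigned" for r in roster}
    for k, ids in enumerate(ordered):
        name = chr(ord("A") + k) if k < 26 else f"C{k}"
        for ind in ids:
            final[ind] = name
    sizes = {}
    for r, l in final.items():
        sizes[l] = sizes.get(l, 0) + 1
    return CommunityResult(
        membership=final,
        q_max=result.q_max,
        dendrogram=result.dendrogram,
        sizes=sizes,
    )
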