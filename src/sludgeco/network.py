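"""Co-occurrence network inference and cross-plant consensus.

Two complementary routes are built per plant and intersected:

* Spearman rank correlations between taxa (mid-ranks, t-approximation
  p-values) screened at p < 0.05 on taxa above 0.01% mean relative
  abundance, then re-screened at p < 0.01 for the intersection step.
* Neighborhood-selection ("mb") conditional-dependence estimation on
  CLR-transformed counts: per-node lasso regressions over a 20-value
  penalty path, with the penalty chosen by StARS stability selection.

Edges surviving both methods in at least ``min_plants`` plants, with
consistent sign and at least one endpoint in the core/guild set, form
the consensus network.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path

from .tables import OtuTable, relative_abundance


@dataclass
class EdgeRecord:
    """One association between two taxa (unordered, ``taxon_a < taxon_b``)."""

    taxon_a: str
    taxon_b: str
    rho: float
    p_value: float
    methods: frozenset[str] = frozenset({"spearman"})
    plants: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.taxon_a == self.taxon_b:
            raise ValueError("self-edges not allowed")
        if self.taxon_a > self.taxon_b:
            self.taxon_a, self.taxon_b = self.taxon_b, self.taxon_a
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError(f"|rho| > 1: {self.rho}")

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.taxon_a, self.taxon_b))

    @property
    def sign(self) -> str:
        return "+" if self.rho >= 0 else "-"


@dataclass
class ConsensusNetwork:
    """Cross-plant consensus graph with provenance."""

    edges: list[EdgeRecord]
    core_taxa: frozenset[str]
    guild_taxa: frozenset[str]
    provenance: dict = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.taxon_a)
            seen.setdefault(e.taxon_b)
        return list(seen)

    def node_frequency(self) -> dict[str, int]:
        """Relationship frequency per node (degree in the consensus)."""
        freq: dict[str, int] = {}
        for e in self.edges:
            freq[e.taxon_a] = freq.get(e.taxon_a, 0) + 1
            freq[e.taxon_b] = freq.get(e.taxon_b, 0) + 1
        return freq


# ---------------------------------------------------------------------------
# Spearman route


def _exact_spearman_p(rho: float, n: int) -> float:
    """Two-sided exact permutation p for small n (no ties assumed)."""
    base = np.arange(n, dtype=float)
    target = abs(rho)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = stats.pearsonr(base, np.asarray(perm, dtype=float)).statistic
        if abs(r) >= target - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_network(
    table: OtuTable,
    min_mean_rel: float = 1e-4,
    alpha: float = 0.05,
    exact_small_n: bool = False,
) -> list[EdgeRecord]:
    """All-pairs Spearman network on the >``min_mean_rel`` abundance screen.

    Correlations use mid-ranks with the tie-corrected t-approximation for
    two-sided p-values; edges with p < ``alpha`` are kept.  Zero-variance
    taxa are excluded with a warning.  ``exact_small_n`` switches to the
    exact permutation null for n <= 10 samples.
    """
    if table.n_samples < 4:
        raise ValueError("Spearman network needs at least 4 samples")
    rel = relative_abundance(table)
    mean_rel = rel.mean(axis=1)
    rel = rel.loc[mean_rel > min_mean_rel]
    variances = rel.var(axis=1)
    constant = variances[variances == 0].index.tolist()
    if constant:
        warnings.warn(f"zero-variance taxa excluded from Spearman network: {constant}", stacklevel=2)
        rel = rel.drop(index=constant)
    ids = list(rel.index)
    if len(ids) < 2:
        return []
    rho, pval = stats.spearmanr(rel.to_numpy(), axis=1)
    rho = np.atleast_2d(rho)
    pval = np.atleast_2d(pval)
    n = table.n_samples
    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r, p = float(rho[i, j]), float(pval[i, j])
            if exact_small_n and n <= 10:
                p = _exact_spearman_p(r, n)
            if p < alpha:
                edges.append(EdgeRecord(ids[i], ids[j], rho=r, p_value=p))
    return edges


# ---------------------------------------------------------------------------
# CLR + neighborhood selection (mb) route


def clr_transform(table: OtuTable, pseudocount: float = 1.0) -> pd.DataFrame:
    """Centered log-ratio transform per sample: ln(c + k) minus the
    per-sample mean over taxa.  Columns (samples) sum to zero."""
    logc = np.log(table.counts.to_numpy(dtype=float) + pseudocount)
    z = logc - logc.mean(axis=0, keepdims=True)
    return pd.DataFrame(z, index=table.counts.index, columns=table.counts.columns)


def _neighborhood_adjacency(z: np.ndarray, lams: np.ndarray) -> np.ndarray:
    """OR-rule adjacency along a penalty path.

    ``z``: samples x taxa CLR matrix (columns centered by caller);
    returns a boolean array (len(lams), p, p).
    """
    n, p = z.shape
    adj = np.zeros((len(lams), p, p), dtype=bool)
    for j in range(p):
        X = np.delete(z, j, axis=1)
        y = z[:, j]
        # sklearn path wants decreasing alphas; ours are decreasing already
        with warnings.catch_warnings():
            # small-n fits at the dense end of the path may stop at the
            # iteration cap; the selected-edge pattern is already stable
            warnings.simplefilter("ignore")
            _, coefs, _ = lasso_path(X, y, alphas=lams, max_iter=5000)
        nz = coefs != 0  # (p-1, n_lams)
        others = np.delete(np.arange(p), j)
        for li in range(len(lams)):
            nbrs = others[nz[:, li]]
            adj[li, j, nbrs] = True
    return adj | adj.transpose(0, 2, 1)  # OR symmetrization


def mb_network(
    table: OtuTable,
    lambda_path: int = 20,
    lambda_min_ratio: float = 0.01,
    stars_B: int = 50,
    stars_beta: float = 0.05,
    subsample_ratio: float = 0.8,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> set[frozenset[str]]:
    """Sparse conditional-dependence graph by neighborhood selection.

    Per node, a lasso regression of its CLR column on all others over a
    log-spaced ``lambda_path``-value penalty path from λ_max (the largest
    absolute empirical covariance between CLR columns) down to
    ``lambda_min_ratio``·λ_max.  The penalty is chosen by StARS:
    ``stars_B`` subsamples of ⌊``subsample_ratio``·n⌋ samples without
    replacement; per-λ instability D(λ) = mean over node pairs of
    2·θ̂(1−θ̂) with θ̂ the cross-subsample edge frequency; the selected λ
    is the densest (smallest) whose monotonized instability ≤
    ``stars_beta``.  The returned graph is the full-data refit at that λ
    with OR symmetrization.
    """
    if table.n_samples < 6:
        raise ValueError("mb network needs at least 6 samples")
    z = clr_transform(table, pseudocount=pseudocount).to_numpy().T  # samples x taxa
    ids = np.array(table.taxon_ids)
    keep = z.std(axis=0) > 0
    dropped = ids[~keep].tolist()
    if dropped:
        warnings.warn(f"constant CLR columns excluded from mb network: {dropped}", stacklevel=2)
    z = z[:, keep]
    ids = ids[keep]
    n, p = z.shape
    if p < 2:
        return set()
    zc = z - z.mean(axis=0, keepdims=True)
    cov = (zc.T @ zc) / n
    lam_max = np.abs(cov - np.diag(np.diag(cov))).max()
    if lam_max <= 0:
        return set()
    lams = np.logspace(np.log10(lam_max), np.log10(lam_max * lambda_min_ratio), lambda_path)

    rng = np.random.default_rng(seed)
    b_size = int(subsample_ratio * n)
    theta = np.zeros((lambda_path, p, p))
    for _ in range(stars_B):
        idx = rng.choice(n, size=b_size, replace=False)
        zb = z[idx]
        zb = zb - zb.mean(axis=0, keepdims=True)
        theta += _neighborhood_adjacency(zb, lams)
    theta /= stars_B
    iu = np.triu_indices(p, 1)
    instability = (2 * theta * (1 - theta))[:, iu[0], iu[1]].mean(axis=1)
    # monotonize from the sparse (large λ) end
    mono = np.maximum.accumulate(instability)
    admissible = np.nonzero(mono <= stars_beta)[0]
    sel = admissible[-1] if len(admissible) else 0

    adj = _neighborhood_adjacency(zc, lams)[sel]
    edges = {
        frozenset((ids[i], ids[j]))
        for i, j in zip(*np.nonzero(np.triu(adj, 1)))
    }
    return edges


def intersect_methods(
    spearman_edges: Sequence[EdgeRecord],
    mb_edges: Iterable[frozenset[str]],
) -> list[EdgeRecord]:
    """Keep Spearman edges whose unordered pair also appears in the mb
    graph; rho/p/sign carry over from the Spearman side."""
    mb_set = set(mb_edges)
    sp_universe = {t for e in spearman_edges for t in (e.taxon_a, e.taxon_b)}
    mb_universe = {t for e in mb_set for t in e}
    if sp_universe and mb_universe and not (sp_universe & mb_universe):
        raise ValueError("Spearman and mb edge sets share no taxa; were they built on the same table?")
    out = []
    for e in spearman_edges:
        if e.pair in mb_set:
            out.append(
                EdgeRecord(
                    e.taxon_a, e.taxon_b, rho=e.rho, p_value=e.p_value,
                    methods=e.methods | {"mb"}, plants=e.plants,
                )
            )
    return out


# ---------------------------------------------------------------------------
# core taxa and consensus


def core_taxa(table: OtuTable, prevalence: float = 0.8, min_rel: float = 1e-3) -> set[str]:
    """Taxa above ``min_rel`` relative abundance in strictly more than a
    ``prevalence`` fraction of samples (both thresholds strict)."""
    rel = relative_abundance(table)
    frac = (rel > min_rel).mean(axis=1)
    return set(rel.index[frac > prevalence])


def cross_plant_consensus(
    per_plant_edges: Mapping[str, Sequence[EdgeRecord]],
    core_sets: Mapping[str, Iterable[str]] | Iterable[str] = (),
    guild_sets: Mapping[str, Iterable[str]] | Iterable[str] = (),
    min_plants: int = 2,
    require_sign_agreement: bool = True,
    require_both_endpoints: bool = False,
) -> ConsensusNetwork:
    """Consensus edges across plants.

    A pair is kept when it appears (with a consistent sign when
    ``require_sign_agreement``) in at least ``min_plants`` per-plant edge
    lists and has at least one endpoint (both, if
    ``require_both_endpoints``) in the union of core and guild taxa.
    The mean rho across supporting plants is recorded.
    """
    if len(per_plant_edges) < 2:
        raise ValueError("consensus needs at least 2 plants")

    def _union(sets) -> frozenset[str]:
        if isinstance(sets, Mapping):
            return frozenset(t for s in sets.values() for t in s)
        return frozenset(sets)

    core = _union(core_sets)
    guild = _union(guild_sets)
    privileged = core | guild

    by_pair: dict[tuple[frozenset[str], str], list[tuple[str, EdgeRecord]]] = {}
    for plant, edges in per_plant_edges.items():
        for e in edges:
            key = (e.pair, e.sign if require_sign_agreement else "*")
            by_pair.setdefault(key, []).append((plant, e))

    out = []
    for (pair, _sign), hits in sorted(
        by_pair.items(), key=lambda kv: tuple(sorted(kv[0][0]))
    ):
        plants = {plant for plant, _ in hits}
        if len(plants) < min_plants:
            continue
        a, b = sorted(pair)
        in_priv = (a in privileged) + (b in privileged)
        if require_both_endpoints and in_priv < 2:
            continue
        if not require_both_endpoints and in_priv < 1:
            continue
        rho = float(np.mean([e.rho for _, e in hits]))
        pval = float(np.median([e.p_value for _, e in hits]))
        methods = frozenset().union(*(e.methods for _, e in hits))
        out.append(EdgeRecord(a, b, rho=rho, p_value=pval, methods=methods, plants=frozenset(plants)))
    return ConsensusNetwork(
        edges=out,
        core_taxa=core,
        guild_taxa=guild,
        provenance={
            "min_plants": min_plants,
            "require_sign_agreement": require_sign_agreement,
            "require_both_endpoints": require_both_endpoints,
            "per_plant_edge_counts": {k: len(v) for k, v in per_plant_edges.items()},
        },
    )


# ---------------------------------------------------------------------------
# statistics and export


def to_graph(edges: Sequence[EdgeRecord]) -> nx.Graph:
    g = nx.Graph()
    for e in edges:
        g.add_edge(
            e.taxon_a,
            e.taxon_b,
            rho=e.rho,
            sign=e.sign,
            p_value=e.p_value,
            methods=",".join(sorted(e.methods)),
            plants=",".join(sorted(e.plants)),
        )
    return g


def network_stats(edges: Sequence[EdgeRecord]) -> dict:
    """Node/edge counts, positive-edge fraction, mean degree, and Newman
    modularity with greedy agglomerative module detection (unsigned)."""
    g = to_graph(edges)
    n_nodes, n_edges = g.number_of_nodes(), g.number_of_edges()
    if n_edges == 0:
        return {
            "n_nodes": 0, "n_edges": 0, "positive_fraction": 0.0,
            "mean_degree": 0.0, "modularity": None, "n_modules": 0, "modules": [],
        }
    positive = sum(1 for e in edges if e.sign == "+")
    communities = list(nx.community.greedy_modularity_communities(g))
    q = nx.community.modularity(g, communities)
    return {
        "n_nodes": n_nodes,
        "n_edges": n_edges,
        "positive_fraction": positive / len(edges),
        "mean_degree": 2 * n_edges / n_nodes,
        "modularity": q,
        "n_modules": len(communities),
        "modules": [sorted(c) for c in communities],
    }


def export_graph(
    network: ConsensusNetwork | Sequence[EdgeRecord],
    path,
    fmt: str = "graphml",
) -> None:
    """Write GraphML or GEXF with guild/core flags and relationship
    frequency as node attributes."""
    if isinstance(network, ConsensusNetwork):
        g = to_graph(network.edges)
        freq = network.node_frequency()
        for node in g.nodes:
            g.nodes[node]["core"] = node in network.core_taxa
            g.nodes[node]["guild"] = node in network.guild_taxa
            g.nodes[node]["relationship_frequency"] = freq.get(node, 0)
    else:
        g = to_graph(network)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "gexf":
        nx.write_gexf(g, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
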