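"""Synthetic data generators mirroring the statistical structure of an
activated-sludge amplicon survey.

Four generators cover the assumptions of the downstream stages:

* :func:`simulate_neutral_community` — local communities whose per-taxon
  marginal relative abundance follows Beta(Nmp, Nm(1-p)), the stationary
  distribution of the Sloan neutral model, realized jointly as a
  Dirichlet so compositions close exactly.
* :func:`simulate_graph_community` — compositional counts driven by a
  latent Gaussian with a known sparse conditional-dependence graph, for
  scoring network-recovery.
* :func:`generate_taxonomy_and_guilds` — synthetic Silva-style lineages
  with planted functional-guild genera.
* :func:`generate_reference_set` — query/reference FASTA pairs with a
  known exact-matchable fraction for the genome-sequenced-proportion
  statistics.

All generators are pure functions of their arguments and the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import OtuTable, TaxonomyTable, format_lineage

#: log-series shape parameter for the default metacommunity: with 3,000
#: taxa roughly half fall below a 1/25,000 detection limit, emulating the
#: long rare tail of activated-sludge communities.
LOGSERIES_THETA = 0.9999


@dataclass
class NeutralSimSpec:
    """Design of a neutral-community simulation."""

    S: int = 3000
    n_samples: int = 13
    N: int = 25000
    m: float = 0.08356  # Nm = 2089 at N = 25,000
    metacommunity: str = "logseries"  # or "lognormal"
    theta: float = LOGSERIES_THETA
    lognorm_mu: float = 0.0
    lognorm_sigma: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValueError("S must be >= 2")
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0 < self.m <= 1:
            raise ValueError(f"migration rate m must be in (0, 1], got {self.m}")
        if self.metacommunity not in ("logseries", "lognormal"):
            raise ValueError(f"unknown metacommunity {self.metacommunity!r}")


def metacommunity_abundances(spec: NeutralSimSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw and normalize metacommunity relative abundances p."""
    if spec.metacommunity == "logseries":
        raw = stats.logser.rvs(spec.theta, size=spec.S, random_state=rng).astype(float)
    else:
        raw = rng.lognormal(spec.lognorm_mu, spec.lognorm_sigma, size=spec.S)
    return raw / raw.sum()


def simulate_neutral_community(spec: NeutralSimSpec) -> tuple[OtuTable, np.ndarray]:
    """Simulate an OTU table under the Sloan neutral model.

    Per sample the composition x is Dirichlet(Nm * p), giving each taxon
    the Beta(Nmp, Nm(1-p)) marginal the model assumes, and N reads are
    drawn multinomially from x.

    Returns the table and the true metacommunity abundance vector p.
    """
    rng = np.random.default_rng(spec.seed)
    p = metacommunity_abundances(spec, rng)
    nm = spec.N * spec.m
    counts = np.empty((spec.S, spec.n_samples), dtype=np.int64)
    for j in range(spec.n_samples):
        # gamma representation of the Dirichlet; all-zero draws cannot
        # occur for nm*p > 0 but guard against float underflow anyway
        g = rng.gamma(np.maximum(nm * p, 1e-300))
        total = g.sum()
        if total <= 0:  # pragma: no cover - underflow guard
            g[:] = p
            total = 1.0
        counts[:, j] = rng.multinomial(spec.N, g / total)
    table = OtuTable(
        pd.DataFrame(
            counts,
            index=[f"OTU_{i + 1}" for i in range(spec.S)],
            columns=[f"S{j + 1}" for j in range(spec.n_samples)],
        ),
        depth_note=spec.N,
    )
    table.counts.index.name = "#OTU ID"
    return table, p


# ---------------------------------------------------------------------------
# graph-structured communities


@dataclass
class GraphSimSpec:
    """Design of a latent-Gaussian compositional simulation with a known
    conditional-dependence graph."""

    p: int = 50
    n_samples: int = 200
    graph: str | Sequence[tuple[int, int]] = "chain"  # chain | band | random | edge list
    density: float = 0.04  # for graph="random"
    strength: float = 0.3  # off-diagonal precision magnitude
    N: int = 25000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p < 2:
            raise ValueError("need at least 2 taxa")
        if isinstance(self.graph, str) and self.graph not in ("chain", "band", "random", "empty"):
            raise ValueError(f"unknown graph kind {self.graph!r}")


def _edges_for(spec: GraphSimSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    if not isinstance(spec.graph, str):
        edges = [(min(a, b), max(a, b)) for a, b in spec.graph]
        if any(a == b for a, b in edges):
            raise ValueError("self-loops not allowed")
        return sorted(set(edges))
    if spec.graph == "empty":
        return []
    if spec.graph == "chain":
        return [(i, i + 1) for i in range(spec.p - 1)]
    if spec.graph == "band":
        return [(i, j) for i in range(spec.p) for j in (i + 1, i + 2) if j < spec.p]
    n_possible = spec.p * (spec.p - 1) // 2
    k = int(round(spec.density * n_possible))
    all_pairs = [(i, j) for i in range(spec.p) for j in range(i + 1, spec.p)]
    idx = rng.choice(n_possible, size=k, replace=False)
    return sorted(all_pairs[i] for i in idx)


def simulate_graph_community(spec: GraphSimSpec) -> tuple[OtuTable, set[frozenset[str]]]:
    """Simulate compositional counts from a sparse-precision latent Gaussian.

    The precision matrix has unit diagonal and ``-strength`` on graph
    edges; latent samples are mapped to compositions by softmax and to
    counts by a multinomial at depth N.  Returns the table and the true
    edge set as unordered taxon-id pairs.
    """
    rng = np.random.default_rng(spec.seed)
    edges = _edges_for(spec, rng)
    omega = np.eye(spec.p)
    for a, b in edges:
        omega[a, b] = omega[b, a] = -spec.strength
    eigmin = np.linalg.eigvalsh(omega)[0]
    if eigmin <= 1e-8:
        raise ValueError(
            f"precision matrix not positive definite (min eigenvalue {eigmin:.3g}); "
            "reduce strength or density"
        )
    sigma = np.linalg.inv(omega)
    chol = np.linalg.cholesky(sigma)
    z = rng.standard_normal((spec.n_samples, spec.p)) @ chol.T
    # softmax per sample -> composition -> multinomial counts
    z = z - z.max(axis=1, keepdims=True)
    comp = np.exp(z)
    comp /= comp.sum(axis=1, keepdims=True)
    counts = np.empty((spec.p, spec.n_samples), dtype=np.int64)
    for j in range(spec.n_samples):
        counts[:, j] = rng.multinomial(spec.N, comp[j])
    ids = [f"OTU_{i + 1}" for i in range(spec.p)]
    table = OtuTable(
        pd.DataFrame(counts, index=ids, columns=[f"S{j + 1}" for j in range(spec.n_samples)]),
        depth_note=spec.N,
    )
    table.counts.index.name = "#OTU ID"
    true_edges = {frozenset((ids[a], ids[b])) for a, b in edges}
    return table, true_edges


# ---------------------------------------------------------------------------
# taxonomy / guild fixtures

#: genera planted per guild (one representative per call cycles this list)
GUILD_GENERA: dict[str, list[str]] = {
    "AOB": ["Nitrosomonas", "oc32", "Ellin6067", "DSSD61", "mle1-7", "966-1"],
    "NOB": ["Nitrospira", "Nitrobacter", "Nitrotoga"],
    "PAO": ["Candidatus Accumulibacter", "Tetrasphaera"],
    "BFB": ["Gordonia", "Acinetobacter", "Thiothrix", "Mycobacterium"],
    "anammox": ["Candidatus Brocadia"],
}

_BACKGROUND_PHYLA = [
    "Proteobacteria", "Bacteroidetes", "Chloroflexi", "Patescibacteria",
    "Actinobacteria", "Acidobacteria", "Nitrospirae",
]

_GUILD_LINEAGE_HEAD: dict[str, tuple[str, ...]] = {
    "AOB": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Burkholderiales", "Nitrosomonadaceae"),
    "NOB": ("Bacteria", "Nitrospirae", "Nitrospiria", "Nitrospirales", "Nitrospiraceae"),
    "PAO": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Burkholderiales", "Rhodocyclaceae"),
    "BFB": ("Bacteria", "Actinobacteria", "Actinomycetia", "Mycobacteriales", "Mycobacteriaceae"),
    "anammox": ("Bacteria", "Planctomycetota", "Brocadiae", "Brocadiales", "Brocadiaceae"),
}


def generate_taxonomy_and_guilds(
    taxon_ids: Sequence[str],
    guild_fractions: Mapping[str, float] | None = None,
    seed: int = 0,
) -> TaxonomyTable:
    """Assign synthetic lineages; planted fractions get guild genera.

    ``guild_fractions`` maps guild name (AOB/NOB/PAO/BFB/anammox) to the
    fraction of taxa that should carry a genus of that guild; counts are
    rounded so a 10% fraction of 100 taxa plants exactly 10.  Remaining
    taxa get background lineages that match no guild pattern.
    """
    guild_fractions = dict(guild_fractions or {})
    if sum(guild_fractions.values()) > 1 + 1e-9:
        raise ValueError("guild fractions must sum to <= 1")
    unknown = set(guild_fractions) - set(GUILD_GENERA)
    if unknown:
        raise ValueError(f"unknown guilds: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    n = len(taxon_ids)
    order = rng.permutation(n)
    lineages: dict[str, tuple[str, ...]] = {}
    pos = 0
    for guild, frac in guild_fractions.items():
        k = int(round(frac * n))
        genera = GUILD_GENERA[guild]
        head = _GUILD_LINEAGE_HEAD[guild]
        for i in range(k):
            tid = taxon_ids[order[pos]]
            genus = genera[i % len(genera)]
            lineages[tid] = head + (genus, "")
            pos += 1
    for idx in order[pos:]:
        tid = taxon_ids[idx]
        phylum = _BACKGROUND_PHYLA[idx % len(_BACKGROUND_PHYLA)]
        lineages[tid] = (
            "Bacteria", phylum, f"Class{idx % 11}", f"Order{idx % 17}",
            f"Family{idx % 29}", f"SynGenus{idx}", "",
        )
    return TaxonomyTable({tid: lineages[tid] for tid in taxon_ids})


# ---------------------------------------------------------------------------
# reference-set fixtures

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def random_sequences(ids: Sequence[str], length: int = 250, seed: int = 0) -> dict[str, str]:
    """Random ACGT sequences keyed by id (representative-sequence stand-in)."""
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    return {i: "".join(rng.choice(alphabet, size=length)) for i in ids}


def generate_reference_set(
    otu_sequences: Mapping[str, str],
    include_fraction: float = 0.5,
    mutation_rate: float = 0.02,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Build a (queries, references) FASTA pair with known match structure.

    A rounded ``include_fraction`` of the queries appear verbatim inside a
    reference (embedded in random flanks, half of them reverse
    complemented); the rest are copied with at least one substitution so
    they cannot match under the exact criterion.
    """
    if not 0 <= include_fraction <= 1:
        raise ValueError("include_fraction must be in [0, 1]")
    if not 0 <= mutation_rate <= 1:
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = list(otu_sequences)
    queries = {i: otu_sequences[i].upper() for i in ids}
    k = int(round(include_fraction * len(ids)))
    included = list(rng.permutation(ids)[:k])
    alphabet = "ACGT"
    references: dict[str, str] = {}
    for rank, qid in enumerate(included):
        seq = queries[qid]
        if rank % 2 == 1:
            seq = _revcomp(seq)
        flank_l = "".join(rng.choice(list(alphabet), size=rng.integers(0, 40)))
        flank_r = "".join(rng.choice(list(alphabet), size=rng.integers(0, 40)))
        references[f"REF_{qid}"] = flank_l + seq + flank_r
    for qid in ids:
        if qid in included:
            continue
        seq = list(queries[qid])
        n_mut = max(1, rng.binomial(len(seq), mutation_rate))
        sites = rng.choice(len(seq), size=n_mut, replace=False)
        for s in sites:
            seq[s] = rng.choice([b for b in alphabet if b != seq[s]])
        references[f"REF_{qid}_mut"] = "".join(seq)
    return queries, references
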