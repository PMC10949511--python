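import numpy as np
import pytest
from scipy.special import betaln

from sludgeco.simulate import (
    GraphSimSpec,
    NeutralSimSpec,
    generate_reference_set,
    generate_taxonomy_and_guilds,
    metacommunity_abundances,
    random_sequences,
    simulate_graph_community,
    simulate_neutral_community,
)
from sludgeco.guilds import extract_guilds
from sludgeco.mdm import match_exact
from sludgeco.network import clr_transform

from conftest import make_table


class TestNeutralSimulator:
    def test_huge_nm_gives_full_occupancy(self):
        spec = NeutralSimSpec(S=2, n_samples=20, N=10**6, m=1.0, seed=0)
        table, p = simulate_neutral_community(spec)
        assert (table.counts.to_numpy() > 0).all()

    def test_same_seed_reproduces(self):
        spec = NeutralSimSpec(S=100, n_samples=5, N=1000, m=0.1, seed=7)
        t1, p1 = simulate_neutral_community(spec)
        t2, p2 = simulate_neutral_community(spec)
        assert t1 == t2 and np.array_equal(p1, p2)

    def test_invalid_migration_rate_rejected(self):
        with pytest.raises(ValueError):
            NeutralSimSpec(m=0.0)
        with pytest.raises(ValueError):
            NeutralSimSpec(m=1.5)

    def test_logseries_tail_fraction(self):
        spec = NeutralSimSpec(seed=3)
        p = metacommunity_abundances(spec, np.random.default_rng(3))
        below = (p < 1.0 / spec.N).mean()
        assert 0.4 < below < 0.6

    def test_occupancy_matches_exact_compound_form(self):
        """Binned occupancy tracks the exact Dirichlet-multinomial
        detection probability 1 - B(a, b+N)/B(a, b), and the beta-CDF
        step approximation for taxa well above the detection limit."""
        spec = NeutralSimSpec(S=3000, n_samples=13, N=25000, m=2089 / 25000, seed=11)
        table, p = simulate_neutral_community(spec)
        f_obs = (table.counts.to_numpy() > 0).mean(axis=1)
        nm = spec.N * spec.m
        a, b = nm * p, nm * (1 - p)
        q = 1.0 - np.exp(betaln(a, b + spec.N) - betaln(a, b))
        edges = np.quantile(p, np.linspace(0, 1, 9))
        for lo, hi in zip(edges[:-1], edges[1:]):
            mask = (p >= lo) & (p < hi)
            if mask.sum() < 30:
                continue
            n_eff = mask.sum() * spec.n_samples
            se = np.sqrt(max(q[mask].mean() * (1 - q[mask].mean()), 1e-6) / n_eff)
            assert abs(f_obs[mask].mean() - q[mask].mean()) < 4 * se + 0.01
        # beta-CDF continuous approximation holds far above d = 1/N
        from scipy import stats

        far = p > 5.0 / spec.N
        F = stats.beta.sf(1.0 / spec.N, a[far], b[far])
        assert abs(f_obs[far].mean() - F.mean()) < 0.03

    def test_marginal_mean_converges_to_p(self):
        spec = NeutralSimSpec(
            S=10, n_samples=1000, N=1000, m=0.5, metacommunity="lognormal", seed=5
        )
        table, p = simulate_neutral_community(spec)
        rel = table.counts.to_numpy() / spec.N
        sd = np.sqrt(p * (1 - p) / (spec.N * spec.m + 1) + p * (1 - p) / spec.N)
        se = sd / np.sqrt(spec.n_samples)
        assert (np.abs(rel.mean(axis=1) - p) < 3 * se + 1e-4).all()


class TestGraphSimulator:
    def test_empty_graph_clr_correlations_near_zero(self):
        # clr of a closed composition carries a small negative baseline
        # correlation (~ -1/(p-1)); with p=20 independence leaves all
        # pairwise correlations well inside +/- 0.15
        spec = GraphSimSpec(p=20, n_samples=500, graph="empty", N=25000, seed=0)
        table, truth = simulate_graph_community(spec)
        assert truth == set()
        z = clr_transform(table).to_numpy()
        corr = np.corrcoef(z)
        off = corr[np.triu_indices(spec.p, 1)]
        assert abs(off.mean() + 1.0 / spec.p) < 0.05  # closure baseline ~ -1/p
        assert np.abs(off - off.mean()).max() < 0.15  # no pair stands out

    def test_chain_edges_carry_larger_correlations(self):
        hits = 0
        for seed in range(10):
            spec = GraphSimSpec(p=20, n_samples=500, graph="chain", strength=0.3,
                                N=25000, seed=seed)
            table, truth = simulate_graph_community(spec)
            corr = np.abs(np.corrcoef(clr_transform(table).to_numpy()))
            on = [corr[i, i + 1] for i in range(spec.p - 1)]
            iu = np.triu_indices(spec.p, 2)
            off = corr[iu]
            if min(on) > np.median(off):
                hits += 1
        assert hits >= 9

    def test_reproducible_and_pd_guard(self):
        spec = GraphSimSpec(p=8, n_samples=20, graph="chain", seed=1)
        t1, e1 = simulate_graph_community(spec)
        t2, e2 = simulate_graph_community(spec)
        assert t1 == t2 and e1 == e2
        with pytest.raises(ValueError, match="positive definite"):
            simulate_graph_community(GraphSimSpec(p=10, graph="band", strength=0.6))


class TestTaxonomyGuildFixture:
    def test_zero_fractions_match_nothing(self, random_table):
        tax = generate_taxonomy_and_guilds(random_table.taxon_ids, {}, seed=0)
        summary = extract_guilds(random_table, tax)
        assert all(len(m) == 0 for m in summary.members.values())

    def test_exact_planted_counts(self):
        ids = [f"T{i}" for i in range(100)]
        tax = generate_taxonomy_and_guilds(ids, {"AOB": 0.1}, seed=0)
        aob = [t for t, lin in tax.lineages.items()
               if lin[5] in {"Nitrosomonas", "oc32", "Ellin6067", "DSSD61", "mle1-7", "966-1"}]
        assert len(aob) == 10

    def test_round_trip_recovery_through_extraction(self, random_table):
        fractions = {"AOB": 0.1, "NOB": 0.1, "PAO": 0.06, "BFB": 0.08, "anammox": 0.02}
        tax = generate_taxonomy_and_guilds(random_table.taxon_ids, fractions, seed=2)
        summary = extract_guilds(random_table, tax)
        n = len(random_table.taxon_ids)
        for guild, frac in fractions.items():
            assert len(summary.members[guild]) == int(round(frac * n))


class TestReferenceSetFixture:
    def test_extremes(self):
        seqs = random_sequences([f"Q{i}" for i in range(10)], length=60, seed=0)
        q_all, r_all = generate_reference_set(seqs, include_fraction=1.0, seed=1)
        assert all(m.matched for m in match_exact(q_all, r_all))
        q_none, r_none = generate_reference_set(seqs, include_fraction=0.0,
                                                mutation_rate=0.05, seed=1)
        assert not any(m.matched for m in match_exact(q_none, r_none))

    def test_half_included_of_forty(self):
        seqs = random_sequences([f"Q{i}" for i in range(40)], length=80, seed=3)
        queries, refs = generate_reference_set(seqs, include_fraction=0.5, seed=4)
        matched = sum(m.matched for m in match_exact(queries, refs))
        assert matched == 20
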