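"""Cross-network statistics: CAN, differential network, Jaccard, ARI,
module equivalence, partner overlap."""

import itertools
import math

import numpy as np
import pytest

from conftest import net_from_edges
from coocnet.compare import (
    adjusted_rand_index,
    core_association_network,
    differential_network,
    jaccard_centrality,
    module_equivalence,
    partner_overlap,
)
from coocnet.knockout import EgoSubnetwork
from coocnet.network import centralities
from coocnet.sparcc import CorrelationResult


def corr_from_matrix(rho, taxa=None):
    d = rho.shape[0]
    return CorrelationResult(
        taxon_ids=taxa or [f"t{i}" for i in range(d)], rho=rho,
        logratio_var=np.zeros_like(rho), basis_var=np.ones(d),
        n_inner=1, excluded_pairs=[], seed=0,
    )


class TestCoreAssociationNetwork:
    def test_identical_networks(self, path_net):
        can = core_association_network([path_net, path_net])
        assert can.edges == path_net.edge_set()

    def test_sign_conflict_excluded(self):
        a = net_from_edges([("x", "y", 0.9)])
        b = net_from_edges([("x", "y", -0.9)])
        can = core_association_network([a, b])
        assert can.edges == set()

    def test_matches_set_oracle(self):
        rng = np.random.default_rng(0)
        def random_net(seed):
            r = np.random.default_rng(seed)
            edges = [(f"n{i}", f"n{j}", r.choice([-1, 1]) * r.uniform(0.5, 1))
                     for i in range(10) for j in range(i + 1, 10)
                     if r.random() < 0.4]
            return net_from_edges(edges, nodes=[f"n{k}" for k in range(10)])
        a, b = random_net(1), random_net(2)
        can = core_association_network([a, b])
        assert can.edges == a.edge_set() & b.edge_set()
        assert can.nodes == {u for u, _, _ in can.edges} | {v for _, v, _ in can.edges}

    def test_disjoint_taxa_warns(self):
        a = net_from_edges([("x", "y", 0.9)])
        b = net_from_edges([("p", "q", 0.9)])
        with pytest.warns(UserWarning, match="no taxa"):
            can = core_association_network([a, b])
        assert can.edges == set()


class TestDifferentialNetwork:
    def test_equal_correlations_empty(self):
        rho = np.eye(5)
        rho[0, 1] = rho[1, 0] = 0.6
        res = differential_network(corr_from_matrix(rho), corr_from_matrix(rho),
                                   20, 20)
        assert len(res.significant) == 0

    def test_decision_matches_permutation_oracle(self):
        # rho_A=0.9 vs rho_B=0.0 at n=13 each: compare the Fisher-z decision
        # with a direct permutation test on simulated bivariate samples
        rng = np.random.default_rng(16)
        n = 13
        cov = np.array([[1.0, 0.9], [0.9, 1.0]])
        xa = rng.multivariate_normal([0, 0], cov, size=n)
        xb = rng.standard_normal((n, 2))
        ra = np.corrcoef(xa.T)[0, 1]
        rb = np.corrcoef(xb.T)[0, 1]
        assert ra > 0.85 and abs(rb) < 0.15  # draw represents the design
        obs = abs(ra - rb)
        pooled = np.vstack([xa, xb])
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            perm = rng.permutation(2 * n)
            pa, pb = pooled[perm[:n]], pooled[perm[n:]]
            d = abs(np.corrcoef(pa.T)[0, 1] - np.corrcoef(pb.T)[0, 1])
            count += d >= obs
        p_perm = (count + 1) / (n_perm + 1)

        rho_a = np.eye(4); rho_a[0, 1] = rho_a[1, 0] = ra
        rho_b = np.eye(4); rho_b[0, 1] = rho_b[1, 0] = rb
        res = differential_network(corr_from_matrix(rho_a),
                                   corr_from_matrix(rho_b), n, n)
        row = res.pairs[(res.pairs.taxon_a == "t0") & (res.pairs.taxon_b == "t1")]
        assert (row["p"].iloc[0] < 0.05) == (p_perm < 0.05)

    def test_bh_matches_brute_force_step_up(self):
        rng = np.random.default_rng(2)
        d = 8
        rho_a = rng.uniform(-0.9, 0.9, (d, d)); rho_a = (rho_a + rho_a.T) / 2
        rho_b = rng.uniform(-0.9, 0.9, (d, d)); rho_b = (rho_b + rho_b.T) / 2
        np.fill_diagonal(rho_a, 1); np.fill_diagonal(rho_b, 1)
        res = differential_network(corr_from_matrix(rho_a),
                                   corr_from_matrix(rho_b), 30, 25, alpha=0.05)
        # brute-force BH step-up on the raw p vector
        p = res.pairs["p"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        reject = np.zeros(m, dtype=bool)
        kmax = 0
        for rank, i in enumerate(order, start=1):
            if p[i] <= rank / m * 0.05:
                kmax = rank
        reject[order[:kmax]] = True
        assert set(res.significant.index) == set(np.where(reject)[0])

    def test_small_n_rejected(self):
        rho = np.eye(4)
        with pytest.raises(ValueError, match="3 samples"):
            differential_network(corr_from_matrix(rho), corr_from_matrix(rho), 3, 10)


class TestJaccardCentrality:
    def test_identical_centralities(self, star_net):
        c = centralities(star_net)
        results = {r.measure: r for r in jaccard_centrality(c, c)}
        deg = results["degree"]
        assert deg.J == 1.0
        # closed-form hypergeometric tail for a full overlap
        n, k = deg.universe, deg.size_a
        assert deg.p_ge == pytest.approx(
            1.0 / (math.comb(n, k)), rel=1e-9)

    def test_disjoint_sets(self):
        import pandas as pd

        idx = [f"n{i}" for i in range(8)]
        cols = ["degree", "betweenness", "closeness", "eigenvector"]
        a = pd.DataFrame(0.0, index=idx, columns=cols)
        b = pd.DataFrame(0.0, index=idx, columns=cols)
        a.loc["n0", "degree"] = a.loc["n1", "degree"] = 10
        b.loc["n6", "degree"] = b.loc["n7", "degree"] = 10
        res = {r.measure: r for r in jaccard_centrality(a, b)}
        assert res["degree"].J == 0.0

    def test_p_ge_matches_full_enumeration(self):
        # N=10, |A|=|B|=3, x=2: enumerate all C(10,3)^2 pairs of subsets
        n, k, x = 10, 3, 2
        universe = range(n)
        pairs = total = 0
        for sa in itertools.combinations(universe, k):
            for sb in itertools.combinations(universe, k):
                total += 1
                pairs += len(set(sa) & set(sb)) >= x
        expected = pairs / total
        from scipy import stats

        assert stats.hypergeom(n, k, k).sf(x - 1) == pytest.approx(expected)
        # and p_le + p_ge >= 1 (shared point mass)
        rv = stats.hypergeom(n, k, k)
        assert rv.cdf(x) + rv.sf(x - 1) >= 1.0

    def test_hub_taxa_requires_all_three(self, star_net, path_net):
        ca = centralities(star_net)
        res = {r.measure: r for r in jaccard_centrality(ca, ca)}
        assert "hub_taxa" in res


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        part = {f"n{i}": i // 4 for i in range(12)}
        ari, p = adjusted_rand_index(part, part, n_perm=200, seed=0)
        assert ari == pytest.approx(1.0)
        assert p <= 0.05

    def test_coarsening_gives_zero(self):
        a = {"a": 0, "b": 0, "c": 1, "d": 1}
        b = {"a": 0, "b": 0, "c": 0, "d": 0}
        ari, _ = adjusted_rand_index(a, b, n_perm=50, seed=0)
        assert ari == pytest.approx(0.0)

    def test_hand_contingency_oracle(self):
        # {ab|cd} vs {ac|bd}: contingency all ones; Index=0,
        # Expected = 2*2/6, Max = 2 -> ARI = -0.5
        a = {"a": 0, "b": 0, "c": 1, "d": 1}
        b = {"a": 0, "b": 1, "c": 0, "d": 1}
        ari, _ = adjusted_rand_index(a, b, n_perm=50, seed=0)
        assert ari == pytest.approx(-0.5)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = {f"n{i}": int(rng.integers(3)) for i in range(20)}
        b = {f"n{i}": int(rng.integers(3)) for i in range(20)}
        assert adjusted_rand_index(a, b, n_perm=10, seed=1)[0] == pytest.approx(
            adjusted_rand_index(b, a, n_perm=10, seed=1)[0])

    def test_too_few_shared_rejected(self):
        with pytest.raises(ValueError, match="shared"):
            adjusted_rand_index({"a": 0}, {"b": 0})


class TestModuleEquivalence:
    def test_printed_size_arithmetic(self):
        # 208- and 294-member modules sharing 93 taxa -> 22.7%
        a = {f"s{i}": 0 for i in range(93)}
        a.update({f"a{i}": 0 for i in range(208 - 93)})
        b = {f"s{i}": 0 for i in range(93)}
        b.update({f"b{i}": 0 for i in range(294 - 93)})
        df = module_equivalence(a, b)
        assert df.loc[0, "pct_shared"] == 22.7

    def test_identical_modules_full_overlap(self):
        part = {c: 0 for c in "abcd"}
        df = module_equivalence(part, part)
        assert df.loc[0, "pct_shared"] == 100.0

    @pytest.mark.parametrize(
        "size_a,size_b,shared,expected",
        [(208, 294, 93, 22.7), (143, 191, 92, 38.0),
         (71, 76, 34, 30.1), (208, 28, 14, 6.3)],
    )
    def test_shared_over_union(self, size_a, size_b, shared, expected):
        a = {f"s{i}": 0 for i in range(shared)}
        a.update({f"a{i}": 0 for i in range(size_a - shared)})
        b = {f"s{i}": 0 for i in range(shared)}
        b.update({f"b{i}": 0 for i in range(size_b - shared)})
        df = module_equivalence(a, b)
        assert df.loc[0, "pct_shared"] == expected


class TestPartnerOverlap:
    def test_identical_partner_sets(self):
        sub = EgoSubnetwork("hub", ["a", "b"], {"a": 0.8, "b": 0.9})
        ov = partner_overlap(sub, sub)
        assert ov.counts == (0, 0, 2)

    def test_disjoint(self):
        a = EgoSubnetwork("hub", ["a"], {"a": 0.8})
        b = EgoSubnetwork("hub", ["b"], {"b": 0.8})
        assert partner_overlap(a, b).counts == (1, 1, 0)

    def test_venn_triple(self):
        # mirrors the study's 93 / 161 partner sets sharing 55 taxa
        shared = [f"s{i}" for i in range(55)]
        a = EgoSubnetwork("hub", shared + [f"a{i}" for i in range(38)],
                          dict.fromkeys(shared, 0.8))
        b = EgoSubnetwork("hub", shared + [f"b{i}" for i in range(106)],
                          dict.fromkeys(shared, 0.8))
        assert partner_overlap(a, b).counts == (38, 106, 55)

    def test_different_focal_rejected(self):
        a = EgoSubnetwork("x", [], {})
        b = EgoSubnetwork("y", [], {})
        with pytest.raises(ValueError, match="focal"):
            partner_overlap(a, b)
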