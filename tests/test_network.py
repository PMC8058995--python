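"""Coexpression network: adjacency/TOM, modules, subnetwork, enrichment."""

import numpy as np
import pandas as pd
import pytest

from oracles import adjusted_rand_index, hypergeom_tail, tom_triple_loop
from lilimir.network import (
    NetworkParams,
    build_network,
    correlate_pairs,
    detect_modules,
    enrich,
    extract_subnetwork,
    module_eigengene,
    pick_soft_threshold,
    tom_matrix,
)


def _module_expression(rng, n_modules=3, size=20, n_samples=15, noise=0.1):
    """Planted orthogonal module seeds plus i.i.d. noise."""
    seeds = rng.normal(size=(n_modules, n_samples))
    seeds -= seeds.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(seeds.T)
    seeds = q.T[:n_modules] * np.sqrt(n_samples)
    rows, labels = [], []
    for k in range(n_modules):
        for i in range(size):
            rows.append(seeds[k] + rng.normal(0, noise, size=n_samples))
            labels.append(k)
    idx = [f"m{k}_{i}" for k in range(n_modules) for i in range(size)]
    return pd.DataFrame(rows, index=idx), pd.Series(labels, index=idx)


class TestCorrelatePairs:
    def _expr(self):
        x = np.array([5.0, 4, 3, 2, 1])
        mir = pd.DataFrame([x], index=["mir"], columns=[f"s{i}" for i in range(5)])
        tgt = pd.DataFrame(
            [-x, x], index=["anti", "same"], columns=[f"s{i}" for i in range(5)]
        )
        return mir, tgt

    def test_perfect_anticorrelation(self):
        mir, tgt = self._expr()
        out = correlate_pairs(mir, tgt, [("mir", "anti")])
        assert out.loc[0, "r"] == pytest.approx(-1.0)
        assert bool(out.loc[0, "negative"])

    def test_perfect_correlation_not_negative(self):
        mir, tgt = self._expr()
        out = correlate_pairs(mir, tgt, [("mir", "same")])
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert not bool(out.loc[0, "negative"])

    def test_planted_inverse_pairs_flagged_in_95_percent(self):
        rng = np.random.default_rng(0)
        cols = [f"s{i}" for i in range(15)]
        base = np.tile(np.linspace(2, -2, 5), 3)
        mir = pd.DataFrame(
            [base + rng.normal(0, 0.2, 15) for _ in range(200)],
            index=[f"m{i}" for i in range(200)], columns=cols,
        )
        tgt = pd.DataFrame(
            [-base + rng.normal(0, 0.2, 15) for _ in range(200)],
            index=[f"t{i}" for i in range(200)], columns=cols,
        )
        out = correlate_pairs(mir, tgt, [(f"m{i}", f"t{i}") for i in range(200)])
        assert out["negative"].mean() >= 0.95


class TestSoftThreshold:
    def test_block_diagonal_modules_pick_smallest_candidate(self):
        rng = np.random.default_rng(1)
        expr, _ = _module_expression(rng, noise=0.0)
        beta, table = pick_soft_threshold(expr, candidate_betas=(2, 6, 12))
        assert beta == 2
        assert table.loc[0, "signed_r2"] >= 0.8

    def test_single_candidate_returned(self):
        rng = np.random.default_rng(2)
        expr, _ = _module_expression(rng)
        beta, _ = pick_soft_threshold(
            expr, candidate_betas=(7,), r2_target=-np.inf
        )
        assert beta == 7

    def test_random_expression_warns_and_returns_default(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(
            rng.normal(size=(40, 15)), index=[f"g{i}" for i in range(40)]
        )
        with pytest.warns(UserWarning):
            beta, _ = pick_soft_threshold(
                expr, candidate_betas=(1, 2), r2_target=0.999, default_beta=12
            )
        assert beta == 12


class TestTom:
    def test_two_perfectly_correlated_nodes(self):
        expr = pd.DataFrame(
            [[1.0, 2, 3, 4], [2.0, 4, 6, 8]], index=["a", "b"]
        )
        net = build_network(expr, NetworkParams(beta=12))
        assert net.adjacency[0, 1] == pytest.approx(1.0)
        assert net.tom[0, 1] == pytest.approx(1.0)

    def test_uncorrelated_nodes_near_zero_adjacency(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(2, 200)), index=["a", "b"])
        net = build_network(expr, NetworkParams(beta=12))
        assert net.adjacency[0, 1] < 1e-6

    def test_tom_equals_brute_force_triple_loop(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            expr = pd.DataFrame(
                rng.normal(size=(10, 15)), index=[f"g{i}" for i in range(10)]
            )
            A = build_network(expr, NetworkParams(beta=6)).adjacency
            np.testing.assert_allclose(tom_matrix(A), tom_triple_loop(A), atol=1e-12)

    def test_bounds_and_symmetry(self):
        rng = np.random.default_rng(6)
        expr, _ = _module_expression(rng)
        net = build_network(expr, NetworkParams(beta=12))
        for M in (net.adjacency, net.tom):
            assert np.allclose(M, M.T)
            assert M.min() >= 0 and M.max() <= 1 + 1e-9
            np.testing.assert_allclose(np.diag(M), 1.0)
        assert (net.tom + 1e-12 >= 0).all()


class TestModules:
    def test_three_planted_modules_recovered_with_high_ari(self):
        rng = np.random.default_rng(7)
        expr, truth = _module_expression(rng, n_modules=3, size=20, noise=0.1)
        net = build_network(expr, NetworkParams(beta=12))
        net = detect_modules(net, expr)
        ari = adjusted_rand_index(truth.tolist(), net.modules.tolist())
        assert ari >= 0.9

    def test_identical_expression_single_module(self):
        base = np.linspace(1, 5, 10)
        expr = pd.DataFrame(
            [base] * 15, index=[f"g{i}" for i in range(15)]
        )
        net = detect_modules(build_network(expr, NetworkParams()), expr)
        labels = set(net.modules)
        assert labels == {"turquoise"}

    def test_single_node_module_eigengene_is_standardized_profile(self):
        x = pd.DataFrame([[1.0, 3, 5, 7]], index=["g"])
        eig = module_eigengene(x)
        v = x.iloc[0].to_numpy()
        z = (v - v.mean()) / v.std()  # population std, as in the eigengene
        np.testing.assert_allclose(eig, z, atol=1e-12)

    def test_eigengene_explains_at_least_any_member_projection(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            expr = pd.DataFrame(
                rng.normal(size=(8, 12)), index=[f"g{i}" for i in range(8)]
            )
            eig = module_eigengene(expr)
            X = expr.to_numpy()
            Z = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
            var_eig = np.sum((Z @ eig) ** 2) / np.sum(eig**2)
            for row in Z:
                var_row = np.sum((Z @ row) ** 2) / np.sum(row**2)
                assert var_eig >= var_row - 1e-9

    def test_eigengene_sign_tracks_mean_profile(self):
        rng = np.random.default_rng(9)
        expr, _ = _module_expression(rng, n_modules=1, size=10)
        eig = module_eigengene(expr)
        Z = ((expr.T - expr.T.mean()) / expr.T.std()).T
        assert np.corrcoef(eig, Z.mean(0))[0, 1] > 0


class TestSubnetwork:
    def _net(self):
        rng = np.random.default_rng(10)
        expr, _ = _module_expression(rng, n_modules=2, size=10, noise=0.2)
        return detect_modules(build_network(expr, NetworkParams(beta=6)), expr), expr

    def test_floor_one_keeps_only_perfect_edges(self):
        net, _ = self._net()
        edges, _ = extract_subnetwork(net, list(net.nodes), weight_floor=1.0)
        assert (edges["weight"] >= 1.0).all() if len(edges) else True

    def test_empty_seed_set_empty_edges(self):
        net, _ = self._net()
        edges, degree = extract_subnetwork(net, [], weight_floor=0.0)
        assert len(edges) == 0 and len(degree) == 0

    def test_planted_hub_has_top_degree(self):
        # a star-like network: hub correlated with everyone
        rng = np.random.default_rng(11)
        hub = rng.normal(size=12)
        rows = [hub + rng.normal(0, 0.05, 12) for _ in range(6)]
        rows.append(hub)
        others = [rng.normal(size=12) for _ in range(6)]
        expr = pd.DataFrame(
            rows + others,
            index=[f"n{i}" for i in range(7)] + [f"o{i}" for i in range(6)],
        )
        net = build_network(expr, NetworkParams(beta=6))
        edges, degree = extract_subnetwork(net, list(expr.index), weight_floor=0.3)
        assert degree.index[0].startswith(("n",))

    def test_unknown_seed_raises(self):
        net, _ = self._net()
        with pytest.raises(ValueError):
            extract_subnetwork(net, ["nope"])


class TestEnrich:
    def _annotation(self):
        rows = [(f"g{i}", "T1") for i in range(5)]
        rows += [(f"g{i}", "T2") for i in range(2, 20)]
        return pd.DataFrame(rows, columns=["gene", "term"])

    def test_exclusive_term_exact_closed_form(self):
        ann = self._annotation()
        genes = [f"g{i}" for i in range(5)]  # all of T1
        out = enrich(genes, ann).set_index("term")
        N, K, n, k = 20, 5, 5, 5
        assert out.loc["T1", "p"] == pytest.approx(hypergeom_tail(k, N, K, n), abs=1e-12)

    def test_p_matches_exact_tail_sum(self):
        rng = np.random.default_rng(12)
        ann = self._annotation()
        genes = list(rng.choice([f"g{i}" for i in range(20)], size=8, replace=False))
        out = enrich(genes, ann)
        for _, row in out.iterrows():
            assert row["p"] == pytest.approx(
                hypergeom_tail(int(row["k"]), int(row["N"]), int(row["K"]), int(row["n"])),
                abs=1e-12,
            )

    def test_empty_set_empty_result(self):
        assert enrich([], self._annotation()).empty

    def test_term_absent_from_background_skipped_with_warning(self):
        ann = self._annotation()
        background = [f"g{i}" for i in range(5)]  # excludes most T2 genes
        ann2 = pd.concat(
            [ann, pd.DataFrame([("gX", "T3")], columns=["gene", "term"])]
        )
        with pytest.warns(UserWarning):
            out = enrich(["g0", "g1"], ann2, background=background)
        assert "T3" not in set(out["term"])
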