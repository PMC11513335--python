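"""Dynamical shrinkage GGM: weights, estimator oracles, null model, networks."""

import math

import networkx as nx
import numpy as np
import pytest

from chronomet import (
    DynamicalGGM,
    ModuleSpec,
    SimConfig,
    build_schedule,
    fit_null_kappa,
    merge_multifluid,
    simulate_dataset,
    time_weights,
)
from chronomet.errors import ConfigError, DomainError
from chronomet.ggm import GgmNetwork, NullModel, annotate_and_export
from chronomet.preprocess import log2_values
from chronomet.stats import paired_t_scan

from conftest import make_design


class TestTimeWeights:
    def test_worked_example(self):
        tw = time_weights([0, 1, 2, 3])
        assert tw.w == pytest.approx([1 / 6, 1 / 3, 1 / 3, 1 / 6])

    def test_two_points(self):
        assert time_weights([0, 10]).w == pytest.approx([0.5, 0.5])

    @pytest.mark.parametrize("n", [2, 3, 10, 57, 200])
    def test_equal_spacing_invariant(self, n):
        tw = time_weights(np.arange(n) * 13.0)
        assert tw.w.sum() == pytest.approx(1.0)
        if n > 2:
            inner = tw.w[1:-1]
            assert np.allclose(inner, inner[0])
            assert inner[0] == pytest.approx(2 * tw.w[0])

    def test_irregular_spacing_weights_positive(self):
        tw = time_weights([0, 15, 30, 120, 360, 1440])
        assert np.all(tw.w > 0) and tw.w.sum() == pytest.approx(1.0)

    def test_too_short(self):
        with pytest.raises(DomainError):
            time_weights([5.0])


def _complete_dataset(n_met=6, n_sub=15, seed=0, modules=(), design=None):
    mods = list(modules)
    cfg = SimConfig(
        n_subjects=n_sub, n_metabolites=n_met, modules=mods,
        missing_mcar=0.0, missing_lod_quantile=0.0, seed=seed, design=design,
    )
    ds, truth = simulate_dataset(cfg)
    return log2_values(ds), truth


def _oracle_pcor(model):
    """Independent recomputation: loops + linear solves, no shared code path."""
    X = model._X  # (S, T, p)
    w = model.w
    S, T, p = X.shape
    C = np.zeros((p, p))
    for s in range(S):
        mu = np.zeros(p)
        for k in range(T):
            mu += w[k] * X[s, k]
        for g in range(p):
            for h in range(p):
                acc = 0.0
                for k in range(T):
                    acc += w[k] * (X[s, k, g] - mu[g]) * (X[s, k, h] - mu[h])
                C[g, h] += acc / S
    d = np.sqrt(np.diag(C))
    R = C / np.outer(d, d)
    omega = np.column_stack([np.linalg.solve(R, e) for e in np.eye(p)])
    dd = np.sqrt(np.diag(omega))
    pc = -omega / np.outer(dd, dd)
    np.fill_diagonal(pc, 1.0)
    return pc


class TestShrinkageEstimator:
    def test_lambda_zero_matches_direct_inversion_oracle(self):
        ds, _ = _complete_dataset(n_met=6, seed=4)
        model = DynamicalGGM(ds)
        res = model.fit(lambda_=0.0, fit_kappa=False)
        assert np.max(np.abs(res.pcor - _oracle_pcor(model))) <= 1e-10

    def test_lambda_one_zeroes_off_diagonals(self):
        ds, _ = _complete_dataset(n_met=5, seed=5)
        res = DynamicalGGM(ds).fit(lambda_=1.0, fit_kappa=False)
        off = res.pcor - np.diag(np.diag(res.pcor))
        assert np.all(off == 0.0)
        assert np.all(np.diag(res.pcor) == 1.0)

    def test_pcor_matrix_invariants(self):
        ds, _ = _complete_dataset(n_met=8, seed=6,
                                  modules=[ModuleSpec("m", tuple(f"met{i:03d}.P.nt-ms" for i in (1, 2, 3)), 0.8)])
        res = DynamicalGGM(ds).fit(fit_kappa=False)
        pc = res.pcor
        assert np.allclose(pc, pc.T)
        assert np.allclose(np.diag(pc), 1.0)
        assert np.all(np.abs(pc) <= 1.0 + 1e-12)
        assert 0.0 <= res.lambda_star <= 1.0

    def test_pcor_magnitude_shrinks_with_lambda(self):
        ds, _ = _complete_dataset(n_met=5, seed=7)
        model = DynamicalGGM(ds)
        iu = np.triu_indices(5, k=1)
        prev = None
        for lam in (0.0, 0.2, 0.5, 0.9):
            cur = np.abs(model.fit(lambda_=lam, fit_kappa=False).pcor[iu])
            if prev is not None:
                assert np.all(cur <= prev + 1e-12)
            prev = cur

    def test_independent_uids_have_small_pcor(self):
        ds, _ = _complete_dataset(n_met=2, seed=8)
        res = DynamicalGGM(ds).fit(fit_kappa=False)
        assert abs(res.pcor[0, 1]) < 0.1

    def test_single_subject_equal_grid_matches_weighted_pearson(self):
        # one subject, equally spaced: dynamical correlation must equal the
        # trapezoid-weighted Pearson correlation, recomputed independently
        design = build_schedule("uniform", n=30, subjects=[1, 2])
        ds, _ = _complete_dataset(n_met=2, n_sub=2, seed=9, design=design)
        one = ds.subset(subjects=[1])
        # bypass the >= 2 subject guard by duplicating the subject would change
        # pooling; instead compute from the model internals on subject 1 only
        model = DynamicalGGM(ds)
        x = model._X[0][:, 0]
        y = model._X[0][:, 1]
        w = model.w
        mx, my = np.sum(w * x), np.sum(w * y)
        cxy = np.sum(w * (x - mx) * (y - my))
        r_oracle = cxy / math.sqrt(np.sum(w * (x - mx) ** 2) * np.sum(w * (y - my) ** 2))
        C = (model._X[0] - np.array([mx, my])).T @ ((model._X[0] - np.array([mx, my])) * w[:, None])
        d = np.sqrt(np.diag(C))
        assert C[0, 1] / (d[0] * d[1]) == pytest.approx(r_oracle, abs=1e-12)

    def test_requires_complete_data(self):
        cfg = SimConfig(n_subjects=4, n_metabolites=3, missing_mcar=0.2, seed=1)
        ds, _ = simulate_dataset(cfg)
        with pytest.raises(DomainError):
            DynamicalGGM(log2_values(ds))


class TestNullModel:
    def test_kappa_three_density_is_uniform_and_p_is_one_minus_abs_r(self):
        null = NullModel(kappa=3.0)
        grid = np.linspace(-0.99, 0.99, 199)
        assert np.max(np.abs(np.exp(null.logpdf(grid)) - 0.5)) <= 1e-10
        assert np.max(np.abs(null.p_value(grid) - (1 - np.abs(grid)))) <= 1e-10

    def test_p_at_zero_is_one(self):
        for kappa in (3.0, 50.0, 1000.0):
            assert NullModel(kappa).p_value(0.0) == pytest.approx(1.0)

    def test_mle_recovers_kappa_100(self, rng):
        r2 = rng.beta(0.5, 99 / 2.0, size=5000)
        r = np.sqrt(r2) * np.where(rng.random(5000) < 0.5, -1, 1)
        null = fit_null_kappa(r)
        assert 80 <= null.kappa <= 125

    def test_rejects_bad_input(self):
        with pytest.raises(DomainError):
            fit_null_kappa(np.linspace(-0.5, 1.0, 100))
        with pytest.raises(DomainError):
            fit_null_kappa([0.1] * 10)


class TestNetworkExtraction:
    def setup_method(self):
        mods = [ModuleSpec("m1", tuple(f"met{i:03d}.P.nt-ms" for i in (1, 2, 3)), 0.8),
                ModuleSpec("m2", tuple(f"met{i:03d}.P.nt-ms" for i in (4, 5, 6)), 0.8)]
        self.ds, self.truth = _complete_dataset(n_met=12, seed=10, modules=mods)
        self.res = DynamicalGGM(self.ds).fit()

    def test_cutoff_mode_thresholds_signed_pcor(self):
        iu = np.triu_indices(len(self.res.uids), k=1)
        c = float(np.sort(self.res.pcor[iu])[-4])  # keep exactly 4 edges
        net = self.res.network(mode="cutoff", cutoff=c)
        assert net.n_edges == 4
        assert all(d["pcor"] >= c for _, _, d in net.edges("pcor"))

    def test_cutoff_out_of_range(self):
        with pytest.raises(ConfigError):
            self.res.network(mode="cutoff", cutoff=1.01)

    def test_significance_mode_recovers_modules(self):
        net = self.res.network(mode="significance", correction="bonferroni")
        edges = {frozenset({u, v}) for u, v, _ in net.edges("pcor")}
        assert edges  # something was found
        assert edges <= self.truth.true_edges  # precision 1 on this fixture

    def test_pearson_gate_removes_edges(self):
        loose = self.res.network(mode="significance", correction="raw5",
                                 require_pearson=False)
        gated = self.res.network(mode="significance", correction="raw5",
                                 require_pearson=True)
        assert gated.n_edges <= loose.n_edges
        for _, _, d in gated.edges("pcor"):
            assert d["p_pearson"] < 0.05

    def test_edges_carry_all_statistics(self):
        net = self.res.network(mode="significance", correction="fdr")
        for _, _, d in net.edges("pcor"):
            for key in ("pcor", "pearson_r", "p_pcor", "p_pearson"):
                assert np.isfinite(d[key])


def _toy_net(uids, fluid, edges=(), names=None):
    g = nx.Graph()
    for u in uids:
        g.add_node(u, fluid=fluid, platform="nt-ms",
                   display_name=(names or {}).get(u, u.split(".")[0]))
    for a, b in edges:
        g.add_edge(a, b, pcor=0.5, edge_type="pcor")
    return GgmNetwork(g)


class TestMergeMultifluid:
    def test_matching_names_get_same_metabolite_edge(self):
        net_p = _toy_net(["A.P.nt-ms", "B.P.nt-ms"], "P")
        net_u = _toy_net(["A.U.nt-ms", "C.U.nt-ms"], "U")
        merged = merge_multifluid(net_p, net_u, "display_name")
        cross = [(u, v) for u, v, d in merged.edges("same_metabolite")]
        assert cross == [("A.P.nt-ms", "A.U.nt-ms")]
        assert merged.n_nodes == 4

    def test_no_shared_names_zero_cross_edges(self):
        merged = merge_multifluid(_toy_net(["A.P.nt-ms"], "P"),
                                  _toy_net(["B.U.nt-ms"], "U"), "display_name")
        assert sum(1 for _ in merged.edges("same_metabolite")) == 0

    def test_multi_partner_matching_yields_one_edge_each(self):
        net_p = _toy_net(["A.P.nt-ms"], "P")
        net_u = _toy_net(["iso1.U.nt-ms", "iso2.U.nt-ms"], "U")
        for n in net_u.graph.nodes:
            net_u.graph.nodes[n]["kegg"] = "C00031"
        net_p.graph.nodes["A.P.nt-ms"]["kegg"] = "c00031"  # case-insensitive
        merged = merge_multifluid(net_p, net_u, "kegg")
        assert sum(1 for _ in merged.edges("same_metabolite")) == 2

    def test_absent_key_everywhere_rejected(self):
        with pytest.raises(ConfigError):
            merge_multifluid(_toy_net(["A.P.nt-ms"], "P"),
                             _toy_net(["B.U.nt-ms"], "U"), "hmdb")


class TestAnnotateAndExport:
    def test_graphml_round_trip_and_attrs(self, tmp_path):
        mods = [ModuleSpec("m1", tuple(f"met{i:03d}.P.nt-ms" for i in (1, 2, 3)), 0.8)]
        ds, _ = _complete_dataset(n_met=12, seed=11, modules=mods)
        res = DynamicalGGM(ds).fit()
        net = res.network(mode="significance", correction="raw5")
        scan = paired_t_scan(ds, "OGTT", tps=ds.design.challenge("OGTT").tested_tps[0])
        path = tmp_path / "net.graphml"
        annotate_and_export(net, scan, "OGTT", scan[0].tp, path, "graphml")
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == net.n_nodes
        assert back.number_of_edges() == net.n_edges

    def test_neg_log10_p(self, tmp_path):
        net = _toy_net(["A.P.nt-ms"], "P")
        from chronomet.stats import ChallengeTestResult

        r = ChallengeTestResult("A.P.nt-ms", "OGTT", 2, 15, 1.0, 5.0, 1e-14,
                                0.05, 1e-13, True, True)
        annotate_and_export(net, [r], "OGTT", 2, tmp_path / "x.json", "json")
        assert net.graph.nodes["A.P.nt-ms"]["neg_log10_p"] == pytest.approx(14.0)

    def test_uid_absent_from_stats_keeps_null_attrs(self, tmp_path):
        net = _toy_net(["A.P.nt-ms"], "P")
        annotate_and_export(net, [], "OGTT", 2, tmp_path / "x.tsv", "edge_tsv")
        assert "log2fc" not in net.graph.nodes["A.P.nt-ms"]

    def test_unknown_format(self, tmp_path):
        with pytest.raises(ConfigError):
            annotate_and_export(_toy_net(["A.P.nt-ms"], "P"), [], "OGTT", 1,
                                tmp_path / "x", "xlsx")
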