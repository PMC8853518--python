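"""Module-dependence linkage and the cross-tissue overlap meta-network."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from bloodbrain import modlink
from bloodbrain.coexpr import ModuleAssignment
from bloodbrain.diffexpr import GeneSet


def _assignment(labels_dict):
    return ModuleAssignment(pd.Series(labels_dict))


def _hypergeom_enumerate(overlap, size_a, size_b, universe):
    """P(X >= overlap) by direct summation of the pmf."""
    total = 0.0
    for x in range(overlap, min(size_a, size_b) + 1):
        if size_b - x > universe - size_a:
            continue
        total += (
            math.comb(size_a, x)
            * math.comb(universe - size_a, size_b - x)
            / math.comb(universe, size_b)
        )
    return total


class TestHypergeometricTail:
    def test_exact_example(self):
        assert modlink.hypergeometric_tail(4, 5, 4, 10) == pytest.approx(5 / 210, abs=1e-12)

    def test_degenerate_tails(self):
        assert modlink.hypergeometric_tail(0, 5, 4, 10) == pytest.approx(1.0)
        assert modlink.hypergeometric_tail(3, 3, 10, 10) == pytest.approx(1.0)

    def test_matches_enumeration_small_universes(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            universe = int(rng.integers(2, 31))
            size_a = int(rng.integers(1, universe + 1))
            size_b = int(rng.integers(1, universe + 1))
            lo = max(0, size_a + size_b - universe)
            overlap = int(rng.integers(lo, min(size_a, size_b) + 1))
            expected = _hypergeom_enumerate(overlap, size_a, size_b, universe)
            got = modlink.hypergeometric_tail(overlap, size_a, size_b, universe)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_impossible_configuration_rejected(self):
        with pytest.raises(ValueError):
            modlink.hypergeometric_tail(5, 4, 4, 10)
        with pytest.raises(ValueError):
            modlink.hypergeometric_tail(0, 8, 8, 10)  # overlap >= 6 is forced


class TestModuleDegEnrichment:
    def test_module_equal_to_deg_set(self):
        genes = [f"g{i}" for i in range(200)]
        labels = {g: (1 if i < 20 else 0) for i, g in enumerate(genes)}
        degs_up = GeneSet("up", genes[:20], "up")
        degs_down = GeneSet("down", [], "down")
        table = modlink.module_deg_enrichment(
            _assignment(labels), degs_up, degs_down, set(genes)
        )
        assert table.loc[0, "p_all"] < 1e-6
        assert table.loc[0, "direction"] == "up"
        assert table.loc[0, "intensity"] == "strong"

    def test_no_degs_gives_unit_pvalues(self):
        genes = [f"g{i}" for i in range(50)]
        labels = {g: 1 for g in genes[:30]} | {g: 0 for g in genes[30:]}
        table = modlink.module_deg_enrichment(
            _assignment(labels), GeneSet("u", [], "up"), GeneSet("d", [], "down"), set(genes)
        )
        assert (table["p_all"] == 1.0).all()

    def test_null_calibration(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(300)]
        labels = {g: (i // 60 + 1 if i < 240 else 0) for i, g in enumerate(genes)}
        assignment = _assignment(labels)
        hits = trials = 0
        for _ in range(200):
            deg_genes = rng.choice(genes, size=30, replace=False)
            table = modlink.module_deg_enrichment(
                assignment,
                GeneSet("u", deg_genes[:15], "up"),
                GeneSet("d", deg_genes[15:], "down"),
                set(genes),
            )
            hits += int((table["p_all"] < 0.05).sum())
            trials += len(table)
        rate = hits / trials
        assert 0.01 < rate < 0.10


class TestTraitAssociation:
    def test_perfect_correlation(self):
        rng = np.random.default_rng(2)
        consumption = rng.uniform(5, 15, 20)
        eig = pd.DataFrame({1: consumption})
        meta = pd.DataFrame(
            {"group": ["CIE"] * 10 + ["Air"] * 10, "consumption": consumption,
             "preference": rng.uniform(0, 1, 20)}
        )
        table = modlink.eigengene_trait_association(eig, meta)
        row = table[(table["module"] == 1) & (table["trait"] == "consumption")].iloc[0]
        assert row["r"] == pytest.approx(1.0)
        assert row["p"] < 1e-12

    def test_constant_trait_skipped(self):
        eig = pd.DataFrame({1: np.arange(10.0)})
        meta = pd.DataFrame(
            {"group": ["CIE"] * 10, "consumption": np.ones(10), "preference": np.arange(10.0)}
        )
        with pytest.warns(UserWarning):
            table = modlink.eigengene_trait_association(eig, meta)
        assert set(table["trait"]) == {"preference"}

    def test_permuted_trait_null(self):
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            eig = pd.DataFrame({1: rng.standard_normal(20)})
            meta = pd.DataFrame(
                {"group": rng.permutation(["CIE"] * 10 + ["Air"] * 10),
                 "consumption": rng.uniform(5, 15, 20),
                 "preference": rng.uniform(0, 1, 20)}
            )
            table = modlink.eigengene_trait_association(eig, meta, traits=("consumption",))
            pvals.append(table["p"].iloc[0])
        assert abs(np.mean(pvals) - 0.5) < 0.08
        assert (np.array(pvals) < 0.05).mean() < 0.12


class TestSelectCieModules:
    def test_or_rule(self):
        enrich = pd.DataFrame({"module": [1, 2, 3], "p_all": [0.9, 0.01, 0.8]})
        assoc = pd.DataFrame(
            {"module": [1, 2, 3], "trait": ["group"] * 3, "p": [0.01, 0.5, 0.9],
             "r": [0.8, 0.1, 0.0], "n": [20] * 3}
        )
        selected = modlink.select_cie_modules(enrich, assoc)
        assert set(selected["module"]) == {1, 2}
        assert selected.set_index("module").loc[1, "trait_correlated"]
        assert selected.set_index("module").loc[2, "deg_enriched"]

    def test_nothing_significant(self):
        enrich = pd.DataFrame({"module": [1], "p_all": [0.9]})
        assoc = pd.DataFrame({"module": [1], "trait": ["group"], "p": [0.9],
                              "r": [0.0], "n": [20]})
        assert len(modlink.select_cie_modules(enrich, assoc)) == 0


class TestOverrepresentation:
    def test_exact_set_is_top_hit(self):
        universe = {f"g{i}" for i in range(100)}
        collections = {
            "setA": {f"g{i}" for i in range(10)},
            "setB": {f"g{i}" for i in range(40, 80)},
        }
        table = modlink.gene_set_overrepresentation(
            {"query": collections["setA"]}, collections, universe
        )
        assert table.iloc[0]["set"] == "setA"
        assert table.iloc[0]["p_adj"] == pytest.approx(min(1.0, table.iloc[0]["p"] * 2))

    def test_bonferroni_definition_and_bound(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(200)]
        collections = {f"s{k}": set(rng.choice(universe, 20, replace=False)) for k in range(8)}
        queries = {"q": set(rng.choice(universe, 25, replace=False))}
        table = modlink.gene_set_overrepresentation(queries, collections, set(universe))
        np.testing.assert_allclose(
            table["p_adj"], np.minimum(1.0, table["p"] * len(table))
        )
        assert (table["p_adj"] >= table["p"] - 1e-15).all()

    def test_random_queries_null_rate(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(400)]
        collections = {f"s{k}": set(rng.choice(universe, 30, replace=False)) for k in range(10)}
        hits = trials = 0
        for _ in range(60):
            queries = {"q": set(rng.choice(universe, 30, replace=False))}
            table = modlink.gene_set_overrepresentation(
                queries, collections, set(universe), correction="none"
            )
            hits += int((table["p"] < 0.05).sum())
            trials += len(table)
        assert hits / trials < 0.12

    def test_disjoint_set_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            table = modlink.gene_set_overrepresentation(
                {"q": {"g1"}}, {"out": {"zz"}, "in": {"g1", "g2"}}, {"g1", "g2", "g3"}
            )
        assert set(table["set"]) == {"in"}


class TestGmtIo:
    def test_roundtrip(self, tmp_path):
        sets = {"a": frozenset({"g1", "g2"}), "b": frozenset({"g3"})}
        path = tmp_path / "sets.gmt"
        modlink.write_gmt(sets, path)
        assert modlink.read_gmt(path) == sets

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_name\n")
        with pytest.raises(ValueError):
            modlink.read_gmt(path)


class TestCrossTissueOverlap:
    def test_identical_assignments_self_overlap(self):
        genes = [f"g{i}" for i in range(300)]
        labels = {g: (i // 100 + 1 if i < 200 else 0) for i, g in enumerate(genes)}
        a = _assignment(labels)
        table = modlink.cross_tissue_overlap(a, a)
        diag = table[table["module_a"] == table["module_b"]]
        assert (diag["p"] < 1e-10).all()

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(200)]
        pvals = []
        for _ in range(100):
            la = rng.permutation([1] * 60 + [2] * 60 + [0] * 80)
            lb = rng.permutation([1] * 60 + [2] * 60 + [0] * 80)
            table = modlink.cross_tissue_overlap(
                _assignment(dict(zip(genes, la))), _assignment(dict(zip(genes, lb)))
            )
            pvals.extend(table["p"])
        pvals = np.asarray(pvals)
        # discrete p-values are conservative; check mean and tail mass
        assert 0.35 < pvals.mean() < 0.75
        assert (pvals < 0.05).mean() < 0.12

    def test_disjoint_universes_rejected(self):
        a = _assignment({"g1": 1, "g2": 1, "g3": 1})
        b = _assignment({"h1": 1, "h2": 1, "h3": 1})
        with pytest.raises(ValueError):
            modlink.cross_tissue_overlap(a, b)


def _overlap_table(pairs):
    return pd.DataFrame(
        [
            {"module_a": a, "module_b": b, "size_a": 50, "size_b": 50,
             "universe": 500, "overlap": 40, "p": p}
            for a, b, p in pairs
        ]
    )


class TestMetaNetwork:
    def test_blood_module_with_two_brain_regions_flagged(self):
        overlaps = {
            ("BLD", "PFC"): _overlap_table([(1, 1, 1e-8)]),
            ("BLD", "AMY"): _overlap_table([(1, 1, 1e-6)]),
        }
        cie = {"BLD": {1}, "PFC": {1}, "AMY": {1}}
        net = modlink.build_meta_network(overlaps, cie)
        assert ("BLD", 1) in net.blood_brain_nodes()

    def test_single_brain_region_not_flagged(self):
        overlaps = {("BLD", "PFC"): _overlap_table([(1, 1, 1e-8)])}
        cie = {"BLD": {1}, "PFC": {1}}
        net = modlink.build_meta_network(overlaps, cie)
        assert net.blood_brain_clusters == []
        assert not net.graph.nodes[("BLD", 1)]["blood_brain"]

    def test_edge_set_invariant_to_tissue_order(self):
        pairs = {
            ("BLD", "PFC"): _overlap_table([(1, 1, 1e-8)]),
            ("AMY", "BLD"): _overlap_table([(2, 1, 1e-7)]),
            ("AMY", "PFC"): _overlap_table([(2, 1, 1e-4)]),
        }
        cie = {"BLD": {1}, "PFC": {1}, "AMY": {2}}
        nets = []
        for order in (list(pairs), list(reversed(list(pairs)))):
            net = modlink.build_meta_network({k: pairs[k] for k in order}, cie)
            nets.append({frozenset(e) for e in net.graph.edges()})
        assert nets[0] == nets[1]

    def test_insignificant_overlap_makes_no_edge(self):
        overlaps = {("BLD", "PFC"): _overlap_table([(1, 1, 0.2)])}
        net = modlink.build_meta_network(overlaps, {"BLD": {1}, "PFC": {1}})
        assert net.graph.number_of_edges() == 0

    def test_export_formats(self, tmp_path):
        overlaps = {
            ("BLD", "PFC"): _overlap_table([(1, 1, 1e-8)]),
            ("BLD", "AMY"): _overlap_table([(1, 1, 1e-6)]),
        }
        net = modlink.build_meta_network(overlaps, {"BLD": {1}, "PFC": {1}, "AMY": {1}})
        sif = tmp_path / "net.sif"
        graphml = tmp_path / "net.graphml"
        net.write_sif(sif)
        net.write_graphml(graphml)
        assert "BLD.1" in sif.read_text()
        import networkx as nx

        g = nx.read_graphml(graphml)
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
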