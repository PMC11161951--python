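"""Correlation primitives, sponge test and ceRNA network assembly."""
from __future__ import annotations

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr

import cerna_forge as cf
from cerna_forge.cerna import (
    CorrelationPair,
    build_cerna_network,
    export_network,
    pearson_cc,
    select_coexpr_pairs,
    select_mirna_pairs,
    spearman_cc,
    sponge_test,
)
from cerna_forge.io import read_sif


def sponge_oracle(x, M, N, U):
    """Exhaustive rational enumeration of P(shared >= x)."""
    total = Fraction(0)
    denom = comb(U, N)
    for i in range(x, min(M, N) + 1):
        if N - i <= U - M:
            total += Fraction(comb(M, i) * comb(U - M, N - i), denom)
    return float(total)


class TestCorrelations:
    def test_anti_monotone_gives_minus_one(self):
        x = np.array([1.0, 5.0, 9.0, 12.0, 20.0, 33.0])
        assert spearman_cc(x, -(x ** 3)) == -1.0

    def test_identity_gives_plus_one(self):
        x = np.arange(6.0)
        assert spearman_cc(x, x) == 1.0

    def test_rank_difference_formula_by_hand(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 = 6 at n = 6
        scc = spearman_cc([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5])
        assert scc == pytest.approx(1 - 6 * 6 / (6 * 35), abs=1e-12)

    def test_pearson_affine_and_reflection(self):
        x = np.array([0.0, 1.5, 2.0, 7.0])
        assert pearson_cc(x, 3 * x + 1) == pytest.approx(1.0)
        assert pearson_cc(x, -x) == pytest.approx(-1.0)

    def test_pearson_matches_direct_moment_computation(self):
        x, y = np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 3.0])
        expected = np.cov(x, y, ddof=0)[0, 1] / (x.std() * y.std())
        assert pearson_cc(x, y) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_on_random_length6_vectors(self):
        # independent rank/moment oracle over many random vectors
        rng = np.random.default_rng(99)
        for _ in range(2000):
            x, y = rng.normal(size=6), rng.normal(size=6)
            assert pearson_cc(x, y) == pytest.approx(pearsonr(x, y).statistic, abs=1e-12)
            assert spearman_cc(x, y) == pytest.approx(
                spearmanr(x, y).statistic, abs=1e-12
            )

    def test_ties_use_midranks(self):
        x = np.array([1.0, 1.0, 2.0, 3.0])
        y = np.array([5.0, 5.0, 7.0, 9.0])
        assert spearman_cc(x, y) == pytest.approx(spearmanr(x, y).statistic, abs=1e-12)

    def test_zero_variance_is_nan(self):
        assert np.isnan(pearson_cc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
        assert np.isnan(spearman_cc([2.0, 2.0, 2.0], [1.0, 2.0, 3.0]))

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            pearson_cc([1.0, 2.0], [3.0, 4.0])


class TestSpongeTest:
    def test_x_zero_gives_one(self):
        assert sponge_test(0, 5, 7, 50) == 1.0

    def test_spot_value_one_over_120(self):
        assert sponge_test(3, 3, 3, 10) == pytest.approx(1 / 120, abs=1e-12)

    def test_spot_value_u20(self):
        # 1 - [C(5,0)C(15,4) + C(5,1)C(15,3)] / C(20,4)
        expected = 1 - (comb(15, 4) + 5 * comb(15, 3)) / comb(20, 4)
        assert sponge_test(2, 5, 4, 20) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.24871, abs=5e-6)

    def test_matches_enumeration_for_all_universes_up_to_30(self):
        for U in range(1, 31, 2):
            for M in range(0, U + 1, 2):
                for N in range(0, U + 1, 3):
                    for x in range(0, min(M, N) + 1):
                        assert sponge_test(x, M, N, U) == pytest.approx(
                            sponge_oracle(x, M, N, U), abs=1e-12
                        )

    def test_non_increasing_in_x(self):
        values = [sponge_test(x, 8, 6, 40) for x in range(7)]
        assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))

    def test_preconditions_enforced(self):
        with pytest.raises(ValueError):
            sponge_test(4, 3, 5, 10)
        with pytest.raises(ValueError):
            sponge_test(1, 11, 5, 10)


def _expr(values_by_class, samples=6):
    cols = [f"s{j}" for j in range(samples)]
    out = {}
    for cls, rows in values_by_class.items():
        frame = pd.DataFrame(
            {fid: np.asarray(v, dtype=float) for fid, v in rows.items()}, index=cols
        ).T
        out[cls] = cf.ExpressionMatrix(frame, cls, "FPKM" if cls in ("mRNA", "lncRNA")
                                       else ("RPM" if cls == "circRNA" else "TPM"))
    return out


class TestSelection:
    up = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
    down = [12.0, 11.0, 10.0, 3.0, 2.0, 1.0]

    def _fixture(self):
        expr = _expr({
            "mRNA": {"G1": self.up, "G2": self.down},
            "lncRNA": {},
            "circRNA": {"C1": self.up},
            "miRNA": {"M1": self.down, "M2": self.up},
        })
        tmap = cf.TargetMap.from_pairs(
            [("M1", "C1"), ("M1", "G1"), ("M2", "G1"), ("M1", "G2")]
        )
        de = {"mRNA": {"G1", "G2"}, "lncRNA": set(), "circRNA": {"C1"},
              "miRNA": {"M1", "M2"}}
        return expr, tmap, de

    def test_anti_correlated_map_pairs_retained(self):
        expr, tmap, de = self._fixture()
        pairs = select_mirna_pairs(expr, tmap, de)
        got = {(p.a, p.b) for p in pairs}
        # M1 is anti-monotone with C1 and G1; M2 is anti-monotone with G2
        # but (M2, G2) is not in the map; (M1, G2) is in the map but positive
        assert got == {("M1", "C1"), ("M1", "G1")}
        assert all(p.coefficient < -0.7 and p.kind == "SCC" for p in pairs)

    def test_non_de_member_excluded(self):
        expr, tmap, de = self._fixture()
        de["miRNA"] = set()
        assert select_mirna_pairs(expr, tmap, de) == []

    def test_threshold_is_strict(self):
        expr, tmap, de = self._fixture()
        assert select_mirna_pairs(expr, tmap, de, scc_max=-1.0) == []
        assert len(select_mirna_pairs(expr, tmap, de, scc_max=-0.999)) == 2

    def test_coexpr_pairs_classes_and_threshold(self):
        expr, tmap, de = self._fixture()
        pairs = select_coexpr_pairs(expr, de)
        got = {(p.a, p.b) for p in pairs}
        assert got == {("C1", "G1")}  # C1 ~ G1 positively; G2 anti-correlated
        pairs_strict = select_coexpr_pairs(expr, de, pcc_min=1.0)
        assert pairs_strict == []

    def test_sample_order_mismatch_rejected(self):
        expr, tmap, de = self._fixture()
        shuffled = expr["mRNA"].data[[f"s{j}" for j in (1, 0, 2, 3, 4, 5)]]
        expr["mRNA"] = cf.ExpressionMatrix(shuffled, "mRNA", "FPKM")
        with pytest.raises(ValueError, match="sample order"):
            select_mirna_pairs(expr, tmap, de)


class TestNetwork:
    def _one_triplet_inputs(self):
        class_of = {"C1": "circRNA", "G1": "mRNA", "M1": "miRNA"}
        mirna_pairs = [
            CorrelationPair("M1", "C1", "SCC", -0.95, 6),
            CorrelationPair("M1", "G1", "SCC", -0.9, 6),
        ]
        coexpr = [CorrelationPair("C1", "G1", "PCC", 0.97, 6)]
        tmap = cf.TargetMap.from_pairs(
            [("M1", "C1"), ("M1", "G1")] + [(f"MX{i}", "ZZ") for i in range(48)]
        )
        return mirna_pairs, coexpr, tmap, class_of

    def test_single_surviving_triplet_topology(self):
        mirna_pairs, coexpr, tmap, class_of = self._one_triplet_inputs()
        net = build_cerna_network(mirna_pairs, coexpr, tmap, class_of=class_of)
        assert net.pair_counts() == {
            "circRNA-miRNA": 1, "lncRNA-miRNA": 0, "miRNA-mRNA": 1, "cerna_pair": 1,
        }
        assert net.node_counts() == {"mRNA": 1, "lncRNA": 0, "circRNA": 1, "miRNA": 1}
        # x=1 shared of M=1, N=1 in U=49 -> p = 1/49 < 0.05
        [result] = net.sponge_tests
        assert (result.x, result.M, result.N, result.U) == (1, 1, 1, 49)
        assert result.pvalue == pytest.approx(1 / 49, abs=1e-12)

    def test_empty_inputs_empty_network(self):
        tmap = cf.TargetMap.from_pairs([("M1", "G1")])
        net = build_cerna_network([], [], tmap, class_of={})
        assert net.n_nodes == 0 and net.n_edges == 0
        assert all(v == 0 for v in net.pair_counts().values())

    def test_alpha_strictness_excludes_boundary(self):
        mirna_pairs, coexpr, tmap, class_of = self._one_triplet_inputs()
        p = 1 / 49
        net = build_cerna_network(mirna_pairs, coexpr, tmap, class_of=class_of,
                                  alpha=p)  # strict: p < alpha fails at equality
        assert net.n_edges == 0

    def test_counts_match_brute_force_tally(self, default_bundle_run):
        report = default_bundle_run["report"]["network"]
        edges = default_bundle_run["edges"]
        sponges = sum(1 for _, rel, _ in edges if rel == "sponges")
        targets = sum(1 for _, rel, _ in edges if rel == "targets")
        assert report["pairs"]["cerna_pair"] == sponges
        assert (report["pairs"]["circRNA-miRNA"] + report["pairs"]["lncRNA-miRNA"]
                + report["pairs"]["miRNA-mRNA"]) == targets

    def test_degree_equals_incident_edge_count(self, default_bundle_run):
        nodes = pd.read_csv(default_bundle_run["outdir"] / "nodes.tsv", sep="\t")
        tally: dict[str, int] = {}
        for a, _, b in default_bundle_run["edges"]:
            tally[a] = tally.get(a, 0) + 1
            tally[b] = tally.get(b, 0) + 1
        for _, row in nodes.iterrows():
            assert row["degree"] == tally.get(row["id"], 0)


class TestExport:
    def test_empty_network_headers_only(self, tmp_path):
        net = cf.CeRNANetwork()
        paths = export_network(net, tmp_path)
        assert paths["sif"].read_text() == ""
        assert paths["nodes"].read_text() == "id\trna_class\tdegree\n"
        assert paths["edges"].read_text().count("\n") == 1

    def test_sif_round_trip_and_determinism(self, tmp_path):
        mirna_pairs = [
            CorrelationPair("M1", "C1", "SCC", -0.95, 6),
            CorrelationPair("M1", "G1", "SCC", -0.9, 6),
        ]
        coexpr = [CorrelationPair("C1", "G1", "PCC", 0.97, 6)]
        tmap = cf.TargetMap.from_pairs([("M1", "C1"), ("M1", "G1")])
        class_of = {"C1": "circRNA", "G1": "mRNA", "M1": "miRNA"}
        net = build_cerna_network(mirna_pairs, coexpr, tmap, class_of=class_of,
                                  universe_size=40)
        p1 = export_network(net, tmp_path / "x")
        p2 = export_network(net, tmp_path / "y")
        assert p1["sif"].read_bytes() == p2["sif"].read_bytes()
        edges = read_sif(p1["sif"])
        expected = {("C1", "sponges", "G1"), ("M1", "targets", "C1"),
                    ("M1", "targets", "G1")}
        assert set(edges) == expected and len(edges) == 3
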