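"""NetExpress: weighted neighbour-expression sums, file ingest, invariances."""

import numpy as np
import pytest

from crisprattn.errors import LookupError_, ParseError
from crisprattn.netexpress import (
    ExpressionProfile,
    GeneNetwork,
    compute_all,
    compute_netexpress,
    read_expression,
    read_network,
)


def brute_force_score(gene, net, expr):
    return sum(w * expr.values.get(j, 0.0) for j, w in net.neighbors(gene))


class TestComputeNetexpress:
    def test_weighted_sum_example(self):
        net = GeneNetwork.from_edges([("A", "B", 0.5), ("A", "C", 1.0)])
        expr = ExpressionProfile("X", {"B": 2.0, "C": 3.0})
        assert compute_netexpress("A", net, expr).score == pytest.approx(4.0)

    def test_isolated_gene_scores_zero(self):
        net = GeneNetwork.from_edges([("A", "B", 1.0)])
        net.add_node("Z")
        expr = ExpressionProfile("X", {"A": 5.0, "B": 5.0})
        assert compute_netexpress("Z", net, expr).score == 0.0

    def test_unknown_gene_raises_distinct_from_zero(self):
        net = GeneNetwork.from_edges([("A", "B", 1.0)])
        with pytest.raises(LookupError_):
            compute_netexpress("missing", net, ExpressionProfile("X", {}))

    def test_missing_neighbour_contributes_zero_or_raises_in_strict(self):
        net = GeneNetwork.from_edges([("A", "B", 0.7), ("A", "C", 0.3)])
        expr = ExpressionProfile("X", {"B": 10.0})
        assert compute_netexpress("A", net, expr).score == pytest.approx(7.0)
        with pytest.raises(LookupError_):
            compute_netexpress("A", net, expr, strict=True)

    def test_linearity_in_expression(self, toy):
        doubled = ExpressionProfile(
            toy.expression.cell_line, {g: 2 * v for g, v in toy.expression.values.items()}
        )
        for gene in toy.network.nodes:
            s1 = compute_netexpress(gene, toy.network, toy.expression).score
            s2 = compute_netexpress(gene, toy.network, doubled).score
            assert s2 == pytest.approx(2 * s1)

    def test_path_network_hand_sums(self, toy):
        for gene, expected in toy.expected_netexpress.items():
            assert compute_netexpress(gene, toy.network, toy.expression).score == pytest.approx(
                expected
            )


class TestComputeAll:
    def test_matches_per_gene_loop_on_random_graph(self, rng):
        genes = [f"g{i}" for i in range(100)]
        edges = []
        for _ in range(300):
            a, b = rng.choice(100, size=2, replace=False)
            edges.append((genes[a], genes[b], float(rng.uniform(0.1, 1.0))))
        net = GeneNetwork.from_edges(edges)
        expr = ExpressionProfile(
            "X", {g: float(rng.normal()) for g in rng.choice(genes, size=80, replace=False)}
        )
        allscores = compute_all(net, expr)
        for gene in net.nodes:
            assert allscores[gene].score == pytest.approx(brute_force_score(gene, net, expr))

    def test_empty_expression_zero_fill(self):
        net = GeneNetwork.from_edges([("A", "B", 1.0), ("B", "C", 1.0)])
        scores = compute_all(net, ExpressionProfile("X", {}))
        assert all(s.score == 0.0 for s in scores.values())

    def test_invariant_under_relabeling(self, rng):
        genes = [f"g{i}" for i in range(20)]
        edges = [
            (genes[a], genes[b], float(rng.uniform(0.1, 1.0)))
            for a, b in rng.choice(20, size=(40, 2))
            if a != b
        ]
        net = GeneNetwork.from_edges(edges)
        expr_vals = {g: float(rng.normal()) for g in genes}
        mapping = {g: f"x_{g}" for g in genes}
        net2 = GeneNetwork.from_edges([(mapping[a], mapping[b], w) for a, b, w in edges])
        scores1 = compute_all(net, ExpressionProfile("X", expr_vals))
        scores2 = compute_all(
            net2, ExpressionProfile("X", {mapping[g]: v for g, v in expr_vals.items()})
        )
        for g in net.nodes:
            assert scores2[mapping[g]].score == pytest.approx(scores1[g].score)


class TestFileIngest:
    def test_edge_list_roundtrip(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("geneA\tgeneB\tconfidence\nA\tB\t0.5\nB\tC\t0.8\n")
        net = read_network(p)
        assert net.graph.number_of_edges() == 2

    def test_duplicate_edges_collapse_to_max(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\t0.4\nB\tA\t0.9\n")
        net = read_network(p)
        assert net.graph["A"]["B"]["weight"] == pytest.approx(0.9)

    def test_negative_confidence_is_parse_error_with_line(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\t0.4\nB\tC\t-1\n")
        with pytest.raises(ParseError) as e:
            read_network(p)
        assert "line 2" in str(e.value)

    def test_string_raw_scores_rescaled(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("A\tB\t900\nB\tC\t400\n")
        net = read_network(p)
        assert net.graph["A"]["B"]["weight"] == pytest.approx(0.9)

    def test_expression_two_column_and_wide(self, tmp_path):
        two = tmp_path / "expr.tsv"
        two.write_text("gene\tvalue\nA\t1.5\nB\t2.5\n")
        prof = read_expression(two, cell_line="K562")
        assert prof.values["B"] == pytest.approx(2.5)
        wide = tmp_path / "wide.tsv"
        wide.write_text("gene\tK562\tA549\nA\t1\t9\nB\t2\t8\n")
        prof = read_expression(wide, cell_line="A549")
        assert prof.values["A"] == pytest.approx(9.0)
        with pytest.raises(ParseError):
            read_expression(wide, cell_line="NB4")
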