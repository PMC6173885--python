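import numpy as np
import pandas as pd
import pytest

from regcircuit import (
    DiffExpressionTable,
    FilterCriteria,
    RegulatoryNetwork,
    ValidationError,
    average_technical_replicates,
    filter_network,
    per_replicate_log2fc,
)

from conftest import expression_from_matrix, random_network, simple_de


class TestAverageTechnicalReplicates:
    def test_pair_mean(self):
        m = pd.DataFrame({"s1": [4.0], "s2": [6.0]}, index=["g"])
        expr = expression_from_matrix(m, groups=["X", "X"], bio=["b1", "b1"])
        out = average_technical_replicates(expr)
        assert out.abundance.loc["g", "b1"] == 5.0
        assert list(out.abundance.columns) == ["b1"]

    def test_single_replicate_identity(self):
        m = pd.DataFrame({"s1": [3.5]}, index=["g"])
        expr = expression_from_matrix(m, groups=["X"], bio=["b1"])
        out = average_technical_replicates(expr)
        assert out.abundance.loc["g", "b1"] == 3.5

    def test_random_matrix_matches_per_pair_mean(self):
        rng = np.random.default_rng(3)
        cols = [f"b{i}_t{j}" for i in range(3) for j in range(2)]
        m = pd.DataFrame(rng.uniform(0, 10, (10, 6)), columns=cols,
                         index=[f"g{i}" for i in range(10)])
        expr = expression_from_matrix(
            m, groups=["X"] * 6, bio=[c.split("_")[0] for c in cols]
        )
        out = average_technical_replicates(expr)
        for i in range(3):
            expected = (m[f"b{i}_t0"] + m[f"b{i}_t1"]) / 2
            np.testing.assert_allclose(out.abundance[f"b{i}"], expected)

    def test_groups_preserved(self):
        m = pd.DataFrame({"s1": [1.0], "s2": [2.0]}, index=["g"])
        expr = expression_from_matrix(m, groups=["X", "Y"], bio=["b1", "b2"])
        out = average_technical_replicates(expr)
        assert list(out.samples["group"]) == ["X", "Y"]


class TestPerReplicateLog2fc:
    def test_fourfold(self):
        m = pd.DataFrame({"a1": [2.0], "b1": [8.0]}, index=["g"])
        expr = expression_from_matrix(m, groups=["A", "B"], bio=["a1", "b1"])
        out = per_replicate_log2fc(expr, ("A", "B"))
        assert out.loc["g", "b1"] == 2.0

    def test_equal_abundance_zero(self):
        m = pd.DataFrame({"a1": [5.0], "b1": [5.0]}, index=["g"])
        expr = expression_from_matrix(m, groups=["A", "B"], bio=["a1", "b1"])
        assert per_replicate_log2fc(expr, ("A", "B")).loc["g", "b1"] == 0.0

    def test_random_matches_direct_formula(self):
        rng = np.random.default_rng(11)
        cols = ["a1", "a2", "a3", "b1", "b2", "b3"]
        m = pd.DataFrame(rng.uniform(0.1, 20, (10, 6)), columns=cols,
                         index=[f"g{i}" for i in range(10)])
        expr = expression_from_matrix(m, groups=["A"] * 3 + ["B"] * 3, bio=cols)
        pc = 0.5
        out = per_replicate_log2fc(expr, ("A", "B"), pseudocount=pc)
        ref = m[["a1", "a2", "a3"]].mean(axis=1)
        for col in ["b1", "b2", "b3"]:
            expected = np.log2((m[col] + pc) / (ref + pc))
            np.testing.assert_allclose(out[col], expected)

    def test_zero_reference_gives_infinite_fold_change(self):
        m = pd.DataFrame({"a1": [0.0], "b1": [4.0]}, index=["g"])
        expr = expression_from_matrix(m, groups=["A", "B"], bio=["a1", "b1"])
        assert np.isposinf(per_replicate_log2fc(expr, ("A", "B")).loc["g", "b1"])

    def test_missing_group_errors(self):
        m = pd.DataFrame({"a1": [1.0]}, index=["g"])
        expr = expression_from_matrix(m, groups=["A"], bio=["a1"])
        with pytest.raises(ValidationError, match="absent"):
            per_replicate_log2fc(expr, ("A", "Z"))


def make_filter_fixture(rng_seed=0, n_edges=10):
    """Random network + expression/DE data with heterogeneous criteria."""
    rng = np.random.default_rng(rng_seed)
    net = random_network(rng_seed, n_tf=4, n_nontf=6, n_edges=n_edges)
    genes = sorted(net.nodes)
    cols = ["a1", "a2", "b1", "b2"]
    m = pd.DataFrame(rng.uniform(0, 10, (len(genes), 4)), index=genes,
                     columns=cols)
    # force some regulators undetected and some targets flat
    for g in genes[::3]:
        m.loc[g, ["b1", "b2"]] = m.loc[g, ["a1", "a2"]].mean()
    m.iloc[0] = 0.0
    expr = expression_from_matrix(m, groups=["A", "A", "B", "B"], bio=cols)
    sig = set(rng.choice(genes, size=len(genes) // 2, replace=False))
    de = DiffExpressionTable(records=pd.DataFrame(
        [(g, "A_vs_B", 1.0 if g in sig else 0.0, g in sig) for g in genes],
        columns=["gene", "comparison", "log2fc", "significant"],
    ))
    return net, expr, de


class TestFilterNetwork:
    def setup_method(self):
        edges = [("TFa", "geneB")]
        self.net = RegulatoryNetwork.from_edges(edges, tfs=["TFa"])

    def expr_with_lfc(self, lfcs):
        """TFa detected everywhere; geneB with given per-rep fold changes."""
        cols = ["a1", "a2", "a3", "b1", "b2", "b3"]
        ref = 4.0
        rows = {
            "TFa": [5.0] * 6,
            "geneB": [ref] * 3 + [ref * 2 ** l for l in lfcs],
        }
        m = pd.DataFrame(rows, index=cols).T
        return expression_from_matrix(m, groups=["A"] * 3 + ["B"] * 3, bio=cols)

    def test_edge_retained_when_all_replicates_pass(self):
        expr = self.expr_with_lfc([0.5, 0.6, 0.7])
        de = simple_de(["geneB"])
        out, report = filter_network(self.net, expr, de, FilterCriteria())
        assert out.edge_pairs() == {("TFa", "geneB")}
        assert report.n_retained == 1

    def test_flat_target_dropped_with_fold_change_reason(self):
        expr = self.expr_with_lfc([0.0, 0.0, 0.0])
        de = simple_de(["geneB"])
        out, report = filter_network(self.net, expr, de, FilterCriteria())
        assert out.n_edges == 0
        assert report.per_edge.iloc[0]["reason"] == "target-fold-change"

    def test_undetected_regulator_dropped(self):
        expr = self.expr_with_lfc([0.5, 0.6, 0.7])
        expr.abundance.loc["TFa"] = 0.0
        de = simple_de(["geneB"])
        _, report = filter_network(self.net, expr, de, FilterCriteria())
        assert report.per_edge.iloc[0]["reason"] == "regulator-detection"

    def test_insignificant_target_dropped(self):
        expr = self.expr_with_lfc([0.5, 0.6, 0.7])
        de = simple_de(["geneB"], significant=False)
        _, report = filter_network(self.net, expr, de, FilterCriteria())
        assert report.per_edge.iloc[0]["reason"] == "target-de-significance"

    def test_gene_absent_from_expression_is_not_detected(self):
        net = RegulatoryNetwork.from_edges(
            [("TFa", "geneB"), ("TFx", "geneB")], tfs=["TFa", "TFx"]
        )
        expr = self.expr_with_lfc([0.5, 0.6, 0.7])  # has no TFx row
        de = simple_de(["geneB"])
        out, report = filter_network(net, expr, de, FilterCriteria())
        assert ("TFx", "geneB") not in out.edge_pairs()
        assert "TFx" in report.missing_from_expression

    @pytest.mark.parametrize("rule", ["all", "any"])
    def test_retained_set_equals_per_edge_recheck(self, rule):
        """Brute-force oracle: re-evaluate (a) and (b) and (c) per edge."""
        net, expr, de = make_filter_fixture(5)
        crit = FilterCriteria(replicate_rule=rule)
        out, report = filter_network(net, expr, de, crit)

        avg = average_technical_replicates(expr)
        b_cols = [c for c in avg.abundance.columns
                  if avg.samples.loc[c, "group"] == "B"]
        ref = avg.abundance[[c for c in avg.abundance.columns
                             if avg.samples.loc[c, "group"] == "A"]].mean(axis=1)
        combine = all if rule == "all" else any
        sig = de.significant_genes("A_vs_B")
        expected = set()
        for e in net.edges:
            det = combine(
                avg.abundance.loc[e.regulator, c] > 0 for c in avg.abundance.columns
            )
            de_ok = e.target in sig
            with np.errstate(divide="ignore", invalid="ignore"):
                lfc_ok = combine(
                    abs(np.log2(avg.abundance.loc[e.target, c] / ref[e.target]))
                    >= 0.4
                    for c in b_cols
                )
            if det and de_ok and lfc_ok:
                expected.add(e.pair)
        assert out.edge_pairs() == expected

    def test_monotone_in_threshold(self):
        net, expr, de = make_filter_fixture(7, n_edges=15)
        prev = None
        for thr in (0.0, 0.4, 1.0, 2.0):
            out, _ = filter_network(net, expr, de,
                                    FilterCriteria(min_abs_log2fc=thr))
            assert out.edge_pairs() <= net.edge_pairs()
            if prev is not None:
                assert out.edge_pairs() <= prev
            prev = out.edge_pairs()

    def test_idempotent(self):
        net, expr, de = make_filter_fixture(9, n_edges=15)
        crit = FilterCriteria()
        once, _ = filter_network(net, expr, de, crit)
        twice, _ = filter_network(once, expr, de, crit)
        assert twice.edge_pairs() == once.edge_pairs()
        assert twice.is_tf == once.is_tf

    def test_report_conservation(self):
        net, expr, de = make_filter_fixture(13, n_edges=20)
        _, report = filter_network(net, expr, de, FilterCriteria())
        assert report.n_retained + sum(report.reason_counts().values()) \
            == report.n_input == net.n_edges
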