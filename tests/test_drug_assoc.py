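"""Drug-response screens, labelling conventions and multi-layer bias."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from triadnet.drug_assoc import (
    DrugAssociation,
    cag_bias,
    ffl_drug_network,
    gene_drug_screen,
    score_drug_screen,
)
from triadnet.grn_ffl import FFLTriad
from triadnet.synthetic_data import (
    SimConfig,
    generate_drug_response,
    generate_expression,
    generate_truth,
)


def _expr(rng, n_genes=10, n_samples=200):
    return pd.DataFrame(
        rng.standard_normal((n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n_samples)],
    )


class TestLabels:
    def test_inconsistent_label_rejected(self):
        with pytest.raises(ValueError):
            DrugAssociation("g", "d", rho=-0.5, p_value=0.001, fdr=0.01, label="resistant")

    def test_planted_negative_effect_labeled_sensitive(self, rng):
        expr = _expr(rng, n_samples=300)
        resp = pd.DataFrame(
            rng.standard_normal((300, 2)) * 0.3,
            index=expr.columns,
            columns=["dA", "dB"],
        )
        resp["dA"] -= expr.loc["g0"]
        result = gene_drug_screen(expr, resp)
        labels = {(a.feature, a.drug): a.label for a in result.associations}
        assert labels[("g0", "dA")] == "sensitive"

    def test_positive_effect_labeled_resistant(self, rng):
        expr = _expr(rng, n_samples=300)
        resp = pd.DataFrame(
            rng.standard_normal((300, 1)) * 0.3, index=expr.columns, columns=["d"]
        )
        resp["d"] += expr.loc["g1"]
        result = gene_drug_screen(expr, resp)
        assert any(
            a.feature == "g1" and a.label == "resistant" for a in result.associations
        )

    def test_negating_response_flips_every_label(self, rng):
        expr = _expr(rng, 5, 150)
        resp = pd.DataFrame(
            rng.standard_normal((150, 3)) * 0.2, index=expr.columns,
            columns=list("xyz"),
        )
        resp["x"] -= expr.loc["g0"]
        resp["y"] += expr.loc["g2"]
        a = gene_drug_screen(expr, resp)
        b = gene_drug_screen(expr, -resp)
        flip = {"sensitive": "resistant", "resistant": "sensitive"}
        assert {(x.feature, x.drug, flip[x.label]) for x in a.associations} == {
            (x.feature, x.drug, x.label) for x in b.associations
        }


class TestScreenMechanics:
    def test_boundary_rs_excluded_by_strict_inequality(self):
        # retention requires |Rs| strictly above the threshold: a pair whose
        # |Rs| equals the threshold exactly is excluded
        x = np.arange(1, 6, dtype=float)
        expr = pd.DataFrame([x], index=["g"], columns=list("abcde"))
        y = np.array([2.0, 1, 4, 3, 5])  # Rs = 0.8 exactly
        resp = pd.DataFrame({"d": y}, index=list("abcde"))
        at = gene_drug_screen(expr, resp, rs_threshold=0.8, fdr_threshold=1.1)
        below = gene_drug_screen(expr, resp, rs_threshold=0.79, fdr_threshold=1.1)
        assert at.associations == ()
        assert len(below.associations) == 1

    def test_monotone_transform_invariance(self, rng):
        expr = _expr(rng, 4, 100)
        resp = pd.DataFrame(
            rng.standard_normal((100, 2)), index=expr.columns, columns=["d1", "d2"]
        )
        a = gene_drug_screen(expr, resp).tested
        b = gene_drug_screen(expr, np.exp(resp)).tested
        np.testing.assert_allclose(a["rho"], b["rho"], atol=1e-12)

    def test_missing_values_pairwise_deleted(self, rng):
        expr = _expr(rng, 3, 50)
        resp = pd.DataFrame(
            rng.standard_normal((50, 2)), index=expr.columns, columns=["d1", "d2"]
        )
        resp.iloc[:10, 0] = np.nan
        result = gene_drug_screen(expr, resp)
        row = result.tested.query("feature == 'g0' and drug == 'd1'")
        ref_r, ref_p = stats.spearmanr(
            expr.loc["g0"].iloc[10:], resp["d1"].iloc[10:]
        )
        assert row["rho"].iloc[0] == pytest.approx(ref_r)
        assert row["p"].iloc[0] == pytest.approx(ref_p)

    def test_constant_score_skipped(self, rng):
        resp = pd.DataFrame(
            rng.standard_normal((30, 2)), index=[f"s{i}" for i in range(30)],
            columns=["d1", "d2"],
        )
        score = pd.Series(np.ones(30), index=resp.index, name="score")
        result = score_drug_screen(score, resp)
        assert result.associations == ()
        assert all(s[2] == "degenerate_feature_or_response" for s in result.skipped)

    def test_bh_family_is_whole_screen(self, rng):
        expr = _expr(rng, 6, 80)
        resp = pd.DataFrame(
            rng.standard_normal((80, 4)), index=expr.columns,
            columns=[f"d{i}" for i in range(4)],
        )
        tested = gene_drug_screen(expr, resp).tested
        from triadnet.stats_core import bh_adjust

        np.testing.assert_allclose(
            tested["fdr"], bh_adjust(tested["p"].to_numpy()).adjusted
        )

    def test_null_screen_retains_nothing_much(self, rng):
        expr = _expr(rng, 50, 100)
        resp = pd.DataFrame(
            rng.standard_normal((100, 10)), index=expr.columns,
            columns=[f"d{i}" for i in range(10)],
        )
        result = gene_drug_screen(expr, resp)
        assert len(result.associations) <= 2


class TestEndToEndScoreScreen:
    def test_score_built_from_sensitivity_genes_is_sensitive(self):
        cfg = SimConfig(seed=13, n_samples=300)
        truth = generate_truth(cfg)
        expr, _ = generate_expression(truth, cfg)
        gene = truth.targets[0]
        resp = generate_drug_response(expr, {(gene, "dX"): -1.0}, 0.3, seed=2)
        z = (expr.loc[gene] - expr.loc[gene].mean()) / expr.loc[gene].std(ddof=1)
        score = pd.Series(z.to_numpy() * 2.0, index=expr.columns, name="ptpscore")
        result = score_drug_screen(score, resp)
        assert any(a.drug == "dX" and a.label == "sensitive" for a in result.associations)

    def test_permuted_score_rarely_retained(self, rng):
        cfg = SimConfig(seed=14, n_samples=200)
        truth = generate_truth(cfg)
        expr, _ = generate_expression(truth, cfg)
        gene = truth.targets[0]
        resp = generate_drug_response(expr, {(gene, "dX"): -1.0}, 0.3, seed=3)
        z = (expr.loc[gene] - expr.loc[gene].mean()) / expr.loc[gene].std(ddof=1)
        hits = 0
        for _ in range(40):
            perm = pd.Series(
                rng.permutation(z.to_numpy()), index=expr.columns, name="s"
            )
            hits += bool(score_drug_screen(perm, resp).associations)
        assert hits / 40 <= 0.05 + 0.1


class TestCagBias:
    def test_identical_groups_yield_no_fdr_hits(self, rng):
        mat = pd.DataFrame(
            rng.standard_normal((20, 100)),
            index=[f"g{i}" for i in range(20)],
            columns=[f"s{i}" for i in range(100)],
        )
        records, _ = cag_bias(
            high=mat.columns[:50], low=mat.columns[50:], layers={"mRNA": mat}
        )
        assert sum(r.fdr < 0.05 for r in records) == 0

    def test_planted_mrna_shift_detected(self, rng):
        mat = pd.DataFrame(
            rng.standard_normal((5, 200)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(200)],
        )
        high, low = list(mat.columns[:100]), list(mat.columns[100:])
        mat.loc["g0", high] += 1.5
        records, _ = cag_bias(high, low, {"mRNA": mat})
        rec = next(r for r in records if r.gene == "g0")
        assert rec.fdr < 0.05
        assert rec.statistic == pytest.approx(1.5, abs=0.5)
        assert rec.biased_group == "high"

    def test_binary_layer_fisher_matches_exact_oracle(self):
        # 20/100 vs 2/100 mutated
        mut = pd.DataFrame(
            [[1] * 20 + [0] * 80 + [1] * 2 + [0] * 98],
            index=["g0"],
            columns=[f"s{i}" for i in range(200)],
        )
        high, low = [f"s{i}" for i in range(100)], [f"s{i}" for i in range(100, 200)]
        records, _ = cag_bias(high, low, {"mutation": mut})
        expected_p = stats.fisher_exact([[20, 80], [2, 98]])[1]
        assert records[0].p_value == pytest.approx(expected_p, abs=1e-12)
        assert records[0].statistic == pytest.approx(0.18)
        assert records[0].biased_group == "high"

    def test_missing_gene_recorded_untested(self, rng):
        mat = pd.DataFrame(
            rng.standard_normal((2, 20)),
            index=["g0", "g1"],
            columns=[f"s{i}" for i in range(20)],
        )
        _, untested = cag_bias(
            mat.columns[:10], mat.columns[10:], {"mRNA": mat}, genes=["g0", "g1", "gX"]
        )
        assert ("gX", "mRNA") in untested


class TestIntegratedNetwork:
    def _triads(self):
        return [
            FFLTriad("TF1", "miR1", "g1", "TF-FFL"),
            FFLTriad("TF2", "miR1", "g2", "composite-FFL"),
        ]

    def test_no_associations_is_plain_projection(self):
        g = ffl_drug_network(self._triads())
        assert not [n for n, d in g.nodes(data=True) if d["node_class"] == "drug"]

    def test_single_association_adds_one_drug_node(self):
        assoc = [DrugAssociation("g1", "dA", -0.5, 1e-4, 1e-3, "sensitive")]
        g = ffl_drug_network(self._triads(), assoc)
        assert g.nodes["dA"]["node_class"] == "drug"
        assert g.edges["g1", "dA"]["label"] == "sensitive"

    def test_gene_sensitive_mirna_resistant_pattern(self):
        gene_assoc = [DrugAssociation("g1", "dA", -0.6, 1e-5, 1e-4, "sensitive")]
        mirna_assoc = [DrugAssociation("miR1", "dA", 0.55, 1e-4, 1e-3, "resistant")]
        g = ffl_drug_network(self._triads(), gene_assoc, mirna_assoc)
        assert g.edges["g1", "dA"]["label"] == "sensitive"
        assert g.edges["miR1", "dA"]["label"] == "resistant"

    def test_association_for_absent_feature_ignored(self):
        assoc = [DrugAssociation("nowhere", "dZ", -0.9, 1e-9, 1e-8, "sensitive")]
        g = ffl_drug_network(self._triads(), assoc)
        assert "dZ" not in g
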