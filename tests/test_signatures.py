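"""Signature derivation, temporal classes, and induction-repression sets."""

import numpy as np
import pandas as pd
import pytest

from grnx.diffexpr import DETable, PairwiseNB
from grnx.io_formats import ExpressionMatrix, SampleMeta
from grnx.signatures import (
    ContrastCriterion,
    FoldGapCriterion,
    GeneSignature,
    SignatureRule,
    classify_temporal,
    derive_signature,
    fraction_of_signature,
    load_rules,
    repressed_by_induction,
)

from conftest import two_group_matrix


def _table(key_genes: dict[str, str], cond_a="A", cond_b="B", time_h=36.0) -> DETable:
    """Tiny DE table with prescribed directions."""
    frame = pd.DataFrame(
        {
            "base_mean": 100.0,
            "log2fc": [3.0 if d == "up" else -3.0 if d == "down" else 0.0
                       for d in key_genes.values()],
            "p": 1e-6,
            "padj": [1e-5 if d != "none" else 0.9 for d in key_genes.values()],
            "direction": list(key_genes.values()),
        },
        index=pd.Index(list(key_genes), name="gene_id"),
    )
    return DETable(cond_a, cond_b, time_h, 0.05, 1.0, frame)


class TestDeriveSignature:
    def test_conjunction_is_intersection(self):
        tables = {
            "c1": _table({"g1": "up", "g2": "up", "g3": "none"}),
            "c2": _table({"g1": "up", "g2": "none", "g3": "up"}),
        }
        rule = SignatureRule("sig", (ContrastCriterion("c1", "up"),
                                     ContrastCriterion("c2", "up")))
        sig = derive_signature(tables, rule)
        assert sig.gene_ids == {"g1"}

    def test_missing_contrast_fatal(self):
        rule = SignatureRule("sig", (ContrastCriterion("absent", "up"),))
        with pytest.raises(KeyError, match="absent"):
            derive_signature({}, rule)

    def test_empty_intersection_warns(self):
        tables = {"c1": _table({"g1": "up"}), "c2": _table({"g1": "down"})}
        rule = SignatureRule("sig", (ContrastCriterion("c1", "up"),
                                     ContrastCriterion("c2", "up")))
        with pytest.warns(UserWarning, match="empty"):
            sig = derive_signature(tables, rule)
        assert len(sig) == 0

    def test_peak_time_filter_excludes_wrong_maximum(self):
        # g1 peaks at 36 h, g2 at 60 h; rule demands peak at 60 h
        counts = pd.DataFrame(
            {
                "A_12h_r1": [10, 10], "A_24h_r1": [50, 20],
                "A_36h_r1": [200, 50], "A_60h_r1": [100, 400],
            },
            index=["g1", "g2"],
        )
        metas = [SampleMeta(f"A_{t:g}h_r1", "A", t, 1) for t in (12, 24, 36, 60)]
        matrix = ExpressionMatrix(counts, metas)
        tables = {"c1": _table({"g1": "up", "g2": "up"})}
        rule = SignatureRule("late", (ContrastCriterion("c1", "up"),),
                             peak_time_h=60.0, peak_time_condition="A")
        sig = derive_signature(tables, rule, matrix)
        assert sig.gene_ids == {"g2"}

    def test_fold_gap_encodes_much_greater_ordering(self):
        """'Much higher in one contrast than another': the gap criterion
        keeps only genes with log2fc(large) >= log2fc(small) + min_gap."""
        frame_large = pd.DataFrame(
            {"base_mean": 100.0, "log2fc": [4.0, 2.5, 4.0], "p": 1e-6,
             "padj": 1e-5, "direction": "up"},
            index=pd.Index(["g1", "g2", "g3"], name="gene_id"))
        frame_small = pd.DataFrame(
            {"base_mean": 100.0, "log2fc": [1.5, 2.0, 3.5], "p": 1e-6,
             "padj": 1e-5, "direction": "up"},
            index=pd.Index(["g1", "g2", "g3"], name="gene_id"))
        tables = {
            "FP_vs_pMN": DETable("pMN", "FP", 36.0, 0.05, 1.0, frame_large),
            "FP_vs_p3": DETable("p3", "FP", 36.0, 0.05, 1.0, frame_small),
        }
        rule = SignatureRule(
            "FP_p3",
            (ContrastCriterion("FP_vs_pMN", "up"),
             ContrastCriterion("FP_vs_p3", "up")),
            gaps=(FoldGapCriterion("FP_vs_pMN", "FP_vs_p3", min_gap=1.0),),
        )
        sig = derive_signature(tables, rule)
        # g1: 4.0 >= 1.5 + 1 kept; g2: 2.5 < 2.0 + 1 dropped; g3: 4.0 < 4.5
        assert sig.gene_ids == {"g1"}

    def test_membership_recomputable_from_rule(self):
        tables = {"c1": _table({"g1": "up", "g2": "none"})}
        rule = SignatureRule("sig", (ContrastCriterion("c1", "up"),))
        first = derive_signature(tables, rule)
        again = derive_signature(tables, first.rule)
        assert first.gene_ids == again.gene_ids

    def test_planted_domain_recovery_and_disjointness(self, small_truth, small_matrix):
        """High-SNR synthetic data: rules recover the planted domain sets,
        and opposite directions in a shared contrast keep them disjoint."""
        de = {}
        for a, b in [("dorsal", "p3"), ("dorsal", "pMN"), ("p3", "pMN"),
                     ("dorsal", "FP"), ("p3", "FP"), ("pMN", "FP")]:
            de[f"{b}_vs_{a}"] = PairwiseNB(small_matrix, a, b, 36.0).fit()
        dorsal_rule = SignatureRule("dorsal", (
            ContrastCriterion("p3_vs_dorsal", "down"),
            ContrastCriterion("pMN_vs_dorsal", "down"),
            ContrastCriterion("FP_vs_dorsal", "down"),
        ))
        p3_rule = SignatureRule("p3", (
            ContrastCriterion("p3_vs_dorsal", "up"),
            ContrastCriterion("pMN_vs_p3", "down"),
            ContrastCriterion("FP_vs_p3", "down"),
        ))
        dorsal = derive_signature(de, dorsal_rule)
        p3 = derive_signature(de, p3_rule)
        planted = small_truth.domain_set("dorsal")
        jacc = len(dorsal.gene_ids & planted) / len(dorsal.gene_ids | planted)
        assert jacc >= 0.9
        assert dorsal.gene_ids & p3.gene_ids == set()


class TestClassifyTemporal:
    def _matrix(self, profiles: dict[str, list[float]]):
        # pad with flat reference genes so size factors stay at 1 and the
        # toy profiles survive normalization unchanged
        profiles = dict(profiles)
        for i in range(20):
            profiles[f"ref{i}"] = [100, 100, 100, 100]
        grid = (12.0, 24.0, 36.0, 60.0)
        counts = pd.DataFrame(
            {f"A_{t:g}h_r1": [int(v[i]) for v in profiles.values()]
             for i, t in enumerate(grid)},
            index=list(profiles),
        )
        metas = [SampleMeta(f"A_{t:g}h_r1", "A", t, 1) for t in grid]
        return ExpressionMatrix(counts, metas)

    def test_rule_by_hand(self):
        m = self._matrix({
            "flat": [100, 100, 100, 100],
            "early": [10, 60, 80, 90],
            "inter": [10, 15, 70, 90],
            "late": [10, 12, 15, 90],
        })
        out = classify_temporal(m, "A", fold_threshold=3.0)
        assert out.loc["flat", "temporal_class"] == "unclassified"
        assert out.loc["early", "temporal_class"] == "early"
        assert out.loc["inter", "temporal_class"] == "intermediate"
        assert out.loc["late", "temporal_class"] == "late"

    def test_classes_partition(self):
        rng = np.random.default_rng(5)
        m = self._matrix({f"g{i}": list(rng.integers(1, 300, 4)) for i in range(40)})
        out = classify_temporal(m, "A")
        assert set(out["temporal_class"]) <= {
            "early", "intermediate", "late", "unclassified"}
        assert len(out) == 60  # every gene (incl. references) gets one class

    def test_too_few_time_points_fatal(self):
        counts = pd.DataFrame({"A_12h_r1": [1], "A_24h_r1": [2]}, index=["g"])
        metas = [SampleMeta("A_12h_r1", "A", 12.0, 1),
                 SampleMeta("A_24h_r1", "A", 24.0, 1)]
        with pytest.raises(ValueError, match="3 time points"):
            classify_temporal(ExpressionMatrix(counts, metas), "A")


class TestRepressedByInduction:
    def test_planted_knockdown_fraction_recovered(self):
        """An induced repressor knocking down 86 of 100 signature genes is
        recovered as a repressed fraction close to the planted 0.86."""
        rng = np.random.default_rng(42)
        mu_a = np.full(600, 150.0)
        mu_b = mu_a.copy()
        mu_b[:86] /= 8  # 86 of the first 100 genes knocked down
        m = two_group_matrix(rng, mu_a, mu_b, phi=0.05)
        table = PairwiseNB(m, "A", "B", 36.0).fit()
        sig = GeneSignature("sig", frozenset(f"g{j}" for j in range(100)),
                            SignatureRule("sig", ()))
        frac = fraction_of_signature(sig, repressed_by_induction(table))
        assert frac >= 0.8
        assert frac <= 0.9

    def test_null_induction_fraction_near_false_positive_floor(self):
        rng = np.random.default_rng(43)
        mu = np.full(600, 150.0)
        m = two_group_matrix(rng, mu, mu, phi=0.05)
        table = PairwiseNB(m, "A", "B", 36.0).fit()
        sig = GeneSignature("sig", frozenset(f"g{j}" for j in range(100)),
                            SignatureRule("sig", ()))
        assert fraction_of_signature(sig, repressed_by_induction(table)) <= 0.05

    def test_empty_signature_reports_nan(self):
        sig = GeneSignature("none", frozenset(), SignatureRule("none", ()))
        assert np.isnan(fraction_of_signature(sig, {"g1"}))


def test_rules_yaml_round_trip(tmp_path):
    text = """
- name: dorsal
  contrasts:
    - {contrast: "p3_vs_dorsal@36", direction: down}
    - {contrast: "pMN_vs_dorsal@36", direction: down}
- name: FP_late
  contrasts:
    - {contrast: "FP_vs_p3@36", direction: up}
  gaps:
    - {contrast_large: "FP_vs_pMN@36", contrast_small: "FP_vs_p3@36"}
  peak_time_h: 60
  peak_time_condition: FP
"""
    path = tmp_path / "rules.yaml"
    path.write_text(text)
    rules = load_rules(path)
    assert rules[0].name == "dorsal"
    assert rules[0].criteria[0].direction == "down"
    assert rules[1].peak_time_h == 60
    assert rules[1].peak_time_condition == "FP"
    assert rules[1].gaps[0].contrast_large == "FP_vs_pMN@36"
    assert rules[1].gaps[0].min_gap == 1.0
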