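"""Gene-level feature classification and census arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as hst

from siptraits import (
    FeatureCensus,
    GeneRecord,
    LabeledContigSet,
    Treatment,
    census,
    census_by_genome,
    census_pool,
    classify_gene,
    classify_table,
    default_rules,
    secreted_enzyme_gate,
)
from siptraits.census import GENE_LEVEL_FEATURES
from siptraits.errors import UndefinedStatisticError, ValidationError

from conftest import GENE_DEFAULTS, make_genes


def record(**kwargs) -> GeneRecord:
    rec = dict(GENE_DEFAULTS, gene_id="g")
    rec.update(kwargs)
    return GeneRecord(**rec)


class TestClassifyGene:
    def test_mcp_case_insensitive(self, rules):
        assert "MCP" in classify_gene(
            record(product="Methyl-Accepting Chemotaxis Protein McpB"), rules
        )

    def test_transporter_requires_tm_helix(self, rules):
        on = record(product="sugar ABC transporter permease", tm_helices=6)
        off = record(product="sugar ABC transporter permease", tm_helices=0)
        assert "MT" in classify_gene(on, rules)
        assert "MT" not in classify_gene(off, rules)

    def test_generic_transport_protein_not_a_transporter(self, rules):
        assert "MT" not in classify_gene(
            record(product="transport protein", tm_helices=5), rules
        )

    def test_adhesion_exact_name_only(self, rules):
        assert "ADH" in classify_gene(record(product="surface adhesion protein"), rules)
        assert "ADH" not in classify_gene(
            record(product="surface adhesion-like protein"), rules
        )

    def test_adhesion_whitespace_and_case_collapse(self, rules):
        assert "ADH" in classify_gene(
            record(product="  Autotransporter   Adhesin "), rules
        )

    def test_adhesion_terms_mode_is_substring(self):
        rules = default_rules(adhesion_mode="terms")
        assert "ADH" in classify_gene(
            record(product="surface adhesion-like protein"), rules
        )

    def test_tf_family_wildcard(self, rules):
        assert "TF" in classify_gene(
            record(product="transcriptional XRE-family regulator"), rules
        )
        assert "TF" not in classify_gene(
            record(product="transcription termination factor Rho"), rules
        )

    def test_tf_predictor_flag(self, rules):
        assert "TF" in classify_gene(
            record(product="hypothetical protein", tf_pred=True), rules
        )

    def test_tf_predictor_can_be_disabled(self):
        rules = default_rules()
        rules.use_tf_predictor = False
        assert "TF" not in classify_gene(
            record(product="hypothetical protein", tf_pred=True), rules
        )

    def test_multi_tag_gene(self, rules):
        tags = classify_gene(
            record(product="osmoprotectant ABC transporter permease", tm_helices=4),
            rules,
        )
        assert {"MT", "OSM"} <= tags

    def test_dormancy_toxin_antitoxin(self, rules):
        assert "DOR" in classify_gene(record(product="toxin HipA"), rules)
        assert "DOR" in classify_gene(record(product="antitoxin MazE"), rules)


class TestSecretedEnzymeGate:
    def test_requires_both_enzyme_and_signal(self, rules):
        enzyme_only = record(cazy_family="GH13")
        signal_only = record(signal_peptide=True, signal_gram="gram-")
        both = record(cazy_family="GH13", signal_peptide=True, signal_gram="gram-")
        assert not secreted_enzyme_gate(enzyme_only, rules)
        assert not secreted_enzyme_gate(signal_only, rules)
        assert secreted_enzyme_gate(both, rules)

    def test_gt_and_cbm_classes_excluded(self, rules):
        for fam in ("GT2", "CBM6", "AA9"):
            g = record(cazy_family=fam, signal_peptide=True, signal_gram="gram-")
            assert not secreted_enzyme_gate(g, rules)

    def test_protease_and_abhydrolase_routes(self, rules):
        assert secreted_enzyme_gate(
            record(protease_hit=True, signal_peptide=True, signal_gram="gram-"), rules
        )
        assert secreted_enzyme_gate(
            record(abhydrolase_hit=True, signal_peptide=True, signal_gram="gram-"), rules
        )

    def test_gram_mismatch_warns_but_keeps_gene(self, rules, caplog):
        g = record(
            cazy_family="GH5", signal_peptide=True, signal_gram="gram-",
            taxonomy="Bacteria;Firmicutes;Bacilli;;;;",
        )
        with caplog.at_level("WARNING", logger="siptraits"):
            assert secreted_enzyme_gate(g, rules)
        assert any("gram" in r.message for r in caplog.records)


class TestFixtureCensus:
    def test_counts_match_hand_tally(self, census_fixture, rules):
        genes, expected = census_fixture
        c = census(genes, rules, unit_id="fixture")
        assert c.counts == expected
        assert c.n_genes == 30

    def test_frequencies_are_percent_of_genes(self, census_fixture, rules):
        genes, expected = census_fixture
        c = census(genes, rules)
        for feat, n in expected.items():
            assert c.frequencies[feat] == pytest.approx(100.0 * n / 30)

    def test_smbc_abundance_is_per_gene_not_percent(self, census_fixture, rules):
        genes, _ = census_fixture
        c = census(genes, rules, smbc_count=3, smbc_gene_count=30)
        assert c.smbc_abundance == pytest.approx(3 / 30)
        assert c.feature_value("SM") == pytest.approx(0.1)

    def test_empty_unit_is_undefined(self, rules):
        with pytest.raises(UndefinedStatisticError):
            census(make_genes([]), rules)
        with pytest.raises(UndefinedStatisticError):
            FeatureCensus("u", 0, {})

    def test_overlap_bounds_validated(self):
        with pytest.raises(ValidationError):
            FeatureCensus("u", 10, {"SE": 2}, smbc_gene_count=5, smbc_se_overlap=3)


class TestDualRoute:
    """classify_table (vectorized, production) must agree with
    classify_gene (pure per-record reference)."""

    def test_fixture_agreement(self, census_fixture, rules):
        genes, _ = census_fixture
        table = classify_table(genes, rules)
        for i, row in genes.iterrows():
            tags = classify_gene(GeneRecord.from_row(row), rules)
            for feat in GENE_LEVEL_FEATURES:
                assert table.at[i, feat] == (feat in tags), (row["product"], feat)

    PRODUCT_POOL = [
        "methyl-accepting chemotaxis protein",
        "chemotaxis protein CheY",
        "ABC transporter permease",
        "transport protein",
        "Na+/H+ antiporter",
        "surface adhesion protein",
        "fibronectin-binding protein A",
        "LysR family transcriptional regulator",
        "transcriptional GntR-family regulator",
        "transcription termination factor Rho",
        "osmolarity sensor protein EnvZ",
        "trehalose-6-phosphate synthase",
        "stage II sporulation protein E",
        "resuscitation-promoting factor",
        "toxin RelE",
        "glycoside hydrolase family 10",
        "pectate lyase",
        "hypothetical protein",
        "elongation factor Tu",
        "",
    ]

    @given(
        idx=hst.lists(hst.integers(0, len(PRODUCT_POOL) - 1), min_size=1, max_size=40),
        tm=hst.lists(hst.integers(0, 8), min_size=40, max_size=40),
        bits=hst.lists(hst.integers(0, 31), min_size=40, max_size=40),
    )
    def test_random_tables_agree(self, rules, idx, tm, bits):
        rows = []
        for j, i in enumerate(idx):
            b = bits[j]
            rows.append(
                {
                    "product": self.PRODUCT_POOL[i],
                    "tm_helices": tm[j],
                    "signal_peptide": bool(b & 1),
                    "signal_gram": "gram-" if b & 1 else "",
                    "cazy_family": ["", "GH5", "PL1", "GT2"][(b >> 1) & 3],
                    "protease_hit": bool(b & 8),
                    "abhydrolase_hit": bool(b & 16),
                    "tf_pred": bool(b & 4),
                }
            )
        genes = make_genes(rows)
        table = classify_table(genes, rules)
        for i, row in genes.iterrows():
            tags = classify_gene(GeneRecord.from_row(row), rules)
            vec = {f for f in GENE_LEVEL_FEATURES if table.at[i, f]}
            assert vec == tags, row["product"]


class TestPoolAndGenomeCensus:
    def labeled(self, contig_ids, treatment=None):
        return LabeledContigSet(
            treatment=treatment,
            contig_ids=frozenset(contig_ids),
            fold=pd.Series(dtype=float),
            passed=pd.DataFrame(),
        )

    def test_pool_counts_only_labeled_contigs(self, rules):
        genes = make_genes(
            [
                {"contig_id": "c1", "product": "methyl-accepting chemotaxis protein"},
                {"contig_id": "c1", "product": "toxin HipA"},
                {"contig_id": "c2", "product": "methyl-accepting chemotaxis protein"},
            ]
        )
        c = census_pool(self.labeled({"c1"}), genes, rules)
        assert c.n_genes == 2
        assert c.counts["MCP"] == 1
        assert c.counts["DOR"] == 1

    def test_pool_with_all_contigs_equals_plain_census(self, census_fixture, rules):
        genes, _ = census_fixture
        full = census(genes, rules, unit_id="x")
        pooled = census_pool(self.labeled(set(genes["contig_id"])), genes, rules,
                             unit_id="x")
        assert pooled.counts == full.counts and pooled.n_genes == full.n_genes

    def test_pool_unit_named_after_treatment(self, rules):
        genes = make_genes([{"contig_id": "c1"}])
        c = census_pool(self.labeled({"c1"}, Treatment("xylose", 6)), genes, rules)
        assert c.unit_id == "xylose_day6"

    def test_empty_pool_is_undefined(self, rules):
        genes = make_genes([{"contig_id": "c1"}])
        with pytest.raises(UndefinedStatisticError):
            census_pool(self.labeled(set()), genes, rules)

    def test_by_genome_matches_per_genome_census(self, census_fixture, rules):
        genes_a, expected = census_fixture
        genes_b = make_genes(
            [{"genome_id": "H", "product": "toxin HipA"},
             {"genome_id": "H", "product": "hypothetical protein"}]
        )
        genes_b["gene_id"] = ["h000", "h001"]
        both = pd.concat([genes_a, genes_b], ignore_index=True)
        smbc = pd.DataFrame(
            {"smbc_count": [2], "smbc_genes": [20], "se_overlap": [1]},
            index=pd.Index(["G"], name="genome_id"),
        )
        df = census_by_genome(both, rules, smbc=smbc)
        assert df.at["G", "n_genes"] == 30
        for feat, n in expected.items():
            assert df.at["G", feat] == n
            assert df.at["G", f"freq_{feat}"] == pytest.approx(100.0 * n / 30)
        assert df.at["G", "smbc_abundance"] == pytest.approx(2 / 30)
        assert df.at["H", "DOR"] == 1 and df.at["H", "smbc_count"] == 0

    def test_by_genome_frequency_invariant_to_filler(self, rules):
        # doubling genes with inert filler halves every frequency
        base = [{"product": "toxin HipA"}] + [{"product": "hypothetical protein"}] * 9
        g1 = make_genes(base)
        g2 = make_genes(base + [{"product": "hypothetical protein"}] * 10)
        d1 = census_by_genome(g1, rules)
        d2 = census_by_genome(g2, rules)
        assert d2.at["G", "freq_DOR"] == pytest.approx(d1.at["G", "freq_DOR"] / 2)
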