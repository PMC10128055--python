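"""Shared fixtures: small hand-built tables with known expected values."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from siptraits import default_rules

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

GENE_DEFAULTS = {
    "genome_id": "G",
    "contig_id": "G_c000",
    "product": "hypothetical protein",
    "tm_helices": 0,
    "signal_peptide": False,
    "signal_gram": "",
    "cazy_family": "",
    "protease_hit": False,
    "abhydrolase_hit": False,
    "tf_pred": False,
    "taxonomy": "Bacteria;Proteobacteria;Gammaproteobacteria;;;;",
}


def make_genes(rows: list[dict]) -> pd.DataFrame:
    """Build a gene table from partial row dicts, filling defaults."""
    full = []
    for i, row in enumerate(rows):
        rec = dict(GENE_DEFAULTS, gene_id=f"g{i:03d}")
        rec.update(row)
        full.append(rec)
    return pd.DataFrame(full)


@pytest.fixture(scope="session")
def rules():
    return default_rules()


# ---------------------------------------------------------------------------
# 30-gene fixture covering every rule category plus near-miss decoys.
# Expected counts were tallied by hand against the classification rules.
# ---------------------------------------------------------------------------

CENSUS_FIXTURE_ROWS = [
    # MCP (2)
    {"product": "methyl-accepting chemotaxis protein McpA"},
    {"product": "Methyl-Accepting Chemotaxis Protein"},
    # MCP near-miss
    {"product": "chemotaxis protein CheY"},
    # MT (3): transporter term AND >= 1 transmembrane helix
    {"product": "sugar ABC transporter ATP-binding protein", "tm_helices": 3},
    {"product": "sugar ABC transporter ATP-binding protein", "tm_helices": 0},  # gated off
    {"product": "Na+/H+ antiporter NhaA", "tm_helices": 8},
    {"product": "transport protein", "tm_helices": 5},  # near-miss term
    # MT + OSM multi-tag
    {"product": "osmoprotectant ABC transporter permease", "tm_helices": 4},
    # ADH (2): exact product-name membership
    {"product": "surface adhesion protein"},
    {"product": "surface adhesion-like protein"},  # near-miss
    {"product": "  Autotransporter   Adhesin "},  # whitespace + case collapse
    # TF (3)
    {"product": "LysR family transcriptional regulator"},
    {"product": "transcriptional XRE-family regulator"},  # wildcard pattern
    {"product": "hypothetical protein", "tf_pred": True},  # predictor-only
    {"product": "transcription termination factor Rho"},  # near-miss
    # OSM (2 more; total 4 with the multi-tagged transporter and OsmC below)
    {"product": "osmolarity sensor protein EnvZ"},
    {"product": "L-ectoine synthase"},
    # DOR (3)
    {"product": "resuscitation-promoting factor RpfC"},
    {"product": "toxin HipA"},
    {"product": "antitoxin MazE"},
    # SE (3): enzyme-database hit AND signal peptide
    {"product": "glycoside hydrolase family 5", "cazy_family": "GH5",
     "signal_peptide": True, "signal_gram": "gram-"},
    {"product": "alpha-amylase", "cazy_family": "GH13"},  # no signal peptide
    {"product": "subtilisin-like serine protease", "protease_hit": True,
     "signal_peptide": True, "signal_gram": "gram-"},
    {"product": "carboxylesterase", "abhydrolase_hit": True,
     "signal_peptide": True, "signal_gram": "gram+",
     "taxonomy": "Bacteria;Firmicutes;Bacilli;;;;"},
    {"product": "glycosyltransferase", "cazy_family": "GT2",
     "signal_peptide": True, "signal_gram": "gram-"},  # class not GH/PL/CE
    {"product": "cellulose-binding protein", "cazy_family": "CBM6",
     "signal_peptide": True, "signal_gram": "gram-"},  # class not GH/PL/CE
    # OSM (the fourth)
    {"product": "osmotically inducible protein OsmC"},
    # filler
    {"product": "elongation factor Tu"},
    {"product": "50S ribosomal protein L2"},
    {"product": "chaperonin GroEL"},
]

# hand-tallied expectation for the table above (30 genes)
CENSUS_FIXTURE_EXPECTED = {
    "MCP": 2,
    "MT": 3,
    "ADH": 2,
    "TF": 3,
    "OSM": 4,
    "DOR": 3,
    "SE": 3,
}


@pytest.fixture(scope="session")
def census_fixture():
    genes = make_genes(CENSUS_FIXTURE_ROWS)
    assert len(genes) == 30
    return genes, dict(CENSUS_FIXTURE_EXPECTED)
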