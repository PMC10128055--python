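"""Census of life-history-associated genomic features.

Eight features are counted per genome, MAG, or labeled-contig pool:

- ``MCP``  methyl-accepting chemotaxis proteins (motility toward resources)
- ``MT``   membrane transporters (uptake of dissolved substrates)
- ``ADH``  adhesion and holdfast proteins (surface attachment)
- ``TF``   transcription factors (regulatory flexibility)
- ``OSM``  osmotic stress response genes
- ``DOR``  dormancy machinery (sporulation, resuscitation, toxin-antitoxin)
- ``SE``   secreted depolymerizing enzymes (CAZymes, proteases,
  alpha/beta-hydrolases carrying a secretion signal peptide)
- ``SM``   secondary metabolite biosynthetic gene clusters (SMBCs)

The first seven are classified from product-name strings plus precomputed
annotation flags; SMBC detection is an upstream annotator's job and arrives
as per-genome counts.  Feature frequency is the percentage of protein-coding
genes carrying the feature, except SMBCs, whose abundance is the cluster
count divided by the protein-coding gene count.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import UndefinedStatisticError, ValidationError
from .labeling import LabeledContigSet

logger = logging.getLogger("siptraits")

FEATURES = ("MCP", "MT", "ADH", "TF", "OSM", "DOR", "SE", "SM")
GENE_LEVEL_FEATURES = FEATURES[:-1]  # SM is counted at the cluster level

GRAM_POSITIVE_PHYLA = ("Firmicutes", "Actinobacteria")


def _norm(text: str, case_sensitive: bool) -> str:
    out = " ".join(str(text).split())
    return out if case_sensitive else out.lower()


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene with its annotation flags."""

    gene_id: str
    genome_id: str = ""
    contig_id: str = ""
    product: str = ""
    tm_helices: int = 0
    signal_peptide: bool = False
    signal_gram: str = ""  # "gram+", "gram-" or "" when not recorded
    cazy_family: str = ""
    protease_hit: bool = False
    abhydrolase_hit: bool = False
    tf_pred: bool = False
    taxonomy: str = ""

    def __post_init__(self) -> None:
        if self.tm_helices < 0:
            raise ValidationError(f"gene {self.gene_id}: tm_helices must be >= 0")

    @classmethod
    def from_row(cls, row) -> "GeneRecord":
        return cls(
            gene_id=row["gene_id"],
            genome_id=row["genome_id"],
            contig_id=row["contig_id"],
            product=row["product"],
            tm_helices=int(row["tm_helices"]),
            signal_peptide=bool(row["signal_peptide"]),
            signal_gram=row.get("signal_gram", ""),
            cazy_family=row["cazy_family"],
            protease_hit=bool(row["protease_hit"]),
            abhydrolase_hit=bool(row["abhydrolase_hit"]),
            tf_pred=bool(row["tf_pred"]),
            taxonomy=row["taxonomy"],
        )


@dataclass
class FeatureRuleSet:
    """Term lists and flag requirements that define the gene-level features."""

    mcp_terms: tuple[str, ...]
    transporter_terms: tuple[str, ...]
    adhesion_names: tuple[str, ...]
    adhesion_terms: tuple[str, ...]
    adhesion_mode: str  # "exact" (curated names) or "terms" (substring)
    tf_terms: tuple[str, ...]
    tf_family_pattern: str
    use_tf_predictor: bool
    osmotic_terms: tuple[str, ...]
    dormancy_terms: tuple[str, ...]
    se_cazy_classes: tuple[str, ...]
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        for name in ("mcp_terms", "transporter_terms", "tf_terms",
                     "osmotic_terms", "dormancy_terms"):
            if not getattr(self, name):
                raise ValidationError(f"rule list {name} must be non-empty")
        if self.adhesion_mode not in ("exact", "terms"):
            raise ValidationError("adhesion_mode must be 'exact' or 'terms'")
        flags = 0 if self.case_sensitive else re.IGNORECASE
        object.__setattr__(self, "_tf_regex", re.compile(self.tf_family_pattern, flags))

    @classmethod
    def from_dict(cls, data: dict, case_sensitive: bool | None = None,
                  adhesion_mode: str | None = None) -> "FeatureRuleSet":
        return cls(
            mcp_terms=tuple(data["mcp"]["terms"]),
            transporter_terms=tuple(data["transporter"]["terms"]),
            adhesion_names=tuple(data["adhesion"].get("names", ())),
            adhesion_terms=tuple(data["adhesion"].get("terms", ())),
            adhesion_mode=adhesion_mode or data["adhesion"].get("mode", "exact"),
            tf_terms=tuple(data["transcription_factor"]["terms"]),
            tf_family_pattern=data["transcription_factor"]["family_pattern"],
            use_tf_predictor=bool(data["transcription_factor"].get("use_tf_predictor", True)),
            osmotic_terms=tuple(data["osmotic_stress"]["terms"]),
            dormancy_terms=tuple(data["dormancy"]["terms"]),
            se_cazy_classes=tuple(data["secreted_enzyme"]["cazy_classes"]),
            case_sensitive=(
                data.get("case_sensitive", False) if case_sensitive is None else case_sensitive
            ),
        )

    @classmethod
    def load(cls, path: str | Path, **kwargs) -> "FeatureRuleSet":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh), **kwargs)


def default_rules(case_sensitive: bool = False, adhesion_mode: str = "exact") -> FeatureRuleSet:
    """The shipped rule set; ``adhesion_mode='terms'`` selects the substring
    variant used for externally annotated genome collections."""
    text = resources.files("siptraits.rules").joinpath("default.yaml").read_text()
    return FeatureRuleSet.from_dict(
        yaml.safe_load(text), case_sensitive=case_sensitive, adhesion_mode=adhesion_mode
    )


def _cazy_class(cazy_family: str) -> str:
    m = re.match(r"[A-Za-z]+", cazy_family.strip())
    return m.group(0).upper() if m else ""


def _expects_gram_positive(taxonomy: str) -> bool:
    return any(p.lower() in taxonomy.lower() for p in GRAM_POSITIVE_PHYLA)


def secreted_enzyme_gate(gene: GeneRecord, rules: FeatureRuleSet | None = None) -> bool:
    """A gene is a secreted enzyme when it hits one of the enzyme databases
    (CAZy GH/PL/CE, protease, alpha/beta-hydrolase) AND carries a secretion
    signal peptide.

    Signal peptides should be predicted with the gram-positive model for
    Firmicutes/Actinobacteria lineages and the gram-negative model otherwise;
    a mismatch is logged and the gene kept with its recorded model.
    """
    classes = rules.se_cazy_classes if rules is not None else ("GH", "PL", "CE")
    enzyme = (
        _cazy_class(gene.cazy_family) in classes
        or gene.protease_hit
        or gene.abhydrolase_hit
    )
    if not (enzyme and gene.signal_peptide):
        return False
    if gene.signal_gram:
        expected = "gram+" if _expects_gram_positive(gene.taxonomy) else "gram-"
        if gene.signal_gram != expected:
            logger.warning(
                "gene %s: signal peptide model %s does not match lineage "
                "(expected %s); gene kept",
                gene.gene_id, gene.signal_gram, expected,
            )
    return True


def classify_gene(gene: GeneRecord, rules: FeatureRuleSet) -> set[str]:
    """Return the set of feature tags a single gene carries.

    Pure reference implementation; the vectorized :func:`classify_table` is
    used for whole tables and must agree with this record-level rule.
    """
    cs = rules.case_sensitive
    product = _norm(gene.product, cs)
    tags: set[str] = set()

    def contains_any(terms) -> bool:
        return any(_norm(t, cs) in product for t in terms)

    if contains_any(rules.mcp_terms):
        tags.add("MCP")
    if gene.tm_helices >= 1 and contains_any(rules.transporter_terms):
        tags.add("MT")
    if rules.adhesion_mode == "exact":
        if product in {_norm(n, cs) for n in rules.adhesion_names}:
            tags.add("ADH")
    elif contains_any(rules.adhesion_terms):
        tags.add("ADH")
    if (
        contains_any(rules.tf_terms)
        or rules._tf_regex.search(" ".join(str(gene.product).split()))
        or (rules.use_tf_predictor and gene.tf_pred)
    ):
        tags.add("TF")
    if contains_any(rules.osmotic_terms):
        tags.add("OSM")
    if contains_any(rules.dormancy_terms):
        tags.add("DOR")
    if secreted_enzyme_gate(gene, rules):
        tags.add("SE")
    return tags


def classify_table(genes: pd.DataFrame, rules: FeatureRuleSet) -> pd.DataFrame:
    """Vectorized classification: one boolean column per gene-level feature."""
    cs = rules.case_sensitive
    product = genes["product"].astype(str).str.replace(r"\s+", " ", regex=True).str.strip()
    if not cs:
        product = product.str.lower()

    def contains_any(terms) -> pd.Series:
        mask = pd.Series(False, index=genes.index)
        for t in terms:
            mask |= product.str.contains(_norm(t, cs), regex=False)
        return mask

    out = pd.DataFrame(index=genes.index)
    out["MCP"] = contains_any(rules.mcp_terms)
    out["MT"] = contains_any(rules.transporter_terms) & (genes["tm_helices"] >= 1)
    if rules.adhesion_mode == "exact":
        names = {_norm(n, cs) for n in rules.adhesion_names}
        out["ADH"] = product.isin(names)
    else:
        out["ADH"] = contains_any(rules.adhesion_terms)
    tf = contains_any(rules.tf_terms)
    tf |= genes["product"].astype(str).str.replace(r"\s+", " ", regex=True).str.contains(
        rules.tf_family_pattern, regex=True,
        case=rules.case_sensitive, na=False,
    )
    if rules.use_tf_predictor:
        tf |= genes["tf_pred"].astype(bool)
    out["TF"] = tf
    out["OSM"] = contains_any(rules.osmotic_terms)
    out["DOR"] = contains_any(rules.dormancy_terms)
    cazy = genes["cazy_family"].astype(str).str.extract(r"^\s*([A-Za-z]+)", expand=False)
    enzyme = (
        cazy.str.upper().isin(rules.se_cazy_classes).fillna(False)
        | genes["protease_hit"].astype(bool)
        | genes["abhydrolase_hit"].astype(bool)
    )
    out["SE"] = enzyme & genes["signal_peptide"].astype(bool)
    return out


@dataclass
class FeatureCensus:
    """Counts and frequencies of the eight features for one unit."""

    unit_id: str
    n_genes: int
    counts: dict[str, int]  # gene-level features: MCP MT ADH TF OSM DOR SE
    smbc_count: int = 0
    smbc_gene_count: int = 0
    smbc_se_overlap: int = 0
    trna_count: int = 0
    rrn_copies: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise UndefinedStatisticError(
                f"unit {self.unit_id}: frequencies undefined with 0 protein-coding genes"
            )
        for feat, c in self.counts.items():
            if not 0 <= c <= self.n_genes:
                raise ValidationError(
                    f"unit {self.unit_id}: count for {feat} outside [0, n_genes]"
                )
        if self.smbc_se_overlap > min(self.counts.get("SE", 0), self.smbc_gene_count):
            raise ValidationError(
                f"unit {self.unit_id}: SE/SMBC overlap exceeds SE or SMBC gene count"
            )

    @property
    def frequencies(self) -> dict[str, float]:
        """Percentage of protein-coding genes per gene-level feature."""
        return {f: 100.0 * c / self.n_genes for f, c in self.counts.items()}

    @property
    def smbc_abundance(self) -> float:
        """SMBC cluster count divided by protein-coding gene count."""
        return self.smbc_count / self.n_genes

    def feature_value(self, feature: str) -> float:
        """The abundance measure used in screens: percentage for gene-level
        features, cluster count per gene for SM."""
        if feature == "SM":
            return self.smbc_abundance
        return self.frequencies[feature]


def census(
    genes: pd.DataFrame,
    rules: FeatureRuleSet,
    unit_id: str = "unit",
    smbc_count: int = 0,
    smbc_gene_count: int = 0,
    smbc_se_overlap: int = 0,
    trna_count: int = 0,
    rrn_copies: int | None = None,
) -> FeatureCensus:
    """Count features over one unit's protein-coding genes.

    A gene may carry several tags; each tag counts the gene once (set
    semantics, so a product matching two transporter terms is one MT gene).
    """
    if len(genes) == 0:
        raise UndefinedStatisticError(
            f"unit {unit_id}: frequencies undefined with 0 protein-coding genes"
        )
    tags = classify_table(genes, rules)
    return FeatureCensus(
        unit_id=unit_id,
        n_genes=len(genes),
        counts={f: int(tags[f].sum()) for f in GENE_LEVEL_FEATURES},
        smbc_count=smbc_count,
        smbc_gene_count=smbc_gene_count,
        smbc_se_overlap=smbc_se_overlap,
        trna_count=trna_count,
        rrn_copies=rrn_copies,
    )


def census_pool(
    labeled: LabeledContigSet,
    genes: pd.DataFrame,
    rules: FeatureRuleSet,
    unit_id: str | None = None,
    **kwargs,
) -> FeatureCensus:
    """Census over exactly the genes residing on labeled contigs."""
    subset = genes[genes["contig_id"].isin(labeled.contig_ids)]
    if unit_id is None:
        unit_id = labeled.treatment.id if labeled.treatment else "pool"
    return census(subset, rules, unit_id=unit_id, **kwargs)


def census_by_genome(
    genes: pd.DataFrame,
    rules: FeatureRuleSet,
    smbc: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-genome feature counts and frequencies as a DataFrame.

    ``smbc`` is an optional per-genome table with columns smbc_count,
    smbc_genes, se_overlap (index genome_id).  Output columns: ``n_genes``,
    one count per gene-level feature, SMBC fields, ``freq_<feature>`` in
    percent, and ``smbc_abundance``.
    """
    tags = classify_table(genes, rules)
    tags = tags.assign(genome_id=genes["genome_id"].to_numpy())
    counts = tags.groupby("genome_id").sum()
    counts["n_genes"] = genes.groupby("genome_id").size()
    for col, src in (("smbc_count", "smbc_count"), ("smbc_genes", "smbc_genes"),
                     ("se_overlap", "se_overlap")):
        if smbc is not None and src in smbc.columns:
            counts[col] = smbc[src].reindex(counts.index).fillna(0).astype(int)
        else:
            counts[col] = 0
    for f in GENE_LEVEL_FEATURES:
        counts[f"freq_{f}"] = 100.0 * counts[f] / counts["n_genes"]
    counts["smbc_abundance"] = counts["smbc_count"] / counts["n_genes"]
    counts.index.name = "genome_id"
    return counts


def write_census_table(rows: list[FeatureCensus], path) -> None:
    records = []
    for c in rows:
        rec = {"unit_id": c.unit_id, "n_genes": c.n_genes}
        rec.update({f"count_{f}": n for f, n in c.counts.items()})
        rec.update({f"freq_{f}": v for f, v in c.frequencies.items()})
        rec.update(
            smbc_count=c.smbc_count,
            smbc_gene_count=c.smbc_gene_count,
            smbc_se_overlap=c.smbc_se_overlap,
            smbc_abundance=c.smbc_abundance,
            trna_count=c.trna_count,
            rrn_copies="" if c.rrn_copies is None else c.rrn_copies,
        )
        records.append(rec)
    pd.DataFrame(records).to_csv(path, sep="\t", index=False)
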