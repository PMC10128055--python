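"""Synthetic soil community generator with planted ground truth.

Every downstream stage of the pipeline — labeled-contig filtering, the
feature census, activity mapping, correlation screens, and life history
clustering — can be exercised without external data by simulating a
community of genomes drawn from three life history archetypes
(competitor C, scarcity specialist S, ruderal R):

- gene tables whose product strings come from the census rule vocabularies
  (plus near-miss decoys such as "transport protein" that test matching
  strictness), with annotation flags set consistently;
- paired 13C/12C library coverage with a planted fold enrichment for the
  contigs of labeled genomes and negative-binomial depth noise;
- OTU activity tables whose abundance series, substrate assignments, and
  labeling times realize each archetype's activity parameters.

Counts are drawn negative-binomially with variance ``(1 + dispersion) * mean``
(``dispersion = 0`` switches every stochastic quantity to its deterministic
expectation, which the recovery tests exploit).  All generators require an
explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ReferentialError, ValidationError
from .io import LibraryInfo, OTUInput, Treatment
from .labeling import CoverageTable

# ---------------------------------------------------------------------------
# study design defaults: substrates, treatments
# ---------------------------------------------------------------------------

DEFAULT_SUBSTRATES = pd.DataFrame(
    {
        "substrate": [
            "glucose", "amino_acids", "glycerol", "xylose", "lactate",
            "oxalate", "vanillin", "cellulose", "palmitic_acid",
        ],
        "bioavailability": [0.95, 0.88, 0.82, 0.75, 0.65, 0.50, 0.35, 0.15, 0.05],
        "peak_day": [2, 2, 3, 4, 3, 5, 10, 20, 25],
    }
).set_index("substrate")

# eight isotope treatments spanning five harvest days, so the paired design
# yields 8 treatment libraries plus 5 day-matched controls (13 libraries)
DEFAULT_TREATMENTS = (
    Treatment("glucose", 1),
    Treatment("amino_acids", 1),
    Treatment("xylose", 6),
    Treatment("glycerol", 14),
    Treatment("cellulose", 30),
    Treatment("palmitic_acid", 30),
    Treatment("palmitic_acid", 48),
    Treatment("vanillin", 48),
)

# ---------------------------------------------------------------------------
# product-string vocabularies (matching the census rules, plus decoys)
# ---------------------------------------------------------------------------

PRODUCT_VOCAB: dict[str, tuple[str, ...]] = {
    "MCP": (
        "methyl-accepting chemotaxis protein",
        "methyl-accepting chemotaxis protein McpA",
        "methyl-accepting chemotaxis protein WspA",
    ),
    "MT": (
        "sugar ABC transporter permease",
        "ABC transporter ATP-binding protein",
        "multidrug efflux pump subunit AcrB",
        "voltage-gated potassium channel protein",
        "Na+/H+ antiporter NhaA",
        "sodium/proline symporter PutP",
        "phosphate transporter PitA",
        "copper-translocating P-type ATPase",
    ),
    "ADH": (
        "holdfast attachment protein HfaA",
        "surface adhesion protein",
        "autotransporter adhesin",
        "fibronectin-binding autotransporter adhesin",
        "Tfp pilus tip-associated adhesin PilY1",
        "type V secretory pathway adhesin AidA",
    ),
    "TF": (
        "LysR family transcriptional regulator",
        "MarR family transcriptional repressor",
        "transcriptional activator FtrA",
        "sigma-54 dependent transcriptional regulator",
        "transcription factor WhiB",
    ),
    "OSM": (
        "osmotically inducible protein OsmC",
        "osmolarity sensor protein EnvZ",
        "L-ectoine synthase",
        "osmoprotectant binding protein",
    ),
    "DOR": (
        "resuscitation-promoting factor RpfC",
        "toxin HipA",
        "antitoxin HipB",
        "mRNA interferase MazF",
        "antitoxin MazE",
        "toxin RelE",
        "antitoxin DinJ",
    ),
    "SE": (
        "glycoside hydrolase family 5 protein",
        "subtilisin-like serine protease",
        "alpha/beta fold hydrolase lipase",
        "pectate lyase",
    ),
    "SM": (
        "polyketide synthase module",
        "non-ribosomal peptide synthetase",
        "siderophore biosynthesis protein",
    ),
}

# near-misses that must NOT be counted by a strict matcher
DECOY_PRODUCTS = (
    "transport protein",
    "chemotaxis protein CheY",
    "mechanosensitive channel-like protein",  # tm_helices stays 0, so no MT
    "surface adhesion-like protein",
    "transcription termination factor Rho",
    "osmC-like family protein",
)

FILLER_PRODUCTS = (
    "hypothetical protein",
    "DNA polymerase III subunit alpha",
    "50S ribosomal protein L2",
    "elongation factor Tu",
    "chaperonin GroEL",
    "cell division protein FtsZ",
    "DNA gyrase subunit A",
    "phenylalanine--tRNA ligase subunit beta",
    "NADH-quinone oxidoreductase subunit B",
    "acetyl-CoA carboxylase biotin carboxylase subunit",
)

# SE enzyme-class flags cycled over secreted-enzyme genes
_SE_FLAGS = (
    {"cazy_family": "GH5"},
    {"cazy_family": "PL1"},
    {"cazy_family": "CE4"},
    {"protease_hit": True},
    {"abhydrolase_hit": True},
)

_LINEAGES = {
    "C": (
        "Bacteria;Myxococcota;Polyangia;Polyangiales;Polyangiaceae",
        "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Rhizobiaceae",
        "Bacteria;Actinobacteria;Actinomycetia;Streptomycetales;Streptomycetaceae",
    ),
    "S": (
        "Bacteria;Acidobacteria;Acidobacteriia;Acidobacteriales;Acidobacteriaceae",
        "Bacteria;Verrucomicrobia;Verrucomicrobiae;Chthoniobacterales;Chthoniobacteraceae",
        "Bacteria;Planctomycetes;Planctomycetia;Gemmatales;Gemmataceae",
    ),
    "R": (
        "Bacteria;Proteobacteria;Gammaproteobacteria;Pseudomonadales;Pseudomonadaceae",
        "Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;Burkholderiaceae",
        "Bacteria;Firmicutes;Bacilli;Bacillales;Bacillaceae",
    ),
}


# ---------------------------------------------------------------------------
# archetypes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArchetypeSpec:
    """Parameters of one life history archetype.

    ``feature_freqs`` are mean gene counts per 100 protein-coding genes for
    the gene-level features; ``sm_gene_freq`` is the mean count of genes
    inside SMBCs per 100 genes.  Activity parameters describe the archetype's
    growth response (max log2 fold change), preferred substrate
    bioavailability, assimilation latency in days, and substrate breadth.
    """

    strategy: str
    feature_freqs: Mapping[str, float]
    sm_gene_freq: float
    genome_genes_mean: float = 4000.0
    smbc_genes_per_cluster: float = 15.0
    se_overlap_frac: float = 0.05
    dispersion: float = 0.3
    decoy_freq: float = 2.0  # near-miss products per 100 genes
    tf_predictor_frac: float = 0.2  # TF genes detectable only by the predictor
    max_lfc_mean: float = 3.0
    max_lfc_sd: float = 0.5
    bioavailability_mean: float = 0.5
    latency_mean: float = 3.0
    latency_sd: float = 1.5
    breadth_mean: float = 3.0
    breadth_sd: float = 0.8
    trna_mean: float = 50.0
    rrn_mean: float = 3.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.feature_freqs.values()) or self.sm_gene_freq < 0:
            raise ValidationError("feature frequencies must be >= 0")
        if not 0 <= self.bioavailability_mean <= 1:
            raise ValidationError("bioavailability mean must lie in [0,1]")


def default_archetypes() -> tuple[ArchetypeSpec, ArchetypeSpec, ArchetypeSpec]:
    """The three C-S-R archetypes used throughout testing.

    Qualitative orderings follow the life history expectations: ruderals have
    the most chemoreceptors, transporters, and the strongest growth response;
    scarcity specialists have the fewest transcription factors, low-
    bioavailability substrates, and narrow substrate breadth; competitors
    carry the highest relative investment in secreted products.
    """
    competitor = ArchetypeSpec(
        strategy="C",
        feature_freqs={
            "MCP": 0.12, "MT": 2.0, "ADH": 0.30, "TF": 3.0,
            "OSM": 0.35, "DOR": 0.15, "SE": 2.0,
        },
        sm_gene_freq=1.0,
        max_lfc_mean=3.5,
        bioavailability_mean=0.55,
        latency_mean=3.0,
        breadth_mean=3.0,
        rrn_mean=3.0,
        trna_mean=50.0,
    )
    scarcity = ArchetypeSpec(
        strategy="S",
        feature_freqs={
            "MCP": 0.03, "MT": 2.5, "ADH": 0.15, "TF": 1.2,
            "OSM": 0.12, "DOR": 0.12, "SE": 1.2,
        },
        sm_gene_freq=0.30,
        max_lfc_mean=1.5,
        bioavailability_mean=0.25,
        latency_mean=6.0,
        breadth_mean=1.5,
        rrn_mean=1.5,
        trna_mean=42.0,
    )
    ruderal = ArchetypeSpec(
        strategy="R",
        feature_freqs={
            "MCP": 0.35, "MT": 4.0, "ADH": 0.08, "TF": 3.2,
            "OSM": 0.40, "DOR": 0.10, "SE": 0.5,
        },
        sm_gene_freq=0.25,
        max_lfc_mean=5.0,
        bioavailability_mean=0.85,
        latency_mean=0.0,
        breadth_mean=4.0,
        rrn_mean=6.0,
        trna_mean=62.0,
    )
    return competitor, scarcity, ruderal


@dataclass
class SyntheticTruth:
    """Planted ground truth carried alongside every simulated table."""

    genome_strategy: dict[str, str] = field(default_factory=dict)
    genome_lineage: dict[str, str] = field(default_factory=dict)
    planted_counts: pd.DataFrame | None = None  # per-genome feature counts
    contigs: pd.DataFrame | None = None  # contig_id, genome_id, length
    labeled_map: dict[str, frozenset[Treatment]] = field(default_factory=dict)
    otu_params: pd.DataFrame | None = None  # per-OTU planted activity values

    def labeled_contigs(self, treatment: Treatment) -> frozenset[str]:
        """Contigs of genomes planted as labeled in a treatment."""
        if self.contigs is None:
            raise ValidationError("truth has no contig table")
        labeled_genomes = {
            g for g, ts in self.labeled_map.items() if treatment in ts
        }
        mask = self.contigs["genome_id"].isin(labeled_genomes)
        return frozenset(self.contigs.loc[mask, "contig_id"])


def _rng(seed) -> np.random.Generator:
    if seed is None:
        raise ValidationError("an explicit seed is required for simulation")
    return np.random.default_rng(seed)


def _nb_count(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial with variance (1+dispersion)*mean; deterministic
    rounded mean at dispersion 0."""
    if mean <= 0:
        return 0
    if dispersion == 0:
        return int(round(mean))
    r = mean / dispersion
    return int(rng.negative_binomial(r, 1.0 / (1.0 + dispersion)))


def _nb_depths(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return mean
    out = np.zeros_like(mean)
    pos = mean > 0
    r = mean[pos] / dispersion
    out[pos] = rng.negative_binomial(r, 1.0 / (1.0 + dispersion))
    return out


# ---------------------------------------------------------------------------
# genomes
# ---------------------------------------------------------------------------

def simulate_genomes(
    archetypes: Sequence[ArchetypeSpec],
    n_per: int,
    seed: int,
    genes_per_contig: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate ``n_per`` genomes per archetype as annotation tables.

    Returns the gene table, the per-genome SMBC summary, and the truth
    object recording planted per-feature counts, contigs, and lineages.
    """
    if n_per < 1:
        raise ValidationError("n_per must be >= 1")
    rng = _rng(seed)
    truth = SyntheticTruth()
    gene_rows: list[dict] = []
    smbc_rows: list[dict] = []
    planted: list[dict] = []
    contig_rows: list[dict] = []

    for a_idx, arch in enumerate(archetypes):
        lineages = _LINEAGES.get(arch.strategy, _LINEAGES["C"])
        for g in range(n_per):
            genome_id = f"{arch.strategy}{a_idx}_{g:03d}"
            lineage = lineages[g % len(lineages)] + f";Genus_{genome_id};"
            gram_pos = any(p in lineage for p in ("Firmicutes", "Actinobacteria"))
            gram = "gram+" if gram_pos else "gram-"
            n_genes_target = _nb_count(rng, arch.genome_genes_mean, arch.dispersion)

            counts = {
                f: _nb_count(rng, freq * n_genes_target / 100.0, arch.dispersion)
                for f, freq in arch.feature_freqs.items()
            }
            sm_genes = _nb_count(
                rng, arch.sm_gene_freq * n_genes_target / 100.0, arch.dispersion
            )
            smbc_count = int(np.ceil(sm_genes / arch.smbc_genes_per_cluster)) if sm_genes else 0
            overlap = int(round(arch.se_overlap_frac * min(counts["SE"], sm_genes)))
            n_decoys = _nb_count(rng, arch.decoy_freq * n_genes_target / 100.0,
                                 arch.dispersion)
            trna = _nb_count(rng, arch.trna_mean, arch.dispersion)
            rrn = max(1, _nb_count(rng, arch.rrn_mean, arch.dispersion))

            products: list[str] = []
            specs: list[dict] = []

            def vocab_pick(feature: str, n: int) -> list[str]:
                pool = PRODUCT_VOCAB[feature]
                return [pool[int(i)] for i in rng.integers(0, len(pool), max(n, 0))]

            for p in vocab_pick("MCP", counts["MCP"]):
                specs.append({"product": p})
            for p in vocab_pick("MT", counts["MT"]):
                specs.append({"product": p, "tm_helices": int(rng.integers(1, 13))})
            for p in vocab_pick("ADH", counts["ADH"]):
                specs.append({"product": p})
            n_tf_pred = int(round(arch.tf_predictor_frac * counts["TF"]))
            for p in vocab_pick("TF", counts["TF"] - n_tf_pred):
                specs.append({"product": p})
            for _ in range(n_tf_pred):
                specs.append({"product": "hypothetical protein", "tf_pred": True})
            for p in vocab_pick("OSM", counts["OSM"]):
                specs.append({"product": p})
            for p in vocab_pick("DOR", counts["DOR"]):
                specs.append({"product": p})
            for i, p in enumerate(vocab_pick("SE", counts["SE"])):
                spec = {"product": p, "signal_peptide": True, "signal_gram": gram}
                spec.update(_SE_FLAGS[i % len(_SE_FLAGS)])
                specs.append(spec)
            # SM genes not already counted as secreted enzymes
            for p in vocab_pick("SM", max(sm_genes - overlap, 0)):
                specs.append({"product": p})
            for i in range(n_decoys):
                specs.append({"product": DECOY_PRODUCTS[int(rng.integers(0, len(DECOY_PRODUCTS)))]})
            n_filler = n_genes_target - len(specs)
            for i in range(max(n_filler, 0)):
                specs.append({"product": FILLER_PRODUCTS[int(rng.integers(0, len(FILLER_PRODUCTS)))]})

            order = rng.permutation(len(specs))
            n_genes = len(specs)
            for rank, idx in enumerate(order):
                spec = specs[idx]
                contig_idx = rank // genes_per_contig
                gene_rows.append(
                    {
                        "gene_id": f"{genome_id}_g{rank:05d}",
                        "genome_id": genome_id,
                        "contig_id": f"{genome_id}_c{contig_idx:03d}",
                        "product": spec["product"],
                        "tm_helices": spec.get("tm_helices", 0),
                        "signal_peptide": spec.get("signal_peptide", False),
                        "signal_gram": spec.get("signal_gram", ""),
                        "cazy_family": spec.get("cazy_family", ""),
                        "protease_hit": spec.get("protease_hit", False),
                        "abhydrolase_hit": spec.get("abhydrolase_hit", False),
                        "tf_pred": spec.get("tf_pred", False),
                        "taxonomy": lineage,
                    }
                )
            n_contigs = int(np.ceil(n_genes / genes_per_contig))
            for c in range(n_contigs):
                genes_on = min(genes_per_contig, n_genes - c * genes_per_contig)
                contig_rows.append(
                    {
                        "contig_id": f"{genome_id}_c{c:03d}",
                        "genome_id": genome_id,
                        "length": int(genes_on * 1000),
                    }
                )
            smbc_rows.append(
                {
                    "genome_id": genome_id,
                    "smbc_count": smbc_count,
                    "smbc_genes": sm_genes,
                    "se_overlap": overlap,
                }
            )
            planted.append(
                {
                    "genome_id": genome_id,
                    "strategy": arch.strategy,
                    "n_genes": n_genes,
                    **counts,
                    "SM_genes": sm_genes,
                    "smbc_count": smbc_count,
                    "se_overlap": overlap,
                    "trna_count": trna,
                    "rrn_copies": rrn,
                }
            )
            truth.genome_strategy[genome_id] = arch.strategy
            truth.genome_lineage[genome_id] = lineage

    genes = pd.DataFrame(gene_rows)
    smbc = pd.DataFrame(smbc_rows).set_index("genome_id")
    truth.planted_counts = pd.DataFrame(planted).set_index("genome_id")
    truth.contigs = pd.DataFrame(contig_rows)
    return genes, smbc, truth


# ---------------------------------------------------------------------------
# substrate assignment / labeling map
# ---------------------------------------------------------------------------

def assign_substrate_use(
    truth: SyntheticTruth,
    archetypes: Sequence[ArchetypeSpec],
    treatments: Sequence[Treatment],
    substrates: pd.DataFrame,
    seed: int,
) -> dict[str, frozenset[Treatment]]:
    """Choose, per genome, which substrates it assimilates (hence in which
    treatments it is isotopically labeled).

    Breadth is drawn around the archetype mean; substrates are picked by
    proximity of their bioavailability score to the archetype's preferred
    bioavailability (deterministically closest when dispersion is 0,
    otherwise sampled with a Gaussian proximity weight).
    """
    rng = _rng(seed)
    by_strategy = {a.strategy: a for a in archetypes}
    available = sorted({t.substrate for t in treatments})
    missing = [s for s in available if s not in substrates.index]
    if missing:
        raise ReferentialError(f"treatment substrate(s) missing from score table: {missing}")
    scores = substrates.loc[available, "bioavailability"].to_numpy(dtype=float)
    labeled_map: dict[str, frozenset[Treatment]] = {}
    for genome_id, strategy in truth.genome_strategy.items():
        arch = by_strategy[strategy]
        noise_off = arch.dispersion == 0
        if noise_off:
            breadth = int(round(arch.breadth_mean))
        else:
            breadth = int(round(rng.normal(arch.breadth_mean, arch.breadth_sd)))
        breadth = min(max(breadth, 1), len(available))
        dist = np.abs(scores - arch.bioavailability_mean)
        if noise_off:
            chosen_idx = np.argsort(dist, kind="stable")[:breadth]
        else:
            w = np.exp(-((dist / 0.15) ** 2) / 2.0)
            w = w / w.sum()
            chosen_idx = rng.choice(len(available), size=breadth, replace=False, p=w)
        chosen = {available[int(i)] for i in chosen_idx}
        labeled_map[genome_id] = frozenset(
            t for t in treatments if t.substrate in chosen
        )
    truth.labeled_map = labeled_map
    return labeled_map


# ---------------------------------------------------------------------------
# coverage experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepthParams:
    """Coverage model settings for the paired-library simulation."""

    base_depth: float = 50.0  # expected contig depth at the reference read count
    planted_fold: float = 3.0  # 13C enrichment of labeled contigs
    dispersion: float = 0.3  # excess variance factor; 0 = noise off
    read_count_mean: float = 2e6
    read_count_cv: float = 0.2
    base_depth_sigma: float = 0.3  # lognormal spread of per-contig base depth

    def __post_init__(self) -> None:
        if self.planted_fold <= 0 or self.base_depth <= 0:
            raise ValidationError("base_depth and planted_fold must be > 0")


def simulate_sip_experiment(
    truth: SyntheticTruth,
    treatments: Sequence[Treatment],
    labeled_map: Mapping[str, frozenset[Treatment]],
    depth_params: DepthParams,
    seed: int,
) -> tuple[CoverageTable, list[LibraryInfo]]:
    """Simulate paired 13C/12C coverage for every treatment.

    Each treatment gets one 13C library; 12C controls are shared per harvest
    day.  Expected depth scales with the library's read count; contigs of
    genomes labeled in a treatment get ``planted_fold`` times the base depth
    in that treatment's 13C library.  Depths are negative-binomial draws, or
    exact expectations when ``dispersion`` is 0.
    """
    if truth.contigs is None:
        raise ValidationError("truth has no contig table; run simulate_genomes first")
    unknown = set(labeled_map) - set(truth.genome_strategy)
    if unknown:
        raise ReferentialError(f"labeled_map references unknown genome(s): {sorted(unknown)}")
    rng = _rng(seed)
    dp = depth_params
    noise_off = dp.dispersion == 0

    libraries: list[LibraryInfo] = []
    for t in treatments:
        libraries.append(
            LibraryInfo(
                library_id=f"13C_{t.id}",
                substrate=t.substrate, day=t.day, isotope="C13",
                read_count=_draw_read_count(rng, dp),
            )
        )
    for day in sorted({t.day for t in treatments}):
        libraries.append(
            LibraryInfo(
                library_id=f"12C_day{day}",
                substrate="control", day=day, isotope="C12",
                read_count=_draw_read_count(rng, dp),
            )
        )

    contigs = truth.contigs
    n = len(contigs)
    if noise_off:
        base = np.full(n, dp.base_depth)
    else:
        base = dp.base_depth * rng.lognormal(
            -0.5 * dp.base_depth_sigma**2, dp.base_depth_sigma, n
        )
    genome_ids = contigs["genome_id"].to_numpy()

    depths: dict[str, np.ndarray] = {}
    for lib in libraries:
        scale = lib.read_count / dp.read_count_mean
        mean = base * scale
        if lib.isotope == "C13":
            t = Treatment(lib.substrate, lib.day)
            labeled = np.array(
                [t in labeled_map.get(g, frozenset()) for g in genome_ids]
            )
            mean = np.where(labeled, mean * dp.planted_fold, mean)
        depths[lib.library_id] = _nb_depths(rng, mean, dp.dispersion)

    table = CoverageTable(
        lengths=pd.Series(
            contigs["length"].to_numpy(),
            index=pd.Index(contigs["contig_id"], name="contig_id"),
            name="length",
        ),
        depths=pd.DataFrame(depths, index=pd.Index(contigs["contig_id"], name="contig_id")),
        libraries={l.library_id: l for l in libraries},
    )
    return table, libraries


def _draw_read_count(rng, dp: DepthParams) -> int:
    if dp.dispersion == 0 or dp.read_count_cv == 0:
        return int(dp.read_count_mean)
    sigma = np.sqrt(np.log1p(dp.read_count_cv**2))
    return int(dp.read_count_mean * rng.lognormal(-0.5 * sigma**2, sigma))


# ---------------------------------------------------------------------------
# OTU activity
# ---------------------------------------------------------------------------

SERIES_DAYS = (0, 1, 3, 6, 14, 30, 48)


def simulate_otu_activity(
    truth: SyntheticTruth,
    archetypes: Sequence[ArchetypeSpec],
    substrates: pd.DataFrame,
    seed: int,
) -> list[OTUInput]:
    """One OTU per simulated genome, with taxonomy copied from the genome.

    The abundance series rises from a baseline to ``2**max_lfc`` times the
    baseline (exactly, so the computed characteristic recovers the planted
    value when noise is off) and decays afterwards; first labeling days are
    placed at the substrate's mineralization peak plus the archetype latency.
    """
    bad = substrates[(substrates["bioavailability"] < 0) | (substrates["bioavailability"] > 1)]
    if len(bad):
        raise ValidationError(f"substrate score outside [0,1]: {bad.index[0]!r}")
    if not truth.labeled_map:
        raise ValidationError("truth has no labeled_map; run assign_substrate_use first")
    rng = _rng(seed)
    by_strategy = {a.strategy: a for a in archetypes}
    otus: list[OTUInput] = []
    params_rows = []
    baseline = 0.005
    for genome_id, strategy in truth.genome_strategy.items():
        arch = by_strategy[strategy]
        noise_off = arch.dispersion == 0
        treatments = truth.labeled_map.get(genome_id, frozenset())
        chosen = sorted({t.substrate for t in treatments})
        if noise_off:
            lfc = arch.max_lfc_mean
        else:
            lfc = max(0.1, rng.normal(arch.max_lfc_mean, arch.max_lfc_sd))
        first_days: dict[str, int] = {}
        for s in chosen:
            peak = float(substrates.loc[s, "peak_day"])
            if noise_off:
                day = peak + arch.latency_mean
            else:
                day = peak + rng.normal(arch.latency_mean, arch.latency_sd)
            first_days[s] = max(0, int(round(day)))
        peak_day = _nearest_series_day(
            np.mean([substrates.loc[s, "peak_day"] for s in chosen]) if chosen else 6
        )
        abundance = _abundance_series(baseline, lfc, peak_day)
        otus.append(
            OTUInput(
                otu_id=f"OTU_{genome_id}",
                taxonomy=truth.genome_lineage[genome_id],
                labeled_treatments=treatments,
                abundance=abundance,
                first_label_days=first_days,
            )
        )
        planted_bioavail = (
            float(np.mean([substrates.loc[s, "bioavailability"] for s in chosen]))
            if chosen
            else np.nan
        )
        planted_latency = (
            float(np.mean([first_days[s] - substrates.loc[s, "peak_day"] for s in chosen]))
            if chosen
            else np.nan
        )
        params_rows.append(
            {
                "otu_id": f"OTU_{genome_id}",
                "genome_id": genome_id,
                "strategy": strategy,
                "max_lfc": lfc,
                "bioavailability": planted_bioavail,
                "latency": planted_latency,
                "n_sources": len(chosen),
            }
        )
    truth.otu_params = pd.DataFrame(params_rows).set_index("otu_id")
    return otus


def _nearest_series_day(day: float) -> int:
    days = np.asarray(SERIES_DAYS[1:])
    return int(days[np.argmin(np.abs(days - day))])


def _abundance_series(baseline: float, lfc: float, peak_day: int) -> dict[int, float]:
    """Rise log-linearly from baseline to baseline * 2**lfc at ``peak_day``,
    then decay by 30% per subsequent sampling point."""
    peak = baseline * 2.0**lfc
    out: dict[int, float] = {}
    past = 0
    for d in SERIES_DAYS:
        if d < peak_day:
            frac = d / peak_day
            out[d] = baseline * (peak / baseline) ** frac if d > 0 else baseline
        elif d == peak_day:
            out[d] = peak
        else:
            past += 1
            out[d] = peak * 0.7**past
    return out


# ---------------------------------------------------------------------------
# whole-experiment convenience wrapper
# ---------------------------------------------------------------------------

@dataclass
class SimulationResult:
    genes: pd.DataFrame
    smbc: pd.DataFrame
    coverage: CoverageTable
    libraries: list[LibraryInfo]
    otus: list[OTUInput]
    substrates: pd.DataFrame
    treatments: tuple[Treatment, ...]
    truth: SyntheticTruth


def simulate_experiment(
    seed: int,
    archetypes: Sequence[ArchetypeSpec] | None = None,
    n_per: int = 10,
    treatments: Sequence[Treatment] | None = None,
    substrates: pd.DataFrame | None = None,
    depth_params: DepthParams | None = None,
    genes_per_contig: int = 100,
) -> SimulationResult:
    """Run the full generator: genomes, labeling map, coverage, OTU table."""
    archetypes = tuple(archetypes) if archetypes else default_archetypes()
    treatments = tuple(treatments) if treatments else DEFAULT_TREATMENTS
    substrates = substrates if substrates is not None else DEFAULT_SUBSTRATES
    depth_params = depth_params or DepthParams()
    rng = _rng(seed)
    s_genomes, s_label, s_cov, s_otu = rng.integers(0, 2**31 - 1, 4)
    genes, smbc, truth = simulate_genomes(
        archetypes, n_per, int(s_genomes), genes_per_contig=genes_per_contig
    )
    labeled_map = assign_substrate_use(truth, archetypes, treatments, substrates, int(s_label))
    coverage, libraries = simulate_sip_experiment(
        truth, treatments, labeled_map, depth_params, int(s_cov)
    )
    otus = simulate_otu_activity(truth, archetypes, substrates, int(s_otu))
    return SimulationResult(
        genes=genes,
        smbc=smbc,
        coverage=coverage,
        libraries=libraries,
        otus=otus,
        substrates=substrates,
        treatments=treatments,
        truth=truth,
    )


def with_dispersion(arch: ArchetypeSpec, dispersion: float) -> ArchetypeSpec:
    """Copy of an archetype with a different count dispersion (0 = noise off)."""
    return replace(arch, dispersion=dispersion)


# ---------------------------------------------------------------------------
# screen operating-characteristics generator
# ---------------------------------------------------------------------------

def simulate_screen_tables(
    seed: int,
    n_units: int = 8,
    features: Sequence[str] = ("MCP", "MT", "ADH", "TF", "OSM", "DOR", "SE", "SM"),
    planted_feature: str | None = "MT",
    characteristic: str = "bioavailability",
    rho: float = 0.9,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treatment-level tables with one planted feature-characteristic
    correlation.

    The planted feature's frequencies form a fixed, evenly spaced design
    across the units (feature abundances are properties of the contig
    pools); the characteristic is that design plus Gaussian noise scaled so
    the population correlation is ``rho``.  Other features are independent
    noise.  ``planted_feature=None`` gives the global null.
    """
    if not 0 <= abs(rho) <= 1:
        raise ValidationError("rho must lie in [-1, 1]")
    rng = _rng(seed)
    units = [f"treatment_{i}" for i in range(n_units)]
    census = pd.DataFrame(index=pd.Index(units, name="unit_id"))
    for f in features:
        if f == planted_feature:
            census[f] = np.linspace(1.0, 4.0, n_units)
        else:
            census[f] = np.abs(rng.normal(2.0, 0.8, n_units))
    if planted_feature is not None and rho != 0:
        x = census[planted_feature].to_numpy()
        xs = (x - x.mean()) / x.std()
        sigma = np.sqrt(1.0 - rho**2) / abs(rho)
        y = np.sign(rho) * xs + sigma * rng.standard_normal(n_units)
    else:
        y = rng.standard_normal(n_units)
    activity = pd.DataFrame({characteristic: y}, index=census.index)
    return census, activity
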