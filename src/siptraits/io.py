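"""Readers and writers for every table the pipeline touches.

All tables are tab-separated UTF-8 with one header row; lines starting
with ``#`` are comments.  Parsing is keyed by identifiers, never by row
order, so a round trip through ``write_*``/``read_*`` reproduces field
values exactly regardless of how rows were shuffled on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
import yaml

from .errors import (
    FormatError,
    IntegrityError,
    ParseError,
    ReferentialError,
    ValidationError,
)

logger = logging.getLogger("siptraits")

_READ_KW = dict(sep="\t", comment="#", dtype=str, keep_default_na=False)


class Treatment(NamedTuple):
    """A (substrate, harvest day) pair identifying one isotope treatment."""

    substrate: str
    day: int

    @property
    def id(self) -> str:
        return f"{self.substrate}_day{self.day}"

    @classmethod
    def parse(cls, text: str) -> "Treatment":
        substrate, _, day = text.rpartition("_day")
        if not substrate or not day.isdigit():
            raise ParseError(f"cannot parse treatment id {text!r}; expected '<substrate>_day<N>'")
        return cls(substrate, int(day))


@dataclass(frozen=True)
class LibraryInfo:
    """One sequencing library: which treatment, which isotope, how deep."""

    library_id: str
    substrate: str
    day: int
    isotope: str  # "C13" or "C12"
    read_count: int

    def __post_init__(self) -> None:
        if self.isotope not in ("C13", "C12"):
            raise ValidationError(f"isotope must be C13 or C12, got {self.isotope!r}")
        if self.read_count <= 0:
            raise ValidationError(f"library {self.library_id}: read_count must be > 0")

    @property
    def treatment(self) -> Treatment:
        return Treatment(self.substrate, self.day)


@dataclass
class PipelineConfig:
    """Flat bag of pipeline settings, loadable from a key/value YAML file."""

    min_length: int = 1000
    min_cov: float = 5.0
    min_fold: float = 1.5
    rules_file: str | None = None
    case_sensitive_products: bool = False
    k: int = 3
    seed: int = 1
    bh_family: int | None = None
    alpha: float = 0.05
    lfc_pseudocount: float = 0.0
    latency_agg: str = "mean"
    dunn_adjust: str = "bh"

    def __post_init__(self) -> None:
        if min(self.min_length, self.min_cov, self.min_fold) <= 0:
            raise ValidationError("all labeling thresholds must be > 0")
        if self.k < 2:
            raise ValidationError("cluster count k must be >= 2")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")


def _numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    """Convert a string column to float, citing the first bad line."""
    out = pd.to_numeric(df[col], errors="coerce")
    bad = out.isna()
    if bad.any():
        row = int(bad.idxmax())
        # +2: one header line plus 1-based numbering (comments not counted)
        raise ParseError(
            f"{path}: non-numeric value {df[col].iloc[row]!r} in column {col!r} at data line {row + 2}"
        )
    return out


# ---------------------------------------------------------------------------
# depth tables (MetaBAT-style jgi_summarize_bam_contig_depths output)
# ---------------------------------------------------------------------------

def _library_id_from_column(col: str) -> str:
    return col[:-4] if col.endswith(".bam") else col


def read_depth_table(path: str | Path, libraries: Mapping[str, LibraryInfo] | None = None):
    """Parse a per-contig depth summary into a :class:`CoverageTable`.

    Accepts both the paired ``sample.bam`` / ``sample.bam-var`` dialect and
    plain per-sample columns; variance columns are detected by the ``-var``
    suffix and ignored.  Depth column names are mapped to library ids by
    stripping a trailing ``.bam``.
    """
    from .labeling import CoverageTable

    df = pd.read_csv(path, **_READ_KW)
    _require_columns(df, ["contigName", "contigLen", "totalAvgDepth"], path)
    lengths = _numeric(df, "contigLen", path).astype(int)
    depth_cols = [
        c
        for c in df.columns
        if c not in ("contigName", "contigLen", "totalAvgDepth") and not c.endswith("-var")
    ]
    depths = pd.DataFrame(
        {_library_id_from_column(c): _numeric(df, c, path).to_numpy() for c in depth_cols},
        index=pd.Index(df["contigName"], name="contig_id"),
    )
    lengths.index = depths.index
    if df["contigName"].duplicated().any():
        dup = df["contigName"][df["contigName"].duplicated()].iloc[0]
        raise IntegrityError(f"{path}: duplicate contig id {dup!r}")
    return CoverageTable(lengths=lengths.rename("length"), depths=depths,
                         libraries=dict(libraries) if libraries else {})


def write_depth_table(table, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "contigName": table.depths.index,
            "contigLen": table.lengths.to_numpy(),
            "totalAvgDepth": table.depths.mean(axis=1).to_numpy(),
        }
    )
    for col in table.depths.columns:
        df[col] = table.depths[col].to_numpy()
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# library metadata
# ---------------------------------------------------------------------------

def read_library_table(path: str | Path) -> dict[str, LibraryInfo]:
    df = pd.read_csv(path, **_READ_KW)
    _require_columns(df, ["library_id", "substrate", "day", "isotope", "read_count"], path)
    if df["library_id"].duplicated().any():
        raise IntegrityError(f"{path}: duplicate library_id")
    out: dict[str, LibraryInfo] = {}
    for _, row in df.iterrows():
        out[row["library_id"]] = LibraryInfo(
            library_id=row["library_id"],
            substrate=row["substrate"],
            day=int(row["day"]),
            isotope=row["isotope"],
            read_count=int(row["read_count"]),
        )
    return out


def write_library_table(libraries: Mapping[str, LibraryInfo] | Iterable[LibraryInfo],
                        path: str | Path) -> None:
    libs = list(libraries.values()) if isinstance(libraries, Mapping) else list(libraries)
    pd.DataFrame(
        {
            "library_id": [l.library_id for l in libs],
            "substrate": [l.substrate for l in libs],
            "day": [l.day for l in libs],
            "isotope": [l.isotope for l in libs],
            "read_count": [l.read_count for l in libs],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene annotation tables
# ---------------------------------------------------------------------------

GENE_COLUMNS = [
    "gene_id",
    "genome_id",
    "contig_id",
    "product",
    "tm_helices",
    "signal_peptide",
    "cazy_family",
    "protease_hit",
    "abhydrolase_hit",
    "tf_pred",
    "taxonomy",
]

_TRUTHY = {"1", "true", "yes", "y"}


def _flag(series: pd.Series) -> pd.Series:
    return series.str.strip().str.lower().isin(_TRUTHY)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Load a per-gene annotation table, one row per protein-coding gene.

    Empty flag cells become absent/zero.  The ``signal_peptide`` column may
    hold a bare truthy value or a gram model (``gram+`` / ``gram-``); the
    model, when given, is preserved in ``signal_gram``.
    """
    df = pd.read_csv(path, **_READ_KW)
    _require_columns(df, GENE_COLUMNS, path)
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise IntegrityError(f"{path}: duplicate gene_id {dup!r}")
    tm = pd.to_numeric(df["tm_helices"].replace("", "0"), errors="coerce")
    if tm.isna().any():
        row = int(tm.isna().idxmax())
        raise ParseError(f"{path}: non-numeric tm_helices at data line {row + 2}")
    sp = df["signal_peptide"].str.strip().str.lower()
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "genome_id": df["genome_id"],
            "contig_id": df["contig_id"],
            "product": df["product"],
            "tm_helices": tm.astype(int),
            "signal_peptide": sp.isin(_TRUTHY | {"gram+", "gram-"}),
            "signal_gram": sp.where(sp.isin({"gram+", "gram-"}), ""),
            "cazy_family": df["cazy_family"].str.strip(),
            "protease_hit": _flag(df["protease_hit"]),
            "abhydrolase_hit": _flag(df["abhydrolase_hit"]),
            "tf_pred": _flag(df["tf_pred"]),
            "taxonomy": df["taxonomy"],
        }
    )
    out.index = pd.RangeIndex(len(out))
    return out


def write_gene_table(genes: pd.DataFrame, path: str | Path) -> None:
    df = genes.copy()
    sp = df["signal_gram"].where(df["signal_gram"] != "", df["signal_peptide"].map({True: "1", False: ""}))
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "genome_id": df["genome_id"],
            "contig_id": df["contig_id"],
            "product": df["product"],
            "tm_helices": df["tm_helices"],
            "signal_peptide": sp,
            "cazy_family": df["cazy_family"],
            "protease_hit": df["protease_hit"].map({True: "1", False: ""}),
            "abhydrolase_hit": df["abhydrolase_hit"].map({True: "1", False: ""}),
            "tf_pred": df["tf_pred"].map({True: "1", False: ""}),
            "taxonomy": df["taxonomy"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SMBC (secondary metabolite biosynthetic gene cluster) counts per genome
# ---------------------------------------------------------------------------

def read_smbc_table(path: str | Path) -> pd.DataFrame:
    """Per-genome SMBC summary: cluster count, genes inside clusters, and the
    number of those genes that also pass the secreted-enzyme gate."""
    df = pd.read_csv(path, **_READ_KW)
    _require_columns(df, ["genome_id", "smbc_count", "smbc_genes", "se_overlap"], path)
    if df["genome_id"].duplicated().any():
        raise IntegrityError(f"{path}: duplicate genome_id")
    out = pd.DataFrame(
        {
            "genome_id": df["genome_id"],
            "smbc_count": _numeric(df, "smbc_count", path).astype(int),
            "smbc_genes": _numeric(df, "smbc_genes", path).astype(int),
            "se_overlap": _numeric(df, "se_overlap", path).astype(int),
        }
    )
    return out.set_index("genome_id")


def write_smbc_table(smbc: pd.DataFrame, path: str | Path) -> None:
    smbc.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# OTU activity inputs
# ---------------------------------------------------------------------------

@dataclass
class OTUInput:
    """Raw per-OTU inputs before activity characteristics are computed."""

    otu_id: str
    taxonomy: str
    labeled_treatments: frozenset[Treatment]
    abundance: dict[int, float]  # day -> relative abundance
    first_label_days: dict[str, int] = field(default_factory=dict)  # substrate -> day


def read_otu_table(
    path: str | Path,
    known_treatments: Iterable[Treatment] | None = None,
    labels_path: str | Path | None = None,
) -> list[OTUInput]:
    """Load OTU taxonomy, labeling flags and abundance series.

    Abundance columns are named ``abund_d<day>``.  When a long-format first
    labeling table (otu_id, substrate, first_label_day) is given it overrides
    the default of "earliest labeled treatment day per substrate".
    """
    df = pd.read_csv(path, **_READ_KW)
    _require_columns(df, ["otu_id", "taxonomy", "labeled_treatments"], path)
    if df["otu_id"].duplicated().any():
        raise IntegrityError(f"{path}: duplicate otu_id")
    known = set(known_treatments) if known_treatments is not None else None
    day_cols = {c: int(c[7:]) for c in df.columns if c.startswith("abund_d")}

    label_days: dict[str, dict[str, int]] = {}
    if labels_path is not None:
        ldf = pd.read_csv(labels_path, **_READ_KW)
        _require_columns(ldf, ["otu_id", "substrate", "first_label_day"], labels_path)
        for _, row in ldf.iterrows():
            label_days.setdefault(row["otu_id"], {})[row["substrate"]] = int(row["first_label_day"])

    records: list[OTUInput] = []
    for _, row in df.iterrows():
        raw = row["labeled_treatments"].strip()
        treatments = frozenset(Treatment.parse(t) for t in raw.split(",") if t)
        if known is not None:
            unknown = {t for t in treatments if t not in known}
            if unknown:
                raise ReferentialError(
                    f"{path}: OTU {row['otu_id']} labeled in unknown treatment(s) "
                    + ", ".join(sorted(t.id for t in unknown))
                )
        abundance = {
            day: float(row[col]) for col, day in day_cols.items() if row[col].strip() != ""
        }
        records.append(
            OTUInput(
                otu_id=row["otu_id"],
                taxonomy=row["taxonomy"],
                labeled_treatments=treatments,
                abundance=abundance,
                first_label_days=label_days.get(row["otu_id"], {}),
            )
        )
    if not records:
        logger.warning("%s: empty OTU table", path)
    return records


def write_otu_table(otus: Sequence[OTUInput], path: str | Path,
                    labels_path: str | Path | None = None) -> None:
    days = sorted({d for o in otus for d in o.abundance})
    rows = []
    for o in otus:
        row = {
            "otu_id": o.otu_id,
            "taxonomy": o.taxonomy,
            "labeled_treatments": ",".join(sorted(t.id for t in o.labeled_treatments)),
        }
        for d in days:
            row[f"abund_d{d}"] = o.abundance.get(d, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if labels_path is not None:
        lrows = [
            {"otu_id": o.otu_id, "substrate": s, "first_label_day": d}
            for o in otus
            for s, d in sorted(o.first_label_days.items())
        ]
        pd.DataFrame(lrows, columns=["otu_id", "substrate", "first_label_day"]).to_csv(
            labels_path, sep="\t", index=False
        )


# ---------------------------------------------------------------------------
# substrate metadata
# ---------------------------------------------------------------------------

def read_substrate_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, **_READ_KW)
    _require_columns(df, ["substrate", "bioavailability", "peak_day"], path)
    out = pd.DataFrame(
        {
            "substrate": df["substrate"],
            "bioavailability": _numeric(df, "bioavailability", path),
            "peak_day": _numeric(df, "peak_day", path),
        }
    ).set_index("substrate")
    bad = out[(out["bioavailability"] < 0) | (out["bioavailability"] > 1)]
    if len(bad):
        raise ValidationError(
            f"{path}: bioavailability outside [0,1] for {bad.index[0]!r}"
        )
    return out


def write_substrate_table(substrates: pd.DataFrame, path: str | Path) -> None:
    substrates.reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run manifest
# ---------------------------------------------------------------------------

def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(path: str | Path, command: str, seed: int | None,
                       config: Mapping | None, inputs: Iterable[str | Path]) -> None:
    """Write a machine-readable record of one CLI run: command, seed, config
    values, and a SHA-256 digest of every input file."""
    manifest = {
        "command": command,
        "seed": seed,
        "config": dict(config) if config else {},
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).exists()},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
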