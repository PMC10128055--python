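"""Identify isotopically labeled contigs from paired-library coverage.

In metagenomic stable isotope probing, genomes that assimilated a heavy
(13C) substrate are enriched in the heavy buoyant-density fraction, so
their contigs show elevated coverage in the 13C-treatment library relative
to the matched 12C control.  A contig is called labeled when it is longer
than ``min_length`` (strict), has at least ``min_cov`` raw coverage in the
13C library, and shows at least ``min_fold`` sequencing-depth-normalized
coverage enrichment over the control.

Normalization divides mean depth by the library's total read count, so the
fold ratio is invariant to sequencing effort.  Conventions for zero control
coverage: fold is +infinity when the 13C signal is positive, and 0 for 0/0.
No pseudocounts are added to depths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ReferentialError, ValidationError
from .io import LibraryInfo, Treatment


@dataclass
class CoverageTable:
    """Per-contig length and per-library mean read depth.

    ``depths`` is indexed by contig id with one column per library id;
    ``lengths`` shares the index; ``libraries`` maps library id to its
    metadata (isotope, treatment, read count).
    """

    lengths: pd.Series
    depths: pd.DataFrame
    libraries: dict[str, LibraryInfo] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lengths.index.equals(self.depths.index):
            raise ValidationError("lengths and depths must share a contig index")
        if len(self.lengths) and int(self.lengths.min()) < 1:
            raise ValidationError("contig lengths must be >= 1")
        if len(self.depths) and (self.depths.to_numpy() < 0).any():
            raise ValidationError("depths must be >= 0")

    @property
    def contig_ids(self) -> pd.Index:
        return self.depths.index

    @property
    def n_contigs(self) -> int:
        return len(self.depths)

    def library(self, library_id: str) -> LibraryInfo:
        try:
            return self.libraries[library_id]
        except KeyError:
            raise ReferentialError(f"unknown library {library_id!r}") from None

    def pair_for_treatment(self, treatment: Treatment) -> tuple[str, str]:
        """Return (13C library id, matched 12C control id) for a treatment.

        The control is the 12C library harvested on the same day.
        """
        c13 = [
            l.library_id
            for l in self.libraries.values()
            if l.isotope == "C13" and l.treatment == treatment
        ]
        c12 = [
            l.library_id
            for l in self.libraries.values()
            if l.isotope == "C12" and l.day == treatment.day
        ]
        if not c13 or not c12:
            raise ReferentialError(
                f"no 13C/12C library pair for treatment {treatment.id!r}"
            )
        return c13[0], c12[0]


@dataclass(frozen=True)
class LabelingThresholds:
    """The three labeling criteria.

    length is strict (> min_length); coverage and fold are inclusive
    (>= min_cov, >= min_fold).  Coverage applies to the raw 13C depth;
    normalization enters only the fold ratio.
    """

    min_length: int = 1000
    min_cov: float = 5.0
    min_fold: float = 1.5

    def __post_init__(self) -> None:
        if min(self.min_length, self.min_cov, self.min_fold) <= 0:
            raise ValidationError("all labeling thresholds must be > 0")


@dataclass
class LabeledContigSet:
    """Contigs passing all three labeling criteria for one treatment."""

    treatment: Treatment | None
    contig_ids: frozenset[str]
    fold: pd.Series  # normalized fold enrichment for every contig in the table
    passed: pd.DataFrame  # per-contig boolean columns: length, coverage, fold

    def __len__(self) -> int:
        return len(self.contig_ids)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self.contig_ids


def normalized_coverage(depth: float, read_count: float) -> float:
    """Mean depth divided by the library's total read count."""
    if read_count <= 0:
        raise ValidationError("read_count must be > 0")
    return depth / read_count


def _fold_from_normalized(n13: np.ndarray, n12: np.ndarray) -> np.ndarray:
    """Vectorized fold with the zero-control conventions."""
    n13 = np.asarray(n13, dtype=float)
    n12 = np.asarray(n12, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = n13 / n12
    fold = np.where((n12 == 0) & (n13 > 0), np.inf, fold)
    fold = np.where((n12 == 0) & (n13 == 0), 0.0, fold)
    return fold


def fold_enrichment(table: CoverageTable, contig_id: str, pair: tuple[str, str]) -> float:
    """Normalized 13C/12C coverage ratio for one contig.

    Returns +infinity when the control has zero normalized coverage but the
    treatment does not, and 0 for 0/0.
    """
    lib13, lib12 = pair
    for lib in pair:
        if lib not in table.depths.columns:
            raise ReferentialError(f"unknown library {lib!r} in depth table")
    if contig_id not in table.depths.index:
        raise ReferentialError(f"unknown contig {contig_id!r}")
    n13 = normalized_coverage(table.depths.at[contig_id, lib13], table.library(lib13).read_count)
    n12 = normalized_coverage(table.depths.at[contig_id, lib12], table.library(lib12).read_count)
    return float(_fold_from_normalized(np.array([n13]), np.array([n12]))[0])


def label_contigs(
    table: CoverageTable,
    pair: tuple[str, str],
    thresholds: LabelingThresholds = LabelingThresholds(),
    treatment: Treatment | None = None,
) -> LabeledContigSet:
    """Apply the three labeling criteria to every contig in the table.

    An empty table yields an empty set, not an error.
    """
    lib13, lib12 = pair
    for lib in pair:
        if lib not in table.depths.columns:
            raise ReferentialError(f"unknown library {lib!r} in depth table")
    d13 = table.depths[lib13].to_numpy(dtype=float)
    d12 = table.depths[lib12].to_numpy(dtype=float)
    r13 = table.library(lib13).read_count
    r12 = table.library(lib12).read_count
    fold = _fold_from_normalized(d13 / r13, d12 / r12)

    pass_length = table.lengths.to_numpy() > thresholds.min_length
    pass_cov = d13 >= thresholds.min_cov
    pass_fold = fold >= thresholds.min_fold
    selected = pass_length & pass_cov & pass_fold

    passed = pd.DataFrame(
        {"length": pass_length, "coverage": pass_cov, "fold": pass_fold},
        index=table.contig_ids,
    )
    if treatment is None and lib13 in table.libraries:
        treatment = table.libraries[lib13].treatment
    return LabeledContigSet(
        treatment=treatment,
        contig_ids=frozenset(table.contig_ids[selected]),
        fold=pd.Series(fold, index=table.contig_ids, name="fold"),
        passed=passed,
    )


def write_labeled_set(labeled: LabeledContigSet, path) -> None:
    out = labeled.passed.rename(columns=lambda c: f"pass_{c}")
    out.insert(0, "fold", labeled.fold)
    out["labeled"] = out.index.isin(labeled.contig_ids)
    out.index.name = "contig_id"
    out.reset_index().to_csv(path, sep="\t", index=False)
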