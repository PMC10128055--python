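"""Per-OTU activity characteristics and their mapping onto treatments and MAGs.

Three characteristics summarize how a taxon behaves after carbon enters the
soil:

- **max LFC** — log2 change in relative abundance from time zero to the
  point of maximal abundance (growth response).
- **bioavailability** — mean operational bioavailability score of the carbon
  sources the taxon assimilated (what it eats).
- **latency** — mean difference in days between a substrate's mineralization
  peak and the taxon's first observed isotope labeling on that substrate
  (positive values suggest secondary, food-web assimilation).

MAGs carry no amplicon identity, so they are linked to OTUs by walking the
taxonomic ranks from the MAG's deepest assigned rank and selecting OTUs with
the same name at that rank, then keeping only OTUs isotopically labeled in
the MAG's treatment of origin.  Characteristics are averaged over the
matched set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ReferentialError, UndefinedStatisticError, ValidationError
from .io import OTUInput, Treatment

logger = logging.getLogger("siptraits")

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

CHARACTERISTICS = ("max_lfc", "bioavailability", "latency", "n_sources")


def parse_lineage(text: str) -> tuple[str, ...]:
    """Split a semicolon-separated lineage into the seven canonical ranks.

    Missing trailing ranks are padded with empty strings; rank prefixes such
    as ``p__`` are stripped.
    """
    parts = [p.strip() for p in str(text).split(";")]
    parts = [p[3:] if len(p) > 2 and p[1:3] == "__" else p for p in parts]
    parts = (parts + [""] * len(RANKS))[: len(RANKS)]
    return tuple(parts)


def deepest_assigned_rank(lineage: Sequence[str]) -> int:
    """Index of the deepest non-empty rank, or -1 for a fully unassigned
    lineage."""
    for i in range(len(lineage) - 1, -1, -1):
        if lineage[i]:
            return i
    return -1


@dataclass(frozen=True)
class OTUActivity:
    """One OTU with its computed activity characteristics."""

    otu_id: str
    lineage: tuple[str, ...]
    labeled_treatments: frozenset[Treatment]
    max_lfc: float
    bioavailability: float
    latency: float
    n_sources: int

    def characteristic(self, name: str) -> float:
        return float(getattr(self, name))


@dataclass(frozen=True)
class MAGRecord:
    """A metagenome-assembled genome binned from one treatment's labeled
    contigs."""

    mag_id: str
    treatment: Treatment
    lineage: tuple[str, ...]
    completeness: float = 100.0
    contamination: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.completeness <= 100:
            raise ValidationError(f"MAG {self.mag_id}: completeness outside [0,100]")
        if self.contamination < 0:
            raise ValidationError(f"MAG {self.mag_id}: contamination must be >= 0")


@dataclass(frozen=True)
class MAGActivity:
    """Activity characteristics of a MAG, averaged over its matched OTUs."""

    mag_id: str
    matched_otu_ids: tuple[str, ...]
    max_lfc: float
    bioavailability: float
    latency: float
    n_sources: float


def compute_max_lfc(series: Mapping[int, float], pseudocount: float = 0.0) -> float:
    """log2((max abundance + eps) / (abundance at time zero + eps)).

    The maximum is taken over all time points including time zero, so a
    series peaking at t0 gives 0.
    """
    if 0 not in series:
        raise ValidationError("abundance series must include time zero")
    if len(series) < 2:
        raise ValidationError("abundance series needs at least one post-t0 point")
    values = list(series.values())
    if any(v < 0 for v in values):
        raise ValidationError("abundances must be >= 0")
    a0 = series[0]
    amax = max(values)
    if amax == 0:
        raise ValidationError("all-zero abundance series")
    if a0 + pseudocount == 0:
        raise ValidationError("zero abundance at time zero with zero pseudocount")
    return math.log2((amax + pseudocount) / (a0 + pseudocount))


def compute_bioavailability(
    substrates: Iterable[str], substrate_scores: Mapping[str, float]
) -> float:
    """Arithmetic mean bioavailability score of the distinct assimilated
    substrates; a substrate assimilated at several time points counts once."""
    distinct = sorted(set(substrates))
    if not distinct:
        raise UndefinedStatisticError("no assimilated substrates")
    missing = [s for s in distinct if s not in substrate_scores]
    if missing:
        raise ReferentialError(f"no bioavailability score for substrate(s) {missing}")
    return float(np.mean([substrate_scores[s] for s in distinct]))


def compute_latency(
    first_label_days: Mapping[str, float],
    peak_days: Mapping[str, float],
    agg: str = "mean",
) -> float:
    """Per-substrate latency = first labeling day minus mineralization peak
    day; the OTU's latency aggregates over its substrates (mean by default,
    median as a config alternative).  Negative values mean labeling before
    the mineralization peak."""
    if not first_label_days:
        raise UndefinedStatisticError("no labeled substrates")
    missing = [s for s in first_label_days if s not in peak_days]
    if missing:
        raise ReferentialError(f"no mineralization peak day for substrate(s) {missing}")
    lat = [first_label_days[s] - peak_days[s] for s in first_label_days]
    if agg == "mean":
        return float(np.mean(lat))
    if agg == "median":
        return float(np.median(lat))
    raise ValidationError(f"unknown latency aggregation {agg!r}")


def build_otu_activity(
    otu: OTUInput,
    substrates: pd.DataFrame,
    pseudocount: float = 0.0,
    latency_agg: str = "mean",
) -> OTUActivity:
    """Compute the three characteristics for one OTU from its raw inputs.

    First labeling days default to the earliest labeled treatment day per
    substrate when no explicit labeling time course is provided.
    """
    assimilated = sorted({t.substrate for t in otu.labeled_treatments})
    if not assimilated:
        raise UndefinedStatisticError(f"OTU {otu.otu_id} is not labeled in any treatment")
    first_days: dict[str, float] = {}
    for s in assimilated:
        if s in otu.first_label_days:
            first_days[s] = otu.first_label_days[s]
        else:
            first_days[s] = min(t.day for t in otu.labeled_treatments if t.substrate == s)
    scores = substrates["bioavailability"].to_dict()
    peaks = substrates["peak_day"].to_dict()
    return OTUActivity(
        otu_id=otu.otu_id,
        lineage=parse_lineage(otu.taxonomy),
        labeled_treatments=otu.labeled_treatments,
        max_lfc=compute_max_lfc(otu.abundance, pseudocount),
        bioavailability=compute_bioavailability(assimilated, scores),
        latency=compute_latency(first_days, peaks, latency_agg),
        n_sources=len(assimilated),
    )


def pool_activity(otus: Iterable[OTUActivity], treatment: Treatment) -> dict[str, float]:
    """Treatment-level activity: mean characteristic over the OTUs labeled in
    that treatment."""
    labeled = [o for o in otus if treatment in o.labeled_treatments]
    if not labeled:
        raise UndefinedStatisticError(f"no OTU labeled in treatment {treatment.id!r}")
    return {
        name: float(np.mean([o.characteristic(name) for o in labeled]))
        for name in CHARACTERISTICS
    }


def match_mag_to_otus(mag: MAGRecord, otus: Iterable[OTUActivity]) -> list[OTUActivity]:
    """OTUs matching the MAG's deepest assigned taxon name and labeled in the
    MAG's treatment.

    No fallback to shallower ranks is performed when the deepest assigned
    rank has no labeled OTU; an empty result is a valid outcome and signals
    that the MAG should be discarded from activity analyses.
    """
    depth = deepest_assigned_rank(mag.lineage)
    if depth < 0:
        logger.warning("MAG %s has no taxonomic assignment; no OTU match", mag.mag_id)
        return []
    name = mag.lineage[depth]
    return [
        o
        for o in otus
        if len(o.lineage) > depth
        and o.lineage[depth] == name
        and mag.treatment in o.labeled_treatments
    ]


def mag_activity(mag: MAGRecord, matched: Sequence[OTUActivity]) -> MAGActivity | None:
    """Average characteristics over the matched OTUs; ``None`` (a discard
    signal, not an exception) when no OTU matched."""
    if not matched:
        logger.warning("MAG %s matched no labeled OTU; discarded", mag.mag_id)
        return None
    return MAGActivity(
        mag_id=mag.mag_id,
        matched_otu_ids=tuple(o.otu_id for o in matched),
        max_lfc=float(np.mean([o.max_lfc for o in matched])),
        bioavailability=float(np.mean([o.bioavailability for o in matched])),
        latency=float(np.mean([o.latency for o in matched])),
        n_sources=float(np.mean([o.n_sources for o in matched])),
    )


def write_mag_activity_table(rows: Iterable[MAGActivity], path) -> None:
    pd.DataFrame(
        [
            {
                "mag_id": r.mag_id,
                "matched_otus": ",".join(r.matched_otu_ids),
                "max_lfc": r.max_lfc,
                "bioavailability": r.bioavailability,
                "latency": r.latency,
                "n_sources": r.n_sources,
            }
            for r in rows
        ]
    ).to_csv(path, sep="\t", index=False)
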