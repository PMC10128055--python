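"""Genomic-investment trade-offs and C-S-R life history strategies.

Two statistics place a genome in trade-off space:

- ``tf_per_gene`` — transcription factor genes per protein-coding gene, a
  proxy for regulatory flexibility;
- ``acquisition_ratio`` — deduplicated secreted-enzyme plus SMBC gene count
  divided by membrane-transporter gene count, a proxy for investment in
  extracellular resource acquisition relative to uptake.

Units are clustered by k-means (k = 3 by default) after centering and
scaling both axes.  Clusters are labeled with Grime's strategies from their
unscaled centroids: the scarcity strategist (S, oligotroph) has the lowest
regulatory flexibility; of the remaining two, the competitor (C) has the
higher acquisition ratio and the ruderal (R) the lower.  A fitted model
stores the training scaling and centroids, so new genomes are projected into
the training space and assigned to the nearest centroid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .census import FeatureCensus
from .errors import UndefinedStatisticError, ValidationError
from .stats import GroupTestResult, dunn_posthoc, kruskal_wallis

logger = logging.getLogger("siptraits")

STRATEGIES = ("C", "S", "R")


@dataclass(frozen=True)
class InvestmentScores:
    """One unit's position in trade-off space, with component counts."""

    unit_id: str
    tf_per_gene: float
    acquisition_ratio: float
    tf: int = 0
    se: int = 0
    sm: int = 0
    mt: int = 0
    genes: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.tf_per_gene <= 1:
            raise ValidationError(f"unit {self.unit_id}: tf_per_gene outside [0,1]")
        if self.acquisition_ratio < 0:
            raise ValidationError(f"unit {self.unit_id}: acquisition_ratio must be >= 0")


def investment_scores(
    census: FeatureCensus, overlap: int | None = None
) -> InvestmentScores:
    """Trade-off statistics from a feature census.

    ``overlap`` is the number of genes both tagged as secreted enzymes and
    lying inside an SMBC; it is subtracted once so such genes are not double
    counted.  Defaults to the census's recorded overlap.  A unit with no
    membrane transporter genes has an undefined acquisition ratio and is
    excluded by callers.
    """
    if overlap is None:
        overlap = census.smbc_se_overlap
    se = census.counts["SE"]
    sm = census.smbc_gene_count
    mt = census.counts["MT"]
    tf = census.counts["TF"]
    if overlap > min(se, sm):
        raise ValidationError(
            f"unit {census.unit_id}: overlap {overlap} exceeds SE ({se}) or SMBC genes ({sm})"
        )
    if mt == 0:
        raise UndefinedStatisticError(
            f"unit {census.unit_id}: acquisition ratio undefined with 0 transporter genes"
        )
    return InvestmentScores(
        unit_id=census.unit_id,
        tf_per_gene=tf / census.n_genes,
        acquisition_ratio=(se + sm - overlap) / mt,
        tf=tf,
        se=se,
        sm=sm,
        mt=mt,
        genes=census.n_genes,
    )


def scores_from_counts(counts: pd.DataFrame) -> list[InvestmentScores]:
    """Build scores from a per-genome census table (see
    :func:`siptraits.census.census_by_genome`), excluding and logging units
    with no transporter genes."""
    out: list[InvestmentScores] = []
    for unit_id, row in counts.iterrows():
        if row["MT"] == 0:
            logger.warning("unit %s excluded: no membrane transporter genes", unit_id)
            continue
        out.append(
            InvestmentScores(
                unit_id=str(unit_id),
                tf_per_gene=row["TF"] / row["n_genes"],
                acquisition_ratio=(row["SE"] + row["smbc_genes"] - row["se_overlap"])
                / row["MT"],
                tf=int(row["TF"]),
                se=int(row["SE"]),
                sm=int(row["smbc_genes"]),
                mt=int(row["MT"]),
                genes=int(row["n_genes"]),
            )
        )
    return out


@dataclass
class ClusterModel:
    """A trained trade-off clustering: axis scaling, centroids, labels."""

    mean: np.ndarray  # per-axis training mean (tf_per_gene, acquisition_ratio)
    sd: np.ndarray  # per-axis training standard deviation
    centroids: np.ndarray  # k x 2, in scaled space
    k: int
    seed: int
    cluster_to_strategy: dict[int, str] = field(default_factory=dict)
    training_assignments: dict[str, int] = field(default_factory=dict)

    @property
    def centroids_raw(self) -> np.ndarray:
        """Centroids back-transformed to the original axes."""
        return self.centroids * self.sd + self.mean

    def scale(self, points: np.ndarray) -> np.ndarray:
        return (points - self.mean) / self.sd

    def to_json(self, path: str | Path) -> None:
        data = {
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "centroids": self.centroids.tolist(),
            "k": self.k,
            "seed": self.seed,
            "cluster_to_strategy": {str(c): s for c, s in self.cluster_to_strategy.items()},
            "training_assignments": self.training_assignments,
        }
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            mean=np.asarray(data["mean"], dtype=float),
            sd=np.asarray(data["sd"], dtype=float),
            centroids=np.asarray(data["centroids"], dtype=float),
            k=int(data["k"]),
            seed=int(data["seed"]),
            cluster_to_strategy={int(c): s for c, s in data["cluster_to_strategy"].items()},
            training_assignments={u: int(c) for u, c in data["training_assignments"].items()},
        )


@dataclass(frozen=True)
class StrategyAssignment:
    unit_id: str
    cluster: int
    strategy: str
    distance: float


def _points(scores: Sequence[InvestmentScores]) -> np.ndarray:
    return np.array([[s.tf_per_gene, s.acquisition_ratio] for s in scores], dtype=float)


def fit_clusters(
    scores: Sequence[InvestmentScores],
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 25,
) -> ClusterModel:
    """k-means (Lloyd, Euclidean, best of ``n_restarts`` random starts) on
    z-scored trade-off space; the training scaling is stored in the model."""
    if seed is None:
        raise ValidationError("a seed is required for k-means restarts")
    if len(scores) < k:
        raise ValidationError(f"need at least k={k} units, got {len(scores)}")
    pts = _points(scores)
    mean = pts.mean(axis=0)
    sd = pts.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValidationError("zero variance on a trade-off axis; cannot scale")
    scaled = (pts - mean) / sd
    km = KMeans(
        n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd"
    ).fit(scaled)
    model = ClusterModel(
        mean=mean,
        sd=sd,
        centroids=km.cluster_centers_,
        k=k,
        seed=seed,
        training_assignments={
            s.unit_id: int(c) for s, c in zip(scores, km.labels_)
        },
    )
    if k == 3:
        model.cluster_to_strategy = label_strategies(model)
    return model


def label_strategies(model: ClusterModel) -> dict[int, str]:
    """Map the three clusters onto C/S/R from their unscaled centroids.

    S is the centroid with the lowest tf_per_gene; of the remaining two, C
    has the higher acquisition ratio and R the lower.  Exact ties break
    toward the lower cluster index, with a warning.
    """
    if model.k != 3:
        logger.info("strategy labeling skipped for k=%d (only defined for k=3)", model.k)
        return {}
    raw = model.centroids_raw
    tf_vals = raw[:, 0]
    if len(set(tf_vals)) < len(tf_vals):
        logger.warning("tied tf_per_gene centroids; breaking tie by cluster index")
    s_idx = int(np.argmin(tf_vals))  # argmin takes the lowest index on ties
    rest = [i for i in range(3) if i != s_idx]
    acq = raw[rest, 1]
    if acq[0] == acq[1]:
        logger.warning("tied acquisition_ratio centroids; breaking tie by cluster index")
    c_idx = rest[int(np.argmax(acq))]
    r_idx = [i for i in rest if i != c_idx][0]
    return {s_idx: "S", c_idx: "C", r_idx: "R"}


def predict(
    model: ClusterModel, scores: Sequence[InvestmentScores]
) -> list[StrategyAssignment]:
    """Assign new units to the nearest training centroid.

    Units are scaled with the TRAINING mean/sd (never re-scaled on the
    prediction set).  Equidistant points go to the lowest cluster index.
    """
    if len(scores) == 0:
        return []
    scaled = model.scale(_points(scores))
    d = np.linalg.norm(scaled[:, None, :] - model.centroids[None, :, :], axis=2)
    clusters = np.argmin(d, axis=1)  # argmin resolves ties to the lowest index
    out = []
    for s, c, dist in zip(scores, clusters, d[np.arange(len(scores)), clusters]):
        out.append(
            StrategyAssignment(
                unit_id=s.unit_id,
                cluster=int(c),
                strategy=model.cluster_to_strategy.get(int(c), str(int(c))),
                distance=float(dist),
            )
        )
    return out


def characterize_clusters(
    assignments: Sequence[StrategyAssignment],
    values: pd.DataFrame,
    alpha: float = 0.05,
    dunn_adjust: str = "bh",
) -> list[GroupTestResult]:
    """Kruskal-Wallis per value column across clusters, with Dunn pairwise
    tests where the omnibus test is significant at ``alpha``.

    ``values`` is indexed by unit id (activity characteristics or feature
    frequencies).  Columns with degenerate cluster sizes (< 2 clusters with
    >= 2 units) are skipped with a warning.
    """
    by_strategy: dict[str, list[str]] = {}
    for a in assignments:
        by_strategy.setdefault(a.strategy, []).append(a.unit_id)
    results: list[GroupTestResult] = []
    for col in values.columns:
        groups, labels = [], []
        for strat, units in sorted(by_strategy.items()):
            vals = values.loc[values.index.intersection(units), col].dropna()
            if len(vals):
                groups.append(vals.to_numpy(dtype=float))
                labels.append(strat)
        if sum(len(g) >= 2 for g in groups) < 2:
            logger.warning("characteristic %s skipped: degenerate cluster sizes", col)
            continue
        h, df, p = kruskal_wallis(groups)
        pairs: tuple = ()
        if p < alpha:
            pairs = tuple(dunn_posthoc(groups, labels=labels, adjust=dunn_adjust))
        results.append(GroupTestResult(characteristic=col, h=h, df=df, p=p, pairs=pairs))
    return results


def write_assignments(assignments: Iterable[StrategyAssignment], path) -> None:
    pd.DataFrame([a.__dict__ for a in assignments]).to_csv(path, sep="\t", index=False)


def strategy_taxon_table(
    assignments: Sequence[StrategyAssignment], taxa: Mapping[str, str]
) -> pd.DataFrame:
    """Per-strategy taxon counts (e.g. phylum composition of each cluster)."""
    rows = [
        {"strategy": a.strategy, "taxon": taxa.get(a.unit_id, "unclassified")}
        for a in assignments
    ]
    df = pd.DataFrame(rows)
    return df.groupby(["strategy", "taxon"]).size().rename("n_units").reset_index()
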