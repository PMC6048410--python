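"""Infiltration-tier clustering and dichotomized survival classes.

Samples are cut into k = 3 hierarchical clusters (Ward linkage on z-scored
cell-type rows; Euclidean or 1 - Pearson distance) and relabeled H/M/L by
descending mean overall infiltration.  Median splits assign Hi to values
strictly above the median, Lo to the rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .data_io import ValidationError
from .scores import overall_infiltration, zscore_rows
from .ssgsea import EnrichmentMatrix

DISTANCES = ("euclidean", "pearson")
TIER_ORDER = ("H", "M", "L")


@dataclass(frozen=True)
class InfiltrationClusters:
    labels: pd.Series  # sample_id -> {"H", "M", "L"}
    distance: str
    linkage: str = "ward"
    k: int = 3

    @property
    def sizes(self) -> dict[str, int]:
        return {t: int((self.labels == t).sum()) for t in TIER_ORDER}


def cluster_infiltration(
    enrich: EnrichmentMatrix,
    distance: str = "euclidean",
    linkage: str = "ward",
) -> InfiltrationClusters:
    """Cut the sample dendrogram at k = 3 and rank clusters by mean infiltration.

    Rows are z-scored across samples before computing distances so that no
    cell type dominates by scale.  H gets the largest mean overall
    infiltration (computed on the raw rows), L the smallest.
    """
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {DISTANCES}")
    if linkage != "ward":
        raise ValueError("only Ward linkage is supported")
    df = enrich.scores
    n = df.shape[1]
    if n < 3:
        raise ValidationError(f"clustering needs >= 3 samples, got {n}")
    X = zscore_rows(df).T.to_numpy()  # samples x cell types
    if distance == "euclidean":
        condensed = pdist(X, metric="euclidean")
    else:
        corr = np.corrcoef(X)
        condensed = squareform(1.0 - corr, checks=False)
    if np.all(condensed == 0):
        raise ValidationError(
            "all samples are identical after z-scoring; clustering is degenerate"
        )
    tree = sch.linkage(condensed, method="ward")
    raw = sch.fcluster(tree, t=3, criterion="maxclust")
    if len(np.unique(raw)) < 3:
        raise ValidationError(
            "dendrogram could not be cut into 3 clusters (tied merge heights)"
        )
    infil = overall_infiltration(enrich, list(df.index))
    means = {c: infil.to_numpy()[raw == c].mean() for c in np.unique(raw)}
    ranked = sorted(means, key=means.get, reverse=True)
    relabel = {c: TIER_ORDER[i] for i, c in enumerate(ranked)}
    labels = pd.Series([relabel[c] for c in raw], index=df.columns, name="cluster")
    return InfiltrationClusters(labels, distance=distance, linkage=linkage)


def median_split(values: pd.Series, name: str | None = None) -> pd.Series:
    """Hi = strictly above the median, Lo = at or below it.

    For n distinct values this puts floor((n - 1) / 2) samples in Hi — e.g.
    199 -> 99/100 and 359 -> 179/180.
    """
    if len(values) < 2:
        raise ValidationError("median split needs >= 2 samples")
    if values.nunique() == 1:
        raise ValidationError(
            f"all values of {name or values.name or 'score'} are identical; "
            "median split undefined"
        )
    med = values.median()
    out = pd.Series(np.where(values > med, "Hi", "Lo"), index=values.index)
    out.name = name or (f"{values.name}_split" if values.name else "split")
    return out


def cross_classes(split_a: pd.Series, split_b: pd.Series) -> pd.Series:
    """Crossed 4-level labels HiHi/HiLo/LoHi/LoLo over a shared sample universe."""
    sym_diff = set(split_a.index).symmetric_difference(split_b.index)
    if sym_diff:
        raise ValidationError(
            f"splits cover different samples; symmetric difference: {sorted(sym_diff)}"
        )
    b = split_b.loc[split_a.index]
    out = split_a.str.cat(b)
    out.name = f"{split_a.name}x{split_b.name}"
    return out


def write_classes(frames: pd.DataFrame, path) -> None:
    frames.to_csv(path, sep="\t", index_label="sample_id")
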