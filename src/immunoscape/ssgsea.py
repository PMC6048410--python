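"""Single-sample gene set enrichment scoring (rank-weighted running sum).

For one sample, genes are ranked by expression (highest expression gets the
largest rank).  Walking the genes in decreasing-rank order, the enrichment
score of a set is the sum over all positions of the difference between the
weighted fraction of set members seen so far (weights ``rank ** alpha``) and
the plain fraction of non-members seen so far.  Scores are optionally
normalized by the global max - min of the raw score matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data_io import ExpressionMatrix, GeneSetCollection, ValidationError

TIE_POLICIES = ("average_rank", "stable_ordinal")


@dataclass(frozen=True)
class SsgseaConfig:
    """Scoring parameters.

    alpha: exponent on rank weights (0 <= alpha <= 1).
    normalize: divide the raw score matrix by its global max - min.
    tie_policy: 'stable_ordinal' breaks expression ties lexicographically by
        gene symbol (bit-reproducible); 'average_rank' assigns tied values the
        mean rank, for parity with reference implementations.
    min_set_size: sets with fewer measured members are skipped.
    """

    alpha: float = 0.25
    normalize: bool = True
    tie_policy: str = "stable_ordinal"
    min_set_size: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.min_set_size < 1:
            raise ValueError(f"min_set_size must be >= 1, got {self.min_set_size}")
        if self.tie_policy not in TIE_POLICIES:
            raise ValueError(f"tie_policy must be one of {TIE_POLICIES}")


@dataclass(frozen=True)
class EnrichmentMatrix:
    """Gene sets x samples enrichment scores plus the parameters that made them."""

    scores: pd.DataFrame
    normalized: bool
    alpha: float
    tie_policy: str = "stable_ordinal"

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def row(self, name: str) -> pd.Series:
        if name not in self.scores.index:
            raise KeyError(
                f"gene set {name!r} not scored; available: {sorted(self.scores.index)}"
            )
        return self.scores.loc[name]


def rank_transform(expr: ExpressionMatrix, tie_policy: str = "stable_ordinal") -> pd.DataFrame:
    """Per-sample ranks, 1..N with N for the highest expression.

    Under ``stable_ordinal`` ties are broken lexicographically (the
    alphabetically earlier symbol receives the lower rank); under
    ``average_rank`` tied values share the mean of their ordinal ranks.
    """
    if tie_policy not in TIE_POLICIES:
        raise ValueError(f"tie_policy must be one of {TIE_POLICIES}")
    vals = expr.values.to_numpy(dtype=float)
    n_genes, n_samples = vals.shape
    if n_genes < 2:
        raise ValidationError("rank transform needs at least 2 genes")
    if tie_policy == "average_rank":
        ranks = rankdata(vals, axis=0, method="average")
    else:
        lex_pos = np.argsort(np.argsort(expr.values.index.to_numpy().astype(str)))
        ranks = np.empty_like(vals)
        stairs = np.arange(1, n_genes + 1, dtype=float)
        for j in range(n_samples):
            order = np.lexsort((lex_pos, vals[:, j]))
            ranks[order, j] = stairs
    return pd.DataFrame(ranks, index=expr.values.index, columns=expr.values.columns)


def _walk_order(ranks: np.ndarray, lex_pos: np.ndarray) -> np.ndarray:
    """Indices of genes in decreasing-rank order (lex tie-break), per column."""
    n_genes, n_samples = ranks.shape
    out = np.empty((n_genes, n_samples), dtype=np.intp)
    for j in range(n_samples):
        out[:, j] = np.lexsort((lex_pos, -ranks[:, j]))
    return out


def enrichment_score(
    ranks_one_sample: pd.Series,
    gene_set: Sequence[str],
    alpha: float = 0.25,
) -> float:
    """Raw enrichment score of one gene set in one sample.

    Members missing from the ranked universe are dropped with a warning; a
    set covering every measured gene is an error (the non-member fraction is
    undefined).
    """
    index = ranks_one_sample.index
    present = [g for g in gene_set if g in index]
    absent = [g for g in gene_set if g not in index]
    if absent:
        warnings.warn(f"dropping {len(absent)} set member(s) absent from matrix: {absent}", stacklevel=2)
    n = len(index)
    m = len(present)
    if m == 0:
        raise ValidationError("gene set has no members in the measured genes")
    if m == n:
        raise ValidationError(
            "gene set covers every measured gene; enrichment is undefined (N - m = 0)"
        )
    ranks = ranks_one_sample.to_numpy(dtype=float)
    lex_pos = np.argsort(np.argsort(index.to_numpy().astype(str)))
    order = np.lexsort((lex_pos, -ranks))
    member = np.zeros(n, dtype=bool)
    member[index.get_indexer(present)] = True
    in_sorted = member[order]
    w = np.where(in_sorted, ranks[order] ** alpha, 0.0)
    p_in = np.cumsum(w) / w.sum()
    p_out = np.cumsum(~in_sorted) / (n - m)
    return float(np.sum(p_in - p_out))


def score_matrix(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    cfg: SsgseaConfig | None = None,
) -> EnrichmentMatrix:
    """Score every gene set against every sample.

    Sets shrinking below ``cfg.min_set_size`` after intersection with the
    measured genes are skipped (NaN row, warning).  With ``cfg.normalize``
    the full raw matrix is divided by its global max - min; this couples
    samples through the range and is recorded on the output.
    """
    cfg = cfg or SsgseaConfig()
    ranks_df = rank_transform(expr, cfg.tie_policy)
    ranks = ranks_df.to_numpy(dtype=float)
    index = ranks_df.index
    n = len(index)
    lex_pos = np.argsort(np.argsort(index.to_numpy().astype(str)))
    order = _walk_order(ranks, lex_pos)
    ranks_sorted = np.take_along_axis(ranks, order, axis=0)

    rows: dict[str, np.ndarray] = {}
    n_scored = 0
    for name, members in sets.sets.items():
        present = [g for g in members if g in index]
        absent_count = len(members) - len(present)
        if absent_count:
            warnings.warn(
                f"set {name!r}: dropping {absent_count} member(s) absent from matrix",
                stacklevel=2,
            )
        m = len(present)
        if m < cfg.min_set_size:
            warnings.warn(
                f"set {name!r}: only {m} measured member(s) "
                f"(< min_set_size {cfg.min_set_size}); skipped",
                stacklevel=2,
            )
            rows[name] = np.full(ranks.shape[1], np.nan)
            continue
        if m == n:
            raise ValidationError(
                f"set {name!r} covers every measured gene; enrichment undefined"
            )
        member = np.zeros(n, dtype=bool)
        member[index.get_indexer(present)] = True
        in_sorted = member[order]
        w = np.where(in_sorted, ranks_sorted**cfg.alpha, 0.0)
        p_in = np.cumsum(w, axis=0) / w.sum(axis=0)
        p_out = np.cumsum(~in_sorted, axis=0) / (n - m)
        rows[name] = np.sum(p_in - p_out, axis=0)
        n_scored += 1

    if n_scored == 0:
        raise ValidationError("every gene set was skipped; nothing to score")

    scores = pd.DataFrame(rows, index=ranks_df.columns).T
    scores.index.name = "gene_set"
    if cfg.normalize:
        arr = scores.to_numpy()
        rng = np.nanmax(arr) - np.nanmin(arr)
        if rng > 0:
            scores = scores / rng
        else:
            warnings.warn("raw score range is zero; normalization skipped", stacklevel=2)
    return EnrichmentMatrix(
        scores, normalized=cfg.normalize, alpha=cfg.alpha, tie_policy=cfg.tie_policy
    )


def write_enrichment(enrich: EnrichmentMatrix, path: str | Path) -> None:
    """TSV with `#`-prefixed metadata header lines followed by sets x samples."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# alpha={enrich.alpha}\n")
        fh.write(f"# normalized={str(enrich.normalized).lower()}\n")
        fh.write(f"# tie_policy={enrich.tie_policy}\n")
        enrich.scores.to_csv(fh, sep="\t", index_label="gene_set")


def read_enrichment(path: str | Path) -> EnrichmentMatrix:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        scores = pd.read_csv(fh, sep="\t", index_col=0)
    return EnrichmentMatrix(
        scores,
        normalized=meta.get("normalized", "false") == "true",
        alpha=float(meta.get("alpha", 0.25)),
        tie_policy=meta.get("tie_policy", "stable_ordinal"),
    )
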