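"""Per-sample composite immune scores built on expression and enrichment.

CYT: geometric mean of PRF1 and GZMA expression (pseudocount epsilon).
TIS: mean of nine z-standardized T-subset enrichment rows (sample sd, ddof 1).
CD8/Treg ratio: both rows min-max rescaled to [delta, 1] first, so the ratio
is strictly positive even though raw enrichment scores can be negative.
Pathway / APM scores delegate to the ssGSEA engine on named sets.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix, GeneSetCollection, ValidationError
from .ssgsea import EnrichmentMatrix, SsgseaConfig, score_matrix

#: Shipped default MHC class I processing/presentation signature; overridable
#: via any GMT set named "APM".  Configuration, not ground truth.
DEFAULT_APM_GENES = [
    "HLA-A",
    "HLA-B",
    "HLA-C",
    "B2M",
    "TAP1",
    "TAP2",
    "TAPBP",
    "PSMB9",
]

#: The nine T-subset rows averaged into the T-cell infiltration score.
DEFAULT_TIS_SETS = [
    "CD8 T cells",
    "Central memory CD4 T cells",
    "Effector memory CD4 T cells",
    "Central memory CD8 T cells",
    "Effector memory CD8 T cells",
    "Th1 cells",
    "Th2 cells",
    "Th17 cells",
    "Treg cells",
]


def _require_gene(expr: ExpressionMatrix, symbol: str) -> pd.Series:
    if symbol not in expr.values.index:
        raise ValidationError(f"required gene {symbol!r} absent from expression matrix")
    return expr.values.loc[symbol]


def cyt_score(
    expr: ExpressionMatrix,
    pseudocount: float = 0.01,
    prf1: str = "PRF1",
    gzma: str = "GZMA",
) -> pd.Series:
    """Cytolytic activity: sqrt((PRF1 + eps) * (GZMA + eps)) per sample."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    p = _require_gene(expr, prf1)
    g = _require_gene(expr, gzma)
    out = np.sqrt((p + pseudocount) * (g + pseudocount))
    out.name = "cyt"
    return out


def zscore_rows(df: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Row-wise z-scores across samples; zero-variance rows become all zeros."""
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=ddof)
    zero = sd == 0
    if zero.any():
        for name in df.index[zero]:
            warnings.warn(f"row {name!r} has zero variance; z-scores set to 0", stacklevel=3)
    sd = sd.replace(0, np.nan)
    z = df.sub(mean, axis=0).div(sd, axis=0)
    return z.fillna(0.0)


def tis_score(enrich: EnrichmentMatrix, tis_set_names: Sequence[str] | None = None) -> pd.Series:
    """T-cell infiltration score: mean of the z-scored named rows per sample."""
    names = list(tis_set_names or DEFAULT_TIS_SETS)
    missing = [n for n in names if n not in enrich.scores.index]
    if missing:
        raise ValidationError(f"TIS rows absent from enrichment matrix: {missing}")
    z = zscore_rows(enrich.scores.loc[names])
    out = z.mean(axis=0)
    out.name = "tis"
    return out


def _rescale_row(row: pd.Series, delta: float) -> pd.Series:
    lo, hi = row.min(), row.max()
    if hi == lo:
        raise ValidationError(
            f"row {row.name!r} has zero variance; min-max rescaling (and hence the "
            "ratio) is undefined"
        )
    return delta + (1.0 - delta) * (row - lo) / (hi - lo)


def cd8_treg_ratio(
    enrich: EnrichmentMatrix,
    cd8_name: str = "CD8 T cells",
    treg_name: str = "Treg cells",
    delta: float = 0.01,
) -> pd.Series:
    """Ratio of min-max rescaled (to [delta, 1]) CD8 over Treg enrichment."""
    cd8 = _rescale_row(enrich.row(cd8_name), delta)
    treg = _rescale_row(enrich.row(treg_name), delta)
    out = cd8 / treg
    out.name = "cd8_treg_ratio"
    return out


def pathway_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    names: Sequence[str],
    cfg: SsgseaConfig | None = None,
) -> pd.DataFrame:
    """ssGSEA scores (pathways x samples) for the named sets only."""
    try:
        subset = sets.subset(names)
    except KeyError as exc:
        raise ValidationError(str(exc)) from exc
    return score_matrix(expr, subset, cfg).scores


def ifng_readout(
    expr: ExpressionMatrix,
    mode: str = "gene",
    sets: GeneSetCollection | None = None,
    signature_name: str = "IFNG signature",
    cfg: SsgseaConfig | None = None,
) -> pd.Series:
    """IFN-gamma readout: single-gene IFNG expression or a signature ssGSEA score."""
    if mode == "gene":
        out = _require_gene(expr, "IFNG").copy()
    elif mode == "signature":
        if sets is None:
            raise ValueError("signature mode needs a GeneSetCollection")
        out = pathway_scores(expr, sets, [signature_name], cfg).loc[signature_name]
    else:
        raise ValueError(f"ifng mode must be 'gene' or 'signature', got {mode!r}")
    out.name = "ifng"
    return out


def overall_infiltration(
    enrich: EnrichmentMatrix, cell_type_names: Sequence[str]
) -> pd.Series:
    """Arithmetic mean of the designated cell-type enrichment rows per sample."""
    missing = [n for n in cell_type_names if n not in enrich.scores.index]
    if missing:
        raise ValidationError(f"cell-type rows absent from enrichment matrix: {missing}")
    out = enrich.scores.loc[list(cell_type_names)].mean(axis=0)
    out.name = "overall_infiltration"
    return out


def build_composite_table(
    expr: ExpressionMatrix,
    enrich: EnrichmentMatrix,
    sets: GeneSetCollection,
    cell_type_names: Sequence[str],
    tis_set_names: Sequence[str] | None = None,
    cd8_name: str = "CD8 T cells",
    treg_name: str = "Treg cells",
    pathway_names: Mapping[str, str] | None = None,
    ifng_mode: str = "gene",
    pseudocount: float = 0.01,
    delta: float = 0.01,
    cfg: SsgseaConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, object]]:
    """Assemble the samples x scores table and its formula metadata.

    ``pathway_names`` maps output column -> GMT set name, default
    ``{"p41bb": "41BB signaling pathway", "ifna": "Interferon-a response",
    "apm": "APM"}``; pathway columns whose set is absent raise.
    """
    pathway_names = dict(
        pathway_names
        or {"p41bb": "41BB signaling pathway", "ifna": "Interferon-a response", "apm": "APM"}
    )
    cols: dict[str, pd.Series] = {}
    cols["cyt"] = cyt_score(expr, pseudocount=pseudocount)
    cols["tis"] = tis_score(enrich, tis_set_names)
    cols["cd8_treg_ratio"] = cd8_treg_ratio(enrich, cd8_name, treg_name, delta=delta)
    cols["ifng"] = ifng_readout(expr, mode=ifng_mode, sets=sets, cfg=cfg)
    cols["overall_infiltration"] = overall_infiltration(enrich, cell_type_names)
    if pathway_names:
        pw = pathway_scores(expr, sets, list(pathway_names.values()), cfg)
        for col, set_name in pathway_names.items():
            cols[col] = pw.loc[set_name]
    table = pd.DataFrame(cols)
    table.index.name = "sample_id"
    meta = {
        "pseudocount": pseudocount,
        "delta": delta,
        "ddof": 1,
        "ifng_mode": ifng_mode,
        "pathway_names": pathway_names,
    }
    return table, meta


def write_scores(
    table: pd.DataFrame, meta: Mapping[str, object], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        table.to_csv(fh, sep="\t", index_label="sample_id")


def read_scores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")
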