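"""Synthetic expression + clinical cohorts with known ground truth.

The generator plants, per sample, an infiltration tier and side, per-module
infiltration fractions with side-specific log-shifts, signature-gene
expression amplified by those fractions under multiplicative log-normal
noise, a right-side-only negative VEGFA coupling to CD8 infiltration, and
exponential survival whose log-hazard is linear in chosen standardized
truths.  Everything is reproducible from the seed, and the emitted GMT lists
exactly the true signature genes so the whole pipeline can be run against
recoverable truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import ClinicalTable, ExpressionMatrix, GeneSetCollection

#: Default immune cell-type modules (name -> signature size).
DEFAULT_CELL_TYPES: dict[str, int] = {
    "NK cells": 12,
    "CD56dim NK cells": 12,
    "CD56bright NK cells": 12,
    "Plasmacytoid DC": 12,
    "Immature DC": 12,
    "Activated DC": 12,
    "Neutrophils": 12,
    "Monocytes": 12,
    "Mast cells": 12,
    "Eosinophils": 12,
    "Macrophages": 12,
    "Immature B cells": 12,
    "Activated B cells": 12,
    "Central memory CD4 T cells": 12,
    "Effector memory CD4 T cells": 12,
    "Activated CD4 T cells": 12,
    "Central memory CD8 T cells": 12,
    "Effector memory CD8 T cells": 12,
    "Activated CD8 T cells": 12,
    "CD8 T cells": 12,
    "NKT cells": 12,
    "T follicular helper cells": 12,
    "T gamma delta cells": 12,
    "Th1 cells": 12,
    "Th2 cells": 12,
    "Th17 cells": 12,
    "Treg cells": 12,
}

#: Pathway / machinery modules scored like cell types but with tier-free latents.
DEFAULT_PATHWAYS: dict[str, int] = {
    "41BB signaling pathway": 10,
    "Interferon-a response": 10,
    "APM": 8,
    "IFNG signature": 8,
}

T_SUBSET_NAMES = [
    "Central memory CD4 T cells",
    "Effector memory CD4 T cells",
    "Activated CD4 T cells",
    "Central memory CD8 T cells",
    "Effector memory CD8 T cells",
    "Activated CD8 T cells",
    "CD8 T cells",
    "Th1 cells",
    "Th2 cells",
    "Th17 cells",
    "Treg cells",
]


def default_delta_side(
    t_shift: float = 0.5, nk_shift: float = -0.3
) -> dict[str, float]:
    """Log-shift applied on the right side: positive = more on the right.

    T subsets shift up on the right; CD56bright NK shifts up on the left
    (negative right-shift).
    """
    delta = {name: t_shift for name in T_SUBSET_NAMES}
    delta["CD56bright NK cells"] = nk_shift
    return delta


@dataclass(frozen=True)
class GeneratorConfig:
    n_samples: int = 200
    p_right: float = 0.45
    cell_types: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_CELL_TYPES))
    pathways: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_PATHWAYS))
    n_background_genes: int = 500
    tier_multipliers: tuple[float, ...] = (0.2, 1.0, 3.0)
    tier_probs: tuple[float, ...] = (0.26, 0.41, 0.33)
    kappa: float = 1.0
    sigma: float = 0.3
    delta_side: Mapping[str, float] = field(default_factory=default_delta_side)
    tier_jitter_sd: float = 0.1
    w_vegfa: float = 1.0
    vegfa_mu: float = 2.0
    cd8_module: str = "Activated CD8 T cells"
    lambda0: float = 1.0 / 1500.0  # baseline hazard per day
    beta: Mapping[str, float] = field(
        default_factory=lambda: {"CD56bright NK cells": -0.4}
    )
    censor_max: float = 4000.0
    mutations: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"EGFR": (0.05, 0.25)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_right <= 1.0:
            raise ValueError("p_right must be a probability")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be > 0")
        if len(self.tier_multipliers) != len(self.tier_probs):
            raise ValueError("tier multipliers and probabilities must align")
        if abs(sum(self.tier_probs) - 1.0) > 1e-9:
            raise ValueError("tier probabilities must sum to 1")
        for name in self.beta:
            if name not in self.cell_types and name not in self.pathways:
                raise ValueError(f"beta references unknown module {name!r}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Latent generator state; stored beside, never consumed by, the pipeline."""

    samples: pd.DataFrame  # tier, tier_label, side, log_hazard, event_time, censor_time
    fractions: pd.DataFrame  # modules x samples


def _special_genes(cfg: GeneratorConfig) -> dict[str, str]:
    """Marker genes the composite scores need, mapped to their host module."""
    host_cd8 = cfg.cd8_module
    return {
        "PRF1": host_cd8,
        "GZMA": host_cd8,
        "IFNG": "Th1 cells" if "Th1 cells" in cfg.cell_types else host_cd8,
    }


def generate(
    cfg: GeneratorConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, GeneSetCollection, SyntheticTruth]:
    """Draw one synthetic cohort; bit-reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]

    tiers_idx = rng.choice(len(cfg.tier_multipliers), size=n, p=cfg.tier_probs)
    u = np.asarray(cfg.tier_multipliers)[tiers_idx]
    side = np.where(rng.random(n) < cfg.p_right, "right", "left")

    modules = list(cfg.cell_types) + list(cfg.pathways)
    sizes = {**cfg.cell_types, **cfg.pathways}
    special = _special_genes(cfg)
    for gene, host in special.items():
        if host not in sizes:
            raise ValueError(f"special gene {gene} host module {host!r} not configured")
    if cfg.cd8_module not in cfg.cell_types:
        raise ValueError(f"cd8_module {cfg.cd8_module!r} not among cell types")

    # latent infiltration / activity fractions
    frac = np.empty((len(modules), n))
    for mi, name in enumerate(modules):
        jitter = np.exp(rng.normal(0.0, cfg.tier_jitter_sd, size=n))
        if name in cfg.cell_types:
            delta = cfg.delta_side.get(name, 0.0)
            shift = np.where(side == "right", np.exp(delta), 1.0)
            frac[mi] = u * shift * jitter
        else:
            delta = cfg.delta_side.get(name, 0.0)
            shift = np.where(side == "right", np.exp(delta), 1.0)
            frac[mi] = np.exp(rng.normal(0.0, 0.5, size=n)) * shift * jitter
    fractions = pd.DataFrame(
        frac, index=pd.Index(modules, name="module"), columns=sample_ids
    )

    # gene universe: per-module signatures (disjoint), special markers, background, VEGFA
    gene_names: list[str] = []
    gene_module: list[str | None] = []
    for mi, name in enumerate(modules):
        size = sizes[name]
        hosted = [g for g, h in special.items() if h == name]
        n_anon = size - len(hosted)
        if n_anon < 0:
            raise ValueError(f"module {name!r} smaller than its hosted marker genes")
        tag = f"M{mi:02d}"
        members = [f"{tag}_G{j:03d}" for j in range(n_anon)] + hosted
        gene_names.extend(members)
        gene_module.extend([name] * len(members))
    for b in range(cfg.n_background_genes):
        gene_names.append(f"BG_G{b:04d}")
        gene_module.append(None)
    gene_names.append("VEGFA")
    gene_module.append("__vegfa__")

    n_genes = len(gene_names)
    base = rng.lognormal(mean=2.0, sigma=0.5, size=n_genes)
    noise = np.exp(rng.normal(0.0, cfg.sigma, size=(n_genes, n)))
    expr = np.empty((n_genes, n))
    f_cd8 = fractions.loc[cfg.cd8_module].to_numpy()
    right_mask = (side == "right").astype(float)
    for gi, module in enumerate(gene_module):
        if module is None:
            expr[gi] = base[gi] * noise[gi]
        elif module == "__vegfa__":
            expr[gi] = np.exp(
                cfg.vegfa_mu - cfg.w_vegfa * f_cd8 * right_mask
            ) * noise[gi]
        else:
            f = fractions.loc[module].to_numpy()
            expr[gi] = base[gi] * (1.0 + cfg.kappa * f) * noise[gi]
    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=gene_names, columns=sample_ids)
    )

    # survival: exponential with log-hazard linear in standardized truths
    log_hazard = np.full(n, np.log(cfg.lambda0))
    for name, b in cfg.beta.items():
        z = fractions.loc[name].to_numpy()
        z = (z - z.mean()) / z.std()
        log_hazard += b * z
    event_time = rng.exponential(1.0 / np.exp(log_hazard))
    censor_time = rng.uniform(0.0, cfg.censor_max, size=n)
    os_days = np.floor(np.minimum(event_time, censor_time)).astype(int)
    event = (event_time <= censor_time).astype(int)

    clin = pd.DataFrame(
        {
            "os_days": os_days,
            "event": event,
            "side": side,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    tier_rank = {m: r for r, m in enumerate(sorted(set(cfg.tier_multipliers)))}
    for gene, (p_lo, p_hi) in cfg.mutations.items():
        n_levels = max(len(cfg.tier_multipliers) - 1, 1)
        p_mut = p_lo + (p_hi - p_lo) * np.array(
            [tier_rank[m] for m in u], dtype=float
        ) / n_levels
        clin[f"{gene}_mutant"] = (rng.random(n) < p_mut).astype(int)
    clinical = ClinicalTable(clin)

    gmt_sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for name in modules:
        members = [g for g, m in zip(gene_names, gene_module) if m == name]
        gmt_sets[name] = members
        descriptions[name] = "synthetic signature"
    gene_sets = GeneSetCollection(gmt_sets, descriptions)

    truth_samples = pd.DataFrame(
        {
            "tier": u,
            "tier_label": tiers_idx,
            "side": side,
            "log_hazard": log_hazard,
            "event_time": event_time,
            "censor_time": censor_time,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = SyntheticTruth(truth_samples, fractions)
    return expression, clinical, gene_sets, truth


def truth_report(truth: SyntheticTruth, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the latent variables as two TSVs (samples, fractions)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples_path = out_dir / "truth_samples.tsv"
    fractions_path = out_dir / "truth_fractions.tsv"
    truth.samples.to_csv(samples_path, sep="\t", index_label="sample_id")
    truth.fractions.to_csv(fractions_path, sep="\t", index_label="module")
    return samples_path, fractions_path


def read_truth(out_dir: str | Path) -> SyntheticTruth:
    out_dir = Path(out_dir)
    samples = pd.read_csv(out_dir / "truth_samples.tsv", sep="\t", index_col=0)
    fractions = pd.read_csv(out_dir / "truth_fractions.tsv", sep="\t", index_col=0)
    return SyntheticTruth(samples, fractions)


def simulate_survival_cohort(
    n: int,
    log_hr: float,
    lambda0: float = 1.0 / 1500.0,
    censor_max: float = 4000.0,
    p_exposed: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary-covariate exponential survival cohort for recovery checks."""
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < p_exposed).astype(int)
    rate = lambda0 * np.exp(log_hr * x)
    event_time = rng.exponential(1.0 / rate)
    censor_time = rng.uniform(0.0, censor_max, size=n)
    return pd.DataFrame(
        {
            "time": np.minimum(event_time, censor_time),
            "event": (event_time <= censor_time).astype(int),
            "x": x,
        }
    )
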