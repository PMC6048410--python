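import warnings

import numpy as np
import pandas as pd
import pytest

from immunoscape.data_io import ExpressionMatrix, GeneSetCollection
from immunoscape.simulate import GeneratorConfig, generate
from immunoscape.ssgsea import SsgseaConfig, score_matrix


@pytest.fixture
def toy_expr() -> ExpressionMatrix:
    """3 genes x 1 sample with strictly ordered values -> ranks (3, 2, 1)."""
    return ExpressionMatrix(
        pd.DataFrame({"s1": [3.0, 2.0, 1.0]}, index=["g1", "g2", "g3"])
    )


@pytest.fixture
def random_expr() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    genes = [f"g{i:03d}" for i in range(50)]
    samples = [f"s{j}" for j in range(5)]
    return ExpressionMatrix(
        pd.DataFrame(rng.gamma(2.0, 2.0, size=(50, 5)), index=genes, columns=samples)
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One shared default synthetic cohort (n = 200, kappa = 1, sigma = 0.3, seed 1)."""
    cfg = GeneratorConfig(n_samples=200, kappa=1.0, sigma=0.3, seed=1)
    expr, clinical, sets, truth = generate(cfg)
    return cfg, expr, clinical, sets, truth


@pytest.fixture(scope="session")
def default_enrichment(default_cohort):
    cfg, expr, _, sets, _ = default_cohort
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enrich = score_matrix(expr, sets, SsgseaConfig())
    return enrich


def brute_force_es(ranks: pd.Series, members, alpha: float) -> float:
    """Independent running-sum oracle: explicit position-by-position walk."""
    idx = list(ranks.index)
    present = [g for g in members if g in idx]
    order = sorted(idx, key=lambda g: (-ranks[g], g))
    m, n = len(present), len(idx)
    denom = sum(ranks[g] ** alpha for g in present)
    es = 0.0
    hits = 0.0
    misses = 0
    for g in order:
        if g in present:
            hits += ranks[g] ** alpha
        else:
            misses += 1
        es += hits / denom - misses / (n - m)
    return es
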