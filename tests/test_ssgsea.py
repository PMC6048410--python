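import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunoscape.data_io import ExpressionMatrix, GeneSetCollection, ValidationError
from immunoscape.ssgsea import (
    EnrichmentMatrix,
    SsgseaConfig,
    enrichment_score,
    rank_transform,
    read_enrichment,
    score_matrix,
    write_enrichment,
)

from conftest import brute_force_es


class TestRankTransform:
    def test_strict_ordering(self, toy_expr):
        ranks = rank_transform(toy_expr)
        assert ranks["s1"].tolist() == [3.0, 2.0, 1.0]

    def test_stable_ordinal_tie_break_is_lexicographic(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [5.0, 5.0]}, index=["gA", "gB"])
        )
        ranks = rank_transform(expr, "stable_ordinal")
        # alphabetically earlier symbol gets the lower rank
        assert ranks.loc["gA", "s1"] == 1.0
        assert ranks.loc["gB", "s1"] == 2.0

    def test_average_rank_ties_share_mean(self):
        expr = ExpressionMatrix(
            pd.DataFrame({"s1": [5.0, 5.0, 1.0]}, index=["a", "b", "c"])
        )
        ranks = rank_transform(expr, "average_rank")
        assert ranks.loc["a", "s1"] == 2.5
        assert ranks.loc["b", "s1"] == 2.5
        assert ranks.loc["c", "s1"] == 1.0

    def test_monotone_transform_invariance(self, random_expr):
        r1 = rank_transform(random_expr)
        transformed = ExpressionMatrix(np.exp(random_expr.values / 3.0))
        r2 = rank_transform(transformed)
        pd.testing.assert_frame_equal(r1, r2)

    def test_permutation_of_1_to_n(self, random_expr):
        ranks = rank_transform(random_expr)
        n = random_expr.shape[0]
        for col in ranks.columns:
            assert sorted(ranks[col]) == list(range(1, n + 1))

    def test_unknown_policy(self, toy_expr):
        with pytest.raises(ValueError):
            rank_transform(toy_expr, "banana")


class TestEnrichmentScore:
    def test_top_singleton(self, toy_expr):
        ranks = rank_transform(toy_expr)["s1"]
        assert enrichment_score(ranks, ["g1"], 0.25) == pytest.approx(1.5)

    def test_bottom_singleton(self, toy_expr):
        ranks = rank_transform(toy_expr)["s1"]
        assert enrichment_score(ranks, ["g3"], 0.25) == pytest.approx(-1.5)

    def test_full_coverage_is_error(self, toy_expr):
        ranks = rank_transform(toy_expr)["s1"]
        with pytest.raises(ValidationError, match="every measured gene"):
            enrichment_score(ranks, ["g1", "g2", "g3"], 0.25)

    def test_absent_members_dropped_with_warning(self, toy_expr):
        ranks = rank_transform(toy_expr)["s1"]
        with pytest.warns(UserWarning, match="absent"):
            es = enrichment_score(ranks, ["g1", "zz"], 0.25)
        assert es == pytest.approx(1.5)

    def test_reversal_antisymmetry(self, toy_expr):
        ranks = rank_transform(toy_expr)["s1"]
        reversed_ranks = pd.Series(
            ranks.to_numpy()[::-1], index=ranks.index
        )
        assert enrichment_score(reversed_ranks, ["g1"], 0.25) == pytest.approx(
            -enrichment_score(ranks, ["g1"], 0.25)
        )


class TestScoreMatrix:
    def test_singleton_toy(self, toy_expr):
        sets = GeneSetCollection({"top": ["g1"]})
        em = score_matrix(toy_expr, sets, SsgseaConfig(normalize=False, min_set_size=1))
        assert em.scores.loc["top", "s1"] == pytest.approx(1.5)

    def test_normalization_identity(self, random_expr):
        rng = np.random.default_rng(0)
        genes = random_expr.gene_ids
        sets = GeneSetCollection(
            {f"s{k}": list(rng.choice(genes, 8, replace=False)) for k in range(4)}
        )
        em = score_matrix(random_expr, sets, SsgseaConfig(normalize=True))
        arr = em.scores.to_numpy()
        assert np.nanmax(arr) - np.nanmin(arr) == pytest.approx(1.0)
        assert em.normalized

    def test_oracle_equivalence(self, random_expr):
        rng = np.random.default_rng(7)
        genes = random_expr.gene_ids
        sets = {
            f"set{k}": list(rng.choice(genes, int(rng.integers(3, 15)), replace=False))
            for k in range(4)
        }
        cfg = SsgseaConfig(normalize=False)
        em = score_matrix(random_expr, GeneSetCollection(sets), cfg)
        ranks = rank_transform(random_expr)
        for name, members in sets.items():
            for s in random_expr.sample_ids:
                expected = brute_force_es(ranks[s], members, cfg.alpha)
                assert em.scores.loc[name, s] == pytest.approx(expected, abs=1e-10)

    def test_sample_independence_raw(self, random_expr):
        sets = GeneSetCollection({"s": random_expr.gene_ids[:6]})
        cfg = SsgseaConfig(normalize=False)
        full = score_matrix(random_expr, sets, cfg)
        sub = score_matrix(
            random_expr.subset_samples(random_expr.sample_ids[:2]), sets, cfg
        )
        pd.testing.assert_frame_equal(full.scores.iloc[:, :2], sub.scores)

    def test_small_set_skipped_nan(self, random_expr):
        sets = GeneSetCollection(
            {"tiny": ["not_there", random_expr.gene_ids[0]], "ok": random_expr.gene_ids[:5]}
        )
        with pytest.warns(UserWarning, match="skipped"):
            em = score_matrix(random_expr, sets, SsgseaConfig(normalize=False))
        assert em.scores.loc["tiny"].isna().all()
        assert em.scores.loc["ok"].notna().all()

    def test_all_sets_skipped_is_error(self, random_expr):
        import warnings

        sets = GeneSetCollection({"tiny": ["nope", "nada"]})
        with pytest.raises(ValidationError, match="nothing to score"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                score_matrix(random_expr, sets)

    def test_determinism(self, random_expr):
        sets = GeneSetCollection({"s": random_expr.gene_ids[:6]})
        a = score_matrix(random_expr, sets)
        b = score_matrix(random_expr, sets)
        pd.testing.assert_frame_equal(a.scores, b.scores)

    def test_tsv_round_trip(self, random_expr, tmp_path):
        sets = GeneSetCollection({"s": random_expr.gene_ids[:6]})
        em = score_matrix(random_expr, sets, SsgseaConfig(alpha=0.5, normalize=False))
        write_enrichment(em, tmp_path / "e.tsv")
        em2 = read_enrichment(tmp_path / "e.tsv")
        assert em2.alpha == 0.5
        assert not em2.normalized
        pd.testing.assert_frame_equal(em.scores, em2.scores)


class TestConfigValidation:
    def test_alpha_range(self):
        with pytest.raises(ValueError):
            SsgseaConfig(alpha=1.5)

    def test_min_set_size(self):
        with pytest.raises(ValueError):
            SsgseaConfig(min_set_size=0)


@settings(max_examples=100, deadline=None)
@given(
    seed=st.integers(0, 10_000),
    scale=st.floats(0.1, 10.0),
    shift=st.floats(0.0, 100.0),
)
def test_rank_invariance_property(seed, scale, shift):
    """Raw ES is unchanged by any strictly increasing per-sample transform."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(20)]
    vals = rng.permutation(np.arange(1.0, 21.0))  # tie-free
    expr = ExpressionMatrix(pd.DataFrame({"s": vals}, index=genes))
    members = list(rng.choice(genes, 5, replace=False))
    sets = GeneSetCollection({"m": members})
    cfg = SsgseaConfig(normalize=False)
    base = score_matrix(expr, sets, cfg).scores.iloc[0, 0]
    # strictly increasing map: affine then exp keeps order
    transformed = ExpressionMatrix(np.exp((expr.values * scale + shift) / 50.0))
    after = score_matrix(transformed, sets, cfg).scores.iloc[0, 0]
    assert after == pytest.approx(base, abs=1e-12)


@settings(max_examples=30, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_reversal_antisymmetry_property(seed):
    """Reversing the ranking swaps top/bottom singleton scores with a sign flip."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(15)]
    vals = rng.permutation(np.arange(1.0, 16.0))
    expr = ExpressionMatrix(pd.DataFrame({"s": vals}, index=genes))
    rev = ExpressionMatrix(pd.DataFrame({"s": 16.0 - vals}, index=genes))
    top_gene = [expr.values["s"].idxmax()]
    cfg = SsgseaConfig(normalize=False, min_set_size=1)
    sets = GeneSetCollection({"m": top_gene})
    es_fwd = score_matrix(expr, sets, cfg).scores.iloc[0, 0]
    es_rev = score_matrix(rev, sets, cfg).scores.iloc[0, 0]
    assert es_rev == pytest.approx(-es_fwd, abs=1e-12)
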