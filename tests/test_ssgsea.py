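import string

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from immunopanel import (
    GeneSet,
    SsgseaParams,
    ValidationError,
    pearson,
    rank_within_sample,
    score_matrix,
    ssgsea_score,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent direct-summation oracle (O(N^2), no shared code with the
# implementation): a threshold sweep over positions in the decreasing-rank
# ordering, where every position contributes the cumulative fractions of
# all genes ranked at or above its own rank.


def oracle_rank(values):
    ranks = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def oracle_es(values, gene_ids, set_genes, alpha):
    ranks = dict(zip(gene_ids, oracle_rank(values)))
    in_set = set(set_genes) & set(gene_ids)
    n_total = len(gene_ids)
    n_in = len(in_set)
    assert 0 < n_in < n_total
    denom_in = sum(ranks[g] ** alpha for g in in_set)
    order = sorted(gene_ids, key=lambda g: (-ranks[g], g))
    es = 0.0
    for g in order:
        threshold = ranks[g]
        p_in = sum(ranks[h] ** alpha for h in in_set if ranks[h] >= threshold)
        p_out = sum(1 for h in gene_ids if h not in in_set and ranks[h] >= threshold)
        es += p_in / denom_in - p_out / (n_total - n_in)
    return es


def _gene_names(n):
    alphabet = string.ascii_uppercase
    return [alphabet[i] if n <= 26 else f"G{i:03d}" for i in range(n)]


class TestRankWithinSample:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([10, 20, 30], [1, 2, 3]),
            ([5, 5], [1.5, 1.5]),
            ([7, 3, 7, 1], [3.5, 2, 3.5, 1]),
        ],
    )
    def test_examples(self, values, expected):
        np.testing.assert_array_equal(rank_within_sample(values), expected)

    def test_needs_two_genes(self):
        with pytest.raises(ValidationError):
            rank_within_sample([1.0])


class TestSsgseaScore:
    def test_top_set_unweighted(self):
        values = pd.Series([5.0, 4, 3, 2, 1], index=list("ABCDE"))
        es = ssgsea_score(values, GeneSet("top", frozenset("AB")), SsgseaParams(alpha=0))
        assert es == pytest.approx(2.5, abs=1e-12)

    def test_bottom_set_antisymmetric(self):
        values = pd.Series([5.0, 4, 3, 2, 1], index=list("ABCDE"))
        es = ssgsea_score(values, GeneSet("bot", frozenset("DE")), SsgseaParams(alpha=0))
        assert es == pytest.approx(-2.5, abs=1e-12)

    def test_constant_expression_scores_zero(self):
        values = pd.Series([2.0] * 6, index=list("ABCDEF"))
        for genes in ("AB", "CF", "ABE"):
            assert ssgsea_score(values, GeneSet("s", frozenset(genes))) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_empty_effective_set_errors(self):
        values = pd.Series([1.0, 2.0], index=["A", "B"])
        with pytest.raises(ValidationError, match="no gene"):
            ssgsea_score(values, GeneSet("s", frozenset(["Z"])))

    def test_full_universe_set_errors(self):
        values = pd.Series([1.0, 2.0], index=["A", "B"])
        with pytest.raises(ValidationError, match="whole universe"):
            ssgsea_score(values, GeneSet("s", frozenset(["A", "B"])))

    def test_absent_genes_dropped_with_warning(self, caplog):
        values = pd.Series([3.0, 2.0, 1.0], index=["A", "B", "C"])
        with caplog.at_level("WARNING"):
            es = ssgsea_score(values, GeneSet("s", frozenset(["A", "MISSING"])))
        assert any("absent" in r.message for r in caplog.records)
        assert es == ssgsea_score(values, GeneSet("s", frozenset(["A"])))

    def test_alpha_zero_closed_form_two_gene_sets(self):
        # closed form for a tie-free sample: with the set at descending-rank
        # positions i1 < i2, ES = (2N - i1 - i2 + 2)/2
        #                          - (N(N+1)/2 - (2N - i1 - i2 + 2)) / (N - 2)
        rng = np.random.default_rng(3)
        for n_total in (4, 7, 11):
            genes = _gene_names(n_total)
            values = pd.Series(
                rng.permutation(np.arange(1.0, n_total + 1)), index=genes
            )
            desc = values.sort_values(ascending=False).index.tolist()
            for _ in range(5):
                pair = rng.choice(n_total, size=2, replace=False)
                i1, i2 = sorted(int(p) + 1 for p in pair)
                set_genes = {desc[i1 - 1], desc[i2 - 1]}
                covered = 2 * n_total - i1 - i2 + 2
                expected = covered / 2 - (
                    n_total * (n_total + 1) / 2 - covered
                ) / (n_total - 2)
                es = ssgsea_score(
                    values, GeneSet("s", frozenset(set_genes)), SsgseaParams(alpha=0)
                )
                assert es == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 1.0])
    def test_matches_oracle_small_universes(self, alpha):
        """Direct-summation oracle equivalence across universes N = 3..12,
        with and without ties."""
        rng = np.random.default_rng(11)
        for n_total in range(3, 13):
            genes = _gene_names(n_total)
            for tie_levels in (None, 3):
                for _ in range(8):
                    if tie_levels:
                        vals = rng.integers(1, tie_levels + 1, n_total).astype(float)
                    else:
                        vals = rng.normal(size=n_total)
                    n_in = int(rng.integers(1, n_total))
                    set_genes = set(rng.choice(genes, size=n_in, replace=False))
                    values = pd.Series(vals, index=genes)
                    es = ssgsea_score(
                        values, GeneSet("s", frozenset(set_genes)),
                        SsgseaParams(alpha=alpha),
                    )
                    expected = oracle_es(vals, genes, set_genes, alpha)
                    assert es == pytest.approx(expected, abs=1e-10)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        data=st.data(),
        n_total=st.integers(min_value=4, max_value=30),
    )
    def test_monotone_transform_invariance(self, data, n_total):
        """Any strictly increasing map of a sample's values leaves the
        enrichment score bit-identical (the statistic is rank-based)."""
        genes = _gene_names(n_total)
        vals = np.array(
            data.draw(
                st.lists(
                    st.integers(min_value=0, max_value=8),
                    min_size=n_total, max_size=n_total,
                )
            ),
            dtype=float,
        )
        n_in = data.draw(st.integers(min_value=1, max_value=n_total - 1))
        set_genes = frozenset(genes[:n_in])
        c1 = data.draw(st.floats(min_value=0.1, max_value=3))
        c2 = data.draw(st.floats(min_value=0.01, max_value=2))
        transformed = 5.0 + c1 * vals + c2 * vals**3  # strictly increasing
        base = ssgsea_score(pd.Series(vals, index=genes), GeneSet("s", set_genes))
        mapped = ssgsea_score(
            pd.Series(transformed, index=genes), GeneSet("s", set_genes)
        )
        assert base == mapped


class TestScoreMatrix:
    def test_single_sample(self):
        m = make_matrix([[3.0], [2.0], [1.0]], ["A", "B", "C"], ["s1"])
        table = score_matrix(m, [GeneSet("s", frozenset(["A"]))])
        assert table.shape == (1, 1)

    def test_per_sample_independence_under_permutation(self):
        rng = np.random.default_rng(5)
        genes = _gene_names(15)
        samples = [f"s{i}" for i in range(6)]
        m = make_matrix(rng.random((15, 6)), genes, samples)
        sets = [GeneSet("s", frozenset(genes[:4]))]
        base = score_matrix(m, sets)
        shuffled = m.subset_samples(samples[::-1])
        out = score_matrix(shuffled, sets)
        for s in samples:
            assert out.loc[s, "s"] == base.loc[s, "s"]

    def test_matches_oracle_on_every_cell(self):
        rng = np.random.default_rng(9)
        genes = _gene_names(20)
        samples = [f"s{i}" for i in range(10)]
        values = rng.lognormal(size=(20, 10))
        m = make_matrix(values, genes, samples)
        sets = [
            GeneSet("a", frozenset(genes[:5])),
            GeneSet("b", frozenset(genes[5:12])),
            GeneSet("c", frozenset(genes[3:8])),
        ]
        table = score_matrix(m, sets)
        for j, s in enumerate(samples):
            for gs in sets:
                expected = oracle_es(values[:, j], genes, gs.genes, 0.25)
                assert table.loc[s, gs.name] == pytest.approx(expected, abs=1e-10)

    def test_range_rescaling_dialect(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.random((10, 8)), _gene_names(10), [f"s{i}" for i in range(8)])
        sets = [GeneSet("s", frozenset(_gene_names(10)[:3]))]
        raw = score_matrix(m, sets)
        rescaled = score_matrix(m, sets, SsgseaParams(rescale_range=True))
        rng_raw = raw["s"].max() - raw["s"].min()
        np.testing.assert_allclose(rescaled["s"], raw["s"] / rng_raw)

    def test_invalid_alpha(self):
        with pytest.raises(ValidationError):
            SsgseaParams(alpha=-0.1)


def test_panel_level_additivity(tissue_scores):
    """The 15-gene score behaves like the sum of its 6-gene and 9-gene
    parts: Pearson r > 0.99 across a cohort of >= 50 samples."""
    r = pearson(
        tissue_scores["immunogenicity"],
        tissue_scores["activation"] + tissue_scores["checkpoint"],
    )
    assert len(tissue_scores) >= 50
    assert r.r > 0.99
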