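import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from micropheno.model import AbundanceMatrix, DataError
from micropheno.preprocess import (
    DominanceConfig,
    alpha_diversity,
    chao1,
    collapse_minor_taxa,
    rollup_rank,
    shannon,
    simpson,
)

from conftest import lineage, make_study

counts_vectors = st.lists(st.integers(min_value=0, max_value=30), min_size=1, max_size=25).filter(
    lambda v: sum(v) > 0
)


class TestRollup:
    def test_family_sums_over_genera(self, three_sample_study):
        genus = three_sample_study.matrix("genus")
        fam = rollup_rank(genus, "family")
        assert fam.taxon_names == ["L", "R"]
        np.testing.assert_allclose(fam.values[:, 0], genus.values[:, 0] + genus.values[:, 1])

    def test_rollup_to_own_rank_is_identity(self, three_sample_study):
        genus = three_sample_study.matrix("genus")
        same = rollup_rank(genus, "genus")
        np.testing.assert_array_equal(same.values, genus.values)
        assert same.taxon_names == genus.taxon_names

    def test_rollup_downward_is_an_error(self, three_sample_study):
        with pytest.raises(DataError, match="rollup"):
            rollup_rank(three_sample_study.matrix("family"), "genus")

    def test_row_sums_preserved_exactly_on_random_forest(self, rng):
        # 5 genera under 2 families, random fractions
        fams = ["Fa", "Fb"]
        lineages = [("P", "C", "O", fams[int(rng.integers(2))], f"g{i}") for i in range(5)]
        frac = rng.dirichlet(np.ones(5), size=4)
        study = make_study(frac, lineages)
        fam = study.matrix("family")
        np.testing.assert_allclose(fam.values.sum(axis=1), frac.sum(axis=1), atol=1e-12)


class TestCollapseMinorTaxa:
    def _matrix(self, means):
        # 2 samples straddling each mean so column means equal `means`
        taxa = [lineage("P", "C", "O", "F", name) for name in means]
        vals = np.array([list(means.values()), list(means.values())])
        return AbundanceMatrix("genus", ["s1", "s2"], taxa, vals)

    def test_greedy_accumulation_keeps_others_below_threshold(self):
        m = self._matrix({"A": 0.5, "B": 0.3, "C": 0.12, "D": 0.05, "E": 0.03})
        out = collapse_minor_taxa(m, DominanceConfig(threshold=0.10))
        assert out.taxon_names == ["A", "B", "C", "others"]
        np.testing.assert_allclose(out.values[:, -1], 0.08)
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-12)

    def test_all_taxa_above_threshold_yields_empty_others(self):
        m = self._matrix({"A": 0.4, "B": 0.35, "C": 0.25})
        out = collapse_minor_taxa(m, DominanceConfig(threshold=0.10))
        assert out.taxon_names == ["A", "B", "C", "others"]
        np.testing.assert_array_equal(out.values[:, -1], 0.0)
        np.testing.assert_array_equal(out.values[:, :-1], m.values)

    def test_single_taxon_matrix_unchanged(self):
        m = self._matrix({"A": 1.0})
        out = collapse_minor_taxa(m, DominanceConfig(threshold=0.10))
        np.testing.assert_array_equal(out.values[:, 0], m.values[:, 0])
        np.testing.assert_array_equal(out.values[:, -1], 0.0)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(DataError):
            DominanceConfig(threshold=0.0)
        with pytest.raises(DataError):
            DominanceConfig(threshold=1.5)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.05, 0.5))
    def test_conserves_rows_and_retained_values(self, seed, threshold):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 12))
        vals = rng.dirichlet(np.full(p, 0.7), size=5)
        taxa = [lineage("P", "C", "O", "F", f"g{j}") for j in range(p)]
        m = AbundanceMatrix("genus", [f"s{i}" for i in range(5)], taxa, vals)
        out = collapse_minor_taxa(m, DominanceConfig(threshold=threshold))
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-12)
        assert out.values[:, -1].mean() < threshold
        for name in out.taxon_names[:-1]:
            np.testing.assert_array_equal(out.column(name), m.column(name))

    def test_per_sample_scope_conserves_each_row(self, rng):
        vals = rng.dirichlet(np.full(8, 0.5), size=6)
        taxa = [lineage("P", "C", "O", "F", f"g{j}") for j in range(8)]
        m = AbundanceMatrix("genus", [f"s{i}" for i in range(6)], taxa, vals)
        out = collapse_minor_taxa(m, DominanceConfig(threshold=0.2, scope="per_sample"))
        np.testing.assert_allclose(out.values.sum(axis=1), 1.0, atol=1e-12)
        assert np.all(out.values[:, -1] < 0.2)


class TestAlphaDiversity:
    def test_uniform_shannon_is_log_richness(self):
        assert shannon([1, 1, 1, 1]) == pytest.approx(math.log(4), abs=1e-12)
        assert shannon([1, 1, 1, 1], base=2) == pytest.approx(2.0)

    def test_single_taxon_has_zero_diversity(self):
        assert shannon([7]) == 0.0
        assert simpson([7]) == 0.0

    def test_chao1_bias_corrected_hand_value(self):
        # S_obs=5, F1=2, F2=1: 5 + 2*1/(2*2) = 5.5
        counts = [1, 1, 2, 3, 4]
        assert chao1(counts) == 5.5

    def test_chao1_equals_richness_without_singletons(self):
        assert chao1([2, 3, 5, 2]) == 4.0

    def test_chao1_classical_form_and_f2_zero_error(self):
        assert chao1([1, 1, 2, 3, 4], bias_corrected=False) == pytest.approx(5 + 4 / 2)
        with pytest.raises(DataError, match="F2"):
            chao1([1, 3, 4], bias_corrected=False)

    def test_chao1_rejects_fractions_and_empty_input(self):
        with pytest.raises(DataError, match="integer"):
            chao1([0.5, 0.5])
        with pytest.raises(DataError):
            chao1([0, 0])
        with pytest.raises(DataError):
            shannon([])

    def test_simpson_dominance_form(self):
        assert simpson([1, 1], form="dominance") == pytest.approx(0.5)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(counts_vectors)
    def test_chao1_lower_bounded_by_observed_richness(self, counts):
        s_obs = sum(1 for c in counts if c > 0)
        est = chao1(counts)
        assert est >= s_obs
        if not any(c == 1 for c in counts):
            assert est == s_obs

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(counts_vectors)
    def test_indices_match_reference_implementation(self, counts):
        """Shannon/Simpson/Chao1 agree with scikit-bio on integer counts."""
        from skbio.diversity.alpha import chao1 as sk_chao1
        from skbio.diversity.alpha import shannon as sk_shannon
        from skbio.diversity.alpha import simpson as sk_simpson

        c = np.array(counts)
        assert shannon(c) == pytest.approx(sk_shannon(c, base=math.e), abs=1e-12)
        assert simpson(c) == pytest.approx(sk_simpson(c), abs=1e-12)
        assert chao1(c) == pytest.approx(sk_chao1(c, bias_corrected=True), abs=1e-12)

    def test_shannon_maximal_at_uniform(self, rng):
        k = 6
        h_uniform = shannon(np.full(k, 1 / k))
        for _ in range(200):
            assert shannon(rng.dirichlet(np.ones(k))) <= h_uniform + 1e-12

    def test_simpson_range_and_dispatch(self, rng):
        for _ in range(50):
            v = rng.dirichlet(np.ones(5))
            assert 0 <= simpson(v) < 1
        assert alpha_diversity([1, 1, 1, 1], "shannon") == pytest.approx(math.log(4))
        with pytest.raises(DataError):
            alpha_diversity([1], "richness")
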