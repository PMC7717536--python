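import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from micropheno.correlation import (
    CorrelationTable,
    UndefinedResult,
    correlate_pair,
    correlate_parameter_vs_taxa,
    correlate_taxon_vs_parameters,
)
from micropheno.model import DataError
from micropheno.simulate import FixtureSpec, PlantedLink, generate_study

from conftest import make_study


def as_map(values):
    return {f"s{i}": float(v) for i, v in enumerate(values)}


class TestCorrelatePair:
    def test_perfect_linearity_gives_pearson_one(self):
        r = correlate_pair(as_map([1, 2, 3]), as_map([2, 4, 6]), "pearson")
        assert r.coefficient == pytest.approx(1.0)

    def test_monotone_nonlinear_separates_methods(self):
        x, y = as_map([1, 2, 3]), as_map([10, 100, 1000])
        assert correlate_pair(x, y, "spearman").coefficient == pytest.approx(1.0)
        assert correlate_pair(x, y, "pearson").coefficient < 1.0

    def test_midrank_tie_handling_matches_explicit_arithmetic(self):
        x = [1, 2, 2, 3]
        y = [4, 3, 3, 1]
        # independent oracle: midranks by hand, then product-moment formula
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        ry = np.array([4.0, 2.5, 2.5, 1.0])
        expect = float(
            np.sum((rx - rx.mean()) * (ry - ry.mean()))
            / np.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2))
        )
        got = correlate_pair(as_map(x), as_map(y), "spearman").coefficient
        assert got == pytest.approx(expect, abs=1e-12)

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.5 * x
            p = correlate_pair(as_map(x), as_map(y), "pearson")
            sp = correlate_pair(as_map(x), as_map(y), "spearman")
            rr, pp = stats.pearsonr(x, y)
            assert p.coefficient == pytest.approx(rr, abs=1e-12)
            assert p.p_value == pytest.approx(pp, abs=1e-9)
            rs, ps = stats.spearmanr(x, y)
            assert sp.coefficient == pytest.approx(rs, abs=1e-12)

    def test_pairwise_complete_deletion(self):
        x = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        y = {"a": 2.0, "b": 4.0, "c": 6.0, "e": 9.0}
        r = correlate_pair(x, y, "pearson")
        assert r.n == 3
        assert r.coefficient == pytest.approx(1.0)
        assert r.low_n

    def test_undefined_below_three_pairs(self):
        with pytest.raises(UndefinedResult):
            correlate_pair({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 3.0}, "pearson")

    def test_constant_side_is_named(self):
        with pytest.raises(DataError, match="y side"):
            correlate_pair(as_map([1, 2, 3]), as_map([5, 5, 5]), "pearson")

    def test_exact_permutation_p_matches_independent_enumeration(self):
        xs, ys = [1.0, 2.0, 3.0, 4.0, 5.0], [1.0, 3.0, 2.0, 5.0, 4.0]
        exact = correlate_pair(as_map(xs), as_map(ys), "spearman", exact_p=True)
        ref = stats.permutation_test(
            (xs, ys),
            lambda a, b: stats.spearmanr(a, b).statistic,
            permutation_type="pairings",
            n_resamples=np.inf,
            alternative="two-sided",
        )
        assert exact.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(-5, 5).filter(lambda a: abs(a) > 1e-3))
    def test_symmetry_and_transform_invariances(self, seed, a):
        rng = np.random.default_rng(seed)
        x = as_map(rng.normal(size=8))
        y = as_map(rng.normal(size=8))
        for method in ("pearson", "spearman"):
            rxy = correlate_pair(x, y, method).coefficient
            ryx = correlate_pair(y, x, method).coefficient
            assert rxy == pytest.approx(ryx, abs=1e-12)
            scaled = {k: a * v + 2.0 for k, v in y.items()}
            r2 = correlate_pair(x, scaled, method).coefficient
            assert r2 == pytest.approx(np.sign(a) * rxy, abs=1e-12)
        # spearman invariance under any strictly monotone transform
        mono = {k: np.exp(3 * v) for k, v in y.items()}
        assert correlate_pair(x, mono, "spearman").coefficient == pytest.approx(
            correlate_pair(x, y, "spearman").coefficient, abs=1e-12
        )


@pytest.fixture
def planted_study():
    return generate_study(
        FixtureSpec(
            seed=42,
            n_samples=20,
            n_genera=30,
            planted_links=(PlantedLink(1, "param_c03", 1, 0.05, "family"),),
        ),
        compute_distances=False,
    )


class TestSearchModes:
    def test_planted_parameter_ranks_first_for_its_taxon(self, planted_study):
        m = planted_study.matrix("family")
        taxon = m.taxa[1].name
        table = correlate_taxon_vs_parameters(planted_study, taxon, "family", "spearman")
        assert table.rows[0].y_id == "param_c03"

    def test_planted_taxon_ranks_first_for_its_parameter(self, planted_study):
        table = correlate_parameter_vs_taxa(planted_study, "param_c03", "family", "spearman")
        expected = planted_study.matrix("family").taxa[1].name
        assert table.rows[0].y_id == f"{expected}@family"

    def test_reversed_link_puts_taxon_last(self):
        study = generate_study(
            FixtureSpec(
                seed=42, n_samples=20, n_genera=30,
                planted_links=(PlantedLink(1, "param_c03", -1, 0.05, "family"),),
            ),
            compute_distances=False,
        )
        table = correlate_parameter_vs_taxa(study, "param_c03", "family", "spearman")
        expected = study.matrix("family").taxa[1].name
        assert table.rows[-1].y_id == f"{expected}@family"
        assert table.rows[-1].coefficient < 0

    def test_text_and_nominal_parameters_never_appear(self, planted_study):
        m = planted_study.matrix("family")
        table = correlate_taxon_vs_parameters(planted_study, m.taxa[0].name, "family")
        names = {r.y_id for r in table.rows}
        for d in planted_study.parameters.defs:
            if d.vtype in ("text", "nominal"):
                assert d.name not in names
                assert (d.name, f"vtype_{d.vtype}") in table.excluded

    def test_ordinal_joins_only_under_spearman_opt_in(self, planted_study):
        m = planted_study.matrix("family")
        base = correlate_taxon_vs_parameters(planted_study, m.taxa[0].name, "family", "spearman")
        assert not any(r.y_id.startswith("param_o") for r in base.rows)
        opted = correlate_taxon_vs_parameters(
            planted_study, m.taxa[0].name, "family", "spearman", include_ordinal=True
        )
        assert any(r.y_id.startswith("param_o") for r in opted.rows)
        pearson = correlate_taxon_vs_parameters(
            planted_study, m.taxa[0].name, "family", "pearson", include_ordinal=True
        )
        assert not any(r.y_id.startswith("param_o") for r in pearson.rows)

    def test_only_text_parameters_yields_empty_table_with_counts(self):
        study = make_study(
            [[0.3, 0.7], [0.6, 0.4], [0.2, 0.8]],
            [("P", "C", "O", "F", "g1"), ("P", "C", "O", "F", "g2")],
            params=[("memo", "text", {"s1": "x", "s2": "y", "s3": "z"})],
        )
        table = correlate_taxon_vs_parameters(study, "g1", "genus")
        assert table.rows == []
        assert table.excluded == [("memo", "vtype_text")]

    def test_constant_parameters_excluded_as_constant_input(self):
        study = make_study(
            [[0.3, 0.7], [0.6, 0.4], [0.2, 0.8]],
            [("P", "C", "O", "F", "g1"), ("P", "C", "O", "F", "g2")],
            params=[("flat", "continuous", {"s1": 5.0, "s2": 5.0, "s3": 5.0})],
        )
        table = correlate_taxon_vs_parameters(study, "g1", "genus")
        assert table.rows == []
        assert table.excluded == [("flat", "constant_input")]

    def test_single_taxon_rank_is_constant_after_normalization(self):
        study = make_study(
            [[0.3, 0.7], [0.6, 0.4], [0.2, 0.8]],
            [("P", "C", "O", "F", "g1"), ("P", "C", "O", "F", "g2")],
            params=[("age", "continuous", {"s1": 30.0, "s2": 40.0, "s3": 20.0})],
        )
        table = correlate_parameter_vs_taxa(study, "age", "family")
        assert table.rows == []
        assert [reason for _, reason in table.excluded] == ["constant_input"]

    def test_non_continuous_target_parameter_rejected(self, planted_study):
        with pytest.raises(DataError) as e:
            correlate_parameter_vs_taxa(planted_study, "param_t00", "family")
        assert e.value.code == "vtype_not_continuous"

    def test_unknown_taxon_rejected(self, planted_study):
        with pytest.raises(DataError):
            correlate_taxon_vs_parameters(planted_study, "Slimemold99", "family")

    def test_no_microbiome_samples_do_not_enter_correlation(self):
        study = generate_study(
            FixtureSpec(seed=9, n_samples=12, n_genera=20, n_no_microbiome=3),
            compute_distances=False,
        )
        m = study.matrix("family")
        table = correlate_taxon_vs_parameters(study, m.taxa[0].name, "family")
        assert all(r.n <= 12 for r in table.rows)


class TestTableBehavior:
    def test_rows_sorted_descending_and_toggle_reverses(self, planted_study):
        table = correlate_parameter_vs_taxa(planted_study, "param_c03", "family")
        coefs = [r.coefficient for r in table.rows]
        assert coefs == sorted(coefs, reverse=True)
        before = list(table.rows)
        table.toggle_order()
        assert [r.coefficient for r in table.rows] == sorted(coefs)
        assert sorted(r.y_id for r in table.rows) == sorted(r.y_id for r in before)

    def test_top_and_bottom_views(self, planted_study):
        table = correlate_parameter_vs_taxa(planted_study, "param_c03", "family")
        top = table.top(3)
        bottom = table.bottom(3)
        assert [r.coefficient for r in top] == sorted(
            (r.coefficient for r in table.rows), reverse=True
        )[:3]
        assert [r.coefficient for r in bottom] == sorted(
            r.coefficient for r in table.rows
        )[:3]

    def test_bh_adjustment_is_monotone_and_bounded(self, planted_study):
        table = correlate_parameter_vs_taxa(planted_study, "param_c03", "family")
        table.add_bh_adjusted_p()
        for r in table.rows:
            assert r.adjusted_p is not None
            assert r.p_value <= r.adjusted_p + 1e-15
            assert r.adjusted_p <= 1.0

    def test_noise_sweep_coefficient_monotone_to_one(self):
        """As planted noise shrinks, the planted pair's coefficient rises to 1."""
        coefs = []
        for sigma in (1.0, 0.3, 0.0):
            study = generate_study(
                FixtureSpec(
                    seed=7, n_samples=20, n_genera=30,
                    planted_links=(PlantedLink(0, "param_c00", 1, sigma, "family"),),
                ),
                compute_distances=False,
            )
            taxon = study.matrix("family").taxa[0].name
            table = correlate_parameter_vs_taxa(study, "param_c00", "family")
            row = next(r for r in table.rows if r.y_id == f"{taxon}@family")
            coefs.append(row.coefficient)
        assert coefs[0] < coefs[2]
        assert coefs[1] < coefs[2]
        assert coefs[2] == 1.0  # exact at sigma=0 (monotone construction)
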