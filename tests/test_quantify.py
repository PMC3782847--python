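"""RPSM, TMM normalisation and induction coefficients."""

import math

import numpy as np
import pandas as pd
import pytest

from flyimm import synthetic as syn
from flyimm.quantify import (
    CountTable,
    IC_INFINITY,
    format_ic,
    ic_is_undefined,
    induction_coefficient,
    normalized_expression,
    rpsm,
    tmm_factors,
)


def make_table(rng, n=50, totals=None):
    naive = rng.integers(10, 500, size=n)
    infected = rng.integers(10, 500, size=n)
    frame = pd.DataFrame(
        {
            "reads_infected": infected,
            "reads_naive": naive,
            "transcript_length": rng.integers(200, 2000, size=n),
        },
        index=[f"g{i}" for i in range(n)],
    )
    if totals:
        return CountTable(frame, total_infected=totals[0], total_naive=totals[1])
    return CountTable(frame)


class TestRpsm:
    def test_zero_reads_give_zero(self):
        assert rpsm(0, 10**6, 1000) == 0.0

    def test_direct_evaluation(self):
        assert rpsm(10, 10**6, 1000) == pytest.approx(0.01)

    def test_linearity_in_reads_and_inverse_in_total_and_length(self):
        base = rpsm(10, 10**6, 1000)
        assert rpsm(20, 10**6, 1000) == pytest.approx(2 * base)
        assert rpsm(10, 2 * 10**6, 1000) == pytest.approx(base / 2)
        assert rpsm(10, 10**6, 2000) == pytest.approx(base / 2)

    @pytest.mark.parametrize("total,length", [(0, 100), (100, 0)])
    def test_zero_denominators_rejected(self, total, length):
        with pytest.raises(ValueError):
            rpsm(1, total, length)


def brute_force_tmm(x_inf, x_nv, n_inf, n_nv, trim_m=0.30, trim_a=0.05):
    """Independent reference: trimmed weighted mean of M values, from the
    estimator definition (no code shared with the implementation)."""
    keep = [(i, n) for i, n in zip(x_inf, x_nv) if i > 0 and n > 0]
    m = [math.log2((i / n_inf) / (n / n_nv)) for i, n in keep]
    a = [0.5 * math.log2((i / n_inf) * (n / n_nv)) for i, n in keep]
    w = [(n_inf - i) / (n_inf * i) + (n_nv - n) / (n_nv * n) for i, n in keep]
    m_sorted = sorted(m)
    a_sorted = sorted(a)
    m_lo = float(np.quantile(m_sorted, trim_m))
    m_hi = float(np.quantile(m_sorted, 1 - trim_m))
    a_lo = float(np.quantile(a_sorted, trim_a))
    a_hi = float(np.quantile(a_sorted, 1 - trim_a))
    kept = [
        (mi, wi)
        for mi, ai, wi in zip(m, a, w)
        if m_lo <= mi <= m_hi and a_lo <= ai <= a_hi
    ]
    num = sum(mi / wi for mi, wi in kept)
    den = sum(1 / wi for mi, wi in kept)
    return 2 ** (num / den)


class TestTmm:
    def test_identical_libraries_give_unit_factors(self):
        rng = np.random.default_rng(1)
        table = make_table(rng)
        table.data["reads_infected"] = table.data["reads_naive"]
        table = CountTable(table.data)
        f_inf, f_nv = tmm_factors(table)
        assert f_inf == pytest.approx(1.0)
        assert f_nv == pytest.approx(1.0)

    def test_exact_twofold_scaling_gives_relative_factor_two(self):
        """Doubling every gene against fixed library totals doubles the factor."""
        rng = np.random.default_rng(2)
        naive = rng.integers(10, 500, size=50)
        frame = pd.DataFrame(
            {
                "reads_infected": 2 * naive,
                "reads_naive": naive,
                "transcript_length": rng.integers(200, 2000, size=50),
            },
            index=[f"g{i}" for i in range(50)],
        )
        table = CountTable(frame, total_infected=10**6, total_naive=10**6)
        f_inf, f_nv = tmm_factors(table)
        assert f_inf / f_nv == pytest.approx(2.0, abs=1e-9)
        assert f_inf * f_nv == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_matches_brute_force_reference(self, seed):
        rng = np.random.default_rng(seed)
        table = make_table(rng)
        f_inf, f_nv = tmm_factors(table)
        expected = brute_force_tmm(
            table.data["reads_infected"],
            table.data["reads_naive"],
            table.total_infected,
            table.total_naive,
        )
        assert f_inf / f_nv == pytest.approx(expected, rel=1e-9)

    def test_gene_relabeling_invariance(self):
        rng = np.random.default_rng(6)
        table = make_table(rng)
        shuffled = CountTable(
            table.data.sample(frac=1.0, random_state=0),
            total_infected=table.total_infected,
            total_naive=table.total_naive,
        )
        assert tmm_factors(table) == pytest.approx(tmm_factors(shuffled))

    def test_too_few_usable_genes_rejected(self):
        frame = pd.DataFrame(
            {
                "reads_infected": [5, 0, 3],
                "reads_naive": [0, 7, 2],
                "transcript_length": [100, 100, 100],
            },
            index=["a", "b", "c"],
        )
        with pytest.raises(ValueError):
            tmm_factors(CountTable(frame))


class TestNormalizedExpression:
    def test_equal_libraries_tmm_equals_rpsm(self):
        rng = np.random.default_rng(7)
        table = make_table(rng)
        table.data["reads_infected"] = table.data["reads_naive"]
        table = CountTable(table.data)
        expr = normalized_expression(table)
        assert np.allclose(expr["tmm_infected"], expr["rpsm_infected"])
        assert np.allclose(expr["tmm_naive"], expr["rpsm_naive"])

    def test_total_rescaling_leaves_ic_invariant(self):
        """Scaling one library's stated total must not change between-condition
        ratios of unaffected genes (depth is already in RPSM)."""
        rng = np.random.default_rng(8)
        table = make_table(rng, totals=(10**6, 10**6))
        expr1 = normalized_expression(table)
        table2 = CountTable(table.data, total_infected=3 * 10**6, total_naive=10**6)
        expr2 = normalized_expression(table2)
        assert np.allclose(expr1["ic"], expr2["ic"], rtol=1e-6)

    def test_all_zero_gene_is_zero_in_both_conditions(self):
        rng = np.random.default_rng(9)
        table = make_table(rng)
        table.data.loc["g0", ["reads_infected", "reads_naive"]] = 0
        expr = normalized_expression(CountTable(table.data))
        assert expr.loc["g0", "tmm_infected"] == 0
        assert expr.loc["g0", "tmm_naive"] == 0
        assert ic_is_undefined(expr.loc["g0", "ic"])


class TestInductionCoefficient:
    @pytest.mark.parametrize(
        "tmm_inf,tmm_nv,expected",
        [
            # printed TMM pairs from the published effector tables
            (23.719, 3.673, 6.457),   # Metchnikowin
            (7.542, 13.521, 0.558),   # IM4 homologue
        ],
    )
    def test_published_tmm_pairs(self, tmm_inf, tmm_nv, expected):
        assert induction_coefficient(tmm_inf, tmm_nv) == pytest.approx(expected, abs=0.005)

    def test_identity_and_reciprocal_symmetry(self):
        assert induction_coefficient(3.7, 3.7) == 1.0
        a, b = 2.5, 0.7
        assert induction_coefficient(a, b) * induction_coefficient(b, a) == pytest.approx(1.0)

    def test_infected_only_is_infinity(self):
        assert induction_coefficient(2.445, 0.0) is IC_INFINITY
        assert math.isinf(induction_coefficient(2.445, 0.0))

    def test_both_zero_is_undefined(self):
        assert ic_is_undefined(induction_coefficient(0.0, 0.0))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            induction_coefficient(-1.0, 2.0)

    def test_table_style_formatting(self):
        assert format_ic(6.4572) == "6.457"
        assert format_ic(IC_INFINITY) == "Infinity"


def test_estimated_ic_converges_to_true_fold_change(catalog):
    """Deep Poisson libraries: estimated IC within 5% of truth for well-read genes."""
    fc = {g: 1.0 for g in catalog.gene_ids}
    induced = catalog.gene_ids[10]
    suppressed = catalog.gene_ids[12]
    fc[induced], fc[suppressed] = 4.0, 0.25
    spec = syn.InductionSpec(fc, dispersion=0.0, depth_infected=10**6, depth_naive=10**6)
    counts, truth = syn.generate_count_experiment(catalog, spec, seed=17)
    expr = normalized_expression(CountTable(counts))
    for gene in (induced, suppressed):
        if min(truth.loc[gene, "mean_infected"], truth.loc[gene, "mean_naive"]) >= 100:
            assert expr.loc[gene, "ic"] == pytest.approx(fc[gene], rel=0.05)


# -- property tests ---------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=100)
@given(
    a=st.floats(min_value=1e-6, max_value=1e6, allow_nan=False),
    b=st.floats(min_value=1e-6, max_value=1e6, allow_nan=False),
)
def test_ic_reciprocal_identity_property(a, b):
    assert induction_coefficient(a, b) * induction_coefficient(b, a) == pytest.approx(1.0)


@settings(derandomize=True, max_examples=100)
@given(
    reads=st.integers(min_value=0, max_value=10**6),
    total=st.integers(min_value=1, max_value=10**8),
    length=st.integers(min_value=1, max_value=10**5),
)
def test_rpsm_scale_properties(reads, total, length):
    base = rpsm(reads, total, length)
    assert base >= 0
    assert rpsm(2 * reads, total, length) == pytest.approx(2 * base)
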