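"""U statistic, normal approximation, weights, and the composite Z."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from csefinder.diffexp import (
    composite_z,
    pair_weight,
    run_differential,
    u_matrix,
    u_statistic,
    z_from_u,
)


def u_brute(x, y):
    """O(n1*n2) enumeration: 1 if y<x, 1/2 if tie, 0 otherwise."""
    return sum(1.0 if yj < xi else 0.5 if yj == xi else 0.0 for xi in x for yj in y)


class TestU:
    @pytest.mark.parametrize("x,y,expected", [
        ([2, 3], [0, 1], 4.0),      # complete separation: U = n1*n2
        ([1], [1], 0.5),            # single tie
        ([3, 1, 2], [2, 2], 3.0),   # brute-force over all 6 pairs
    ])
    def test_examples(self, x, y, expected):
        assert u_statistic(x, y) == expected
        assert u_brute(x, y) == expected

    def test_brute_force_equivalence_with_ties(self):
        rng = np.random.default_rng(42)
        for _ in range(2000):
            n1, n2 = rng.integers(1, 9, size=2)
            x = rng.integers(0, 5, size=n1).astype(float)
            y = rng.integers(0, 5, size=n2).astype(float)
            assert u_statistic(x, y) == pytest.approx(u_brute(x, y), abs=1e-12)

    def test_matches_scipy_mannwhitneyu(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            x = rng.integers(0, 4, size=6).astype(float)
            y = rng.integers(0, 4, size=5).astype(float)
            ref = mannwhitneyu(x, y, alternative="two-sided").statistic
            assert u_statistic(x, y) == pytest.approx(ref)

    def test_matrix_matches_scalar(self):
        rng = np.random.default_rng(3)
        X = rng.integers(0, 4, size=(20, 6)).astype(float)
        Y = rng.integers(0, 4, size=(20, 9)).astype(float)
        U = u_matrix(X, Y)
        for i in range(20):
            assert U[i] == pytest.approx(u_statistic(X[i], Y[i]))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            u_statistic([], [1.0])


class TestZ:
    def test_mean_case_zero(self):
        assert z_from_u(6 * 4 / 2, 6, 4) == 0.0

    def test_closed_form(self):
        expected = (4 - 2.0) / np.sqrt(2 * 2 * 5 / 12.0)
        assert z_from_u(4, 2, 2) == pytest.approx(expected, abs=1e-12)
        assert z_from_u(4, 2, 2) == pytest.approx(1.5491933384829668, abs=1e-12)

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            x = rng.normal(size=5)
            y = rng.normal(size=7)  # continuous: no ties
            u_xy = u_statistic(x, y)
            u_yx = u_statistic(y, x)
            assert u_xy + u_yx == pytest.approx(35.0)
            assert z_from_u(u_xy, 5, 7) == pytest.approx(-z_from_u(u_yx, 7, 5))


class TestWeight:
    def test_hand_medians(self):
        assert pair_weight([0.9, 0.8], [0.2, 0.1]) == pytest.approx(0.7)

    def test_identical_groups_zero(self):
        assert pair_weight([0.3, 0.6], [0.3, 0.6]) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(0.001, 0.999), min_size=1, max_size=20),
        st.lists(st.floats(0.001, 0.999), min_size=1, max_size=20),
    )
    def test_bounded(self, a, b):
        assert -1.0 <= pair_weight(a, b) <= 1.0


class TestComposite:
    def test_single_pair_identity(self):
        val, deg = composite_z([2.0], [0.5])
        assert val == pytest.approx(2.0) and not deg
        val, _ = composite_z([2.0], [-0.5])
        assert val == pytest.approx(-2.0)  # sign(w) * z

    def test_equal_weights_reduce_to_stouffer(self):
        zs = [1.0, 2.0, -0.5, 0.3]
        val, _ = composite_z(zs, [0.7] * 4)
        assert val == pytest.approx(sum(zs) / np.sqrt(4))

    def test_cancellation(self):
        val, _ = composite_z([1.0, -1.0], [1.0, 1.0])
        assert val == pytest.approx(0.0)

    def test_all_zero_weights_degenerate(self):
        val, deg = composite_z([1.0, 2.0], [0.0, 0.0])
        assert val == 0.0 and deg

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            composite_z([1.0], [0.5, 0.5])

    def test_monotone_in_tumor_shift(self):
        """Raising all tumor values cannot decrease U, z, w, or the composite."""
        rng = np.random.default_rng(1)
        x = rng.lognormal(1, 0.5, size=10)
        y1 = rng.lognormal(1, 0.5, size=12)
        y2 = rng.lognormal(0.5, 0.5, size=12)
        from csefinder.quant import percentile_ranks

        def stats(xv):
            zs, ws = [], []
            for y in (y1, y2):
                u = u_statistic(xv, y)
                zs.append(z_from_u(u, len(xv), len(y)))
                pool = pd.DataFrame([np.concatenate([xv, y])],
                                    columns=[f"s{i}" for i in range(len(xv) + len(y))])
                pr = percentile_ranks(pool).iloc[0].to_numpy()
                ws.append(pair_weight(pr[: len(xv)], pr[len(xv):]))
            return zs, ws, composite_z(zs, ws)[0]

        z0, w0, c0 = stats(x)
        z1, w1, c1 = stats(x + 5.0)
        assert all(b >= a for a, b in zip(z0, z1))
        assert all(b >= a for a, b in zip(w0, w1))
        assert c1 >= c0


@pytest.fixture(scope="module")
def tiny():
    rng = np.random.default_rng(0)
    rows = []
    for grp, comp, cohort, n in [
        ("T1", "solid", "tumor", 5), ("T2", "solid", "tumor", 5),
        ("N1", "normal", "normal", 6), ("N2", "normal", "normal", 6),
        ("N3", "normal", "normal", 6),
    ]:
        for i in range(n):
            rows.append({"sample_id": f"{grp}_{i}", "group": grp,
                         "cohort": cohort, "compartment": comp, "data_source": "X"})
    samples = pd.DataFrame(rows).set_index("sample_id", drop=False)
    expr = pd.DataFrame(
        rng.lognormal(1, 0.5, size=(8, len(samples))),
        index=[f"e{i}" for i in range(8)], columns=samples.index,
    )
    return expr, samples


class TestRunDifferential:
    def test_pair_count(self, tiny):
        expr, samples = tiny
        pairs, comps = run_differential(expr, samples, "solid")
        assert (comps["k"] == 2 * 3).all()
        assert len(pairs) == 8 * 6

    def test_no_tumor_groups_error(self, tiny):
        expr, samples = tiny
        with pytest.raises(ValueError):
            run_differential(expr, samples, "brain")

    def test_shifted_exon_beats_null_composites(self, tiny):
        """A tumor-shifted exon's composite exceeds every null composite.

        Note the null composite is not centered at zero: the rank weight
        and z are computed from the same data and co-vary, so their
        product is positively biased under the null.  Selection relies on
        the threshold plus the normal-tissue filters, not on a zero-mean
        null.
        """
        expr, samples = tiny
        _, null_comps = run_differential(expr, samples, "solid")
        shifted = expr.copy()
        tumor_cols = samples.index[samples["cohort"] == "tumor"]
        shifted.loc["e0", tumor_cols] *= 50.0
        _, comps = run_differential(shifted, samples, "solid")
        target = comps.set_index("exon_id").at["e0", "composite_z"]
        assert target > null_comps["composite_z"].max()
        assert not comps["degenerate"].any()

    def test_planted_exon_composite_large(self, default_scenario, default_run):
        truth = default_scenario.truth
        comp = default_run.composites
        for g in truth.planted_gene_level:
            exon = default_scenario.models.exons_of_gene(g)[0].exon_id
            comps = [c for c in truth.designated_groups[g]]
            compartment = default_scenario.samples.loc[
                default_scenario.samples["group"] == comps[0], "compartment"
            ].iloc[0]
            val = comp.loc[
                (comp["exon_id"] == exon) & (comp["compartment"] == compartment),
                "composite_z",
            ].iloc[0]
            assert val > 1.0
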