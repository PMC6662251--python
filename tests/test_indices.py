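"""Prey-importance, Schoener overlap, and Levins' breadth statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutdiet import (
    EmptyGroupError,
    GutDietError,
    ValidationError,
    build_diet_matrix,
    diet_proportions,
    levins_breadth,
    overlap_matrix,
    prey_importance,
    round_half_up,
    schoener_overlap,
)
from gutdiet.datasets import (
    composition_proportions,
    published_breadths,
    published_overlaps,
)

from conftest import make_table


def simplex(draw, k, scale=100.0):
    raw = draw(
        st.lists(st.floats(0.01, 1.0), min_size=k, max_size=k)
    )
    arr = np.asarray(raw)
    return scale * arr / arr.sum()


class TestPreyImportance:
    def test_worked_example(self, matrix_w):
        imp = prey_importance(matrix_w)
        f = imp.frame
        assert round_half_up(f.loc["A", "F"]) == 66.67
        assert round_half_up(f.loc["B", "F"]) == 66.67
        assert round_half_up(f.loc["A", "A"]) == 42.86
        assert round_half_up(f.loc["B", "A"]) == 57.14
        assert round_half_up(f.loc["A", "P"]) == 75.00
        assert round_half_up(f.loc["B", "P"]) == 80.00

    def test_single_fish_single_prey_is_100_everywhere(self):
        table = make_table([("f1", "S", "spring", 150.0, "A", 0.5)])
        (mat,) = build_diet_matrix(table)
        f = prey_importance(mat).frame
        assert f.loc["A"].tolist() == [100.0, 100.0, 100.0]

    def test_empty_group_raises(self):
        table = make_table([("f1", "S", "spring", 150.0, "", None)])
        (mat,) = build_diet_matrix(table)
        with pytest.raises(EmptyGroupError):
            prey_importance(mat)

    def test_p_at_least_a_on_random_matrices(self):
        # P_i >= A_i always; equality iff every non-empty gut has prey i.
        rng = np.random.default_rng(42)
        for _ in range(500):
            n, k = rng.integers(2, 8), rng.integers(1, 5)
            w = rng.random((n, k)) * (rng.random((n, k)) < 0.6)
            if not (w.sum(axis=1) > 0).any():
                continue
            rows = [
                (f"f{j}", "S", "spring", 150.0, f"p{i}", w[j, i])
                for j in range(n)
                for i in range(k)
                if w[j, i] > 0
            ]
            rows += [
                (f"f{j}", "S", "spring", 150.0, "", None)
                for j in range(n)
                if w[j].sum() == 0
            ]
            (mat,) = build_diet_matrix(make_table(rows))
            f = prey_importance(mat).frame
            assert (f["P"] >= f["A"] - 1e-9).all()
            ubiquitous = f.index[np.isclose(f["P"], f["A"])]
            nonempty = mat.fish_totals > 0
            for prey in ubiquitous:
                assert ((mat.weights.loc[nonempty, prey] > 0)).all()


class TestDietProportions:
    def test_worked_example(self, matrix_w):
        p = diet_proportions(matrix_w)
        assert round_half_up(p.p["A"]) == 42.86
        assert round_half_up(p.p["B"]) == 57.14
        assert p.p.sum() == pytest.approx(100.0)

    def test_exact_percent_column_unchanged(self):
        src = pd.Series({"A": 40.0, "B": 60.0})
        p = diet_proportions(src)
        assert p.p.tolist() == [40.0, 60.0]

    def test_printed_column_renormalized_to_100(self):
        # Published R. ventralis autumn column prints (99.37, 0.64),
        # summing to 100.01; renormalization scales by 100/100.01.
        p = composition_proportions("Rhinogobio ventralis", "autumn", renormalize=True)
        assert p.p.sum() == pytest.approx(100.0)
        assert p.p["Limnoperna lacustris"] == pytest.approx(99.37 * 100 / 100.01)

    def test_all_zero_input_rejected(self):
        with pytest.raises(GutDietError):
            diet_proportions(pd.Series({"A": 0.0}))


class TestSchoenerOverlap:
    def test_identity_and_disjoint(self):
        p = pd.Series({"A": 70.0, "B": 30.0})
        assert schoener_overlap(p, p) == pytest.approx(100.0)
        q = pd.Series({"C": 50.0, "D": 50.0})
        assert schoener_overlap(p, q) == pytest.approx(0.0)

    def test_symmetry(self):
        p = pd.Series({"A": 70.0, "B": 30.0})
        q = pd.Series({"A": 20.0, "C": 80.0})
        assert schoener_overlap(p, q) == pytest.approx(schoener_overlap(q, p))

    def test_bad_sum_rejected(self):
        with pytest.raises(ValidationError):
            schoener_overlap(pd.Series({"A": 50.0}), pd.Series({"A": 100.0}))

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_matches_min_sum_oracle(self, data):
        # When both vectors sum to 100, 100 - 0.5*sum|p-q| == sum min(p,q).
        k = data.draw(st.integers(1, 5))
        names = [f"p{i}" for i in range(k)]
        p = pd.Series(simplex(data.draw, k), index=names)
        q = pd.Series(simplex(data.draw, k), index=names)
        oracle = float(np.minimum(p, q).sum())
        assert schoener_overlap(p, q) == pytest.approx(oracle, abs=1e-9)

    def test_range_is_0_to_100(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = rng.dirichlet(np.ones(4)) * 100
            q = rng.dirichlet(np.ones(4)) * 100
            d = schoener_overlap(
                pd.Series(p, index=list("abcd")), pd.Series(q, index=list("abcd"))
            )
            assert 0.0 <= d <= 100.0 + 1e-9


class TestOverlapMatrix:
    def test_published_spring_pairs_all_exceed_60(self):
        om = published_overlaps("spring")
        pairs = om.significant_pairs()
        assert len(pairs) == 6  # all pairwise overlaps significant

    def test_identical_groups_give_100(self):
        p = diet_proportions(pd.Series({"A": 60.0, "B": 40.0}), species="x", season="s")
        q = diet_proportions(pd.Series({"A": 60.0, "B": 40.0}), species="y", season="s")
        om = overlap_matrix([p, q])
        assert om.values.iloc[0, 1] == pytest.approx(100.0)

    def test_matrix_matches_pairwise_calls(self):
        rng = np.random.default_rng(3)
        groups = []
        for i, k in enumerate((2, 3, 4)):  # nested supports
            p = rng.dirichlet(np.ones(k)) * 100
            groups.append(
                diet_proportions(
                    pd.Series(p, index=[f"p{j}" for j in range(k)]),
                    species=f"g{i}",
                    season="s",
                )
            )
        om = overlap_matrix(groups)
        vals = om.values
        assert np.allclose(vals, vals.T)
        assert np.allclose(np.diag(vals), 100.0)
        for i in range(3):
            for j in range(i + 1, 3):
                assert vals.iloc[i, j] == pytest.approx(
                    schoener_overlap(groups[i], groups[j])
                )

    def test_single_group_rejected(self):
        p = diet_proportions(pd.Series({"A": 100.0}))
        with pytest.raises(GutDietError):
            overlap_matrix([p])


class TestLevinsBreadth:
    def test_bounds(self):
        assert levins_breadth(pd.Series({"A": 100.0})).B == pytest.approx(1.0)
        uniform = pd.Series({c: 25.0 for c in "abcd"})
        nb = levins_breadth(uniform)
        assert nb.B == pytest.approx(4.0)
        assert nb.S == 4

    def test_worked_example(self, matrix_w):
        nb = levins_breadth(diet_proportions(matrix_w))
        assert round_half_up(nb.B) == 1.96

    def test_published_near_monophagous_group(self):
        # R. ventralis autumn: ~99.4% of diet weight in one mussel prey.
        nb = levins_breadth(composition_proportions("Rhinogobio ventralis", "autumn", True))
        assert nb.B == pytest.approx(1.013, abs=0.001)
        assert nb.S == 2

    def test_scale_invariance(self):
        pct = pd.Series({"A": 70.0, "B": 30.0})
        frac = pct / 100.0
        assert levins_breadth(pct).B == pytest.approx(levins_breadth(frac).B)

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_between_1_and_S_and_maximized_by_uniform(self, data):
        k = data.draw(st.integers(1, 6))
        p = pd.Series(simplex(data.draw, k), index=[f"p{i}" for i in range(k)])
        nb = levins_breadth(p)
        assert 1.0 - 1e-9 <= nb.B <= nb.S + 1e-9
        uniform = pd.Series(100.0 / k, index=p.index)
        assert nb.B <= levins_breadth(uniform).B + 1e-9

    def test_zero_vector_rejected(self):
        with pytest.raises(GutDietError):
            levins_breadth(pd.Series(dtype=float))


class TestPublishedOverlapReproduction:
    # Pairwise overlaps recomputed from the printed composition columns.
    @pytest.mark.parametrize(
        "a, b, season, expected",
        [
            ("Coreius guichenoti", "Rhinogobio cylindricus", "spring", 78.93),
            ("Coreius heterodon", "Rhinogobio ventralis", "spring", 82.65),
            ("Coreius heterodon", "Rhinogobio ventralis", "autumn", 98.38),
            ("Coreius heterodon", "Rhinogobio cylindricus", "autumn", 57.80),
        ],
    )
    def test_exact_cells(self, a, b, season, expected):
        d = schoener_overlap(
            composition_proportions(a, season), composition_proportions(b, season)
        )
        assert round_half_up(d) == expected

    @pytest.mark.parametrize(
        "a, b, season, expected",
        [
            ("Rhinogobio ventralis", "Rhinogobio cylindricus", "autumn", 56.18),
            ("Rhinogobio ventralis", "Rhinogobio cylindricus", "spring", 89.68),
            ("Coreius heterodon", "Rhinogobio cylindricus", "spring", 84.48),
        ],
    )
    def test_rounding_limited_cells(self, a, b, season, expected):
        # 2-dp printed inputs leave +/-0.02 of rounding slack on these.
        d = schoener_overlap(
            composition_proportions(a, season), composition_proportions(b, season)
        )
        assert d == pytest.approx(expected, abs=0.02)

    def test_breadths_computable_for_all_groups(self):
        breadths = published_breadths()
        assert len(breadths) == 8
        for nb in breadths:
            assert 1.0 <= nb.B <= nb.S


class TestRounding:
    def test_half_up_at_two_decimals(self):
        assert round_half_up(57.795) == 57.80
        assert round_half_up(0.125) == 0.13
        assert round_half_up(66.666666) == 66.67
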