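"""Breadth indices, jackknife resampling, overlap, permutation comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gutshift import (DietTable, ValidationError, composition,
                      diversity_permutation_test, horn_ro, jackknife,
                      niche_breadth, overlap, schoener_alpha)
from gutshift.cohort import CohortSpec, simulate_cohort

from conftest import build_table


class TestNicheBreadth:
    def test_uniform_four_categories(self):
        nb = niche_breadth([0.25] * 4)
        assert nb.d == pytest.approx(0.25)
        assert nb.b == pytest.approx(4.0)
        assert nb.ba == pytest.approx(1.0)
        assert nb.j == pytest.approx(1.0)
        assert nb.h == pytest.approx(np.log(4), abs=1e-12)

    def test_single_category_degenerate(self):
        nb = niche_breadth([1.0, 0.0])
        assert (nb.s, nb.d, nb.b, nb.h) == (1, 1.0, 1.0, 0.0)
        assert np.isnan(nb.ba) and np.isnan(nb.j)

    def test_two_category_values(self):
        nb = niche_breadth([0.7, 0.3])
        assert nb.d == pytest.approx(0.58)
        assert nb.b == pytest.approx(1 / 0.58, abs=1e-9)
        assert nb.h == pytest.approx(0.6108643, abs=1e-6)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            niche_breadth([0.0, 0.0])

    def test_evenness_is_log_base_invariant(self, rng):
        for _ in range(10):
            p = rng.dirichlet(np.ones(8))
            je = niche_breadth(p, "e").j
            j10 = niche_breadth(p, "10").j
            assert je == pytest.approx(j10, abs=1e-12)

    def test_shannon_bounds(self, rng):
        p = rng.dirichlet(np.ones(12))
        nb = niche_breadth(p)
        assert 0 <= nb.h <= np.log(12) + 1e-12
        assert 1 / 12 <= nb.d <= 1 and 1 <= nb.b <= 12


class TestJackknife:
    def test_linear_statistic_closed_form(self):
        t = build_table({f"F{i}": {"a": v} for i, v in enumerate([1, 2, 3])},
                        gut_mass={f"F{i}": v for i, v in enumerate([1, 2, 3])})
        stat = lambda tt: float(tt.df["gut_mass_mg"].mean())
        jk = jackknife(stat, t)
        assert jk.jack_mean == pytest.approx(2.0)
        assert jk.theta_hat == pytest.approx(2.0)
        assert jk.se == pytest.approx(np.std([1, 2, 3], ddof=1) / np.sqrt(3))
        assert jk.se == pytest.approx(0.5774, abs=1e-4)

    def test_constant_statistic_has_zero_se(self):
        t = build_table({"F1": {"a": 1}, "F2": {"a": 2}, "F3": {"a": 4}})
        jk = jackknife(lambda tt: 7.0, t)
        assert jk.se == 0.0 and jk.jack_mean == 7.0

    def test_simpson_dominance_matches_brute_force(self, rng):
        bm = rng.gamma(1.0, 5.0, size=(4, 3))
        t = build_table({f"F{i}": dict(zip("abc", bm[i])) for i in range(4)})
        stat = lambda tt: float((composition(tt) ** 2).sum())
        jk = jackknife(stat, t)
        # independent brute force over every leave-one-out subset
        n = 4
        theta = stat(t)
        pseudo = []
        for fid in t.fish_ids:
            keep = [f for f in t.fish_ids if f != fid]
            sub = build_table({f: dict(zip("abc", bm[int(f[1:])]))
                               for f in keep})
            pseudo.append(n * theta - (n - 1) * stat(sub))
        pseudo = np.array(pseudo)
        assert jk.jack_mean == pytest.approx(pseudo.mean(), abs=1e-12)
        assert jk.se == pytest.approx(pseudo.std(ddof=1) / 2, abs=1e-12)

    def test_undefined_subset_names_fish(self):
        t = build_table({"F1": {"a": 1}, "F2": {"a": 1}})

        def stat(tt):
            if len(tt) < 2:
                raise ValueError("needs two fish")
            return 1.0

        with pytest.raises(ValidationError, match="F1"):
            jackknife(stat, t)


class TestOverlap:
    def test_identical_compositions(self):
        assert schoener_alpha([0.3, 0.7], [0.3, 0.7]) == pytest.approx(1.0)
        assert horn_ro([0.3, 0.7], [0.3, 0.7]) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        assert schoener_alpha([1, 0], [0, 1]) == pytest.approx(0.0)
        assert horn_ro([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_half_overlap_hand_values(self):
        assert schoener_alpha([0.5, 0.5], [1, 0]) == pytest.approx(0.5)
        for base in ("e", "10"):
            assert horn_ro([0.5, 0.5], [1, 0], base) == pytest.approx(
                0.688722, abs=1e-5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_schoener_triangle_bound(self, seed):
        r = np.random.default_rng(seed)
        x, y, z = r.dirichlet(np.ones(6), size=3)
        assert schoener_alpha(x, z) >= (
            schoener_alpha(x, y) + schoener_alpha(y, z) - 1 - 1e-12)

    def test_group_overlap_with_jackknife(self):
        t = build_table(
            {"F1": {"a": 1, "b": 1}, "F2": {"a": 3, "b": 1},
             "F3": {"a": 0, "b": 2}, "F4": {"a": 1, "b": 3}},
            groups={"F1": "x", "F2": "x", "F3": "y", "F4": "y"})
        res = overlap(t, "x", "y")
        assert 0 <= res.schoener.theta_hat <= 1
        assert 0 <= res.horn.theta_hat <= 1
        assert res.schoener.n == 4 and res.schoener.se >= 0


def _null_spec(n=12, seed=None):
    cats = tuple("c%d" % i for i in range(6))
    mean = np.array([30, 25, 20, 12, 8, 5], dtype=float)
    return CohortSpec(
        categories=cats, groups=("x", "y"),
        n_per_group={"x": n, "y": n},
        mean_composition={"x": mean, "y": mean},
        occurrence_prob={"x": np.full(6, 0.9), "y": np.full(6, 0.9)},
        concentration=3.0, empty_prob=0.0, seed=seed).calibrated()


class TestDiversityPermutationTest:
    def test_identical_groups_not_significant(self):
        bm = {"F%d" % i: {"a": 1 + i % 3, "b": 2, "c": i % 2 + 1}
              for i in range(6)}
        dup = {**bm, **{"G%d" % i: v for i, (_, v) in enumerate(bm.items())}}
        groups = {f: ("x" if f.startswith("F") else "y") for f in dup}
        t = build_table(dup, groups=groups)
        res = diversity_permutation_test(t, "D", ("x", "y"), n_perm=199, seed=0)
        assert res["p"] > 0.5

    def test_distinct_dirichlet_means_detected(self):
        # one concentrated diet vs one even diet: Simpson dominance differs
        cats = tuple("c%d" % i for i in range(4))
        spec = CohortSpec(
            categories=cats, groups=("x", "y"), n_per_group={"x": 15, "y": 15},
            mean_composition={"x": np.array([0.85, 0.05, 0.05, 0.05]),
                              "y": np.array([0.25, 0.25, 0.25, 0.25])},
            occurrence_prob={"x": np.ones(4), "y": np.ones(4)},
            concentration=50.0, empty_prob=0.0).calibrated()
        t = simulate_cohort(spec, seed=1)
        res = diversity_permutation_test(t, "D", ("x", "y"), n_perm=499, seed=2)
        assert res["p"] < 0.05

    def test_p_bounds_and_nperm_floor(self):
        t = simulate_cohort(_null_spec(), seed=3)
        res = diversity_permutation_test(t, "B", ("x", "y"), n_perm=99, seed=4)
        assert 1 / 100 <= res["p"] <= 1.0
        with pytest.raises(ValueError):
            diversity_permutation_test(t, "B", ("x", "y"), n_perm=10)
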