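"""Statistical layer: Fisher/BH/ANOVA, two-group clustering, multitrait."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoplate import screen
from phenoplate.screen import (
    bh_adjust,
    fisher_exact_2x2,
    line_significance,
    multitrait_profile_heatmap,
    oneway_anova,
    two_group_color_clustering,
)

from _oracles import bh_stepup, fisher_two_sided_exact


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((5, 5, 5, 5), 1.0),
            ((10, 0, 0, 10), 2 / 184756),
            ((2, 8, 7, 3), 12892 / 184756),
        ],
    )
    def test_known_tables(self, table, expected):
        assert fisher_exact_2x2(*table) == pytest.approx(expected, rel=1e-7)

    def test_matches_enumeration_for_small_margins(self):
        """Exhaustive agreement with rational hypergeometric enumeration for
        every table with row sums at most 12."""
        for r1 in range(1, 13):
            for r2 in range(1, 13):
                for a in range(r1 + 1):
                    for c in range(r2 + 1):
                        b, d = r1 - a, r2 - c
                        if a + c == 0 or b + d == 0:
                            continue
                        got = fisher_exact_2x2(a, b, c, d)
                        want = fisher_two_sided_exact(a, b, c, d)
                        assert got == pytest.approx(want, rel=1e-7, abs=1e-12)

    def test_zero_margin_returns_one_with_warning(self):
        with pytest.warns(UserWarning):
            assert fisher_exact_2x2(0, 0, 5, 5) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01], [0.01]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.001, 0.5], [0.002, 0.5]),
        ],
    )
    def test_hand_computed_values(self, p, expected):
        assert bh_adjust(np.array(p)) == pytest.approx(expected)

    def test_empty_vector(self):
        assert bh_adjust(np.array([])).size == 0

    def test_matches_stepup_definition_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 21)))
            assert bh_adjust(p) == pytest.approx(bh_stepup(p), rel=1e-12)

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        p = rng.random(50)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=25))
    def test_stepup_definition_holds_for_arbitrary_vectors(self, p):
        assert bh_adjust(np.array(p)) == pytest.approx(
            bh_stepup(np.array(p)), rel=1e-12, abs=1e-15
        )


class TestFisherProperties:
    @settings(derandomize=True, max_examples=150)
    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_table_symmetries(self, table):
        """Swapping rows, or swapping columns, leaves the two-sided p
        unchanged."""
        a, b, c, d = table
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        p = fisher_exact_2x2(a, b, c, d)
        assert fisher_exact_2x2(c, d, a, b) == pytest.approx(p, rel=1e-9)
        assert fisher_exact_2x2(b, a, d, c) == pytest.approx(p, rel=1e-9)
        assert 0.0 <= p <= 1.0


class TestOnewayAnova:
    def test_identical_groups_give_f_zero(self):
        f, p = oneway_anova([1, 2, 3], [1, 2, 3])
        assert f == 0.0 and p == 1.0

    def test_known_f_statistic(self):
        f, p = oneway_anova([1, 2, 3], [2, 3, 4])
        assert f == pytest.approx(1.5)
        assert p == pytest.approx(0.2879, abs=1e-3)

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova([1.0], [1, 2, 3])

    def test_constant_unequal_groups_flagged(self):
        with pytest.warns(UserWarning):
            f, p = oneway_anova([1, 1, 1], [2, 2, 2])
        assert p == 0.0


def _profiles(n_green, n_brown, rng, noise=0.02, flip_frac=0.0):
    """Joined 32-length profiles: green mass in VIS class 5 + FLUO class 0,
    brown mass in VIS class 1 with empty FLUO."""
    green = np.zeros(32)
    green[5] = 1.0
    green[16] = 1.0
    brown = np.zeros(32)
    brown[1] = 1.0
    base = np.vstack([green] * n_green + [brown] * n_brown)
    truth = np.array([1] * n_green + [0] * n_brown)
    if flip_frac:
        k = int(round(flip_frac * len(base)))
        idx = rng.choice(len(base), size=k, replace=False)
        base[idx] = np.where(truth[idx, None] == 1, brown, green)
    base = base + rng.normal(0, noise, base.shape)
    return np.clip(base, 0, None), truth


class TestTwoGroupClustering:
    def test_separable_profiles_split_perfectly(self, rng):
        profiles, truth = _profiles(10, 10, rng)
        res = two_group_color_clustering(profiles)
        assert not res.degenerate
        assert (res.alive == truth.astype(bool)).all()

    def test_identical_profiles_flagged_degenerate(self):
        res = two_group_color_clustering(np.ones((6, 32)))
        assert res.degenerate and set(res.labels) == {0}

    def test_order_permutation_invariance(self, rng):
        profiles, _ = _profiles(8, 8, rng)
        res = two_group_color_clustering(profiles)
        perm = rng.permutation(len(profiles))
        res_p = two_group_color_clustering(profiles[perm])
        assert (res.alive[perm] == res_p.alive).all()

    def test_accuracy_above_90pct_with_label_noise(self, rng):
        profiles, truth = _profiles(50, 50, rng, flip_frac=0.05)
        res = two_group_color_clustering(profiles)
        acc = (res.alive == truth.astype(bool)).mean()
        assert acc >= 0.90

    def test_needs_at_least_two_records(self):
        with pytest.raises(ValueError):
            two_group_color_clustering(np.ones((1, 32)))


class TestLineSignificance:
    def test_line_identical_to_wild_type_not_significant(self):
        tab = pd.DataFrame(
            {
                "line": ["Col-0", "mut"],
                "n_group1": [50, 50],
                "n_group2": [58, 58],
            }
        )
        res = line_significance(tab, test="fisher")
        assert res.loc[0, "p_raw"] == pytest.approx(1.0)
        assert not res.loc[0, "significant"]

    def test_strong_effect_line_flagged_in_large_family(self, rng):
        lines = {"Col-0": (71, 37), "hit": (14, 94)}
        for i in range(100):
            alive = int(rng.binomial(108, 71 / 108))
            lines[f"null-{i}"] = (alive, 108 - alive)
        tab = pd.DataFrame(
            [
                {"line": k, "n_group1": a, "n_group2": d}
                for k, (a, d) in lines.items()
            ]
        )
        res = line_significance(tab, test="fisher").set_index("line")
        assert res.loc["hit", "p_adj"] < 1e-6
        assert res.loc["hit", "significant"]

    def test_empty_line_omitted_with_warning(self):
        tab = pd.DataFrame(
            {
                "line": ["Col-0", "ghost"],
                "n_group1": [50, 0],
                "n_group2": [58, 0],
            }
        )
        with pytest.warns(UserWarning):
            res = line_significance(tab, test="fisher")
        assert "ghost" not in set(res["line"])

    def test_missing_wild_type_raises(self):
        tab = pd.DataFrame({"line": ["a"], "n_group1": [5], "n_group2": [5]})
        with pytest.raises(ValueError):
            line_significance(tab, test="fisher", wild_type="Col-0")

    def test_anova_mode_on_long_format(self, rng):
        vals = []
        for line, mu in (("Col-0", 300.0), ("long", 420.0)):
            for _ in range(12):
                vals.append({"line": line, "value": rng.normal(mu, 25)})
        res = line_significance(pd.DataFrame(vals), test="anova")
        assert res.loc[0, "significant"]

    def test_null_simulation_controls_false_positives(self, rng):
        """200 null lines at wild-type survival: flagged fraction <= 0.10."""
        tab = [{"line": "Col-0", "n_group1": 70, "n_group2": 38}]
        for i in range(200):
            alive = int(rng.binomial(108, 0.65))
            tab.append({"line": f"n{i}", "n_group1": alive, "n_group2": 108 - alive})
        res = line_significance(pd.DataFrame(tab), test="fisher")
        assert res["significant"].mean() <= 0.10


class TestMultiTrait:
    def _records(self, rng, n_per_line=20):
        rows = []
        for line, (area_mu, hue) in {
            "big-green-1": (900, 0),
            "big-green-2": (880, 0),
            "small-yellow-1": (300, 1),
            "small-yellow-2": (320, 1),
        }.items():
            for _ in range(n_per_line):
                rows.append(
                    {
                        "line": line,
                        "area": rng.normal(area_mu, 40),
                        "perimeter": rng.normal(np.sqrt(area_mu) * 4, 5),
                        "circularity": rng.uniform(0.7, 0.9),
                        "compactness": rng.normal(8, 1),
                        "major_axis": rng.normal(np.sqrt(area_mu) * 1.2, 3),
                        "minor_axis": rng.normal(np.sqrt(area_mu), 3),
                        "eccentricity": rng.normal(1.2, 0.05),
                        "hisgreypeak": rng.normal(90 + 60 * hue, 5),
                    }
                )
        return pd.DataFrame(rows)

    FEATS = (
        "area",
        "perimeter",
        "circularity",
        "compactness",
        "major_axis",
        "minor_axis",
        "eccentricity",
        "hisgreypeak",
    )

    def test_density_rows_sum_to_one(self, rng):
        res = multitrait_profile_heatmap(self._records(rng), self.FEATS)
        assert np.allclose(res.density.sum(axis=1), 1.0, atol=1e-9)
        assert res.density.shape[1] == 5

    def test_phenotype_populations_cluster_adjacently(self, rng):
        res = multitrait_profile_heatmap(self._records(rng), self.FEATS)
        order = res.line_order
        big = {i for i, l in enumerate(order) if l.startswith("big")}
        assert big in ({0, 1}, {2, 3})

    def test_duplicated_line_gets_identical_density(self, rng):
        df = self._records(rng)
        dup = df[df["line"] == "big-green-1"].copy()
        dup["line"] = "copycat"
        res = multitrait_profile_heatmap(pd.concat([df, dup]), self.FEATS)
        a = res.density.loc["big-green-1"].to_numpy()
        b = res.density.loc["copycat"].to_numpy()
        assert np.allclose(a, b)

    def test_too_few_plants_raises(self, rng):
        with pytest.raises(ValueError):
            multitrait_profile_heatmap(self._records(rng).head(3), self.FEATS)

    def test_constant_feature_dropped_with_warning(self, rng):
        df = self._records(rng)
        df["circularity"] = 0.5
        with pytest.warns(UserWarning):
            res = multitrait_profile_heatmap(df, self.FEATS)
        assert "circularity" in res.dropped_features
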