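"""Entropy-based selectivity score, bootstrap, beta regression, effect sizes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stimselect as ss
from stimselect.selectivity import shannon_entropy, smithson_verkuilen


def epochs_frame(spans, retained=None):
    rows = []
    for i, (a, b) in enumerate(spans):
        rows.append({"label": i + 1, "mode": "TIS4", "on_start": a, "on_stop": b,
                     "off_start": b, "off_stop": b + 10})
    df = pd.DataFrame(rows)
    if retained is not None:
        df["retained"] = retained
    return df


class TestSyllableConfigTable:
    def test_pure_configuration(self):
        states = np.array([3] * 10 + [0] * 10)
        table = ss.syllable_config_table(states, epochs_frame([(0, 10), (10, 20)]))
        p = table.loc[1] / table.loc[1].sum()
        assert p[3] == 1.0 and p[0] == 0.0

    def test_even_split(self):
        states = np.array([0] * 5 + [1] * 5)
        table = ss.syllable_config_table(states, epochs_frame([(0, 10)]))
        np.testing.assert_allclose(table.loc[1] / table.loc[1].sum(), [0.5, 0.5])

    def test_gated_out_configuration_absent(self):
        states = np.zeros(20, dtype=int)
        table = ss.syllable_config_table(
            states, epochs_frame([(0, 10), (10, 20)], retained=[True, False])
        )
        assert list(table.index) == [1]

    def test_zero_on_frames_excluded_with_note(self):
        states = np.zeros(10, dtype=int)
        epochs = epochs_frame([(0, 10), (10, 10)])
        with pytest.warns(UserWarning, match="zero ON"):
            table = ss.syllable_config_table(states, epochs)
        assert table.attrs["excluded_zero_on"] == [2]

    def test_bout_counting_option(self):
        states = np.array([0, 0, 0, 1, 1, 0, 0, 1, 1, 1])
        table = ss.syllable_config_table(states, epochs_frame([(0, 10)]), by_bout=True)
        assert table.loc[1].tolist() == [2, 2]  # two bouts of each syllable


class TestSelectivityScore:
    def test_single_syllable_scores_one(self):
        table = pd.DataFrame({0: [10], 1: [0]}, index=[1])
        assert ss.selectivity_score(table, n_total=4)[1] == pytest.approx(1.0)

    def test_uniform_over_all_syllables_scores_zero(self):
        table = pd.DataFrame({j: [5] for j in range(6)}, index=[1])
        assert ss.selectivity_score(table, n_total=6)[1] == pytest.approx(0.0, abs=1e-12)

    def test_two_of_four_scores_half(self):
        table = pd.DataFrame({0: [5], 1: [5], 2: [0], 3: [0]}, index=[1])
        assert ss.selectivity_score(table, n_total=4)[1] == pytest.approx(
            1 - np.log(2) / np.log(4)
        )

    def test_single_total_syllable_warns_and_scores_one(self):
        table = pd.DataFrame({0: [10]}, index=[1])
        with pytest.warns(UserWarning, match="single syllable"):
            assert ss.selectivity_score(table, n_total=1)[1] == 1.0

    @settings(max_examples=50, deadline=None)
    @given(counts=st.lists(st.integers(1, 50), min_size=2, max_size=8))
    def test_base_invariance_and_relabeling(self, counts):
        table = pd.DataFrame({j: [c] for j, c in enumerate(counts)}, index=[1])
        n = len(counts)
        score = ss.selectivity_score(table, n_total=n)[1]
        # base-2 identity: 1 - H2/log2(N) equals 1 - H/ln(N)
        p = np.array(counts) / sum(counts)
        h2 = -(p * np.log2(p)).sum()
        assert score == pytest.approx(1 - h2 / np.log2(n), abs=1e-12)
        # permutation of syllable identities leaves the score unchanged
        shuffled = table[list(reversed(table.columns))]
        assert ss.selectivity_score(shuffled, n_total=n)[1] == pytest.approx(
            score, abs=1e-12
        )

    @settings(max_examples=50, deadline=None)
    @given(
        counts=st.lists(st.integers(1, 40), min_size=2, max_size=6),
        frac=st.floats(0.05, 0.5),
    )
    def test_spreading_mass_never_raises_score(self, counts, frac):
        p = np.array(counts, dtype=float)
        p /= p.sum()
        top = int(np.argmax(p))
        other = (top + 1) % len(p)
        if p[top] - frac * p[top] < p[other] + frac * p[top]:
            # only move mass while the donor stays dominant
            return
        q = p.copy()
        q[top] -= frac * p[top]
        q[other] += frac * p[top]
        n = len(p)
        s_p = 1 - shannon_entropy(p) / np.log(n)
        s_q = 1 - shannon_entropy(q) / np.log(n)
        assert s_q <= s_p + 1e-12


class TestBootstrap:
    def test_constant_scores_zero_width_ci(self):
        res = ss.bootstrap_means({"g": np.full(50, 0.7)}, seed=0)
        assert res["groups"]["g"]["mean"] == pytest.approx(0.7)
        lo, hi = res["groups"]["g"]["ci95"]
        assert lo == hi == pytest.approx(0.7)

    def test_same_seed_identical(self):
        scores = {"a": np.random.default_rng(0).beta(4, 2, 60)}
        r1 = ss.bootstrap_means(scores, seed=9)
        r2 = ss.bootstrap_means(scores, seed=9)
        assert r1 == r2

    def test_paper_scale_groups_have_disjoint_cis(self):
        """Beta-distributed groups with means 0.79 / 0.63 at the study's group
        sizes (676 vs 164) separate cleanly at m=100, B=1000."""
        rng = np.random.default_rng(12)
        phi = 8.0
        tis = rng.beta(0.7854 * phi, (1 - 0.7854) * phi, size=676)
        bip = rng.beta(0.6294 * phi, (1 - 0.6294) * phi, size=164)
        res = ss.bootstrap_means({"TIS": tis, "Biphasic": bip}, m=100, B=1000, seed=1)
        assert res["groups"]["TIS"]["mean"] > res["groups"]["Biphasic"]["mean"]
        assert res["ci_overlap"]["TIS|Biphasic"] is False

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ss.bootstrap_means({"g": np.ones(5)}, m=0)
        with pytest.raises(ValueError):
            ss.bootstrap_means({"g": np.array([])})


class TestBetaRegression:
    def test_matches_glmmtmb_reference_fixture(self):
        """Frozen oracle: the same fixture fitted with R glmmTMB
        (beta_family, logit link) gives intercept 0.408375631528 (SE
        0.0739418627878), group coefficient 0.844535715752 (SE
        0.113372095308), phi 24.3457423550, logLik 60.5333041953."""
        rng = np.random.default_rng(42)
        phi = 20.0
        ya = rng.beta(0.8 * phi, 0.2 * phi, size=30)
        yb = rng.beta(0.6 * phi, 0.4 * phi, size=30)
        df = pd.DataFrame({
            "selectivity": np.concatenate([ya, yb]),
            "stim_type": ["A"] * 30 + ["B"] * 30,
        })
        res = ss.beta_regression(df, reference={"stim_type": "B"})
        coef = res["coefficients"]
        assert coef.loc["intercept", "coef"] == pytest.approx(0.408375631528, abs=1e-4)
        assert coef.loc["intercept", "se"] == pytest.approx(0.0739418627878, abs=1e-4)
        assert coef.loc["stim_type[A]", "coef"] == pytest.approx(0.844535715752, abs=1e-4)
        assert coef.loc["stim_type[A]", "se"] == pytest.approx(0.113372095308, abs=1e-4)
        assert res["phi"] == pytest.approx(24.3457423550, rel=1e-4)
        assert res["loglik"] == pytest.approx(60.5333041953, abs=1e-4)

    def test_constant_scores_give_zero_effect(self):
        df = pd.DataFrame({
            "selectivity": np.full(40, 0.5),
            "stim_type": ["TIS"] * 20 + ["Biphasic"] * 20,
        })
        res = ss.beta_regression(df)
        assert res["coefficients"].loc["stim_type[TIS]", "coef"] == pytest.approx(
            0.0, abs=1e-6
        )

    def test_rank_deficient_design_rejected(self):
        df = pd.DataFrame({
            "selectivity": np.random.default_rng(0).beta(3, 2, 20),
            "stim_type": ["A"] * 20,  # single level: dummy column is absent
            "copy": ["A"] * 20,
        })
        # two identical constant predictors after encoding -> intercept only,
        # so force collinearity through a duplicated numeric column
        df["x1"] = np.arange(20.0) * 37 + 1  # > 12 levels: numeric passthrough
        df["x2"] = df["x1"]
        with pytest.raises(ValueError, match="rank"):
            ss.beta_regression(df, predictors=("x1", "x2"))

    def test_boundary_compression(self):
        y = np.array([0.0, 0.5, 1.0])
        out = smithson_verkuilen(y)
        assert (out > 0).all() and (out < 1).all()
        assert out[1] == pytest.approx(0.5)


class TestNonparametricEffects:
    def test_identical_groups_zero_effects(self):
        g = np.array([0.2, 0.4, 0.6, 0.8])
        res = ss.nonparametric_effects(g, g.copy())
        assert res["cohens_d"] == pytest.approx(0.0)
        assert res["cliffs_delta"] == pytest.approx(0.0)

    def test_complete_dominance_delta_one(self):
        assert ss.cliffs_delta([1.0, 1.0], [0.0, 0.0]) == 1.0

    def test_worked_pair_enumeration(self):
        # pairs of {3,4,5} x {1,2,3}: 8 wins, 0 losses, 1 tie -> 8/9
        assert ss.cliffs_delta([3, 4, 5], [1, 2, 3]) == pytest.approx(8 / 9)

    def test_cohens_d_pooled_convention(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([0.0, 1.0, 2.0])
        sp = np.sqrt((2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4)
        assert ss.cohens_d(a, b) == pytest.approx(1.0 / sp)

    def test_mann_whitney_direction(self):
        rng = np.random.default_rng(4)
        hi = rng.beta(8, 2, 50)
        lo = rng.beta(2, 8, 50)
        res = ss.nonparametric_effects(hi, lo)
        assert res["p"] < 1e-6
        assert res["cliffs_delta"] > 0.8

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            ss.nonparametric_effects([1.0], [2.0, 3.0])
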