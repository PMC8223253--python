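import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import oracle_holm
from scalphfo.stats import (
    align,
    align_and_rank,
    art_anova,
    art_diagnostic,
    describe,
    holm,
    paired_compare,
    posthoc_pairwise,
)


def make_mixed_table(
    rng, n=10, group_shift=0.0, interaction=0.0, states=("x", "y"), bands=("p", "q", "r")
):
    rows = []
    for g in ("A", "B"):
        for s in range(n):
            subj = f"{g}{s}"
            intercept = rng.normal(0, 1)
            for w1 in states:
                for w2 in bands:
                    y = intercept + rng.normal()
                    if g == "A":
                        y += group_shift
                        if w1 == states[0]:
                            y += interaction
                    rows.append(
                        dict(subject=subj, group=g, state=w1, band=w2, avg_energy=y)
                    )
    return pd.DataFrame(rows)


class TestHolm:
    def test_hand_example(self):
        np.testing.assert_allclose(holm([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm([0.2])[0] == pytest.approx(0.2)

    def test_all_ones(self):
        np.testing.assert_array_equal(holm([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            holm([0.5, 1.5])

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 12))
            adj = holm(p)
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= 1.0)
            order = np.argsort(p, kind="stable")
            assert np.all(np.diff(adj[order]) >= -1e-15)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=15))
    @settings(max_examples=100, deadline=None)
    def test_matches_stepdown_oracle(self, pvals):
        np.testing.assert_array_equal(holm(pvals), oracle_holm(pvals))


class TestDescribe:
    def test_one_to_nine(self):
        assert describe(range(1, 10)) == (5.0, 3.0, 7.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            describe([])


class TestPairedCompare:
    def test_identical_series(self):
        res = paired_compare([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.test == "paired_t"
        assert res.statistic == 0.0
        assert res.p == 1.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_compare([1, 2, 3], [1, 2])

    def test_gaussian_shift_uses_t(self):
        rng = np.random.default_rng(2)
        chose_t, pvals = 0, []
        for _ in range(100):
            before = rng.normal(0, 1, size=16)
            after = before + 1 + rng.normal(0, 1, size=16)
            res = paired_compare(before, after)
            chose_t += res.test == "paired_t"
            pvals.append(res.p)
        assert chose_t >= 90
        assert np.mean(pvals) < 0.01

    def test_skewed_differences_use_wilcoxon(self):
        rng = np.random.default_rng(3)
        picked = 0
        for _ in range(50):
            before = rng.normal(size=30)
            after = before + rng.exponential(1.0, size=30) ** 3
            if paired_compare(before, after).test == "wilcoxon":
                picked += 1
        assert picked >= 40


class TestAlignment:
    def test_toy_2x2_main_effect(self):
        # cells A1B1..A2B2 = 1,2,3,4: hand cell-means decomposition gives
        # A-effect -1,-1,+1,+1 and exactly zero interaction
        toy = pd.DataFrame(
            dict(
                subject=list("abcd"),
                A=["a1", "a1", "a2", "a2"],
                B=["b1", "b2", "b1", "b2"],
                avg_energy=[1.0, 2.0, 3.0, 4.0],
            )
        )
        np.testing.assert_allclose(align(toy, ("A",), ("A", "B")), [-1, -1, 1, 1])
        np.testing.assert_allclose(align(toy, ("A", "B"), ("A", "B")), [0, 0, 0, 0], atol=1e-12)

    def test_pure_main_effect_leaves_flat_interaction_column(self, rng):
        tab = make_mixed_table(rng, n=8, group_shift=5.0)
        aligned = align(tab, ("group", "state"), ("group", "state", "band"))
        cell_means = (
            pd.DataFrame(dict(g=tab.group, s=tab.state, y=aligned))
            .groupby(["g", "s"])["y"]
            .mean()
        )
        # interaction-aligned column: per-cell means differ only through the
        # group x state estimate, which is ~0 under a pure main effect
        assert np.abs(cell_means.to_numpy()).max() < 0.5

    def test_constant_responses_rank_equal(self, rng):
        tab = make_mixed_table(rng, n=4)
        tab["avg_energy"] = 7.0
        aligned, ranked = align_and_rank(tab, ("group",), ("group", "state", "band"))
        np.testing.assert_allclose(aligned, 0.0, atol=1e-12)
        assert len(set(ranked)) == 1

    def test_unknown_effect_rejected(self, rng):
        tab = make_mixed_table(rng, n=3)
        with pytest.raises(ValueError):
            align(tab, ("zzz",), ("group", "state"))


class TestARTAnova:
    def test_result_shape(self, rng):
        tab = make_mixed_table(rng, n=6)
        res = art_anova(tab, between=("group",), within=("state", "band"))
        assert len(res.effects) == 7  # 3 mains + 3 two-way + 1 three-way
        assert (res.effects["p_holm"] >= res.effects["p"] - 1e-12).all()
        assert (res.effects["df1"] >= 1).all() and (res.effects["df2"] >= 1).all()

    def test_detects_strong_interaction(self, rng):
        tab = make_mixed_table(rng, n=20, interaction=2.0)
        res = art_anova(tab, between=("group",), within=("state", "band"))
        assert res.effect_row(("group", "state"))["p"] < 0.001

    def test_diagnostic_single_effect_design(self, rng):
        tab = make_mixed_table(rng, n=10, group_shift=3.0)
        res = art_anova(tab, between=("group",), within=("state", "band"), run_diagnostic=True)
        assert max(res.diagnostics.values()) < 0.1

    def test_art_diagnostic_recompute(self, rng):
        tab = make_mixed_table(rng, n=6, group_shift=2.0)
        res = art_anova(tab, between=("group",), within=("state", "band"))
        diag = art_diagnostic(res)
        assert max(diag.values()) < 0.1

    def test_rank_invariance_under_affine_transform(self, rng):
        # alignment is linear in the responses, so positive affine maps leave
        # every aligned rank (hence every F) exactly unchanged
        tab = make_mixed_table(rng, n=8, interaction=1.0)
        res1 = art_anova(tab, between=("group",), within=("state", "band"))
        for a, b in ((3.0, 0.0), (0.5, 7.0), (10.0, -2.0)):
            tab2 = tab.copy()
            tab2["avg_energy"] = a * tab2["avg_energy"] + b
            res2 = art_anova(tab2, between=("group",), within=("state", "band"))
            np.testing.assert_allclose(
                res1.effects["F"].to_numpy(), res2.effects["F"].to_numpy(), rtol=1e-9
            )

    def test_stability_under_monotone_transform(self, rng):
        # nonlinear monotone maps perturb the aligned values, but the rank
        # step keeps the F statistics close (ART is not exactly invariant)
        tab = make_mixed_table(rng, n=12, interaction=1.5)
        tab["avg_energy"] += 10  # keep positive
        res1 = art_anova(tab, between=("group",), within=("state", "band"))
        p1 = res1.effect_row(("group", "state"))["p"]
        for transform in (np.log, np.sqrt):
            tab2 = tab.copy()
            tab2["avg_energy"] = transform(tab2["avg_energy"].to_numpy())
            res2 = art_anova(tab2, between=("group",), within=("state", "band"))
            p2 = res2.effect_row(("group", "state"))["p"]
            assert (p1 < 0.05) == (p2 < 0.05)

    def test_between_factor_varying_within_subject_rejected(self, rng):
        tab = make_mixed_table(rng, n=4)
        tab.loc[0, "group"] = "B"
        with pytest.raises(ValueError):
            art_anova(tab, between=("group",), within=("state", "band"))

    def test_two_level_between_close_to_mannwhitney(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(8)
        diffs = []
        for _ in range(20):
            rows = []
            for g in ("A", "B"):
                for s in range(30):
                    y = rng.normal(0.5 if g == "A" else 0.0, 1)
                    rows.append(dict(subject=f"{g}{s}", group=g, avg_energy=y))
            tab = pd.DataFrame(rows)
            res = art_anova(tab, between=("group",), within=())
            p_art = res.effect_row(("group",))["p"]
            p_mw = mannwhitneyu(
                tab.loc[tab.group == "A", "avg_energy"],
                tab.loc[tab.group == "B", "avg_energy"],
            ).pvalue
            diffs.append(abs(p_art - p_mw))
        assert np.median(diffs) < 0.02

    def test_empty_cell_named(self, rng):
        tab = make_mixed_table(rng, n=4)
        tab = tab[~((tab.group == "A") & (tab.state == "x") & (tab.band == "p"))]
        with pytest.raises(ValueError, match="empty design cell"):
            art_anova(tab, between=("group",), within=("state", "band"))


class TestPosthoc:
    def test_contrast_count(self, rng):
        tab = make_mixed_table(rng, n=6)
        res = art_anova(tab, between=("group",), within=("state", "band"))
        con = posthoc_pairwise(res, ("state", "band"))
        assert len(con) == 6 * 5 // 2

    def test_unknown_cells_rejected(self, rng):
        tab = make_mixed_table(rng, n=6)
        res = art_anova(tab, between=("group",), within=("state", "band"))
        with pytest.raises(ValueError):
            posthoc_pairwise(res, ("state",), cells=["nope"])

    def test_within_contrast_detects_direction(self, rng):
        tab = make_mixed_table(rng, n=20)
        tab.loc[tab.state == "x", "avg_energy"] += 2.0
        res = art_anova(tab, between=("group",), within=("state", "band"))
        con = posthoc_pairwise(res, ("state",))
        row = con.iloc[0]
        assert row["p_holm"] < 0.01
        # estimate is mean_rank(cell_a) - mean_rank(cell_b) with cells sorted
        sign = 1 if row["cell_a"] == "x" else -1
        assert sign * row["estimate"] > 0

    def test_null_familywise_error(self):
        rng = np.random.default_rng(12)
        any_reject = 0
        n_rep = 60
        for _ in range(n_rep):
            tab = make_mixed_table(rng, n=8)
            res = art_anova(tab, between=("group",), within=("state", "band"))
            con = posthoc_pairwise(res, ("state", "band"))
            any_reject += (con["p_holm"] < 0.05).any()
        # FWER <= 0.05; allow binomial slack at n=60
        assert any_reject / n_rep <= 0.12
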