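"""Nonparametric tests: exact enumerations, Holm step-down, ART split-plot."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cuticleflex import stats


def _wilcoxon_exact_p_enumeration(diffs):
    """Independent oracle: two-sided exact p over all 2^n sign patterns."""
    d = np.asarray(diffs, float)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1
    w_obs = ranks[d > 0].sum()
    n = len(d)
    total = ranks.sum()
    w_all = []
    for signs in itertools.product([0, 1], repeat=n):
        w_all.append(np.sum(ranks * np.array(signs)))
    w_all = np.array(w_all)
    lo, hi = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
    return float(np.mean((w_all <= lo) | (w_all >= hi)))


class TestWilcoxonSignedRank:
    def test_all_positive_n9_exact(self):
        # n = 9 with all differences positive: W = 45 and the one-sided
        # extreme doubles to 2 / 2^9 = 0.00390625
        paired = stats.PairedSamples(
            tuple(2 * k for k in range(1, 10)), tuple(range(1, 10))
        )
        w, p = stats.wilcoxon_signed_rank(paired)
        assert w == 45.0
        assert p == pytest.approx(0.00390625, abs=1e-12)
        assert p < 0.01

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.2, 1.0, 9)
        d = d[d != 0]
        paired = stats.PairedSamples(tuple(d), tuple(np.zeros_like(d)))
        _, p = stats.wilcoxon_signed_rank(paired)
        assert p == pytest.approx(_wilcoxon_exact_p_enumeration(d), abs=1e-12)

    def test_antisymmetric_two_pairs_nonsignificant(self):
        paired = stats.PairedSamples((1.0, -1.0), (0.0, 0.0))
        _, p = stats.wilcoxon_signed_rank(paired)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance_of_p(self):
        d = np.array([0.3, -0.1, 0.5, 0.7, -0.2, 0.4, 0.9, 0.6, -0.8])
        p1 = stats.wilcoxon_signed_rank(
            stats.PairedSamples(tuple(d), tuple(np.zeros(9)))
        )[1]
        p2 = stats.wilcoxon_signed_rank(
            stats.PairedSamples(tuple(17.3 * d), tuple(np.zeros(9)))
        )[1]
        assert p1 == p2

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            stats.wilcoxon_signed_rank(stats.PairedSamples((1.0, 2.0), (1.0, 2.0)))

    def test_type_one_error_controlled_under_null(self):
        # 1e4 simulated null datasets (n=9): exact test rejects at most 5%
        rng = np.random.default_rng(42)
        d = rng.standard_normal((10_000, 9))
        ranks = np.argsort(np.argsort(np.abs(d), axis=1), axis=1) + 1
        w = np.sum(np.where(d > 0, ranks, 0), axis=1)
        # exact null distribution of W+ for n=9
        w_all = np.array(
            [np.sum(np.arange(1, 10) * np.array(s))
             for s in itertools.product([0, 1], repeat=9)]
        )
        lo = np.minimum(w, 45 - w)
        hi = np.maximum(w, 45 - w)
        p = np.array(
            [np.mean((w_all <= a) | (w_all >= b)) for a, b in zip(lo, hi)]
        )
        assert np.mean(p <= 0.05) <= 0.05 + 0.01


class TestMannWhitneyHolm:
    def test_complete_separation_exact(self):
        res = stats.mann_whitney_holm([([1, 2, 3, 4], [5, 6, 7, 8, 9])])
        assert res[0]["U"] == 0.0
        # 2 extreme orderings out of C(9,4) = 126
        assert res[0]["p_raw"] == pytest.approx(2.0 / 126.0, abs=1e-9)

    def test_identical_groups_nonsignificant(self):
        res = stats.mann_whitney_holm([([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])])
        assert res[0]["p_raw"] > 0.95

    def test_holm_step_down_worked_example(self):
        adj = stats.holm_adjust([0.01, 0.04])
        assert adj[0] == pytest.approx(0.02)
        assert adj[1] == pytest.approx(0.04)

    def test_family_adjustment_applied(self):
        res = stats.mann_whitney_holm(
            [
                ("a", [1, 2, 3, 4], [5, 6, 7, 8]),
                ("b", [1, 2, 3, 4], [4.5, 5.5, 6.5, 7.5]),
            ]
        )
        assert all(r["p_holm"] >= r["p_raw"] for r in res)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.mann_whitney_holm([([1.0], [1.0, 2.0])])


def _design(n_per_mode=4, layer_shift=0.0, mode_shift=0.0, sd=1.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    subj = 0
    for mode in ("compression", "tension"):
        for _ in range(n_per_mode):
            base = rng.normal(0, sd)
            for layer in ("exo", "endo"):
                val = base + rng.normal(0, sd)
                if layer == "endo":
                    val += layer_shift
                if mode == "tension":
                    val += mode_shift
                rows.append(dict(subject=f"s{subj}", mode=mode, layer=layer,
                                 value=val))
            subj += 1
    return pd.DataFrame(rows)


class TestArtMixedAnova:
    def test_detects_pure_layer_effect(self):
        df = _design(layer_shift=3.0, mode_shift=0.0, seed=3)
        res = stats.art_mixed_anova(df)
        assert res["layer"]["p"] < 0.05
        assert res["mode"]["p"] > 0.05

    def test_constant_data_degenerate(self):
        df = _design(seed=1)
        df["value"] = 5.0
        res = stats.art_mixed_anova(df)
        for effect in ("mode", "layer", "interaction"):
            assert res[effect]["degenerate"] or not np.isfinite(res[effect]["F"])

    def test_mode_relabelling_invariance(self):
        df = _design(layer_shift=1.0, mode_shift=0.5, seed=7)
        res1 = stats.art_mixed_anova(df, posthoc=False)
        swapped = df.assign(
            mode=df["mode"].map({"compression": "tension", "tension": "compression"})
        )
        res2 = stats.art_mixed_anova(swapped, posthoc=False)
        for effect in ("mode", "layer", "interaction"):
            assert res1[effect]["p"] == pytest.approx(res2[effect]["p"], rel=1e-12)

    def test_incomplete_design_rejected(self):
        df = _design(seed=2).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            stats.art_mixed_anova(df)

    def test_posthoc_pairwise_within_mode(self):
        df = _design(n_per_mode=6, layer_shift=3.0, seed=9)
        res = stats.art_mixed_anova(df)
        ph = res["posthoc_layer_within_mode"]
        assert {r["mode"] for r in ph} == {"compression", "tension"}


class TestStars:
    @pytest.mark.parametrize(
        "p,mark",
        [(0.2, "ns"), (0.04, "*"), (0.009, "**"), (0.0009, "***"),
         (float("nan"), "n/a")],
    )
    def test_thresholds(self, p, mark):
        assert stats.significance_stars(p) == mark
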