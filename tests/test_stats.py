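"""Wilcoxon signed-rank test, multiplicity correction, session comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from fcgraph import (
    SyntheticConfig,
    compare_sessions,
    compute_metric_table,
    consistent_direction,
    correct_multiple,
    correlation_matrix,
    generate_dataset,
    mann_whitney_groups,
    node_strength,
    threshold_binarize,
    wilcoxon_signed_rank,
)


class TestWilcoxon:
    def test_unit_shift_exact_p(self):
        x = np.arange(12.0)
        res = wilcoxon_signed_rank(x, x + 1)
        assert res.method == "exact"
        assert res.p == pytest.approx(2 / 2**12)
        assert res.n_pairs == 12

    def test_identical_samples_flagged_undefined(self):
        x = np.arange(8.0)
        res = wilcoxon_signed_rank(x, x)
        assert res.undefined and np.isnan(res.p)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(20):
            x = rng.standard_normal(15)
            y = x + rng.standard_normal(15)
            mine = wilcoxon_signed_rank(x, y)
            ref = sps.wilcoxon(y, x, alternative="two-sided", method="exact",
                               zero_method="wilcox")
            assert mine.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_matches_scipy_approx_large_n(self, rng):
        x = rng.standard_normal(60)
        y = x + 0.3 + rng.standard_normal(60)
        mine = wilcoxon_signed_rank(x, y)
        ref = sps.wilcoxon(y, x, alternative="two-sided", method="approx",
                           correction=True, zero_method="wilcox")
        assert mine.method == "approx"
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_null_p_values_uniform(self, rng):
        # KS calibration under the null of symmetric noise around x
        ps = []
        for _ in range(300):
            x = rng.standard_normal(20)
            y = x + rng.standard_normal(20)
            ps.append(wilcoxon_signed_rank(x, y).p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="pairs"):
            wilcoxon_signed_rank(np.arange(3.0), np.arange(3.0) + 1)

    def test_mostly_tied_pairs_flagged_undefined(self):
        x = np.arange(8.0)
        y = x.copy()
        y[:3] += 1.0  # only 3 informative pairs remain
        res = wilcoxon_signed_rank(x, y)
        assert res.undefined and res.n_pairs == 3


class TestCorrectMultiple:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(correct_multiple([0.03], "bh"), [0.03])
        np.testing.assert_allclose(correct_multiple([0.03], "bonferroni"), [0.03])

    def test_bonferroni_multiplies(self):
        np.testing.assert_allclose(
            correct_multiple([0.01, 0.02, 0.03, 0.04], "bonferroni"),
            [0.04, 0.08, 0.12, 0.16],
        )

    def test_bh_step_up(self):
        np.testing.assert_allclose(
            correct_multiple([0.01, 0.02, 0.03, 0.04], "bh"),
            [0.04, 0.04, 0.04, 0.04],
        )

    def test_bonferroni_dominates_bh(self, rng):
        p = rng.uniform(0.001, 1, 50)
        assert np.all(
            correct_multiple(p, "bonferroni") >= correct_multiple(p, "bh") - 1e-12
        )

    def test_capped_at_one(self):
        assert np.all(correct_multiple([0.9, 0.95], "bonferroni") <= 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            correct_multiple([], "bh")


def _long_tables(post_delta, seed=101, n_subjects=8, thresholds=(0.3, 0.4)):
    cfg = SyntheticConfig(
        n_subjects=n_subjects, n_regions=24, n_timepoints=256,
        module_sizes=(12, 12), r_within=0.35, r_between=0.1,
        post_delta=post_delta, seed=seed,
    )
    ds = generate_dataset(cfg)
    frames = {"pre": [], "post": []}
    for (subj, ses), ts in ds.series.items():
        cm = correlation_matrix(ts)
        s = node_strength(cm)[0]
        for r in thresholds:
            g = threshold_binarize(cm, r)
            frames[ses].append(
                compute_metric_table(g, subj, ses, strength=s).to_long()
            )
    return (
        pd.concat(frames["pre"], ignore_index=True),
        pd.concat(frames["post"], ignore_index=True),
    )


class TestCompareSessions:
    def test_identical_tables_flagged_not_significant(self):
        pre, _ = _long_tables(0.0)
        res = compare_sessions(pre, pre.assign(session="post"), scope="global")
        assert res["undefined"].all()

    def test_planted_increase_recovered(self):
        pre, post = _long_tables(+0.15)
        res = compare_sessions(pre, post, scope="global")
        strength = res[res["measure"] == "strength"]
        assert (strength["direction"] == "increase").all()
        assert consistent_direction(res, "strength") == "increase"

    def test_planted_decrease_recovered(self):
        pre, post = _long_tables(-0.15)
        res = compare_sessions(pre, post, scope="global")
        for measure in ("strength", "degree"):
            sub = res[res["measure"] == measure]
            assert (sub["direction"] == "decrease").all()

    def test_node_scope_corrects_across_nodes(self):
        pre, post = _long_tables(+0.15)
        res = compare_sessions(pre, post, scope="node")
        one = res[(res["measure"] == "strength") & (res["threshold"] == 0.3)]
        assert len(one) == 24
        defined = res[res["p_raw"].notna()]
        assert np.all(defined["p_corrected"] >= defined["p_raw"] - 1e-12)

    def test_regional_means_pairing(self):
        pre, post = _long_tables(+0.15)
        res = compare_sessions(pre, post, scope="global", pairing="regions")
        strength = res[res["measure"] == "strength"]
        assert (strength["n_pairs"] <= 24).all()
        assert (strength["direction"] == "increase").all()

    def test_subject_mismatch_rejected(self):
        pre, post = _long_tables(0.1)
        with pytest.raises(ValueError, match="subject"):
            compare_sessions(pre, post[post["subject"] != "sub-1"])

    def test_power_monotone_in_effect_size(self):
        ps = []
        for delta in (0.0, 0.1, 0.2):
            pre, post = _long_tables(delta, seed=55, thresholds=(0.3,))
            res = compare_sessions(pre, post, scope="global")
            row = res[(res["measure"] == "strength")]
            ps.append(float(row["p_raw"].iloc[0]) if not row["undefined"].iloc[0] else 1.0)
        assert ps[2] < ps[0] and ps[1] < ps[0]


class TestBetweenGroups:
    def test_rank_sum_with_group_correction(self, rng):
        x = rng.standard_normal(12)
        y = rng.standard_normal(12) + 3.0
        _, p1 = mann_whitney_groups(x, y, n_groups=1)
        _, p4 = mann_whitney_groups(x, y, n_groups=4)
        assert p4 == pytest.approx(min(1.0, 4 * p1))
        assert p1 < 0.01
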