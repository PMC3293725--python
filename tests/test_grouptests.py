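import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mircontext import Assay, ExperimentSet, Platform, Sample, SmallRNA
from mircontext.features import FeatureBins
from mircontext.grouptests import (
    SubgroupTestResult,
    benjamini_hochberg,
    characteristic_test,
    competition_test,
    run_feature_scan,
    sample_level_score,
    sample_level_scores,
    subgroup_downreg_test,
    trend_correlation,
    trend_counts,
)
from mircontext.seed import TargetAssignment


class TestSubgroupDownregTest:
    def test_exact_minimal_ranksum(self):
        # rank-sum 6 is the single most extreme of C(6,3)=20 arrangements
        assert subgroup_downreg_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.05)

    def test_identical_groups(self):
        p = subgroup_downreg_test([1.0, 2.0, 3.5], [1.5, 2.5, 3.0])
        assert p >= 0.35

    def test_opposite_tail(self):
        assert subgroup_downreg_test([4, 5, 6], [1, 2, 3]) >= 0.95

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            subgroup_downreg_test([], [1.0])

    def test_ks_direction(self, rng):
        shifted = rng.normal(-1.0, 1.0, 80)
        ref = rng.normal(0.0, 1.0, 80)
        assert subgroup_downreg_test(shifted, ref, "ks") < 1e-4
        assert subgroup_downreg_test(ref, shifted, "ks") > 0.5

    def test_unknown_method_errors(self):
        with pytest.raises(ValueError, match="method"):
            subgroup_downreg_test([1.0], [2.0], "ttest")


@settings(max_examples=60, deadline=None)
@given(
    st.lists(st.integers(0, 200), min_size=1, max_size=12),
    st.lists(st.integers(0, 200), min_size=1, max_size=12),
)
def test_wilcoxon_symmetry(a, b):
    pg, pl = characteristic_test(a, b)
    pg2, pl2 = characteristic_test(b, a)
    assert pg == pytest.approx(pl2, rel=1e-10)
    assert pl == pytest.approx(pg2, rel=1e-10)


class TestSampleLevelScore:
    def test_half_significant(self):
        assert sample_level_score([0.01, 0.2, 0.04, 0.8]) == 0.5

    def test_none_significant(self):
        assert sample_level_score([0.5] * 6) == 0.0

    def test_seventy_of_140(self):
        ps = [0.01] * 70 + [0.5] * 70
        assert sample_level_score(ps) == 0.5

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="empty"):
            sample_level_score([])


def _res(exp_id, feature, sub, p, sample_id=None):
    return SubgroupTestResult(exp_id, feature, sub, "wilcoxon", p, 5, 5, sample_id)


class TestTrendCounts:
    def test_single_significant_subgroup(self):
        results = [_res("e1", "length", "Short", 0.01), _res("e1", "length", "Long", 0.4)]
        counts = trend_counts(results, {})
        by_sub = {c.subgroup: c for c in counts}
        assert by_sub["Short"].expr_count == 1
        assert by_sub["Long"].expr_count == 0

    def test_impossible_threshold(self):
        results = [_res("e1", "length", "Short", 0.01)]
        scores = {("e1", "length", "Short"): 1.0}
        counts = trend_counts(results, scores, score_threshold=1.1)
        assert all(c.smpl_count == 0 for c in counts)

    def test_strict_threshold_at_half(self):
        results = [_res("e1", "length", "Short", 0.5)]
        scores = {("e1", "length", "Short"): 0.5}
        (c,) = trend_counts(results, scores, score_threshold=0.5)
        assert c.smpl_count == 0  # strictly greater than required


class TestTrendCorrelation:
    def test_perfectly_proportional(self):
        r, p = trend_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)

    def test_formula_matches_t_distribution_oracle(self):
        from scipy import stats

        x = [0.0, 1, 7, 6, 5]
        y = [0.0, 0, 3, 3, 0]
        r, p = trend_correlation(x, y)
        rr = np.corrcoef(x, y)[0, 1]
        t = rr * math.sqrt(3) / math.sqrt(1 - rr**2)
        assert r == pytest.approx(rr)
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 3))

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            trend_correlation([1, 1, 1], [1, 2, 3])

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match=">= 3"):
            trend_correlation([1, 2], [3, 4])


def _toy_experiment(rng, n_genes=400, planted_group="MedShort", shift=-0.4,
                    assay=Assay.TRANSFECTION, endo_frac=0.0):
    """One-sample experiment where only genes in ``planted_group`` are
    shifted down; every gene is an exogenous target."""
    groups = ["VeryLong", "Long", "MedLong", "MedShort", "Short"]
    gene_ids = [f"g{i}" for i in range(n_genes)]
    features = {}
    values = {}
    assignments = {}
    for i, g in enumerate(gene_ids):
        grp = groups[i % len(groups)]
        features[g] = FeatureBins(gene_id=g, length_group=grp)
        v = rng.normal(0, 0.1)
        if grp == planted_group:
            v += shift
        values[g] = float(v)
        n_endo = 1 if rng.random() < endo_frac else 0
        assignments[g] = TargetAssignment(g, "x", n_sites=1, n_endo_sites=n_endo)
    exp = ExperimentSet(
        "toy", Platform.MICROARRAY, assay,
        [Sample("s1", SmallRNA("x", "ACGUACGU"), log_ratios=values)],
    )
    return exp, {"s1": assignments}, features


class TestRunFeatureScan:
    def test_planted_subgroup_has_smallest_p(self, rng):
        exp, assignments, features = _toy_experiment(rng)
        results = run_feature_scan(exp, assignments, features, "length")
        ps = {r.subgroup: r.p_value for r in results}
        assert min(ps, key=lambda s: ps[s]) == "MedShort"
        assert ps["MedShort"] < 1e-6

    def test_single_sample_scope_equivalence(self, rng):
        exp, assignments, features = _toy_experiment(rng)
        exp_scope = run_feature_scan(exp, assignments, features, "length")
        smp_scope = run_feature_scan(
            exp, assignments, features, "length", scope="per_sample"
        )
        assert [(r.subgroup, r.p_value) for r in exp_scope] == [
            (r.subgroup, r.p_value) for r in smp_scope
        ]

    def test_subgroup_without_targets_reported_absent(self, rng):
        exp, assignments, features = _toy_experiment(rng)
        for g, ta in assignments["s1"].items():
            if features[g].length_group == "VeryLong":
                ta.n_sites = 0
        results = run_feature_scan(exp, assignments, features, "length")
        by_sub = {r.subgroup: r for r in results}
        assert by_sub["VeryLong"].p_value is None
        assert by_sub["VeryLong"].n_in == 0

    def test_missing_feature_bins_error(self, rng):
        exp, assignments, features = _toy_experiment(rng)
        del features["g3"]
        with pytest.raises(ValueError, match="g3"):
            run_feature_scan(exp, assignments, features, "length")

    def test_neg_log2_p_monotone(self):
        rs = [_res("e", "length", "a", p) for p in (0.001, 0.01, 0.5, 1.0)]
        logs = [r.neg_log2_p for r in rs]
        assert logs == sorted(logs, reverse=True)


class TestCompetitionTest:
    def test_inhibition_rejected(self, rng):
        exp, assignments, features = _toy_experiment(rng, assay=Assay.INHIBITION)
        with pytest.raises(ValueError, match="transfection"):
            competition_test(exp, assignments, features, "length")

    def test_planted_competition_detected(self, rng):
        exp, assignments, features = _toy_experiment(
            rng, planted_group="nothing", shift=0.0, endo_frac=0.5
        )
        # up-shift endogenous targets: T-Endo become more down-regulated
        s = exp.samples[0]
        for g, ta in assignments["s1"].items():
            if ta.is_endo_target:
                s.log_ratios[g] += 0.3
        results = competition_test(exp, assignments, features, "length")
        assert all(r.p_value < 0.01 for r in results if r.p_value is not None)

    def test_empty_side_absent(self, rng):
        exp, assignments, features = _toy_experiment(rng, endo_frac=0.0)
        results = competition_test(exp, assignments, features, "length")
        assert all(r.p_value is None for r in results)  # no T+Endo genes anywhere


class TestCharacteristicTest:
    def test_separated_groups(self):
        pg, pl = characteristic_test([4, 5, 6], [1, 2, 3])
        assert pg == pytest.approx(0.05)
        assert pl > 0.9

    def test_identical_groups(self):
        pg, pl = characteristic_test(list(range(20)), list(range(20)))
        assert 0.3 < pg < 0.7
        assert 0.3 < pl < 0.7

    def test_empty_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            characteristic_test([], [1.0])


class TestSampleLevelScores:
    def test_grouping(self):
        results = [
            _res("e1", "length", "Short", 0.01, "s1"),
            _res("e1", "length", "Short", 0.20, "s2"),
            _res("e1", "length", "Short", None, "s3"),
        ]
        scores = sample_level_scores(results)
        assert scores[("e1", "length", "Short")] == 0.5


def test_benjamini_hochberg_monotone_and_bounded():
    ps = [0.001, 0.01, 0.02, 0.5, 0.9]
    qs = benjamini_hochberg(ps)
    assert all(0 <= q <= 1 for q in qs)
    assert all(q >= p for p, q in zip(ps, qs))
    order = np.argsort(ps)
    assert all(qs[order[i]] <= qs[order[i + 1]] for i in range(len(ps) - 1))
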