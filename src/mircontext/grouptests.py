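"""Non-parametric subgroup testing of log-ratio knockdown.

Implements the one-sided down-regulation tests per feature subgroup (each
subgroup of predicted target genes against all remaining target genes),
per-sample variants with sample-level scores, experiment-vs-sample trend
counts and their Pearson correlation, the endogenous-competition test
(T−Endo vs T+Endo within subgroups), and two-sided feature-characteristic
tests for labelled gene classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .datamodel import Assay, ExperimentSet
from .features import FEATURE_SUBGROUPS, FeatureBins
from .seed import TargetAssignment

EXACT_N_MAX = 25  # exact Wilcoxon enumeration limit per group


@dataclass
class SubgroupTestResult:
    experiment_id: str
    feature: str
    subgroup: str
    method: str
    p_value: Optional[float]
    n_in: int
    n_out: int
    sample_id: Optional[str] = None

    @property
    def neg_log2_p(self) -> Optional[float]:
        if self.p_value is None:
            return None
        return -math.log2(self.p_value)


@dataclass
class TrendCounts:
    feature: str
    subgroup: str
    expr_count: int
    smpl_count: int


def subgroup_downreg_test(
    values_in: Sequence[float], values_out: Sequence[float], method: str = "wilcoxon"
) -> float:
    """One-sided p-value for "``values_in`` stochastically smaller than
    ``values_out``" (more negative log-ratios = more down-regulated).

    ``wilcoxon`` is the rank-sum test — exact enumeration when both groups
    have ≤ 25 values and no ties, normal approximation with continuity and
    tie correction otherwise. ``ks`` is the one-sided Kolmogorov-Smirnov
    test with the alternative that the CDF of ``values_in`` lies above that
    of ``values_out``.
    """
    a = np.asarray(values_in, dtype=float)
    b = np.asarray(values_out, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "wilcoxon":
        pooled = np.concatenate([a, b])
        exact = (
            a.size <= EXACT_N_MAX
            and b.size <= EXACT_N_MAX
            and np.unique(pooled).size == pooled.size
        )
        res = stats.mannwhitneyu(
            a, b, alternative="less", method="exact" if exact else "asymptotic"
        )
        return float(res.pvalue)
    if method == "ks":
        return float(stats.ks_2samp(a, b, alternative="greater").pvalue)
    raise ValueError(f"unknown method {method!r}")


def _pooled_target_values(
    exp: ExperimentSet,
    assignments: Dict[str, Dict[str, TargetAssignment]],
    samples=None,
) -> List[Tuple[str, float]]:
    """(gene, log-ratio) pairs for predicted exogenous targets, pooled over
    samples; a gene contributes once per sample where it is measured."""
    pairs = []
    for s in samples if samples is not None else exp.samples:
        asg = assignments[s.sample_id]
        for gene, lr in s.log_ratios.items():
            ta = asg.get(gene)
            if ta is not None and ta.is_exo_target:
                pairs.append((gene, lr))
    return pairs


def run_feature_scan(
    exp: ExperimentSet,
    assignments: Dict[str, Dict[str, TargetAssignment]],
    features: Dict[str, FeatureBins],
    feature: str,
    method: str = "wilcoxon",
    scope: str = "experiment",
) -> List[SubgroupTestResult]:
    """Test each subgroup of a feature for stronger down-regulation than the
    rest of the predicted target genes.

    ``assignments`` maps sample_id → gene_id → :class:`TargetAssignment`.
    ``scope='experiment'`` pools (gene, sample) pairs across the experiment;
    ``scope='per_sample'`` emits one result per subgroup per sample.
    Subgroups with no target genes get ``p_value=None``; a missing feature
    bin for a tested gene is an error.
    """
    if feature not in FEATURE_SUBGROUPS:
        raise ValueError(f"unknown feature {feature!r}")
    if scope not in ("experiment", "per_sample"):
        raise ValueError(f"unknown scope {scope!r}")
    sample_sets = (
        [None] if scope == "experiment" else [[s] for s in exp.samples]
    )
    results: List[SubgroupTestResult] = []
    for subset in sample_sets:
        pairs = _pooled_target_values(exp, assignments, subset)
        labelled: List[Tuple[object, float]] = []
        for gene, lr in pairs:
            if gene not in features:
                raise ValueError(f"no feature bins for tested gene {gene!r}")
            labelled.append((features[gene].value(feature), lr))
        sample_id = subset[0].sample_id if subset is not None else None
        for sub in FEATURE_SUBGROUPS[feature]:
            vin = [lr for lab, lr in labelled if lab == sub]
            vout = [lr for lab, lr in labelled if lab != sub]
            p = (
                subgroup_downreg_test(vin, vout, method)
                if vin and vout
                else None
            )
            results.append(
                SubgroupTestResult(
                    exp.experiment_id, feature, str(sub), method, p,
                    len(vin), len(vout), sample_id=sample_id,
                )
            )
    return results


def sample_level_score(per_sample_pvalues: Sequence[float], alpha: float = 0.05) -> float:
    """Fraction of per-sample p-values strictly below ``alpha``."""
    if len(per_sample_pvalues) == 0:
        raise ValueError("empty p-value list")
    return sum(1 for p in per_sample_pvalues if p < alpha) / len(per_sample_pvalues)


def sample_level_scores(
    per_sample_results: Iterable[SubgroupTestResult], alpha: float = 0.05
) -> Dict[Tuple[str, str, str], float]:
    """Sample-level score per (experiment, feature, subgroup) from a
    per-sample scan; samples whose test was not computable are skipped."""
    groups: Dict[Tuple[str, str, str], List[float]] = {}
    for r in per_sample_results:
        if r.p_value is not None:
            groups.setdefault((r.experiment_id, r.feature, r.subgroup), []).append(
                r.p_value
            )
    return {k: sample_level_score(v, alpha) for k, v in groups.items()}


def trend_counts(
    experiment_results: Iterable[SubgroupTestResult],
    scores: Dict[Tuple[str, str, str], float],
    alpha: float = 0.05,
    score_threshold: float = 0.5,
) -> List[TrendCounts]:
    """Per subgroup: the number of experiments with a significant
    experiment-level p, and the number of experiments whose sample-level
    score strictly exceeds ``score_threshold``."""
    expr: Dict[Tuple[str, str], int] = {}
    smpl: Dict[Tuple[str, str], int] = {}
    seen: List[Tuple[str, str]] = []
    for r in experiment_results:
        key = (r.feature, r.subgroup)
        if key not in seen:
            seen.append(key)
        if r.p_value is not None and r.p_value < alpha:
            expr[key] = expr.get(key, 0) + 1
    for (eid, feature, sub), score in scores.items():
        if score > score_threshold:
            key = (feature, sub)
            smpl[key] = smpl.get(key, 0) + 1
    return [
        TrendCounts(f, s, expr.get((f, s), 0), smpl.get((f, s), 0)) for f, s in seen
    ]


def trend_correlation(
    expr_counts: Sequence[float], smpl_counts: Sequence[float]
) -> Tuple[float, float]:
    """Pearson r between experiment-level and sample-level trend counts and
    its two-sided p-value from the t distribution."""
    x = np.asarray(expr_counts, dtype=float)
    y = np.asarray(smpl_counts, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length count vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in trend counts")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def competition_test(
    exp: ExperimentSet,
    assignments: Dict[str, Dict[str, TargetAssignment]],
    features: Dict[str, FeatureBins],
    feature: str,
    method: str = "wilcoxon",
    scope: str = "experiment",
) -> List[SubgroupTestResult]:
    """Within each subgroup, test whether T−Endo target genes are more
    down-regulated than T+Endo target genes.

    Only valid for transfection experiments (inhibition assays perturb the
    endogenous miRNAs themselves). Subgroups with an empty side are
    reported with ``p_value=None``.
    """
    if exp.assay == Assay.INHIBITION:
        raise ValueError(
            f"experiment {exp.experiment_id}: competition test requires a "
            "transfection assay"
        )
    if scope not in ("experiment", "per_sample"):
        raise ValueError(f"unknown scope {scope!r}")
    sample_sets = [None] if scope == "experiment" else [[s] for s in exp.samples]
    results: List[SubgroupTestResult] = []
    for subset in sample_sets:
        by_group: Dict[object, Dict[str, List[float]]] = {}
        for s in subset if subset is not None else exp.samples:
            asg = assignments[s.sample_id]
            for gene, lr in s.log_ratios.items():
                ta = asg.get(gene)
                if ta is None or not ta.is_exo_target:
                    continue
                if gene not in features:
                    raise ValueError(f"no feature bins for tested gene {gene!r}")
                lab = features[gene].value(feature)
                side = "T-Endo" if not ta.is_endo_target else "T+Endo"
                by_group.setdefault(lab, {"T-Endo": [], "T+Endo": []})[side].append(lr)
        sample_id = subset[0].sample_id if subset is not None else None
        for sub in FEATURE_SUBGROUPS[feature]:
            sides = by_group.get(sub, {"T-Endo": [], "T+Endo": []})
            vin, vout = sides["T-Endo"], sides["T+Endo"]
            p = subgroup_downreg_test(vin, vout, method) if vin and vout else None
            results.append(
                SubgroupTestResult(
                    exp.experiment_id, feature, str(sub), method, p,
                    len(vin), len(vout), sample_id=sample_id,
                )
            )
    return results


def characteristic_test(
    member_scores: Sequence[float], nonmember_scores: Sequence[float]
) -> Tuple[float, float]:
    """Both one-sided Wilcoxon rank-sum p-values for a labelled gene class:
    (members greater than non-members, members less than non-members)."""
    a = np.asarray(member_scores, dtype=float)
    b = np.asarray(nonmember_scores, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    exact = (
        a.size <= EXACT_N_MAX
        and b.size <= EXACT_N_MAX
        and np.unique(pooled).size == pooled.size
    )
    meth = "exact" if exact else "asymptotic"
    p_greater = float(stats.mannwhitneyu(a, b, alternative="greater", method=meth).pvalue)
    p_less = float(stats.mannwhitneyu(a, b, alternative="less", method=meth).pvalue)
    return p_greater, p_less


def benjamini_hochberg(pvalues: Sequence[float]) -> List[float]:
    """BH step-up q-values (optional output; raw p-values are the default
    reporting convention)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        val = min(prev, p[i] * n / (rank_idx + 1))
        q[i] = val
        prev = val
    return q.tolist()
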