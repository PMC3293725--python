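"""AGO-binding calls from mapped read depths, long-vs-short binding
enrichment, target-dilution statistics, and platform-bias enrichment fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .datamodel import ExperimentSet, Platform, RNAKind, Sample
from .features import EXPR_GROUPS, FeatureBins
from .seed import TargetAssignment

DEPTH_THRESHOLD = 5  # minimum read depth at one position to call binding
LONG_GROUPS = frozenset({"VeryLong", "Long"})
SHORT_GROUPS = frozenset({"MedLong", "MedShort", "Short"})


@dataclass
class BindingCall:
    gene_id: str
    ago_id: str
    bound: bool
    max_depth: int


@dataclass
class DilutionPoint:
    sample_id: str
    total_sites: int
    mean_target_log_ratio: float
    rna_kind: RNAKind


@dataclass
class EnrichmentPoint:
    experiment_id: str
    expr_group: str
    log2_enrichment: float
    n_down: int
    n_all: int


def call_binding(
    read_positions: Sequence[Tuple[int, int]],
    depth_threshold: int = DEPTH_THRESHOLD,
    gene_id: str = "",
    ago_id: str = "",
) -> BindingCall:
    """A gene is called bound when any single position has read depth at or
    above ``depth_threshold``."""
    if any(c < 0 for _, c in read_positions):
        raise ValueError("negative read count")
    max_depth = max((c for _, c in read_positions), default=0)
    return BindingCall(gene_id, ago_id, max_depth >= depth_threshold, max_depth)


def call_binding_map(
    read_positions: Dict[str, List[Tuple[int, int]]],
    gene_ids: Sequence[str],
    depth_threshold: int = DEPTH_THRESHOLD,
    ago_id: str = "",
) -> Dict[str, BindingCall]:
    """Binding calls for a full cohort; genes with no mapped reads are
    unbound with depth 0."""
    return {
        g: call_binding(read_positions.get(g, []), depth_threshold, g, ago_id)
        for g in gene_ids
    }


def long_short_fisher(
    calls: Dict[str, BindingCall], length_groups: Dict[str, str]
) -> Tuple[float, float, np.ndarray]:
    """One-sided Fisher's exact test for binding enrichment among long
    (VeryLong/Long) vs short (MedLong/MedShort/Short) 3' UTR genes.

    Returns (odds ratio, p-value, 2×2 table [[long_bound, long_unbound],
    [short_bound, short_unbound]]).
    """
    table = np.zeros((2, 2), dtype=int)
    for gene, call in calls.items():
        group = length_groups[gene]
        row = 0 if group in LONG_GROUPS else 1
        col = 0 if call.bound else 1
        table[row, col] += 1
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError(f"degenerate 2x2 table: {table.tolist()}")
    odds, p = stats.fisher_exact(table, alternative="greater")
    return float(odds), float(p), table


def binding_summary(
    calls: Dict[str, BindingCall], length_groups: Dict[str, str]
) -> Dict[str, Tuple[int, int, float]]:
    """Per length subgroup: (n bound, n total, bound percentage)."""
    out: Dict[str, Tuple[int, int, float]] = {}
    for group in ("VeryLong", "Long", "MedLong", "MedShort", "Short"):
        genes = [g for g, lg in length_groups.items() if lg == group and g in calls]
        n = len(genes)
        nb = sum(1 for g in genes if calls[g].bound)
        out[group] = (nb, n, 100.0 * nb / n if n else float("nan"))
    return out


def dilution_scan(
    samples: Sequence[Sample],
    assignments: Dict[str, Dict[str, TargetAssignment]],
    restrict_no_endo: bool = False,
    use_expression: bool = False,
    expr_scores: Optional[Dict[str, float]] = None,
) -> Tuple[List[DilutionPoint], float, float]:
    """Per-sample target-dilution points and their Pearson correlation.

    For each sample: ``total_sites`` is the sum of seed-site counts over
    predicted target genes, and ``mean_target_log_ratio`` the mean log-ratio
    of those genes. ``restrict_no_endo=True`` restricts the averaged genes
    to targets without endogenous sites (T−Endo). ``use_expression=True``
    totals target expression scores instead of site counts. Samples with no
    target genes are omitted with a warning.
    """
    points: List[DilutionPoint] = []
    for s in samples:
        asg = assignments[s.sample_id]
        total = 0.0
        lrs: List[float] = []
        for gene, lr in s.log_ratios.items():
            ta = asg.get(gene)
            if ta is None or not ta.is_exo_target:
                continue
            if use_expression:
                if expr_scores is None:
                    raise ValueError("use_expression requires expr_scores")
                total += expr_scores.get(gene, 0.0)
            else:
                total += ta.n_sites
            if not restrict_no_endo or not ta.is_endo_target:
                lrs.append(lr)
        if not lrs:
            warnings.warn(
                f"sample {s.sample_id}: no predicted target genes; point omitted"
            )
            continue
        points.append(
            DilutionPoint(
                s.sample_id, int(total) if not use_expression else total,
                float(np.mean(lrs)), s.small_rna.kind,
            )
        )
    if len(points) < 3:
        raise ValueError("need at least 3 dilution points for a correlation")
    x = np.array([p.total_sites for p in points], dtype=float)
    y = np.array([p.mean_target_log_ratio for p in points])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in dilution points")
    res = stats.pearsonr(x, y)
    return points, float(res.statistic), float(res.pvalue)


EXPR_ORDINAL = {g: i for i, g in enumerate(EXPR_GROUPS)}  # NoExp=0 … VeryHigh=5


def _down_regulated(
    sample: Sample, platform: Platform, p_cut: float, lr_cut: float
) -> List[str]:
    down = []
    for gene, lr in sample.log_ratios.items():
        if lr >= lr_cut:
            continue
        if platform == Platform.MICROARRAY:
            if sample.detection_pvalues is None:
                raise ValueError(
                    f"sample {sample.sample_id}: microarray down-regulation "
                    "rule needs detection p-values; configure the proteomics "
                    "(log-ratio only) rule to proceed without them"
                )
            if sample.detection_pvalues.get(gene, 1.0) >= p_cut:
                continue
        down.append(gene)
    return down


def downreg_enrichment(
    exp: ExperimentSet,
    features: Dict[str, FeatureBins],
    mode: str = "count_enrichment",
    p_cut: float = 0.01,
    lr_cut: float = -0.01,
    min_down: int = 2,
) -> Tuple[List[EnrichmentPoint], float, float]:
    """Enrichment of down-regulated genes per expression subgroup, with a
    linear fit of enrichment against the subgroup ordinal.

    Down-regulation: detection p < ``p_cut`` and log-ratio < ``lr_cut`` for
    microarray; log-ratio < ``lr_cut`` alone for proteomics.
    ``count_enrichment`` (default): log2 of the down-regulated fraction in a
    subgroup relative to the all-gene fraction. ``ratio_of_means``: log2 of
    the mean log-ratio of down-regulated genes over the mean of all genes in
    the subgroup. Points based on fewer than ``min_down`` down-regulated
    genes are excluded. Returns (points, slope, two-sided slope p).
    """
    if mode not in ("count_enrichment", "ratio_of_means"):
        raise ValueError(f"unknown enrichment mode {mode!r}")
    per_group_down: Dict[str, List[float]] = {}
    per_group_all: Dict[str, List[float]] = {}
    for s in exp.samples:
        down = set(_down_regulated(s, exp.platform, p_cut, lr_cut))
        for gene, lr in s.log_ratios.items():
            grp = features[gene].expr_group
            per_group_all.setdefault(grp, []).append(lr)
            if gene in down:
                per_group_down.setdefault(grp, []).append(lr)
    n_down_tot = sum(len(v) for v in per_group_down.values())
    n_all_tot = sum(len(v) for v in per_group_all.values())
    points: List[EnrichmentPoint] = []
    for grp in EXPR_GROUPS:
        alls = per_group_all.get(grp, [])
        downs = per_group_down.get(grp, [])
        if len(downs) < min_down or not alls:
            continue
        if mode == "count_enrichment":
            enr = np.log2(
                (len(downs) / n_down_tot) / (len(alls) / n_all_tot)
            )
        else:
            ratio = np.mean(downs) / np.mean(alls)
            if ratio <= 0:
                continue
            enr = np.log2(ratio)
        points.append(
            EnrichmentPoint(exp.experiment_id, grp, float(enr), len(downs), len(alls))
        )
    if len(points) < 3:
        raise ValueError("need at least 3 enrichment points for a fit")
    x = np.array([EXPR_ORDINAL[p.expr_group] for p in points], dtype=float)
    y = np.array([p.log2_enrichment for p in points])
    fit = stats.linregress(x, y)
    return points, float(fit.slope), float(fit.pvalue)
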