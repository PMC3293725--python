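"""Gene-context features: 3' UTR length bins, 3' UTR conservation bins,
expression-level bins, promoter CpG class, and housekeeping/developmental
labels.

Two binning modes are supported everywhere: data-driven empirical quantile
cuts over the analysed cohort, and fixed cuts (e.g. the published
thresholds) supplied explicitly. Ties at a cut always go to the lower bin,
and interval edges are inclusive on both printed bounds, so a fixed cut ``c``
separates ``value <= c`` (lower bin) from ``value > c``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

# ordered low → high
LENGTH_GROUPS = ("Short", "MedShort", "MedLong", "Long", "VeryLong")
CONS_GROUPS = ("NoConsv", "Low", "Medium", "High")
EXPR_GROUPS = ("NoExp", "VeryLow", "Low", "Medium", "High", "VeryHigh")
CPG_GROUPS = ("low", "medium", "high", "unknown")

#: published fixed thresholds: UTR-length quartile cuts below the 4000-nt
#: very-long cut, conservation tertile cuts, expression quintile cuts.
DEFAULT_LENGTH_FIXED_CUT = 4000
PAPER_LENGTH_CUTS = (247.0, 629.0, 1372.0)
PAPER_CONS_CUTS = (0.054, 0.238)
PAPER_EXPR_CUTS = (0.008, 0.0344, 0.0795, 0.2007)


@dataclass
class FeatureBins:
    """Discretized gene-context features for one gene."""

    gene_id: str
    utr_length: int = 0
    length_group: str = "Short"
    cons_score: float = 0.0
    cons_group: str = "NoConsv"
    expr_score: float = 0.0
    expr_group: str = "NoExp"
    cpg_group: str = "unknown"
    hk: Optional[bool] = None
    dev: Optional[bool] = None

    def value(self, feature: str):
        """The subgroup label (or boolean) of this gene for a feature name."""
        return {
            "length": self.length_group,
            "conservation": self.cons_group,
            "expression": self.expr_group,
            "cpg": self.cpg_group,
            "hk": self.hk,
            "dev": self.dev,
        }[feature]


FEATURE_SUBGROUPS: Dict[str, Tuple] = {
    "length": tuple(reversed(LENGTH_GROUPS)),
    "conservation": tuple(reversed(CONS_GROUPS)),
    "expression": tuple(reversed(EXPR_GROUPS)),
    "cpg": ("high", "medium", "low", "unknown"),
    "hk": (True, False),
    "dev": (True, False),
}


def conservation_score(cons_track: Sequence[int]) -> float:
    """Fraction of conserved bases: (# flags set) / track length."""
    if len(cons_track) == 0:
        raise ValueError("empty conservation track")
    return float(np.count_nonzero(np.asarray(cons_track))) / len(cons_track)


def quantile_cuts(cohort: Sequence[float], k: int) -> List[float]:
    """Upper-edge cuts that split ``cohort`` into ``k`` rank-balanced bins.

    ``cuts[i]`` is the value of the last member of bin ``i`` in sort order;
    assignment is ``value <= cut → bin``. With all-distinct values the bin
    sizes differ by at most one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    vals = sorted(cohort)
    n = len(vals)
    if n == 0:
        raise ValueError("empty cohort")
    return [vals[math.ceil(n * (i + 1) / k) - 1] for i in range(k - 1)]


def bin_from_cuts(value: float, cuts: Sequence[float]) -> int:
    """Index of the bin (0 = lowest) given ascending upper-edge cuts."""
    for i, c in enumerate(cuts):
        if value <= c:
            return i
    return len(cuts)


def bin_length(
    utr_len: int,
    fixed_cut: int = DEFAULT_LENGTH_FIXED_CUT,
    quantile_cuts_: Optional[Sequence[float]] = None,
    cohort_lengths: Optional[Sequence[int]] = None,
) -> str:
    """Assign a UTR length to one of the five length subgroups.

    Lengths above ``fixed_cut`` are VeryLong; the rest are binned by the
    given quartile cuts, or by empirical quartiles of the ≤ ``fixed_cut``
    part of ``cohort_lengths``. Exactly one of ``quantile_cuts_`` /
    ``cohort_lengths`` must be given.
    """
    if utr_len < 0:
        raise ValueError("negative UTR length")
    if (quantile_cuts_ is None) == (cohort_lengths is None):
        raise ValueError("give exactly one of quantile_cuts_ or cohort_lengths")
    if utr_len > fixed_cut:
        return "VeryLong"
    if cohort_lengths is not None:
        sub = [x for x in cohort_lengths if x <= fixed_cut]
        quantile_cuts_ = quantile_cuts(sub, 4)
    return LENGTH_GROUPS[bin_from_cuts(utr_len, quantile_cuts_)]


def bin_by_quantiles(
    score: float,
    labels: Sequence[str],
    zero_label: str,
    k: int,
    cohort_scores: Optional[Sequence[float]] = None,
    cuts: Optional[Sequence[float]] = None,
) -> str:
    """Assign a non-negative score to ``zero_label`` (score == 0) or to one
    of ``k`` quantile bins of the non-zero cohort.

    ``labels`` are ordered low → high and must have length ``k``. Either
    precomputed ``cuts`` (k−1 ascending upper edges) or the raw
    ``cohort_scores`` (from which nonzero values form the cohort) are given.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(labels) != k:
        raise ValueError(f"need {k} labels, got {len(labels)}")
    if score == 0:
        return zero_label
    if cuts is None:
        if cohort_scores is None:
            raise ValueError("give cuts or cohort_scores")
        nonzero = [s for s in cohort_scores if s != 0]
        if not nonzero:
            raise ValueError("empty non-zero cohort")
        cuts = quantile_cuts(nonzero, k)
    return labels[bin_from_cuts(score, cuts)]


def bin_conservation(score, cohort_scores=None, cuts=None) -> str:
    return bin_by_quantiles(
        score, CONS_GROUPS[1:], "NoConsv", 3, cohort_scores=cohort_scores, cuts=cuts
    )


def bin_expression(score, cohort_scores=None, cuts=None) -> str:
    return bin_by_quantiles(
        score, EXPR_GROUPS[1:], "NoExp", 5, cohort_scores=cohort_scores, cuts=cuts
    )


def cpg_class(promoter_seq: Optional[str], window: int = 500, step: int = 5) -> str:
    """Classify a promoter by sliding-window GC and CpG observed/expected.

    Per window: GC fraction, and CpG o/e = (#CG dinucleotides × window) /
    (#C × #G). 'high' if any window has GC > 0.55 and o/e > 0.75; 'low' if no
    window has o/e > 0.48; 'medium' otherwise. Promoters shorter than one
    window are 'unknown'.
    """
    if promoter_seq is None or len(promoter_seq) < window:
        return "unknown"
    seq = promoter_seq.upper().replace("U", "T")
    any_high = False
    any_above_low = False
    for start in range(0, len(seq) - window + 1, step):
        w = seq[start : start + window]
        c = w.count("C")
        g = w.count("G")
        cg = w.count("CG")
        gc_frac = (c + g) / window
        oe = (cg * window) / (c * g) if c and g else 0.0
        if gc_frac > 0.55 and oe > 0.75:
            any_high = True
        if oe > 0.48:
            any_above_low = True
    if any_high:
        return "high"
    if not any_above_low:
        return "low"
    return "medium"


def label_gene_lists(
    genes: Iterable[str], hk_ids: Set[str], dev_ids: Set[str]
) -> Dict[str, Tuple[bool, bool]]:
    """Per-gene (housekeeping, developmental) membership flags; genes in
    neither list get (False, False)."""
    return {g: (g in hk_ids, g in dev_ids) for g in genes}


def build_feature_bins(
    genes,
    mode: str = "quantile",
    hk_ids: Optional[Set[str]] = None,
    dev_ids: Optional[Set[str]] = None,
    length_fixed_cut: int = DEFAULT_LENGTH_FIXED_CUT,
) -> Dict[str, FeatureBins]:
    """Compute all feature bins for a cohort of :class:`GeneAnnotation`.

    ``mode='quantile'`` derives cuts from the cohort itself (the published
    procedure); ``mode='fixed'`` uses the published thresholds.
    """
    if mode not in ("quantile", "fixed"):
        raise ValueError(f"unknown binning mode {mode!r}")
    genes = list(genes)
    if mode == "fixed":
        len_cuts = PAPER_LENGTH_CUTS
        cons_cuts = PAPER_CONS_CUTS
        expr_cuts = PAPER_EXPR_CUTS
    else:
        lengths = [g.utr_length for g in genes if g.utr_length <= length_fixed_cut]
        len_cuts = quantile_cuts(lengths, 4)
        cons_scores = [
            conservation_score(g.cons_track) for g in genes if any(g.cons_track)
        ]
        cons_cuts = quantile_cuts(cons_scores, 3) if cons_scores else None
        expr_scores = [g.expr_score for g in genes if g.expr_score != 0]
        expr_cuts = quantile_cuts(expr_scores, 5) if expr_scores else None

    out: Dict[str, FeatureBins] = {}
    for g in genes:
        cs = conservation_score(g.cons_track) if len(g.cons_track) else 0.0
        fb = FeatureBins(
            gene_id=g.gene_id,
            utr_length=g.utr_length,
            length_group=bin_length(
                g.utr_length, length_fixed_cut, quantile_cuts_=len_cuts
            ),
            cons_score=cs,
            cons_group="NoConsv"
            if cs == 0 or cons_cuts is None
            else bin_conservation(cs, cuts=cons_cuts),
            expr_score=g.expr_score,
            expr_group="NoExp"
            if g.expr_score == 0 or expr_cuts is None
            else bin_expression(g.expr_score, cuts=expr_cuts),
            cpg_group=cpg_class(g.promoter_seq),
        )
        if hk_ids is not None:
            fb.hk = g.gene_id in hk_ids
        elif g.is_housekeeping is not None:
            fb.hk = g.is_housekeeping
        if dev_ids is not None:
            fb.dev = g.gene_id in dev_ids
        elif g.is_developmental is not None:
            fb.dev = g.is_developmental
        out[g.gene_id] = fb
    return out
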