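"""Linear models of target knockdown from min-max normalized gene-context
factors.

Factor codes follow the reporting convention: ``ln3`` 3' UTR length, ``cs3``
3' UTR conservation, ``exp`` expression score, ``site_m`` exogenous seed-site
count, ``endo_m`` endogenous seed-site count, ``site_s`` per-sample total
site count, ``p_ma`` microarray indicator, ``e_oe`` transfection indicator,
``ts_score`` aggregated per-pair context score. The response is the negated
log-ratio, so positive coefficients associate with down-regulation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .datamodel import Assay, ExperimentSet, Platform
from .features import FeatureBins
from .seed import TargetAssignment

#: published normalization ranges per factor
FACTOR_RANGES: Dict[str, Tuple[float, float]] = {
    "ln3": (0.0, 1000.0),
    "cs3": (0.0, 1.0),
    "exp": (6.1e-5, 64.0),
    "site_m": (0.0, 20.0),
    "endo_m": (0.0, 30.0),
    "site_s": (0.0, 6000.0),
    "ts_score": (0.0, 2.0),
}

MAIN_8 = ("ln3", "cs3", "exp", "site_m", "endo_m", "site_s", "p_ma", "e_oe")
MAIN_9 = MAIN_8 + ("ts_score",)


@dataclass
class FactorRow:
    gene_id: str
    sample_id: str
    factors: Dict[str, float]
    response: float


@dataclass
class RegressionResult:
    terms: List[str]
    coefficients: Dict[str, float]
    p_values: Dict[str, float]
    r2: float
    adjusted_r2: float
    n_rows: int
    model: object = field(default=None, repr=False)


def aggregate_ts_scores(site_scores: Sequence[float]) -> float:
    """Negated sum of per-site scores for one RNA:gene pair; higher means a
    stronger predicted knockdown. No sites → 0."""
    return -float(sum(site_scores))


def normalize_factor(raw: float, min_: float, max_: float) -> float:
    """Min-max map to [0,1], clipping values outside the range."""
    if max_ <= min_:
        raise ValueError(f"max ({max_}) must exceed min ({min_})")
    return float(np.clip((raw - min_) / (max_ - min_), 0.0, 1.0))


def build_factor_table(
    experiments: Sequence[ExperimentSet],
    assignments: Dict[str, Dict[str, TargetAssignment]],
    features: Dict[str, FeatureBins],
    ts_scores: Optional[Dict[Tuple[str, str], float]] = None,
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
) -> List[FactorRow]:
    """One row per (predicted target gene, sample) with normalized factors.

    ``ts_scores`` maps (rna_id, gene_id) to an already-aggregated pair score
    (absent pairs score 0). The response is the negated log-ratio. Non-target
    genes are excluded; a missing feature entry for an included gene is an
    error.
    """
    ranges = dict(FACTOR_RANGES if ranges is None else ranges)
    rows: List[FactorRow] = []
    for exp in experiments:
        p_ma = 1.0 if exp.platform == Platform.MICROARRAY else 0.0
        e_oe = 1.0 if exp.assay == Assay.TRANSFECTION else 0.0
        for s in exp.samples:
            asg = assignments[s.sample_id]
            site_s = sum(
                ta.n_sites
                for g, ta in asg.items()
                if ta.is_exo_target and g in s.log_ratios
            )
            for gene, lr in s.log_ratios.items():
                ta = asg.get(gene)
                if ta is None or not ta.is_exo_target:
                    continue
                if gene not in features:
                    raise ValueError(f"no features for target gene {gene!r}")
                fb = features[gene]
                factors = {
                    "ln3": normalize_factor(fb.utr_length, *ranges["ln3"]),
                    "cs3": normalize_factor(fb.cons_score, *ranges["cs3"]),
                    "exp": normalize_factor(fb.expr_score, *ranges["exp"]),
                    "site_m": normalize_factor(ta.n_sites, *ranges["site_m"]),
                    "endo_m": normalize_factor(ta.n_endo_sites, *ranges["endo_m"]),
                    "site_s": normalize_factor(site_s, *ranges["site_s"]),
                    "p_ma": p_ma,
                    "e_oe": e_oe,
                }
                if ts_scores is not None:
                    factors["ts_score"] = normalize_factor(
                        ts_scores.get((s.small_rna.rna_id, gene), 0.0),
                        *ranges["ts_score"],
                    )
                rows.append(FactorRow(gene, s.sample_id, factors, -lr))
    return rows


def _design(rows: Sequence[FactorRow], terms: str) -> Tuple[pd.DataFrame, np.ndarray]:
    mains = MAIN_9 if terms.endswith("9") else MAIN_8
    if terms.endswith("9") and any("ts_score" not in r.factors for r in rows):
        raise ValueError("9-factor model requires ts_score in every row")
    X = pd.DataFrame([{m: r.factors[m] for m in mains} for r in rows])
    if terms.startswith("interactions"):
        for a, b in itertools.combinations(mains, 2):
            X[f"{a}*{b}"] = X[a] * X[b]
    y = np.array([r.response for r in rows])
    return X, y


def fit_linear(rows: Sequence[FactorRow], terms: str = "main_8") -> RegressionResult:
    """Ordinary least squares with intercept on the chosen term set.

    ``terms`` is one of ``main_8``, ``main_9``, ``interactions_8``,
    ``interactions_9``; the interaction sets add all pairwise products of
    the (normalized) main effects. Errors on zero-variance terms,
    rank-deficient designs, and under-determined fits.
    """
    if terms not in ("main_8", "main_9", "interactions_8", "interactions_9"):
        raise ValueError(f"unknown term set {terms!r}")
    X, y = _design(rows, terms)
    if len(rows) <= X.shape[1] + 1:
        raise ValueError(
            f"under-determined fit: {len(rows)} rows for {X.shape[1]} terms"
        )
    for col in X.columns:
        if np.ptp(X[col].to_numpy()) == 0:
            raise ValueError(f"zero-variance term: {col}")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = sm.OLS(y, Xc).fit()
    return RegressionResult(
        terms=list(X.columns),
        coefficients=fit.params.to_dict(),
        p_values=fit.pvalues.to_dict(),
        r2=float(fit.rsquared),
        adjusted_r2=float(fit.rsquared_adj),
        n_rows=len(rows),
        model=fit,
    )
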