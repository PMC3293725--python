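"""Seeded generator of complete synthetic perturbation studies.

Produces genomes (UTRs with conservation tracks, expression scores,
promoters, housekeeping/developmental labels), small RNAs with planted seed
sites, and microarray/proteomics perturbation experiments with planted,
recoverable effects:

* knockdown proportional to the exogenous seed-site count, diluted by the
  sample's total target-site count;
* competition-driven up-shift of endogenous-miRNA targets;
* microarray observations attenuated for lowly expressed genes (with
  matching detection p-values); proteomics observations unattenuated but
  increasingly missing at low expression.

Effects compose additively on the log10 scale. All randomness flows from a
single :class:`numpy.random.Generator`, so a fixed seed gives identical
studies across runs.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .datamodel import (
    Assay,
    ExperimentSet,
    GeneAnnotation,
    Platform,
    RNAKind,
    Sample,
    SmallRNA,
)
from .seed import TargetAssignment, _scan_sites, seed_patterns, SiteType

_NT = np.array(list("ACGT"))
_NT_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Parameters of a synthetic study; see module docstring for the
    planted mechanisms each field controls."""

    n_genes: int = 2000
    utr_length_log_mean: float = 6.5  # natural-log scale; exp(6.5) ≈ 665 nt
    utr_length_log_sd: float = 0.8
    gc_content: float = 0.42
    cons_rate_alpha: float = 0.8
    cons_rate_beta: float = 2.0
    expr_zero_frac: float = 0.15
    expr_log_mean: float = -2.5  # natural log of tag score
    expr_log_sd: float = 1.8
    n_endo_families: int = 10
    site_rate_per_kb: float = 0.6  # exogenous planted-site intensity
    endo_site_rate_per_kb: float = 0.4  # per endogenous family
    knockdown_per_site: float = 0.15  # log10 units per exogenous site
    competition_shift: float = 0.0  # log10 up-shift for endogenous targets
    dilution_strength: float = 0.0  # 1/(1 + strength · total_sites)
    array_sensitivity_slope: float = 0.0  # logistic slope over expression rank
    proteomics_detect_midpoint: float = 0.3  # rank01 of 50% detection
    noise_sd: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        for name in ("gc_content", "expr_zero_frac", "proteomics_detect_midpoint"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "knockdown_per_site",
            "competition_shift",
            "dilution_strength",
            "noise_sd",
            "site_rate_per_kb",
            "endo_site_rate_per_kb",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """What was actually planted: per-(gene, RNA) site counts, endogenous
    RNA ids, and per-sample realized effect parameters."""

    site_counts: Dict[Tuple[str, str], int] = field(default_factory=dict)
    endo_rna_ids: List[str] = field(default_factory=list)
    skipped_genes: List[str] = field(default_factory=list)
    sample_effects: Dict[str, Dict[str, float]] = field(default_factory=dict)
    sample_total_sites: Dict[str, int] = field(default_factory=dict)

    def n_sites(self, gene_id: str, rna_id: str) -> int:
        return self.site_counts.get((gene_id, rna_id), 0)

    def n_endo_sites(self, gene_id: str) -> int:
        return sum(self.n_sites(gene_id, r) for r in self.endo_rna_ids)

    def assignment(self, gene_id: str, exo_id: str) -> TargetAssignment:
        return TargetAssignment(
            gene_id,
            exo_id,
            sites=[],
            n_sites=self.n_sites(gene_id, exo_id),
            n_endo_sites=self.n_endo_sites(gene_id),
        )


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = np.searchsorted(np.cumsum(p), rng.random(n), side="right")
    return _NT_BYTES[codes].tobytes().decode("ascii")


def generate_small_rnas(
    rng: np.random.Generator,
    n: int,
    kind: RNAKind = RNAKind.MIRNA,
    prefix: str = "rna",
    length: int = 22,
    avoid: Sequence[SmallRNA] = (),
    max_tries: int = 10000,
) -> List[SmallRNA]:
    """Random mature sequences whose seed cores are mutually exclusive.

    No RNA's 6-nt core may occur inside any other RNA's 8mer site pattern
    (including those in ``avoid``), so planted sites for one RNA can never
    create matches for another.
    """
    rnas: List[SmallRNA] = list(avoid)
    out: List[SmallRNA] = []
    for i in range(n):
        for _ in range(max_tries):
            cand = SmallRNA(
                f"{prefix}-{i + 1}", _random_seq(rng, length, 0.5), kind=kind,
                family_id=f"{prefix}-fam-{i + 1}",
            )
            pats = seed_patterns(cand)
            core = pats[SiteType.SEVENMER_A1][:-1]
            ok = True
            for other in rnas:
                opats = seed_patterns(other)
                ocore = opats[SiteType.SEVENMER_A1][:-1]
                if core in opats[SiteType.EIGHTMER] or ocore in pats[SiteType.EIGHTMER]:
                    ok = False
                    break
            if ok:
                rnas.append(cand)
                out.append(cand)
                break
        else:
            raise RuntimeError("could not draw mutually exclusive RNA seeds")
    return out


def generate_genome(
    cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> List[GeneAnnotation]:
    """Draw a synthetic gene cohort.

    UTR lengths are log-normal; conservation tracks are Bernoulli with a
    per-gene Beta-distributed rate; expression is zero-inflated log-normal.
    Housekeeping labels are enriched among highly expressed genes,
    developmental labels among lowly expressed ones, and CpG-rich promoters
    among housekeeping genes.
    """
    rng = cfg.rng() if rng is None else rng
    n = cfg.n_genes
    lengths = np.maximum(
        rng.lognormal(cfg.utr_length_log_mean, cfg.utr_length_log_sd, n).astype(int),
        50,
    )
    cons_rates = rng.beta(cfg.cons_rate_alpha, cfg.cons_rate_beta, n)
    zero = rng.random(n) < cfg.expr_zero_frac
    expr = np.where(zero, 0.0, rng.lognormal(cfg.expr_log_mean, cfg.expr_log_sd, n))
    rank01 = stats.rankdata(expr, method="average") / n
    p_hk = 0.05 + 0.4 * rank01
    p_dev = 0.05 + 0.4 * (1 - rank01)
    hk = rng.random(n) < p_hk
    dev = rng.random(n) < p_dev

    # batch-draw all sequence and conservation randomness, then slice per gene
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    all_seq = _random_seq(rng, int(offsets[-1]), cfg.gc_content)
    all_cons = (
        rng.random(int(offsets[-1])) < np.repeat(cons_rates, lengths)
    ).astype(np.uint8)
    cpg_rich = rng.random(n) < np.where(hk, 0.7, 0.25)
    plen = 1000
    rich_pool = _random_seq(rng, plen * int(cpg_rich.sum()), 0.60)
    poor_pool = _random_seq(rng, plen * int((~cpg_rich).sum()), 0.40).replace("CG", "CA")
    genes: List[GeneAnnotation] = []
    i_rich = i_poor = 0
    for i in range(n):
        lo, hi = int(offsets[i]), int(offsets[i + 1])
        if cpg_rich[i]:
            promoter = rich_pool[i_rich * plen : (i_rich + 1) * plen]
            i_rich += 1
        else:
            promoter = poor_pool[i_poor * plen : (i_poor + 1) * plen]
            i_poor += 1
        genes.append(
            GeneAnnotation(
                gene_id=f"g{i + 1:05d}",
                utr_seq=all_seq[lo:hi],
                cons_track=all_cons[lo:hi],
                expr_score=float(expr[i]),
                promoter_seq=promoter,
                is_housekeeping=bool(hk[i]),
                is_developmental=bool(dev[i]),
            )
        )
    return genes


def _scrub_cores(seq: str, pattern: re.Pattern, rng: np.random.Generator,
                 max_rounds: int = 50) -> str:
    """Mutate one base inside every spurious core occurrence until none
    remain (mutations can create new cores, hence the rounds)."""
    for _ in range(max_rounds):
        hits = [m.start() for m in pattern.finditer(seq)]
        if not hits:
            return seq
        chars = list(seq)
        for start in hits:
            pos = start + 3
            old = chars[pos]
            chars[pos] = "ACGT".replace(old, "")[int(rng.integers(3))]
        seq = "".join(chars)
    raise RuntimeError("core scrubbing did not converge")


def plant_sites(
    genes: Sequence[GeneAnnotation],
    rnas: Sequence[SmallRNA],
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    rates_per_kb: Optional[Dict[str, float]] = None,
    max_tries: int = 20,
) -> Tuple[List[GeneAnnotation], GroundTruth]:
    """Insert exact seed-site strings into UTRs and record the truth.

    Spurious core matches in the background sequence are first scrubbed, so
    re-scanning a planted gene recovers exactly the planted counts (this is
    verified per gene; a gene whose placement cannot be verified within
    ``max_tries`` redraws is skipped with a warning and carries no sites).
    Planted site counts are Poisson with per-kb intensity, so longer UTRs
    receive proportionally more sites.
    """
    rng = cfg.rng() if rng is None else rng
    pats = {r.rna_id: seed_patterns(r) for r in rnas}
    core_re = re.compile(
        "|".join(
            sorted({p[SiteType.SEVENMER_A1][:-1] for p in pats.values()})
        )
    )
    site_type_choices = list(SiteType)
    # endo_rna_ids is filled in by the caller once it knows which RNAs are
    # the endogenous set
    truth = GroundTruth()
    out_genes: List[GeneAnnotation] = []
    for gene in genes:
        planted = None
        seq = _scrub_cores(gene.utr_seq, core_re, rng)
        for _ in range(max_tries):
            wanted: Dict[str, int] = {}
            placements: List[Tuple[int, str, SiteType]] = []  # (pos, rna, type)
            occupied: List[Tuple[int, int]] = []
            ok = True
            for r in rnas:
                rate = (
                    rates_per_kb[r.rna_id]
                    if rates_per_kb is not None
                    else cfg.site_rate_per_kb
                )
                k = int(rng.poisson(rate * len(seq) / 1000.0))
                placed = 0
                for _ in range(k):
                    u = rng.random()
                    t = site_type_choices[0 if u < 0.5 else (1 if u < 0.75 else 2)]
                    width = len(pats[r.rna_id][t])
                    lo, hi = 1, len(seq) - width - 1
                    if hi <= lo:
                        continue
                    for _attempt in range(30):
                        pos = int(rng.integers(lo, hi))
                        span = (pos - 2, pos + width + 2)  # reserve flanks
                        if all(span[0] >= e or span[1] <= s for s, e in occupied):
                            occupied.append(span)
                            placements.append((pos, r.rna_id, t))
                            placed += 1
                            break
                wanted[r.rna_id] = placed
            chars = list(seq)
            for pos, rid, t in placements:
                pat = pats[rid][t]
                chars[pos : pos + len(pat)] = pat
                if t == SiteType.SEVENMER_M8 and chars[pos + 7] == "A":
                    chars[pos + 7] = "C"
                if t == SiteType.SEVENMER_A1:
                    m8 = pats[rid][SiteType.EIGHTMER][0]
                    if chars[pos - 1] == m8:
                        chars[pos - 1] = "A" if m8 != "A" else "C"
            new_seq = "".join(chars)
            if all(
                len(_scan_sites(new_seq, pats[r.rna_id])) == wanted[r.rna_id]
                for r in rnas
            ):
                planted = (new_seq, wanted)
                break
        if planted is None:
            warnings.warn(f"gene {gene.gene_id}: could not verify planted sites; skipped")
            truth.skipped_genes.append(gene.gene_id)
            clean = _scrub_cores(gene.utr_seq, core_re, rng)
            out_genes.append(replace(gene, utr_seq=clean,
                                     cons_track=gene.cons_track[: len(clean)]))
            for r in rnas:
                truth.site_counts[(gene.gene_id, r.rna_id)] = 0
            continue
        new_seq, wanted = planted
        out_genes.append(replace(gene, utr_seq=new_seq))
        for rid, k in wanted.items():
            truth.site_counts[(gene.gene_id, rid)] = k
    return out_genes, truth


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _expression_rank01(genes: Sequence[GeneAnnotation]) -> np.ndarray:
    expr = np.array([g.expr_score for g in genes])
    return stats.rankdata(expr, method="average") / len(genes)


def simulate_experiment(
    genes: Sequence[GeneAnnotation],
    exo_rnas: Sequence[SmallRNA],
    truth: GroundTruth,
    platform: Platform,
    assay: Assay,
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    experiment_id: Optional[str] = None,
    n_detect_reps: int = 3,
) -> ExperimentSet:
    """Simulate one experiment with one sample per exogenous RNA.

    The planted (true) log-ratio of gene g in the sample transfecting RNA x:

        lr = −k · n_sites(g,x) / (1 + d · total_sites(x))
             + competition_shift · [g is an endogenous target] + N(0, σ²)

    For inhibition assays the sign of the exogenous term is flipped (the
    emitted raw values then follow the positive-means-target convention and
    are restored by preprocessing) and no competition term is planted —
    competition is caused by the transfected RNA occupying the silencing
    machinery, a mechanism inhibition assays do not trigger.
    Microarray observations attenuate the
    deterministic change by a logistic factor of expression rank and carry
    detection p-values from simulated replicates; proteomics observations
    are unattenuated but genes drop out with probability logistic in
    expression rank.
    """
    rng = cfg.rng() if rng is None else rng
    platform = Platform(platform)
    assay = Assay(assay)
    rank01 = _expression_rank01(genes)
    is_endo = np.array([truth.n_endo_sites(g.gene_id) > 0 for g in genes])
    gene_ids = [g.gene_id for g in genes]
    s = cfg.array_sensitivity_slope
    atten = (
        _sigmoid(s * (rank01 - 0.5)) / _sigmoid(s * 0.5)
        if platform == Platform.MICROARRAY and s != 0
        else np.ones(len(genes))
    )
    detect_p = _sigmoid(6.0 * (rank01 - cfg.proteomics_detect_midpoint))
    exo_sign = -1.0 if assay == Assay.INHIBITION else 1.0
    comp = cfg.competition_shift if assay == Assay.TRANSFECTION else 0.0

    samples: List[Sample] = []
    for x in exo_rnas:
        n_sites = np.array([truth.n_sites(g, x.rna_id) for g in gene_ids], dtype=float)
        total_sites = int(n_sites.sum())
        knock = cfg.knockdown_per_site * n_sites / (
            1.0 + cfg.dilution_strength * total_sites
        )
        effect = exo_sign * -knock + comp * is_endo
        noise = rng.normal(0.0, cfg.noise_sd, len(genes))
        obs = atten * effect + noise
        sid = f"{x.rna_id}"
        truth.sample_effects[sid] = {
            "knockdown_per_site": cfg.knockdown_per_site,
            "competition_shift": cfg.competition_shift,
            "dilution_strength": cfg.dilution_strength,
        }
        truth.sample_total_sites[sid] = total_sites
        if platform == Platform.MICROARRAY:
            treated = obs[:, None] + rng.normal(0, cfg.noise_sd, (len(genes), n_detect_reps))
            control = rng.normal(0, cfg.noise_sd, (len(genes), n_detect_reps))
            pvals = stats.ttest_ind(treated, control, axis=1).pvalue
            samples.append(
                Sample(
                    sid, x,
                    log_ratios=dict(zip(gene_ids, obs.tolist())),
                    detection_pvalues=dict(zip(gene_ids, pvals.tolist())),
                )
            )
        else:
            kept = rng.random(len(genes)) < detect_p
            samples.append(
                Sample(
                    sid, x,
                    log_ratios={
                        g: float(v) for g, v, k in zip(gene_ids, obs, kept) if k
                    },
                )
            )
    return ExperimentSet(
        experiment_id or f"sim-{platform.value}-{assay.value}",
        platform, assay, samples,
    )


def truth_assignments(
    genes: Sequence[GeneAnnotation],
    truth: GroundTruth,
    experiments: Sequence[ExperimentSet],
) -> Dict[str, Dict[str, TargetAssignment]]:
    """sample_id → gene_id → assignment, from the planted ground truth."""
    out: Dict[str, Dict[str, TargetAssignment]] = {}
    for exp in experiments:
        for s in exp.samples:
            xid = s.small_rna.rna_id
            out[s.sample_id] = {
                g.gene_id: truth.assignment(g.gene_id, xid) for g in genes
            }
    return out


@dataclass
class Study:
    """A complete synthetic study plus its ground truth."""

    config: SimConfig
    genes: List[GeneAnnotation]
    exo_rnas: List[SmallRNA]
    endo_rnas: List[SmallRNA]
    experiment: ExperimentSet
    truth: GroundTruth

    def assignments(self) -> Dict[str, Dict[str, TargetAssignment]]:
        return truth_assignments(self.genes, self.truth, [self.experiment])

    def family_ranking(self) -> Dict[str, float]:
        """Endogenous families ranked by (synthetic) expression; the planted
        families are the top ones by construction."""
        return {
            r.family_id: float(len(self.endo_rnas) - i)
            for i, r in enumerate(self.endo_rnas)
        }


@dataclass
class MixedStudy:
    """One genome shared by several experiments of differing platform/assay."""

    config: SimConfig
    genes: List[GeneAnnotation]
    exo_rnas: List[SmallRNA]
    endo_rnas: List[SmallRNA]
    experiments: List[ExperimentSet]
    truth: GroundTruth

    def assignments(self) -> Dict[str, Dict[str, TargetAssignment]]:
        return truth_assignments(self.genes, self.truth, self.experiments)


DEFAULT_DESIGN = (
    (Platform.MICROARRAY, Assay.TRANSFECTION, 3),
    (Platform.PROTEOMICS, Assay.TRANSFECTION, 2),
    (Platform.MICROARRAY, Assay.INHIBITION, 1),
)


def generate_mixed_study(
    cfg: SimConfig,
    design: Sequence[Tuple[Platform, Assay, int]] = DEFAULT_DESIGN,
    exo_kind: RNAKind = RNAKind.MIRNA,
) -> MixedStudy:
    """Generate one genome and a set of experiments per ``design`` (each
    entry: platform, assay, number of samples). Raw values are emitted;
    apply :func:`mircontext.io.preprocess_log_ratios` before analysis."""
    rng = cfg.rng()
    genes = generate_genome(cfg, rng)
    endo = generate_small_rnas(rng, cfg.n_endo_families, prefix="endo")
    n_exo = sum(k for _, _, k in design)
    exo = generate_small_rnas(rng, n_exo, kind=exo_kind, prefix="exo", avoid=endo)
    rates = {r.rna_id: cfg.endo_site_rate_per_kb for r in endo}
    rates.update({r.rna_id: cfg.site_rate_per_kb for r in exo})
    genes, truth = plant_sites(genes, endo + exo, cfg, rng, rates_per_kb=rates)
    truth.endo_rna_ids = [r.rna_id for r in endo]
    experiments = []
    i = 0
    for j, (platform, assay, k) in enumerate(design):
        experiments.append(
            simulate_experiment(
                genes, exo[i : i + k], truth, platform, assay, cfg, rng,
                experiment_id=f"sim{j + 1}-{Platform(platform).value}-{Assay(assay).value}",
            )
        )
        i += k
    return MixedStudy(cfg, genes, exo, endo, experiments, truth)


def generate_study(
    cfg: SimConfig,
    platform: Platform = Platform.MICROARRAY,
    assay: Assay = Assay.TRANSFECTION,
    n_samples: int = 5,
    exo_kind: RNAKind = RNAKind.MIRNA,
) -> Study:
    """Generate genome, RNAs, planted sites, and one simulated experiment
    from a single seed."""
    rng = cfg.rng()
    genes = generate_genome(cfg, rng)
    endo = generate_small_rnas(rng, cfg.n_endo_families, prefix="endo")
    exo = generate_small_rnas(rng, n_samples, kind=exo_kind, prefix="exo", avoid=endo)
    rates = {r.rna_id: cfg.endo_site_rate_per_kb for r in endo}
    rates.update({r.rna_id: cfg.site_rate_per_kb for r in exo})
    genes, truth = plant_sites(genes, endo + exo, cfg, rng, rates_per_kb=rates)
    truth.endo_rna_ids = [r.rna_id for r in endo]
    experiment = simulate_experiment(genes, exo, truth, platform, assay, cfg, rng)
    return Study(cfg, genes, exo, endo, experiment, truth)


def simulate_read_positions(
    genes: Sequence[GeneAnnotation],
    truth: GroundTruth,
    rng: np.random.Generator,
    bound_depth: float = 9.0,
    background_depth: float = 1.0,
) -> Dict[str, List[Tuple[int, int]]]:
    """Synthetic AGO-binding read positions: endogenous targets receive a
    high-depth position per endogenous site, all genes get sparse
    background reads."""
    out: Dict[str, List[Tuple[int, int]]] = {}
    for g in genes:
        positions: List[Tuple[int, int]] = []
        for _ in range(truth.n_endo_sites(g.gene_id)):
            pos = int(rng.integers(0, max(1, g.utr_length - 1)))
            positions.append((pos, int(rng.poisson(bound_depth)) + 1))
        for _ in range(int(rng.poisson(background_depth))):
            pos = int(rng.integers(0, max(1, g.utr_length - 1)))
            positions.append((pos, int(rng.poisson(1.0)) + 1))
        if positions:
            out[g.gene_id] = sorted(positions)
    return out
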