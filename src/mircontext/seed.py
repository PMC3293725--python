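"""Canonical stringent seed-site detection and target-group assignment.

A small RNA's seed match in a 3' UTR (read 5'→3' on the UTR) is built from
the reverse complement of RNA positions 2–7 (the 6-nt core, ``S``) and the
complement of position 8 (``m8``):

* ``8mer``     — ``m8 + S`` followed by a literal ``A``;
* ``7mer-m8``  — ``m8 + S`` not followed by ``A``;
* ``7mer-A1``  — ``S`` followed by ``A``, not preceded by ``m8``.

The ``A`` opposite RNA position 1 must be a literal ``A`` in the UTR, not a
complement of position 1. Overlapping matches are resolved left-to-right
with precedence 8mer > 7mer-m8 > 7mer-A1; each UTR base belongs to at most
one reported site.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set

from .datamodel import GeneAnnotation, SmallRNA

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class SiteType(str, enum.Enum):
    EIGHTMER = "8mer"
    SEVENMER_M8 = "7mer-m8"
    SEVENMER_A1 = "7mer-A1"


# precedence for overlap resolution, strongest first
_PRECEDENCE = (SiteType.EIGHTMER, SiteType.SEVENMER_M8, SiteType.SEVENMER_A1)


@dataclass(frozen=True)
class SeedSite:
    gene_id: str
    rna_id: str
    start: int
    end: int
    site_type: SiteType

    def __post_init__(self) -> None:
        want = 8 if self.site_type == SiteType.EIGHTMER else 7
        if self.end - self.start != want:
            raise ValueError(
                f"{self.site_type.value} site must span {want} nt, "
                f"got [{self.start}, {self.end})"
            )


@dataclass
class TargetAssignment:
    """Exogenous/endogenous targeting status of one gene for one small RNA."""

    gene_id: str
    rna_id: str
    sites: List[SeedSite] = field(default_factory=list)
    n_sites: int = 0
    n_endo_sites: int = 0

    @property
    def is_exo_target(self) -> bool:
        return self.n_sites >= 1

    @property
    def is_endo_target(self) -> bool:
        return self.n_endo_sites >= 1

    @property
    def group(self) -> str:
        t = "T" if self.is_exo_target else "NT"
        e = "+Endo" if self.is_endo_target else "-Endo"
        return t + e


def _dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return _dna(seq).translate(_COMPLEMENT)[::-1]


def seed_patterns(rna: SmallRNA) -> Dict[SiteType, str]:
    """The UTR-side match strings for each stringent site type.

    ``8mer`` and ``7mer-A1`` patterns include the literal trailing ``A``;
    context constraints (the flanking base checks) are applied by the
    scanners, not encoded here.
    """
    seq = _dna(rna.mature_seq)
    if len(seq) < 8:
        raise ValueError(f"small RNA {rna.rna_id} shorter than 8 nt")
    core = reverse_complement(seq[1:7])  # positions 2-7
    m8 = seq[7].translate(_COMPLEMENT)  # complement of position 8
    return {
        SiteType.EIGHTMER: m8 + core + "A",
        SiteType.SEVENMER_M8: m8 + core,
        SiteType.SEVENMER_A1: core + "A",
    }


def classify_offset(utr: str, offset: int, patterns: Dict[SiteType, str]) -> SiteType | None:
    """Classify the (unique) stringent site type starting at ``offset``.

    ``utr`` must already be uppercase DNA. Returns None when no site type
    starts at this offset. The three definitions are mutually exclusive per
    offset, so at most one type applies.
    """
    p8 = patterns[SiteType.EIGHTMER]
    p7m8 = patterns[SiteType.SEVENMER_M8]
    p7a1 = patterns[SiteType.SEVENMER_A1]
    if utr.startswith(p8, offset):
        return SiteType.EIGHTMER
    if utr.startswith(p7m8, offset):
        # not followed by A, else it would be an 8mer
        nxt = utr[offset + 7 : offset + 8]
        if nxt != "A":
            return SiteType.SEVENMER_M8
    if utr.startswith(p7a1, offset):
        # not preceded by the m8 match, else part of an 8mer at offset-1
        prev = utr[offset - 1 : offset] if offset > 0 else ""
        if prev != p8[0]:
            return SiteType.SEVENMER_A1
    return None


def _core_occurrences(utr: str, core: str) -> List[int]:
    """All (possibly overlapping) start positions of the 6-nt core."""
    hits, pos = [], utr.find(core)
    while pos != -1:
        hits.append(pos)
        pos = utr.find(core, pos + 1)
    return hits


def _scan_sites(utr: str, patterns: Dict[SiteType, str]) -> List[Tuple[int, int, SiteType]]:
    """Resolved (start, end, type) spans in an uppercase-DNA UTR.

    Every site type contains the 6-nt core, so candidates are found by
    scanning for core occurrences and classifying each one from its
    flanking bases (equivalent to classifying every UTR offset, but linear
    in the number of core hits). Overlaps are resolved by precedence
    (8mer > 7mer-m8 > 7mer-A1), then left-to-right within a type.
    """
    core = patterns[SiteType.SEVENMER_A1][:-1]
    m8 = patterns[SiteType.EIGHTMER][0]
    candidates: Dict[SiteType, List[int]] = {t: [] for t in _PRECEDENCE}
    for p in _core_occurrences(utr, core):
        before = utr[p - 1 : p] if p > 0 else ""
        after = utr[p + 6 : p + 7]
        if before == m8:
            if after == "A":
                candidates[SiteType.EIGHTMER].append(p - 1)
            else:
                candidates[SiteType.SEVENMER_M8].append(p - 1)
        elif after == "A":
            candidates[SiteType.SEVENMER_A1].append(p)

    taken: List[Tuple[int, int]] = []  # accepted (start, end) spans
    spans: List[Tuple[int, int, SiteType]] = []
    for t in _PRECEDENCE:
        width = 8 if t == SiteType.EIGHTMER else 7
        for off in candidates[t]:
            if not any(off < e and s < off + width for s, e in taken):
                taken.append((off, off + width))
                spans.append((off, off + width, t))
    spans.sort()
    return spans


def find_seed_sites(rna: SmallRNA, utr_seq: str, gene_id: str = "") -> List[SeedSite]:
    """All non-overlapping stringent seed sites of ``rna`` in ``utr_seq``,
    sorted by start coordinate. See :func:`_scan_sites` for the overlap
    resolution rule."""
    return [
        SeedSite(gene_id, rna.rna_id, s, e, t)
        for s, e, t in _scan_sites(_dna(utr_seq), seed_patterns(rna))
    ]


def count_sites(rna: SmallRNA, gene: GeneAnnotation) -> int:
    """Number of stringent seed sites of ``rna`` in the gene's 3' UTR."""
    return len(find_seed_sites(rna, gene.utr_seq, gene.gene_id))


def select_endogenous_families(
    family_expression: Dict[str, float], k: int = 10
) -> Set[str]:
    """The ``k`` most highly expressed families; ties at the k-th rank are
    broken by lexicographic family id for determinism."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(family_expression) < k:
        raise ValueError(
            f"requested top {k} families but only {len(family_expression)} given"
        )
    ranked = sorted(family_expression.items(), key=lambda kv: (-kv[1], kv[0]))
    return {fam for fam, _ in ranked[:k]}


def assign_group(
    gene: GeneAnnotation,
    exo: SmallRNA,
    endo_rnas: Iterable[SmallRNA],
) -> TargetAssignment:
    """Classify one gene into T/NT ± Endo for an exogenous RNA.

    ``n_endo_sites`` is the total stringent site count summed over the
    endogenous RNAs (one representative mature sequence per family).
    """
    sites = find_seed_sites(exo, gene.utr_seq, gene.gene_id)
    n_endo = sum(len(find_seed_sites(r, gene.utr_seq, gene.gene_id)) for r in endo_rnas)
    return TargetAssignment(
        gene.gene_id, exo.rna_id, sites=sites, n_sites=len(sites), n_endo_sites=n_endo
    )


def assign_groups(
    genes: Sequence[GeneAnnotation],
    exo: SmallRNA,
    endo_rnas: Sequence[SmallRNA],
) -> Dict[str, TargetAssignment]:
    return {g.gene_id: assign_group(g, exo, endo_rnas) for g in genes}
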