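"""Core domain types shared by all pipeline stages.

Conventions used throughout the package:

* all log-ratios are on the log10 scale after preprocessing, with negative
  values indicating candidate down-regulation in every assay type;
* sequence coordinates are 0-based, half-open, on the sense strand of the
  (already strand-resolved) 3' UTR;
* U and T are interchangeable — matching is done after mapping U to T.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional

_VALID_NT = frozenset("ACGTUN")


class Platform(str, enum.Enum):
    MICROARRAY = "microarray"
    PROTEOMICS = "proteomics"


class Assay(str, enum.Enum):
    TRANSFECTION = "transfection"
    INHIBITION = "inhibition"


class RNAKind(str, enum.Enum):
    MIRNA = "miRNA"
    SIRNA = "siRNA"


def _check_alphabet(seq: str, what: str) -> None:
    bad = set(seq.upper()) - _VALID_NT
    if bad:
        raise ValueError(f"{what} contains invalid characters: {sorted(bad)}")


@dataclass
class GeneAnnotation:
    """One gene's 3' UTR sequence plus its gene-context features.

    ``cons_track`` is a per-base binary conservation flag vector aligned to
    ``utr_seq``; ``expr_score`` is a non-negative expression tag score.
    """

    gene_id: str
    utr_seq: str
    cons_track: List[int] = field(default_factory=list)
    expr_score: float = 0.0
    promoter_seq: Optional[str] = None
    is_housekeeping: Optional[bool] = None
    is_developmental: Optional[bool] = None

    def __post_init__(self) -> None:
        _check_alphabet(self.utr_seq, f"UTR of {self.gene_id}")
        if len(self.cons_track) and len(self.cons_track) != len(self.utr_seq):
            raise ValueError(
                f"gene {self.gene_id}: conservation track length "
                f"{len(self.cons_track)} != UTR length {len(self.utr_seq)}"
            )
        if self.expr_score < 0:
            raise ValueError(f"gene {self.gene_id}: negative expression score")

    @property
    def utr_length(self) -> int:
        return len(self.utr_seq)


@dataclass(frozen=True)
class SmallRNA:
    """A mature small RNA sequence, written 5'→3'."""

    rna_id: str
    mature_seq: str
    kind: RNAKind = RNAKind.MIRNA
    family_id: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.mature_seq) < 8:
            raise ValueError(
                f"small RNA {self.rna_id}: mature sequence shorter than 8 nt"
            )
        _check_alphabet(self.mature_seq, f"small RNA {self.rna_id}")


@dataclass
class Sample:
    """One perturbation sample: a transfected/inhibited small RNA and the
    resulting per-gene log-ratios (log10 after preprocessing)."""

    sample_id: str
    small_rna: SmallRNA
    log_ratios: Dict[str, float] = field(default_factory=dict)
    detection_pvalues: Optional[Dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.detection_pvalues is not None:
            missing = set(self.detection_pvalues) - set(self.log_ratios)
            if missing:
                raise ValueError(
                    f"sample {self.sample_id}: detection p-values for genes "
                    f"absent from log-ratios: {sorted(missing)[:5]}"
                )


@dataclass
class ExperimentSet:
    """A set of samples sharing one platform and one assay type."""

    experiment_id: str
    platform: Platform
    assay: Assay
    samples: List[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.platform = Platform(self.platform)
        self.assay = Assay(self.assay)
        if not self.samples:
            raise ValueError(f"experiment {self.experiment_id}: no samples")

    def gene_ids(self) -> List[str]:
        """All gene ids measured in at least one sample, sorted."""
        ids: set = set()
        for s in self.samples:
            ids.update(s.log_ratios)
        return sorted(ids)
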