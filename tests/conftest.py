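"""Shared fixtures and independent oracles.

The brute-force seed-site matcher here is deliberately written from scratch
(per-offset string comparison, no shared scanning code) so it can serve as
an independent oracle for the package's core-occurrence scanner.
"""

from __future__ import annotations

import random
from typing import List, Tuple

import numpy as np
import pytest

from mircontext import SmallRNA

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}


def brute_force_sites(rna_seq: str, utr_seq: str) -> List[Tuple[int, int, str]]:
    """Reference matcher: classify every UTR offset independently, then
    resolve overlaps with precedence 8mer > 7mer-m8 > 7mer-A1 and
    left-to-right within a type. Returns (start, end, type) sorted by start.
    """
    rna = rna_seq.upper().replace("U", "T")
    utr = utr_seq.upper().replace("U", "T")
    core = "".join(_COMP[c] for c in rna[1:7])[::-1]  # rc of positions 2-7
    m8 = _COMP[rna[7]]
    per_type = {"8mer": [], "7mer-m8": [], "7mer-A1": []}
    for off in range(len(utr)):
        if utr[off : off + 8] == m8 + core + "A":
            per_type["8mer"].append(off)
        elif utr[off : off + 7] == m8 + core and utr[off + 7 : off + 8] != "A":
            per_type["7mer-m8"].append(off)
        elif (
            utr[off : off + 7] == core + "A"
            and (off == 0 or utr[off - 1] != m8)
        ):
            per_type["7mer-A1"].append(off)
    accepted: List[Tuple[int, int, str]] = []
    for t, width in (("8mer", 8), ("7mer-m8", 7), ("7mer-A1", 7)):
        for off in per_type[t]:
            if all(off + width <= s or e <= off for s, e, _ in accepted):
                accepted.append((off, off + width, t))
    return sorted(accepted)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def let7():
    return SmallRNA("let7", "UGAGGUAGUAGGUUGUAUAGUU")


def random_rna(rng, length: int = 22) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))


def random_utr(rng, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
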