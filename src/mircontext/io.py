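"""Readers and writers for the plain-text formats the pipeline consumes, and
the preprocessing transform applied to every expression table.

Formats: FASTA for sequences, tab-delimited gene × sample matrices (``NA``
for missing) for log-ratios and detection p-values, BED5 for mapped read
positions, and two-column tab-delimited tables for family expression
rankings and per-pair TargetScan-style scores.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

from .datamodel import Assay, ExperimentSet, Platform, RNAKind, Sample, SmallRNA

LOG10_2 = math.log10(2.0)


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` map.

    Sequences are uppercased; both U and T are accepted. The id is the first
    whitespace-delimited token of the header. Duplicate ids and empty files
    are errors.
    """
    out: Dict[str, str] = {}
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            name = header.split()[0] if header.split() else header
            if name in out:
                raise ValueError(f"duplicate FASTA id: {name!r} in {path}")
            out[name] = seq.upper()
    if not out:
        raise ValueError(f"empty FASTA file: {path}")
    return out


def write_fasta(path, records: Dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_small_rnas(path, kind: RNAKind = RNAKind.MIRNA) -> List[SmallRNA]:
    """Read mature small-RNA sequences from FASTA.

    A header of the form ``id family=fam`` attaches a family id.
    """
    rnas = []
    with open(path) as fh:
        for header, seq in SimpleFastaParser(fh):
            toks = header.split()
            family = None
            for t in toks[1:]:
                if t.startswith("family="):
                    family = t[len("family=") :]
            rnas.append(SmallRNA(toks[0], seq.upper(), kind=kind, family_id=family))
    if not rnas:
        raise ValueError(f"empty FASTA file: {path}")
    ids = [r.rna_id for r in rnas]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate FASTA id: {dup[0]!r} in {path}")
    return rnas


def _parse_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        for gene, cell in df[col].items():
            if pd.isna(cell) or cell == "NA":
                continue
            try:
                out.at[gene, col] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at gene {gene!r}, "
                    f"sample {col!r} in {path}"
                ) from None
    return out


def read_log_ratio_table(
    path,
    platform: Platform,
    assay: Assay,
    experiment_id: Optional[str] = None,
    rnas: Optional[Dict[str, SmallRNA]] = None,
    pvalue_path=None,
) -> ExperimentSet:
    """Read a tab-delimited gene × sample log-ratio matrix into an
    :class:`ExperimentSet`.

    Rows are genes, columns samples; ``NA`` cells are omitted from the
    sample's map. Sample columns are matched to small RNAs by sample id when
    ``rnas`` is given (column name, or its prefix before the last ``.``);
    otherwise a placeholder RNA is attached. An optional parallel matrix of
    detection p-values may be supplied.
    """
    df = _parse_matrix(path)
    pdf = _parse_matrix(pvalue_path) if pvalue_path is not None else None
    samples = []
    for col in df.columns:
        vals = df[col].dropna()
        rna = None
        if rnas is not None:
            key = col if col in rnas else col.rsplit(".", 1)[0]
            if key not in rnas:
                raise ValueError(f"no small RNA found for sample column {col!r}")
            rna = rnas[key]
        else:
            rna = SmallRNA(col, "N" * 22)
        pvals = None
        if pdf is not None and col in pdf.columns:
            pvals = pdf[col].dropna().to_dict()
            pvals = {g: p for g, p in pvals.items() if g in vals.index}
        samples.append(
            Sample(col, rna, log_ratios=vals.to_dict(), detection_pvalues=pvals)
        )
    return ExperimentSet(
        experiment_id or Path(path).stem, Platform(platform), Assay(assay), samples
    )


def write_log_ratio_table(path, exp: ExperimentSet, float_fmt: str = "%.17g") -> None:
    genes = exp.gene_ids()
    df = pd.DataFrame(index=genes, columns=[s.sample_id for s in exp.samples], dtype=float)
    for s in exp.samples:
        for g, v in s.log_ratios.items():
            df.at[g, s.sample_id] = v
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format=float_fmt)


def preprocess_log_ratios(exp: ExperimentSet, input_log_base: float) -> ExperimentSet:
    """Bring an experiment's log-ratios onto the canonical scale.

    Values are converted to log10 (multiplied by log10(2) when the input is
    log2) and inhibition-assay values are negated, so that negative values
    mark candidate targeting in both assay types. Calling with base 10 on a
    transfection set is the identity.
    """
    if input_log_base not in (2, 10):
        raise ValueError(f"input_log_base must be 2 or 10, got {input_log_base}")
    scale = LOG10_2 if input_log_base == 2 else 1.0
    sign = -1.0 if exp.assay == Assay.INHIBITION else 1.0
    samples = [
        Sample(
            s.sample_id,
            s.small_rna,
            log_ratios={g: sign * scale * v for g, v in s.log_ratios.items()},
            detection_pvalues=dict(s.detection_pvalues)
            if s.detection_pvalues is not None
            else None,
        )
        for s in exp.samples
    ]
    return ExperimentSet(exp.experiment_id, exp.platform, exp.assay, samples)


def read_read_positions(path) -> Dict[str, List[Tuple[int, int]]]:
    """Read BED5-style mapped read positions on UTR coordinates.

    Returns ``{gene_id: [(start, read_count), ...]}``. Intervals are 0-based
    half-open; the score column carries the read count, which must be a
    non-negative integer.
    """
    out: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: expected ≥5 BED columns")
            gene, start, _end, _name, score = fields[:5]
            count = int(score)
            if count < 0:
                raise ValueError(f"{path}:{lineno}: negative read count {count}")
            out.setdefault(gene, []).append((int(start), count))
    return out


def read_ranking_table(path) -> Dict[str, float]:
    """Read a two-column tab-delimited (id, score) ranking table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (id, score)")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))


def read_gene_list(path) -> set:
    """Read a one-id-per-line gene list."""
    with open(path) as fh:
        return {ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")}


def read_site_scores(path) -> Dict[Tuple[str, str], List[float]]:
    """Read per-site scores keyed by (rna_id, gene_id).

    Tab-delimited with columns rna_id, gene_id, score; one row per site.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    out: Dict[Tuple[str, str], List[float]] = {}
    for rna, gene, score in zip(
        df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str), df.iloc[:, 2].astype(float)
    ):
        out.setdefault((rna, gene), []).append(score)
    return out
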