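"""Harmonized peptide abundance and expression filtering.

The central metric is read support: the number of tumor RNA-sequencing
reads containing, as an exact substring on either strand, the nucleotide
sequence that codes a candidate peptide. Unlike TPM it quantifies only the
peptide-generating subsequence (not the whole transcript, not the
wild-type allele) and is comparable across all antigen source classes.

Also implemented here: the TPM percentile filter used for SNV/InDel and
CTA/self-antigen transcripts, plain counts-per-million, and the ERV
tumor/normal log2 fold-change filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import pysam

from .reference import InputContractError, reverse_complement


@dataclass(frozen=True)
class Read:
    read_id: str
    sequence: str
    # aligned interval present iff the read came from SAM/BAM
    contig: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None

    @property
    def is_aligned(self) -> bool:
        return self.contig is not None


@dataclass(frozen=True)
class AbundanceRecord:
    peptide_key: Tuple[str, str, str]  # (peptide, source_class, origin)
    read_support: int
    origin_read_total: int


def read_fastq(path: str | Path) -> List[Read]:
    """Load reads from a FASTQ file (plain or gzipped), uppercased."""
    p = Path(path)
    if not p.exists():
        raise InputContractError(f"FASTQ not found: {p}")
    reads = []
    with pysam.FastxFile(str(p)) as fh:
        for entry in fh:
            reads.append(Read(entry.name, entry.sequence.upper()))
    return reads


def read_sam(path: str | Path) -> List[Read]:
    """Load aligned reads (with reference intervals) from SAM/BAM."""
    p = Path(path)
    if not p.exists():
        raise InputContractError(f"SAM/BAM not found: {p}")
    reads = []
    with pysam.AlignmentFile(str(p), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            reads.append(
                Read(
                    aln.query_name,
                    aln.query_sequence.upper(),
                    contig=aln.reference_name,
                    start=aln.reference_start,
                    end=aln.reference_end,
                )
            )
    return reads


def _matches(read_seq: str, coding_nt: str, both_strands: bool = True) -> bool:
    if coding_nt in read_seq:
        return True
    return both_strands and reverse_complement(coding_nt) in read_seq


def count_read_support(
    coding_nt: str,
    read_set: Sequence[Read],
    origin: Optional[Sequence[Tuple[str, int, int, str]]] = None,
    both_strands: bool = True,
    max_mismatches: int = 0,
) -> AbundanceRecord:
    """Count reads containing the peptide-coding sequence.

    A read supports the peptide when its sequence contains ``coding_nt`` as
    an exact substring, or its reverse complement does (library strandedness
    is not assumed). Each read counts at most once regardless of how many
    match offsets it has. When reads carry alignments and ``origin`` is
    given, only reads whose alignment overlaps an origin interval are
    scanned, and ``origin_read_total`` is that pool's size; otherwise the
    pool is the whole read set.

    ``max_mismatches=1`` enables Hamming-distance-1 matching (off by
    default; the harmonized metric is exact).
    """
    if not coding_nt:
        raise ValueError("coding_nt must be non-empty")
    pool = list(read_set)
    if origin and any(r.is_aligned for r in pool):
        pool = [
            r
            for r in pool
            if r.is_aligned
            and any(
                r.contig == c and r.start < e and r.end > s
                for c, s, e, _strand in origin
            )
        ]
    if max_mismatches == 0:
        support = sum(1 for r in pool if _matches(r.sequence, coding_nt, both_strands))
    else:
        support = sum(
            1
            for r in pool
            if _matches_hamming(r.sequence, coding_nt, both_strands, max_mismatches)
        )
    return AbundanceRecord(
        peptide_key=("", "", ""),
        read_support=support,
        origin_read_total=len(pool),
    )


def _matches_hamming(
    read_seq: str, coding_nt: str, both_strands: bool, max_mm: int
) -> bool:
    targets = [coding_nt]
    if both_strands:
        targets.append(reverse_complement(coding_nt))
    m = len(coding_nt)
    for t in targets:
        for i in range(len(read_seq) - m + 1):
            mm = 0
            for a, b in zip(read_seq[i : i + m], t):
                if a != b:
                    mm += 1
                    if mm > max_mm:
                        break
            if mm <= max_mm:
                return True
    return False


def fusion_read_support(
    coding_nt: str,
    junction_reads: Sequence[Read],
    spanning_read_pairs: Sequence[Tuple[Read, Read]] = (),
) -> AbundanceRecord:
    """Read support for a fusion peptide.

    Junction-crossing reads are scanned as in :func:`count_read_support`;
    spanning pairs are scanned mate by mate and a pair counts once even if
    both mates match. The union over reads and pairs is reported.
    """
    support = sum(
        1 for r in junction_reads if _matches(r.sequence, coding_nt)
    )
    for m1, m2 in spanning_read_pairs:
        if _matches(m1.sequence, coding_nt) or _matches(m2.sequence, coding_nt):
            support += 1
    return AbundanceRecord(
        peptide_key=("", "", ""),
        read_support=support,
        origin_read_total=len(junction_reads) + len(spanning_read_pairs),
    )


def tpm_percentile_filter(
    expression_table: Dict[str, float],
    feature_ids: Iterable[str],
    percentile: float,
    population: str = "expressed",
) -> Set[str]:
    """Features among ``feature_ids`` whose TPM strictly exceeds the
    percentile threshold.

    The threshold is the linear-interpolation percentile of TPM over the
    population — by default every feature with TPM > 0 in the table
    (``population='all'`` includes zeros). Strict '>' so that at the 100th
    percentile nothing passes.
    """
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    values = [
        v for v in expression_table.values() if (population == "all" or v > 0)
    ]
    if not values:
        return set()
    threshold = float(np.percentile(values, percentile))
    return {
        f
        for f in feature_ids
        if expression_table.get(f, 0.0) > threshold
    }


def compute_cpm(
    counts: Dict[str, float], library_size: Optional[float] = None
) -> Dict[str, float]:
    """Plain counts-per-million. Library size defaults to the table total."""
    if library_size is None:
        library_size = float(sum(counts.values()))
    if library_size <= 0:
        raise InputContractError("library size must be positive for CPM")
    return {k: v / library_size * 1e6 for k, v in counts.items()}


def erv_fold_change_filter(
    cpm_tumor: Dict[str, float],
    cpm_normal: Dict[str, float],
    threshold: float = 1.0,
) -> Set[str]:
    """ERV ORFs passing the tumor/normal expression fold-change rule.

    An ORF passes iff log2(CPM_tumor + 1) - log2(CPM_normal + 1) is
    strictly greater than ``threshold`` (default 1). An ORF missing from
    the normal table is treated as 0 CPM in normal.
    """
    passing = set()
    for orf, t in cpm_tumor.items():
        n = cpm_normal.get(orf, 0.0)
        if t < 0 or n < 0:
            raise InputContractError(f"negative CPM for ORF {orf}")
        if math.log2(t + 1.0) - math.log2(n + 1.0) > threshold:
            passing.add(orf)
    return passing


def rna_evidence_filter(
    candidates: Sequence,
    abundance_records: Dict[int, AbundanceRecord],
    min_support: int = 1,
) -> List:
    """Keep candidates whose harmonized read support meets ``min_support``.

    ``abundance_records`` is keyed by candidate index; every candidate must
    have a record (a missing one is a pipeline wiring bug, not missing
    evidence).
    """
    out = []
    for i, cand in enumerate(candidates):
        if i not in abundance_records:
            raise InputContractError(
                f"candidate {i} lacks an abundance record"
            )
        if abundance_records[i].read_support >= min_support:
            out.append(cand)
    return out


def load_expression_table(path: str | Path) -> pd.DataFrame:
    """Load a quantifier output TSV with columns feature_id, count, tpm.

    Missing count or tpm columns are tolerated (filled with 0); CPM is
    derived from counts when present.
    """
    p = Path(path)
    if not p.exists():
        raise InputContractError(f"expression table not found: {p}")
    df = pd.read_csv(p, sep="\t")
    if "feature_id" not in df.columns:
        df = df.rename(columns={df.columns[0]: "feature_id"})
    for col in ("count", "tpm"):
        if col not in df.columns:
            df[col] = 0.0
    total = df["count"].sum()
    df["cpm"] = df["count"] / total * 1e6 if total > 0 else 0.0
    return df.set_index("feature_id")


def load_count_table(path: str | Path) -> Dict[str, float]:
    """Load a two-column (feature_id, count) TSV into a dict."""
    p = Path(path)
    if not p.exists():
        raise InputContractError(f"count table not found: {p}")
    df = pd.read_csv(p, sep="\t")
    if df.shape[1] < 2:
        raise InputContractError(f"count table needs two columns: {p}")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(float)))
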