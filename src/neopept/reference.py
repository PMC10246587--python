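"""Reference genome and annotation handling.

Loads multi-record FASTA genomes, builds per-transcript coding models from
GTF annotation, and extracts/translates spliced coding sequences.

Coordinate conventions
----------------------
All intervals are stored internally as 0-based, half-open ``(start, end)``
tuples in genomic orientation. GTF input (1-based, inclusive) is converted
at the boundary; helpers are provided to print intervals back in the 1-based
inclusive community convention for logs and reports.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

Interval = Tuple[int, int]

STOP = "*"


class InputContractError(ValueError):
    """Raised when an input file violates its documented contract."""


@dataclass(frozen=True)
class GenomeSequence:
    """One reference contig: name plus uppercase DNA over {A,C,G,T,N}."""

    contig_name: str
    sequence: str

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


@dataclass
class TranscriptModel:
    """Gene/transcript identity plus ordered exon and CDS intervals.

    Exons and CDS intervals are kept in genomic (ascending-start) order
    regardless of strand; :func:`extract_cds` handles orientation. A
    transcript without CDS features is retained and flagged non-coding.
    """

    transcript_id: str
    gene_id: str
    gene_name: str
    contig: str
    strand: str
    exons: List[Interval] = field(default_factory=list)
    cds_intervals: List[Interval] = field(default_factory=list)
    coding_start_phase: int = 0

    @property
    def is_coding(self) -> bool:
        return bool(self.cds_intervals)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def cds_offset_of(self, genomic_pos: int) -> int:
        """Map a genomic position (0-based) to its offset in the spliced,
        phase-trimmed CDS. Raises ValueError if the position is not in the CDS.
        """
        running = 0
        if self.strand == "+":
            for s, e in self.cds_intervals:
                if s <= genomic_pos < e:
                    off = running + (genomic_pos - s)
                    return off - self.coding_start_phase
                running += e - s
        else:
            for s, e in reversed(self.cds_intervals):
                if s <= genomic_pos < e:
                    off = running + (e - 1 - genomic_pos)
                    return off - self.coding_start_phase
                running += e - s
        raise ValueError(
            f"position {genomic_pos} not in CDS of {self.transcript_id}"
        )

    def contains_in_cds(self, genomic_pos: int) -> bool:
        return any(s <= genomic_pos < e for s, e in self.cds_intervals)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved upper)."""
    return str(Seq(seq).reverse_complement())


def load_genome(fasta_path: str | Path) -> Dict[str, GenomeSequence]:
    """Load a multi-record FASTA into a contig-name keyed map.

    Sequences are uppercased (soft-masking is irrelevant downstream).
    Duplicate contig names and empty files are hard errors.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise InputContractError(f"genome FASTA not found: {path}")
    genome: Dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise InputContractError(f"duplicate contig name in FASTA: {rec.id}")
        genome[rec.id] = GenomeSequence(rec.id, str(rec.seq).upper())
    if not genome:
        raise InputContractError(f"FASTA contains no records: {path}")
    return genome


def build_transcript_models(gtf_path: str | Path) -> List[TranscriptModel]:
    """Build :class:`TranscriptModel` objects from a GTF file.

    Exon and CDS features are grouped per ``transcript_id`` and sorted by
    genomic start; GTF 1-based inclusive coordinates become 0-based
    half-open. Transcripts whose CDS escapes the exon union are rejected
    with a warning (annotation defect), not a hard error. Transcripts with
    exons but no CDS are retained as non-coding.
    """
    path = Path(gtf_path)
    if not path.exists():
        raise InputContractError(f"GTF not found: {path}")
    if not path.read_text().strip():
        return []  # empty annotation: a valid (if degenerate) run
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    by_tx: Dict[str, TranscriptModel] = {}
    phase_feats: Dict[str, List[Tuple[int, int, int]]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tx_id = feat.attributes.get("transcript_id", [None])[0]
        if tx_id is None:
            continue
        gene_id = feat.attributes.get("gene_id", [tx_id])[0]
        gene_name = feat.attributes.get("gene_name", [gene_id])[0]
        model = by_tx.setdefault(
            tx_id,
            TranscriptModel(
                transcript_id=tx_id,
                gene_id=gene_id,
                gene_name=gene_name,
                contig=feat.seqid,
                strand=feat.strand,
            ),
        )
        iv = (feat.start - 1, feat.end)  # GTF 1-based inclusive -> 0-based half-open
        if feat.featuretype == "exon":
            model.exons.append(iv)
        else:
            model.cds_intervals.append(iv)
            frame = feat.frame if feat.frame in ("0", "1", "2") else "0"
            phase_feats.setdefault(tx_id, []).append((iv[0], iv[1], int(frame)))

    models: List[TranscriptModel] = []
    for tx_id, model in by_tx.items():
        model.exons.sort()
        model.cds_intervals.sort()
        if model.is_coding and not _cds_within_exons(model):
            logger.warning(
                "transcript %s rejected: CDS feature outside exon union", tx_id
            )
            continue
        if model.is_coding:
            feats = sorted(phase_feats[tx_id])
            # phase of the 5'-most CDS feature in transcription order
            first = feats[0] if model.strand == "+" else feats[-1]
            model.coding_start_phase = first[2]
        models.append(model)
    return models


def _cds_within_exons(model: TranscriptModel) -> bool:
    for cs, ce in model.cds_intervals:
        if not any(es <= cs and ce <= ee for es, ee in model.exons):
            return False
    return True


def extract_intervals(
    genome: Dict[str, GenomeSequence],
    contig: str,
    intervals: Sequence[Interval],
    strand: str,
) -> str:
    """Concatenate genomic intervals in transcription order.

    Intervals are given in genomic order; for the minus strand the
    concatenation is reverse complemented.
    """
    if contig not in genome:
        raise InputContractError(f"contig {contig!r} absent from genome")
    seq = genome[contig].sequence
    for s, e in intervals:
        if s < 0 or e > len(seq) or s >= e:
            raise InputContractError(
                f"interval ({s},{e}) exceeds bounds of contig {contig} "
                f"(length {len(seq)})"
            )
    joined = "".join(seq[s:e] for s, e in intervals)
    if strand == "-":
        joined = reverse_complement(joined)
    return joined


def extract_cds(genome: Dict[str, GenomeSequence], transcript: TranscriptModel) -> str:
    """Spliced CDS of a coding transcript, in transcription order.

    The ``coding_start_phase`` bases are trimmed from the 5' end so that
    translation can start at offset 0.
    """
    if not transcript.is_coding:
        raise ValueError(f"transcript {transcript.transcript_id} is non-coding")
    nt = extract_intervals(
        genome, transcript.contig, transcript.cds_intervals, transcript.strand
    )
    return nt[transcript.coding_start_phase :]


def translate(nt: str, to_first_stop: bool = False) -> str:
    """Translate DNA with NCBI table 1.

    A trailing partial codon is ignored. Codons containing N translate to
    'X'. With ``to_first_stop`` the translation ends before the first stop
    codon (the stop symbol is not emitted); otherwise stops appear as '*'.
    A sequence shorter than one codon yields the empty string.
    """
    usable = len(nt) - len(nt) % 3
    if usable < 3:
        return ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aa = str(Seq(nt[:usable]).translate(table=1))
    if to_first_stop:
        stop = aa.find(STOP)
        if stop != -1:
            aa = aa[:stop]
    return aa


def to_one_based(iv: Interval) -> Tuple[int, int]:
    """Internal 0-based half-open interval -> 1-based inclusive for display."""
    return iv[0] + 1, iv[1]


def format_origin(
    contig: str, intervals: Iterable[Interval], strand: str
) -> str:
    """Human-readable origin string, 1-based inclusive, e.g. chr1:5-12(+)."""
    parts = ",".join(f"{s + 1}-{e}" for s, e in intervals)
    return f"{contig}:{parts}({strand})"
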