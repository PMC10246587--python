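"""pMHC feature prediction (pluggable), per-source filtering, and the
harmonized prioritization report.

Binding predictors are integrated as adapters only: either the built-in
deterministic mock (a pure, seeded function of peptide and allele, so whole
runs are reproducible without external binaries) or a parser over a
NetMHCpan-style output file. No subprocess is ever launched here.
"""

from __future__ import annotations

import hashlib
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Protocol, Sequence, Tuple

import pandas as pd

from .quantify import AbundanceRecord
from .reference import InputContractError
from .sources import PeptideCandidate, SourceClass

logger = logging.getLogger(__name__)

_ALLELE_RE = re.compile(r"^HLA-[A-Z]+\*\d{2,3}:\d{2,3}$")


@dataclass(frozen=True)
class HlaAllele:
    """An MHC class I allele in 4-digit nomenclature, e.g. HLA-A*02:01."""

    name: str

    def __post_init__(self):
        if not _ALLELE_RE.match(self.name):
            raise InputContractError(
                f"invalid HLA allele string: {self.name!r} "
                "(expected e.g. HLA-A*02:01)"
            )

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.name


def load_alleles(path: str | Path) -> List[HlaAllele]:
    """One allele per line; duplicates removed, order preserved."""
    p = Path(path)
    if not p.exists():
        raise InputContractError(f"HLA allele list not found: {p}")
    seen, out = set(), []
    for line in p.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line not in seen:
            seen.add(line)
            out.append(HlaAllele(line))
    return out


@dataclass(frozen=True)
class PMHCRecord:
    peptide: str
    allele: HlaAllele
    affinity_nM: Optional[float]
    stability_halflife_h: Optional[float] = None
    processing_score: Optional[float] = None
    presentation_score: Optional[float] = None
    immunogenicity_score: Optional[float] = None
    dissimilarity: Optional[float] = None
    foreignness: Optional[float] = None
    agretopicity: Optional[float] = None
    error: Optional[str] = None


class Predictor(Protocol):
    """Adapter contract: map (peptide, allele) to a pMHC feature dict."""

    def predict(self, peptide: str, allele: str) -> Dict[str, float]: ...


class MockPredictor:
    """Deterministic stand-in predictor for offline, reproducible runs.

    Affinity and stability are pure functions of (seed, peptide, allele)
    via SHA-256: affinity is log-uniform over [1, 50000] nM (the span MHC
    binding predictors report) and stability half-life uniform over
    [0, 12] h. Identical inputs always give identical outputs.
    """

    def __init__(self, seed: int = 0):
        self.seed = int(seed)

    def _unit(self, tag: str, peptide: str, allele: str) -> float:
        digest = hashlib.sha256(
            f"{self.seed}|{tag}|{peptide}|{allele}".encode()
        ).digest()
        return int.from_bytes(digest[:8], "big") / 2**64

    def predict(self, peptide: str, allele: str) -> Dict[str, float]:
        u_aff = self._unit("affinity", peptide, allele)
        u_stab = self._unit("stability", peptide, allele)
        return {
            "affinity_nM": math.exp(u_aff * math.log(50000.0)),
            "stability_halflife_h": 12.0 * u_stab,
        }


class NetMHCpanFileAdapter:
    """Predictor backed by a parsed NetMHCpan-style output table.

    Accepts the whitespace-delimited peptide lines of NetMHCpan's ``-BA``
    text output (columns include Peptide, the allele, and Aff(nM)). Pairs
    absent from the file raise KeyError, which predict_pmhc records as a
    flagged record.
    """

    def __init__(self, path: str | Path):
        self.table = parse_netmhcpan_output(path)

    def predict(self, peptide: str, allele: str) -> Dict[str, float]:
        return {"affinity_nM": self.table[(peptide, allele)]}


def parse_netmhcpan_output(path: str | Path) -> Dict[Tuple[str, str], float]:
    """Parse (peptide, allele) -> affinity nM from NetMHCpan-format text."""
    p = Path(path)
    if not p.exists():
        raise InputContractError(f"predictor output not found: {p}")
    out: Dict[Tuple[str, str], float] = {}
    for line in p.read_text().splitlines():
        fields = line.split()
        if len(fields) < 4 or not fields[0].isdigit():
            continue
        # NetMHCpan peptide lines: pos, allele, peptide, ..., Aff(nM) near end
        allele = fields[1].replace("HLA-A", "HLA-A*") if "*" not in fields[1] else fields[1]
        peptide = fields[2]
        aff = None
        for f in reversed(fields):
            try:
                val = float(f)
            except ValueError:
                continue
            aff = val
            break
        if aff is not None:
            out[(peptide, allele)] = aff
    return out


def predict_pmhc(
    candidates: Sequence[PeptideCandidate],
    alleles: Sequence[HlaAllele],
    predictor: Predictor,
) -> List[PMHCRecord]:
    """One record per (candidate peptide, allele) pair.

    Agretopicity (mutant/wild-type affinity ratio) is filled when the
    candidate carries a positionally aligned wild-type peptide; classes
    without a wild-type counterpart leave it absent. A predictor failure
    on a pair yields a flagged record and the run continues.
    """
    records: List[PMHCRecord] = []
    seen = set()
    for cand in candidates:
        for allele in alleles:
            key = (cand.peptide, allele.name)
            if key in seen:
                continue
            seen.add(key)
            try:
                feats = predictor.predict(cand.peptide, allele.name)
            except Exception as exc:
                records.append(
                    PMHCRecord(
                        peptide=cand.peptide,
                        allele=allele,
                        affinity_nM=None,
                        error=str(exc) or exc.__class__.__name__,
                    )
                )
                continue
            agre = None
            if cand.wt_peptide is not None:
                try:
                    wt_aff = predictor.predict(cand.wt_peptide, allele.name).get(
                        "affinity_nM"
                    )
                    mut_aff = feats.get("affinity_nM")
                    if wt_aff and mut_aff:
                        agre = agretopicity(mut_aff, wt_aff)
                except Exception:
                    agre = None
            records.append(
                PMHCRecord(
                    peptide=cand.peptide,
                    allele=allele,
                    affinity_nM=feats.get("affinity_nM"),
                    stability_halflife_h=feats.get("stability_halflife_h"),
                    processing_score=feats.get("processing_score"),
                    presentation_score=feats.get("presentation_score"),
                    immunogenicity_score=feats.get("immunogenicity_score"),
                    dissimilarity=feats.get("dissimilarity"),
                    foreignness=feats.get("foreignness"),
                    agretopicity=agre,
                )
            )
    return records


def agretopicity(
    mutant_affinity_nM: float, wildtype_affinity_nM: float
) -> float:
    """Mutant/wild-type binding affinity ratio; < 1 means the mutant binds
    tighter than its normal counterpart."""
    if mutant_affinity_nM <= 0 or wildtype_affinity_nM <= 0:
        raise ValueError("affinities must be positive")
    return mutant_affinity_nM / wildtype_affinity_nM


@dataclass
class FilterConfig:
    """Per-source report filters.

    ``affinity_ceilings`` maps source class to a strict nM ceiling; the
    CTA/self class defaults to the stringent 50 nM rule, all other classes
    to the community 500 nM convention. A ``None`` ceiling disables the
    affinity filter for that class. ``stability_floors`` (hours) are
    optional. ``min_read_support`` applies to every row.
    """

    affinity_ceilings: Dict[SourceClass, Optional[float]] = field(
        default_factory=lambda: {
            **{sc: 500.0 for sc in SourceClass},
            SourceClass.CTA_SELF: 50.0,
        }
    )
    stability_floors: Dict[SourceClass, float] = field(default_factory=dict)
    min_read_support: int = 1


REPORT_COLUMNS = [
    "source_class",
    "peptide",
    "allele",
    "gene_id",
    "transcript_id",
    "origin",
    "coding_nt",
    "affinity_nM",
    "stability_halflife_h",
    "agretopicity",
    "read_support",
    "origin_read_total",
    "tpm",
    "caller_provenance",
    "clonality",
]


def assemble_report(
    candidates: Sequence[PeptideCandidate],
    pmhc_records: Sequence[PMHCRecord],
    abundance: Dict[int, AbundanceRecord],
    expression: Optional[Dict[str, float]] = None,
    provenance: Optional[Dict[str, str]] = None,
    clonality: Optional[Dict[str, float]] = None,
) -> pd.DataFrame:
    """Join candidates, pMHC features, and abundance into the final table.

    One row per (peptide, allele, source_class, origin, coding_nt);
    deterministic sort
    by source class, then ascending affinity, then descending read support,
    ties broken lexicographically by peptide then allele. A candidate
    without an abundance record is a hard error — it means the pipeline
    wiring dropped a quantification step.
    """
    pmhc_by_pep: Dict[str, List[PMHCRecord]] = {}
    for rec in pmhc_records:
        pmhc_by_pep.setdefault(rec.peptide, []).append(rec)

    rows = []
    seen = set()
    for i, cand in enumerate(candidates):
        if i not in abundance:
            raise InputContractError(
                f"candidate {cand.peptide} ({cand.source_class.value}) lacks "
                "an abundance record"
            )
        ab = abundance[i]
        for rec in pmhc_by_pep.get(cand.peptide, []):
            # coding_nt is part of the key: distinct windows of one origin can
            # encode the same peptide through different nucleotide sequences
            key = (
                cand.peptide,
                rec.allele.name,
                cand.source_class.value,
                cand.origin,
                cand.coding_nt,
            )
            if key in seen:
                continue
            seen.add(key)
            rows.append(
                {
                    "source_class": cand.source_class.value,
                    "peptide": cand.peptide,
                    "allele": rec.allele.name,
                    "gene_id": cand.gene_id or "",
                    "transcript_id": cand.transcript_id or "",
                    "origin": cand.origin,
                    "coding_nt": cand.coding_nt,
                    "affinity_nM": rec.affinity_nM,
                    "stability_halflife_h": rec.stability_halflife_h,
                    "agretopicity": rec.agretopicity,
                    "read_support": ab.read_support,
                    "origin_read_total": ab.origin_read_total,
                    "tpm": (expression or {}).get(cand.transcript_id or "", ""),
                    "caller_provenance": (provenance or {}).get(cand.origin, ""),
                    "clonality": (clonality or {}).get(cand.origin, ""),
                }
            )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if not df.empty:
        df = df.sort_values(
            by=["source_class", "affinity_nM", "read_support", "peptide", "allele"],
            ascending=[True, True, False, True, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def filter_report(df: pd.DataFrame, config: FilterConfig) -> pd.DataFrame:
    """Apply per-source affinity ceilings, stability floors, and the
    read-support floor. Row order is preserved; output is a subset."""
    if df.empty:
        return df
    keep = []
    for _, row in df.iterrows():
        sc = SourceClass(row["source_class"])
        ceiling = config.affinity_ceilings.get(sc, 500.0)
        if ceiling is not None:
            aff = row["affinity_nM"]
            if aff is None or pd.isna(aff) or not aff < ceiling:
                keep.append(False)
                continue
        floor = config.stability_floors.get(sc)
        if floor is not None:
            stab = row["stability_halflife_h"]
            if stab is None or pd.isna(stab) or stab < floor:
                keep.append(False)
                continue
        if row["read_support"] < config.min_read_support:
            keep.append(False)
            continue
        keep.append(True)
    return df[pd.Series(keep, index=df.index)].copy()


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    """Write the report TSV with a stable header and float format, so that
    identical inputs produce byte-identical files."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
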