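"""Promoter extraction and LBD-motif (5'-GCGGCG-3') scanning.

Promoters are the ``promoter_len`` bases immediately upstream of the ATG
translation start, strand-corrected so the stored sequence reads 5'->3'
toward the ATG. Scanning is exact sliding-window matching; overlapping
occurrences count, and N never matches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import ValidationError, reverse_complement

__all__ = ["MotifHits", "extract_promoters", "scan_lbd", "motif_set_summary",
           "LBD_MOTIF"]

LBD_MOTIF = "GCGGCG"


@dataclass
class MotifHits:
    """Match offsets (0-based within the promoter) per strand for one gene."""

    gene_id: str
    offsets: list[int] = field(default_factory=list)
    strands: list[str] = field(default_factory=list)

    @property
    def has_motif(self) -> bool:
        return bool(self.offsets)


def extract_promoters(
    annotation: pd.DataFrame,
    genome: Mapping[str, str],
    promoter_len: int = 1000,
) -> dict[str, str]:
    """Extract strand-corrected upstream promoter windows from a genome.

    For a + strand gene with the A of its ATG at 1-based position p, the
    promoter is bases [p - L, p - 1]; for a - strand gene it is bases
    [p + 1, p + L] reverse-complemented. Windows are clipped at contig
    bounds with a warning; genes with unknown strand are skipped.
    """
    out: dict[str, str] = {}
    for gene, row in annotation.iterrows():
        chrom, strand, atg = row.get("chrom"), row.get("strand"), row.get("atg_pos")
        if pd.isna(chrom) or pd.isna(atg):
            continue
        if pd.isna(strand) or strand not in ("+", "-"):
            warnings.warn(f"gene {gene!r}: unknown strand; skipped")
            continue
        if chrom not in genome:
            raise ValidationError(f"gene {gene!r}: contig {chrom!r} not in genome")
        contig = genome[chrom]
        atg = int(atg)
        if not 1 <= atg <= len(contig):
            raise ValidationError(
                f"gene {gene!r}: atg_pos {atg} beyond contig {chrom!r} "
                f"(length {len(contig)})"
            )
        if strand == "+":
            start = max(atg - 1 - promoter_len, 0)   # 0-based half-open
            end = atg - 1
            seq = contig[start:end]
        else:
            start = atg                               # 0-based: base after ATG's A
            end = min(atg + promoter_len, len(contig))
            seq = reverse_complement(contig[start:end])
        if len(seq) < promoter_len:
            warnings.warn(
                f"gene {gene!r}: promoter clipped to {len(seq)} bp at contig edge"
            )
        out[str(gene)] = seq.upper()
    return out


def scan_lbd(
    promoter: str,
    motif: str = LBD_MOTIF,
    both_strands: bool = False,
    gene_id: str = "",
) -> MotifHits:
    """All exact (overlapping) occurrences of the motif in one promoter."""
    motif = motif.upper()
    if set(motif) - set("ACGT"):
        raise ValidationError(f"motif {motif!r} contains non-ACGT characters")
    seq = promoter.upper()
    hits = MotifHits(gene_id=gene_id)
    k = len(motif)
    targets = [("+", motif)]
    if both_strands:
        targets.append(("-", reverse_complement(motif)))
    for strand, pat in targets:
        for i in range(len(seq) - k + 1):
            if seq[i:i + k] == pat:
                hits.offsets.append(i)
                hits.strands.append(strand)
    order = np.argsort(hits.offsets, kind="stable")
    hits.offsets = [hits.offsets[i] for i in order]
    hits.strands = [hits.strands[i] for i in order]
    return hits


def scan_promoter_set(
    promoters: Mapping[str, str],
    motif: str = LBD_MOTIF,
    both_strands: bool = False,
) -> dict[str, MotifHits]:
    return {
        g: scan_lbd(seq, motif=motif, both_strands=both_strands, gene_id=g)
        for g, seq in promoters.items()
    }


def motif_set_summary(
    hits: Mapping[str, MotifHits],
    gene_sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per gene set: how many members carry >= 1 motif, with the fraction.

    Raises when a set contains unscanned genes; empty sets report NA.
    Percentages are rounded to the nearest integer for display.
    """
    rows = []
    for name, genes in gene_sets.items():
        genes = list(dict.fromkeys(genes))
        missing = [g for g in genes if g not in hits]
        if missing:
            raise ValidationError(
                f"set {name!r}: {len(missing)} gene(s) not scanned "
                f"(first: {missing[0]!r})"
            )
        n = len(genes)
        k = sum(1 for g in genes if hits[g].has_motif)
        frac = k / n if n else float("nan")
        rows.append({
            "set": name, "n_with_motif": k, "n_total": n,
            "fraction": frac,
            "percent": int(round(100 * frac)) if n else pd.NA,
        })
    return pd.DataFrame(rows).set_index("set")
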