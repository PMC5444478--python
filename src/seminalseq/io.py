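"""Domain containers and readers/writers for the tabular and sequence formats
the pipeline touches.

All genomic coordinates in files are 1-based inclusive (GFF convention);
in-memory offsets (e.g. motif hit positions) are 0-based half-open.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SampleMeta",
    "CountMatrix",
    "ContingencyTable2x2",
    "FormatError",
    "ValidationError",
    "read_counts",
    "write_counts",
    "read_annotation",
    "write_annotation",
    "read_fasta",
    "write_fasta",
    "SYNTENY_CLASSES",
]

SYNTENY_CLASSES = ("SYNTENIC", "NON_SYNTENIC", "UNKNOWN")
GENOTYPES = ("WT", "MUT")

META_FIELDS = ("genotype", "stage", "replicate", "lane")

DNA_ALPHABET = frozenset("ACGTN")


class FormatError(ValueError):
    """Malformed file content (wrong type, bad cell), with location."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a domain invariant."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one RNA-seq library.

    genotype is "WT" or "MUT"; stage is in days after pollination
    (25/30/35 in the reference design, but any integer set is accepted);
    lane is the sequencing-lane label used as a blocking factor.
    """

    sample_id: str
    genotype: str
    stage: int
    replicate: int
    lane: str

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValidationError(
                f"sample {self.sample_id!r}: genotype must be one of {GENOTYPES}, "
                f"got {self.genotype!r}"
            )
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )

    @property
    def cell(self) -> tuple[str, int]:
        """The (genotype, stage) design cell this sample belongs to."""
        return (self.genotype, self.stage)


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, with per-sample metadata.

    ``counts`` is a pandas DataFrame indexed by gene id with one column per
    sample, in the same order as ``samples``.
    """

    counts: pd.DataFrame
    samples: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate sample ids in metadata")
        if list(self.counts.columns) != ids:
            raise ValidationError(
                "count matrix columns do not match sample metadata order"
            )
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id {dup!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            raise ValidationError("counts must be integers")
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def meta(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame indexed by sample id."""
        return pd.DataFrame(
            {
                "genotype": [s.genotype for s in self.samples],
                "stage": [s.stage for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
                "lane": [s.lane for s in self.samples],
            },
            index=pd.Index([s.sample_id for s in self.samples], name="sample_id"),
        )

    def cells(self) -> list[tuple[str, int]]:
        """Distinct (genotype, stage) cells, genotype-major, stages ascending."""
        genotypes = sorted({s.genotype for s in self.samples}, reverse=True)  # WT first
        stages = sorted({s.stage for s in self.samples})
        return [(g, t) for g in genotypes for t in stages]

    def cell_columns(self) -> dict[tuple[str, int], list[int]]:
        """Map each (genotype, stage) cell to its sample column indices."""
        out: dict[tuple[str, int], list[int]] = {c: [] for c in self.cells()}
        for j, s in enumerate(self.samples):
            out[s.cell].append(j)
        return out

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)], list(self.samples))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 contingency table; rows = in-set/out-of-set, columns = property yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in cells):
            raise ValidationError(f"negative cell in contingency table {cells}")
        if sum(cells) == 0:
            raise ValidationError("contingency table grand total is zero")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


# ---------------------------------------------------------------------------
# counts TSV
# ---------------------------------------------------------------------------

def _parse_inline_meta(lines: list[str], sample_ids: list[str]) -> list[SampleMeta]:
    fields: dict[str, list[str]] = {}
    for line in lines:
        parts = line.lstrip("#").rstrip("\n").split("\t")
        key = parts[0].strip().lower()
        if key in META_FIELDS:
            if len(parts) - 1 != len(sample_ids):
                raise FormatError(
                    f"metadata line {key!r} has {len(parts) - 1} values for "
                    f"{len(sample_ids)} samples"
                )
            fields[key] = [p.strip() for p in parts[1:]]
    missing = [k for k in META_FIELDS if k not in fields]
    if missing:
        raise FormatError(f"inline metadata is missing line(s): {', '.join(missing)}")
    return [
        SampleMeta(
            sample_id=sid,
            genotype=fields["genotype"][j],
            stage=int(fields["stage"][j]),
            replicate=int(fields["replicate"][j]),
            lane=fields["lane"][j],
        )
        for j, sid in enumerate(sample_ids)
    ]


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read a sample metadata TSV (sample_id, genotype, stage, replicate, lane)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    required = ("sample_id",) + META_FIELDS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: metadata missing column(s) {missing}")
    return [
        SampleMeta(
            sample_id=row["sample_id"],
            genotype=row["genotype"],
            stage=int(row["stage"]),
            replicate=int(row["replicate"]),
            lane=row["lane"],
        )
        for _, row in df.iterrows()
    ]


def read_counts(path: str | Path, meta_path: str | Path | None = None) -> CountMatrix:
    """Read a genes-in-rows counts TSV into a :class:`CountMatrix`.

    Sample metadata comes either from ``meta_path`` (a separate TSV) or from
    '#'-prefixed header lines in the counts file itself
    (``#genotype<TAB>WT<TAB>...`` etc.). An explicit ``meta_path`` takes
    precedence over inline lines.
    """
    path = Path(path)
    meta_lines: list[str] = []
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            meta_lines.append(line)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    sample_ids = [str(c) for c in df.columns]
    df.columns = sample_ids
    df.index = df.index.astype(str)
    df.index.name = "gene_id"

    # locate non-integer / negative cells with a named error
    for col in df.columns:
        series = df[col]
        numeric = pd.to_numeric(series, errors="coerce")
        if numeric.isna().any():
            gene = series.index[numeric.isna()][0]
            raise FormatError(
                f"{path}: non-numeric count at gene {gene!r}, sample {col!r}"
            )
        if (numeric % 1 != 0).any():
            gene = series.index[numeric % 1 != 0][0]
            raise FormatError(
                f"{path}: non-integer count at gene {gene!r}, sample {col!r}"
            )
        if (numeric < 0).any():
            gene = series.index[numeric < 0][0]
            raise FormatError(
                f"{path}: negative count at gene {gene!r}, sample {col!r}"
            )
    df = df.astype(np.int64)

    if meta_path is not None:
        samples = read_sample_meta(meta_path)
        order = {s.sample_id: s for s in samples}
        missing = [sid for sid in sample_ids if sid not in order]
        if missing:
            raise FormatError(f"{meta_path}: no metadata for sample(s) {missing}")
        samples = [order[sid] for sid in sample_ids]
    elif meta_lines:
        samples = _parse_inline_meta(meta_lines, sample_ids)
    else:
        raise FormatError(
            f"{path}: no sample metadata (no '#' header lines and no meta_path)"
        )
    return CountMatrix(df, samples)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write counts with inline '#' metadata header lines (read_counts inverse)."""
    with open(path, "w") as fh:
        for key in META_FIELDS:
            vals = [str(getattr(s, key)) for s in cm.samples]
            fh.write("#" + key + "\t" + "\t".join(vals) + "\n")
        buf = _io.StringIO()
        cm.counts.to_csv(buf, sep="\t", index_label="gene_id")
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# gene annotation TSV
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = (
    "gene_id",
    "length_bp",
    "gc",
    "synteny",
    "category",
    "tf_family",
    "chrom",
    "strand",
    "atg_pos",
)


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read the per-gene annotation TSV.

    Required columns: ``gene_id`` and ``length_bp``. Optional: ``gc``,
    ``synteny``, ``category``, ``tf_family``, ``chrom``, ``strand``,
    ``atg_pos``. Missing optional columns are created as UNKNOWN/NaN, never
    fabricated from other fields. Returns a DataFrame indexed by gene_id.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    df.columns = [c.strip().lower() for c in df.columns]
    for col in ("gene_id", "length_bp"):
        if col not in df.columns:
            raise FormatError(f"{path}: annotation missing required column {col!r}")
    if df["gene_id"].duplicated().any():
        dup = df["gene_id"][df["gene_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate gene id {dup!r}")
    df = df.set_index("gene_id")

    df["length_bp"] = pd.to_numeric(df["length_bp"], errors="raise")
    if (df["length_bp"] < 1).any():
        gene = df.index[df["length_bp"] < 1][0]
        raise ValidationError(f"{path}: gene {gene!r} has length_bp < 1")
    df["length_bp"] = df["length_bp"].astype(np.int64)

    if "gc" in df.columns:
        df["gc"] = pd.to_numeric(df["gc"], errors="raise")
        bad = (df["gc"] < 0) | (df["gc"] > 1)
        if bad.any():
            gene = df.index[bad][0]
            raise ValidationError(
                f"{path}: gene {gene!r} has gc={df.loc[gene, 'gc']} outside [0, 1]"
            )
    else:
        df["gc"] = np.nan

    if "synteny" in df.columns:
        df["synteny"] = df["synteny"].fillna("UNKNOWN").astype(str).str.upper()
        bad = ~df["synteny"].isin(SYNTENY_CLASSES)
        if bad.any():
            gene = df.index[bad][0]
            raise ValidationError(
                f"{path}: gene {gene!r} has unknown synteny class "
                f"{df.loc[gene, 'synteny']!r}"
            )
    else:
        df["synteny"] = "UNKNOWN"

    for col in ("category", "tf_family", "chrom", "strand"):
        if col not in df.columns:
            df[col] = pd.NA

    if "atg_pos" in df.columns:
        df["atg_pos"] = pd.to_numeric(df["atg_pos"], errors="raise").astype("Int64")
        if (df["atg_pos"].dropna() < 1).any():
            raise ValidationError(f"{path}: atg_pos must be >= 1 (1-based)")
    else:
        df["atg_pos"] = pd.array([pd.NA] * len(df), dtype="Int64")

    return df[list(ANNOTATION_COLUMNS[1:])]


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    annotation.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into {record id: uppercase sequence}; alphabet {A,C,G,T,N}."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty record {rec.id!r}")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains non-IUPAC-DNA "
                f"character(s) {sorted(bad)}"
            )
        if rec.id in out:
            raise ValidationError(f"{path}: duplicate record id {rec.id!r}")
        out[rec.id] = seq
    return out


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(seq.upper()), id=name, description="")
        for name, seq in seqs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
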