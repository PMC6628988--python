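"""sgRNA library, count-table and read-counting I/O.

The countable unit of a pooled CRISPR screen is the sgRNA spacer (19 nt by
default) amplified from the integrated lentiviral cassette.  Because the
amplicon is fully determined by the cloning vector, spacers are recovered
from merged single-end reads by locating the two constant flanking
sequences and taking the bases between them; assignment to the library is
by exact sequence match (no mismatches), so sequencing errors inside the
spacer simply leave the read unassigned.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "SgRNARecord",
    "ScreenCountTable",
    "ReadBatch",
    "parse_library",
    "write_library",
    "extract_spacer",
    "count_spacers",
    "read_counts",
    "write_counts",
    "read_fastq",
]

_VALID_BASES = re.compile(r"^[ACGT]+$")

SAMPLE_SHEET_COLUMNS = ["sample_id", "condition", "replicate_id", "paired_control_id"]
CONDITIONS = ("pre_induction", "induced")


@dataclass(frozen=True)
class SgRNARecord:
    """One library entry: a guide, its spacer and its target gene."""

    sgrna_id: str
    spacer: str
    gene_id: str
    is_negative_control: bool


@dataclass
class ReadBatch:
    """Merged single-end reads plus the constant flanks bracketing the spacer."""

    reads: Sequence[str]
    flank5: str
    flank3: str

    def __post_init__(self) -> None:
        if not self.flank5 or not self.flank3:
            raise ValueError("flank5 and flank3 must be non-empty")


@dataclass
class ScreenCountTable:
    """sgRNA x sample integer counts with the sample pairing metadata.

    ``counts`` is indexed by sgrna_id with one column per sample_id;
    ``samples`` carries (sample_id, condition, replicate_id,
    paired_control_id) with each induced sample naming exactly one
    pre-induction sample as its paired control.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.samples = self.samples.reset_index(drop=True).copy()
        missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        validate_counts_matrix(self.counts)
        sample_ids = list(self.samples["sample_id"])
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample_id in sample sheet")
        unknown = [c for c in self.counts.columns if c not in sample_ids]
        if unknown:
            raise ValueError(f"count columns absent from sample sheet: {unknown}")
        for _, row in self.samples.iterrows():
            if row["condition"] not in CONDITIONS:
                raise ValueError(
                    f"sample {row['sample_id']!r}: condition must be one of {CONDITIONS}"
                )
            if row["condition"] == "induced":
                ctrl = row["paired_control_id"]
                if not isinstance(ctrl, str) or not ctrl:
                    raise ValueError(
                        f"induced sample {row['sample_id']!r} has no paired control"
                    )
                if ctrl not in sample_ids:
                    raise ValueError(
                        f"induced sample {row['sample_id']!r} pairs to missing "
                        f"sample {ctrl!r}"
                    )
                paired = self.samples.set_index("sample_id").loc[ctrl]
                if paired["condition"] != "pre_induction":
                    raise ValueError(
                        f"paired control {ctrl!r} of {row['sample_id']!r} is not "
                        "a pre_induction sample"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def pairs(self) -> list[tuple[str, str, str]]:
        """(replicate_id, induced_sample_id, control_sample_id) triples."""
        out = []
        for _, row in self.samples.iterrows():
            if row["condition"] == "induced":
                out.append(
                    (str(row["replicate_id"]), row["sample_id"], row["paired_control_id"])
                )
        return out


def validate_counts_matrix(counts: pd.DataFrame) -> None:
    arr = counts.to_numpy()
    if arr.size:
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise ValueError("counts must be integers")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
    if counts.index.has_duplicates:
        raise ValueError("duplicate sgrna_id rows in count table")


def _validate_records(records: list[SgRNARecord], spacer_length: int) -> list[SgRNARecord]:
    seen: set[str] = set()
    gene_flags: dict[str, bool] = {}
    for rec in records:
        if rec.sgrna_id in seen:
            raise ValueError(f"duplicate sgrna_id {rec.sgrna_id!r}")
        seen.add(rec.sgrna_id)
        if not _VALID_BASES.match(rec.spacer):
            raise ValueError(
                f"sgRNA {rec.sgrna_id!r}: spacer contains non-ACGT characters"
            )
        if len(rec.spacer) != spacer_length:
            raise ValueError(
                f"sgRNA {rec.sgrna_id!r}: spacer length {len(rec.spacer)} != "
                f"{spacer_length}"
            )
        prev = gene_flags.setdefault(rec.gene_id, rec.is_negative_control)
        if prev != rec.is_negative_control:
            raise ValueError(
                f"gene {rec.gene_id!r}: inconsistent is_negative_control flag"
            )
    return records


def parse_library(path, spacer_length: int = 19) -> list[SgRNARecord]:
    """Read a library TSV (sgrna_id, spacer, gene_id, is_negative_control).

    Enforces unique ids, uniform spacer length, ACGT alphabet and a
    control flag constant within each gene.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sgrna_id", "spacer", "gene_id", "is_negative_control"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"library TSV missing columns: {missing}")
    records = [
        SgRNARecord(
            sgrna_id=row.sgrna_id,
            spacer=row.spacer.upper(),
            gene_id=row.gene_id,
            is_negative_control=str(row.is_negative_control).strip().lower()
            in ("true", "1", "yes"),
        )
        for row in df.itertuples()
    ]
    return _validate_records(records, spacer_length)


def write_library(records: Iterable[SgRNARecord], path) -> None:
    df = pd.DataFrame(
        [
            {
                "sgrna_id": r.sgrna_id,
                "spacer": r.spacer,
                "gene_id": r.gene_id,
                "is_negative_control": r.is_negative_control,
            }
            for r in records
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def extract_spacer(
    read: str, flank5: str, flank3: str, spacer_length: int = 19
) -> str | None:
    """Return the spacer between the flanks, or None if the read does not match.

    The first exact occurrence of ``flank5`` anchors the spacer; the
    ``spacer_length`` bases after it are returned only when immediately
    followed by an exact ``flank3``.
    """
    i = read.find(flank5)
    if i < 0:
        return None
    start = i + len(flank5)
    end = start + spacer_length
    if read[end : end + len(flank3)] != flank3:
        return None
    spacer = read[start:end]
    if len(spacer) != spacer_length:
        return None
    return spacer


def build_spacer_index(
    library: Sequence[SgRNARecord],
) -> dict[str, str]:
    """spacer -> sgrna_id lookup; duplicate spacers are ambiguous, hence fatal."""
    index: dict[str, str] = {}
    for rec in library:
        if rec.spacer in index:
            raise ValueError(
                f"duplicate spacer shared by {index[rec.spacer]!r} and "
                f"{rec.sgrna_id!r}: exact assignment is ambiguous"
            )
        index[rec.spacer] = rec.sgrna_id
    return index


def count_spacers(
    batch: ReadBatch,
    library: Sequence[SgRNARecord],
    spacer_length: int = 19,
) -> tuple[pd.Series, int]:
    """Count exact spacer matches per library sgRNA.

    Returns a Series indexed by sgrna_id (zeros for unseen guides) and the
    number of unassigned reads; assigned + unassigned equals the batch size.
    """
    if not library:
        raise ValueError("library is empty")
    index = build_spacer_index(library)
    counts = {rec.sgrna_id: 0 for rec in library}
    unassigned = 0
    for read in batch.reads:
        spacer = extract_spacer(read, batch.flank5, batch.flank3, spacer_length)
        sgid = index.get(spacer) if spacer is not None else None
        if sgid is None:
            unassigned += 1
        else:
            counts[sgid] += 1
    out = pd.Series(counts, name="count", dtype=np.int64)
    out.index.name = "sgrna_id"
    return out, unassigned


def read_fastq(path) -> list[str]:
    """Read merged single-end FASTQ; qualities are ignored (exact matching only)."""
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fastq")]


def read_counts(counts_path, samples_path) -> ScreenCountTable:
    """Load counts TSV (first column sgrna_id) and its sample sheet TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col="sgrna_id")
    for col in counts.columns:
        vals = pd.to_numeric(counts[col], errors="raise")
        if not np.all(np.equal(np.mod(vals, 1), 0)):
            raise ValueError(f"non-integer counts in sample {col!r}")
        counts[col] = vals.astype(np.int64)
    samples = pd.read_csv(samples_path, sep="\t", dtype=str)
    samples["paired_control_id"] = samples["paired_control_id"].where(
        samples["paired_control_id"].notna(), None
    )
    return ScreenCountTable(counts=counts, samples=samples)


def write_counts(table: ScreenCountTable, counts_path, samples_path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="sgrna_id")
    samples = table.samples.copy()
    samples.to_csv(samples_path, sep="\t", index=False)
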