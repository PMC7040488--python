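"""Shared containers and plain-text I/O.

All intermediate artifacts are plain TSV/FASTA/GMT/FASTQ so that every
pipeline stage can be run, inspected and re-run standalone.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FEATURE_CLASSES = ("mRNA", "lncRNA", "miRNA")
UNITS = ("count", "FPKM", "TPM")


@dataclass
class ExpressionMatrix:
    """A features x samples expression table with sample group labels.

    ``values`` is a DataFrame whose index holds feature ids and whose
    columns are sample labels.  ``groups`` maps every sample label to its
    condition group (e.g. ``30d``).  ``lengths`` (nt per feature) is only
    required for length-aware normalization.
    """

    values: pd.DataFrame
    feature_class: str
    unit: str = "count"
    lengths: pd.Series | None = None
    groups: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature_class {self.feature_class!r}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.values.columns.duplicated().any():
            raise ValueError("sample labels must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.groups is None:
            # sample labels follow the "<group>_r<rep>" convention by default
            self.groups = pd.Series(
                [str(c).rsplit("_", 1)[0] for c in self.values.columns],
                index=self.values.columns,
            )
        else:
            self.groups = self.groups.reindex(self.values.columns)
            if self.groups.isna().any():
                missing = list(self.groups.index[self.groups.isna()])
                raise ValueError(f"samples without group label: {missing}")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.values.index)
            if (self.lengths.dropna() <= 0).any():
                raise ValueError("feature lengths must be positive")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_groups(self, groups: list[str]) -> list[str]:
        wanted = set(groups)
        return [s for s in self.samples if self.groups[s] in wanted]

    def copy_with(self, values: pd.DataFrame, unit: str) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            feature_class=self.feature_class,
            unit=unit,
            lengths=self.lengths,
            groups=self.groups.copy(),
        )


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write matrix as TSV: header row = sample ids, first column = feature id.

    Lengths, when present, are stored as a second column so the file round
    trips without a side-car.
    """
    df = matrix.values.copy()
    df.insert(0, "length", matrix.lengths if matrix.lengths is not None else pd.NA)
    if matrix.lengths is None:
        df = df.drop(columns="length")
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_expression_tsv(
    path: str | Path, feature_class: str, unit: str = "count"
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    lengths = None
    if "length" in df.columns:
        lengths = df.pop("length").astype(float)
    return ExpressionMatrix(df, feature_class=feature_class, unit=unit, lengths=lengths)


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq)
    return seqs


# ---------------------------------------------------------------------------
# GMT gene sets: term <TAB> description <TAB> member...


def write_gmt(genesets: "list", path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in genesets:
            members = "\t".join(sorted(gs.members))
            fh.write(f"{gs.term_id}\t{gs.term_name}\t{members}\n")


def read_gmt(path: str | Path) -> "list":
    from .enrich import GeneSet  # local import: avoid cycle

    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs term, description, members")
            out.append(GeneSet(term_id=parts[0], term_name=parts[1], members=set(parts[2:])))
    return out


# ---------------------------------------------------------------------------
# FASTQ


def open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def parse_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id, seq, qual) records; malformed input raises with a record hint."""
    with open_text(path) as fh:
        it = SeqIO.parse(fh, "fastq")
        n = 0
        while True:
            try:
                rec = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ near record {n + 1} "
                    f"(line ~{4 * n + 1}) in {path}: {exc}"
                ) from exc
            n += 1
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            yield rec.id, str(rec.seq), qual


def write_fastq(records: Iterator[tuple[str, str, str]] | list, path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
            n += 1
    return n
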