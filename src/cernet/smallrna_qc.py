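"""Small-RNA read cleaning: raw FASTQ -> clean tags.

Rules are applied to every read in a fixed order, and a read is charged
to the first rule it violates:

1. ``low_quality``   — more than ``max_low_quality`` bases at or below the
                       Phred threshold (Q <= 20 by default; "more than one"
                       means rejection at >= 2 such bases);
2. ``unknown_base``  — the read contains N;
3. ``missing_adapter`` — a required adapter is absent (exact substring
                       match; the 3' adapter is the first occurrence after
                       the 5' adapter);
4. ``no_insert``     — both adapters present but nothing between them;
5. ``too_short``     — insert shorter than ``min_insert_len`` (18 nt,
                       adapters excluded).

Surviving inserts keep their original read ids and are collapsed into a
(sequence, count) tag table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .io import parse_fastq

RULE_ORDER = ("low_quality", "unknown_base", "missing_adapter", "no_insert", "too_short")


@dataclass
class QCParams:
    q_threshold: int = 20
    max_low_quality: int = 1
    min_insert_len: int = 18
    adapter3: str = ""
    adapter5: str = ""
    require_adapters: bool = True

    def __post_init__(self) -> None:
        if self.min_insert_len < 1:
            raise ValueError("min_insert_len must be >= 1")
        if self.q_threshold < 0:
            raise ValueError("q_threshold must be >= 0")


@dataclass
class QCReport:
    total: int = 0
    kept: int = 0
    rejections: dict[str, int] = field(default_factory=lambda: {r: 0 for r in RULE_ORDER})

    def as_frame(self) -> pd.DataFrame:
        rows = [{"rule": "kept", "reads": self.kept}]
        rows += [{"rule": r, "reads": n} for r, n in self.rejections.items()]
        rows.append({"rule": "total", "reads": self.total})
        return pd.DataFrame(rows)


def _classify(seq: str, qual: str, params: QCParams) -> tuple[str | None, str | None]:
    """Return (insert, None) for a clean read or (None, violated rule)."""
    n_low = sum(1 for q in qual if ord(q) - 33 <= params.q_threshold)
    if n_low > params.max_low_quality:
        return None, "low_quality"
    if "N" in seq.upper():
        return None, "unknown_base"

    insert = seq
    if params.require_adapters:
        if params.adapter5:
            if not seq.startswith(params.adapter5):
                return None, "missing_adapter"
            insert = seq[len(params.adapter5) :]
        if params.adapter3:
            j = insert.find(params.adapter3)
            if j == -1:
                return None, "missing_adapter"
            insert = insert[:j]
        if not insert:
            return None, "no_insert"
    if len(insert) < params.min_insert_len:
        return None, "too_short"
    return insert, None


def clean_reads(
    reads: Iterable[tuple[str, str, str]], params: QCParams
) -> tuple[list[tuple[str, str]], QCReport]:
    """Filter (id, seq, qual) records; return surviving (id, insert) and a report.

    Conservation holds by construction: kept + sum of per-rule rejections
    equals the number of input reads.
    """
    report = QCReport()
    kept: list[tuple[str, str]] = []
    for name, seq, qual in reads:
        if len(seq) != len(qual):
            raise ValueError(f"read {name!r}: sequence and quality lengths differ")
        report.total += 1
        insert, rule = _classify(seq, qual, params)
        if rule is None:
            report.kept += 1
            kept.append((name, insert))
        else:
            report.rejections[rule] += 1
    return kept, report


def clean_fastq(path: str | Path, params: QCParams) -> tuple[list[tuple[str, str]], QCReport]:
    return clean_reads(parse_fastq(path), params)


def collapse_tags(inserts: Iterable[str]) -> pd.DataFrame:
    """Collapse clean inserts to unique tags.

    One row per unique sequence with its occurrence count; counts sum to
    the number of inserts; sorted by descending count, ties broken
    lexicographically by sequence.
    """
    counts: dict[str, int] = {}
    for s in inserts:
        if not s:
            raise ValueError("empty insert cannot be collapsed")
        counts[s] = counts.get(s, 0) + 1
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["sequence", "count"])
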