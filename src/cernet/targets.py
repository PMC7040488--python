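"""Canonical miRNA seed-match target prediction and predictor consensus.

A miRNA represses a transcript through Watson-Crick pairing of its seed
(nucleotides 2-8 counted from the miRNA 5' end) with a complementary site
— the miRNA recognition element (MRE) — on the transcript.  Sites are
graded into the four canonical classes:

* ``8mer``     — perfect match to seed positions 2-8 plus an A on the
                 transcript facing miRNA position 1;
* ``7mer-m8``  — perfect match to positions 2-8, no A1;
* ``7mer-A1``  — match to positions 2-7 plus the A1;
* ``6mer``     — match to positions 2-7 only.

Coordinates are 0-based half-open on the transcript, 5'->3'.  T and U are
interchangeable on input; the internal alphabet is DNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

SITE_TYPES = ("6mer", "7mer-A1", "7mer-m8", "8mer")
SITE_RANK = {t: i for i, t in enumerate(SITE_TYPES)}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def normalize_nt(seq: str) -> str:
    """Uppercase and convert RNA (U) to the canonical DNA alphabet."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return normalize_nt(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedSite:
    mirna_id: str
    transcript_id: str
    start: int
    end: int
    site_type: str

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site_type {self.site_type!r}")
        span = self.end - self.start
        expected = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}[self.site_type]
        if span != expected:
            raise ValueError(f"{self.site_type} site must span {expected} nt, got {span}")


@dataclass
class TargetPair:
    mirna_id: str
    transcript_id: str
    transcript_class: str = "mRNA"
    sites: list[SeedSite] = field(default_factory=list)
    support: set[str] = field(default_factory=set)

    @property
    def best_site_type(self) -> str:
        return max((s.site_type for s in self.sites), key=SITE_RANK.__getitem__)


def find_seed_sites(
    mirna_seq: str, transcript_seq: str, mirna_id: str = "miRNA", transcript_id: str = "tx"
) -> list[SeedSite]:
    """Locate every canonical seed site of ``mirna_seq`` on ``transcript_seq``.

    Each match of the reverse-complemented 6-nt seed (miRNA positions 2-7)
    yields exactly one site, upgraded to 7mer-m8/8mer when the transcript
    also pairs with miRNA position 8, and to an A1 class when the
    transcript presents an A opposite miRNA position 1.  Sites are sorted
    by start coordinate.
    """
    mirna = normalize_nt(mirna_seq)
    if len(mirna) < 8:
        raise ValueError(f"miRNA {mirna_id!r} shorter than 8 nt")
    tx = normalize_nt(transcript_seq)

    match6 = revcomp(mirna[1:7])  # seed positions 2-7
    m8_comp = revcomp(mirna[7])  # transcript base pairing miRNA position 8

    sites: list[SeedSite] = []
    j = tx.find(match6)
    while j != -1:
        has_m8 = j >= 1 and tx[j - 1] == m8_comp
        has_a1 = j + 6 < len(tx) and tx[j + 6] == "A"
        if has_m8 and has_a1:
            site = SeedSite(mirna_id, transcript_id, j - 1, j + 7, "8mer")
        elif has_m8:
            site = SeedSite(mirna_id, transcript_id, j - 1, j + 6, "7mer-m8")
        elif has_a1:
            site = SeedSite(mirna_id, transcript_id, j, j + 7, "7mer-A1")
        else:
            site = SeedSite(mirna_id, transcript_id, j, j + 6, "6mer")
        sites.append(site)
        j = tx.find(match6, j + 1)
    return sites


def predict_targets(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    min_site_type: str = "7mer-A1",
    transcript_class: str = "mRNA",
    predictor_label: str = "seedmatch",
) -> list[TargetPair]:
    """All (miRNA, transcript) pairs holding >=1 site of class >= ``min_site_type``."""
    if min_site_type not in SITE_RANK:
        raise ValueError(f"unknown site type {min_site_type!r}")
    min_rank = SITE_RANK[min_site_type]
    pairs: list[TargetPair] = []
    for mid, mseq in mirnas.items():
        for tid, tseq in transcripts.items():
            sites = [
                s
                for s in find_seed_sites(mseq, tseq, mirna_id=mid, transcript_id=tid)
                if SITE_RANK[s.site_type] >= min_rank
            ]
            if sites:
                pairs.append(
                    TargetPair(mid, tid, transcript_class, sites, {predictor_label})
                )
    return pairs


def intersect_predictions(prediction_sets: list[list[TargetPair]]) -> list[TargetPair]:
    """Consensus rule: keep pairs present in every predictor's output.

    Support labels are unioned; sites are unioned and de-duplicated by
    coordinates.  With a single collection this is the identity.
    """
    if not prediction_sets:
        raise ValueError("need at least one prediction collection")

    def key(p: TargetPair) -> tuple[str, str]:
        return (p.mirna_id, p.transcript_id)

    keysets = [set(map(key, coll)) for coll in prediction_sets]
    common = set.intersection(*keysets)

    merged: dict[tuple[str, str], TargetPair] = {}
    for coll in prediction_sets:
        for p in coll:
            k = key(p)
            if k not in common:
                continue
            if k not in merged:
                merged[k] = TargetPair(p.mirna_id, p.transcript_id, p.transcript_class)
            merged[k].support |= p.support
            seen = {(s.start, s.end, s.site_type) for s in merged[k].sites}
            for s in p.sites:
                if (s.start, s.end, s.site_type) not in seen:
                    merged[k].sites.append(s)
                    seen.add((s.start, s.end, s.site_type))
    out = [merged[k] for k in sorted(merged)]
    for p in out:
        p.sites.sort(key=lambda s: (s.start, s.end))
    return out


# ---------------------------------------------------------------------------
# TSV interchange (also used to import externally produced predictions)


def write_site_table(pairs: list[TargetPair], path: str | Path) -> None:
    rows = [
        {
            "mirna_id": p.mirna_id,
            "transcript_id": p.transcript_id,
            "transcript_class": p.transcript_class,
            "start": s.start,
            "end": s.end,
            "site_type": s.site_type,
            "support": ",".join(sorted(p.support)) or "external",
        }
        for p in pairs
        for s in p.sites
    ]
    pd.DataFrame(
        rows,
        columns=[
            "mirna_id",
            "transcript_id",
            "transcript_class",
            "start",
            "end",
            "site_type",
            "support",
        ],
    ).to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> list[TargetPair]:
    """Read a prediction TSV; only (mirna_id, transcript_id) are required."""
    df = pd.read_csv(path, sep="\t")
    for col in ("mirna_id", "transcript_id"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    pairs: dict[tuple[str, str], TargetPair] = {}
    for row in df.itertuples(index=False):
        k = (row.mirna_id, row.transcript_id)
        if k not in pairs:
            pairs[k] = TargetPair(
                row.mirna_id,
                row.transcript_id,
                getattr(row, "transcript_class", "mRNA"),
            )
        if hasattr(row, "start") and not pd.isna(row.start):
            site = SeedSite(
                row.mirna_id, row.transcript_id, int(row.start), int(row.end), row.site_type
            )
            if (site.start, site.end, site.site_type) not in {
                (s.start, s.end, s.site_type) for s in pairs[k].sites
            }:
                pairs[k].sites.append(site)
        if hasattr(row, "support") and isinstance(row.support, str):
            pairs[k].support |= set(row.support.split(","))
    return [pairs[k] for k in sorted(pairs)]
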