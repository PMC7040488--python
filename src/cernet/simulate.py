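"""Synthetic whole-transcriptome bundles with planted ground truth.

The generator emulates the study design the pipeline is built for: three
developmental time points x three biological replicates, profiled for
mRNA, lncRNA and miRNA abundance, plus a small-RNA FASTQ library.  A
configurable number of ceRNA triplets is planted: a miRNA whose abundance
trends across time points, an mRNA and a lncRNA that both carry an 8mer
seed site for that miRNA and whose abundance moves oppositely, so the
planted miRNA-target Pearson correlation approximates ``repression_r``.

Counts are negative-binomial around log-normal means, the standard
overdispersed model for bulk RNA-seq replicates.  Background transcript
sequences are rejection-sampled to be free of any planted miRNA's seed
match, so sequence-level truth is exact: a seed site exists on 100% of
planted targets and on no background transcript.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .enrich import GeneSet
from .io import (
    ExpressionMatrix,
    read_expression_tsv,
    read_fasta,
    read_gmt,
    write_expression_tsv,
    write_fasta,
    write_fastq,
    write_gmt,
)
from .targets import SeedSite, find_seed_sites, revcomp

_NT = np.array(list("ACGT"))

#: QC-violation labels, in the order the cleaner applies its rules.
QC_RULES = ("low_quality", "unknown_base", "missing_adapter", "no_insert", "too_short")

# Illumina TruSeq small-RNA adapters
DEFAULT_ADAPTER3 = "TGGAATTCTCGGGTGCCAAGG"
DEFAULT_ADAPTER5 = "GTTCAGAGTTCTACAGTCCGACGATC"


class ConfigError(ValueError):
    """A SimulationConfig field violates its invariant."""


@dataclass
class SimulationConfig:
    n_mrna: int = 200
    n_lncrna: int = 50
    n_mirna: int = 30
    n_groups: int = 3
    n_reps: int = 3
    n_triplets: int = 10
    repression_r: float = -0.9
    de_lfc: float = 3.0
    dispersion: float = 0.05
    utr_len: int = 500
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    n_reads: int = 400
    frac_bad_reads: float = 0.1
    rng_seed: int = 0
    # latent per-sample factor shared within a triplet (log2 sd); creates
    # within-group co-variation beyond the group trend.  Calibrated jointly
    # with the repression-noise budget so that, at defaults, planted pairs
    # reach the configured correlation while planted effects stay detectable
    # from three replicates
    latent_sd: float = 0.35

    def validate(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_mirna", "n_groups", "n_reps", "utr_len", "n_reads"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.n_triplets < 0:
            raise ConfigError(f"n_triplets must be >= 0, got {self.n_triplets}")
        if self.n_triplets > min(self.n_mrna, self.n_lncrna, self.n_mirna):
            raise ConfigError(
                "n_triplets exceeds the smallest feature class: "
                f"{self.n_triplets} > min(n_mrna, n_lncrna, n_mirna)"
            )
        if not (-1.0 <= self.repression_r < 0.0):
            raise ConfigError(f"repression_r must lie in [-1, 0), got {self.repression_r}")
        if self.dispersion < 0:
            raise ConfigError(f"dispersion must be >= 0, got {self.dispersion}")
        if not (0.0 <= self.frac_bad_reads <= 1.0):
            raise ConfigError(f"frac_bad_reads must lie in [0, 1], got {self.frac_bad_reads}")
        if not self.adapter3 or not self.adapter5:
            raise ConfigError("adapter3 and adapter5 must be non-empty")
        if self.utr_len < 10:
            raise ConfigError(f"utr_len must leave room for a seed site, got {self.utr_len}")

    @property
    def group_labels(self) -> list[str]:
        if self.n_groups == 3:
            return ["30d", "60d", "90d"]
        return [f"t{k + 1}" for k in range(self.n_groups)]

    @property
    def sample_labels(self) -> list[str]:
        return [f"{g}_r{j + 1}" for g in self.group_labels for j in range(self.n_reps)]

    @property
    def comparisons(self) -> list[tuple[str, str]]:
        labels = self.group_labels
        return [(labels[i], labels[j]) for i in range(len(labels)) for j in range(i + 1, len(labels))]


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated bundle."""

    planted_de: pd.DataFrame  # feature_id, feature_class, comparison, direction, expected_log2fc
    planted_triplets: list[tuple[str, str, str]]  # (miRNA, mRNA, lncRNA)
    planted_sites: list[SeedSite]
    development_term_members: list[str]
    expected_clean_reads: int = 0
    planted_qc_failures: dict[str, int] = field(default_factory=dict)
    surviving_read_ids: list[str] = field(default_factory=list)


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    mrna: ExpressionMatrix
    lncrna: ExpressionMatrix
    mirna: ExpressionMatrix
    mirna_seqs: dict[str, str]
    mrna_seqs: dict[str, str]
    lncrna_seqs: dict[str, str]
    genesets: list[GeneSet]
    smallrna_reads: list[tuple[str, str, str]]
    truth: SyntheticTruth


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_NT[rng.integers(0, 4, n)])


def _seed_free(seq: str, forbidden: list[str]) -> bool:
    return not any(f in seq for f in forbidden)


def _rejection_seq(rng: np.random.Generator, n: int, forbidden: list[str], what: str) -> str:
    for _ in range(1000):
        seq = _random_seq(rng, n)
        if _seed_free(seq, forbidden):
            return seq
    raise RuntimeError(f"rejection sampling exhausted (1000 tries) for {what}")


def _nb_counts(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate one internally consistent bundle with planted truth.

    Identical configs (including ``rng_seed``) give identical bundles.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    cfg = config

    groups = cfg.group_labels
    samples = cfg.sample_labels
    n_samples = len(samples)
    sample_group_idx = np.repeat(np.arange(cfg.n_groups), cfg.n_reps)

    mrna_ids = [f"gene-{i + 1:04d}" for i in range(cfg.n_mrna)]
    lnc_ids = [f"lnc-{i + 1:03d}" for i in range(cfg.n_lncrna)]
    mir_ids = [f"miR-{i + 1:03d}" for i in range(cfg.n_mirna)]

    # planted members: one miRNA, one mRNA, one lncRNA per triplet
    p_mir = sorted(rng.choice(cfg.n_mirna, cfg.n_triplets, replace=False))
    p_mrna = sorted(rng.choice(cfg.n_mrna, cfg.n_triplets, replace=False))
    p_lnc = sorted(rng.choice(cfg.n_lncrna, cfg.n_triplets, replace=False))
    triplets = [
        (mir_ids[p_mir[t]], mrna_ids[p_mrna[t]], lnc_ids[p_lnc[t]])
        for t in range(cfg.n_triplets)
    ]

    # --- miRNA sequences (22 nt, DNA internally).  Seeds must be pairwise
    # distinct AND non-nested: no miRNA's seed match may occur inside
    # another's 8mer site string, or planted targets could never be made
    # free of cross-triplet sites
    mir_dna: dict[str, str] = {}
    seed_matches: list[str] = []  # rc(seed6) per accepted miRNA
    site_strings: list[str] = []  # rc(seed7) + A per accepted miRNA
    for mid in mir_ids:
        for _ in range(1000):
            s = _random_seq(rng, 22)
            match6 = revcomp(s[1:7])
            site = revcomp(s[1:8]) + "A"
            if any(match6 in st for st in site_strings):
                continue
            if any(m in site for m in seed_matches):
                continue
            seed_matches.append(match6)
            site_strings.append(site)
            mir_dna[mid] = s
            break
        else:
            raise RuntimeError("rejection sampling exhausted (1000 tries) for miRNA seeds")

    planted_mir_ids = [t[0] for t in triplets]
    forbidden = [revcomp(mir_dna[m][1:7]) for m in planted_mir_ids]

    # --- transcript sequences: planted targets carry one 8mer site for
    # their partner miRNA; everything else is seed-free for planted miRNAs
    planted_target_partner = {t[1]: t[0] for t in triplets}
    planted_target_partner.update({t[2]: t[0] for t in triplets})

    def make_transcript(tid: str) -> str:
        partner = planted_target_partner.get(tid)
        if partner is None:
            return _rejection_seq(rng, cfg.utr_len, forbidden, tid)
        site = revcomp(mir_dna[partner][1:8]) + "A"  # 8mer: rc(seed7) + A1
        others = [f for m, f in zip(planted_mir_ids, forbidden) if m != partner]
        for _ in range(1000):
            pos = int(rng.integers(0, cfg.utr_len - len(site) + 1))
            ctx = _random_seq(rng, cfg.utr_len - len(site))
            seq = ctx[:pos] + site + ctx[pos:]
            if _seed_free(seq, others):
                return seq
        raise RuntimeError(f"rejection sampling exhausted (1000 tries) for {tid}")

    mrna_seqs = {tid: make_transcript(tid) for tid in mrna_ids}
    lnc_seqs = {tid: make_transcript(tid) for tid in lnc_ids}

    planted_sites: list[SeedSite] = []
    for mid, gid, lid in triplets:
        for tid, seqs in ((gid, mrna_seqs), (lid, lnc_seqs)):
            hits = [
                s
                for s in find_seed_sites(mir_dna[mid], seqs[tid], mirna_id=mid, transcript_id=tid)
                if s.site_type == "8mer"
            ]
            planted_sites.extend(hits[:1])

    # --- expression model -------------------------------------------------
    log2e_sq = 1.0 / math.log(2.0) ** 2

    def baselines(n: int, planted_idx: list[int]) -> np.ndarray:
        base = rng.normal(6.0, 2.0, n)
        base[planted_idx] = rng.normal(9.0, 0.5, len(planted_idx))
        return base

    # group trend spans de_lfc between the extreme groups; sign alternates
    # across triplets so per-million normalization is not systematically
    # distorted by the planted features moving together
    offsets = np.linspace(-cfg.de_lfc / 2.0, cfg.de_lfc / 2.0, cfg.n_groups)
    trend_var = float(np.var(offsets[sample_group_idx]))
    signal_var = trend_var + cfg.latent_sd**2
    r = cfg.repression_r
    w_total = signal_var * (1.0 + r) / (-r)

    def planted_noise_sd(mu0: float) -> float:
        w_nb = log2e_sq * math.log(1.0 + 1.0 / mu0 + cfg.dispersion)
        return math.sqrt(max(0.0, w_total - w_nb))

    def class_matrix(
        ids: list[str], planted_idx: list[int], planted_signal: dict[int, np.ndarray]
    ) -> pd.DataFrame:
        base = baselines(len(ids), planted_idx)
        log2mu = np.tile(base[:, None], (1, n_samples))
        for i in planted_idx:
            sd = planted_noise_sd(2.0 ** base[i])
            log2mu[i] += planted_signal[i] + rng.normal(0.0, sd, n_samples)
        counts = _nb_counts(rng, 2.0**log2mu, cfg.dispersion)
        return pd.DataFrame(counts, index=ids, columns=samples)

    # per-triplet signal: trend (sign-alternating) plus shared latent factor
    mir_signal: dict[int, np.ndarray] = {}
    mrna_signal: dict[int, np.ndarray] = {}
    lnc_signal: dict[int, np.ndarray] = {}
    triplet_sign: list[int] = []
    for t in range(cfg.n_triplets):
        sign = 1 if t % 2 == 0 else -1
        triplet_sign.append(sign)
        latent = rng.normal(0.0, cfg.latent_sd, n_samples)
        s = sign * (offsets[sample_group_idx] + latent)
        mir_signal[p_mir[t]] = s
        mrna_signal[p_mrna[t]] = -s
        lnc_signal[p_lnc[t]] = -s

    mrna_counts = class_matrix(mrna_ids, p_mrna, mrna_signal)
    lnc_counts = class_matrix(lnc_ids, p_lnc, lnc_signal)
    mir_counts = class_matrix(mir_ids, p_mir, mir_signal)

    mrna_lengths = pd.Series(rng.integers(500, 3001, cfg.n_mrna), index=mrna_ids, dtype=float)
    lnc_lengths = pd.Series(rng.integers(300, 2001, cfg.n_lncrna), index=lnc_ids, dtype=float)
    mir_lengths = pd.Series(22.0, index=mir_ids)

    mrna_em = ExpressionMatrix(mrna_counts, "mRNA", "count", mrna_lengths)
    lnc_em = ExpressionMatrix(lnc_counts, "lncRNA", "count", lnc_lengths)
    mir_em = ExpressionMatrix(mir_counts, "miRNA", "count", mir_lengths)

    # --- planted DE records ----------------------------------------------
    de_rows = []
    for t in range(cfg.n_triplets):
        mid, gid, lid = triplets[t]
        for ia, ib in [(i, j) for i in range(cfg.n_groups) for j in range(i + 1, cfg.n_groups)]:
            comparison = f"{groups[ia]}-{groups[ib]}"
            lfc_mir = triplet_sign[t] * (offsets[ib] - offsets[ia])
            for fid, fclass, lfc in (
                (mid, "miRNA", lfc_mir),
                (gid, "mRNA", -lfc_mir),
                (lid, "lncRNA", -lfc_mir),
            ):
                de_rows.append(
                    {
                        "feature_id": fid,
                        "feature_class": fclass,
                        "comparison": comparison,
                        "direction": "up" if lfc > 0 else "down",
                        "expected_log2fc": lfc,
                    }
                )
    planted_de = pd.DataFrame(
        de_rows,
        columns=["feature_id", "feature_class", "comparison", "direction", "expected_log2fc"],
    )

    # --- gene sets ---------------------------------------------------------
    planted_mrna_ids = [t[1] for t in triplets]
    decoy_pool = [g for g in mrna_ids if g not in set(planted_mrna_ids)]
    n_decoys = min(20, len(decoy_pool))
    dev_members = sorted(
        set(planted_mrna_ids)
        | set(rng.choice(decoy_pool, n_decoys, replace=False).tolist())
    )
    genesets = [
        GeneSet("GO:SYN0001", "tissue development (synthetic)", set(dev_members), "GO-like")
    ]
    for k in range(10):
        size = int(rng.integers(15, 41))
        members = set(rng.choice(mrna_ids, min(size, cfg.n_mrna), replace=False).tolist())
        genesets.append(
            GeneSet(f"PW:SYN{k + 1:04d}", f"synthetic pathway {k + 1}", members, "pathway-like")
        )

    truth = SyntheticTruth(
        planted_de=planted_de,
        planted_triplets=triplets,
        planted_sites=planted_sites,
        development_term_members=dev_members,
    )

    # miRNA FASTA is emitted in the RNA alphabet, as mature miRNAs are
    mirna_seqs = {mid: s.replace("T", "U") for mid, s in mir_dna.items()}

    reads, qc_truth = generate_smallrna_fastq(cfg, mirna_dna=mir_dna, rng=rng)
    truth.expected_clean_reads = qc_truth.expected_clean_reads
    truth.planted_qc_failures = qc_truth.planted_qc_failures
    truth.surviving_read_ids = qc_truth.surviving_read_ids

    return SyntheticDataset(
        config=cfg,
        mrna=mrna_em,
        lncrna=lnc_em,
        mirna=mir_em,
        mirna_seqs=mirna_seqs,
        mrna_seqs=mrna_seqs,
        lncrna_seqs=lnc_seqs,
        genesets=genesets,
        smallrna_reads=reads,
        truth=truth,
    )


@dataclass
class FastqTruth:
    expected_clean_reads: int
    planted_qc_failures: dict[str, int]
    surviving_read_ids: list[str]


def generate_smallrna_fastq(
    config: SimulationConfig,
    mirna_dna: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, str]], FastqTruth]:
    """Emit adapter-flanked small-RNA reads with planted QC violations.

    Reads are ``adapter5 + insert + adapter3`` with Phred+33 qualities.
    Each planted bad read violates exactly one cleaning rule; insert
    lengths of good reads concentrate at 21-23 nt.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    cfg = config
    a5, a3 = cfg.adapter5, cfg.adapter3
    pool = list(mirna_dna.values()) if mirna_dna else []

    n_bad = int(round(cfg.frac_bad_reads * cfg.n_reads))
    n_good = cfg.n_reads - n_bad
    failures = {rule: 0 for rule in QC_RULES}

    def good_insert() -> str:
        if pool and rng.random() < 0.7:
            s = pool[int(rng.integers(len(pool)))]
        else:
            s = _random_seq(rng, int(rng.integers(21, 24)))
        return s

    records: list[tuple[str, str, str]] = []
    survivors: list[str] = []

    def emit(seq: str, rule: str | None, low_q_positions: list[int] | None = None) -> None:
        i = len(records)
        qual = ["I"] * len(seq)  # Q40
        for p in low_q_positions or []:
            qual[p] = "5"  # Q20, at the inclusive rejection threshold
        name = f"read_{i + 1:05d}"
        records.append((name, seq, "".join(qual)))
        if rule is None:
            survivors.append(name)
        else:
            failures[rule] += 1

    for _ in range(n_good):
        emit(a5 + good_insert() + a3, None)

    for k in range(n_bad):
        rule = QC_RULES[k % len(QC_RULES)]
        if rule == "low_quality":
            seq = a5 + good_insert() + a3
            pos = rng.choice(len(seq), 2, replace=False).tolist()
            emit(seq, rule, low_q_positions=pos)
        elif rule == "unknown_base":
            ins = good_insert()
            j = int(rng.integers(len(ins)))
            emit(a5 + ins[:j] + "N" + ins[j + 1 :] + a3, rule)
        elif rule == "missing_adapter":
            emit(a5 + good_insert(), rule)  # 3' adapter absent
        elif rule == "no_insert":
            emit(a5 + a3, rule)
        elif rule == "too_short":
            emit(a5 + _random_seq(rng, 17) + a3, rule)

    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    survivor_set = set(survivors)
    surviving_ids = [name for name, _, _ in records if name in survivor_set]

    return records, FastqTruth(
        expected_clean_reads=n_good,
        planted_qc_failures=failures,
        surviving_read_ids=surviving_ids,
    )


# ---------------------------------------------------------------------------
# on-disk bundle


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write the bundle as TSV/FASTA/GMT/FASTQ plus truth tables; return a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    def put(name: str, path: Path) -> Path:
        manifest[name] = path
        return path

    write_expression_tsv(dataset.mrna, put("mrna_counts", directory / "mrna_counts.tsv"))
    write_expression_tsv(dataset.lncrna, put("lncrna_counts", directory / "lncrna_counts.tsv"))
    write_expression_tsv(dataset.mirna, put("mirna_counts", directory / "mirna_counts.tsv"))
    write_fasta(dataset.mirna_seqs, put("mirna_fasta", directory / "mirna.fa"))
    write_fasta(dataset.mrna_seqs, put("mrna_fasta", directory / "mrna_utr.fa"))
    write_fasta(dataset.lncrna_seqs, put("lncrna_fasta", directory / "lncrna.fa"))
    write_gmt(dataset.genesets, put("genesets", directory / "genesets.gmt"))
    write_fastq(dataset.smallrna_reads, put("smallrna_fastq", directory / "smallrna.fastq"))

    truth = dataset.truth
    truth.planted_de.to_csv(put("truth_planted_de", directory / "truth_planted_de.tsv"), sep="\t", index=False)
    pd.DataFrame(truth.planted_triplets, columns=["mirna_id", "mrna_id", "lncrna_id"]).to_csv(
        put("truth_triplets", directory / "truth_triplets.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "mirna_id": s.mirna_id,
                "transcript_id": s.transcript_id,
                "start": s.start,
                "end": s.end,
                "site_type": s.site_type,
            }
            for s in truth.planted_sites
        ]
    ).to_csv(put("truth_sites", directory / "truth_sites.tsv"), sep="\t", index=False)
    qc_df = pd.DataFrame(
        [{"rule": k, "planted": v} for k, v in truth.planted_qc_failures.items()]
        + [{"rule": "expected_clean_reads", "planted": truth.expected_clean_reads}]
    )
    qc_df.to_csv(put("truth_smallrna_qc", directory / "truth_smallrna_qc.tsv"), sep="\t", index=False)
    with open(put("truth_dev_members", directory / "truth_dev_members.txt"), "w") as fh:
        fh.write("\n".join(truth.development_term_members) + "\n")
    with open(put("truth_surviving_reads", directory / "truth_surviving_reads.txt"), "w") as fh:
        fh.write("\n".join(truth.surviving_read_ids) + "\n")
    return manifest


def read_dataset(directory: str | Path) -> SyntheticDataset:
    """Read back a bundle written by :func:`write_dataset` (sans RNG state)."""
    directory = Path(directory)
    mrna = read_expression_tsv(directory / "mrna_counts.tsv", "mRNA")
    lncrna = read_expression_tsv(directory / "lncrna_counts.tsv", "lncRNA")
    mirna = read_expression_tsv(directory / "mirna_counts.tsv", "miRNA")
    planted_de = pd.read_csv(directory / "truth_planted_de.tsv", sep="\t")
    trip_df = pd.read_csv(directory / "truth_triplets.tsv", sep="\t")
    triplets = [tuple(r) for r in trip_df.itertuples(index=False)]
    sites_df = pd.read_csv(directory / "truth_sites.tsv", sep="\t")
    sites = [
        SeedSite(r.mirna_id, r.transcript_id, int(r.start), int(r.end), r.site_type)
        for r in sites_df.itertuples(index=False)
    ]
    qc_df = pd.read_csv(directory / "truth_smallrna_qc.tsv", sep="\t").set_index("rule")["planted"]
    dev_members = (directory / "truth_dev_members.txt").read_text().split()
    surviving = (directory / "truth_surviving_reads.txt").read_text().split()
    from .io import parse_fastq

    reads = list(parse_fastq(directory / "smallrna.fastq"))
    truth = SyntheticTruth(
        planted_de=planted_de,
        planted_triplets=triplets,
        planted_sites=sites,
        development_term_members=dev_members,
        expected_clean_reads=int(qc_df["expected_clean_reads"]),
        planted_qc_failures={k: int(v) for k, v in qc_df.items() if k != "expected_clean_reads"},
        surviving_read_ids=surviving,
    )
    return SyntheticDataset(
        config=SimulationConfig(),
        mrna=mrna,
        lncrna=lncrna,
        mirna=mirna,
        mirna_seqs=read_fasta(directory / "mirna.fa"),
        mrna_seqs=read_fasta(directory / "mrna_utr.fa"),
        lncrna_seqs=read_fasta(directory / "lncrna.fa"),
        genesets=read_gmt(directory / "genesets.gmt"),
        smallrna_reads=reads,
        truth=truth,
    )
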