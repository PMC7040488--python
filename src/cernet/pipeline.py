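"""End-to-end orchestration: simulate/load -> QC -> normalize -> DE ->
targets -> negative co-expression -> enrichment -> ceRNET, per comparison.

Every stage writes plain TSV so any step can be rerun or inspected
standalone; the run log records every threshold and the seed.  Stage
outputs are pure functions of (inputs, config), so identical configs
give identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coexpr, diffexpr, enrich, network, quantify, smallrna_qc, targets
from .simulate import SimulationConfig, SyntheticDataset, generate_dataset, read_dataset
from .targets import TargetPair


@dataclass
class PipelineConfig:
    synthetic: bool = True
    input_dir: str | None = None
    out_dir: str = "cernet_out"
    comparisons: list[str] | None = None  # default: all group pairs
    p_thr: float = 0.05
    lfc_thr: float = 1.0
    r_thr: float = -0.7
    coexpr_p_thr: float = 0.05
    q_thr: float = 0.05
    min_site_type: str = "7mer-A1"
    sample_scope: str = "all"  # "all" or "comparison"
    dev_patterns: list[str] = field(default_factory=lambda: ["development"])
    rng_seed: int = 0
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if not (0 < self.p_thr <= 1) or not (0 < self.q_thr <= 1) or not (0 < self.coexpr_p_thr <= 1):
            raise ValueError("probability thresholds must lie in (0, 1]")
        if self.r_thr >= 0:
            raise ValueError("r_thr must be negative (negative co-expression screen)")
        if self.sample_scope not in ("all", "comparison"):
            raise ValueError("sample_scope must be 'all' or 'comparison'")
        if not self.synthetic and not self.input_dir:
            raise ValueError("input_dir is required when synthetic mode is off")
        self.sim.rng_seed = self.rng_seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)


@dataclass
class ComparisonResult:
    comparison: str
    de: dict[str, pd.DataFrame]
    screen_mrna: pd.DataFrame
    screen_lncrna: pd.DataFrame
    enrichment: pd.DataFrame
    dev_genes: set[str]
    graph: "network.nx.DiGraph"
    triplets: list[network.CeRNATriplet]


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: SyntheticDataset
    consensus: dict[str, list[TargetPair]]
    per_comparison: dict[str, ComparisonResult]
    triplet_union: list[tuple[str, str, str]]
    recovery: dict[str, float] | None
    manifest: dict[str, Path]


def _comparison_pairs(cfg: PipelineConfig, dataset: SyntheticDataset) -> list[tuple[str, str]]:
    groups = list(dict.fromkeys(dataset.mrna.groups))
    all_pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    if cfg.comparisons is None:
        return all_pairs
    wanted = []
    valid = {f"{a}-{b}": (a, b) for a, b in all_pairs}
    for label in cfg.comparisons:
        if label not in valid:
            raise ValueError(f"comparison {label!r} does not reference declared groups")
        wanted.append(valid[label])
    return wanted


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Path] = {}

    if cfg.synthetic:
        dataset = generate_dataset(cfg.sim)
        from .simulate import write_dataset

        manifest.update(write_dataset(dataset, out / "inputs"))
    else:
        dataset = read_dataset(cfg.input_dir)

    # --- small-RNA QC ------------------------------------------------------
    qc_params = smallrna_qc.QCParams(
        adapter3=dataset.config.adapter3, adapter5=dataset.config.adapter5
    )
    kept, report = smallrna_qc.clean_reads(dataset.smallrna_reads, qc_params)
    tags = smallrna_qc.collapse_tags(s for _, s in kept)
    report.as_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
    tags.to_csv(out / "clean_tags.tsv", sep="\t", index=False)
    manifest["qc_report"] = out / "qc_report.tsv"
    manifest["clean_tags"] = out / "clean_tags.tsv"

    # --- normalization -----------------------------------------------------
    mrna_fpkm = quantify.fpkm_matrix(dataset.mrna)
    lnc_fpkm = quantify.fpkm_matrix(dataset.lncrna)
    mir_tpm = quantify.tpm_matrix(dataset.mirna)
    from .io import write_expression_tsv

    for name, mat in [("mrna_fpkm", mrna_fpkm), ("lncrna_fpkm", lnc_fpkm), ("mirna_tpm", mir_tpm)]:
        write_expression_tsv(mat, out / f"{name}.tsv")
        manifest[name] = out / f"{name}.tsv"

    # --- consensus target prediction --------------------------------------
    consensus = {
        "mRNA": targets.intersect_predictions(
            [
                targets.predict_targets(
                    dataset.mirna_seqs,
                    dataset.mrna_seqs,
                    min_site_type=cfg.min_site_type,
                    transcript_class="mRNA",
                )
            ]
        ),
        "lncRNA": targets.intersect_predictions(
            [
                targets.predict_targets(
                    dataset.mirna_seqs,
                    dataset.lncrna_seqs,
                    min_site_type=cfg.min_site_type,
                    transcript_class="lncRNA",
                )
            ]
        ),
    }
    for cls, pairs in consensus.items():
        path = out / f"targets_{cls}.tsv"
        targets.write_site_table(pairs, path)
        manifest[f"targets_{cls}"] = path

    # --- per-comparison screening ------------------------------------------
    per_comparison: dict[str, ComparisonResult] = {}
    union: set[tuple[str, str, str]] = set()
    background = set(dataset.mrna.feature_ids)

    for group_a, group_b in _comparison_pairs(cfg, dataset):
        label = f"{group_a}-{group_b}"
        cdir = out / label
        cdir.mkdir(exist_ok=True)

        de = {}
        for cls, mat in [("mRNA", mrna_fpkm), ("lncRNA", lnc_fpkm), ("miRNA", mir_tpm)]:
            de[cls] = diffexpr.de_screen(
                mat, group_a, group_b, p_thr=cfg.p_thr, lfc_thr=cfg.lfc_thr
            )
            de[cls].to_csv(cdir / f"de_{cls}.tsv", sep="\t", index=False)
            manifest[f"{label}/de_{cls}"] = cdir / f"de_{cls}.tsv"

        sig = {
            cls: set(df.loc[df.significant, "feature_id"]) for cls, df in de.items()
        }

        scope = None
        if cfg.sample_scope == "comparison":
            scope = mir_tpm.samples_in_groups([group_a, group_b])

        def de_candidates(cls: str) -> list[TargetPair]:
            return [
                p
                for p in consensus[cls]
                if p.mirna_id in sig["miRNA"] and p.transcript_id in sig[cls]
            ]

        screen_m = coexpr.screen_negative_pairs(
            mir_tpm, mrna_fpkm, de_candidates("mRNA"),
            r_thr=cfg.r_thr, p_thr=cfg.coexpr_p_thr, sample_scope=scope,
        )
        screen_l = coexpr.screen_negative_pairs(
            mir_tpm, lnc_fpkm, de_candidates("lncRNA"),
            r_thr=cfg.r_thr, p_thr=cfg.coexpr_p_thr, sample_scope=scope,
        )
        screen_m.to_csv(cdir / "coexpr_mrna.tsv", sep="\t", index=False)
        screen_l.to_csv(cdir / "coexpr_lncrna.tsv", sep="\t", index=False)
        manifest[f"{label}/coexpr_mrna"] = cdir / "coexpr_mrna.tsv"
        manifest[f"{label}/coexpr_lncrna"] = cdir / "coexpr_lncrna.tsv"

        enrichment = enrich.enrich_genesets(
            sig["mRNA"], background, dataset.genesets, q_thr=cfg.q_thr
        )
        enrichment.to_csv(cdir / "enrichment.tsv", sep="\t", index=False)
        enrich.top_terms(enrichment).to_csv(cdir / "enrichment_top20.tsv", sep="\t", index=False)
        manifest[f"{label}/enrichment"] = cdir / "enrichment.tsv"

        dev_genes = enrich.select_development_genes(
            sig["mRNA"], dataset.genesets, name_patterns=cfg.dev_patterns
        )

        graph, triplets = network.build_cernet(
            coexpr.retained_pairs(screen_m),
            coexpr.retained_pairs(screen_l),
            consensus["mRNA"] + consensus["lncRNA"],
            dev_genes,
            comparison=label,
        )
        exported = network.export_network(graph, cdir / "network")
        manifest.update({f"{label}/network_{k}": v for k, v in exported.items()})
        pd.DataFrame(
            [
                {
                    "mirna_id": t.mirna_id,
                    "mrna_id": t.mrna_id,
                    "lncrna_id": t.lncrna_id,
                    "mrna_r": t.mrna_edge.r,
                    "lncrna_r": t.lncrna_edge.r,
                }
                for t in triplets
            ],
            columns=["mirna_id", "mrna_id", "lncrna_id", "mrna_r", "lncrna_r"],
        ).to_csv(cdir / "triplets.tsv", sep="\t", index=False)
        manifest[f"{label}/triplets"] = cdir / "triplets.tsv"

        union |= {t.key for t in triplets}
        per_comparison[label] = ComparisonResult(
            label, de, screen_m, screen_l, enrichment, dev_genes, graph, triplets
        )

    recovery = None
    if cfg.synthetic:
        recovery = network.evaluate_recovery(
            sorted(union), dataset.truth.planted_triplets
        )
        pd.DataFrame([recovery]).to_csv(out / "recovery.tsv", sep="\t", index=False)
        manifest["recovery"] = out / "recovery.tsv"

    log = {
        "seed": cfg.rng_seed,
        "thresholds": {
            "p_thr": cfg.p_thr,
            "lfc_thr": cfg.lfc_thr,
            "r_thr": cfg.r_thr,
            "coexpr_p_thr": cfg.coexpr_p_thr,
            "q_thr": cfg.q_thr,
            "min_site_type": cfg.min_site_type,
            "sample_scope": cfg.sample_scope,
        },
        "comparisons": sorted(per_comparison),
        "synthetic": cfg.synthetic,
        "sim": asdict(cfg.sim) if cfg.synthetic else None,
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    manifest["run_log"] = out / "run_log.yaml"

    return PipelineResult(
        config=cfg,
        dataset=dataset,
        consensus=consensus,
        per_comparison=per_comparison,
        triplet_union=sorted(union),
        recovery=recovery,
        manifest=manifest,
    )
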