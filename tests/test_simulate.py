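"""Generator tests: determinism, planted structure, sequence truth, round trips."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from cernet import (
    SimulationConfig,
    generate_dataset,
    generate_smallrna_fastq,
    read_dataset,
    write_dataset,
)
from cernet.simulate import ConfigError
from cernet.targets import find_seed_sites


def test_fixed_seed_determinism(small_config):
    a = generate_dataset(dataclasses.replace(small_config))
    b = generate_dataset(dataclasses.replace(small_config))
    pd.testing.assert_frame_equal(a.mrna.values, b.mrna.values)
    pd.testing.assert_frame_equal(a.mirna.values, b.mirna.values)
    assert a.mirna_seqs == b.mirna_seqs
    assert a.mrna_seqs == b.mrna_seqs
    assert a.smallrna_reads == b.smallrna_reads
    assert a.truth.planted_triplets == b.truth.planted_triplets


def test_matrix_dimensions():
    ds = generate_dataset(SimulationConfig(n_mrna=200, n_reps=3, n_groups=3, rng_seed=3))
    assert ds.mrna.values.shape == (200, 9)
    assert list(ds.mrna.groups.unique()) == ["30d", "60d", "90d"]


@pytest.mark.parametrize(
    "field,value",
    [
        ("n_mrna", 0),
        ("n_triplets", 100),
        ("repression_r", 0.2),
        ("repression_r", -1.5),
        ("dispersion", -0.1),
        ("frac_bad_reads", 1.5),
        ("adapter3", ""),
    ],
)
def test_invalid_config_names_field(field, value):
    cfg = dataclasses.replace(SimulationConfig(), **{field: value})
    with pytest.raises(ConfigError) as err:
        generate_dataset(cfg)
    assert field in str(err.value) or "n_triplets" in str(err.value)


def test_sequence_truth_exact(small_dataset):
    """Planted targets all carry a partner seed site; background carries none."""
    ds = small_dataset
    planted_mirs = {t[0] for t in ds.truth.planted_triplets}
    planted_targets = {t[1] for t in ds.truth.planted_triplets} | {
        t[2] for t in ds.truth.planted_triplets
    }
    transcripts = {**ds.mrna_seqs, **ds.lncrna_seqs}
    for mid, gid, lid in ds.truth.planted_triplets:
        for tid in (gid, lid):
            sites = find_seed_sites(ds.mirna_seqs[mid], transcripts[tid])
            assert any(s.site_type == "8mer" for s in sites)
    for tid, seq in transcripts.items():
        if tid in planted_targets:
            continue
        for mid in planted_mirs:
            assert find_seed_sites(ds.mirna_seqs[mid], seq) == []


def test_planted_sites_recorded_on_both_partners(small_dataset):
    truth = small_dataset.truth
    sited = {(s.mirna_id, s.transcript_id) for s in truth.planted_sites}
    for mid, gid, lid in truth.planted_triplets:
        assert (mid, gid) in sited and (mid, lid) in sited


def test_planted_coupling_strength():
    """At repression_r=-0.9 the planted log-scale correlation is strongly negative."""
    rs = []
    for seed in range(20):
        cfg = SimulationConfig(
            n_mrna=60, n_lncrna=20, n_mirna=15, n_triplets=5, n_reads=10, rng_seed=seed
        )
        ds = generate_dataset(cfg)
        logm = np.log2(ds.mirna.values + 1)
        logg = np.log2(ds.mrna.values + 1)
        for mid, gid, _ in ds.truth.planted_triplets:
            rs.append(np.corrcoef(logm.loc[mid], logg.loc[gid])[0, 1])
    rs = np.asarray(rs)
    assert rs.mean() <= -0.6
    assert (rs < -0.7).mean() >= 0.8


def test_development_gene_set(small_dataset):
    ds = small_dataset
    dev = [g for g in ds.genesets if "development" in g.term_name.lower()]
    assert len(dev) == 1
    planted_mrnas = {t[1] for t in ds.truth.planted_triplets}
    assert planted_mrnas <= dev[0].members
    assert dev[0].members - planted_mrnas, "development term must also contain decoys"
    assert sorted(dev[0].members) == sorted(ds.truth.development_term_members)


def test_fastq_truth_bookkeeping(small_config):
    reads, truth = generate_smallrna_fastq(small_config)
    assert len(reads) == small_config.n_reads
    n_bad = sum(truth.planted_qc_failures.values())
    assert truth.expected_clean_reads + n_bad == small_config.n_reads
    assert len(truth.surviving_read_ids) == truth.expected_clean_reads
    for _, seq, qual in reads:
        assert len(seq) == len(qual)


def test_fastq_no_failures_when_frac_zero(small_config):
    cfg = dataclasses.replace(small_config, frac_bad_reads=0.0)
    reads, truth = generate_smallrna_fastq(cfg)
    assert truth.expected_clean_reads == len(reads) == cfg.n_reads
    assert all(v == 0 for v in truth.planted_qc_failures.values())


def test_good_read_inserts_concentrate_at_mirna_length(small_config):
    cfg = dataclasses.replace(small_config, frac_bad_reads=0.0)
    reads, _ = generate_smallrna_fastq(cfg)
    for _, seq, _ in reads:
        insert = seq[len(cfg.adapter5) : len(seq) - len(cfg.adapter3)]
        assert 21 <= len(insert) <= 23


def test_write_read_round_trip(small_dataset, tmp_path):
    manifest = write_dataset(small_dataset, tmp_path)
    for name, path in manifest.items():
        assert path.exists(), name
    back = read_dataset(tmp_path)
    pd.testing.assert_frame_equal(
        back.mrna.values.astype(float), small_dataset.mrna.values.astype(float)
    )
    assert back.mirna_seqs == small_dataset.mirna_seqs
    assert back.truth.planted_triplets == small_dataset.truth.planted_triplets
    assert back.truth.expected_clean_reads == small_dataset.truth.expected_clean_reads
    assert back.smallrna_reads == small_dataset.smallrna_reads
    got = {g.term_id: g.members for g in back.genesets}
    want = {g.term_id: g.members for g in small_dataset.genesets}
    assert got == want
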