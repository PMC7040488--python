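"""Seed-site detection against a naive per-offset oracle, plus consensus rules."""

import numpy as np
import pytest

from cernet import find_seed_sites, intersect_predictions, predict_targets
from cernet.targets import (
    SeedSite,
    TargetPair,
    normalize_nt,
    read_site_table,
    revcomp,
    write_site_table,
)

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"


def oracle_sites(mirna, tx):
    """Test every offset and class rule independently of the scanner."""
    mirna = normalize_nt(mirna)
    tx = normalize_nt(tx)
    m6 = revcomp(mirna[1:7])
    m7 = revcomp(mirna[1:8])
    out = []
    for j in range(len(tx) - 5):
        if tx[j : j + 6] != m6:
            continue
        seed7 = j >= 1 and tx[j - 1 : j + 6] == m7
        a1 = j + 6 < len(tx) and tx[j + 6] == "A"
        if seed7 and a1:
            out.append((j - 1, j + 7, "8mer"))
        elif seed7:
            out.append((j - 1, j + 6, "7mer-m8"))
        elif a1:
            out.append((j, j + 7, "7mer-A1"))
        else:
            out.append((j, j + 6, "6mer"))
    return out


def test_let7_8mer_hand_example():
    sites = find_seed_sites(LET7, "GGGCTACCTCAGGG")
    assert [(s.start, s.end, s.site_type) for s in sites] == [(3, 11, "8mer")]


def test_no_complement_no_sites():
    assert find_seed_sites(LET7, "AAAAAAAAAAAAAA") == []


def test_class_enumeration():
    m6 = revcomp(normalize_nt(LET7)[1:7])  # TACCTC
    m8 = revcomp(normalize_nt(LET7)[7])  # C pairs miRNA position 8
    cases = {
        "6mer": "GG" + m6 + "G",
        "7mer-A1": "GG" + m6 + "A",
        "7mer-m8": "G" + m8 + m6 + "G",
        "8mer": "G" + m8 + m6 + "A",
    }
    for expect, tx in cases.items():
        sites = find_seed_sites(LET7, tx)
        assert [s.site_type for s in sites] == [expect], tx


def test_rna_dna_insensitive():
    assert find_seed_sites(LET7, "GGGCUACCUCAGGG") == find_seed_sites(
        LET7.replace("U", "T"), "GGGCTACCTCAGGG"
    )


def test_short_mirna_rejected():
    with pytest.raises(ValueError, match="shorter than 8"):
        find_seed_sites("UGAGGUA", "GGGCTACCTCAGGG")


def _random_pairs(n, seed=0):
    rng = np.random.default_rng(seed)
    nts = np.array(list("ACGT"))
    for _ in range(n):
        mir = "".join(nts[rng.integers(0, 4, 22)])
        # low-entropy transcripts so matches actually occur
        tx = "".join(np.array(list("ACT"))[rng.integers(0, 3, rng.integers(30, 200))])
        yield mir, tx


@pytest.mark.parametrize("n", [200])
def test_scanner_matches_oracle(n):
    checked = hits = 0
    for mir, tx in _random_pairs(n):
        got = [(s.start, s.end, s.site_type) for s in find_seed_sites(mir, tx)]
        want = oracle_sites(mir, tx)
        assert got == want
        checked += 1
        hits += len(want)
    assert checked == n


def test_sites_stay_in_bounds_and_are_exclusive(small_dataset):
    ds = small_dataset
    for mid, mseq in ds.mirna_seqs.items():
        for tid, tseq in list(ds.mrna_seqs.items())[:20]:
            sites = find_seed_sites(mseq, tseq, mirna_id=mid, transcript_id=tid)
            starts6 = [s.start + 1 if s.site_type in ("8mer", "7mer-m8") else s.start for s in sites]
            assert len(starts6) == len(set(starts6))  # one class per seed hit
            for s in sites:
                assert 0 <= s.start < s.end <= len(tseq)


def test_predict_targets_threshold_semantics():
    mirnas = {"m1": LET7}
    transcripts = {
        "t8": "GG" + revcomp(normalize_nt(LET7)[1:8]) + "A",
        "t7": "GG" + revcomp(normalize_nt(LET7)[1:8]) + "G",  # best is 7mer-m8
    }
    all_pairs = predict_targets(mirnas, transcripts, min_site_type="6mer")
    assert {p.transcript_id for p in all_pairs} == {"t8", "t7"}
    only8 = predict_targets(mirnas, transcripts, min_site_type="8mer")
    assert {p.transcript_id for p in only8} == {"t8"}
    assert predict_targets(mirnas, {}, min_site_type="6mer") == []


def test_planted_pairs_all_predicted(small_dataset):
    ds = small_dataset
    pairs = predict_targets(ds.mirna_seqs, {**ds.mrna_seqs, **ds.lncrna_seqs}, "7mer-A1")
    keys = {(p.mirna_id, p.transcript_id) for p in pairs}
    for mid, gid, lid in ds.truth.planted_triplets:
        assert (mid, gid) in keys and (mid, lid) in keys


def test_intersection_consensus():
    def pair(m, t, label):
        return TargetPair(m, t, "mRNA", [SeedSite(m, t, 0, 6, "6mer")], {label})

    a = [pair("m1", "t1", "A"), pair("m1", "t2", "A")]
    b = [pair("m1", "t1", "B"), pair("m2", "t9", "B")]
    c = [pair("m1", "t1", "C")]
    common = intersect_predictions([a, b, c])
    assert [(p.mirna_id, p.transcript_id) for p in common] == [("m1", "t1")]
    assert common[0].support == {"A", "B", "C"}
    assert len(common[0].sites) == 1  # deduplicated by coordinates
    # 2-of-3 is dropped; single collection is identity
    assert {(p.mirna_id, p.transcript_id) for p in intersect_predictions([a])} == {
        ("m1", "t1"),
        ("m1", "t2"),
    }


def test_site_table_round_trip(tmp_path):
    mirnas = {"m1": LET7}
    transcripts = {"t1": "GG" + revcomp(normalize_nt(LET7)[1:8]) + "AGGCTACCTCA"}
    pairs = predict_targets(mirnas, transcripts, "6mer")
    path = tmp_path / "sites.tsv"
    write_site_table(pairs, path)
    back = read_site_table(path)
    assert [(p.mirna_id, p.transcript_id) for p in back] == [("m1", "t1")]
    assert {(s.start, s.end, s.site_type) for s in back[0].sites} == {
        (s.start, s.end, s.site_type) for s in pairs[0].sites
    }
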