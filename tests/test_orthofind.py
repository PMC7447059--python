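"""Reciprocal-best-hit cascade: parsing, ranking, reciprocity, disambiguation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from orthodiverge.orthofind import (
    HitTableFormatError,
    best_hits,
    disambiguate_by_reference,
    find_orthologs,
    read_hit_table,
    reciprocal_best_hits,
    write_hit_table,
)
from orthodiverge.simdata import BLAST6_COLUMNS, make_hit_tables


def _hits(rows):
    return pd.DataFrame(
        [
            dict(
                qseqid=q, sseqid=s, pident=90.0, length=length, mismatch=0,
                gapopen=0, qstart=1, qend=length, sstart=1, send=length,
                evalue=ev, bitscore=bits,
            )
            for q, s, length, ev, bits in rows
        ],
        columns=BLAST6_COLUMNS,
    )


def test_read_hit_table_empty_and_roundtrip(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("")
    assert len(read_hit_table(p)) == 0

    df = _hits([("q1", "s1", 300, 1e-50, 100.0), ("q1", "s2", 250, 1e-40, 90.0),
                ("q2", "s1", 400, 1e-60, 120.0)])
    out = tmp_path / "hits.tsv"
    write_hit_table(df, out)
    back = read_hit_table(out)
    assert len(back) == 3
    pd.testing.assert_frame_equal(back, df, check_dtype=False)


def test_read_hit_table_reports_bad_line(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("a\tb\t90\t100\t0\t0\t1\t100\t1\t100\t1e-5\t50\n" + "a\tb\tc\n")
    with pytest.raises(HitTableFormatError, match="line 2"):
        read_hit_table(p)
    p.write_text("a\tb\tNINETY\t100\t0\t0\t1\t100\t1\t100\t1e-5\t50\n")
    with pytest.raises(HitTableFormatError, match="line 1"):
        read_hit_table(p)


def test_best_hits_ranking_and_length_filter():
    hits = _hits([("q", "s1", 300, 1e-10, 100.0), ("q", "s2", 300, 1e-10, 90.0)])
    assert best_hits(hits) == {"q": "s1"}
    # single hit below the 200 bp minimum: query disappears
    assert best_hits(_hits([("q", "s1", 199, 1e-80, 500.0)])) == {}
    # ties: lower evalue, then lexicographic subject
    hits = _hits([("q", "s2", 300, 1e-10, 100.0), ("q", "s1", 300, 1e-10, 100.0)])
    assert best_hits(hits) == {"q": "s1"}
    hits = _hits([("q", "s2", 300, 1e-12, 100.0), ("q", "s1", 300, 1e-10, 100.0)])
    assert best_hits(hits) == {"q": "s2"}


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.data())
def test_best_hits_matches_exhaustive_oracle(data):
    rows = []
    for qi in range(5):
        for _ in range(4):
            rows.append(
                (
                    f"q{qi}",
                    f"s{data.draw(st.integers(0, 6))}",
                    data.draw(st.integers(150, 400)),
                    10.0 ** -data.draw(st.integers(1, 50)),
                    float(data.draw(st.integers(10, 200))),
                )
            )
    hits = _hits(rows)
    result = best_hits(hits, 200)
    # oracle: full scan over surviving rows per query
    surviving = [r for r in rows if r[2] >= 200]
    for q in {r[0] for r in rows}:
        mine = result.get(q)
        qrows = [r for r in surviving if r[0] == q]
        if not qrows:
            assert mine is None
            continue
        expected = min(qrows, key=lambda r: (-r[4], r[3], r[1]))[1]
        assert mine == expected


def test_reciprocal_examples_and_oracle(rng):
    assert reciprocal_best_hits({"a": "b"}, {"b": "a"}) == [("a", "b")]
    assert reciprocal_best_hits({"a": "b"}, {"b": "c"}) == []
    # random bipartite maps vs O(n^2) enumeration
    fwd = {f"a{i}": f"b{rng.integers(0, 8)}" for i in range(10)}
    rev = {f"b{i}": f"a{rng.integers(0, 10)}" for i in range(8)}
    oracle = sorted(
        (a, b)
        for a in fwd
        for b in rev
        if fwd[a] == b and rev[b] == a
    )
    assert reciprocal_best_hits(fwd, rev) == oracle


def test_disambiguation_rules():
    pairs = [("a1", "b1")]
    ra = _hits([("a1", "P12345", 300, 1e-20, 200.0)])
    rb = _hits([("b1", "P12345", 300, 1e-20, 200.0)])
    kept = disambiguate_by_reference(pairs, ra, rb)
    assert len(kept) == 1 and kept[0].reference_accession == "P12345"
    # different best accessions: dropped
    rb2 = _hits([("b1", "P99999", 300, 1e-30, 250.0)])
    assert disambiguate_by_reference(pairs, ra, rb2) == []
    # best reference evalue above 1e-5: dropped
    rb3 = _hits([("b1", "P12345", 300, 1e-4, 200.0)])
    assert disambiguate_by_reference(pairs, ra, rb3) == []


def test_strict_unambiguous_flag():
    pairs = [("a1", "b1")]
    ra = _hits([("a1", "P1", 300, 1e-20, 200.0), ("a1", "P2", 300, 1e-10, 150.0)])
    rb = _hits([("b1", "P1", 300, 1e-20, 200.0)])
    assert len(disambiguate_by_reference(pairs, ra, rb)) == 1
    assert disambiguate_by_reference(pairs, ra, rb, strict_unambiguous=True) == []


def _toy_dataset(rng, n=12):
    tx_a = {f"A{i}": "A" * 300 for i in range(n)}
    tx_b = {f"B{i}": "A" * 300 for i in range(n)}
    truth = [(f"OG{i}", f"A{i}", f"B{i}") for i in range(n)]
    return tx_a, tx_b, truth


def test_hit_table_roundtrip_recovers_truth(rng):
    tx_a, tx_b, truth = _toy_dataset(rng)
    tabs = make_hit_tables(tx_a, tx_b, truth, rng)
    pairs = find_orthologs(tabs["ab"], tabs["ba"], tabs["aref"], tabs["bref"])
    assert sorted(zip(pairs.id_A, pairs.id_B)) == sorted((a, b) for _, a, b in truth)


def test_hit_table_confounders_are_rejected(rng):
    tx_a, tx_b, truth = _toy_dataset(rng)
    tabs = make_hit_tables(
        tx_a, tx_b, truth, rng,
        short_match_pairs={"OG0"}, ambiguous_ref_pairs={"OG1"}, weak_ref_pairs={"OG2"},
    )
    pairs = find_orthologs(tabs["ab"], tabs["ba"], tabs["aref"], tabs["bref"])
    got = set(pairs.id_A)
    assert {"A0", "A1", "A2"} & got == set()
    assert got == {f"A{i}" for i in range(3, 12)}


def test_cascade_is_order_independent(rng):
    tx_a, tx_b, truth = _toy_dataset(rng)
    tabs = make_hit_tables(tx_a, tx_b, truth, rng, short_match_pairs={"OG3"})
    shuffled = {
        k: v.sample(frac=1.0, random_state=5).reset_index(drop=True)
        for k, v in tabs.items()
    }
    p1 = find_orthologs(tabs["ab"], tabs["ba"], tabs["aref"], tabs["bref"])
    p2 = find_orthologs(shuffled["ab"], shuffled["ba"], shuffled["aref"], shuffled["bref"])
    pd.testing.assert_frame_equal(p1, p2)


def test_no_transcript_appears_twice(rng):
    tx_a, tx_b, truth = _toy_dataset(rng)
    tabs = make_hit_tables(tx_a, tx_b, truth, rng)
    pairs = find_orthologs(tabs["ab"], tabs["ba"], tabs["aref"], tabs["bref"])
    assert pairs.id_A.is_unique and pairs.id_B.is_unique


def test_make_hit_tables_rejects_unknown_ids(rng):
    with pytest.raises(ValueError, match="unknown"):
        make_hit_tables({"A0": "ACGT"}, {"B0": "ACGT"}, [("OG0", "A0", "BX")], rng)
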