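"""Reciprocal-best-hit orthology with a reference-protein disambiguation step.

The filter cascade mirrors standard cross-transcriptome ortholog calling:

1. drop hits with match length below a minimum (default 200 bp) from the
   reciprocal tables, then take each query's best surviving hit (bitscore,
   ties broken by lower e-value, then lexicographically smaller subject id);
2. keep a pair (a, b) iff a's best hit is b AND b's best hit is a;
3. keep a pair iff both members' best reference-protein hits (at e-value
   <= 1e-5) point to the same accession — removing likely paralog pairings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .simdata import BLAST6_COLUMNS

_NUMERIC = {
    "pident": float, "length": int, "mismatch": int, "gapopen": int,
    "qstart": int, "qend": int, "sstart": int, "send": int,
    "evalue": float, "bitscore": float,
}


class HitTableFormatError(ValueError):
    pass


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read a 12-column BLAST tabular (outfmt 6) file.

    Malformed rows (wrong column count, non-numeric score fields) raise
    HitTableFormatError naming the 1-based line number. An empty file yields
    an empty table with the standard columns.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise HitTableFormatError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, got {len(parts)}"
                )
            rec = dict(zip(BLAST6_COLUMNS, parts))
            for col, typ in _NUMERIC.items():
                try:
                    rec[col] = typ(float(rec[col])) if typ is int else typ(rec[col])
                except ValueError as exc:
                    raise HitTableFormatError(
                        f"{path}: line {lineno}: non-numeric value {rec[col]!r} in column {col}"
                    ) from exc
            if rec["length"] < 1:
                raise HitTableFormatError(f"{path}: line {lineno}: match length < 1")
            if rec["evalue"] < 0:
                raise HitTableFormatError(f"{path}: line {lineno}: negative evalue")
            rows.append(rec)
    return pd.DataFrame(rows, columns=BLAST6_COLUMNS)


def write_hit_table(hits: pd.DataFrame, path: str | Path) -> None:
    hits[BLAST6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def best_hits(hits: pd.DataFrame, min_match_len: int = 200) -> dict[str, str]:
    """Best subject per query after discarding matches shorter than min_match_len.

    Ranking: maximal bitscore; ties by lower evalue, then lexicographically
    smaller subject id (fully deterministic).
    """
    if min_match_len < 1:
        raise ValueError("min_match_len must be >= 1")
    best: dict[str, tuple] = {}
    for row in hits.itertuples(index=False):
        if row.length < min_match_len:
            continue
        key = (-row.bitscore, row.evalue, row.sseqid)
        cur = best.get(row.qseqid)
        if cur is None or key < cur:
            best[row.qseqid] = key
    return {q: key[2] for q, key in best.items()}


def reciprocal_best_hits(fwd_map: dict[str, str], rev_map: dict[str, str]) -> list[tuple[str, str]]:
    """Pairs (a, b) with fwd[a] == b and rev[b] == a, sorted by a."""
    return sorted(
        (a, b) for a, b in fwd_map.items() if rev_map.get(b) == a
    )


@dataclass(frozen=True)
class CandidatePair:
    id_a: str
    id_b: str
    reference_accession: str


def disambiguate_by_reference(
    pairs: list[tuple[str, str]],
    ref_hits_a: pd.DataFrame,
    ref_hits_b: pd.DataFrame,
    evalue_max: float = 1e-5,
    strict_unambiguous: bool = False,
) -> list[CandidatePair]:
    """Keep pairs whose members' best reference-protein hits agree.

    Each member must have a best reference hit (same ranking rule as
    best_hits, no length filter) with evalue <= evalue_max, and both best
    accessions must be identical. With strict_unambiguous, a member is also
    rejected if more than one distinct accession falls below the threshold.
    """
    def _best_and_count(hits: pd.DataFrame):
        best: dict[str, tuple] = {}
        n_below: dict[str, set] = {}
        for row in hits.itertuples(index=False):
            key = (-row.bitscore, row.evalue, row.sseqid)
            cur = best.get(row.qseqid)
            if cur is None or key < cur:
                best[row.qseqid] = key
            if row.evalue <= evalue_max:
                n_below.setdefault(row.qseqid, set()).add(row.sseqid)
        return best, n_below

    best_a, below_a = _best_and_count(ref_hits_a)
    best_b, below_b = _best_and_count(ref_hits_b)
    kept = []
    for a, b in pairs:
        ka, kb = best_a.get(a), best_b.get(b)
        if ka is None or kb is None:
            continue
        if ka[1] > evalue_max or kb[1] > evalue_max:
            continue
        if ka[2] != kb[2]:
            continue
        if strict_unambiguous and (len(below_a.get(a, ())) > 1 or len(below_b.get(b, ())) > 1):
            continue
        kept.append(CandidatePair(a, b, ka[2]))
    return kept


def find_orthologs(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    hits_aref: pd.DataFrame,
    hits_bref: pd.DataFrame,
    min_match_len: int = 200,
    evalue_max: float = 1e-5,
    strict_unambiguous: bool = False,
) -> pd.DataFrame:
    """Full cascade; returns a table (id_A, id_B, reference_accession)."""
    fwd = best_hits(hits_ab, min_match_len)
    rev = best_hits(hits_ba, min_match_len)
    pairs = reciprocal_best_hits(fwd, rev)
    kept = disambiguate_by_reference(
        pairs, hits_aref, hits_bref, evalue_max, strict_unambiguous
    )
    return pd.DataFrame(
        [(p.id_a, p.id_b, p.reference_accession) for p in kept],
        columns=["id_A", "id_B", "reference_accession"],
    )
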