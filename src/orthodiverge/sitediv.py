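"""Site-class divergence accounting between orthologous CDS pairs.

Aligned coding sites are classified by codon-position degeneracy (nd = any
change is nonsynonymous, 4d = no change is nonsynonymous, with 2d/3d between)
and by CpG context (a base participating in a C immediately followed by G on
the degapped sequence; hypermutable via deamination of methylated cytosine).
Divergence is then tabulated per (region, CpG context) cell: regions are the
whole CDS, nd sites and 4d sites; contexts are All / No CpG / CpG.

A site enters the nd (resp. 4d) tally only when both sequences' codons assign
it that class; discordant columns are 'mixed' and count in the CDS region
only. Columns with a gap or an ambiguous base (N) in either row are excluded
from all tallies (gap/N codons are excluded whole, since degeneracy is a
property of the full codon). Per-cell means and standard errors are taken
across pairs, unweighted; 'compared kb' is the pooled site count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._codons import CODON_INDEX, DEG64, degeneracy_class  # noqa: F401 (re-export)
from .cdsproc import CodonAlignment

MIXED = 5
_CLASS_CODE = {"nd": 0, "2d": 2, "3d": 3, "4d": 4}

REGIONS = ("CDS", "nd", "4d")
CONTEXTS = ("All", "No CpG", "CpG")


def classify_cpg(aligned_a: str, aligned_b: str, mode: str = "first") -> np.ndarray:
    """Per-column CpG-context flags for a pair of equal-length gapped strings.

    A base is in CpG context when it participates in a 5'-CG-3' dinucleotide
    of its own degapped sequence (both members of the CG are flagged). mode:
    'first' (default) annotates context on sequence A alone, the rule that is
    calibrated under a CpG-neutral model; 'either' flags a column if either
    sequence's base is in context (inflates apparent CpG divergence by
    ascertainment: a mismatched column has two chances to carry a CG);
    'both' requires both sequences (deflates it symmetrically).
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings differ in length")
    if mode not in ("either", "both", "first"):
        raise ValueError(f"unknown cpg mode {mode!r}")

    def _row_flags(aligned: str) -> np.ndarray:
        cols = np.frombuffer(aligned.encode(), dtype="S1")
        idx = np.nonzero(cols != b"-")[0]
        seq = cols[idx]
        flags_seq = np.zeros(len(seq), dtype=bool)
        if len(seq) > 1:
            cg = (seq[:-1] == b"C") & (seq[1:] == b"G")
            flags_seq[:-1] |= cg
            flags_seq[1:] |= cg
        flags = np.zeros(len(aligned), dtype=bool)
        flags[idx] = flags_seq
        return flags

    fa, fb = _row_flags(aligned_a), _row_flags(aligned_b)
    if mode == "either":
        return fa | fb
    if mode == "both":
        return fa & fb
    return fa


@dataclass
class SiteClassMap:
    """Per aligned nucleotide column: validity, degeneracy class, CpG flag,
    mismatch flag, and the two bases (for GC accounting)."""

    valid: np.ndarray      # bool: both rows gap-free, N-free
    clazz: np.ndarray      # int: 0 nd, 2 2d, 3 3d, 4 4d, 5 mixed (-1 invalid)
    cpg: np.ndarray        # bool
    mismatch: np.ndarray   # bool
    gc_count: np.ndarray   # int 0..2: G/C bases among the two rows


def classify_alignment(aln: CodonAlignment, cpg_mode: str = "first") -> SiteClassMap:
    n = len(aln.aligned_a)
    valid = np.zeros(n, dtype=bool)
    clazz = np.full(n, -1, dtype=np.int8)
    mismatch = np.zeros(n, dtype=bool)
    gc_count = np.zeros(n, dtype=np.int8)
    cpg = classify_cpg(aln.aligned_a, aln.aligned_b, cpg_mode)
    for col, (ca, cb) in enumerate(aln.codon_columns()):
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        ia, ib = CODON_INDEX[ca], CODON_INDEX[cb]
        da, db = DEG64[ia], DEG64[ib]
        if da[0] < 0 or db[0] < 0:
            raise ValueError(f"stop codon in alignment column {col}")
        for p in range(3):
            j = 3 * col + p
            valid[j] = True
            clazz[j] = da[p] if da[p] == db[p] else MIXED
            mismatch[j] = ca[p] != cb[p]
            gc_count[j] = (ca[p] in "GC") + (cb[p] in "GC")
    return SiteClassMap(valid, clazz, cpg, mismatch, gc_count)


def pairwise_divergence(aln: CodonAlignment, site_mask: np.ndarray) -> tuple[float, int]:
    """(% mismatched columns, number of compared columns) under a mask.

    With an empty mask the percentage is undefined (nan) and the pair
    contributes zero sites.
    """
    smap = classify_alignment(aln)
    mask = np.asarray(site_mask, dtype=bool) & smap.valid
    n = int(mask.sum())
    if n == 0:
        return float("nan"), 0
    return 100.0 * float(smap.mismatch[mask].sum()) / n, n


def _region_mask(smap: SiteClassMap, region: str) -> np.ndarray:
    if region == "CDS":
        return smap.valid
    code = _CLASS_CODE[region]
    return smap.valid & (smap.clazz == code)


def _context_mask(smap: SiteClassMap, context: str) -> np.ndarray:
    if context == "All":
        return smap.valid
    if context == "CpG":
        return smap.valid & smap.cpg
    return smap.valid & ~smap.cpg


def divergence_table(alignments: dict[str, CodonAlignment], cpg_mode: str = "first") -> pd.DataFrame:
    """Per (region, context) divergence summary across all pairs.

    Columns: region, context, loci, mean_pct_diff, se, compared_kb and, for
    the All context, pct_cpg / pct_gc over the region's classified sites.
    """
    if not alignments:
        raise ValueError("no alignments")
    per_cell_pcts: dict[tuple[str, str], list[float]] = {
        (r, c): [] for r in REGIONS for c in CONTEXTS
    }
    per_cell_sites = {(r, c): 0 for r in REGIONS for c in CONTEXTS}
    per_cell_mm = {(r, c): 0 for r in REGIONS for c in CONTEXTS}
    region_cpg = {r: 0 for r in REGIONS}
    region_gc = {r: 0 for r in REGIONS}
    region_loci = {r: 0 for r in REGIONS}

    for pid in sorted(alignments):
        smap = classify_alignment(alignments[pid], cpg_mode)
        for region in REGIONS:
            rmask = _region_mask(smap, region)
            if rmask.any():
                region_loci[region] += 1
                region_cpg[region] += int((smap.cpg & rmask).sum())
                region_gc[region] += int(smap.gc_count[rmask].sum())
            for context in CONTEXTS:
                mask = rmask & _context_mask(smap, context)
                n = int(mask.sum())
                if n == 0:
                    continue
                mm = int(smap.mismatch[mask].sum())
                per_cell_sites[(region, context)] += n
                per_cell_mm[(region, context)] += mm
                per_cell_pcts[(region, context)].append(100.0 * mm / n)

    rows = []
    for region in REGIONS:
        n_region = per_cell_sites[(region, "All")]
        for context in CONTEXTS:
            pcts = np.array(per_cell_pcts[(region, context)])
            mean = float(pcts.mean()) if len(pcts) else float("nan")
            se = float(pcts.std(ddof=1) / np.sqrt(len(pcts))) if len(pcts) > 1 else 0.0
            rows.append(
                {
                    "region": region,
                    "context": context,
                    "loci": region_loci[region],
                    "mean_pct_diff": mean,
                    "se": se,
                    "compared_kb": per_cell_sites[(region, context)] / 1000.0,
                    "pct_cpg": 100.0 * region_cpg[region] / n_region if context == "All" and n_region else float("nan"),
                    "pct_gc": 100.0 * region_gc[region] / (2 * n_region) if context == "All" and n_region else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def sequence_identity(aln: CodonAlignment) -> tuple[float, float]:
    """(% nucleotide identity over ungapped columns, % amino-acid identity
    over aligned residue pairs); gap/N columns are excluded."""
    from ._codons import AA64

    nt_n = nt_same = aa_n = aa_same = 0
    for ca, cb in aln.codon_columns():
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        aa_n += 1
        if AA64[CODON_INDEX[ca]] == AA64[CODON_INDEX[cb]]:
            aa_same += 1
        for p in range(3):
            nt_n += 1
            if ca[p] == cb[p]:
                nt_same += 1
    if nt_n == 0:
        return float("nan"), float("nan")
    return 100.0 * nt_same / nt_n, 100.0 * aa_same / aa_n


def identity_table(alignments: dict[str, CodonAlignment]) -> pd.DataFrame:
    """Per-pair nt/aa identity and per-class site counts."""
    rows = []
    for pid in sorted(alignments):
        aln = alignments[pid]
        nt_id, aa_id = sequence_identity(aln)
        smap = classify_alignment(aln)
        counts = {
            name: int((smap.clazz[smap.valid] == code).sum())
            for name, code in (("nd", 0), ("2d", 2), ("3d", 3), ("4d", 4), ("mixed", MIXED))
        }
        rows.append(
            {"pair_id": pid, "nt_identity": nt_id, "aa_identity": aa_id,
             "n_sites": int(smap.valid.sum()), **{f"n_{k}": v for k, v in counts.items()}}
        )
    return pd.DataFrame(rows)
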