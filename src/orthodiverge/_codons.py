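"""Genetic-code lookup tables shared by the simulator, the site classifier and
the substitution-rate estimators.

Everything here is derived once, at import time, from the standard nuclear
genetic code (NCBI translation table 1) as provided by Biopython. Codons are
indexed 0..63 in TCAG order (the classic codon-table ordering), nucleotides
0..3 = T, C, A, G.
"""

from __future__ import annotations

from Bio.Data import CodonTable

NUCS = "TCAG"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

#: transitions pair T<->C (0,1) and A<->G (2,3)
def is_transition(a: str, b: str) -> bool:
    """True if a->b is a transition (purine<->purine or pyrimidine<->pyrimidine)."""
    i, j = NUC_INDEX[a], NUC_INDEX[b]
    return i != j and (i // 2) == (j // 2)


CODONS = tuple(a + b + c for a in NUCS for b in NUCS for c in NUCS)
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_table = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_table.stop_codons)
SENSE_CODONS = tuple(c for c in CODONS if c not in STOP_CODONS)
SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}  # 0..60

#: amino acid (one letter) per sense codon string
AA_OF = {c: _table.forward_table[c] for c in SENSE_CODONS}

#: amino acid per 64-codon index; '*' for stops
AA64 = tuple(AA_OF.get(c, "*") for c in CODONS)


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate(cds: str) -> str:
    """Translate an in-frame CDS (no terminal stop required); stops become '*'."""
    if len(cds) % 3:
        raise ValueError("CDS length not a multiple of 3")
    return "".join(AA64[CODON_INDEX[cds[i : i + 3]]] for i in range(0, len(cds), 3))


# --- single-nucleotide mutation structure -----------------------------------
# MUTATIONS[c64] = tuple of (pos, new_c64, is_ts, is_syn) over the 9 single-nt
# neighbours of codon c64, excluding mutations that create a stop codon.
# Stops themselves have an empty tuple.
def _build_mutations():
    out = []
    for c in CODONS:
        if c in STOP_CODONS:
            out.append(())
            continue
        rows = []
        for pos in range(3):
            for n in NUCS:
                if n == c[pos]:
                    continue
                m = c[:pos] + n + c[pos + 1 :]
                if m in STOP_CODONS:
                    continue
                rows.append(
                    (
                        pos,
                        CODON_INDEX[m],
                        is_transition(c[pos], n),
                        AA_OF[m] == AA_OF[c],
                    )
                )
        out.append(tuple(rows))
    return tuple(out)


MUTATIONS = _build_mutations()

# degeneracy class codes
ND, TWOFOLD, THREEFOLD, FOURFOLD = 0, 2, 3, 4
CLASS_NAMES = {ND: "nd", TWOFOLD: "2d", THREEFOLD: "3d", FOURFOLD: "4d"}


def degeneracy_class(codon: str, position: int) -> str:
    """Degeneracy class of one codon position: 'nd', '2d', '3d' or '4d'.

    Among the three single-nucleotide variants at `position`, variants that
    create stop codons are excluded from the denominator; the class counts how
    many of the remaining variants are synonymous. Zero -> 'nd'; all three
    possible and synonymous -> '4d'; otherwise '2d' (one) or '3d' (two).
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no degeneracy class")
    if any(n not in NUC_INDEX for n in codon):
        raise ValueError(f"ambiguous codon {codon!r}")
    if position not in (0, 1, 2):
        raise ValueError("position must be 0, 1 or 2")
    syn = 0
    possible = 0
    for n in NUCS:
        if n == codon[position]:
            continue
        m = codon[:position] + n + codon[position + 1 :]
        if m in STOP_CODONS:
            continue
        possible += 1
        if AA_OF[m] == AA_OF[codon]:
            syn += 1
    if syn == 0:
        return "nd"
    if syn == 3:  # implies possible == 3
        return "4d"
    return "2d" if syn == 1 else "3d"


# DEG64[c64][pos] = class code, -1 for stop codons
def _build_deg():
    codes = {"nd": ND, "2d": TWOFOLD, "3d": THREEFOLD, "4d": FOURFOLD}
    out = []
    for c in CODONS:
        if c in STOP_CODONS:
            out.append((-1, -1, -1))
        else:
            out.append(tuple(codes[degeneracy_class(c, p)] for p in range(3)))
    return tuple(out)


DEG64 = _build_deg()
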