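"""CDS prediction, UTR delineation and codon-aware pairwise alignment.

CDS calls come from a deterministic longest-complete-ORF finder over all six
reading frames (a complete ORF starts with ATG and ends with TAA/TGA/TAG, with
no internal stop). An external predictor's CDS calls can be supplied instead
(per-transcript coordinate hints); those calls, like any trained gene
predictor's, may read through unexpected in-frame stop codons — exactly the
miscalls the internal-stop filter exists to remove.

Pair alignment is done in protein space (BLOSUM62, affine gaps) and
back-translated, which guarantees frame-preserving whole-codon gaps — a
requirement of every downstream codon-level operation. The standard nuclear
genetic code (translation table 1) is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from ._codons import STOP_CODONS, translate

GAP_CODON = "---"


@dataclass(frozen=True)
class OrfCall:
    """An open reading frame on a transcript.

    start/end are 0-based half-open nucleotide coordinates on the chosen
    orientation ('+' = input strand, '-' = reverse complement); end includes
    the stop codon. complete means ATG start and TAA/TGA/TAG end.
    """

    strand: str
    frame: int
    start: int
    end: int
    complete: bool

    @property
    def cds_len(self) -> int:
        """CDS length in nucleotides, excluding the terminal stop codon."""
        return self.end - self.start - 3


def _scan_forward_frames(seq: str):
    """Yield (frame, start, end) for every complete ORF (first-ATG per
    inter-stop interval) in the three forward frames of seq."""
    n = len(seq)
    for frame in range(3):
        start = None
        broken = False  # current interval contains an N-codon
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                start = None
                broken = True
                continue
            if codon in STOP_CODONS:
                if start is not None and not broken:
                    yield frame, start, i + 3
                start = None
                broken = False
                continue
            if start is None and codon == "ATG" and not broken:
                start = i
            # an N earlier in the interval only poisons ORFs that span it
            if broken and codon == "ATG":
                start = i
                broken = False


def predict_orf(transcript: str) -> OrfCall | None:
    """Longest complete ORF over all six frames, or None if there is none.

    Ties prefer forward frames over reverse, then smaller start, then smaller
    frame. ORFs spanning an N are rejected.
    """
    seq = transcript.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("transcript must be over A/C/G/T/N")
    candidates = []
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for frame, start, end in _scan_forward_frames(s):
            candidates.append(
                (-(end - start), 0 if strand == "+" else 1, start, frame, strand, end)
            )
    if not candidates:
        return None
    neg_len, _, start, frame, strand, end = min(candidates)
    return OrfCall(strand=strand, frame=frame, start=start, end=end, complete=True)


def oriented_sequence(transcript: str, orf: OrfCall) -> str:
    """The transcript in the ORF's orientation."""
    seq = transcript.upper()
    return seq if orf.strand == "+" else str(Seq(seq).reverse_complement())


def delineate_utrs(transcript: str, orf: OrfCall) -> tuple[str, str, str]:
    """Split the (oriented) transcript into (utr5, cds, utr3).

    cds excludes the terminal stop codon; the oriented transcript is exactly
    utr5 + cds + stop + utr3.
    """
    seq = oriented_sequence(transcript, orf)
    return seq[: orf.start], seq[orf.start : orf.end - 3], seq[orf.end :]


# --------------------------------------------------------------------------
# protein alignment and back-translation

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def align_proteins(prot_a: str, prot_b: str) -> tuple[str, str, float]:
    """Optimal global alignment under BLOSUM62 with affine gaps (open 10,
    extend 1). Returns (gapped_a, gapped_b, score); the first optimal
    traceback is taken, which is deterministic."""
    if not prot_a or not prot_b:
        raise ValueError("protein sequences must be non-empty")
    alignment = next(iter(_ALIGNER.align(prot_a, prot_b)))
    return str(alignment[0]), str(alignment[1]), float(alignment.score)


@dataclass(frozen=True)
class CodonAlignment:
    """A gap-aware codon alignment; gaps occur only as whole '---' codons."""

    aligned_a: str
    aligned_b: str

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")
        if len(self.aligned_a) % 3:
            raise ValueError("alignment length not a multiple of 3")

    @property
    def n_codon_columns(self) -> int:
        return len(self.aligned_a) // 3

    def codon_columns(self):
        """Yield (codon_a, codon_b) per aligned codon column."""
        for i in range(0, len(self.aligned_a), 3):
            yield self.aligned_a[i : i + 3], self.aligned_b[i : i + 3]

    def degapped(self) -> tuple[str, str]:
        return self.aligned_a.replace("-", ""), self.aligned_b.replace("-", "")


def backtranslate_alignment(prot_aln_a: str, prot_aln_b: str, cds_a: str, cds_b: str) -> CodonAlignment:
    """Thread the source codons through a protein alignment.

    Each residue becomes its codon, each residue gap becomes '---'. The
    proteins must be the exact translations of their CDS (stop excluded).
    """
    def _row(prot_aln: str, cds: str) -> str:
        plain = prot_aln.replace("-", "")
        if translate(cds) != plain:
            raise ValueError("protein is not the translation of the CDS")
        out = []
        k = 0
        for ch in prot_aln:
            if ch == "-":
                out.append(GAP_CODON)
            else:
                out.append(cds[3 * k : 3 * k + 3])
                k += 1
        return "".join(out)

    return CodonAlignment(_row(prot_aln_a, cds_a), _row(prot_aln_b, cds_b))


def align_cds_pair(cds_a: str, cds_b: str) -> CodonAlignment:
    """Codon-aware alignment of two stop-free CDS via protein space."""
    pa, pb, _ = align_proteins(translate(cds_a), translate(cds_b))
    return backtranslate_alignment(pa, pb, cds_a, cds_b)


# --------------------------------------------------------------------------
# pair filters

def filter_pair(cds_a: str, cds_b: str, min_cds_len: int = 150) -> tuple[bool, str | None]:
    """Apply the CDS-length and unexpected-stop filters to an ortholog pair.

    Drops the pair if either CDS is not strictly longer than min_cds_len
    (reason 'cds_length') or if either CDS contains a stop codon before its
    last codon (reason 'internal_stop').
    """
    if len(cds_a) <= min_cds_len or len(cds_b) <= min_cds_len:
        return False, "cds_length"
    for cds in (cds_a, cds_b):
        body = cds[: len(cds) - (len(cds) % 3)]
        if "*" in translate(body):
            # any stop inside the designated CDS (which excludes the terminal
            # stop codon) is unexpected
            return False, "internal_stop"
    return True, None


# --------------------------------------------------------------------------
# pipeline stage

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_orf_hints(path: str | Path) -> dict[str, OrfCall]:
    """Read external-predictor CDS calls (transcript_id, start, end, strand)."""
    df = pd.read_csv(path, sep="\t")
    hints = {}
    for row in df.itertuples(index=False):
        hints[row.transcript_id] = OrfCall(
            strand=row.strand, frame=int(row.start) % 3,
            start=int(row.start), end=int(row.end), complete=True,
        )
    return hints


def process_pairs(
    pairs: pd.DataFrame,
    transcripts_a: dict[str, str],
    transcripts_b: dict[str, str],
    min_cds_len: int = 150,
    orf_hints: dict[str, OrfCall] | None = None,
) -> tuple[dict[str, CodonAlignment], pd.DataFrame]:
    """Delineate CDS on both members of each pair, filter, and align.

    pairs: table with id_A/id_B columns (orthofind output). Returns
    (alignments keyed by id_A, per-pair metadata table with keep/drop reasons).
    External predictor hints, when provided, take precedence over the internal
    ORF finder for the transcripts they cover.
    """
    orf_hints = orf_hints or {}
    alignments: dict[str, CodonAlignment] = {}
    meta = []
    for row in pairs.itertuples(index=False):
        ida, idb = row.id_A, row.id_B
        rec = {"id_A": ida, "id_B": idb, "status": "kept", "reason": ""}
        cds = {}
        ok = True
        for member, tid, txs in (("A", ida, transcripts_a), ("B", idb, transcripts_b)):
            tx = txs.get(tid)
            if tx is None:
                rec.update(status="dropped", reason="missing_transcript")
                ok = False
                break
            orf = orf_hints.get(tid) or predict_orf(tx)
            if orf is None:
                rec.update(status="dropped", reason="no_orf")
                ok = False
                break
            utr5, c, utr3 = delineate_utrs(tx, orf)
            cds[member] = c
            rec[f"cds_start_{member}"] = orf.start
            rec[f"cds_len_{member}"] = len(c)
            rec[f"utr5_len_{member}"] = len(utr5)
            rec[f"utr3_len_{member}"] = len(utr3)
        if ok:
            keep, reason = filter_pair(cds["A"], cds["B"], min_cds_len)
            if keep:
                alignments[ida] = align_cds_pair(cds["A"], cds["B"])
            else:
                rec.update(status="dropped", reason=reason)
        meta.append(rec)
    return alignments, pd.DataFrame(meta)


def write_alignments(alignments: dict[str, CodonAlignment], path: str | Path) -> None:
    """Write all pair alignments to one FASTA (two records per pair)."""
    with open(path, "w") as fh:
        for pid in sorted(alignments):
            aln = alignments[pid]
            fh.write(f">{pid}|A\n{aln.aligned_a}\n>{pid}|B\n{aln.aligned_b}\n")


def read_alignments(path: str | Path) -> dict[str, CodonAlignment]:
    rows: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pid, member = rec.id.rsplit("|", 1)
        rows.setdefault(pid, {})[member] = str(rec.seq).upper()
    out = {}
    for pid, d in rows.items():
        if set(d) != {"A", "B"}:
            raise ValueError(f"pair {pid}: expected records A and B")
        out[pid] = CodonAlignment(d["A"], d["B"])
    return out
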