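"""Identify orthologs by reciprocal best hits, then align their CDS.

Runs the hit-table cascade (200 bp minimum match, reciprocal best bitscore,
agreement of the best reference-protein accession at e-value <= 1e-5), then
predicts CDS on each member, applies the CDS-length (>150 nt) and unexpected
internal-stop filters, and builds codon-aware alignments in protein space.
"""

from pathlib import Path

from orthodiverge import simulate_dataset
from orthodiverge.cdsproc import process_pairs, read_fasta, read_orf_hints
from orthodiverge.orthofind import find_orthologs, read_hit_table

files = simulate_dataset(
    {"n_pairs": 30, "n_codons": 150, "n_short_match": 2, "n_ambiguous_ref": 2,
     "n_short_cds": 2, "n_internal_stop": 2},
    Path("scratch/example_orth"),
    seed=11,
)

pairs = find_orthologs(
    read_hit_table(files["hits_ab"]), read_hit_table(files["hits_ba"]),
    read_hit_table(files["hits_aref"]), read_hit_table(files["hits_bref"]),
)
print(f"reciprocal-best-hit pairs after reference disambiguation: {len(pairs)} of 30")
print("(2 short-match and 2 ambiguous-reference confounders were removed)")

alignments, meta = process_pairs(
    pairs,
    read_fasta(files["fasta_a"]), read_fasta(files["fasta_b"]),
    orf_hints=read_orf_hints(files["orf_hints"]),
)
print(f"\npairs surviving CDS filters: {len(alignments)}")
print("drop reasons:")
print(meta[meta.status == "dropped"].reason.value_counts().to_string())
print(
    "\n'cds_length' = a CDS of 150 nt or shorter; 'internal_stop' = an"
    " unexpected stop codon inside a predicted CDS."
)
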