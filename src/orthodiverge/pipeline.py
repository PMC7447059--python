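"""End-to-end orchestration of the divergence analysis on files.

Each stage reads and writes plain text tables so any stage can be run alone;
`run_all` chains them: simulate -> orthologs -> CDS/alignment -> site-class
divergence -> Ka/Ks -> differential expression -> enrichment. All floating
point output is formatted with a fixed precision so repeated runs with the
same seed are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import cdsproc, diffexpr, enrich, kaks, orthofind, sitediv
from .simdata import simulate_dataset

FLOAT_FMT = "%.6g"


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
    return path


def run_orthologs(hits_ab, hits_ba, hits_aref, hits_bref, out: Path,
                  min_match_len: int = 200, evalue_max: float = 1e-5,
                  strict_unambiguous: bool = False) -> pd.DataFrame:
    pairs = orthofind.find_orthologs(
        orthofind.read_hit_table(hits_ab),
        orthofind.read_hit_table(hits_ba),
        orthofind.read_hit_table(hits_aref),
        orthofind.read_hit_table(hits_bref),
        min_match_len=min_match_len,
        evalue_max=evalue_max,
        strict_unambiguous=strict_unambiguous,
    )
    _write(pairs, Path(out))
    return pairs


def run_cds(pairs_tsv, fasta_a, fasta_b, out_dir: Path, min_cds_len: int = 150,
            orf_hints=None):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = pd.read_csv(pairs_tsv, sep="\t")
    hints = cdsproc.read_orf_hints(orf_hints) if orf_hints else None
    alignments, meta = cdsproc.process_pairs(
        pairs, cdsproc.read_fasta(fasta_a), cdsproc.read_fasta(fasta_b),
        min_cds_len=min_cds_len, orf_hints=hints,
    )
    cdsproc.write_alignments(alignments, out_dir / "alignments.fa")
    _write(meta, out_dir / "pair_meta.tsv")
    return alignments, meta


def run_divergence(alignments, out_dir: Path, cpg_mode: str = "first"):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = sitediv.divergence_table(alignments, cpg_mode=cpg_mode)
    identity = sitediv.identity_table(alignments)
    _write(table, out_dir / "divergence.tsv")
    _write(identity, out_dir / "identity.tsv")
    return table, identity


def run_kaks(alignments, out_dir: Path, method: str = "yn00"):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table, summary = kaks.batch_kaks(alignments, method=method)
    _write(table, out_dir / "kaks.tsv")
    _write(pd.DataFrame([summary]), out_dir / "kaks_summary.tsv")
    return table, summary


def run_de(counts_tsv, groups_tsv, out: Path, genes: list[str] | None = None,
           lfc_min: float = 1.0, fdr_max: float = 0.05,
           dispersion: float | None = None) -> pd.DataFrame:
    counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    groups = pd.read_csv(groups_tsv, sep="\t").set_index("sample_id")["group"]
    if genes is not None:
        counts = counts.loc[counts.index.intersection(genes)]
    called = diffexpr.call_deg(
        diffexpr.de_test(counts, groups, dispersion=dispersion),
        lfc_min=lfc_min, fdr_max=fdr_max,
    )
    _write(called.reset_index(), Path(out))
    return called


def run_enrich(called: pd.DataFrame, identity: pd.DataFrame,
               kaks_table: pd.DataFrame, annotation_tsv, out_dir: Path,
               quantile: float = 0.25):
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    annotation = enrich.read_annotation(annotation_tsv)
    aa_ident = identity.set_index("pair_id")["aa_identity"]

    deg_enr = enrich.pathway_deg_enrichment(called, annotation)
    _write(deg_enr, out_dir / "enrichment_deg.tsv")

    universe = set(aa_ident.index) & set(annotation.gene_id)
    hidiv, threshold = enrich.high_divergence_set(aa_ident, quantile=quantile)
    div_enr = enrich.pathway_enrichment(hidiv & universe, annotation, universe)
    div_enr.insert(0, "identity_threshold", round(threshold, 6))
    _write(div_enr, out_dir / "enrichment_divergence.tsv")

    summary = enrich.pathway_divergence_summary(aa_ident, kaks_table, annotation)
    _write(summary, out_dir / "pathway_summary.tsv")
    return deg_enr, div_enr, summary


DEFAULT_RUN_CONFIG = {
    "simulate": {},
    "min_match_len": 200,
    "evalue_max": 1e-5,
    "min_cds_len": 150,
    "cpg_mode": "first",
    "kaks_method": "yn00",
    "lfc_min": 1.0,
    "fdr_max": 0.05,
    "divergence_quantile": 0.25,
}


def run_all(config: dict | None, out_dir, seed: int) -> dict:
    """Chain every stage on a freshly simulated dataset; returns key results."""
    cfg = dict(DEFAULT_RUN_CONFIG)
    if config:
        config = dict(config)
        sim_cfg = config.pop("simulate", None)
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown run config keys: {sorted(unknown)}")
        cfg.update(config)
        cfg["simulate"] = sim_cfg or {}
    out_dir = Path(out_dir)
    sim_dir = out_dir / "sim"
    res_dir = out_dir / "results"
    res_dir.mkdir(parents=True, exist_ok=True)

    files = simulate_dataset(cfg["simulate"], sim_dir, seed)
    pairs = run_orthologs(
        files["hits_ab"], files["hits_ba"], files["hits_aref"], files["hits_bref"],
        res_dir / "pairs.tsv", cfg["min_match_len"], cfg["evalue_max"],
    )
    alignments, meta = run_cds(
        res_dir / "pairs.tsv", files["fasta_a"], files["fasta_b"], res_dir,
        cfg["min_cds_len"], orf_hints=files["orf_hints"],
    )
    div_table, identity = run_divergence(alignments, res_dir, cfg["cpg_mode"])
    kaks_table, kaks_summary = run_kaks(alignments, res_dir, cfg["kaks_method"])
    called = run_de(
        files["counts"], files["groups"], res_dir / "de.tsv",
        genes=sorted(alignments), lfc_min=cfg["lfc_min"], fdr_max=cfg["fdr_max"],
    )
    deg_enr, div_enr, pw_summary = run_enrich(
        called, identity, kaks_table, files["annotation"], res_dir,
        cfg["divergence_quantile"],
    )
    return {
        "files": files,
        "pairs": pairs,
        "alignments": alignments,
        "pair_meta": meta,
        "divergence": div_table,
        "identity": identity,
        "kaks": kaks_table,
        "kaks_summary": kaks_summary,
        "de": called,
        "deg_enrichment": deg_enr,
        "divergence_enrichment": div_enr,
        "pathway_summary": pw_summary,
    }
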