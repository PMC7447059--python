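"""Gene-set over-representation and per-pathway divergence summaries.

Over-representation is the one-sided upper-tail hypergeometric ("hyper")
test: given a universe of tested genes, a selected set (e.g. differentially
expressed genes, or the high-divergence quartile of amino-acid identity) and
a pathway's genes, the p-value is P(overlap >= observed) under sampling
without replacement. No gene-length bias correction is applied. Raw and
Benjamini–Hochberg adjusted p-values are both reported, since pathway tables
routinely show nominal enrichment that does not survive adjustment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust


def high_divergence_set(aa_identities: pd.Series, quantile: float = 0.25) -> tuple[set, float]:
    """Genes with amino-acid identity strictly below the lower quantile.

    The threshold is the stated quantile of identity across all genes (linear
    interpolation); returns (gene set, threshold).
    """
    if len(aa_identities) < 4:
        raise ValueError("need at least 4 genes to take a quantile")
    values = aa_identities.astype(float)
    threshold = float(np.quantile(values.to_numpy(), quantile))
    return set(values.index[values < threshold]), threshold


def hypergeom_overrep(gene_set: set, pathway_genes: set, universe: set) -> float:
    """Upper-tail hypergeometric p-value P(X >= |set & pathway|).

    Population = universe, success states = gene_set, draws = pathway_genes.
    Exact summation of the pmf over the upper tail.
    """
    if not universe:
        raise ValueError("empty universe")
    if not gene_set <= universe or not pathway_genes <= universe:
        raise ValueError("set and pathway must be subsets of the universe")
    M, K, n = len(universe), len(gene_set), len(pathway_genes)
    k = len(gene_set & pathway_genes)
    hi = min(K, n)
    if k == 0:
        return 1.0
    support = np.arange(k, hi + 1)
    return float(min(1.0, stats.hypergeom.pmf(support, M, K, n).sum()))


def read_annotation(path) -> pd.DataFrame:
    """gene_id / pathway_id / pathway_name table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "pathway_id"}
    if not required <= set(df.columns):
        raise ValueError("annotation needs gene_id and pathway_id columns")
    if "pathway_name" not in df.columns:
        df["pathway_name"] = df["pathway_id"]
    return df


def _pathway_map(annotation: pd.DataFrame) -> dict[str, set]:
    return {pw: set(sub.gene_id) for pw, sub in annotation.groupby("pathway_id")}


def pathway_enrichment(gene_set: set, annotation: pd.DataFrame,
                       universe: set | None = None) -> pd.DataFrame:
    """One enrichment row per pathway with >= 1 annotated gene in the universe.

    The default universe is every annotated gene; pass the set of all tested
    genes to widen it. Genes outside the universe are ignored.
    """
    if universe is None:
        universe = set(annotation.gene_id)
    gene_set = set(gene_set) & universe
    names = dict(zip(annotation.pathway_id, annotation.pathway_name))
    rows = []
    for pw, members in sorted(_pathway_map(annotation).items()):
        members = members & universe
        if not members:
            continue
        k = len(gene_set & members)
        p = hypergeom_overrep(gene_set, members, universe)
        rows.append(
            {"pathway_id": pw, "pathway_name": names.get(pw, pw),
             "n_in_set": k, "n_in_pathway": len(members), "p": p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out.p.to_numpy())
    else:
        out["fdr"] = []
    return out


def pathway_deg_enrichment(called: pd.DataFrame, annotation: pd.DataFrame,
                           universe: set | None = None) -> pd.DataFrame:
    """Enrichment of differentially expressed genes among pathways.

    called: table with a 'call' column indexed by gene id (from call_deg).
    Universe defaults to the tested genes that carry >= 1 annotation.
    """
    tested = set(called.index)
    annotated = set(annotation.gene_id)
    if universe is None:
        universe = tested & annotated
    degs = set(called.index[called.call != "ns"]) & universe
    return pathway_enrichment(degs, annotation, universe)


def pathway_divergence_summary(aa_identities: pd.Series,
                               kaks_table: pd.DataFrame,
                               annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-pathway gene count, mean amino-acid identity and mean Ka/Ks.

    kaks_table: per-pair table with pair_id and omega columns; omega means are
    over genes with a defined (finite) omega. Sorted by ascending identity, so
    the most divergent pathways rank first.
    """
    kaks = kaks_table.set_index("pair_id") if "pair_id" in kaks_table.columns else kaks_table
    rows = []
    for pw, sub in annotation.groupby("pathway_id"):
        genes = sorted(set(sub.gene_id) & set(aa_identities.index))
        if not genes:
            continue
        omegas = kaks.omega.reindex(genes).dropna() if "omega" in kaks.columns else pd.Series(dtype=float)
        omegas = omegas[np.isfinite(omegas)]
        rows.append(
            {
                "pathway_id": pw,
                "pathway_name": sub.pathway_name.iloc[0],
                "n_genes": len(genes),
                "mean_aa_identity": float(aa_identities.reindex(genes).mean()),
                "mean_omega": float(omegas.mean()) if len(omegas) else float("nan"),
                "n_omega_defined": int(len(omegas)),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values("mean_aa_identity").reset_index(drop=True)
    return out
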