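"""Synthetic data with known ground truth for validating the divergence pipeline.

The generator emulates the statistical structure the analysis assumes:

* orthologous CDS pairs diverged from a common ancestor under a GY94-style
  codon model (parameters: kappa = transition/transversion rate ratio,
  omega = nonsynonymous/synonymous rate ratio, t = expected substitutions per
  codon along the whole pair path, and a CpG hypermutability multiplier on
  transitions at CpG-context sites), wrapped into transcripts with UTRs;
* reciprocal and reference-protein similarity hit tables consistent with the
  true pairing, in BLAST tabular (outfmt 6) dialect, with optional planted
  confounders that exercise each orthology/CDS filter;
* two-group negative-binomial count matrices with planted fold changes;
* pathway annotations with planted enriched gene sets.

Evolution is simulated by exact (Gillespie) simulation of the continuous-time
Markov chain on sense codons: single-nucleotide exchanges only, proposals that
would create a stop codon carry rate zero, and CpG context is evaluated
dynamically on the current sequence (context can be created and destroyed).
The total path length t is split equally between the two lineages. Rates are
normalized so that one unit of t equals one expected codon substitution per
codon at equilibrium (normalization computed with the CpG multiplier off).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._codons import (
    CODONS,
    CODON_INDEX,
    MUTATIONS,
    NUC_INDEX,
    SENSE_CODONS,
    STOP_CODONS,
    translate,
)

_T, _C, _A, _G = 0, 1, 2, 3
_NT64 = tuple(tuple(NUC_INDEX[n] for n in c) for c in CODONS)
_STOPS = ("TAA", "TGA", "TAG")

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def uniform_codon_freqs() -> np.ndarray:
    """Uniform distribution over the 61 sense codons."""
    return np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))


@dataclass
class SimParams:
    """Parameters of the codon-pair simulator.

    t is the expected number of codon substitutions per codon along the whole
    ancestor->A plus ancestor->B path; it is split equally between lineages.
    """

    n_pairs: int = 100
    n_codons: int = 200
    kappa: float = 2.0
    omega: float = 0.2
    t: float = 0.8
    cpg_multiplier: float = 4.0
    utr5_len: int = 50
    utr3_len: int = 50
    codon_freqs: np.ndarray = field(default_factory=uniform_codon_freqs)
    seed: int = 0

    def __post_init__(self):
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.codon_freqs.shape != (len(SENSE_CODONS),):
            raise ValueError("codon_freqs must have one entry per sense codon (61)")
        if np.any(self.codon_freqs < 0) or self.codon_freqs.sum() <= 0:
            raise ValueError("codon_freqs must be non-negative with positive mass")
        if abs(self.codon_freqs.sum() - 1.0) > 1e-9:
            raise ValueError("codon_freqs must sum to 1 within 1e-9")
        for name in ("kappa", "omega", "t", "cpg_multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.kappa <= 0:
            raise ValueError("kappa must be strictly positive")
        if self.cpg_multiplier < 1:
            raise ValueError("cpg_multiplier must be >= 1")
        if self.n_codons < 1 or self.n_pairs < 0:
            raise ValueError("n_codons must be >= 1 and n_pairs >= 0")
        if self.utr5_len < 0 or self.utr3_len < 0:
            raise ValueError("UTR lengths must be >= 0")

    def pi64(self) -> np.ndarray:
        """Codon frequencies indexed on the full 64-codon space (stops = 0)."""
        pi = np.zeros(64)
        for c, f in zip(SENSE_CODONS, self.codon_freqs):
            pi[CODON_INDEX[c]] = f
        return pi


# --------------------------------------------------------------------------
# ancestral sequence

def sample_ancestral_cds(n_codons: int, codon_freqs: np.ndarray, rng: np.random.Generator) -> str:
    """Sample an ancestral CDS: forced ATG first codon, then iid sense codons."""
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    freqs = np.asarray(codon_freqs, dtype=float)
    if freqs.shape != (len(SENSE_CODONS),) or freqs.sum() <= 0:
        raise ValueError("codon_freqs must be a positive-mass vector over sense codons")
    freqs = freqs / freqs.sum()
    idx = rng.choice(len(SENSE_CODONS), size=n_codons - 1, p=freqs)
    return "ATG" + "".join(SENSE_CODONS[i] for i in idx)


# --------------------------------------------------------------------------
# Gillespie simulation on the sense-codon chain

def _site_in_cpg(codons: list[int], k: int, pos: int) -> bool:
    """Is nucleotide (codon k, position pos) in CpG context in the current sequence?"""
    nt = _NT64[codons[k]][pos]
    if nt == _G:
        left = _NT64[codons[k]][pos - 1] if pos > 0 else (
            _NT64[codons[k - 1]][2] if k > 0 else None
        )
        if left == _C:
            return True
    if nt == _C:
        right = _NT64[codons[k]][pos + 1] if pos < 2 else (
            _NT64[codons[k + 1]][0] if k + 1 < len(codons) else None
        )
        if right == _G:
            return True
    return False


def _codon_mutation_weights(codons, k, pi64, kappa, omega, cpg_mult):
    muts = MUTATIONS[codons[k]]
    weights = []
    for pos, new_c, ts, syn in muts:
        w = pi64[new_c]
        if ts:
            w *= kappa
            if cpg_mult != 1.0 and _site_in_cpg(codons, k, pos):
                w *= cpg_mult
        if not syn:
            w *= omega
        weights.append(w)
    return muts, weights


def _codon_total_rate(codons, k, pi64, kappa, omega, cpg_mult):
    _, w = _codon_mutation_weights(codons, k, pi64, kappa, omega, cpg_mult)
    return math.fsum(w)


def substitution_rate_normalizer(params: SimParams) -> float:
    """Expected un-normalized substitution rate per codon at equilibrium.

    Computed without the CpG multiplier (CpG context is sequence-dependent);
    dividing all rates by this makes one unit of t one expected substitution
    per codon.
    """
    pi64 = params.pi64()
    rho = 0.0
    for c, f in zip(SENSE_CODONS, params.codon_freqs):
        for pos, new_c, ts, syn in MUTATIONS[CODON_INDEX[c]]:
            w = pi64[new_c]
            if ts:
                w *= params.kappa
            if not syn:
                w *= params.omega
            rho += f * w
    if rho <= 0:
        raise ValueError("degenerate parameters: zero total substitution rate")
    return rho


def _evolve_lineage(codons: list[int], duration: float, params: SimParams,
                    rho: float, rng: np.random.Generator) -> list[int]:
    if duration == 0:
        return list(codons)
    codons = list(codons)
    n = len(codons)
    pi64 = params.pi64()
    kappa, omega, cpg = params.kappa, params.omega, params.cpg_multiplier
    rates = np.array(
        [_codon_total_rate(codons, k, pi64, kappa, omega, cpg) for k in range(n)]
    ) / rho
    rates[0] = 0.0  # the initiation codon is held fixed
    clock = 0.0
    while True:
        total = rates.sum()
        if total <= 0:
            break
        clock += rng.exponential(1.0 / total)
        if clock >= duration:
            break
        cum = np.cumsum(rates)
        k = int(np.searchsorted(cum, rng.random() * total, side="right"))
        k = min(k, n - 1)
        muts, weights = _codon_mutation_weights(codons, k, pi64, kappa, omega, cpg)
        wsum = math.fsum(weights)
        u = rng.random() * wsum
        acc = 0.0
        choice = muts[-1]
        for m, w in zip(muts, weights):
            acc += w
            if u <= acc:
                choice = m
                break
        codons[k] = choice[1]
        for j in (k - 1, k, k + 1):
            if 1 <= j < n:
                rates[j] = _codon_total_rate(codons, j, pi64, kappa, omega, cpg) / rho
    return codons


def evolve_pair(ancestor: str, params: SimParams, rng: np.random.Generator) -> tuple[str, str]:
    """Evolve two lineages of total path length params.t from a common ancestor.

    Returns (cds_A, cds_B), both the same length as the ancestor, stop-free.
    The initiation codon (codon 0) is held fixed, mirroring the absolute
    functional constraint on the start codon.
    """
    if len(ancestor) % 3:
        raise ValueError("ancestor length must be a multiple of 3")
    codons = []
    for i in range(0, len(ancestor), 3):
        c = ancestor[i : i + 3]
        if c in STOP_CODONS or c not in CODON_INDEX:
            raise ValueError(f"ancestor contains invalid codon {c!r}")
        codons.append(CODON_INDEX[c])
    rho = substitution_rate_normalizer(params)
    half = params.t / 2.0
    a = _evolve_lineage(codons, half, params, rho, rng)
    b = _evolve_lineage(codons, half, params, rho, rng)
    to_str = lambda cs: "".join(CODONS[c] for c in cs)
    return to_str(a), to_str(b)


def calibrate_time_for_ks(params: SimParams, target_ks: float) -> float:
    """Path length t giving an expected synonymous divergence Ks ~= target_ks.

    Uses the model's equilibrium fraction of synonymous substitution events and
    kappa-weighted mutation-opportunity synonymous site counts; exact at small
    divergence, approximate (ignores multiple-hit corrections canceling) but
    adequate for choosing simulation regimes.
    """
    pi64 = params.pi64()
    rho_syn = 0.0
    rho = 0.0
    s_sites = 0.0
    for c, f in zip(SENSE_CODONS, params.codon_freqs):
        wsum = 0.0
        wsyn = 0.0
        for pos, new_c, ts, syn in MUTATIONS[CODON_INDEX[c]]:
            w_mut = pi64[new_c] * (params.kappa if ts else 1.0)
            wsum += w_mut
            if syn:
                wsyn += w_mut
            w = w_mut * (1.0 if syn else params.omega)
            rho += f * w
            if syn:
                rho_syn += f * w
        if wsum > 0:
            s_sites += f * 3.0 * wsyn / wsum
    f_syn = rho_syn / rho
    return target_ks * s_sites / f_syn


# --------------------------------------------------------------------------
# transcripts

def _random_utr(length: int, rng: np.random.Generator) -> str:
    return "".join("TCAG"[i] for i in rng.integers(0, 4, size=length))


def make_transcript(cds: str, utr5_len: int, utr3_len: int,
                    rng: np.random.Generator, max_tries: int = 200) -> str:
    """Wrap a complete CDS in random UTRs: UTR5 + CDS + stop + UTR3.

    UTRs are re-drawn until the planted ORF is recovered as the unique longest
    complete ORF by the ORF finder, so the round trip through CDS prediction
    is exact by construction.
    """
    from .cdsproc import predict_orf  # local import: cdsproc does not import simdata

    if not cds.startswith("ATG"):
        raise ValueError("CDS must start with ATG")
    if "*" in translate(cds):
        raise ValueError("CDS must be stop-free")
    stop = _STOPS[rng.integers(0, 3)]
    for _ in range(max_tries):
        utr5 = _random_utr(utr5_len, rng)
        utr3 = _random_utr(utr3_len, rng)
        tx = utr5 + cds + stop + utr3
        orf = predict_orf(tx)
        if (
            orf is not None
            and orf.strand == "+"
            and orf.start == utr5_len
            and orf.end == utr5_len + len(cds) + 3
        ):
            return tx
    raise RuntimeError("could not plant a unique longest ORF; UTRs too adversarial")


# --------------------------------------------------------------------------
# hit tables

def _blast_row(q, s, length, pident, evalue, bitscore):
    return {
        "qseqid": q, "sseqid": s, "pident": round(pident, 2), "length": int(length),
        "mismatch": int(round(length * (100 - pident) / 100.0)), "gapopen": 0,
        "qstart": 1, "qend": int(length), "sstart": 1, "send": int(length),
        "evalue": evalue, "bitscore": round(bitscore, 1),
    }


def make_hit_tables(
    transcripts_a: dict[str, str],
    transcripts_b: dict[str, str],
    truth_pairs: list[tuple[str, str, str]],
    rng: np.random.Generator,
    *,
    short_match_pairs: set[str] = frozenset(),
    ambiguous_ref_pairs: set[str] = frozenset(),
    weak_ref_pairs: set[str] = frozenset(),
    decoy_fraction: float = 0.5,
    ref_evalue: float = 1e-50,
) -> dict[str, pd.DataFrame]:
    """Fabricate the four similarity-search tables (A->B, B->A, A->ref, B->ref).

    True pairs get mutually best rows (match length = full transcript overlap)
    and agreeing reference-protein accessions at evalue << 1e-5. Confounders:
    short_match_pairs get 199 nt matches (fail the 200 bp reciprocal filter),
    ambiguous_ref_pairs map to different reference accessions, weak_ref_pairs
    get a reference evalue of 1e-4 (above the 1e-5 threshold). Decoy rows have
    strictly lower bitscores than any true row. Bitscores are fabricated
    rank-consistent numbers, not recomputed alignment scores.

    truth_pairs: list of (pair_id, transcript_id_A, transcript_id_B).
    """
    for pid, ida, idb in truth_pairs:
        if ida not in transcripts_a:
            raise ValueError(f"truth pair {pid} references unknown A transcript {ida}")
        if idb not in transcripts_b:
            raise ValueError(f"truth pair {pid} references unknown B transcript {idb}")

    ab, ba, aref, bref = [], [], [], []
    b_ids = [idb for _, _, idb in truth_pairs]
    a_ids = [ida for _, ida, _ in truth_pairs]
    for i, (pid, ida, idb) in enumerate(truth_pairs):
        bits = 900.0 - 0.5 * i
        length = min(len(transcripts_a[ida]), len(transcripts_b[idb]))
        if pid in short_match_pairs:
            length = 199
        pident = 80.0 + 15.0 * rng.random()
        ab.append(_blast_row(ida, idb, length, pident, 1e-150, bits))
        ba.append(_blast_row(idb, ida, length, pident, 1e-150, bits))
        # decoy cross hits: strictly lower bitscore, comfortable length
        if rng.random() < decoy_fraction and len(truth_pairs) > 1:
            j = int(rng.integers(0, len(truth_pairs)))
            if b_ids[j] != idb:
                ab.append(_blast_row(ida, b_ids[j], max(length, 250), 60.0, 1e-30, bits - 400.0))
            j = int(rng.integers(0, len(truth_pairs)))
            if a_ids[j] != ida:
                ba.append(_blast_row(idb, a_ids[j], 150, 60.0, 1e-20, bits - 450.0))
        acc_a = f"P{10000 + i}"
        acc_b = f"Q{90000 + i}" if pid in ambiguous_ref_pairs else acc_a
        ev = 1e-4 if pid in weak_ref_pairs else ref_evalue
        aref.append(_blast_row(ida, acc_a, length, 70.0, ev, 400.0 - 0.1 * i))
        bref.append(_blast_row(idb, acc_b, length, 70.0, ev, 400.0 - 0.1 * i))
        if rng.random() < decoy_fraction:
            aref.append(_blast_row(ida, f"P{50000 + i}", length, 40.0, 1e-8, 120.0))
            bref.append(_blast_row(idb, f"P{60000 + i}", length, 40.0, 1e-8, 120.0))
    cols = BLAST6_COLUMNS
    return {
        "ab": pd.DataFrame(ab, columns=cols),
        "ba": pd.DataFrame(ba, columns=cols),
        "aref": pd.DataFrame(aref, columns=cols),
        "bref": pd.DataFrame(bref, columns=cols),
    }


# --------------------------------------------------------------------------
# counts

def simulate_counts(
    n_genes: int,
    log2fc: np.ndarray,
    dispersion: float,
    lib_sizes: np.ndarray,
    rng: np.random.Generator,
    *,
    base_means: np.ndarray | None = None,
    gene_ids: list[str] | None = None,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Two-group negative-binomial counts (2 replicates per group, A then B).

    Gene means = base mean x relative library size x 2^(+-log2fc/2) (group A
    up, group B down). dispersion is the NB dispersion phi (variance =
    mu + phi mu^2); phi = 0 degenerates to Poisson.
    """
    log2fc = np.asarray(log2fc, dtype=float)
    if log2fc.shape != (n_genes,):
        raise ValueError("log2fc must have one entry per gene")
    if not np.all(np.isfinite(log2fc)):
        raise ValueError("fold changes must be finite")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if lib_sizes.shape != (4,) or np.any(lib_sizes <= 0):
        raise ValueError("lib_sizes must be 4 positive values (A1, A2, B1, B2)")
    if base_means is None:
        base_means = rng.lognormal(mean=np.log(150.0), sigma=1.0, size=n_genes)
    base_means = np.asarray(base_means, dtype=float)
    if np.any(base_means < 0):
        raise ValueError("negative mean")
    rel = lib_sizes / lib_sizes.mean()
    group_scale = np.array([1.0, 1.0, -1.0, -1.0])
    mu = base_means[:, None] * rel[None, :] * 2.0 ** (
        group_scale[None, :] * log2fc[:, None] / 2.0
    )
    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    if gene_ids is None:
        gene_ids = [f"OG{i:04d}" for i in range(n_genes)]
    if sample_ids is None:
        sample_ids = ["A_1", "A_2", "B_1", "B_2"]
    return pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids)


# --------------------------------------------------------------------------
# full dataset with ground truth

DEFAULT_CONFIG = {
    "n_pairs": 100,
    "n_codons": 200,
    "kappa": 2.0,
    "omega": 0.2,
    "t": 0.8,
    "cpg_multiplier": 4.0,
    "utr5_len": 50,
    "utr3_len": 50,
    "n_short_match": 0,
    "n_ambiguous_ref": 0,
    "n_short_cds": 0,
    "n_internal_stop": 0,
    "short_cds_codons": 50,
    "dispersion": 0.05,
    "lib_sizes": [9.0e5, 1.1e6, 1.0e6, 1.05e6],
    "base_mean_log": 5.0,
    "base_mean_sd": 1.0,
    "background_de_frac": 0.10,
    "de_log2fc": 2.0,
    "n_pathways": 20,
    "genes_per_pathway": 15,
    "n_enriched": 2,
    "enriched_de_frac": 0.8,
}


def simulate_dataset(config: dict | None, out_dir: str | Path, seed: int) -> dict[str, Path]:
    """Generate a full synthetic study into out_dir; returns the file map.

    Files: transcripts_A.fa, transcripts_B.fa, hits_{ab,ba,aref,bref}.tsv,
    orf_hints.tsv (external-predictor-style CDS calls, including deliberate
    read-through calls for internal-stop confounders), counts.tsv, groups.tsv,
    annotation.tsv, truth_pairs.tsv, truth_pathways.tsv.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    n = cfg["n_pairs"]
    n_conf = cfg["n_short_match"] + cfg["n_ambiguous_ref"] + cfg["n_short_cds"] + cfg["n_internal_stop"]
    if n_conf > n:
        raise ValueError("more confounders than pairs")

    params = SimParams(
        n_pairs=n, n_codons=cfg["n_codons"], kappa=cfg["kappa"], omega=cfg["omega"],
        t=cfg["t"], cpg_multiplier=cfg["cpg_multiplier"],
        utr5_len=cfg["utr5_len"], utr3_len=cfg["utr3_len"], seed=seed,
    )

    roles = (
        ["short_match"] * cfg["n_short_match"]
        + ["ambiguous_ref"] * cfg["n_ambiguous_ref"]
        + ["short_cds"] * cfg["n_short_cds"]
        + ["internal_stop"] * cfg["n_internal_stop"]
        + ["none"] * (n - n_conf)
    )

    tx_a, tx_b, hints, truth_rows = {}, {}, [], []
    for i, role in enumerate(roles):
        pid, ida, idb = f"OG{i:04d}", f"A_{i:04d}", f"B_{i:04d}"
        n_codons = cfg["short_cds_codons"] if role == "short_cds" else cfg["n_codons"]
        anc = sample_ancestral_cds(n_codons, params.codon_freqs, rng)
        cds_a, cds_b = evolve_pair(anc, params, rng)
        ta = make_transcript(cds_a, cfg["utr5_len"], cfg["utr3_len"], rng)
        if role == "internal_stop":
            mid = n_codons // 2
            corrupted = cds_b[: 3 * mid] + "TGA" + cds_b[3 * mid + 3 :]
            stop = _STOPS[rng.integers(0, 3)]
            tb = (
                _random_utr(cfg["utr5_len"], rng)
                + corrupted + stop
                + _random_utr(cfg["utr3_len"], rng)
            )
        else:
            tb = make_transcript(cds_b, cfg["utr5_len"], cfg["utr3_len"], rng)
        tx_a[ida], tx_b[idb] = ta, tb
        # external-predictor-style CDS calls: the generator's intended span,
        # read through any corruption (as a trained gene predictor would)
        hints.append((ida, cfg["utr5_len"], cfg["utr5_len"] + 3 * n_codons + 3, "+"))
        hints.append((idb, cfg["utr5_len"], cfg["utr5_len"] + 3 * n_codons + 3, "+"))
        truth_rows.append(
            {
                "pair_id": pid, "transcript_id_A": ida, "transcript_id_B": idb,
                "true_omega": params.omega, "true_kappa": params.kappa,
                "true_t": params.t, "confounder": role,
            }
        )
    truth = pd.DataFrame(truth_rows)

    tables = make_hit_tables(
        tx_a, tx_b,
        [(r["pair_id"], r["transcript_id_A"], r["transcript_id_B"]) for r in truth_rows],
        rng,
        short_match_pairs={r["pair_id"] for r in truth_rows if r["confounder"] == "short_match"},
        ambiguous_ref_pairs={r["pair_id"] for r in truth_rows if r["confounder"] == "ambiguous_ref"},
    )

    # pathway annotation with planted enrichment, then fold changes;
    # genes are keyed by the A-member transcript id, the key the pipeline
    # itself can produce (reads are mapped to the orthologous region named
    # after the first species' transcript)
    gene_ids = [r["transcript_id_A"] for r in truth_rows]
    n_pw = cfg["n_pathways"]
    annot_rows = []
    pw_genes: dict[str, list[str]] = {}
    for p in range(n_pw):
        pw = f"path{p:03d}"
        size = min(cfg["genes_per_pathway"], len(gene_ids))
        members = sorted(rng.choice(gene_ids, size=size, replace=False))
        pw_genes[pw] = list(members)
        for g in members:
            annot_rows.append({"gene_id": g, "pathway_id": pw, "pathway_name": f"Pathway {p:03d}"})
    annotation = pd.DataFrame(annot_rows)
    enriched = [f"path{p:03d}" for p in range(min(cfg["n_enriched"], n_pw))]

    lfc = np.zeros(len(gene_ids))
    sign = rng.choice([-1.0, 1.0], size=len(gene_ids))
    is_de = rng.random(len(gene_ids)) < cfg["background_de_frac"]
    enriched_members = set()
    for pw in enriched:
        enriched_members.update(pw_genes[pw])
    for i, g in enumerate(gene_ids):
        if g in enriched_members:
            is_de[i] = rng.random() < cfg["enriched_de_frac"]
    lfc[is_de] = sign[is_de] * cfg["de_log2fc"]

    base = rng.lognormal(cfg["base_mean_log"], cfg["base_mean_sd"], size=len(gene_ids))
    counts = simulate_counts(
        len(gene_ids), lfc, cfg["dispersion"], np.asarray(cfg["lib_sizes"]), rng,
        base_means=base, gene_ids=gene_ids,
    )
    truth["true_log2fc"] = lfc

    # ---- write everything -------------------------------------------------
    paths: dict[str, Path] = {}

    def _w(name: str, path: Path):
        paths[name] = path
        return path

    for sp, txs in (("A", tx_a), ("B", tx_b)):
        p = _w(f"fasta_{sp.lower()}", out_dir / f"transcripts_{sp}.fa")
        with open(p, "w") as fh:
            for tid in sorted(txs):
                fh.write(f">{tid}\n{txs[tid]}\n")
    for key in ("ab", "ba", "aref", "bref"):
        p = _w(f"hits_{key}", out_dir / f"hits_{key}.tsv")
        tables[key].to_csv(p, sep="\t", header=False, index=False)
    p = _w("orf_hints", out_dir / "orf_hints.tsv")
    pd.DataFrame(hints, columns=["transcript_id", "start", "end", "strand"]).to_csv(
        p, sep="\t", index=False
    )
    p = _w("counts", out_dir / "counts.tsv")
    counts.to_csv(p, sep="\t")
    p = _w("groups", out_dir / "groups.tsv")
    pd.DataFrame(
        {"sample_id": counts.columns, "group": ["A", "A", "B", "B"]}
    ).to_csv(p, sep="\t", index=False)
    p = _w("annotation", out_dir / "annotation.tsv")
    annotation.to_csv(p, sep="\t", index=False)
    p = _w("truth_pairs", out_dir / "truth_pairs.tsv")
    truth.to_csv(p, sep="\t", index=False)
    p = _w("truth_pathways", out_dir / "truth_pathways.tsv")
    pd.DataFrame(
        {"pathway_id": sorted(pw_genes), "planted_enriched": [pw in enriched for pw in sorted(pw_genes)]}
    ).to_csv(p, sep="\t", index=False)
    return paths
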