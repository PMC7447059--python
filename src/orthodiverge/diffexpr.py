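"""Differential expression calling on ortholog count matrices.

Design: two groups (species A, species B) with two replicates each. Library
composition is normalized with trimmed-mean-of-M-values (TMM) factors; counts
are then scaled to a common effective library size, a common negative-binomial
dispersion is estimated across genes by method of moments, and each gene is
tested with a two-sided exact NB test comparing the two group sums,
conditioned on their total. Multiple testing uses Benjamini–Hochberg step-up.
A gene is called differentially expressed when |log2 fold change| > 1 and
FDR < 0.05 (the fold-change-2 / FDR-0.05 thresholds), with a pseudo-count of
0.5 used for the fold change only, never for the test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DISPERSION_FLOOR = 1e-4


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")  # stable for ties
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def tmm_factors(counts: pd.DataFrame, trim_logratio: float = 0.3,
                trim_abs: float = 0.05) -> pd.Series:
    """TMM normalization factors, scaled to geometric mean 1.

    The reference sample is the column whose upper-quartile count rate is
    closest to the mean of upper quartiles. Per sample, the factor is the
    weighted (inverse asymptotic variance) trimmed mean of log2 count-rate
    ratios versus the reference, over genes positive in both, trimming
    trim_logratio from each tail by M and trim_abs by A.
    """
    x = counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least two samples")
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("sample with all-zero counts")
    rates = x / lib
    uq = np.array([np.quantile(rates[x[:, j] > 0, j], 0.75) if (x[:, j] > 0).any() else 0.0
                   for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(x.shape[1])
    for j in range(x.shape[1]):
        if j == ref:
            continue
        pos = (x[:, j] > 0) & (x[:, ref] > 0)
        if not pos.any():
            continue
        xj, xr = x[pos, j], x[pos, ref]
        M = np.log2((xj / lib[j]) / (xr / lib[ref]))
        A = 0.5 * np.log2((xj / lib[j]) * (xr / lib[ref]))
        w = 1.0 / ((lib[j] - xj) / (lib[j] * xj) + (lib[ref] - xr) / (lib[ref] * xr))
        n = len(M)
        loM, hiM = np.quantile(M, [trim_logratio, 1 - trim_logratio])
        loA, hiA = np.quantile(A, [trim_abs, 1 - trim_abs])
        keep = (M >= loM) & (M <= hiM) & (A >= loA) & (A <= hiA)
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        factors[j] = 2.0 ** (np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def estimate_common_dispersion(scaled: np.ndarray, groups: np.ndarray) -> float:
    """Pooled method-of-moments NB dispersion across genes.

    Uses within-group sample means/variances of library-size-equalized counts:
    E[var] = mu + phi mu^2, so phi = sum(var - mean) / sum(mean^2), floored.
    """
    num = den = 0.0
    for g in np.unique(groups):
        sub = scaled[:, groups == g]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += float(np.sum(v - m))
        den += float(np.sum(m ** 2))
    if den <= 0:
        return DISPERSION_FLOOR
    return max(num / den, DISPERSION_FLOOR)


def nb_exact_test(y1: int, y2: int, n1: int, n2: int, dispersion: float) -> float:
    """Two-sided exact NB test of equal means between group sums y1 and y2.

    Conditions on the total y1+y2; under the null each group's sum is NB with
    mean proportional to its replicate count and size n_i/phi. The p-value is
    the probability, under the conditional distribution, of outcomes no more
    likely than the observed split.
    """
    total = y1 + y2
    if total == 0:
        return 1.0
    lam = total / (n1 + n2)
    phi = max(dispersion, 1e-10)
    r1, r2 = n1 / phi, n2 / phi
    mu1, mu2 = n1 * lam, n2 * lam
    y = np.arange(total + 1)
    logp = (
        stats.nbinom.logpmf(y, r1, r1 / (r1 + mu1))
        + stats.nbinom.logpmf(y[::-1], r2, r2 / (r2 + mu2))
    )
    logp -= logp.max()
    p = np.exp(logp)
    obs = p[y1]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum() / p.sum()))


def de_test(counts: pd.DataFrame, groups: pd.Series | dict,
            dispersion: float | None = None) -> pd.DataFrame:
    """Per-gene differential expression table: log2fc (A:B), p, fdr.

    groups maps sample id -> group label; exactly two groups are required.
    Counts are TMM-normalized, scaled to a common effective library size and
    rounded; a common dispersion is estimated unless one is supplied.
    """
    if isinstance(groups, dict):
        groups = pd.Series(groups)
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError("exactly two groups are required")
    g = np.asarray(groups == labels[0])  # True = group A
    x = counts.to_numpy(dtype=float)
    if np.any(x < 0):
        raise ValueError("negative counts")

    factors = tmm_factors(counts).to_numpy()
    eff_lib = x.sum(axis=0) * factors
    common = np.exp(np.mean(np.log(eff_lib)))
    scaled = np.rint(x * (common / eff_lib)).astype(np.int64)

    if dispersion is None:
        dispersion = estimate_common_dispersion(scaled, g.astype(int))

    n1, n2 = int(g.sum()), int((~g).sum())
    y1 = scaled[:, g].sum(axis=1)
    y2 = scaled[:, ~g].sum(axis=1)
    pvals = np.array(
        [nb_exact_test(int(a), int(b), n1, n2, dispersion) for a, b in zip(y1, y2)]
    )
    m1 = scaled[:, g].mean(axis=1)
    m2 = scaled[:, ~g].mean(axis=1)
    log2fc = np.log2((m1 + 0.5) / (m2 + 0.5))
    return pd.DataFrame(
        {
            "gene_id": counts.index,
            "log2fc": log2fc,
            "p": pvals,
            "fdr": bh_adjust(pvals),
        }
    ).set_index("gene_id")


def call_deg(de_table: pd.DataFrame, lfc_min: float = 1.0, fdr_max: float = 0.05) -> pd.DataFrame:
    """Classify each gene: A_over (log2fc > lfc_min, strict), B_over, or ns."""
    call = np.where(
        (de_table.log2fc > lfc_min) & (de_table.fdr < fdr_max), "A_over",
        np.where((de_table.log2fc < -lfc_min) & (de_table.fdr < fdr_max), "B_over", "ns"),
    )
    out = de_table.copy()
    out["call"] = call
    return out


def deg_counts(called: pd.DataFrame) -> dict[str, int]:
    return {
        "A_over": int((called.call == "A_over").sum()),
        "B_over": int((called.call == "B_over").sum()),
        "ns": int((called.call == "ns").sum()),
    }
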