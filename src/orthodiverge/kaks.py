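"""Synonymous and nonsynonymous substitution rates between coding sequences.

Two pairwise estimators are implemented:

* ng86 — the Nei–Gojobori counting method: per-position synonymous site
  fractions with equal mutation weights (stop-creating changes excluded from
  the denominator), unweighted averaging over stop-avoiding evolutionary
  pathways for multi-difference codons, and Jukes–Cantor correction of the
  proportions pS and pN.
* yn00 — the Yang–Nielsen approximate method: F3x4 codon frequencies
  estimated from the pair, kappa (transition/transversion rate ratio)
  estimated from K80-corrected transition/transversion proportions at
  nondegenerate and fourfold-degenerate sites, mutation-opportunity site
  counting weighted by kappa and codon frequencies, pathway counting of
  differences weighted by kappa/omega/frequencies, K80-style distance
  correction of dS and dN, and iteration of omega to convergence.

Both estimators exclude mutations to/from stop codons from site and
difference counting and renormalize so each compared codon contributes
exactly 3 sites (S + N = 3 x codons). Pairs with Ks = 0 report omega as
undefined (NaN) rather than infinite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from ._codons import (
    AA64,
    CODON_INDEX,
    CODONS,
    DEG64,
    NUC_INDEX,
    SENSE_CODONS,
    STOP_CODONS,
)
from .cdsproc import CodonAlignment

_NT64 = tuple(tuple(NUC_INDEX[n] for n in c) for c in CODONS)


def _is_ts(i: int, j: int) -> bool:
    return i != j and (i // 2) == (j // 2)


class SaturationError(ValueError):
    pass


class NoDivergenceError(ValueError):
    pass


# --------------------------------------------------------------------------
# K80 (Kimura two-parameter) closed forms

def k80_distance(P: float, Q: float) -> float:
    """K80 sequence distance from transition (P) and transversion (Q)
    proportions: d = -(1/2) ln(1-2P-Q) - (1/4) ln(1-2Q)."""
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K80 correction undefined for P={P}, Q={Q}")
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def estimate_kappa_k80(P: float, Q: float) -> float:
    """Closed-form ML estimate of kappa under K80 from observed proportions.

    The transition distance component is a = -(1/2)ln(1-2P-Q) + (1/4)ln(1-2Q)
    (= alpha*t) and the transversion component b = -(1/2)ln(1-2Q) (= 2*beta*t),
    so kappa = alpha/beta = 2a/b. Q = 0 with P > 0 yields kappa = +inf.
    """
    if P < 0 or Q < 0:
        raise ValueError("P and Q must be non-negative")
    if P == 0 and Q == 0:
        raise NoDivergenceError("no divergence: kappa is not identifiable")
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K80 kappa undefined for P={P}, Q={Q}")
    a = -0.5 * math.log(w1) + 0.25 * math.log(w2)
    b = -0.5 * math.log(w2)
    if b == 0.0:
        return math.inf
    return 2.0 * a / b


# --------------------------------------------------------------------------
# pathway enumeration (cached; shared by both estimators)

# _pathways[(c1, c2)] -> tuple of pathways; each pathway is a tuple of steps
# (from64, to64, is_syn, is_ts). Pathways passing through stop codons are
# omitted; if every ordering is blocked by a stop, all orderings are kept as
# a fallback (steps into stops count as nonsynonymous).
_PATHWAY_CACHE: dict[tuple[int, int], tuple] = {}


def _codon_pathways(c1: int, c2: int) -> tuple:
    key = (c1, c2)
    cached = _PATHWAY_CACHE.get(key)
    if cached is not None:
        return cached
    s1, s2 = CODONS[c1], CODONS[c2]
    diff = [p for p in range(3) if s1[p] != s2[p]]
    paths, blocked = [], []
    for order in permutations(diff):
        cur = s1
        steps = []
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + s2[pos] + cur[pos + 1 :]
            syn = (nxt not in STOP_CODONS and cur not in STOP_CODONS
                   and AA64[CODON_INDEX[nxt]] == AA64[CODON_INDEX[cur]])
            steps.append(
                (CODON_INDEX[cur], CODON_INDEX[nxt], syn,
                 _is_ts(NUC_INDEX[cur[pos]], NUC_INDEX[s2[pos]]))
            )
            if nxt in STOP_CODONS:
                hit_stop = True
            cur = nxt
        (blocked if hit_stop else paths).append(tuple(steps))
    result = tuple(paths) if paths else tuple(blocked)
    _PATHWAY_CACHE[key] = result
    return result


# --------------------------------------------------------------------------
# records

@dataclass
class KaKsRecord:
    pair_id: str = ""
    method: str = ""
    S: float = float("nan")
    N: float = float("nan")
    Sd: float = float("nan")
    Nd: float = float("nan")
    Ka: float = float("nan")
    Ks: float = float("nan")
    omega: float = float("nan")
    kappa: float = float("nan")
    n_codons: int = 0
    status: str = "ok"  # ok | saturated | undefined | nonconvergent

    def as_dict(self) -> dict:
        return dict(
            pair_id=self.pair_id, method=self.method, S=self.S, N=self.N,
            Sd=self.Sd, Nd=self.Nd, Ka=self.Ka, Ks=self.Ks, omega=self.omega,
            kappa=self.kappa, n_codons=self.n_codons, status=self.status,
        )


def _compared_codons(aln: CodonAlignment) -> list[tuple[int, int]]:
    out = []
    for ca, cb in aln.codon_columns():
        if "-" in ca or "-" in cb or "N" in ca or "N" in cb:
            continue
        out.append((CODON_INDEX[ca], CODON_INDEX[cb]))
    return out


# --------------------------------------------------------------------------
# NG86

def _ng86_site_fractions() -> np.ndarray:
    """Synonymous sites per sense codon (0..3), equal mutation weights,
    stop-excluded per-position denominators."""
    s = np.zeros(64)
    for c in SENSE_CODONS:
        ci = CODON_INDEX[c]
        total = 0.0
        for pos in range(3):
            syn = possible = 0
            for n in "TCAG":
                if n == c[pos]:
                    continue
                m = c[:pos] + n + c[pos + 1 :]
                if m in STOP_CODONS:
                    continue
                possible += 1
                if AA64[CODON_INDEX[m]] == AA64[ci]:
                    syn += 1
            if possible:
                total += syn / possible
        s[ci] = total
    return s


_NG86_S = _ng86_site_fractions()


def ng86(aln: CodonAlignment, pair_id: str = "") -> KaKsRecord:
    """Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction."""
    pairs = _compared_codons(aln)
    rec = KaKsRecord(pair_id=pair_id, method="NG86", n_codons=len(pairs))
    if not pairs:
        rec.status = "undefined"
        return rec
    arr = np.asarray(pairs)
    S = 0.5 * float(_NG86_S[arr[:, 0]].sum() + _NG86_S[arr[:, 1]].sum())
    N = 3.0 * len(pairs) - S
    Sd = Nd = 0.0
    for c1, c2 in pairs:
        if c1 == c2:
            continue
        paths = _codon_pathways(c1, c2)
        sd = sum(sum(1 for st in p if st[2]) for p in paths) / len(paths)
        nd = sum(sum(1 for st in p if not st[2]) for p in paths) / len(paths)
        Sd += sd
        Nd += nd
    rec.S, rec.N, rec.Sd, rec.Nd = S, N, Sd, Nd
    # the two corrections are independent: one may saturate while the other
    # remains estimable
    try:
        rec.Ks = _jc(Sd / S)
    except SaturationError:
        rec.status = "saturated"
    try:
        rec.Ka = _jc(Nd / N)
    except SaturationError:
        rec.status = "saturated"
    if rec.status == "ok" and rec.Ks > 0:
        rec.omega = rec.Ka / rec.Ks
    return rec


def _jc(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"Jukes-Cantor correction undefined for p={p}")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


# --------------------------------------------------------------------------
# YN00

def f3x4_frequencies(aln: CodonAlignment) -> np.ndarray:
    """F3x4 sense-codon frequencies (64-vector, stops zero) estimated from the
    pooled position-specific nucleotide frequencies of both sequences."""
    counts = np.zeros((3, 4))
    for ca, cb in aln.codon_columns():
        for codon in (ca, cb):
            if "-" in codon or "N" in codon:
                continue
            for p in range(3):
                counts[p, NUC_INDEX[codon[p]]] += 1
    if counts.sum() == 0:
        raise ValueError("no codons to estimate frequencies from")
    fpos = counts / counts.sum(axis=1, keepdims=True)
    pi = np.zeros(64)
    for c in SENSE_CODONS:
        ci = CODON_INDEX[c]
        n = _NT64[ci]
        pi[ci] = fpos[0, n[0]] * fpos[1, n[1]] * fpos[2, n[2]]
    total = pi.sum()
    if total <= 0:
        raise ValueError("degenerate F3x4 frequencies")
    return pi / total


def _kappa_from_degenerate_sites(pairs: list[tuple[int, int]]) -> float:
    """kappa from K80-corrected P/Q at nondegenerate and fourfold sites,
    weighted by site counts; falls back to 1.0 when neither class informs."""
    L = {0: 0, 4: 0}
    ts = {0: 0, 4: 0}
    tv = {0: 0, 4: 0}
    for c1, c2 in pairs:
        d1, d2 = DEG64[c1], DEG64[c2]
        n1, n2 = _NT64[c1], _NT64[c2]
        for p in range(3):
            if d1[p] != d2[p] or d1[p] not in (0, 4):
                continue
            cls = d1[p]
            L[cls] += 1
            if n1[p] != n2[p]:
                if _is_ts(n1[p], n2[p]):
                    ts[cls] += 1
                else:
                    tv[cls] += 1
    estimates, weights = [], []
    for cls in (0, 4):
        if L[cls] == 0:
            continue
        try:
            k = estimate_kappa_k80(ts[cls] / L[cls], tv[cls] / L[cls])
        except (SaturationError, NoDivergenceError):
            continue
        if math.isfinite(k) and k > 0:
            estimates.append(k)
            weights.append(L[cls])
    if not estimates:
        return 1.0
    return float(np.average(estimates, weights=weights))


def _yn00_site_counts(codon_counts: np.ndarray, pi: np.ndarray, kappa: float) -> tuple[float, float]:
    """Mutation-opportunity S/N site counts: per position the three non-stop
    single-nucleotide changes are weighted by target-codon frequency x kappa
    (transitions); each position contributes one site, split S:N by weight."""
    S = 0.0
    n_codons = 0.0
    for ci, cnt in enumerate(codon_counts):
        if cnt == 0:
            continue
        n_codons += cnt
        by_pos_syn = [0.0, 0.0, 0.0]
        by_pos_sum = [0.0, 0.0, 0.0]
        from ._codons import MUTATIONS

        for pos, new_c, is_ts_flag, syn in MUTATIONS[ci]:
            w = pi[new_c] * (kappa if is_ts_flag else 1.0)
            by_pos_sum[pos] += w
            if syn:
                by_pos_syn[pos] += w
        s_codon = 0.0
        for pos in range(3):
            if by_pos_sum[pos] > 0:
                s_codon += by_pos_syn[pos] / by_pos_sum[pos]
            # an all-stop-neighbour position (cannot occur in table 1) would
            # contribute a full nonsynonymous site
        S += cnt * s_codon
    return S, 3.0 * n_codons - S


def _yn00_difference_counts(pair_counts: dict[tuple[int, int], int], pi: np.ndarray,
                            kappa: float, omega: float):
    """Pathway-weighted difference counts split into ts/tv components.

    Pathway weight = product over steps of pi[target] * kappa^ts * omega^nonsyn,
    summed over both traversal directions (so the estimate is invariant under
    swapping the two sequences), normalized within each codon pair.
    """

    def _weight(path):
        w = 1.0
        for _, to_c, syn, is_ts_flag in path:
            w *= pi[to_c] if pi[to_c] > 0 else 1e-10
            if is_ts_flag:
                w *= kappa
            if not syn:
                w *= omega if omega > 0 else 1e-10
        return w

    def _pos_order(path):
        order = []
        for frm, to, _, _ in path:
            order.append(next(q for q in range(3) if CODONS[frm][q] != CODONS[to][q]))
        return tuple(order)

    sd_ts = sd_tv = nd_ts = nd_tv = 0.0
    for (c1, c2), cnt in pair_counts.items():
        paths = _codon_pathways(c1, c2)
        weights = [_weight(p) for p in paths]
        # a forward pathway ordering positions (p1..pk) is the same physical
        # pathway as the reverse one ordering (pk..p1); sum both weights
        rev_by_order = {_pos_order(p)[::-1]: p for p in _codon_pathways(c2, c1)}
        for i, p in enumerate(paths):
            rev = rev_by_order.get(_pos_order(p))
            if rev is not None:
                weights[i] += _weight(rev)
        wsum = math.fsum(weights)
        if wsum <= 0:
            weights = [1.0] * len(paths)
            wsum = float(len(paths))
        for p, w in zip(paths, weights):
            frac = cnt * w / wsum
            for _, _, syn, is_ts_flag in p:
                if syn:
                    if is_ts_flag:
                        sd_ts += frac
                    else:
                        sd_tv += frac
                else:
                    if is_ts_flag:
                        nd_ts += frac
                    else:
                        nd_tv += frac
    return sd_ts, sd_tv, nd_ts, nd_tv


def yn00(aln: CodonAlignment, pair_id: str = "", max_iter: int = 100,
         tol: float = 1e-6) -> KaKsRecord:
    """Yang–Nielsen (2000) approximate Ka/Ks estimator."""
    pairs = _compared_codons(aln)
    rec = KaKsRecord(pair_id=pair_id, method="YN00", n_codons=len(pairs))
    if not pairs:
        rec.status = "undefined"
        return rec
    pi = f3x4_frequencies(aln)
    kappa = _kappa_from_degenerate_sites(pairs)
    rec.kappa = kappa

    codon_counts = np.zeros(64)
    for c1, c2 in pairs:
        codon_counts[c1] += 0.5
        codon_counts[c2] += 0.5
    S, N = _yn00_site_counts(codon_counts, pi, kappa)
    rec.S, rec.N = S, N
    if S <= 0 or N <= 0:
        rec.status = "undefined"
        return rec

    pair_counts: dict[tuple[int, int], int] = {}
    n_diff = 0
    for c1, c2 in pairs:
        if c1 == c2:
            continue
        n_diff += 1
        pair_counts[(c1, c2)] = pair_counts.get((c1, c2), 0) + 1
    if n_diff == 0:
        rec.Sd = rec.Nd = rec.Ka = rec.Ks = 0.0
        rec.omega = float("nan")
        return rec

    omega = 0.5
    converged = False
    dS = dN = float("nan")
    for _ in range(max_iter):
        sd_ts, sd_tv, nd_ts, nd_tv = _yn00_difference_counts(pair_counts, pi, kappa, omega)
        try:
            dS = k80_distance(sd_ts / S, sd_tv / S)
            dN = k80_distance(nd_ts / N, nd_tv / N)
        except SaturationError:
            rec.Sd, rec.Nd = sd_ts + sd_tv, nd_ts + nd_tv
            rec.status = "saturated"
            return rec
        if dS <= 0:
            new_omega = float("inf")
        else:
            new_omega = dN / dS
        if new_omega == 0.0:
            new_omega = 1e-8  # keep nonsynonymous pathways weighable
        if math.isfinite(new_omega) and abs(new_omega - omega) <= tol * max(omega, 1e-12):
            omega = new_omega
            converged = True
            break
        if not math.isfinite(new_omega):
            omega = 99.0
            converged = True  # dS == 0: omega undefined below
            break
        omega = new_omega
    sd_ts, sd_tv, nd_ts, nd_tv = _yn00_difference_counts(pair_counts, pi, kappa, omega)
    rec.Sd, rec.Nd = sd_ts + sd_tv, nd_ts + nd_tv
    rec.Ks, rec.Ka = dS, dN
    rec.omega = dN / dS if dS > 0 else float("nan")
    if not converged:
        rec.status = "nonconvergent"
    return rec


# --------------------------------------------------------------------------
# batch

METHODS = {"ng86": ng86, "yn00": yn00}


def batch_kaks(alignments: dict[str, CodonAlignment], method: str = "yn00"):
    """Run an estimator over all pairs; returns (per-pair table, summary dict).

    The summary's means are over pairs with status 'ok' and finite Ka and Ks
    ('estimable'); mean omega is over the subset with defined omega (Ks > 0).
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    fn = METHODS[method]
    records = [fn(alignments[pid], pair_id=pid) for pid in sorted(alignments)]
    table = pd.DataFrame([r.as_dict() for r in records])
    est = table[
        (table.status == "ok") & np.isfinite(table.Ka) & np.isfinite(table.Ks)
    ]
    with_omega = est[np.isfinite(est.omega)]
    summary = {
        "method": method,
        "n_pairs": len(records),
        "n_estimable": int(len(est)),
        "n_saturated": int((table.status == "saturated").sum()),
        "n_undefined": int((table.status == "undefined").sum()),
        "n_nonconvergent": int((table.status == "nonconvergent").sum()),
        "mean_ks": float(est.Ks.mean()) if len(est) else float("nan"),
        "median_ks": float(est.Ks.median()) if len(est) else float("nan"),
        "mean_ka": float(est.Ka.mean()) if len(est) else float("nan"),
        "mean_omega": float(with_omega.omega.mean()) if len(with_omega) else float("nan"),
        "median_omega": float(with_omega.omega.median()) if len(with_omega) else float("nan"),
    }
    return table, summary
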