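"""Ka/Ks estimators: NG86 counting, YN00, K80 kappa, batch summaries."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from orthodiverge._codons import CODON_INDEX
from orthodiverge.cdsproc import CodonAlignment
from orthodiverge.kaks import (
    _NG86_S,
    NoDivergenceError,
    SaturationError,
    _yn00_site_counts,
    batch_kaks,
    estimate_kappa_k80,
    k80_distance,
    ng86,
    yn00,
)
from orthodiverge.simdata import (
    SimParams,
    calibrate_time_for_ks,
    evolve_pair,
    sample_ancestral_cds,
    uniform_codon_freqs,
)


def test_ng86_identical_sequences():
    aln = CodonAlignment("ATGGCTAAA", "ATGGCTAAA")
    rec = ng86(aln)
    assert rec.Ka == 0.0 and rec.Ks == 0.0 and math.isnan(rec.omega)
    assert rec.S + rec.N == pytest.approx(9.0, abs=1e-9)


def test_ng86_tta_site_count():
    # TTA: pos1 1/3 syn, pos2 0 of 1 possible (stops excluded), pos3 1/3 syn
    assert _NG86_S[CODON_INDEX["TTA"]] == pytest.approx(2 / 3)


def test_ng86_single_synonymous_difference():
    rec = ng86(CodonAlignment("GGG", "GGA"))
    assert rec.Sd == 1.0 and rec.Nd == 0.0 and rec.Ka == 0.0
    # in a longer alignment the synonymous change yields Ks > 0, Ka = 0
    rec = ng86(CodonAlignment("ATG" + "GGG" * 3, "ATG" + "GGG" * 2 + "GGA"))
    assert rec.Nd == 0.0 and rec.Ka == 0.0 and rec.Ks > 0 and rec.status == "ok"


def test_ng86_saturation_flag():
    # all fourfold positions maximally divergent in a tiny alignment
    rec = ng86(CodonAlignment("GGGGGGGGG", "GGAGGCGGT"))
    # p_S = 3/S with S ~ 3: saturated
    assert rec.status == "saturated"


def test_estimate_kappa_errors():
    with pytest.raises(NoDivergenceError):
        estimate_kappa_k80(0.0, 0.0)
    with pytest.raises(SaturationError):
        estimate_kappa_k80(0.45, 0.2)


def test_estimate_kappa_exact_inversion():
    # closed-form K80 probabilities at kappa = alpha/beta, any time
    def pq(alpha, beta, t):
        P = 0.25 + 0.25 * math.exp(-4 * beta * t) - 0.5 * math.exp(-2 * (alpha + beta) * t)
        Q = 0.5 - 0.5 * math.exp(-4 * beta * t)
        return P, Q

    for kappa in (0.5, 1.0, 2.0, 5.0):
        for t in (0.1, 0.5, 1.5):
            P, Q = pq(kappa * 0.05, 0.05, t)
            assert estimate_kappa_k80(P, Q) == pytest.approx(kappa, rel=1e-9)


def test_estimate_kappa_recovery_from_sampled_sites(rng):
    # multinomial draw of 1e5 sites from K80 at kappa=5
    kappa, beta, t = 5.0, 0.05, 1.0
    P = 0.25 + 0.25 * math.exp(-4 * beta * t) - 0.5 * math.exp(-2 * (kappa * beta + beta) * t)
    Q = 0.5 - 0.5 * math.exp(-4 * beta * t)
    n = 100_000
    ts, tv, _ = rng.multinomial(n, [P, Q, 1 - P - Q])
    k = estimate_kappa_k80(ts / n, tv / n)
    assert 4.5 <= k <= 5.5


def test_estimate_kappa_agrees_with_numerical_ml(rng):
    # independent oracle: maximize the trinomial K80 likelihood numerically
    def neg_loglik(theta, P_obs, Q_obs, n=10_000):
        alpha_t, beta_t = theta
        if alpha_t <= 0 or beta_t <= 0:
            return 1e12
        P = 0.25 + 0.25 * math.exp(-4 * beta_t) - 0.5 * math.exp(-2 * (alpha_t + beta_t))
        Q = 0.5 - 0.5 * math.exp(-4 * beta_t)
        if P <= 0 or Q <= 0 or P + Q >= 1:
            return 1e12
        return -n * (
            P_obs * math.log(P) + Q_obs * math.log(Q) + (1 - P_obs - Q_obs) * math.log(1 - P - Q)
        )

    for _ in range(20):
        P_obs = float(rng.uniform(0.01, 0.2))
        Q_obs = float(rng.uniform(0.01, 0.25))
        if 1 - 2 * P_obs - Q_obs <= 0.05:
            continue
        res = minimize(
            neg_loglik, x0=[0.1, 0.1], args=(P_obs, Q_obs),
            method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        kappa_ml = res.x[0] / res.x[1]
        assert estimate_kappa_k80(P_obs, Q_obs) == pytest.approx(kappa_ml, abs=1e-4)


def test_yn00_identical_sequences():
    rec = yn00(CodonAlignment("ATGGCTAAACCC", "ATGGCTAAACCC"))
    assert rec.Ka == 0.0 and rec.Ks == 0.0 and math.isnan(rec.omega)


def test_yn00_collapses_to_ng86_site_counts():
    # kappa = 1 and uniform codon frequencies: mutation-opportunity weighting
    # degenerates to NG86's equal-weight counting
    pi = np.zeros(64)
    from orthodiverge._codons import SENSE_CODONS

    for c in SENSE_CODONS:
        pi[CODON_INDEX[c]] = 1 / 61
    rng = np.random.default_rng(0)
    counts = np.zeros(64)
    for c in rng.choice(61, size=200):
        counts[CODON_INDEX[SENSE_CODONS[c]]] += 1
    S_yn, N_yn = _yn00_site_counts(counts, pi, kappa=1.0)
    S_ng = float((_NG86_S * counts).sum())
    assert S_yn == pytest.approx(S_ng, abs=1e-6)
    assert S_yn + N_yn == pytest.approx(3 * counts.sum(), abs=1e-6)


def test_site_sum_invariant_both_methods(simulate_pairs):
    for aln in simulate_pairs(5, 120, seed=17):
        for fn in (ng86, yn00):
            rec = fn(aln)
            assert rec.S + rec.N == pytest.approx(3 * rec.n_codons, abs=1e-6)


def test_estimates_symmetric_under_swap(simulate_pairs):
    for aln in simulate_pairs(3, 150, seed=23, t=1.0):
        rev = CodonAlignment(aln.aligned_b, aln.aligned_a)
        for fn in (ng86, yn00):
            r1, r2 = fn(aln), fn(rev)
            assert r1.Ka == pytest.approx(r2.Ka, abs=1e-12)
            assert r1.Ks == pytest.approx(r2.Ks, abs=1e-12)


def test_ks_monotone_in_time():
    medians = []
    for t in (0.2, 0.6, 1.2):
        params = SimParams(n_codons=200, kappa=2.0, omega=0.2, t=t, cpg_multiplier=1.0)
        gen = np.random.default_rng(51)
        ks = []
        for _ in range(15):
            anc = sample_ancestral_cds(200, params.codon_freqs, gen)
            a, b = evolve_pair(anc, params, gen)
            rec = yn00(CodonAlignment(a, b))
            if math.isfinite(rec.Ks):
                ks.append(rec.Ks)
        medians.append(np.median(ks))
    assert medians[0] < medians[1] < medians[2]


def test_calibrated_time_hits_target_ks(simulate_pairs):
    params = SimParams(kappa=2.0, omega=0.2, cpg_multiplier=1.0)
    t = calibrate_time_for_ks(params, 0.5)
    ks = [
        yn00(a).Ks
        for a in simulate_pairs(20, 300, seed=61, kappa=2.0, omega=0.2, t=t, cpg_multiplier=1.0)
    ]
    assert 0.35 < float(np.median(ks)) < 0.7


def test_batch_kaks_summary():
    identical = CodonAlignment("ATGGCTAAA", "ATGGCTAAA")
    saturated = CodonAlignment("GGGGGGGGG", "GGAGGCGGT")
    table, summary = batch_kaks({"a": identical, "b": saturated}, method="ng86")
    assert summary["n_pairs"] == 2
    assert summary["n_saturated"] == 1
    assert summary["n_estimable"] == 1
    assert summary["mean_ks"] == 0.0
    assert math.isnan(summary["mean_omega"])
    with pytest.raises(ValueError):
        batch_kaks({"a": identical}, method="nope")


def test_k80_distance_saturation():
    with pytest.raises(SaturationError):
        k80_distance(0.5, 0.3)
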