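import numpy as np
import pytest

from orthodiverge.cdsproc import CodonAlignment
from orthodiverge.simdata import SimParams, evolve_pair, sample_ancestral_cds


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def simulate_pairs():
    """Factory: n gap-free codon alignments evolved under given parameters."""

    def _make(n_pairs, n_codons, seed=0, **param_kw):
        params = SimParams(n_pairs=n_pairs, n_codons=n_codons, **param_kw)
        gen = np.random.default_rng(seed)
        out = []
        for _ in range(n_pairs):
            anc = sample_ancestral_cds(n_codons, params.codon_freqs, gen)
            a, b = evolve_pair(anc, params, gen)
            out.append(CodonAlignment(a, b))
        return out

    return _make
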