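"""Shared fixtures: crafted instrument sets and simulation helpers."""

import numpy as np
import pytest

from mrpipe.instruments import HarmonizedInstrument
from mrpipe.simulate import SimulatedPair, SyntheticScenario, simulate_pair
from mrpipe import as_instruments


def make_instrument(
    rsid="rs1", beta_exp=0.1, se_exp=0.01, beta_out=0.05, se_out=0.02,
    eaf_exp=0.3, n_exp=10_000, ea="A", oa="G",
) -> HarmonizedInstrument:
    from mrpipe.instruments import compute_r2_f

    r2, f = compute_r2_f(beta_exp, se_exp, eaf_exp, n_exp)
    return HarmonizedInstrument(
        rsid=rsid, effect_allele=ea, other_allele=oa,
        beta_exp=beta_exp, se_exp=se_exp, pval_exp=1e-8,
        beta_out=beta_out, se_out=se_out, pval_out=0.01,
        eaf_exp=eaf_exp, n_exp=n_exp, r2=r2, f_stat=f,
    )


@pytest.fixture
def crafted5():
    """Five hand-set instruments with unequal weights for WLS oracles."""
    specs = [
        ("rs1", 0.12, 0.011, 0.065, 0.031),
        ("rs2", 0.08, 0.009, 0.024, 0.042),
        ("rs3", 0.15, 0.013, 0.091, 0.027),
        ("rs4", 0.06, 0.010, 0.048, 0.055),
        ("rs5", 0.10, 0.012, 0.033, 0.038),
    ]
    return [make_instrument(r, bx, sx, by, sy) for r, bx, sx, by, sy in specs]


@pytest.fixture
def crafted7():
    """Seven instruments with heterogeneous ratios for median/mode oracles."""
    specs = [
        ("rs1", 0.11, 0.012, 0.055, 0.030),
        ("rs2", 0.09, 0.010, 0.018, 0.041),
        ("rs3", 0.14, 0.011, 0.112, 0.026),
        ("rs4", 0.07, 0.009, 0.042, 0.050),
        ("rs5", 0.12, 0.013, 0.048, 0.036),
        ("rs6", 0.10, 0.010, 0.070, 0.044),
        ("rs7", 0.08, 0.011, 0.012, 0.033),
    ]
    return [make_instrument(r, bx, sx, by, sy) for r, bx, sx, by, sy in specs]


def strong_pair(seed, theta=0.0, k=50, gamma_sd=0.1, **kw) -> SimulatedPair:
    """Simulated pair with k uniformly strong, non-palindromic instruments."""
    sc = SyntheticScenario(
        m_snps=k, m_causal=k, gamma_sd=gamma_sd, theta=theta,
        palindrome_fraction=0.0, seed=seed, **kw,
    )
    return simulate_pair(sc)


def strong_instruments(seed, theta=0.0, k=50, gamma_sd=0.1, **kw):
    return as_instruments(strong_pair(seed, theta=theta, k=k, gamma_sd=gamma_sd, **kw))
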