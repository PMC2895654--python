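"""Shared fixtures: small synthetic studies and a reduced two-locus table.

Everything is generated programmatically from fixed seeds; session scope
keeps the expensive objects (coalescent study, Monte-Carlo lookup table)
to one build per run.
"""

import numpy as np
import pytest

from ddpop.recombination import build_two_locus_table
from ddpop.seqio import call_snps
from ddpop.synthetic import SimParams, simulate_study_design


@pytest.fixture(scope="session")
def mini_params() -> SimParams:
    return SimParams(
        seed=7, n_fragments_dense=25, n_fragments_other=10, missing_rate=0.02
    )


@pytest.fixture(scope="session")
def mini_study(mini_params):
    return simulate_study_design(mini_params)


@pytest.fixture(scope="session")
def mini_matrix(mini_study):
    return call_snps(mini_study.fragments).matrix


@pytest.fixture(scope="session")
def small_table():
    """Reduced two-locus lookup table for n=25 (coarse grid, modest sims)."""
    return build_two_locus_table(25, np.linspace(0.0, 100.0, 11), 3000, seed=42)


def dense_region_sim(seed: int, rho: float, params: SimParams = SimParams()):
    """Dense-chromosome haplotypes under the study layout (no nucleotide
    round trip); returns (SnpMatrix, span)."""
    from ddpop.synthetic import _dense_layout, matrix_from_haplotypes, simulate_coalescent

    rng = np.random.default_rng(seed)
    starts, lengths = _dense_layout(params, rng)
    span = float(starts[-1] + lengths[-1] + 10_000)
    windows = [(float(a), float(a + l)) for a, l in zip(starts, lengths)]
    pos, geno = simulate_coalescent(params.n, span, params.theta_site, rho, rng, windows)
    return matrix_from_haplotypes(pos, geno), span
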