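import numpy as np
import pytest
from hypothesis import settings

import sctcr

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from sctcr.pipeline import PipelineConfig
from sctcr.simulate import TruthRecord


@pytest.fixture(scope="session")
def refset():
    """Shared synthetic germline reference (both loci, IMGT-scale lengths)."""
    return sctcr.make_synthetic_reference(7)


@pytest.fixture(scope="session")
def small_refset():
    """Smaller reference for alignment-heavy unit tests."""
    return sctcr.make_synthetic_reference(13, n_per_segment={"V": 3, "J": 2})


def simulate_cell(refset, read_len, coverage, error, ins_len, seed, mix=True):
    """One synthetic cell: 1 alpha + 1 beta chain, reads, optional background.

    Returns (pairs_or_batch, {locus: TruthRecord}).
    """
    rng = np.random.default_rng(seed)
    profile = np.full(read_len, error, dtype=float)
    cfg = sctcr.SimConfig(read_len=read_len, error_profile=profile)
    tcr = []
    truths = {}
    for locus in ("TRA", "TRB"):
        chain = sctcr.simulate_chain(refset, locus, ins_len, rng)
        truths[locus] = TruthRecord(f"{locus}_{seed}", chain)
        tcr.extend(
            sctcr.simulate_read_pairs(
                chain.sequence, cfg, coverage, rng, id_prefix=locus.lower()
            )
        )
    if not mix:
        return tcr, truths
    batch, _ = sctcr.mix_with_background(tcr, cfg, rng, as_batch=True)
    return batch, truths


@pytest.fixture()
def sim_pipeline_config():
    def make(read_len):
        return PipelineConfig().for_simulation(read_len, 300)

    return make
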