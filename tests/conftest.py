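import numpy as np
import pytest

from harimau.mito import demo_haplotree, demo_panel, demo_reference


@pytest.fixture(scope="session")
def ref():
    return demo_reference()


@pytest.fixture(scope="session")
def tree():
    return demo_haplotree()


@pytest.fixture(scope="session")
def panel():
    return demo_panel()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def run_pipeline(pairs, ref, min_depth=3):
    """Convenience: merged pairs through mapping, dedup, pileup, consensus."""
    from harimau.readpipe import (build_pileup, call_consensus,
                                  consensus_to_variants, filter_and_dedup,
                                  map_reads, trim_merge)

    merged = trim_merge(pairs)
    kept = filter_and_dedup(map_reads(merged, ref))
    pileup = build_pileup(kept, ref)
    consensus = call_consensus(pileup, min_depth=min_depth)
    variants = consensus_to_variants(consensus, ref)
    return kept, pileup, consensus, variants
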