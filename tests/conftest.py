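import numpy as np
import pytest

from consegment import alignment, simulate


@pytest.fixture
def tiny_maf(tmp_path):
    """Hand-written three-species MAF: two blocks, one mouse gap, one
    reference gap (dropped on projection), rat absent from block 2."""
    text = """##maf version=1

a score=1.0
s hg19.chr17 10 4 + 1000 ACGT
s mm9.chr11 5 3 + 900 A-GT
s rn4.chr10 7 4 + 800 ACGA

a score=2.0
s hg19.chr17 14 3 + 1000 AC-G
s mm9.chr11 8 4 + 900 ACTG
"""
    path = tmp_path / "tiny.maf"
    path.write_text(text)
    return path


@pytest.fixture
def columns_ctctct():
    """Columns spelling CTCTCT, perfectly conserved in all three species."""
    return [
        alignment.AlignmentColumn(b, (b, b), i)
        for i, b in enumerate("CTCTCT")
    ]


def _fit_scenario(seed, length=20000):
    from consegment import ChangepointModel
    truth = simulate.simulate_scenario("well_separated", seed=seed,
                                       length=length)
    res = ChangepointModel(truth.codes, k=4).fit(
        n_iter=1000, burn_in=500, seed=seed)
    return truth, res


@pytest.fixture(scope="session")
def fitted_well_separated():
    """Three full-scale fits of the well-separated scenario (seeds 1-3),
    shared across the recovery and classifier tests."""
    return {seed: _fit_scenario(seed) for seed in (1, 2, 3)}
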