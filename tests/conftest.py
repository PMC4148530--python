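import numpy as np
import pytest

from bsphase.snp_diagnostics import LocusReference
from bsphase.synthetic_data import LocusScenario, simulate_individual, simulate_parents


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_region_ref():
    """Tiny locus: one shared CG site, one SNP-destroyed site, one C/T SNP."""
    #           0123456789012345678901
    seq_a = "TTTACGTTTTCGTTTCATTTTT"
    seq_b = "TTTACGTTTTTGTTTTATTTTT"  # CG at 10 destroyed (C->T); C/T SNP at 15
    return LocusReference(
        "toy", seq_a, seq_b, regions=[(0, 11, "promoter"), (11, 22, "genic")]
    )


@pytest.fixture
def simulated_bundle():
    """One simulated individual with A methylated on both strands, B not."""
    scenario = LocusScenario(
        locus_id="sim", pattern_A="cg_both", pattern_B="none", seed=7
    )
    ref, truth = simulate_parents(scenario)
    bundle, truth = simulate_individual(scenario, truth)
    return scenario, ref, truth, bundle
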