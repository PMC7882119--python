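import pytest

from dualmlc.commissioning import run_commissioning
from dualmlc.mlc_model import Machine, MLCParameters
from dualmlc.virtual_lab import GroundTruth, gen_bundle


@pytest.fixture(scope="session")
def machine() -> Machine:
    return Machine()


@pytest.fixture(scope="session")
def gt_clean() -> GroundTruth:
    """Noise-free ground truth with the commissioned parameter set
    (offset +0.007 cm, gain 0, curvature 0, T&G 0.05 cm, T 0.47%)."""
    return GroundTruth(noise_sd=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_bundle(gt_clean):
    """Full noise-free session bundle: sweeps at all seven positions,
    abutting fields, bars, edges, and 15 modulated plans (5 per
    technique, 30 chamber points)."""
    return gen_bundle(gt_clean, n_plans_per_technique=5)


@pytest.fixture(scope="session")
def clean_report(clean_bundle, gt_clean):
    """End-to-end commissioning of the noise-free bundle."""
    return run_commissioning(clean_bundle, machine=gt_clean.machine)
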