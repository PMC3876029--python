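import pytest

from ksdev import synthetic as syn
from ksdev.motif import BackgroundModel


@pytest.fixture(scope="session")
def pwm():
    return syn.default_pwm()


@pytest.fixture(scope="session")
def uniform_bg():
    return BackgroundModel.uniform()


@pytest.fixture(scope="session")
def small_study():
    """A compact contaminated profiling study (F = 0.15) with its truth."""
    design = syn.StudyDesign(n_genes=600, seed=11)
    epi, mes, truth = syn.gen_profiling_study(design)
    return design, epi, mes, truth


@pytest.fixture(scope="session")
def genome_bundle(pwm):
    """Toy multi-species genome with planted sites and alignments."""
    return syn.gen_genome_and_alignments(pwm, seed=7)
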