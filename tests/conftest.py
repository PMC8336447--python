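import pytest

import admixorient as ao


@pytest.fixture(scope="session")
def m1():
    """The five-population case-study fixture."""
    return ao.make_m1()


@pytest.fixture(scope="session")
def m1_report(m1):
    """Quick construction-time validation of the case-study phenomenology.

    Provides the NJ/ML starting tree N0 and the edge-addition optimum N1
    (with E admixed) for reuse across tests.
    """
    return ao.validate_m1(m1)


@pytest.fixture(scope="session")
def m1_baseline_run(m1):
    """Baseline pipeline result (no orientation step) on the case study."""
    config = ao.SearchConfig(num_admixture=1, outgroup="E", mlno=False)
    return ao.run_search(m1.data, config)


@pytest.fixture(scope="session")
def m1_mlno_run(m1):
    """Orientation-augmented pipeline result on the case study."""
    config = ao.SearchConfig(num_admixture=1, outgroup="E", mlno=True)
    return ao.run_search(m1.data, config)
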