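import numpy as np
import pytest

from narkit import (
    FDNAR_MODEL,
    KR2_MODEL,
    SRNAR_MODEL,
    simulate_photocycle,
)


@pytest.fixture(scope="session")
def kr2_surface():
    """Noiseless flash-photolysis surface from the 4-step KR2-like model."""
    return simulate_photocycle(KR2_MODEL)


@pytest.fixture(scope="session")
def srnar_surface():
    """Noiseless surface from the 2-step blue-shifted SrNaR-like model."""
    return simulate_photocycle(SRNAR_MODEL)


@pytest.fixture(scope="session")
def fdnar_surface():
    return simulate_photocycle(FDNAR_MODEL)


@pytest.fixture(scope="session")
def quartet_alignment():
    """Poisson-evolved alignment on a known 4-taxon tree."""
    from narkit import simulate_alignment

    newick = "((A:0.08,B:0.12):0.06,(C:0.1,D:0.07):0.06);"
    return simulate_alignment(newick, n_sites=400, seed=11)
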