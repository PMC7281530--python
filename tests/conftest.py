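import numpy as np
import pytest

import poolscreen as ps


@pytest.fixture(scope="session")
def small_library():
    """30 hairpins over 10 genes, 22-nt sequences."""
    return ps.generate_library(n_genes=10, hairpins_per_gene=3, seed=7)


@pytest.fixture(scope="session")
def uniform_profile(small_library):
    return ps.generate_abundance(small_library, dispersion=0.0)


@pytest.fixture(scope="session")
def amplicon_two_samples():
    """Default 634-nt amplicon with two barcoded samples."""
    return ps.AmpliconModel().with_samples(["S1", "S2"], seed=0)


@pytest.fixture(scope="session")
def hill_unit():
    """Hill curve with emin=0, emax=1, ec50=1, slope 1."""
    return ps.DoseResponseCurve(emin=0.0, emax=1.0, ec50=1.0, hill=1.0)


def half_log_doses(dmax: float, n: int) -> np.ndarray:
    """n half-log-spaced doses descending from dmax (ascending order)."""
    return dmax / (10 ** (0.5 * np.arange(n)))[::-1]
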