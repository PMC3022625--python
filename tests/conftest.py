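"""Shared fixtures: the packaged 20-gene synthetic set and derived objects.

Expensive artifacts (fixture generation, panel design, default
simulations) are session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from concatag import datasets
from concatag.deconvolution import build_reference
from concatag.panel_design import design_panel
from concatag.wetlab_sim import SimConfig, simulate_sample


@pytest.fixture(scope="session")
def genes20():
    return datasets.synthetic_gene_targets()


@pytest.fixture(scope="session")
def panel20(genes20):
    return design_panel(genes20)


@pytest.fixture(scope="session")
def profiles2():
    return datasets.two_condition_profiles()


@pytest.fixture(scope="session")
def reference20(panel20, genes20):
    return build_reference(panel20, genes20)


@pytest.fixture(scope="session")
def default_sims(panel20, genes20, profiles2):
    """Default two-condition simulation at error rate 0, fixed seeds."""
    treated, untreated = profiles2
    res_t = simulate_sample("treated", panel20, genes20, treated, SimConfig(rng_seed=11))
    res_u = simulate_sample("untreated", panel20, genes20, untreated, SimConfig(rng_seed=12))
    return {"treated": res_t, "untreated": res_u}


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def toy_gene():
    """A 200 bp gene with no restriction sites, reproducible."""
    r = np.random.default_rng(5)
    from concatag.dna import BAMHI_SITE, HINDIII_SITE

    while True:
        seq = "".join(r.choice(list("ACGT"), size=200))
        if BAMHI_SITE not in seq and HINDIII_SITE not in seq:
            return seq
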