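import numpy as np
import pytest

import thermnorm as tn

ASSAY_TEMPS = np.array([15.0, 18.0, 22.0, 24.0, 26.0, 27.0])


def make_unit(rates_by_temp, rid="R1", sel=15.0, pco2=400.0):
    """Build an ExperimentalUnit from a {assay_temp: rate} mapping."""
    records = [
        tn.GrowthRecord(rid, sel, pco2, float(t), float(mu))
        for t, mu in sorted(rates_by_temp.items())
    ]
    return tn.ExperimentalUnit(rid, sel, pco2, records)


@pytest.fixture(scope="session")
def reference_params():
    """A well-behaved parameter set used across model tests."""
    return tn.ReactionNormParams(z=18.0, w=20.0, a=0.2, b=0.1)


@pytest.fixture(scope="session")
def noiseless_fit(reference_params):
    """Fit to exact curve values at the six assay temperatures."""
    y = tn.eval_reaction_norm(reference_params, ASSAY_TEMPS)
    return tn.fit_reaction_norm((ASSAY_TEMPS, y))


@pytest.fixture(scope="session")
def small_dataset():
    """Paper-like synthetic dataset, fixed seed, with its truth table."""
    spec = tn.paper_like_scenario()
    return tn.generate_dataset(spec, seed=7)
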