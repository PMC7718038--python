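import numpy as np
import pytest

import phagekit as pk


@pytest.fixture(scope="session")
def paper_inoculum():
    """1 mL of 2.5e9 PFU/mL stock into 44 mL of culture at 4e8 CFU/mL."""
    return pk.InoculumSpec(1.0, 2.5e9, 44.0, 4e8)


@pytest.fixture(scope="session")
def operating_params():
    """Published operating point: k=8.5e-10 mL/min, N0=4e8, MOI~0.14,
    L=14 min, B=13, sampled every 2 min for an hour."""
    return pk.SimulationParameters()


@pytest.fixture(scope="session")
def planted_genome():
    spec = pk.SyntheticGenomeSpec(
        length=20_000,
        gc_target=0.5,
        planted_promoters=[(1500, "+"), (5000, "-"), (9000, "+"), (12000, "-"), (16000, "+")],
        planted_rbs_orfs=[(3000, "+", 120), (7000, "-", 150), (14000, "+", 99)],
        planted_cut_sites=[("SacI", 4000), ("XhoI", 10000), ("ApaI", 18000)],
        seed=11,
    )
    return pk.generate_genome(spec)


def flat_series(level=1e6, times=None):
    times = np.arange(0, 31, 2) if times is None else np.asarray(times)
    return pk.TiterSeries(times=times, titers=np.full(len(times), float(level)))
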