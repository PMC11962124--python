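import numpy as np
import pandas as pd
import pytest

from mitentry.model import default_parameters
from mitentry.phospho import GROUPS, PhosphositeTable


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def small_factorial_table():
    """Complete 4-group x 3-replicate table with known group means and
    homoscedastic noise; no reference channels, no missing values."""
    rng = np.random.default_rng(123)
    n = 50
    samples = []
    for b in (1, 2, 3):
        for g, (treat, frac) in GROUPS.items():
            samples.append({
                "sample": f"{g}_r{b}", "group": g, "treatment": treat,
                "fraction": frac, "replicate": b, "batch": b,
                "is_reference": False,
            })
    samples = pd.DataFrame(samples).set_index("sample")
    idx = pd.Index([f"s{i:03d}" for i in range(n)], name="site_id")
    baseline = rng.normal(20, 1, n)
    vals = {
        s: baseline + rng.normal(0, 0.2, n) for s in samples.index
    }
    intens = pd.DataFrame(vals, index=idx)
    sites = pd.DataFrame(
        {"protein": "P0", "gene": "G0", "residue": "S", "position": 1,
         "localization_prob": 1.0, "contaminant": False, "reverse": False},
        index=idx,
    )
    return PhosphositeTable(sites=sites, intensities=intens, samples=samples)


def make_state(**kw):
    from mitentry.model import NetworkState

    defaults = dict(cdc25=0.0, cdc25pp=0.0, cycbcdk1=0.0, wee1=0.0,
                    pp2ab55=0.0, subp=0.0)
    defaults.update(kw)
    return NetworkState(**defaults)
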