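import numpy as np
import pandas as pd
import pytest

from phenodist import (
    default_surface_spec,
    gen_env_stack,
    gen_households,
    gen_weight_records,
)


@pytest.fixture(scope="session")
def small_stack():
    """20x20 grid, 21 layers, 5 regions (last one a desert)."""
    return gen_env_stack(20, 20, n_vars=21, n_regions=5, smoothness=3.0, seed=1)


@pytest.fixture(scope="session")
def tiny_stack():
    """16x16 grid with few layers for fast unit tests."""
    return gen_env_stack(16, 16, n_vars=5, n_regions=4, smoothness=2.0, seed=7)


@pytest.fixture(scope="session")
def households(small_stack):
    return gen_households(small_stack, 40, ["Sasso", "Koekoek"], seed=2)


@pytest.fixture(scope="session")
def noisefree_records(small_stack, households):
    """Records with residual_sd = 0 (household/slope variation kept)."""
    spec = default_surface_spec(small_stack, residual_sd=0.0)
    return gen_weight_records(households, small_stack, spec, seed=3)


@pytest.fixture()
def toy_two_household_records():
    """Noise-free lines y = 100 + 50 w and y = 100 + 30 w."""
    rows = []
    rid = 0
    for hid, slope in (("H1", 50.0), ("H2", 30.0)):
        for w in (14.0, 16.0, 18.0):
            rid += 1
            rows.append(
                {
                    "record_id": f"R{rid}",
                    "household_id": hid,
                    "breed": "A",
                    "sex": "male",
                    "region": "region_1",
                    "week": w,
                    "avg_weight_g": 100.0 + slope * w,
                }
            )
    return pd.DataFrame(rows)


def make_avg_records(rows):
    """Helper to build minimal average-weight record frames in tests."""
    base = {
        "record_id": None,
        "household_id": "H1",
        "breed": "A",
        "sex": "female",
        "region": "region_1",
        "week": 10.0,
        "group_weight_g": 1000.0,
        "n_birds": 5,
    }
    out = []
    for i, r in enumerate(rows):
        d = dict(base)
        d.update(r)
        d["record_id"] = d["record_id"] or f"R{i + 1}"
        out.append(d)
    df = pd.DataFrame(out)
    df["avg_weight_g"] = df["group_weight_g"] / df["n_birds"]
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
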