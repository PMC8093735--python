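import numpy as np
import pandas as pd
import pytest

from gutshift import DietTable, default_spec_from_table1, simulate_cohort


def build_table(biomass_by_fish, groups=None, gut_mass=None, body_mass=None):
    """Helper: DietTable from {fish_id: {category: mg}} plus optional
    {fish_id: group}.  Metadata defaults are benign positive values."""
    fish = list(biomass_by_fish)
    cats = sorted({c for row in biomass_by_fish.values() for c in row})
    rows = []
    for fid in fish:
        bm = {c: float(biomass_by_fish[fid].get(c, 0.0)) for c in cats}
        rows.append({
            "fish_id": fid,
            "group": (groups or {}).get(fid, "g"),
            "tl_cm": 12.0,
            "body_mass_g": (body_mass or {}).get(fid, 8.0),
            "gut_mass_mg": (gut_mass or {}).get(fid, sum(bm.values())),
            **bm,
        })
    return DietTable(pd.DataFrame(rows), cats)


@pytest.fixture(scope="session")
def default_cohort():
    """One study-conditions cohort (33 juvenile + 26 mature, seed fixed)."""
    return simulate_cohort(default_spec_from_table1(seed=11))


@pytest.fixture(scope="session")
def default_spec():
    return default_spec_from_table1(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
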