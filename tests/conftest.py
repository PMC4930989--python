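import numpy as np
import pytest

import coastcline as cc


@pytest.fixture(scope="session")
def grid5():
    return cc.CoastGrid.regular(5, spacing_km=10.0, lat_south=-40.0)


@pytest.fixture(scope="session")
def grid100():
    return cc.CoastGrid.regular(100, spacing_km=10.0, lat_south=-45.0)


@pytest.fixture(scope="session")
def kernel100(grid100):
    """The northward-advective study kernel: mu=15 km, sigma=25 km, loss=0.3."""
    return cc.make_advective_kernel(grid100, 15.0, 25.0, 0.3)


@pytest.fixture()
def two_pop_table():
    """Two sites, hand-built so the reference-allele frequencies are 0.8 and 0.2.

    5 diploids per site; site A carries 8 reference alleles (genotypes
    2,2,2,1,1), site B carries 2 (1,1,0,0,0).
    """
    ga = [2, 2, 2, 1, 1]
    gb = [1, 1, 0, 0, 0]
    return cc.GenotypeTable(
        individual_ids=tuple(f"a{i}" for i in range(5)) + tuple(f"b{i}" for i in range(5)),
        sites=("A",) * 5 + ("B",) * 5,
        mitotypes=np.array(["N"] * 5 + ["S"] * 5, dtype=object),
        loci=("L1",),
        G=np.array(ga + gb, dtype=int).reshape(-1, 1),
        site_coords={"A": (-30.0, -71.0), "B": (-40.0, -73.0)},
    )
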