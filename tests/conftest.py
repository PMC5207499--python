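import numpy as np
import pytest

import greentide as gt


@pytest.fixture(scope="session")
def boundary_table():
    return gt.datasets.load_boundary_table()


@pytest.fixture(scope="session")
def site_assessments():
    return gt.datasets.load_site_assessments().set_index("site_id")


@pytest.fixture(scope="session")
def metal_site_means():
    return gt.datasets.load_metal_site_means()


@pytest.fixture(scope="session")
def published_eqr(site_assessments, metal_site_means):
    """EQR per site, ordered like the metal site-mean table."""
    return site_assessments.loc[metal_site_means.index, "eqr"].astype(float)


@pytest.fixture()
def simple_survey():
    """Two patches, hand-computable sub-metrics."""
    geom = gt.SiteGeometry("demo", aih_ha=80.0, patch_areas_ha={"A": 4.0, "B": 6.0})
    quads = []
    for cover, bio, ent in [(20, 800, False), (30, 1200, True)]:
        quads.append(
            gt.QuadratRecord("demo", "A", "A-T1", cover_pct=cover,
                             biomass_g_m2=bio, entrained=ent, quadrat_id=f"A{cover}")
        )
    for cover, bio, ent in [(40, 2000, False), (60, 1000, False)]:
        quads.append(
            gt.QuadratRecord("demo", "B", "B-T1", cover_pct=cover,
                             biomass_g_m2=bio, entrained=ent, quadrat_id=f"B{cover}")
        )
    return gt.SiteSurvey(geometry=geom, quadrats=tuple(quads))


@pytest.fixture(scope="session")
def nested_layout():
    """8 sites in 3 status classes, 5 samples each, with planted effects."""
    rng = np.random.default_rng(7)
    site = np.repeat([f"s{i}" for i in range(8)], 5)
    esc = np.repeat(["High", "High", "High", "Mod", "Mod", "Mod", "Poor", "Poor"], 5)
    mus = rng.normal(0, 2.0, size=(8, 3))
    x = np.concatenate([rng.normal(mus[i], 1.0, size=(5, 3)) for i in range(8)])
    return x, esc, site
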