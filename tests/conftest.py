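import numpy as np
import pytest

from seedtrend import (
    FecundityModel,
    SimulationConfig,
    SiteClimate,
    TreeRecord,
    simulate_dataset,
)


def make_site(
    site_id="s1",
    ecoregion="ecoA",
    norms=None,
    years=range(2009, 2020),
    trends=None,
) -> SiteClimate:
    norms = norms or {"tsp": 5.0, "tsum": 20.0, "deficit": 50.0}
    trends = trends or {"tsp": 0.02, "tsum": 0.01, "deficit": 0.5}
    anomalies = {y: {"tsp": 0.0, "tsum": 0.0, "deficit": 0.0} for y in years}
    return SiteClimate(
        site_id=site_id, ecoregion=ecoregion, norms=norms,
        anomalies=anomalies, trends=trends,
        window=(min(years), max(years)),
    )


def make_tree(tree_id="t1", diameter=30.0, shade=1, years=range(2010, 2020), **kw):
    return TreeRecord(
        tree_id=tree_id, species=kw.pop("species", "Quercus alba"),
        genus=kw.pop("genus", "Quercus"), site_id=kw.pop("site_id", "s1"),
        plot_id=kw.pop("plot_id", "p1"), x=kw.pop("x", 10.0), y=kw.pop("y", 10.0),
        shade_class=shade,
        diameters={y: diameter + 0.3 * (y - min(years)) for y in years},
        **kw,
    )


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        n_sites=4, n_ecoregions=2, plots_per_site=2, trees_per_plot=8,
        years=(2010, 2017), window=(2011, 2017),
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_dataset(small_config, seed=101)


@pytest.fixture(scope="session")
def small_fit(small_sim):
    dataset, _ = small_sim
    return FecundityModel(n_iter=400, n_burn=200, thin=2, random_state=7).fit(dataset)
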