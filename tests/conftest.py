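"""Shared fixtures: a scaled synthetic study and its fitted pipeline."""

import pandas as pd
import pytest

from deprindex import GISDPipeline
from deprindex.synthdata import (SynthConfig, generate_health_outcomes,
                                 generate_hierarchy, generate_panel)


@pytest.fixture(scope="session")
def cfg() -> SynthConfig:
    return SynthConfig(seed=7)


@pytest.fixture(scope="session")
def hierarchy(cfg):
    return generate_hierarchy(cfg)


@pytest.fixture(scope="session")
def panel_truth(cfg, hierarchy):
    return generate_panel(cfg, hierarchy)


@pytest.fixture(scope="session")
def panel(panel_truth):
    return panel_truth[0]


@pytest.fixture(scope="session")
def truth(panel_truth):
    return panel_truth[1]


@pytest.fixture(scope="session")
def pipeline(cfg, hierarchy, panel) -> GISDPipeline:
    return GISDPipeline(g8_cells=cfg.g8_cells,
                        price_index=cfg.price_index()).fit(panel, hierarchy)


@pytest.fixture(scope="session")
def district_scores(pipeline) -> pd.DataFrame:
    return pipeline.score_panel("district")


@pytest.fixture(scope="session")
def outcomes(cfg, district_scores, hierarchy) -> pd.DataFrame:
    return generate_health_outcomes(cfg, district_scores, hierarchy,
                                    years=range(2012, 2016))


@pytest.fixture()
def toy_hierarchy():
    """Two districts (3 GVB, 4 municipalities), two years."""
    rows = []
    layout = [
        ("01001001", "G01", "01001"), ("01001002", "G01", "01001"),
        ("01001003", "G02", "01001"), ("02002001", "G03", "02002"),
    ]
    pops = {"01001001": 1000, "01001002": 3000, "01001003": 500,
            "02002001": 2000}
    for mun, gvb, dist in layout:
        for year in (2018, 2019):
            rows.append((mun, gvb, dist, "R01", "N01", dist[:2], year,
                         pops[mun]))
    from deprindex.regions import RegionHierarchy
    return RegionHierarchy(pd.DataFrame(rows, columns=[
        "municipality_id", "gvb_id", "district_id", "ror_id", "nuts2_id",
        "state_id", "year", "population"]))
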