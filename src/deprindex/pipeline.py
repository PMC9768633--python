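"""End-to-end index construction: harmonized panel to per-level scores."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator

from . import index as idx
from .harmonize import harmonize_panel
from .regions import (DIMENSIONS, LEVELS, IndicatorPanel, RegionHierarchy)
from .weighting import POOL_YEARS, DimensionPCA, loading_table

__all__ = ["GISDPipeline", "build_gisd"]

SCORE_COLS = ("score_education", "score_employment", "score_income")


class GISDPipeline(BaseEstimator):
    """Full deprivation-index construction pipeline.

    ``fit`` harmonizes the panel, fits one pooled first-component PCA per
    subdimension on the 2001-2019 pool, scores every municipality and
    year on the frozen pooled scale, normalizes, composes, aggregates to
    the requested levels and assigns yearly quintiles.

    Attributes
    ----------
    harmonized_ : IndicatorPanel
        The artefact-corrected, complete panel.
    pcas_ : dict dimension -> DimensionPCA
    loading_table_ : pd.DataFrame
        Loadings, eigenvalues and weight shares per indicator.
    scores_ : dict level -> pd.DataFrame
        Per level: region_id, year, subdimension scores, gisd, quintile.
        GVB rows additionally carry ``reduced_resolution=True`` because
        only a third of the indicators vary below the district level.
    """

    def __init__(self, pool_years: tuple[int, int] = POOL_YEARS,
                 levels: Sequence[str] = ("municipality", "gvb", "district",
                                          "ror", "nuts2"),
                 price_index: Mapping[int, float] | None = None,
                 g8_cells: Sequence[tuple[str, int]] = (),
                 break_year: int = 2013,
                 gap: tuple[int, int] | None = (2011, 2012),
                 harmonize: bool = True) -> None:
        self.pool_years = pool_years
        self.levels = list(levels)
        self.price_index = price_index
        self.g8_cells = g8_cells
        self.break_year = break_year
        self.gap = gap
        self.harmonize = harmonize

    # -- helpers -----------------------------------------------------------
    def _municipal_matrix(self, panel: IndicatorPanel,
                          hierarchy: RegionHierarchy) -> pd.DataFrame:
        """Wide municipality x year matrix of all nine indicators, joined
        from each indicator's native level through the hierarchy."""
        base = hierarchy.table[["municipality_id", "gvb_id", "district_id",
                                "year"]].copy()
        for name, spec in panel.specs.items():
            vals = panel.indicator_values(name)[
                ["region_id", "year", "value"]].rename(
                columns={"value": name})
            key = "gvb_id" if spec.native_level == "gvb" else "district_id"
            base = base.merge(vals, left_on=[key, "year"],
                              right_on=["region_id", "year"],
                              how="left").drop(columns="region_id")
        return base

    # -- fitting -----------------------------------------------------------
    def fit(self, panel: IndicatorPanel,
            hierarchy: RegionHierarchy) -> "GISDPipeline":
        years = hierarchy.years
        if self.harmonize:
            self.harmonized_ = harmonize_panel(
                panel, hierarchy, price_index=self.price_index,
                g8_cells=self.g8_cells, break_year=self.break_year,
                gap=self.gap, target_years=years)
        else:
            self.harmonized_ = panel
        mat = self._municipal_matrix(self.harmonized_, hierarchy)
        names = list(self.harmonized_.specs)
        if mat[names].isna().any().any():
            missing = mat[names].isna().sum()
            raise ValueError("harmonized panel is incomplete:\n"
                             f"{missing[missing > 0]}")

        lo, hi = self.pool_years
        pool = mat[(mat["year"] >= lo) & (mat["year"] <= hi)]
        self.pcas_ = {}
        for dim in DIMENSIONS:
            ind = [n for n in names
                   if self.harmonized_.specs[n].dimension == dim]
            signs = {n: self.harmonized_.specs[n].sign for n in ind}
            self.pcas_[dim] = DimensionPCA(ind, signs=signs).fit(pool)
        self.loading_table_ = loading_table(self.pcas_,
                                            self.harmonized_.specs)

        muni = mat[["municipality_id", "year"]].copy()
        muni.columns = ["region_id", "year"]
        for dim, col in zip(DIMENSIONS, SCORE_COLS):
            muni[col] = self.pcas_[dim].transform(mat)
        muni = idx.normalize_yearly(muni, SCORE_COLS)
        muni = idx.compose_gisd(muni)
        muni = idx.normalize_yearly(muni, ["gisd_raw"]).rename(
            columns={"gisd_raw": "gisd"})

        value_cols = list(SCORE_COLS) + ["gisd"]
        self.scores_ = {}
        for level in self.levels:
            if level == "municipality":
                panel_lvl = muni.copy()
            else:
                panel_lvl = idx.aggregate_scores(
                    muni, hierarchy, level, value_cols)
            panel_lvl = idx.assign_quintiles(panel_lvl, "gisd")
            panel_lvl["quintile_group"] = idx.quintile_group(
                panel_lvl["quintile"])
            if level == "gvb":
                panel_lvl["reduced_resolution"] = True
            self.scores_[level] = panel_lvl
        return self

    def score_panel(self, level: str = "district") -> pd.DataFrame:
        if level not in self.scores_:
            raise KeyError(f"level {level!r} was not built "
                           f"(have {list(self.scores_)})")
        return self.scores_[level]


def build_gisd(panel: IndicatorPanel, hierarchy: RegionHierarchy,
               levels: Iterable[str] = ("municipality", "gvb", "district",
                                        "ror", "nuts2"),
               **kwargs) -> dict[str, pd.DataFrame]:
    """One-call construction: returns ``{level: score panel}``."""
    pipe = GISDPipeline(levels=list(levels), **kwargs).fit(panel, hierarchy)
    return pipe.scores_
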