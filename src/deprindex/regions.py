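"""Administrative region hierarchy, indicator metadata and panel I/O.

The toolkit models the nested German administrative geography:
municipality -> GVB (Gemeindeverband) -> district -> ROR (spatial
planning region) -> NUTS-2.  Municipality identifiers follow the
AGS convention: 8-digit fixed-width strings whose first five digits
give the district and first two the federal state.  GVB, ROR and
NUTS-2 are not AGS prefixes and carry their own code columns.

Populations are stored per municipality and year; populations of all
higher levels are derived by summation, so population conservation
holds by construction and is asserted rather than trusted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "LEVEL_COLS",
    "DIMENSIONS",
    "DEFAULT_EAST_STATES",
    "HierarchyError",
    "PanelError",
    "IndicatorSpec",
    "default_indicator_specs",
    "RegionHierarchy",
    "IndicatorPanel",
    "read_hierarchy",
    "write_hierarchy",
    "read_panel",
    "broadcast_district_to_gvb",
]

#: ordered from finest to coarsest
LEVELS: tuple[str, ...] = ("municipality", "gvb", "district", "ror", "nuts2")

LEVEL_COLS: dict[str, str] = {
    "municipality": "municipality_id",
    "gvb": "gvb_id",
    "district": "district_id",
    "ror": "ror_id",
    "nuts2": "nuts2_id",
}

DIMENSIONS: tuple[str, ...] = ("education", "employment", "income")

#: Brandenburg, Mecklenburg-Vorpommern, Saxony, Saxony-Anhalt, Thuringia.
#: Berlin ("11") is treated as West by default; its mixed history makes the
#: assignment genuinely ambiguous, so the set is configurable everywhere.
DEFAULT_EAST_STATES: frozenset[str] = frozenset({"12", "13", "14", "15", "16"})

YEAR_MIN, YEAR_MAX = 1998, 2019


class HierarchyError(ValueError):
    """Raised when a region hierarchy violates its structural invariants."""


class PanelError(ValueError):
    """Raised when an indicator panel violates its key or type contracts."""


@dataclass(frozen=True)
class IndicatorSpec:
    """Metadata for one deprivation indicator.

    Parameters
    ----------
    name : str
        Canonical indicator name.
    dimension : {"education", "employment", "income"}
        Subdimension the indicator belongs to.
    polarity : {"increasing", "decreasing"}
        Whether larger values mean *more* deprivation (``increasing``,
        e.g. unemployment rate) or less (``decreasing``, e.g. gross wage).
    transform : {"none", "log", "log-after-deflation"}
        Scale transform applied during harmonization.  Currency-valued,
        open-ended indicators are deflated by a price index and logged.
    native_level : {"district", "gvb"}
        Finest spatial level at which the source publishes the indicator.
    available_years : tuple of int
        Years for which source data exist; other years must be imputed.
    corrections : tuple of str
        Artefact corrections to apply: subset of
        ``{"break", "g8", "east_west"}``.
    """

    name: str
    dimension: str
    polarity: str
    transform: str = "none"
    native_level: str = "district"
    available_years: tuple[int, ...] = tuple(range(YEAR_MIN, YEAR_MAX + 1))
    corrections: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.dimension not in DIMENSIONS:
            raise ValueError(f"unknown dimension {self.dimension!r}")
        if self.polarity not in ("increasing", "decreasing"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.transform not in ("none", "log", "log-after-deflation"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.native_level not in ("district", "gvb"):
            raise ValueError(f"unknown native level {self.native_level!r}")

    @property
    def sign(self) -> int:
        """+1 for deprivation-increasing indicators, -1 otherwise."""
        return 1 if self.polarity == "increasing" else -1


def _years(*spans: tuple[int, int]) -> tuple[int, ...]:
    out: list[int] = []
    for a, b in spans:
        out.extend(range(a, b + 1))
    return tuple(out)


def default_indicator_specs() -> dict[str, IndicatorSpec]:
    """The nine canonical indicators, three per subdimension.

    Availability windows mirror the source statistics: the two
    employee-qualification indicators start in 2001 and skip 2012
    (reporting-procedure changeover), wage and household income start
    in 2000, the debtor quota in 2004.  Unemployment and employment
    rates exist from 1998 but only at district resolution before 2001.
    """
    specs = [
        IndicatorSpec(
            "employees_university_degree", "education", "decreasing",
            native_level="district",
            available_years=_years((2001, 2011), (2013, 2019)),
            corrections=("break",),
        ),
        IndicatorSpec(
            "employees_without_qualification", "education", "increasing",
            native_level="district",
            available_years=_years((2001, 2011), (2013, 2019)),
            corrections=("break", "east_west"),
        ),
        IndicatorSpec(
            "school_leavers_without_qualification", "education", "increasing",
            native_level="district",
            available_years=_years((1998, 2019)),
            corrections=("g8",),
        ),
        IndicatorSpec(
            "employment_rate", "employment", "decreasing",
            native_level="gvb", available_years=_years((1998, 2019)),
        ),
        IndicatorSpec(
            "unemployment_rate", "employment", "increasing",
            native_level="gvb", available_years=_years((1998, 2019)),
        ),
        IndicatorSpec(
            "gross_wage", "employment", "decreasing",
            transform="log-after-deflation",
            native_level="district", available_years=_years((2000, 2019)),
        ),
        IndicatorSpec(
            "household_income", "income", "decreasing",
            transform="log-after-deflation",
            native_level="district", available_years=_years((2000, 2019)),
        ),
        IndicatorSpec(
            "debtor_quota", "income", "increasing",
            native_level="district", available_years=_years((2004, 2019)),
        ),
        # income tax is deprivation-decreasing: richer regions collect more
        IndicatorSpec(
            "income_tax", "income", "decreasing",
            transform="log-after-deflation",
            native_level="gvb", available_years=_years((1998, 2019)),
        ),
    ]
    return {s.name: s for s in specs}


_HIER_COLS = ["municipality_id", "gvb_id", "district_id", "ror_id",
              "nuts2_id", "state_id", "year", "population"]


class RegionHierarchy:
    """Nested administrative geography with yearly populations.

    The backing table has one row per municipality and year with the id
    columns of every coarser level.  All parent links are required to be
    time-constant (the source data are harmonized to a single territorial
    status), so the link table is validated to be identical across years.
    """

    def __init__(self, table: pd.DataFrame,
                 east_states: Iterable[str] = DEFAULT_EAST_STATES) -> None:
        missing = [c for c in _HIER_COLS if c not in table.columns]
        if missing:
            raise HierarchyError(f"hierarchy table misses columns {missing}")
        t = table.loc[:, _HIER_COLS].copy()
        for c in _HIER_COLS[:6]:
            t[c] = t[c].astype(str)
        t["year"] = t["year"].astype(int)
        t["population"] = t["population"].astype(float)
        self.table = t.sort_values(["municipality_id", "year"],
                                   ignore_index=True)
        self.east_states = frozenset(str(s) for s in east_states)
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        t = self.table
        for col in _HIER_COLS[:6]:
            bad = t.loc[t[col].isin(("", "nan", "None")) | t[col].isna(),
                        "municipality_id"]
            if len(bad):
                raise HierarchyError(
                    f"orphan region: municipality {bad.iloc[0]!r} has no "
                    f"{col.removesuffix('_id')} parent")
        if (t["population"] < 0).any():
            bad = t.loc[t["population"] < 0, "municipality_id"].iloc[0]
            raise HierarchyError(f"negative population for region {bad!r}")
        dup = t.duplicated(["municipality_id", "year"])
        if dup.any():
            key = t.loc[dup, ["municipality_id", "year"]].iloc[0]
            raise HierarchyError(
                f"duplicate hierarchy row for {key.municipality_id!r} "
                f"in {key.year}")
        pref = t["municipality_id"].str[:5] != t["district_id"]
        if pref.any():
            raise HierarchyError(
                "municipality id prefix disagrees with district id for "
                f"{t.loc[pref, 'municipality_id'].iloc[0]!r}")
        if (t["district_id"].str[:2] != t["state_id"]).any():
            raise HierarchyError("district id prefix disagrees with state id")
        links = t[list(LEVEL_COLS.values()) + ["state_id"]].drop_duplicates()
        if links["municipality_id"].duplicated().any():
            raise HierarchyError("parent links vary over time")

    # -- accessors ---------------------------------------------------------
    @property
    def years(self) -> list[int]:
        return sorted(self.table["year"].unique())

    def counts(self) -> dict[str, int]:
        """Number of regions per level."""
        return {lv: self.table[LEVEL_COLS[lv]].nunique() for lv in LEVELS}

    def level_ids(self, level: str) -> np.ndarray:
        return np.sort(self.table[LEVEL_COLS[level]].unique())

    def population(self, level: str = "municipality") -> pd.DataFrame:
        """Population per region at *level* and year (sum over children)."""
        col = LEVEL_COLS[level]
        out = (self.table.groupby([col, "year"], as_index=False)["population"]
               .sum().rename(columns={col: "region_id"}))
        return out

    def parent_map(self, child_level: str, parent_level: str) -> pd.Series:
        """Series mapping child region ids to parent region ids."""
        ci, pi = LEVELS.index(child_level), LEVELS.index(parent_level)
        if ci >= pi:
            raise ValueError(f"{parent_level} is not coarser than {child_level}")
        cc, pc = LEVEL_COLS[child_level], LEVEL_COLS[parent_level]
        m = self.table[[cc, pc]].drop_duplicates()
        if m[cc].duplicated().any():
            raise HierarchyError(f"{child_level} maps to several {parent_level}s")
        return m.set_index(cc)[pc]

    def state_of(self, level: str) -> pd.Series:
        """State id per region at *level* (modal state for coarse levels)."""
        col = LEVEL_COLS[level]
        return (self.table.groupby(col)["state_id"]
                .agg(lambda s: s.mode().iloc[0]))

    def east_flag(self, level: str) -> pd.Series:
        """Boolean Series: region lies in an East German state."""
        return self.state_of(level).isin(self.east_states)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_csv(cls, path,
                 east_states: Iterable[str] = DEFAULT_EAST_STATES
                 ) -> "RegionHierarchy":
        df = pd.read_csv(path, dtype={c: str for c in _HIER_COLS[:6]}
                         | {"region_id": str})
        if "region_id" in df.columns and "municipality_id" not in df.columns:
            df = df.rename(columns={"region_id": "municipality_id"})
        return cls(df, east_states=east_states)

    def to_csv(self, path) -> None:
        out = self.table.rename(columns={"municipality_id": "region_id"})
        out.to_csv(path, index=False)


def read_hierarchy(path, east_states=DEFAULT_EAST_STATES) -> RegionHierarchy:
    """Read and validate a hierarchy CSV (columns: region_id, gvb_id,
    district_id, ror_id, nuts2_id, state_id, year, population)."""
    return RegionHierarchy.from_csv(path, east_states=east_states)


def write_hierarchy(hierarchy: RegionHierarchy, path) -> None:
    hierarchy.to_csv(path)


_PANEL_COLS = ["region_id", "year", "indicator", "value"]


class IndicatorPanel:
    """Long-format region x year x indicator value panel.

    Carries the indicator specs, an ``imputed`` flag per cell and a
    correction ledger recording every harmonization step that touched
    the panel (used to refuse double application of a correction).
    """

    def __init__(self, df: pd.DataFrame,
                 specs: Mapping[str, IndicatorSpec]) -> None:
        missing = [c for c in _PANEL_COLS if c not in df.columns]
        if missing:
            raise PanelError(f"panel misses columns {missing}")
        d = df.copy()
        d["region_id"] = d["region_id"].astype(str)
        d["year"] = d["year"].astype(int)
        d["value"] = d["value"].astype(float)
        if "imputed" not in d.columns:
            d["imputed"] = False
        unknown = set(d["indicator"]) - set(specs)
        if unknown:
            raise PanelError(f"unknown indicators {sorted(unknown)}")
        dup = d.duplicated(["region_id", "year", "indicator"])
        if dup.any():
            key = d.loc[dup, ["region_id", "year", "indicator"]].iloc[0]
            raise PanelError(
                f"duplicate panel row ({key.region_id}, {key.year}, "
                f"{key.indicator})")
        self.df = d.sort_values(["indicator", "region_id", "year"],
                                ignore_index=True)
        self.specs = dict(specs)
        self.ledger = pd.DataFrame(
            columns=["indicator", "correction", "parameters", "rows_touched"])

    def copy(self) -> "IndicatorPanel":
        new = IndicatorPanel.__new__(IndicatorPanel)
        new.df = self.df.copy()
        new.specs = dict(self.specs)
        new.ledger = self.ledger.copy()
        return new

    def record(self, indicator: str, correction: str, parameters: str,
               rows_touched: int) -> None:
        if self.applied(indicator, correction):
            raise PanelError(
                f"correction {correction!r} already applied to {indicator!r}")
        self.ledger.loc[len(self.ledger)] = [indicator, correction,
                                             parameters, rows_touched]

    def applied(self, indicator: str, correction: str) -> bool:
        L = self.ledger
        return bool(((L["indicator"] == indicator)
                     & (L["correction"] == correction)).any())

    def indicator_values(self, indicator: str) -> pd.DataFrame:
        return self.df[self.df["indicator"] == indicator]

    def wide(self, indicators: Sequence[str] | None = None) -> pd.DataFrame:
        """Pivot to (region_id, year) x indicator matrix."""
        d = self.df
        if indicators is not None:
            d = d[d["indicator"].isin(indicators)]
        return d.pivot_table(index=["region_id", "year"], columns="indicator",
                             values="value", aggfunc="first")

    def validate_regions(self, hierarchy: RegionHierarchy) -> None:
        """Every region id must resolve at the indicator's native level or
        at a coarser level (district values may precede GVB broadcast)."""
        known = {lv: set(hierarchy.level_ids(lv)) for lv in LEVELS[1:]}
        for name, sub in self.df.groupby("indicator"):
            spec = self.specs[name]
            levels = LEVELS[LEVELS.index(spec.native_level):]
            ok = set().union(*(known[lv] for lv in levels))
            bad = set(sub["region_id"]) - ok
            if bad:
                raise PanelError(
                    f"indicator {name!r}: region ids {sorted(bad)[:5]} do not "
                    f"resolve at level {spec.native_level} or coarser")

    @classmethod
    def from_csv(cls, path, specs: Mapping[str, IndicatorSpec],
                 decimal: str = ".") -> "IndicatorPanel":
        # decimal-comma files use the German dialect: semicolon separator
        sep = ";" if decimal == "," else ","
        df = pd.read_csv(path, dtype={"region_id": str}, decimal=decimal,
                         sep=sep)
        out_of_window = ~df["year"].astype(int).between(YEAR_MIN, YEAR_MAX)
        if out_of_window.any():
            warnings.warn(
                f"dropping {int(out_of_window.sum())} rows outside "
                f"{YEAR_MIN}-{YEAR_MAX}", stacklevel=2)
            df = df[~out_of_window]
        return cls(df, specs)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    def write_ledger(self, path) -> None:
        self.ledger.to_csv(path, index=False)


def read_panel(path, specs: Mapping[str, IndicatorSpec],
               decimal: str = ".") -> IndicatorPanel:
    """Read a long-format panel CSV (region_id, year, indicator, value).

    ``decimal=","`` parses German decimal-comma files.  Years outside the
    1998-2019 window are dropped with a warning; duplicate keys and unknown
    indicator names raise :class:`PanelError`.
    """
    return IndicatorPanel.from_csv(path, specs, decimal=decimal)


def broadcast_district_to_gvb(panel: IndicatorPanel,
                              hierarchy: RegionHierarchy,
                              indicator: str,
                              years: Iterable[int]) -> IndicatorPanel:
    """Assign district-level values of *indicator* to every member GVB.

    Used where a GVB-native indicator is only published at district
    resolution for early years: each GVB inherits its district's value, so
    within-district variance is exactly zero for the broadcast years.
    District rows for those years are replaced by the GVB rows; missing
    district values simply yield missing GVB values.
    """
    years = set(int(y) for y in years)
    out = panel.copy()
    d = out.df
    mask = ((d["indicator"] == indicator) & d["year"].isin(years)
            & d["region_id"].isin(hierarchy.level_ids("district")))
    src = d[mask]
    if src.empty:
        return out
    members = (hierarchy.table[["gvb_id", "district_id"]].drop_duplicates()
               .rename(columns={"district_id": "region_id"}))
    new = src.merge(members, on="region_id")
    new = new.drop(columns="region_id").rename(columns={"gvb_id": "region_id"})
    new = new[d.columns]
    out.df = pd.concat([d[~mask], new], ignore_index=True).sort_values(
        ["indicator", "region_id", "year"], ignore_index=True)
    out.record(indicator, "broadcast_district_to_gvb",
               f"years={sorted(years)}", len(new))
    return out
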