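"""Index composition: normalization, aggregation, quintile assignment.

Subdimension factor scores are min-max normalized to [0, 1] within each
year, summed to the raw total index (so each dimension carries a weight
of one third), and normalized again, yielding a deprivation score of 0
for the least and 1 for the most deprived region of the year.  Scores at
coarser spatial levels are population-weighted means of the municipal
scores, renormalized within the level and year so every level spans the
full [0, 1] range.  Regions are finally ranked into five equal fifths
per level and year; quintile 1 is the least deprived fifth.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .regions import RegionHierarchy

__all__ = [
    "IndexError_",
    "normalize_yearly",
    "compose_gisd",
    "aggregate_scores",
    "assign_quintiles",
    "quintile_group",
    "map_to_custom_geography",
]


class IndexError_(ValueError):
    """Raised on degenerate score panels (name avoids the builtin)."""


def normalize_yearly(df: pd.DataFrame, value_cols: Sequence[str],
                     year_col: str = "year") -> pd.DataFrame:
    """Min-max normalize *value_cols* to [0, 1] within each year.

    Raises when a year has no spread (constant scores), since the
    normalization is undefined there.  Idempotent and invariant under
    affine transforms of the inputs.
    """
    out = df.copy()
    g = out.groupby(year_col)
    for col in value_cols:
        lo = g[col].transform("min")
        hi = g[col].transform("max")
        span = hi - lo
        if (span == 0).any():
            bad = out.loc[span == 0, year_col].iloc[0]
            raise IndexError_(
                f"constant {col!r} in year {bad}; cannot normalize")
        out[col] = (out[col] - lo) / span
    return out


def compose_gisd(df: pd.DataFrame,
                 score_cols: Sequence[str] = ("score_education",
                                              "score_employment",
                                              "score_income"),
                 out_col: str = "gisd_raw") -> pd.DataFrame:
    """Sum the three normalized subdimension scores (range [0, 3]).

    The sum gives each dimension a weight of one third in the total
    index; the downstream yearly normalization maps it back to [0, 1].
    """
    missing = [c for c in score_cols if c not in df.columns]
    if missing:
        raise IndexError_(f"missing subdimension scores {missing}")
    if df[list(score_cols)].isna().any().any():
        raise IndexError_("missing subdimension score values")
    out = df.copy()
    out[out_col] = out[list(score_cols)].sum(axis=1)
    return out


def aggregate_scores(scores: pd.DataFrame, hierarchy: RegionHierarchy,
                     target_level: str,
                     value_cols: Sequence[str],
                     source_level: str = "municipality",
                     renormalize: bool = True) -> pd.DataFrame:
    """Population-weighted aggregation of scores to a coarser level.

    ``scores`` has columns region_id, year and *value_cols* at
    *source_level*.  The target score is the population-weighted mean of
    the child scores per year (yearly populations), optionally min-max
    renormalized within the target level and year.
    """
    parent = hierarchy.parent_map(source_level, target_level)
    pop = hierarchy.population(source_level).rename(
        columns={"population": "_pop"})
    d = scores.merge(pop, on=["region_id", "year"], how="left")
    if d["_pop"].isna().any():
        raise IndexError_("population missing for some region-years")
    d["_parent"] = d["region_id"].map(parent)
    if d["_parent"].isna().any():
        bad = d.loc[d["_parent"].isna(), "region_id"].iloc[0]
        raise IndexError_(f"no {target_level} parent for region {bad!r}")
    g = d.groupby(["_parent", "year"])
    wsum = g["_pop"].sum()
    if (wsum == 0).any():
        raise IndexError_(f"zero total population in a {target_level}-year")
    parts = {}
    for col in value_cols:
        parts[col] = (d[col] * d["_pop"]).groupby(
            [d["_parent"], d["year"]]).sum() / wsum
    out = pd.DataFrame(parts).reset_index().rename(
        columns={"_parent": "region_id"})
    if renormalize:
        out = normalize_yearly(out, value_cols)
    return out


def assign_quintiles(scores: pd.DataFrame, value_col: str = "gisd",
                     year_col: str = "year",
                     out_col: str = "quintile") -> pd.DataFrame:
    """Rank regions into five equal fifths per year (1 = least deprived).

    Fifths are over units, not population.  With n regions the cut
    counts are ``ceil(n*k/5)`` so remainders go to the lower quintiles
    (n=401 gives 81/80/80/80/80); tied scores share the lower quintile
    via minimum ranks.
    """
    out = scores.copy()
    labels = np.empty(len(out), dtype=int)
    for year, sub in out.groupby(year_col):
        n = len(sub)
        if n < 5:
            raise IndexError_(f"need >= 5 regions per year, have {n} "
                              f"in {year}")
        rank = sub[value_col].rank(method="min").to_numpy()
        cuts = np.ceil(n * np.arange(1, 6) / 5.0)
        q = np.searchsorted(cuts, rank, side="left") + 1
        labels[out.index.get_indexer(sub.index)] = q
    out[out_col] = labels
    return out


def quintile_group(q: int | pd.Series) -> str | pd.Series:
    """Collapse quintiles to the three analysis groups.

    1 -> ``low`` deprivation, 2-4 -> ``mid``, 5 -> ``high``.
    """
    mapping = {1: "low", 2: "mid", 3: "mid", 4: "mid", 5: "high"}
    if isinstance(q, pd.Series):
        return q.map(mapping)
    return mapping[int(q)]


def map_to_custom_geography(district_scores: pd.DataFrame,
                            crosswalk: pd.DataFrame,
                            value_cols: Sequence[str] = ("gisd",),
                            renormalize: bool = True) -> pd.DataFrame:
    """Project district scores onto a custom geography (e.g. zip codes).

    ``crosswalk`` columns: district_id, unit_id, weight (population in
    the intersection).  Each unit's score is the weight-normalized mean
    of its districts' scores per year; weights are normalized within
    each unit, so any nonnegative mass (population counts, fractions)
    works.
    """
    cw = crosswalk.copy()
    cw["district_id"] = cw["district_id"].astype(str)
    tot = cw.groupby("unit_id")["weight"].transform("sum")
    if (tot <= 0).any():
        raise IndexError_("unit with non-positive total weight")
    cw["_w"] = cw["weight"] / tot
    d = district_scores.rename(columns={"region_id": "district_id"}).merge(
        cw[["district_id", "unit_id", "_w"]], on="district_id")
    parts = {}
    for col in value_cols:
        num = (d[col] * d["_w"]).groupby([d["unit_id"], d["year"]]).sum()
        den = d.groupby(["unit_id", "year"])["_w"].sum()
        parts[col] = num / den
    out = pd.DataFrame(parts).reset_index().rename(
        columns={"unit_id": "region_id"})
    if renormalize and out.groupby("year")["region_id"].count().min() >= 2:
        out = normalize_yearly(out, value_cols)
    return out
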