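"""Synthetic region hierarchies, indicator panels and health outcomes.

The generator emulates the statistical anatomy of the German regional
indicator data at a reduced scale (default: 500 municipalities in 200
GVB, 50 districts, 12 spatial planning regions, 5 NUTS-2 regions across
10 states, three of them "East"), including the data pathologies the
harmonization must handle: indicator-specific availability windows, a
reporting-procedure level break on the two employee-qualification
indicators, reform dips in configured state-years, an East-West offset
that makes one indicator bimodal, and district-only resolution of the
employment-rate indicators before 2001.

Indicator construction.  Three latent deprivation factors (education,
employment, income) evolve per district as AR(1) processes; they share a
common component calibrated so the pairwise factor correlations hit the
configured targets.  Within each dimension the three indicators are a
linear mix ``z = l * f + B^{1/2} eps`` whose mixing matrix is solved so
the *population correlation matrix has the target loading vector as its
exact first principal component* — the generated loadings are therefore
recoverable by pooled PCA up to sampling error alone.  GVB-native
indicators optionally add within-district factor variation; this blurs
the district-level factor geometry, so loading-recovery experiments use
``gvb_within_sd=0``.

Everything is driven by one named ``numpy.random.Generator``; equal
seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import (DIMENSIONS, IndicatorPanel, RegionHierarchy,
                      default_indicator_specs)

__all__ = [
    "SynthConfig",
    "generate_hierarchy",
    "generate_panel",
    "generate_health_outcomes",
    "exact_loading_mixing",
    "AGE_GROUPS",
]

#: 5-year age groups used for the synthetic health outcomes (open-ended 90+).
AGE_GROUPS: tuple[str, ...] = (
    "0-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34", "35-39",
    "40-44", "45-49", "50-54", "55-59", "60-64", "65-69", "70-74",
    "75-79", "80-84", "85-89", "90+",
)

#: rough population share per age group (sums to 1)
_AGE_SHARES = np.array([4.7, 4.6, 4.6, 4.9, 5.5, 6.1, 6.4, 6.3, 6.0, 6.5,
                        8.0, 8.2, 7.0, 5.7, 4.8, 4.3, 3.5, 2.0, 0.9])
_AGE_SHARES = _AGE_SHARES / _AGE_SHARES.sum()

_AGE_MID = np.array([2.5, 7.5, 12.5, 17.5, 22.5, 27.5, 32.5, 37.5, 42.5,
                     47.5, 52.5, 57.5, 62.5, 67.5, 72.5, 77.5, 82.5, 87.5,
                     92.5])

#: Table-3-like signed target loadings (negative = deprivation-decreasing)
DEFAULT_LOADINGS: dict[str, dict[str, float]] = {
    "education": {
        "employees_university_degree": -0.732,
        "employees_without_qualification": 0.771,
        "school_leavers_without_qualification": 0.663,
    },
    "employment": {
        "employment_rate": -0.640,
        "unemployment_rate": 0.841,
        "gross_wage": -0.810,
    },
    "income": {
        "income_tax": -0.914,
        "household_income": -0.921,
        "debtor_quota": 0.608,
    },
}

#: indicator measurement scales: value = loc + scale * z, or exp(loc+scale*z)
#: for the logged currency indicators (then multiplied by the price index)
_SCALES: dict[str, tuple[float, float, bool]] = {
    "employees_university_degree": (12.0, 3.0, False),
    "employees_without_qualification": (12.0, 2.0, False),
    "school_leavers_without_qualification": (6.0, 1.5, False),
    "employment_rate": (55.0, 5.0, False),
    "unemployment_rate": (8.0, 2.5, False),
    "gross_wage": (7.9, 0.15, True),
    "household_income": (9.9, 0.12, True),
    "income_tax": (6.3, 0.35, True),
    "debtor_quota": (9.0, 2.0, False),
}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic replica.

    Counts default to a scaled-down hierarchy so the full pipeline runs
    in seconds; correlation targets and loading patterns default to the
    published index geometry.  Artefact switches inject the pathologies
    the harmonization corrects; turning all of them off with
    ``noise_scale=0`` makes every indicator an exact affine image of its
    latent factor.
    """

    seed: int = 0
    n_municipalities: int = 500
    n_gvb: int = 200
    n_districts: int = 50
    n_ror: int = 12
    n_nuts2: int = 5
    n_states: int = 10
    n_east_states: int = 3
    years: tuple[int, int] = (1998, 2019)
    ar_rho: float = 0.9
    #: target pairwise correlations of the dimension factors
    factor_corr: dict[tuple[str, str], float] = field(default_factory=lambda: {
        ("employment", "income"): 0.66,
        ("employment", "education"): 0.52,
        ("income", "education"): 0.69,
    })
    target_loadings: dict[str, dict[str, float]] = field(
        default_factory=lambda: {d: dict(v)
                                 for d, v in DEFAULT_LOADINGS.items()})
    noise_scale: float = 1.0
    gvb_within_sd: float = 0.3
    #: artefacts
    apply_availability: bool = True
    break_year: int = 2013
    break_shift: float = 3.0  # post-changeover level is higher by this
    g8_cells: tuple[tuple[str, int], ...] = (("03", 2011), ("05", 2012),
                                             ("07", 2013))
    g8_effect: float = -2.0  # dip in affected cells (percentage points)
    east_offset: float = -5.0  # East values lower by 5 points
    price_growth: float = 0.02  # yearly deflator growth, base 1998
    pop_log_mean: float = 7.7
    pop_log_sd: float = 1.0
    #: health-outcome model
    beta_gisd: float = float(np.log(1.46) / 0.5)
    district_sd: float = 0.05
    base_rate_scale: float = 3e-6
    base_rate_slope: float = 0.105
    male_excess: float = 1.5
    rate_decline: float = 0.03  # yearly proportional decline
    #: extra yearly decline per unit of the 0-1 index (programs a
    #: stronger improvement in more deprived districts when positive)
    rate_decline_gradient: float = 0.0

    def price_index(self) -> dict[int, float]:
        y0 = self.years[0]
        return {y: (1 + self.price_growth) ** (y - y0)
                for y in range(self.years[0], self.years[1] + 1)}


def _split_counts(n_children: int, n_parents: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Randomly distribute n_children among n_parents, each getting >= 1."""
    if n_children < n_parents:
        raise ValueError("fewer children than parents")
    extra = rng.multinomial(n_children - n_parents,
                            np.full(n_parents, 1.0 / n_parents))
    return extra + 1


def generate_hierarchy(config: SynthConfig) -> RegionHierarchy:
    """Nested synthetic hierarchy with log-normal municipality populations."""
    c = config
    if not (c.n_municipalities >= c.n_gvb >= c.n_districts >= c.n_ror
            >= c.n_nuts2):
        raise ValueError("level counts must be nested-compatible")
    if c.n_states > c.n_districts or c.n_nuts2 < 1:
        raise ValueError("level counts must be nested-compatible")
    rng = np.random.default_rng(c.seed)

    state_ids = [f"{i + 1:02d}" for i in range(c.n_states)]
    ror_per_nuts = _split_counts(c.n_ror, c.n_nuts2, rng)
    dist_per_ror = _split_counts(c.n_districts, c.n_ror, rng)
    gvb_per_dist = _split_counts(c.n_gvb, c.n_districts, rng)
    mun_per_gvb = _split_counts(c.n_municipalities, c.n_gvb, rng)

    # chain nesting: district in ROR in NUTS-2; states partition districts
    # into contiguous blocks (planning regions may straddle state borders,
    # which is harmless for the index pipeline)
    ror_nuts = np.repeat(np.arange(c.n_nuts2), ror_per_nuts)
    dist_ror = np.repeat(np.arange(c.n_ror), dist_per_ror)
    dist_state = np.repeat(np.arange(c.n_states),
                           _split_counts(c.n_districts, c.n_states, rng))

    rows = []
    gvb_idx = 0
    mun_idx = 0
    years = list(range(c.years[0], c.years[1] + 1))
    drift = rng.normal(0.002, 0.004, size=len(years)).cumsum()
    for d in range(c.n_districts):
        st = state_ids[dist_state[d]]
        district_id = f"{st}{d % 1000:03d}"
        for _ in range(gvb_per_dist[d]):
            gvb_id = f"G{gvb_idx:04d}"
            for _ in range(mun_per_gvb[gvb_idx]):
                mun_id = f"{district_id}{mun_idx % 1000:03d}"
                base_pop = float(np.round(np.exp(
                    rng.normal(c.pop_log_mean, c.pop_log_sd))))
                base_pop = max(base_pop, 10.0)
                for yi, y in enumerate(years):
                    rows.append((mun_id, gvb_id, district_id,
                                 f"R{dist_ror[d]:03d}",
                                 f"N{ror_nuts[dist_ror[d]]:02d}", st, y,
                                 np.round(base_pop * (1 + drift[yi]))))
                mun_idx += 1
            gvb_idx += 1
    table = pd.DataFrame(rows, columns=[
        "municipality_id", "gvb_id", "district_id", "ror_id", "nuts2_id",
        "state_id", "year", "population"])
    east = frozenset(state_ids[:c.n_east_states])
    return RegionHierarchy(table, east_states=east)


def exact_loading_mixing(loadings: Sequence[float]) -> np.ndarray:
    """2-column mixing matrix S with ``R = l l' + S S'`` a correlation
    matrix whose first principal component has loadings exactly ``l``.

    The residual part lives in the orthogonal complement of ``l`` (so
    ``l`` stays an eigenvector) and its diagonal is solved to bring the
    total diagonal to one.  Raises if no positive semidefinite residual
    exists for the requested pattern.
    """
    l = np.asarray(loadings, float)
    if np.allclose(l, 0):
        raise ValueError("loading vector of zeros")
    v = l / np.linalg.norm(l)
    U = np.linalg.svd(np.eye(3) - np.outer(v, v))[0][:, :2]
    A = np.array([[U[i, 0] ** 2, 2 * U[i, 0] * U[i, 1], U[i, 1] ** 2]
                  for i in range(3)])
    m = np.linalg.solve(A, 1 - l ** 2)
    M = np.array([[m[0], m[1]], [m[1], m[2]]])
    w, Q = np.linalg.eigh(M)
    if (w < -1e-10).any():
        raise ValueError(f"no psd residual for loading pattern {l}")
    return U @ Q @ np.diag(np.sqrt(np.clip(w, 0, None)))


def _ar1(rng: np.random.Generator, n: int, T: int, rho: float) -> np.ndarray:
    """n independent AR(1) paths of length T with unit marginal variance."""
    x = np.empty((n, T))
    x[:, 0] = rng.standard_normal(n)
    innov_sd = np.sqrt(1 - rho ** 2)
    for t in range(1, T):
        x[:, t] = rho * x[:, t - 1] + innov_sd * rng.standard_normal(n)
    return x


def _commonalities(factor_corr: Mapping[tuple[str, str], float]
                   ) -> dict[str, float]:
    """Per-dimension commonality c with corr(f_i, f_j) = sqrt(c_i c_j)."""
    def get(a, b):
        return factor_corr.get((a, b), factor_corr.get((b, a)))
    r_ei = get("education", "income")
    r_ee = get("education", "employment")
    r_ie = get("income", "employment")
    c_inc = r_ei * r_ie / r_ee
    return {"education": r_ei * r_ee / r_ie,
            "employment": r_ee * r_ie / r_ei,
            "income": c_inc}


def generate_panel(config: SynthConfig, hierarchy: RegionHierarchy
                   ) -> tuple[IndicatorPanel, dict]:
    """Indicator panel with injected artefacts, plus ground-truth latents.

    Returns ``(panel, truth)`` where ``truth`` holds the district and GVB
    factor paths, the signed generating loadings and the artefact
    parameters actually injected.
    """
    c = config
    rng = np.random.default_rng(np.random.SeedSequence([c.seed, 1]))
    specs = default_indicator_specs()
    years = np.arange(c.years[0], c.years[1] + 1)
    T = len(years)
    districts = hierarchy.level_ids("district")
    gvbs = hierarchy.level_ids("gvb")
    nd, ng = len(districts), len(gvbs)

    comm = _commonalities(c.factor_corr)
    g = _ar1(rng, nd, T, c.ar_rho)
    factors = {}
    for dim in DIMENSIONS:
        u = _ar1(rng, nd, T, c.ar_rho)
        factors[dim] = (np.sqrt(comm[dim]) * g
                        + np.sqrt(1 - comm[dim]) * u)

    gvb_district = hierarchy.parent_map("gvb", "district")
    dist_pos = {d: i for i, d in enumerate(districts)}
    gvb_parent_pos = np.array([dist_pos[gvb_district[gv]] for gv in gvbs])

    gvb_factors = {}
    for dim in DIMENSIONS:
        base = factors[dim][gvb_parent_pos]
        if c.gvb_within_sd > 0:
            base = base + c.gvb_within_sd * _ar1(rng, ng, T, c.ar_rho)
        gvb_factors[dim] = base

    price = c.price_index()
    east_states = hierarchy.east_states
    frames = []
    truth_loadings = {}
    for dim in DIMENSIONS:
        names = list(c.target_loadings[dim])
        lam = np.array([c.target_loadings[dim][n] for n in names])
        S = exact_loading_mixing(lam) * c.noise_scale
        truth_loadings.update(dict(zip(names, lam)))
        # the two residual components are shared by the dimension's three
        # indicators: their cross-correlations are what places the target
        # loading vector exactly on the first principal component
        eps_d = rng.standard_normal((nd, T, 2))
        for j, name in enumerate(names):
            spec = specs[name]
            native_gvb = spec.native_level == "gvb"
            ids = gvbs if native_gvb else districts
            f = gvb_factors[dim] if native_gvb else factors[dim]
            eps = eps_d[gvb_parent_pos] if native_gvb else eps_d
            z = lam[j] * f + eps @ S[j]
            loc, scale, logged = _SCALES[name]
            if logged:
                vals = np.exp(loc + scale * z)
                vals = vals * np.array([price[int(y)] for y in years])
            else:
                vals = loc + scale * z
            df = pd.DataFrame(vals, index=ids, columns=years)
            df = df.stack().rename("value").reset_index()
            df.columns = ["region_id", "year", "value"]
            df["indicator"] = name
            frames.append(df)
    panel_df = pd.concat(frames, ignore_index=True)
    panel_df["year"] = panel_df["year"].astype(int)

    # ---- artefacts -------------------------------------------------------
    applied = {}
    state_of_region = pd.concat([
        hierarchy.state_of("district"), hierarchy.state_of("gvb")])

    if c.break_shift != 0:
        for name in ("employees_university_degree",
                     "employees_without_qualification"):
            m = ((panel_df["indicator"] == name)
                 & (panel_df["year"] < c.break_year))
            panel_df.loc[m, "value"] -= c.break_shift
        applied["break_shift"] = c.break_shift

    if c.g8_cells and c.g8_effect != 0:
        st = panel_df["region_id"].map(state_of_region)
        cells = {(s, int(y)) for s, y in c.g8_cells}
        in_cell = np.array([(s, y) in cells
                            for s, y in zip(st, panel_df["year"])])
        m = ((panel_df["indicator"]
              == "school_leavers_without_qualification") & in_cell)
        panel_df.loc[m, "value"] += c.g8_effect
        applied["g8_effect"] = c.g8_effect

    if c.east_offset != 0:
        st = panel_df["region_id"].map(state_of_region)
        m = ((panel_df["indicator"] == "employees_without_qualification")
             & st.isin(east_states))
        panel_df.loc[m, "value"] += c.east_offset
        applied["east_offset"] = c.east_offset

    # ---- availability calendar ------------------------------------------
    if c.apply_availability:
        keep = np.ones(len(panel_df), dtype=bool)
        for name, spec in specs.items():
            avail = set(spec.available_years)
            m = panel_df["indicator"] == name
            keep &= ~(m & ~panel_df["year"].isin(avail))
        panel_df = panel_df[keep].reset_index(drop=True)
        # employment indicators: district resolution only before 2001
        for name in ("unemployment_rate", "employment_rate"):
            early = ((panel_df["indicator"] == name)
                     & (panel_df["year"] <= 2000))
            sub = panel_df[early].copy()
            sub["district_id"] = sub["region_id"].map(gvb_district)
            agg = (sub.groupby(["district_id", "year"], as_index=False)
                   ["value"].mean()
                   .rename(columns={"district_id": "region_id"}))
            agg["indicator"] = name
            panel_df = pd.concat([panel_df[~early], agg[panel_df.columns]],
                                 ignore_index=True)
        panel_df["value"] = panel_df["value"].astype(float)

    panel = IndicatorPanel(panel_df, specs)
    panel.validate_regions(hierarchy)
    truth = {
        "district_factors": {dim: pd.DataFrame(
            factors[dim], index=districts, columns=years)
            for dim in DIMENSIONS},
        "gvb_factors": {dim: pd.DataFrame(
            gvb_factors[dim], index=gvbs, columns=years)
            for dim in DIMENSIONS},
        "loadings": truth_loadings,
        "commonalities": comm,
        "artefacts": applied,
        "price_index": price,
    }
    return panel, truth


def generate_health_outcomes(config: SynthConfig,
                             district_scores: pd.DataFrame,
                             hierarchy: RegionHierarchy,
                             years: Sequence[int] | None = None
                             ) -> pd.DataFrame:
    """Poisson event counts by district, year, sex and 5-year age group.

    ``district_scores`` must carry region_id, year and a ``gisd`` column
    in [0, 1].  Counts follow
    ``events ~ Poisson(pop_age * base_rate(age, sex) * trend(year)
    * exp(beta * (gisd - 1/2) + u_district))`` with a log-normal district
    frailty.  The deprivation effect ``beta`` defaults to the log of a
    1.46 top-versus-bottom-quintile rate ratio spread over the typical
    0.5 quintile-mean gap of the 0-1 index.
    """
    c = config
    rng = np.random.default_rng(np.random.SeedSequence([c.seed, 2]))
    base = c.base_rate_scale * np.exp(c.base_rate_slope * _AGE_MID)
    if (base < 0).any():
        raise ValueError("negative baseline rates")
    pop = hierarchy.population("district")
    scores = district_scores[["region_id", "year", "gisd"]]
    d = pop.merge(scores, on=["region_id", "year"], how="inner")
    if years is not None:
        d = d[d["year"].isin(set(int(y) for y in years))]
    districts = np.sort(d["region_id"].unique())
    frailty = pd.Series(rng.normal(0.0, c.district_sd, len(districts)),
                        index=districts)
    y0 = int(d["year"].min())
    rows = []
    for _, r in d.iterrows():
        age_pop = np.round(r["population"] * _AGE_SHARES)
        decline = c.rate_decline + c.rate_decline_gradient * r["gisd"]
        trend = (1 - decline) ** (int(r["year"]) - y0)
        lin = np.exp(c.beta_gisd * (r["gisd"] - 0.5)
                     + frailty[r["region_id"]])
        for sex, mult in (("f", 1.0), ("m", c.male_excess)):
            lam = age_pop * base * mult * trend * lin
            events = rng.poisson(lam)
            for a, p, e in zip(AGE_GROUPS, age_pop, events):
                rows.append((r["region_id"], int(r["year"]), sex, a,
                             int(e), float(p)))
    return pd.DataFrame(rows, columns=["district_id", "year", "sex",
                                       "age_group", "events", "population"])
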