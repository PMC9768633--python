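"""Panel harmonization: artefact corrections, gap fill and imputation.

The raw indicator panels carry several statistical artefacts that must be
removed before any variance-based weighting: a reporting-procedure
changeover that shifts the level of two education indicators, double
graduation cohorts from the G8 school reform that deflate the share of
school leavers without a certificate in specific state-years, and a
historically grown East-West gap in the share of employees without
professional qualification that produces a bimodal distribution unrelated
to present-day deprivation.  Currency-valued indicators are deflated and
logged so that multiplicative growth becomes additive.  Remaining gaps are
filled by carrying a neighbouring year forward (single-year reporting
gaps) and by linear random-intercept prediction (missing early years).

All correctors follow the scikit-learn estimator protocol: ``fit``
estimates the correction from the panel, ``transform`` applies it and
records the step in the panel's correction ledger; applying the same
correction twice is refused.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .regions import (IndicatorPanel, PanelError, RegionHierarchy,
                      broadcast_district_to_gvb)

__all__ = [
    "HarmonizeError",
    "deflate_and_log",
    "BreakCorrector",
    "G8Corrector",
    "EastWestCorrector",
    "carry_forward_gap",
    "RandomInterceptImputer",
    "bimodality_coefficient",
    "harmonize_panel",
]


class HarmonizeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# price deflation + log

def deflate_and_log(panel: IndicatorPanel, indicator: str,
                    price_index: Mapping[int, float] | None = None
                    ) -> IndicatorPanel:
    """Replace values by ``ln(value / price_index[year])``.

    Applied to currency-based, open-ended indicators (tax revenue, gross
    wage, household income) so that proportional differences between
    regions are comparable across the income range.  ``price_index`` maps
    year to the deflator relative to a base year; when omitted, an
    identity deflator is used and a warning is emitted.
    """
    if price_index is None:
        warnings.warn(
            f"no price index supplied for {indicator!r}; using identity "
            "deflator", stacklevel=2)
        price_index = {}
    out = panel.copy()
    mask = out.df["indicator"] == indicator
    vals = out.df.loc[mask, "value"]
    years = out.df.loc[mask, "year"]
    defl = years.map(lambda y: float(price_index.get(int(y), 1.0)))
    ratio = vals / defl
    if (ratio <= 0).any():
        bad = out.df.loc[mask][ratio <= 0][["region_id", "year", "value"]]
        raise HarmonizeError(
            f"non-positive values for {indicator!r}; cannot take logs:\n"
            f"{bad.head(10).to_string(index=False)}")
    out.df.loc[mask, "value"] = np.log(ratio)
    out.record(indicator, "deflate_and_log",
               f"base_years={len(price_index)}", int(mask.sum()))
    return out


# ---------------------------------------------------------------------------
# reporting-procedure break

class BreakCorrector(BaseEstimator):
    """Level-shift correction at a known reporting changeover year.

    The shift is estimated by OLS of the indicator on region fixed
    effects, a linear year trend and a post-break step dummy (the step
    coefficient is the estimated level change ``shift_``).  ``transform``
    raises all pre-break values by ``shift_`` so the early series sits on
    the post-changeover level.  Separating the step from the secular
    trend makes the estimator exact on noiseless step fixtures.
    """

    def __init__(self, indicator: str, break_year: int) -> None:
        self.indicator = indicator
        self.break_year = break_year

    def fit(self, panel: IndicatorPanel) -> "BreakCorrector":
        d = panel.indicator_values(self.indicator).dropna(subset=["value"])
        pre = d[d["year"] < self.break_year]
        post = d[d["year"] >= self.break_year]
        if pre.empty or post.empty:
            raise HarmonizeError(
                f"break correction for {self.indicator!r} needs data on "
                f"both sides of {self.break_year}")
        if d["region_id"].nunique() < 2:
            raise HarmonizeError("break correction needs >= 2 regions")
        # within-region demeaning absorbs the region fixed effects
        y = d["value"].to_numpy(float)
        X = np.column_stack([d["year"].to_numpy(float),
                             (d["year"] >= self.break_year).to_numpy(float)])
        g = d.groupby("region_id")
        y_w = y - g["value"].transform("mean").to_numpy()
        X_w = X - np.column_stack([
            g["year"].transform("mean").to_numpy(),
            d.assign(_s=X[:, 1]).groupby("region_id")["_s"]
             .transform("mean").to_numpy()])
        beta, res, *_ = np.linalg.lstsq(X_w, y_w, rcond=None)
        self.shift_ = float(beta[1])
        self.trend_ = float(beta[0])
        self.n_regions_ = int(d["region_id"].nunique())
        resid = y_w - X_w @ beta
        self.resid_sd_ = float(np.std(resid))
        if not np.isfinite(self.shift_):
            raise HarmonizeError("break shift estimate is not finite")
        return self

    def transform(self, panel: IndicatorPanel) -> IndicatorPanel:
        out = panel.copy()
        mask = ((out.df["indicator"] == self.indicator)
                & (out.df["year"] < self.break_year))
        out.df.loc[mask, "value"] += self.shift_
        out.record(self.indicator, "break",
                   f"break_year={self.break_year}, shift={self.shift_:.6g}",
                   int(mask.sum()))
        return out

    def fit_transform(self, panel: IndicatorPanel) -> IndicatorPanel:
        return self.fit(panel).transform(panel)


# ---------------------------------------------------------------------------
# school-reform double cohorts

class G8Corrector(BaseEstimator):
    """Correction for double graduation cohorts in specific state-years.

    In the years when the shortened Gymnasium track produced its first
    graduates, the denominator of 'school leavers without qualification'
    is inflated and the observed share dips.  The dip is estimated by OLS
    on region fixed effects, year fixed effects and a reform-cell dummy;
    the fitted effect is subtracted in the affected cells only (the
    estimated effect is negative, so subtraction raises them).

    ``reform_cells`` is an explicit list of (state_id, year) pairs; the
    reform calendar is configuration, not something the estimator guesses.
    """

    def __init__(self, indicator: str,
                 reform_cells: Sequence[tuple[str, int]] = ()) -> None:
        self.indicator = indicator
        self.reform_cells = reform_cells

    def _cell_mask(self, d: pd.DataFrame, states: pd.Series) -> np.ndarray:
        cells = {(str(s), int(y)) for s, y in self.reform_cells}
        st = d["region_id"].map(states)
        return np.array([(s, y) in cells
                         for s, y in zip(st, d["year"])], dtype=float)

    def fit(self, panel: IndicatorPanel,
            hierarchy: RegionHierarchy) -> "G8Corrector":
        d = panel.indicator_values(self.indicator).dropna(subset=["value"])
        spec = panel.specs[self.indicator]
        states = hierarchy.state_of(spec.native_level)
        if not self.reform_cells:
            self.effect_ = 0.0
            self.n_cells_ = 0
            return self
        dummy = self._cell_mask(d, states)
        present = {(str(s), int(y)) for s, y in self.reform_cells}
        observed = set(zip(d["region_id"].map(states), d["year"]))
        missing = present - {(s, int(y)) for s, y in observed}
        if missing:
            warnings.warn(f"reform cells with no data skipped: "
                          f"{sorted(missing)}", stacklevel=2)
        if dummy.sum() == 0:
            self.effect_ = 0.0
            self.n_cells_ = 0
            return self
        # two-way fixed effects via explicit year dummies + region demeaning
        years = sorted(d["year"].unique())
        Y = np.column_stack([(d["year"] == y).to_numpy(float)
                             for y in years[1:]])
        X = np.column_stack([Y, dummy])
        g = d.groupby("region_id")
        y_w = (d["value"] - g["value"].transform("mean")).to_numpy()
        Xd = pd.DataFrame(X, index=d.index)
        X_w = (Xd - Xd.groupby(d["region_id"]).transform("mean")).to_numpy()
        beta, *_ = np.linalg.lstsq(X_w, y_w, rcond=None)
        self.effect_ = float(beta[-1])
        self.n_cells_ = int(dummy.sum())
        return self

    def transform(self, panel: IndicatorPanel,
                  hierarchy: RegionHierarchy) -> IndicatorPanel:
        out = panel.copy()
        if not self.reform_cells or self.effect_ == 0.0:
            out.record(self.indicator, "g8", "no reform cells", 0)
            return out
        spec = out.specs[self.indicator]
        states = hierarchy.state_of(spec.native_level)
        d = out.df
        sub = d["indicator"] == self.indicator
        dummy = self._cell_mask(d[sub], states).astype(bool)
        idx = d.index[sub][dummy]
        out.df.loc[idx, "value"] -= self.effect_
        out.record(self.indicator, "g8",
                   f"effect={self.effect_:.6g}, cells={len(self.reform_cells)}",
                   len(idx))
        return out

    def fit_transform(self, panel, hierarchy) -> IndicatorPanel:
        return self.fit(panel, hierarchy).transform(panel, hierarchy)


# ---------------------------------------------------------------------------
# East-West level correction

def bimodality_coefficient(x: np.ndarray) -> float:
    """Sarle's bimodality coefficient; > ~0.555 suggests bimodality.

    BC = (skew^2 + 1) / (kurt + 3 (n-1)^2 / ((n-2)(n-3))) with excess
    kurtosis ``kurt``.  A uniform distribution scores exactly 0.555; a
    clear two-component mixture scores well above it.
    """
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    n = len(x)
    if n < 4:
        return float("nan")
    s = stats.skew(x)
    k = stats.kurtosis(x)  # excess
    return float((s ** 2 + 1) / (k + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))))


BIMODALITY_FLAG = 0.555


class EastWestCorrector(BaseEstimator):
    """Equalize the historically grown East-West level gap of an indicator.

    The mean difference West minus East is estimated on the pooled panel
    (all region-year values) and added to every East value, removing the
    bimodality the gap induces while preserving within-part variation.
    """

    def __init__(self, indicator: str, min_regions: int = 5) -> None:
        self.indicator = indicator
        self.min_regions = min_regions

    def fit(self, panel: IndicatorPanel,
            east_flag: pd.Series) -> "EastWestCorrector":
        d = panel.indicator_values(self.indicator).dropna(subset=["value"])
        east = d["region_id"].map(east_flag).astype("boolean")
        if east.isna().any():
            raise HarmonizeError("east_flag does not cover all regions")
        east = east.astype(bool)
        n_e = d.loc[east, "region_id"].nunique()
        n_w = d.loc[~east, "region_id"].nunique()
        if n_e < self.min_regions or n_w < self.min_regions:
            raise HarmonizeError(
                f"need >= {self.min_regions} regions per side, have "
                f"East={n_e}, West={n_w}")
        self.delta_ = float(d.loc[~east, "value"].mean()
                            - d.loc[east, "value"].mean())
        self.bimodality_before_ = bimodality_coefficient(d["value"].to_numpy())
        corrected = d["value"] + self.delta_ * east.to_numpy()
        self.bimodality_after_ = bimodality_coefficient(corrected.to_numpy())
        return self

    def transform(self, panel: IndicatorPanel,
                  east_flag: pd.Series) -> IndicatorPanel:
        out = panel.copy()
        d = out.df
        in_east = d["region_id"].map(east_flag).astype("boolean")
        mask = ((d["indicator"] == self.indicator)
                & in_east.fillna(False).astype(bool))
        out.df.loc[mask, "value"] += self.delta_
        out.record(self.indicator, "east_west",
                   f"delta={self.delta_:.6g}", int(mask.sum()))
        return out

    def fit_transform(self, panel, east_flag) -> IndicatorPanel:
        return self.fit(panel, east_flag).transform(panel, east_flag)


# ---------------------------------------------------------------------------
# single-year reporting gap

def carry_forward_gap(panel: IndicatorPanel, indicator: str,
                      from_year: int, to_year: int) -> IndicatorPanel:
    """Copy *from_year* values into missing *to_year* cells.

    Used for isolated reporting gaps (one missing survey year).  Cells
    where *to_year* is already observed are untouched; regions without a
    *from_year* observation are left to the model-based imputation.
    Copied cells are flagged as imputed.
    """
    out = panel.copy()
    d = out.df
    sub = d[d["indicator"] == indicator]
    src = sub[sub["year"] == from_year].dropna(subset=["value"])
    have_to = set(sub.loc[(sub["year"] == to_year)
                          & sub["value"].notna(), "region_id"])
    new = src[~src["region_id"].isin(have_to)].copy()
    new["year"] = to_year
    new["imputed"] = True
    # drop any all-NaN placeholder rows for the target year
    drop = ((d["indicator"] == indicator) & (d["year"] == to_year)
            & d["value"].isna()
            & d["region_id"].isin(new["region_id"]))
    out.df = pd.concat([d[~drop], new], ignore_index=True).sort_values(
        ["indicator", "region_id", "year"], ignore_index=True)
    out.record(indicator, "carry_forward",
               f"{from_year}->{to_year}", len(new))
    return out


# ---------------------------------------------------------------------------
# linear random-intercept imputation

class RandomInterceptImputer(BaseEstimator):
    """Fill missing years from a linear random-intercept model.

    Model: ``value[r, t] = mu + beta * t + a[r] + e[r, t]`` with region
    intercepts ``a[r] ~ N(0, sigma_a^2)``.  The global slope is the
    within-region (fixed-effects) estimator; variance components come
    from method-of-moments, and region intercepts are empirical-Bayes
    shrunk region means.  This closed-form fit is deterministic, exact in
    the noiseless limit, and needs no iterative optimiser.  Missing cells
    are predicted from the fitted line; observed cells are never touched.
    """

    def __init__(self, indicator: str, years: Iterable[int] | None = None,
                 min_obs_years: int = 3) -> None:
        self.indicator = indicator
        self.years = years
        self.min_obs_years = min_obs_years

    def fit(self, panel: IndicatorPanel) -> "RandomInterceptImputer":
        d = panel.indicator_values(self.indicator).dropna(subset=["value"])
        if d.empty:
            raise HarmonizeError(f"no observed data for {self.indicator!r}")
        n_obs = d.groupby("region_id")["year"].count()
        short = n_obs[n_obs < self.min_obs_years]
        if len(short):
            raise HarmonizeError(
                f"{len(short)} regions have fewer than "
                f"{self.min_obs_years} observed years for {self.indicator!r}")
        y = d["value"].to_numpy(float)
        t = d["year"].to_numpy(float)
        g = d.groupby("region_id")
        y_w = y - g["value"].transform("mean").to_numpy()
        t_w = t - g["year"].transform("mean").to_numpy()
        denom = float(t_w @ t_w)
        self.slope_ = float(t_w @ y_w / denom) if denom > 0 else 0.0
        resid_w = y_w - self.slope_ * t_w
        n, R = len(d), d["region_id"].nunique()
        dof = max(n - R - 1, 1)
        self.sigma_e2_ = max(float(resid_w @ resid_w) / dof, 0.0)
        detr = y - self.slope_ * t
        self.intercept_ = float(detr.mean())
        region_mean = detr - self.intercept_
        means = pd.Series(region_mean, index=d.index).groupby(
            d["region_id"]).mean()
        counts = g["value"].count()
        # method of moments: var of region means = sigma_a^2 + sigma_e^2/n_r
        var_means = float(np.var(means.to_numpy(), ddof=1)) if R > 1 else 0.0
        self.sigma_a2_ = max(
            var_means - self.sigma_e2_ * float((1.0 / counts).mean()), 0.0)
        if self.sigma_a2_ + self.sigma_e2_ == 0:
            shrink = pd.Series(1.0, index=means.index)
        else:
            shrink = self.sigma_a2_ / (self.sigma_a2_
                                       + self.sigma_e2_ / counts)
        self.region_effects_ = means * shrink
        return self

    def predict(self, region_ids: pd.Series, years: pd.Series) -> np.ndarray:
        a = region_ids.map(self.region_effects_).fillna(0.0).to_numpy(float)
        return self.intercept_ + self.slope_ * years.to_numpy(float) + a

    def transform(self, panel: IndicatorPanel) -> IndicatorPanel:
        out = panel.copy()
        d = out.df
        sub = d[d["indicator"] == self.indicator]
        target_years = (sorted(set(int(y) for y in self.years))
                        if self.years is not None
                        else sorted(sub["year"].unique()))
        regions = sub["region_id"].unique()
        full = pd.MultiIndex.from_product([regions, target_years],
                                          names=["region_id", "year"])
        have = sub.dropna(subset=["value"]).set_index(
            ["region_id", "year"]).index
        missing = full.difference(have)
        if len(missing) == 0:
            out.record(self.indicator, "impute_random_intercept",
                       "nothing to fill", 0)
            return out
        new = missing.to_frame(index=False)
        new["indicator"] = self.indicator
        new["value"] = self.predict(new["region_id"], new["year"])
        new["imputed"] = True
        drop = ((d["indicator"] == self.indicator) & d["value"].isna())
        out.df = pd.concat([d[~drop], new[d.columns]],
                           ignore_index=True).sort_values(
            ["indicator", "region_id", "year"], ignore_index=True)
        out.record(self.indicator, "impute_random_intercept",
                   f"slope={self.slope_:.6g}, sigma_a2={self.sigma_a2_:.4g}",
                   len(new))
        return out

    def fit_transform(self, panel: IndicatorPanel) -> IndicatorPanel:
        return self.fit(panel).transform(panel)


def _check_expected_correlations(panel: IndicatorPanel,
                                 indicator: str) -> None:
    """After a level correction, the indicator should correlate with its
    dimension siblings in the direction their polarities imply (the
    empirical confirmation that the correction removed the artefact
    rather than real signal).  Emits a warning on a sign violation."""
    spec = panel.specs[indicator]
    wide = panel.wide([n for n, s in panel.specs.items()
                       if s.dimension == spec.dimension])
    for other in wide.columns:
        if other == indicator:
            continue
        pair = wide[[indicator, other]].dropna()
        if len(pair) < 10:
            continue
        r = float(pair.corr().iloc[0, 1])
        expected = panel.specs[indicator].sign * panel.specs[other].sign
        if r * expected < 0:
            warnings.warn(
                f"unexpected correlation sign between {indicator!r} and "
                f"{other!r} after correction (r={r:.2f})", stacklevel=3)


# ---------------------------------------------------------------------------
# full harmonization pipeline

def harmonize_panel(panel: IndicatorPanel, hierarchy: RegionHierarchy,
                    price_index: Mapping[int, float] | None = None,
                    g8_cells: Sequence[tuple[str, int]] = (),
                    break_year: int = 2013,
                    gap: tuple[int, int] | None = (2011, 2012),
                    broadcast_years: Iterable[int] = (1998, 1999, 2000),
                    target_years: Iterable[int] | None = None,
                    ) -> IndicatorPanel:
    """Run the full harmonization in a fixed order.

    Order: district->GVB broadcast, deflate/log, break correction, G8
    correction, East-West correction, carry-forward, random-intercept
    imputation.  Artefact removal runs before imputation so the imputation
    model never learns the artefacts.  Returns a panel with zero missing
    cells for every indicator over *target_years* at its native level.
    """
    out = panel
    east_by_level = {lv: hierarchy.east_flag(lv) for lv in ("district", "gvb")}

    for name, spec in out.specs.items():
        if spec.native_level == "gvb":
            d = out.df
            has_district = ((d["indicator"] == name) & d["region_id"].isin(
                hierarchy.level_ids("district"))).any()
            if has_district:
                out = broadcast_district_to_gvb(out, hierarchy, name,
                                                broadcast_years)
    for name, spec in out.specs.items():
        if spec.transform == "log-after-deflation":
            out = deflate_and_log(out, name, price_index)
        elif spec.transform == "log":
            out = deflate_and_log(out, name, {})
    for name, spec in out.specs.items():
        if "break" in spec.corrections:
            out = BreakCorrector(name, break_year).fit_transform(out)
    for name, spec in out.specs.items():
        if "g8" in spec.corrections:
            out = G8Corrector(name, g8_cells).fit_transform(out, hierarchy)
    for name, spec in out.specs.items():
        if "east_west" in spec.corrections:
            flag = east_by_level[spec.native_level]
            out = EastWestCorrector(name).fit_transform(out, flag)
            _check_expected_correlations(out, name)
    if gap is not None:
        for name, spec in out.specs.items():
            if "break" in spec.corrections:  # the reporting-gap indicators
                out = carry_forward_gap(out, name, *gap)
    years = (sorted(set(int(y) for y in target_years))
             if target_years is not None else None)
    for name in out.specs:
        out = RandomInterceptImputer(name, years=years).fit_transform(out)
    return out
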