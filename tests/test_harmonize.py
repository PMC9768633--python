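"""Artefact-correction and imputation oracles."""

import numpy as np
import pandas as pd
import pytest

from deprindex.harmonize import (BIMODALITY_FLAG, BreakCorrector,
                                 EastWestCorrector, G8Corrector,
                                 HarmonizeError, RandomInterceptImputer,
                                 bimodality_coefficient, carry_forward_gap,
                                 deflate_and_log)
from deprindex.regions import IndicatorPanel, PanelError, \
    default_indicator_specs

SPECS = default_indicator_specs()


def _panel(rows):
    return IndicatorPanel(pd.DataFrame(
        rows, columns=["region_id", "year", "indicator", "value"]), SPECS)


# ---------------------------------------------------------------- break ----

def _step_panel(step, slope=0.0, region_offsets=(0.0, 5.0)):
    rows = []
    for off, r in zip(region_offsets, "AB"):
        for y in range(2010, 2016):
            v = off + slope * (y - 2010) + (step if y >= 2013 else 0.0)
            rows.append((r, y, "debtor_quota", 10.0 + v))
    return _panel(rows)


@pytest.mark.parametrize("step,slope", [(3.0, 0.0), (3.0, 1.0), (0.0, 0.7)])
def test_break_shift_recovered_exactly_noiseless(step, slope):
    p = _step_panel(step, slope)
    bc = BreakCorrector("debtor_quota", 2013).fit(p)
    assert bc.shift_ == pytest.approx(step, abs=1e-9)
    out = bc.transform(p)
    if step == 0:
        pd.testing.assert_series_equal(out.df["value"], p.df["value"])


def test_break_correction_aligns_pre_to_post_level():
    p = _step_panel(3.0)
    out = BreakCorrector("debtor_quota", 2013).fit_transform(p)
    vals = out.df[out.df["region_id"] == "A"].set_index("year")["value"]
    assert np.allclose(vals, 13.0)


def test_break_requires_both_sides():
    rows = [("A", y, "debtor_quota", 1.0) for y in range(2014, 2018)]
    rows += [("B", y, "debtor_quota", 2.0) for y in range(2014, 2018)]
    with pytest.raises(HarmonizeError, match="both sides"):
        BreakCorrector("debtor_quota", 2013).fit(_panel(rows))


def test_double_application_refused():
    p = _step_panel(3.0)
    bc = BreakCorrector("debtor_quota", 2013).fit(p)
    out = bc.transform(p)
    with pytest.raises(PanelError, match="already applied"):
        bc.transform(out)


# ------------------------------------------------------------------- g8 ----

def test_g8_effect_recovered_and_subtracted(toy_hierarchy):
    ind = "school_leavers_without_qualification"
    rows = []
    for dist, base in (("01001", 6.0), ("02002", 8.0)):
        for y in range(2008, 2014):
            v = base + 0.1 * (y - 2008)
            if (dist[:2], y) == ("01", 2011):
                v -= 2.0
            rows.append((dist, y, ind, v))
    p = _panel(rows)
    g8 = G8Corrector(ind, [("01", 2011)]).fit(p, toy_hierarchy)
    assert g8.effect_ == pytest.approx(-2.0, abs=1e-9)
    out = g8.transform(p, toy_hierarchy)
    fixed = out.df[(out.df["region_id"] == "01001")
                   & (out.df["year"] == 2011)]["value"].iloc[0]
    assert fixed == pytest.approx(6.0 + 0.3, abs=1e-9)
    # the unaffected district is bit-identical
    before = p.df[p.df["region_id"] == "02002"]["value"].to_numpy()
    after = out.df[out.df["region_id"] == "02002"]["value"].to_numpy()
    assert (before == after).all()


def test_g8_empty_cells_is_identity(toy_hierarchy):
    ind = "school_leavers_without_qualification"
    rows = [("01001", y, ind, 5.0 + y % 3) for y in range(2008, 2012)]
    p = _panel(rows)
    out = G8Corrector(ind, []).fit_transform(p, toy_hierarchy)
    assert (out.df["value"] == p.df["value"]).all()


# ------------------------------------------------------------ east-west ----

def test_east_west_delta_equalizes_means():
    ind = "employees_without_qualification"
    rng = np.random.default_rng(0)
    rows = []
    west = rng.normal(12, 1, 40)
    for i, w in enumerate(west):
        rows.append((f"W{i}", 2019, ind, w))
        rows.append((f"E{i}", 2019, ind, w - 5.0))
    p = _panel(rows)
    flag = pd.Series({f"W{i}": False for i in range(40)}
                     | {f"E{i}": True for i in range(40)})
    ew = EastWestCorrector(ind).fit(p, flag)
    assert ew.delta_ == pytest.approx(5.0, abs=1e-9)
    out = ew.transform(p, flag)
    d = out.df.assign(east=out.df["region_id"].map(flag))
    means = d.groupby("east")["value"].mean()
    assert means[True] == pytest.approx(means[False], abs=1e-9)


def test_bimodal_mixture_flag_clears_after_correction():
    ind = "employees_without_qualification"
    rng = np.random.default_rng(1)
    rows = [(f"W{i}", 2019, ind, v)
            for i, v in enumerate(rng.normal(12, 1, 200))]
    rows += [(f"E{i}", 2019, ind, v)
             for i, v in enumerate(rng.normal(4, 1, 200))]
    p = _panel(rows)
    flag = pd.Series({f"W{i}": False for i in range(200)}
                     | {f"E{i}": True for i in range(200)})
    ew = EastWestCorrector(ind).fit(p, flag)
    assert ew.bimodality_before_ > BIMODALITY_FLAG
    assert ew.bimodality_after_ < BIMODALITY_FLAG


def test_east_west_needs_both_sides():
    ind = "employees_without_qualification"
    rows = [(f"W{i}", 2019, ind, 10.0 + i) for i in range(10)]
    flag = pd.Series({f"W{i}": False for i in range(10)})
    with pytest.raises(HarmonizeError, match="regions per side"):
        EastWestCorrector(ind).fit(_panel(rows), flag)


# -------------------------------------------------------- carry forward ----

def test_carry_forward_copies_and_flags():
    ind = "employees_university_degree"
    rows = [("A", 2011, ind, 8.1), ("B", 2011, ind, 7.0),
            ("B", 2012, ind, 7.5)]
    out = carry_forward_gap(_panel(rows), ind, 2011, 2012)
    d = out.df.set_index(["region_id", "year"])
    assert d.loc[("A", 2012), "value"].item() == 8.1
    assert bool(d.loc[("A", 2012), "imputed"].item())
    # observed cell untouched, not flagged
    assert d.loc[("B", 2012), "value"].item() == 7.5
    assert not bool(d.loc[("B", 2012), "imputed"].item())
    # flag count equals the recount of fillable gaps
    assert int(out.df["imputed"].sum()) == 1


# ------------------------------------------------------------ imputation ---

def test_imputer_exact_in_noiseless_limit():
    ind = "debtor_quota"
    rows = []
    for i, a in enumerate([3.0, -1.0, 0.5, 2.0]):
        for y in range(2004, 2020):
            rows.append((f"R{i}", y, ind, a + 2.0 * (y - 2000)))
    p = _panel(rows)
    imp = RandomInterceptImputer(ind, years=range(1998, 2020)).fit(p)
    out = imp.transform(p)
    d = out.df.set_index(["region_id", "year"])
    for i, a in enumerate([3.0, -1.0, 0.5, 2.0]):
        for y in range(1998, 2004):
            assert d.loc[(f"R{i}", y), "value"].item() == pytest.approx(
                a + 2.0 * (y - 2000), abs=1e-8)
            assert bool(d.loc[(f"R{i}", y), "imputed"].item())


def test_imputer_simulation_error_bounded():
    ind = "debtor_quota"
    rng = np.random.default_rng(42)
    noise_sd, slope = 0.1, 0.5
    a = rng.normal(0, 1, 200)
    rows, truth = [], {}
    for i in range(200):
        for y in range(1998, 2020):
            v = a[i] + slope * (y - 1998)
            if y >= 2004:
                rows.append((f"R{i}", y, ind,
                             v + rng.normal(0, noise_sd)))
            else:
                truth[(f"R{i}", y)] = v
    p = _panel(rows)
    out = RandomInterceptImputer(ind, years=range(1998, 2020)
                                 ).fit_transform(p)
    d = out.df[out.df["imputed"]].set_index(["region_id", "year"])
    errs = [abs(d.loc[k, "value"].item() - v) for k, v in truth.items()]
    assert np.mean(errs) <= 3 * noise_sd


def test_imputer_leaves_complete_regions_alone():
    ind = "debtor_quota"
    rows = [("A", y, ind, float(y)) for y in range(2004, 2020)]
    p = _panel(rows)
    out = RandomInterceptImputer(ind, years=range(2004, 2020)
                                 ).fit_transform(p)
    assert int(out.df["imputed"].sum()) == 0
    assert (out.df["value"].to_numpy()
            == p.df["value"].to_numpy()).all()


def test_imputer_requires_data():
    rows = [("A", 2010, "debtor_quota", 1.0)]
    p = _panel(rows)
    with pytest.raises(HarmonizeError, match="no observed data"):
        RandomInterceptImputer("income_tax").fit(p)


# --------------------------------------------------------- deflate/log -----

def test_deflate_and_log_values():
    rows = [("A", 2010, "income_tax", 1000.0), ("A", 2011, "income_tax",
                                                1100.0)]
    p = _panel(rows)
    out = deflate_and_log(p, "income_tax", {2010: 1.0, 2011: 1.1})
    assert out.df["value"].iloc[0] == pytest.approx(np.log(1000))
    assert out.df["value"].iloc[1] == pytest.approx(np.log(1000))


def test_deflate_rejects_nonpositive():
    rows = [("A", 2010, "income_tax", -3.0)]
    with pytest.raises(HarmonizeError, match="non-positive"):
        deflate_and_log(_panel(rows), "income_tax", {})


# --------------------------------------------------- full harmonization ----

def test_full_harmonization_leaves_no_missing_cells(pipeline, hierarchy):
    harm = pipeline.harmonized_
    years = hierarchy.years
    for name, spec in harm.specs.items():
        sub = harm.indicator_values(name)
        n_regions = len(hierarchy.level_ids(spec.native_level))
        assert sub["value"].notna().all(), name
        assert len(sub) == n_regions * len(years), name


def test_expected_correlation_signs_after_east_west(pipeline):
    """Once the East-West level gap is removed, the qualification
    indicator correlates positively with the other deprivation-increasing
    education indicator and negatively with the decreasing one."""
    wide = pipeline.harmonized_.wide(
        ["employees_without_qualification",
         "school_leavers_without_qualification",
         "employees_university_degree"]).dropna()
    c = wide.corr()
    assert c.loc["employees_without_qualification",
                 "school_leavers_without_qualification"] > 0
    assert c.loc["employees_without_qualification",
                 "employees_university_degree"] < 0


def test_harmonization_recovers_generating_artefacts(pipeline, cfg):
    L = pipeline.harmonized_.ledger.set_index(["indicator", "correction"])
    shift = float(L.loc[("employees_without_qualification", "break"),
                        "parameters"].split("shift=")[1])
    assert shift == pytest.approx(cfg.break_shift, abs=0.5)
    delta = float(L.loc[("employees_without_qualification", "east_west"),
                        "parameters"].split("delta=")[1])
    assert delta == pytest.approx(-cfg.east_offset, abs=1.0)
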