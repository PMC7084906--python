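"""Bootstrap, visual predictive check and residual diagnostics."""

import numpy as np
import pandas as pd
import pytest

import pkbridge as pk
from pkbridge.evaluation import bootstrap, gof, vpc
from pkbridge.population import PopPKModel, PopPKResults


def _results_at(params, data):
    """Results object at given parameters without fitting (for diagnostics)."""
    model = PopPKModel(data, params)
    comp, eta = model.engine.ofv_components(params)
    etas = pd.DataFrame(eta, columns=[f"eta_{n}" for n in model.engine.eta_names])
    etas.insert(0, "ID", model.engine.ids)
    return PopPKResults(model=model, params=params, ofv=float(comp.sum()),
                        se=None, rse=None, etas=etas, shrinkage={},
                        converged=True, nfev=0, message="evaluated")


def test_bootstrap_identity_reproduces_fit(fitted):
    b = bootstrap(fitted, n=1, seed=0, identity=True,
                  fit_kwargs=dict(maxfev=1500, fatol=0.05, xatol=1e-3))
    tab = b.table.set_index("parameter")
    for n in ("ka", "fpm", "clp", "clpm", "vp", "clm", "vm"):
        assert tab.loc[n, "median"] == pytest.approx(
            fitted.params.get_value(n), rel=0.02
        ), n
    assert (tab["ci_lo"] <= tab["median"]).all()
    assert (tab["median"] <= tab["ci_hi"]).all()


def test_bootstrap_seed_reproducible(fitted):
    kw = dict(n=3, fit_kwargs=dict(maxfev=300, fatol=0.5, xatol=1e-2))
    a = bootstrap(fitted, seed=11, **kw)
    b = bootstrap(fitted, seed=11, **kw)
    pd.testing.assert_frame_equal(a.estimates, b.estimates)
    c = bootstrap(fitted, seed=12, **kw)
    assert not a.estimates.equals(c.estimates)


def test_vpc_bands_collapse_without_variability(study, final_model):
    tiny = final_model.replace(omega={"clp": 1e-14}, sigma_p=1e-8, sigma_m=1e-8)
    res = _results_at(tiny, study)
    v = vpc(res, n=20, seed=0)
    t = v.table
    width = (t["band_hi"] - t["band_lo"]) / t["band_hi"].clip(lower=1e-9)
    assert (width < 1e-4).all()
    # and the band sits on the typical-value curve
    for _, row in t[t["ANALYTE"] == "parent"].head(4).iterrows():
        ppl = {"G1": 0.0, "G2": 500.0, "G3": 1500.0}[row["GROUP"]]
        cp, _ = pk.concentrations(
            tiny.structural, pk.DoseRegimen(40.0, ppl_dose=ppl), [row["TIME"]]
        )
        assert row["band_lo"] == pytest.approx(cp[0], rel=1e-3)


def test_vpc_bands_widen_with_sigma(study, final_model):
    lo = _results_at(final_model.replace(sigma_p=0.10, sigma_m=0.10), study)
    hi = _results_at(final_model.replace(sigma_p=0.30, sigma_m=0.30), study)
    v_lo = vpc(lo, n=40, seed=5).table
    v_hi = vpc(hi, n=40, seed=5).table
    w_lo = (v_lo["band_hi"] - v_lo["band_lo"]).to_numpy()
    w_hi = (v_hi["band_hi"] - v_hi["band_lo"]).to_numpy()
    assert (w_hi > w_lo).mean() > 0.95


def test_vpc_self_calibration(fitted):
    """Simulating from the fitted model, ~90% of observations sit in the
    5th-95th band (binomial tolerance)."""
    v = vpc(fitted, n=100, seed=2)
    obs = fitted.model.data.observations(drop_blq=False, drop_predose=True).copy()
    obs["GROUP"] = obs["ID"].map(
        fitted.model.data.df.groupby("ID")["GROUP"].first()
    )
    merged = obs.merge(v.table, on=["GROUP", "ANALYTE", "TIME"])
    inside = (
        (merged["DV"] >= merged["band_lo"]) & (merged["DV"] <= merged["band_hi"])
    ).mean()
    assert 0.75 <= inside <= 0.99


def test_gof_perfect_fit_gives_zero_cwres(final_model, rat_design):
    noise_free = final_model.replace(
        omega={"clp": 1e-14}, sigma_p=1e-9, sigma_m=1e-9
    )
    ds = pk.simulate_dataset(noise_free, rat_design, seed=0)
    res = _results_at(noise_free.replace(sigma_p=0.2, sigma_m=0.2), ds)
    tab = gof(res)
    assert np.abs(tab["CWRES"]).max() < 1e-3
    np.testing.assert_allclose(tab["IPRED"], tab["DV"], rtol=1e-5)


def test_gof_calibrated_for_well_specified_model(fitted):
    tab = gof(fitted)
    assert set(tab.columns) >= {"ID", "TIME", "ANALYTE", "DV", "PRED",
                                "IPRED", "CWRES"}
    assert abs(tab["CWRES"].mean()) < 0.3
    assert 0.5 < tab["CWRES"].var() < 1.7


def test_gof_detects_omitted_covariate(study, final_model):
    """Dropping the PPL effects leaves a residual trend across PPL groups."""
    wrong = final_model.replace(
        structural=final_model.structural.replace(emax_fpm=0.0, emax_clpm=0.0),
        covariates=(),
    )
    tab = gof(_results_at(wrong, study))
    data = study.df.groupby("ID")["DOSE_PPL"].first()
    tab = tab.assign(ppl=tab["ID"].map(data))
    by_group = tab[tab["ANALYTE"] == "metabolite"].groupby("ppl")["CWRES"].mean()
    # high-dose PPL group metabolite concentrations are grossly over-predicted
    assert by_group.loc[1500.0] < -0.5
    assert by_group.loc[0.0] > by_group.loc[1500.0]
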