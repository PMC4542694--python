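"""Dose-response fitting, pH-dependency ratio, antagonism index."""

import numpy as np
import pytest

from titrascreen import doseresponse as dr
from titrascreen import synthetic_data as syn


def _table(ec50=1.24, hill=1.5, top=1.0, variant="WT", ph=6.3, n_conc=8):
    c = np.logspace(-2, 1.3, n_conc)
    return dr.ResponseTable(variant, ph, c, dr.hill_curve(c, top, ec50, hill))


def test_noiseless_hill_recovery_within_one_percent():
    fit = dr.fit_hill(_table(ec50=1.24, hill=1.5, top=1.0))
    assert fit.ec50 == pytest.approx(1.24, rel=0.01)
    assert fit.hill == pytest.approx(1.5, rel=0.01)
    assert fit.top == pytest.approx(1.0, rel=0.01)


def _noisy_table(rng, sigma, ec50=1.24, n_conc=12):
    """Recovery-study design: 12-point dilution series with known SEs."""
    t = _table(ec50=ec50, n_conc=n_conc)
    return dr.ResponseTable(
        t.variant, t.ph, t.concentration_um,
        np.clip(t.response + rng.normal(0, sigma, t.response.shape), 0, None),
        se=np.full(n_conc, sigma),
    )


def test_monte_carlo_ec50_recovery():
    """Median relative EC50 error < 10% under Gaussian response noise."""
    rng = np.random.default_rng(42)
    errors = []
    for _ in range(200):
        try:
            fit = dr.fit_hill(_noisy_table(rng, 0.05))
        except dr.FitError:
            continue
        errors.append(abs(fit.ec50 - 1.24) / 1.24)
    assert len(errors) > 180
    assert float(np.median(errors)) < 0.10


def test_ec50_bias_and_interval_coverage():
    """Near-unbiased EC50 with calibrated 95% confidence intervals."""
    rng = np.random.default_rng(7)
    estimates, covered = [], 0
    n = 0
    for _ in range(200):
        try:
            fit = dr.fit_hill(_noisy_table(rng, 0.03))
        except dr.FitError:
            continue
        n += 1
        estimates.append(fit.ec50)
        if fit.ec50_stderr and abs(fit.ec50 - 1.24) <= 1.96 * fit.ec50_stderr:
            covered += 1
    bias = abs(np.mean(estimates) - 1.24) / 1.24
    assert bias < 0.03
    assert 0.90 <= covered / n <= 0.99


def test_all_zero_responses_error():
    c = np.logspace(-2, 1, 6)
    t = dr.ResponseTable("WT", 6.3, c, np.zeros(6))
    with pytest.raises(dr.FitError, match="no signal"):
        dr.fit_hill(t)


def test_monotone_decreasing_suggests_antagonist_mode():
    c = np.logspace(-2, 1, 6)
    t = dr.ResponseTable("R48A", 8.0, c, np.linspace(0.6, 0.1, 6))
    with pytest.raises(dr.FitError, match="antagonist"):
        dr.fit_hill(t)


def test_ec50_unit_equivariance():
    """Fitting in nM instead of uM scales EC50 by exactly the unit factor."""
    t_um = _table(ec50=1.24)
    t_nm = dr.ResponseTable(
        t_um.variant, t_um.ph, t_um.concentration_um * 1000.0, t_um.response
    )
    fit_um, fit_nm = dr.fit_hill(t_um), dr.fit_hill(t_nm)
    assert fit_nm.ec50 == pytest.approx(1000.0 * fit_um.ec50, rel=1e-4)
    assert fit_nm.hill == pytest.approx(fit_um.hill, rel=1e-4)


def test_ph_dependency_identity_and_plateau_ratio():
    fit = dr.fit_hill(_table())
    assert dr.ph_dependency(fit, fit) == pytest.approx(1.0)
    acid = dr.fit_hill(_table(top=1.0, ph=6.3))
    neut = dr.fit_hill(_table(top=0.1, ph=7.4))
    ratio = dr.ph_dependency(acid, neut, ref_conc_um=1000.0)
    assert ratio == pytest.approx(10.0, rel=0.01)


def test_ph_dependency_scenario_separates_variants():
    """pH-insensitive variant ratio ~1; pH-dependent wild type >> 1."""
    tables, _ = syn.generate_assay(syn.reference_assay_scenario())
    ref = 20.0
    wt = dr.ph_dependency(
        dr.fit_hill(tables[("WT", 6.3)]), dr.fit_hill(tables[("WT", 7.4)]), ref
    )
    h11a = dr.ph_dependency(
        dr.fit_hill(tables[("H11A", 6.3)]),
        dr.fit_hill(tables[("H11A", 7.4)]),
        ref,
    )
    assert 0.8 <= h11a <= 1.25
    assert wt > 2.0


def test_ph_dependency_requires_same_variant():
    a = dr.fit_hill(_table(variant="WT"))
    b = dr.fit_hill(_table(variant="R48A"))
    with pytest.raises(ValueError, match="different variants"):
        dr.ph_dependency(a, b)


def test_antagonism_index_identities():
    c = np.logspace(-2, 1, 6)
    alone = dr.ResponseTable("agonist_alone", 8.0, c, np.full(6, 0.6))
    same = dr.ResponseTable("X", 8.0, c, np.full(6, 0.6))
    half = dr.ResponseTable("Y", 8.0, c, np.full(6, 0.3))
    assert dr.antagonism_index(same, alone) == pytest.approx(0.0)
    assert dr.antagonism_index(half, alone) == pytest.approx(0.5)


def test_antagonism_ordering_strong_vs_weak():
    """Stronger generator antagonism gives the larger measured index."""
    _, truth = syn.generate_assay(syn.reference_assay_scenario())
    alone = truth["agonist_alone"]
    idx = {
        v: dr.antagonism_index(m, alone)
        for v, m in truth["mixture_tables"].items()
    }
    assert idx["R48A"] > idx["Y65A"]
    assert idx["V72A"] > idx["F94A"]
    assert idx["R48A"] > idx["WT"] > idx["Y65A"]


def test_antagonism_zero_baseline_flagged():
    c = np.logspace(-2, 1, 6)
    alone = dr.ResponseTable("agonist_alone", 8.0, c, np.zeros(6))
    mix = dr.ResponseTable("X", 8.0, c, np.zeros(6))
    with pytest.raises(dr.FitError, match="undefined"):
        dr.antagonism_index(mix, alone)


def test_response_table_csv_round_trip(tmp_path):
    path = tmp_path / "responses.csv"
    path.write_text(
        "variant,ph,concentration_um,response,se\n"
        "WT,6.3,0.1,0.05,0.01\n"
        "WT,6.3,1.0,0.45,0.02\n"
        "WT,6.3,10.0,0.95,0.02\n"
        "H11A,7.4,1.0,0.30,0.02\n"
    )
    tables = dr.read_response_tables(path)
    assert {(t.variant, t.ph) for t in tables} == {("WT", 6.3), ("H11A", 7.4)}
    wt = next(t for t in tables if t.variant == "WT")
    assert wt.concentration_um.tolist() == [0.1, 1.0, 10.0]
    assert wt.se is not None
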