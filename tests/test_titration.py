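"""Titration screen: tracking, significance, classification, pKa fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from titrascreen import synthetic_data as syn
from titrascreen import titration as ti
from titrascreen.peaklist_io import Assignment, Peak, PeakList


def _series(points, missing=(), subunit="NBS", num=11):
    s = ti.TitrationSeries(subunit, num, "H")
    s.points = dict(points)
    s.missing_phs = set(missing)
    return s


# ---------------------------------------------------------------------------
# compute_csp / significance
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "dh,dn,expected",
    [
        (0.06, 0.1, True),   # 1H rule alone
        (0.04, 0.4, False),  # both below
        (0.02, 0.6, True),   # 15N rule alone
        (0.05, 0.5, False),  # exactly at both thresholds: strict >
    ],
)
def test_significance_or_rule(config, dh, dn, expected):
    # base at 0 keeps the endpoint differences exactly representable, so
    # the strict > comparison at the threshold itself is well defined
    s = _series({3.0: (0.0, 0.0), 7.0: (dh, dn)})
    rec = ti.compute_csp(s, config)
    assert rec.evaluable
    assert bool(rec.significant) is expected


def test_combined_metric_closed_form(config):
    s = _series({3.0: (8.0, 120.0), 7.0: (8.0, 120.5)})
    rec = ti.compute_csp(s, config)
    assert rec.csp_combined == pytest.approx(0.05)


def test_missing_endpoint_yields_not_evaluable(config):
    s = _series({3.0: (8.0, 120.0), 5.0: (8.1, 120.0)}, missing={7.0})
    rec = ti.compute_csp(s, config)
    assert not rec.evaluable and not rec.significant


def test_significance_exhaustive_grid_matches_or_rule(config):
    """Decision over a (dH, dN) lattice around the thresholds == OR truth table."""
    for dh in np.linspace(0.0, 0.12, 25):
        for dn in np.linspace(0.0, 1.2, 25):
            s = _series({3.0: (0.0, 0.0), 7.0: (float(dh), float(dn))})
            rec = ti.compute_csp(s, config)
            assert rec.significant == (
                dh > config.h_threshold or dn > config.n_threshold
            )


@given(
    dh=st.floats(0, 0.5), dn=st.floats(0, 5.0),
    extra_h=st.floats(0, 0.5), extra_n=st.floats(0, 5.0),
)
@settings(deadline=None, max_examples=200, derandomize=True)
def test_significance_is_monotone(dh, dn, extra_h, extra_n):
    """Increasing either endpoint difference never flips significant->not."""
    config = ti.ScreenConfig()
    base = ti.compute_csp(
        _series({3.0: (8.0, 120.0), 7.0: (8.0 + dh, 120.0 + dn)}), config
    )
    bigger = ti.compute_csp(
        _series(
            {3.0: (8.0, 120.0), 7.0: (8.0 + dh + extra_h, 120.0 + dn + extra_n)}
        ),
        config,
    )
    assert not (base.significant and not bigger.significant)


@given(
    offset_h=st.floats(-1, 1), offset_n=st.floats(-3, 3),
    scale=st.floats(0.1, 5.0),
)
@settings(deadline=None, max_examples=100, derandomize=True)
def test_combined_metric_offset_invariant_and_scale_equivariant(
    offset_h, offset_n, scale
):
    config = ti.ScreenConfig()
    pts = {3.0: (8.0, 118.0), 5.0: (8.05, 118.4), 7.0: (8.09, 118.9)}
    rec = ti.compute_csp(_series(pts), config)
    shifted = {
        ph: (h + offset_h, n + offset_n) for ph, (h, n) in pts.items()
    }
    rec_shift = ti.compute_csp(_series(shifted), config)
    assert rec_shift.csp_combined == pytest.approx(rec.csp_combined, abs=1e-9)
    scaled = {
        ph: (8.0 + scale * (h - 8.0), 118.0 + scale * (n - 118.0))
        for ph, (h, n) in pts.items()
    }
    rec_scaled = ti.compute_csp(_series(scaled), config)
    assert rec_scaled.csp_combined == pytest.approx(
        scale * rec.csp_combined, rel=1e-9
    )


# ---------------------------------------------------------------------------
# group classification
# ---------------------------------------------------------------------------

def _hh_series(pka, dh_amp=0.12, dn_amp=1.2, grid=(3.0, 4.0, 5.0, 6.0, 7.0)):
    spec = syn.ResidueSpec("NBS", 11, "H", pka=pka, dh_amp=dh_amp, dn_amp=dn_amp)
    h, n = spec.shifts_at(list(grid))
    return _series({ph: (float(hh), float(nn)) for ph, hh, nn in zip(grid, h, n)})


@pytest.mark.parametrize(
    "pka,expected_f_low,expected_group",
    [(4.0, 0.901, "A"), (6.0, 0.099, "B")],
)
def test_group_from_hh_trajectory(config, pka, expected_f_low, expected_group):
    """Noiseless single-site titrations match the closed-form theta fractions."""
    s = _hh_series(pka)
    rec = ti.classify_group(s, ti.compute_csp(s, config), config)
    assert rec.f_low == pytest.approx(expected_f_low, abs=0.001)
    assert rec.group == expected_group


def test_flat_trajectory_gets_no_group(config):
    s = _series({ph: (8.0, 120.0) for ph in (3.0, 4.0, 5.0, 6.0, 7.0)})
    rec = ti.compute_csp(s, config)
    rec.significant = True  # force past the significance gate
    rec = ti.classify_group(s, rec, config)
    assert rec.group == "none"


def test_tie_at_cut_goes_to_group_b(config):
    """f_low exactly at the cut (symmetric pKa = ph_mid) classifies as B."""
    s = _hh_series(5.0)
    rec = ti.classify_group(s, ti.compute_csp(s, config), config)
    assert rec.f_low == pytest.approx(0.5, abs=1e-9)
    assert rec.group == "B"


@pytest.mark.parametrize("pka", [2.5, 3.0, 3.5, 3.8])
def test_low_pka_always_group_a(config, pka):
    # large amplitude: a pKa below the window leaves only a tail of the
    # transition inside pH 3-7, and the property is about classification,
    # not the significance filter
    s = _hh_series(pka, dh_amp=0.3, dn_amp=3.0)
    rec = ti.classify_group(s, ti.compute_csp(s, config), config)
    assert rec.group == "A", syn.analytic_f_low(pka, config)


@pytest.mark.parametrize("pka", [5.7, 6.0, 6.5, 7.0])
def test_high_pka_always_group_b(config, pka):
    s = _hh_series(pka, dh_amp=0.3, dn_amp=3.0)
    rec = ti.classify_group(s, ti.compute_csp(s, config), config)
    assert rec.group == "B", syn.analytic_f_low(pka, config)


def test_classification_invariant_under_sign_flip(config):
    for pka in (4.0, 5.5, 6.2):
        s_pos = _hh_series(pka)
        s_neg = _hh_series(pka, dh_amp=-0.12, dn_amp=-1.2)
        r_pos = ti.classify_group(s_pos, ti.compute_csp(s_pos, config), config)
        r_neg = ti.classify_group(s_neg, ti.compute_csp(s_neg, config), config)
        assert r_pos.group == r_neg.group
        assert r_pos.f_low == pytest.approx(r_neg.f_low, abs=1e-12)


def test_no_interior_point_gives_group_none(config):
    s = _series({3.0: (8.0, 120.0), 7.0: (8.2, 121.5)})
    rec = ti.compute_csp(s, config)
    rec = ti.classify_group(s, rec, config)
    assert rec.significant and rec.group == "none"


def test_endpoints_only_mode_agrees_on_monotone_hh():
    config = ti.ScreenConfig(use_path_length=False)
    for pka in (4.0, 6.0):
        s = _hh_series(pka)
        rec = ti.classify_group(s, ti.compute_csp(s, config), config)
        assert rec.group == ("A" if pka < 5 else "B")


# ---------------------------------------------------------------------------
# peak tracking
# ---------------------------------------------------------------------------

def _assigned_list(ph, positions):
    peaks = [
        Peak(f"NBS{num}", h, n, None, Assignment("NBS", num, "X"))
        for num, (h, n) in positions.items()
    ]
    return PeakList(condition_ph=ph, peaks=peaks)


def _unassigned_list(ph, positions):
    peaks = [
        Peak(f"pk{num}", h, n, None, None) for num, (h, n) in positions.items()
    ]
    return PeakList(condition_ph=ph, peaks=peaks)


def test_stationary_peak_tracked(config):
    lists = [
        _assigned_list(3.0, {1: (8.20, 120.0)}),
        _unassigned_list(4.0, {1: (8.20, 120.0)}),
        _unassigned_list(5.0, {1: (8.20, 120.0)}),
    ]
    series = ti.build_series(lists, config)
    assert series[0].points[5.0] == (8.20, 120.0)
    assert not series[0].missing_phs


def test_drifting_peak_recovered_exactly(config):
    """+0.03 ppm 1H per pH unit with no competitors: exact trajectory."""
    phs = [3.0, 4.0, 5.0, 6.0, 7.0]
    lists = [_assigned_list(3.0, {1: (8.20, 120.0)})]
    for ph in phs[1:]:
        lists.append(_unassigned_list(ph, {1: (8.20 + 0.03 * (ph - 3), 120.0)}))
    s = ti.build_series(lists, config)[0]
    for ph in phs:
        assert s.points[ph][0] == pytest.approx(8.20 + 0.03 * (ph - 3))
    assert not s.missing_phs


def test_vanished_peak_accumulates_missing_phs(config):
    lists = [
        _assigned_list(3.0, {1: (8.2, 120.0), 2: (9.0, 125.0)}),
        _unassigned_list(4.0, {1: (8.2, 120.0), 2: (9.0, 125.0)}),
    ]
    for ph in (5.0, 6.0, 7.0):
        lists.append(_unassigned_list(ph, {1: (8.2, 120.0)}))
    series = {s.key: s for s in ti.build_series(lists, config)}
    assert series[("NBS", 2)].missing_phs == {5.0, 6.0, 7.0}
    assert not series[("NBS", 1)].missing_phs


def test_out_of_gate_peak_not_claimed(config):
    lists = [
        _assigned_list(3.0, {1: (8.2, 120.0)}),
        _unassigned_list(4.0, {99: (8.2 + 2 * config.gate_h, 120.0)}),
    ]
    s = ti.build_series(lists, config)[0]
    assert s.missing_phs == {4.0}


def test_duplicate_ph_rejected(config):
    lists = [
        _assigned_list(3.0, {1: (8.2, 120.0)}),
        _assigned_list(3.0, {1: (8.2, 120.0)}),
    ]
    with pytest.raises(ValueError, match="duplicate pH"):
        ti.build_series(lists, config)


def test_unassigned_base_list_rejected(config):
    lists = [
        _unassigned_list(3.0, {1: (8.2, 120.0)}),
        _unassigned_list(4.0, {1: (8.2, 120.0)}),
    ]
    with pytest.raises(ValueError, match="no assignments"):
        ti.build_series(lists, config)


def test_tracking_recovers_generator_assignment_matrix(config):
    """Zero noise, non-overlapping trajectories: permutation-oracle identity."""
    scenario = syn.reference_screen_scenario()
    peaklists, _ = syn.generate_titration(scenario, config)
    series = {s.key: s for s in ti.build_series(peaklists, config)}
    for spec in scenario.residues:
        s = series[(spec.subunit, spec.residue_number)]
        for ph in scenario.ph_grid:
            if ph in spec.missing_phs:
                assert ph in s.missing_phs
            else:
                h_true, n_true = spec.shifts_at(ph)
                assert s.points[ph][0] == pytest.approx(float(h_true), abs=1e-9)
                assert s.points[ph][1] == pytest.approx(float(n_true), abs=1e-9)


# ---------------------------------------------------------------------------
# exchange detection
# ---------------------------------------------------------------------------

def test_exchange_detection_matches_generator(reference_screen):
    exch = ti.detect_exchange_candidates(reference_screen["series"])
    keys = [k for k, _ in exch]
    nas = [k for k in keys if k[0] == "NAS"]
    nbs = [k for k in keys if k[0] == "NBS"]
    assert [k[1] for k in nas] == sorted(syn.EXCHANGE_NAS)
    assert [k[1] for k in nbs] == sorted(syn.EXCHANGE_NBS)
    assert all(m == {5.0, 6.0, 7.0} for _, m in exch)
    assert keys == sorted(keys)


def test_no_missing_points_gives_empty_exchange_list(config):
    s = _hh_series(6.0)
    assert ti.detect_exchange_candidates([s]) == []


def test_single_missing_ph_reported(config):
    s = _series({3.0: (8.0, 120.0), 5.0: (8.1, 120.5)}, missing={7.0})
    assert ti.detect_exchange_candidates([s]) == [(("NBS", 11), {7.0})]


# ---------------------------------------------------------------------------
# pKa fitting
# ---------------------------------------------------------------------------

def test_pka_fit_noiseless_recovery(config):
    s = _hh_series(6.0)
    fit = ti.fit_pka(s, config)
    assert fit.pka == pytest.approx(6.0, abs=0.01)
    assert fit.hill_n == pytest.approx(1.0, abs=0.01)


def test_pka_fit_monte_carlo_recovery(config):
    """Median |pKa error| < 0.2 at realistic ppm noise, 100 replicates."""
    errors = []
    for rep in range(100):
        sc = syn.uniform_titration_scenario(
            1, pka=6.0, sigma_h=0.005, sigma_n=0.05, seed=3000 + rep
        )
        lists, _ = syn.generate_titration(sc, config)
        s = ti.build_series(lists, config)[0]
        fit = ti.fit_pka(s, config)
        assert fit.pka is not None
        errors.append(abs(fit.pka - 6.0))
    assert float(np.median(errors)) < 0.2


def test_pka_fit_constant_trajectory_absent(config):
    s = _series({ph: (8.0, 120.0) for ph in (3.0, 4.0, 5.0, 6.0, 7.0)})
    fit = ti.fit_pka(s, config)
    assert fit.pka is None and "unidentifiable" in fit.reason


def test_pka_fit_too_few_points_absent(config):
    s = _series({3.0: (8.0, 120.0), 5.0: (8.1, 120.5), 7.0: (8.2, 121.0)})
    fit = ti.fit_pka(s, config)
    assert fit.pka is None and "points" in fit.reason
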