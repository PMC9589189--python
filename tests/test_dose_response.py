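"""Hill fitting, EC50 summarization and amplitude comparison."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from orscreen import (
    ReceptorTruth,
    build_curve,
    compare_amplitudes,
    fit_hill,
    fit_hill_xy,
    fit_replicates,
    gen_dose_response,
    hill,
    receptor_truth,
    summarize_ec50,
)
from orscreen.dose_response import HillFit
from orscreen.errors import (
    DegenerateNormalizationError,
    InsufficientDataError,
    UnderdeterminedFitError,
    UnmatchedMockError,
)

CONCS = [1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0]


def test_refit_recovers_exact_model_parameters():
    x = np.array(CONCS)
    y = hill(x, 10.0, 1.0, 0.0, 1.0)
    f = fit_hill_xy(x, y)
    assert f.converged
    assert f.ec50_umol_per_L == pytest.approx(10.0, rel=1e-4)
    assert f.hillslope == pytest.approx(1.0, rel=1e-3)
    assert f.min == pytest.approx(0.0, abs=1e-6)
    assert f.max == pytest.approx(1.0, rel=1e-4)


def test_underdetermined_fit_raises():
    with pytest.raises(UnderdeterminedFitError):
        fit_hill_xy([1.0, 10.0, 100.0], [0.1, 0.5, 0.9])


def _grid_oracle(x, y, log_e_grid, slope_grid):
    """Brute-force (EC50, slope) grid search with analytic (min, max)."""
    best = (np.inf, None, None)
    for le in log_e_grid:
        for h in slope_grid:
            u = 1.0 / (1.0 + (x / 10.0**le) ** h)  # f = min*u + max*(1-u)
            A = np.column_stack([u, 1.0 - u])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            ss = float(np.sum((A @ coef - y) ** 2))
            if ss < best[0]:
                best = (ss, le, h)
    return best


def test_fit_matches_grid_search_oracle_on_toy_curve():
    rng = np.random.default_rng(7)
    x = np.array([1.0, 5.0, 25.0, 125.0, 625.0])
    y = hill(x, 20.0, 1.5, 0.05, 0.9) + rng.normal(0, 0.02, size=x.size)
    fit = fit_hill_xy(x, y)
    log_e_grid = np.linspace(np.log10(x.min()), np.log10(x.max()), 241)
    slope_grid = np.linspace(0.5, 3.0, 126)
    _, le, h = _grid_oracle(x, y, log_e_grid, slope_grid)
    d_le = log_e_grid[1] - log_e_grid[0]
    d_h = slope_grid[1] - slope_grid[0]
    assert np.log10(fit.ec50_umol_per_L) == pytest.approx(le, abs=d_le)
    assert fit.hillslope == pytest.approx(h, abs=d_h)


@given(scale=st.floats(0.01, 100.0))
def test_ec50_and_slope_invariant_to_response_rescaling(scale):
    x = np.array(CONCS)
    y = hill(x, 30.0, 1.3, 0.0, 0.8)
    a, b = fit_hill_xy(x, y), fit_hill_xy(x, y * scale)
    assert b.ec50_umol_per_L == pytest.approx(a.ec50_umol_per_L, rel=1e-5)
    assert b.hillslope == pytest.approx(a.hillslope, rel=1e-5)
    assert b.max == pytest.approx(a.max * scale, rel=1e-4)


def test_monotone_data_fit_monotone_increasing():
    rng = np.random.default_rng(3)
    x = np.array(CONCS)
    y = np.sort(hill(x, 50.0, 2.0) + rng.normal(0, 0.01, x.size))
    f = fit_hill_xy(x, y)
    assert f.max > f.min
    assert f.hillslope > 0


def test_build_curve_mock_against_itself_is_zero():
    t = ReceptorTruth("flat", False)
    wells = gen_dose_response(t, CONCS, noise_cv=0.0)
    curve = build_curve(wells, normalize_mode="positive_control")
    assert np.allclose(curve.responses, 0.0)
    assert curve.mock_sd == pytest.approx(0.0, abs=1e-12)


def test_build_curve_max_mode_peaks_at_one():
    t = receptor_truth("OR2W1 ref", "Z4-11Al")
    wells = gen_dose_response(t, CONCS, noise_cv=0.03, seed=5)
    curve = build_curve(wells, normalize_mode="max")
    assert curve.responses.max() == pytest.approx(1.0)


def test_build_curve_missing_mock_raises():
    t = ReceptorTruth("v", True, ec50_umol_per_L=10.0, amplitude=1.0)
    wells = gen_dose_response(t, CONCS, noise_cv=0.0)
    with pytest.raises(UnmatchedMockError):
        build_curve(wells[wells["role"] != "mock"])


def test_build_curve_degenerate_max_raises():
    t = ReceptorTruth("flat", False)
    wells = gen_dose_response(t, CONCS, noise_cv=0.0)
    with pytest.raises(DegenerateNormalizationError):
        build_curve(wells, normalize_mode="max")


@pytest.mark.parametrize(
    "variant, odorant",
    [("OR10A6 L287P", "Z4-9Al"), ("OR2W1 D296N", "Z4-11Al")],
)
def test_noise_free_generator_curves_refit_to_truth(variant, odorant):
    t = receptor_truth(variant, odorant)
    wells = gen_dose_response(t, CONCS, noise_cv=0.0)
    curve = build_curve(wells, normalize_mode="max")
    for f in fit_replicates(curve):
        assert f.converged
        assert f.ec50_umol_per_L == pytest.approx(t.ec50_umol_per_L, rel=1e-3)


def test_noisy_curves_recover_ec50_within_fifteen_percent():
    """Mean recovered EC50 over 50 noisy triplicate curves within 15% of truth."""
    t = receptor_truth("OR10A6 L287P", "Z4-11Al")
    means = []
    for seed in range(50):
        wells = gen_dose_response(t, CONCS, noise_cv=0.05, seed=seed)
        curve = build_curve(wells, normalize_mode="max")
        fits = [f for f in fit_replicates(curve) if f.converged]
        means.append(np.mean([f.ec50_umol_per_L for f in fits]))
    assert np.mean(means) == pytest.approx(t.ec50_umol_per_L, rel=0.15)


def _fit(ec50, amp=1.0, converged=True):
    return HillFit(min=0.0, max=amp, ec50_umol_per_L=ec50, hillslope=1.0,
                   converged=converged, residual_ss=0.0)


def test_summarize_ec50_hand_values():
    s = summarize_ec50([_fit(40.0)] * 3, 1000.0)
    assert (s.mean_ec50, s.sd_ec50) == (pytest.approx(40.0), pytest.approx(0.0))
    s = summarize_ec50([_fit(28.0), _fit(26.0), _fit(30.0)], 1000.0)
    assert s.mean_ec50 == pytest.approx(28.0)
    assert s.sd_ec50 == pytest.approx(2.0)  # sample SD
    assert s.status == "responder"


def test_summarize_ec50_nonresponder_rules():
    # EC50 beyond the tested range in 2 of 3 replicates -> ND
    s = summarize_ec50([_fit(2000.0), _fit(1500.0), _fit(30.0)], 1000.0)
    assert s.is_nd and s.mean_ec50 is None and s.sd_ec50 is None
    # amplitude below 3x the mock noise floor -> ND
    s = summarize_ec50([_fit(10.0, amp=0.01)] * 3, 1000.0, mock_sd=0.02)
    assert s.is_nd
    # all fits failed -> ND
    s = summarize_ec50([_fit(10.0, converged=False)] * 3, 1000.0)
    assert s.is_nd


def test_flat_noise_free_curve_is_nd():
    t = ReceptorTruth("flat", False)
    wells = gen_dose_response(t, CONCS, noise_cv=0.0)
    curve = build_curve(wells, normalize_mode="positive_control")
    fits = fit_replicates(curve)
    assert summarize_ec50(fits, 1000.0, mock_sd=curve.mock_sd).is_nd


def test_flat_noisy_curves_usually_called_nd_up_to_1000():
    """The ND rule on noisy flat curves is statistical; most seeds must be ND."""
    t = ReceptorTruth("flat", False)
    nd = 0
    for seed in range(10):
        wells = gen_dose_response(t, CONCS, noise_cv=0.05, seed=seed)
        curve = build_curve(wells, normalize_mode="positive_control")
        fits = fit_replicates(curve)
        nd += summarize_ec50(fits, 1000.0, mock_sd=curve.mock_sd).is_nd
    assert nd >= 8


def test_published_responders_not_called_nd_under_noise():
    t = receptor_truth("OR10A6 L287P", "Z4-11Al")
    for seed in range(10):
        wells = gen_dose_response(t, CONCS, noise_cv=0.05, seed=seed)
        curve = build_curve(wells, normalize_mode="positive_control")
        fits = fit_replicates(curve)
        assert not summarize_ec50(fits, 1000.0, mock_sd=curve.mock_sd).is_nd


def test_paired_t_identical_samples():
    assert compare_amplitudes([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)


def test_paired_t_textbook_value_and_antisymmetry():
    a, b = [1.0, 2.0, 3.0], [2.0, 4.0, 6.0]
    t, p = compare_amplitudes(a, b)
    # differences (-1,-2,-3): mean -2, sd 1 -> t = -2 / (1/sqrt(3))
    assert t == pytest.approx(-2 * np.sqrt(3))
    t_swapped, p_swapped = compare_amplitudes(b, a)
    assert t_swapped == pytest.approx(-t)
    assert p_swapped == pytest.approx(p)


def test_paired_t_needs_two_pairs():
    with pytest.raises(InsufficientDataError):
        compare_amplitudes([1.0], [2.0])
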