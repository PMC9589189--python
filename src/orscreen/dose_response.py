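"""Concentration-response analysis: Hill fitting and EC50 summarization.

The receptor response to an odorant at concentration x (umol/L) is modelled
with the four-parameter Hill (logistic) function

    f(x) = (min - max) / (1 + (x / EC50)^Hillslope) + max

fitted per replicate by least squares with EC50 optimized in log10 space.
Per-replicate EC50s are then summarized as mean +/- sample SD across the
(typically three) transfection replicates; receptors whose curves stay flat
up to the highest tested concentration are reported as nonresponders (ND).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    DegenerateNormalizationError,
    DegenerateReferenceError,
    InsufficientDataError,
    UnderdeterminedFitError,
    UnmatchedMockError,
)

log = logging.getLogger(__name__)

#: Bounds relative to the tested concentration range, and on the slope.
EC50_BOUND_FACTOR = 100.0
HILLSLOPE_BOUNDS = (0.1, 10.0)


def hill(x, ec50: float, hillslope: float, min_: float = 0.0, max_: float = 1.0):
    """Four-parameter Hill function; increases from min_ to max_ for slope>0."""
    x = np.asarray(x, dtype=float)
    return (min_ - max_) / (1.0 + (x / ec50) ** hillslope) + max_


@dataclass(frozen=True)
class DoseResponseCurve:
    """Mock-subtracted, normalized responses of one (variant, odorant) pair.

    ``responses`` has shape (n_replicates, n_concentrations); ``mock_sd`` is
    the SD of mock-subtracted mock responses on the same normalization scale,
    the assay's noise floor used by the nonresponder rule.
    """

    variant_id: str
    odorant: str
    concentrations: np.ndarray
    responses: np.ndarray
    mock_sd: float

    @property
    def n_replicates(self) -> int:
        return self.responses.shape[0]


@dataclass(frozen=True)
class HillFit:
    """Least-squares Hill parameters for one replicate curve."""

    min: float
    max: float
    ec50_umol_per_L: float
    hillslope: float
    converged: bool
    residual_ss: float

    @property
    def amplitude(self) -> float:
        return self.max - self.min


@dataclass(frozen=True)
class EC50Summary:
    """Cross-replicate EC50 summary: mean +/- sample SD, or ND."""

    mean_ec50: float | None
    sd_ec50: float | None
    n: int
    status: str  # "responder" | "nonresponder"

    @property
    def is_nd(self) -> bool:
        return self.status == "nonresponder"


def _delta(df: pd.DataFrame) -> pd.Series:
    basal = df[["basal_1", "basal_2", "basal_3"]].mean(axis=1)
    post = df[["post_1", "post_2", "post_3"]].mean(axis=1)
    return post - basal


def build_curve(
    wells: pd.DataFrame, normalize_mode: str = "max"
) -> DoseResponseCurve:
    """Assemble a DoseResponseCurve from a plate table.

    Per well, the Delta-signal is mean(post) - mean(basal); the mean mock
    Delta-signal at the same (odorant, concentration) is subtracted from each
    test-well Delta-signal. Responses are then normalized either to the
    plate's positive-control Delta-signal (``positive_control``) or to the
    largest mock-subtracted response of the curve set (``max``). Zero
    concentrations are excluded (the fit runs in log space).
    """
    if normalize_mode not in ("positive_control", "max"):
        raise ValueError(f"unknown normalize_mode {normalize_mode!r}")
    d = wells.copy()
    d["delta"] = _delta(d)
    tests = d[(d["role"] == "test") & (d["conc_umolL"] > 0)]
    mocks = d[(d["role"] == "mock") & (d["conc_umolL"] > 0)]
    if tests.empty:
        raise InsufficientDataError("no test wells with positive concentration")
    variant = tests["variant_id"].iloc[0]
    odorant = tests["odorant"].iloc[0]

    concs = np.sort(tests["conc_umolL"].unique())
    mock_mean = mocks.groupby("conc_umolL")["delta"].mean()
    missing = [c for c in concs if c not in mock_mean.index]
    if missing:
        raise UnmatchedMockError(
            f"{variant}/{odorant}: no mock wells at concentrations {missing}"
        )

    cols = []
    for c in concs:
        sub = tests[tests["conc_umolL"] == c].sort_values("well_id")
        cols.append(sub["delta"].to_numpy() - mock_mean[c])
    n_rep = min(len(c) for c in cols)
    if any(len(c) != n_rep for c in cols):
        log.warning(
            "%s/%s: unequal replicate counts across concentrations; truncating to %d",
            variant, odorant, n_rep,
        )
    resp = np.stack([c[:n_rep] for c in cols], axis=1)  # (reps, concs)

    mock_resid = mocks["delta"].to_numpy() - mock_mean[mocks["conc_umolL"]].to_numpy()
    mock_sd = float(np.std(mock_resid, ddof=1)) if len(mock_resid) > 1 else 0.0

    if normalize_mode == "positive_control":
        pos = d[d["role"] == "positive"]
        if pos.empty:
            raise DegenerateReferenceError("no positive-control wells on the plate")
        ref = float(pos["delta"].mean())
        if ref <= 0:
            raise DegenerateReferenceError(
                f"plate {pos['plate_id'].iloc[0]}: positive-control signal {ref} <= 0"
            )
    else:
        ref = float(resp.max())
        if ref <= 0:
            raise DegenerateNormalizationError(
                f"{variant}/{odorant}: maximum mock-subtracted response {ref} <= 0"
            )
    return DoseResponseCurve(
        variant_id=variant,
        odorant=odorant,
        concentrations=concs.astype(float),
        responses=resp / ref,
        mock_sd=mock_sd / ref,
    )


def fit_hill_xy(x: np.ndarray, y: np.ndarray) -> HillFit:
    """Least-squares Hill fit to one replicate's (concentration, response) data.

    EC50 is optimized as log10(EC50) within [min(x)/100, max(x)*100]; the
    slope within [0.1, 10]; min and max are free. Initial values: smallest /
    largest response, geometric-mean concentration, slope 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(x)) < 4:
        raise UnderdeterminedFitError(
            f"need >= 4 distinct concentrations, got {len(np.unique(x))}"
        )
    if np.any(x <= 0):
        raise UnderdeterminedFitError("concentrations must be strictly positive")

    lo_e = np.log10(x.min() / EC50_BOUND_FACTOR)
    hi_e = np.log10(x.max() * EC50_BOUND_FACTOR)
    # span floor keeps the box non-degenerate when the curve is flat
    span = float(y.max() - y.min())
    if span <= 0:
        span = max(abs(float(y.max())), 1.0)
    p0 = np.array([y.min(), y.max(), np.mean(np.log10(x)), 1.0])
    lo = np.array([y.min() - 10 * span, y.min() - 10 * span, lo_e, HILLSLOPE_BOUNDS[0]])
    hi = np.array([y.max() + 10 * span, y.max() + 10 * span, hi_e, HILLSLOPE_BOUNDS[1]])
    p0 = np.clip(p0, lo + 1e-9, hi - 1e-9)

    def resid(p):
        mn, mx, log_e, h = p
        return hill(x, 10.0 ** log_e, h, mn, mx) - y

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.least_squares(
            resid, p0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12,
            max_nfev=10000,
        )
    mn, mx, log_e, h = res.x
    at_bound = log_e <= lo_e + 1e-6 or log_e >= hi_e - 1e-6
    return HillFit(
        min=float(mn),
        max=float(mx),
        ec50_umol_per_L=float(10.0 ** log_e),
        hillslope=float(h),
        converged=bool(res.success and not at_bound),
        residual_ss=float(np.sum(res.fun ** 2)),
    )


def fit_hill(curve: DoseResponseCurve, replicate: int) -> HillFit:
    """Fit the Hill function to one replicate of a curve."""
    return fit_hill_xy(curve.concentrations, curve.responses[replicate])


def fit_replicates(curve: DoseResponseCurve) -> list[HillFit]:
    """Per-replicate Hill fits for every replicate of a curve."""
    return [fit_hill(curve, r) for r in range(curve.n_replicates)]


def response_span(fit: HillFit, lo_conc: float, hi_conc: float) -> float:
    """Fitted response change across the tested concentration window.

    |f(hi) - f(lo)| is the amplitude the assay could actually observe: it
    equals max - min for a responder whose EC50 sits inside the window, but
    stays at noise level when a fit on flat data pushes its asymptotes
    beyond the data range.
    """
    f_lo = hill(lo_conc, fit.ec50_umol_per_L, fit.hillslope, fit.min, fit.max)
    f_hi = hill(hi_conc, fit.ec50_umol_per_L, fit.hillslope, fit.min, fit.max)
    return abs(float(f_hi) - float(f_lo))


def summarize_ec50(
    fits: list[HillFit],
    max_tested_umol_per_L: float,
    mock_sd: float = 0.0,
    min_tested_umol_per_L: float | None = None,
) -> EC50Summary:
    """Summarize per-replicate EC50s as mean +/- sample SD, or call ND.

    A replicate is non-responding when its fit failed, its observable
    amplitude (fitted response span across the tested window, see
    :func:`response_span`) does not exceed 3x the mock noise floor, or its
    EC50 exceeds the highest tested concentration. The receptor is a
    nonresponder when at least two replicates (or all, if fewer than two
    were run) are non-responding. ``min_tested_umol_per_L`` defaults to
    three decades below the maximum.
    """
    if not fits:
        raise InsufficientDataError("no fits to summarize")
    lo = (
        min_tested_umol_per_L
        if min_tested_umol_per_L is not None
        else max_tested_umol_per_L / 1000.0
    )
    nd_flags = [
        (not f.converged)
        or (response_span(f, lo, max_tested_umol_per_L) <= 3.0 * mock_sd)
        or (f.ec50_umol_per_L > max_tested_umol_per_L)
        for f in fits
    ]
    if sum(nd_flags) >= min(2, len(fits)):
        return EC50Summary(mean_ec50=None, sd_ec50=None, n=len(fits), status="nonresponder")
    usable = [f.ec50_umol_per_L for f, nd in zip(fits, nd_flags) if not nd]
    if any(nd_flags):
        log.warning("summarizing over %d of %d replicates (others non-responding)",
                    len(usable), len(fits))
    mean = float(np.mean(usable))
    sd = float(np.std(usable, ddof=1)) if len(usable) > 1 else 0.0
    return EC50Summary(mean_ec50=mean, sd_ec50=sd, n=len(usable), status="responder")


def compare_amplitudes(a, b) -> tuple[float, float]:
    """Paired two-tailed t-test on replicate-matched raw amplitudes.

    Returns (t, p). Identical samples give (0.0, 1.0) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InsufficientDataError("amplitude samples must be 1-D and replicate-paired")
    if len(a) < 2:
        raise InsufficientDataError("need >= 2 pairs for a paired t-test")
    if np.allclose(a, b):
        return 0.0, 1.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)
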