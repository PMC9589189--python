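"""Sensory-panel statistics and the genotype-expectation model.

A triangle test presents three vials, two identical; a judge succeeds by
chance with probability 1/3 (binary resemblance comparisons: 1/2). Observed
correct counts are tested against chance with a 1-df Pearson chi-square
goodness-of-fit (optional Yates continuity correction).

The genotype-expectation model links receptor genetics to panel performance:
with c functional-haplotype carriers among n panelists, carriers answering
correctly with probability p_detect and the rest guessing at p_chance, the
number of correct answers is the sum of two binomials,
Binomial(c, p_detect) + Binomial(n - c, p_chance), with expectation
c*p_detect + (n - c)*p_chance — e.g. 14 carriers who always detect plus
15 guessers at 1/3 among 29 panelists give 19 expected correct answers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import genotyping
from .errors import InsufficientDataError, InvalidConfigError, UnknownVariantError
from .reference import ATOMIC_WEIGHTS, ODORANT_FORMULAS

TRIANGLE_CHANCE = 1.0 / 3.0
BINARY_CHANCE = 1.0 / 2.0


@dataclass(frozen=True)
class TrialSummary:
    """Correct/total counts of one discrimination test and its chance level."""

    n_correct: int
    n_total: int
    chance_prob: float = TRIANGLE_CHANCE

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_total:
            raise InvalidConfigError("n_correct must be within [0, n_total]")
        if not 0 < self.chance_prob < 1:
            raise InvalidConfigError("chance_prob must be in (0,1)")


def goodness_of_fit(
    summary: TrialSummary, correction: str = "none"
) -> tuple[float, float]:
    """Pearson 1-df chi-square of observed correct/incorrect counts vs chance.

    Returns (chi2, p). ``correction='yates'`` applies the continuity
    correction (|O-E| reduced by 0.5, floored at 0).
    """
    if summary.n_total < 1:
        raise InsufficientDataError("empty trial")
    if correction not in ("none", "yates"):
        raise ValueError(f"unknown correction {correction!r}")
    obs = np.array([summary.n_correct, summary.n_total - summary.n_correct], dtype=float)
    exp = np.array(
        [summary.n_total * summary.chance_prob, summary.n_total * (1 - summary.chance_prob)]
    )
    if np.any(exp == 0):
        raise InsufficientDataError("expected count of zero; chance level degenerate")
    dev = np.abs(obs - exp)
    if correction == "yates":
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float(np.sum(dev**2 / exp))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def expected_correct(
    n_carriers: int, n_total: int, p_detect: float, p_chance: float
) -> tuple[float, np.ndarray]:
    """Expectation and exact pmf of correct answers under the genotype model.

    Returns ``(expectation, pmf)`` where ``pmf[k]`` is the probability of
    exactly k correct answers, k = 0..n_total (convolution of the carrier and
    non-carrier binomials).
    """
    if not 0 <= n_carriers <= n_total:
        raise InvalidConfigError("n_carriers must be within [0, n_total]")
    for p in (p_detect, p_chance):
        if not 0.0 <= p <= 1.0:
            raise InvalidConfigError("probabilities must be in [0,1]")
    n_rest = n_total - n_carriers
    expectation = n_carriers * p_detect + n_rest * p_chance
    pmf_c = stats.binom.pmf(np.arange(n_carriers + 1), n_carriers, p_detect)
    pmf_r = stats.binom.pmf(np.arange(n_rest + 1), n_rest, p_chance)
    pmf = np.convolve(pmf_c, pmf_r)
    return float(expectation), pmf


def carrier_summary(
    panel: pd.DataFrame, variant: str, functional_only: bool = False
) -> tuple[int, float]:
    """Carrier count and percentage (1 decimal) among unique panelists.

    ``variant`` is gene-prefixed (e.g. ``"OR10A6 L287P"``); the matching
    diplotype column of the panel table (``or10a6_diplotype`` /
    ``or2w1_diplotype``) is parsed as ``"hap1|hap2"``. By default carriage
    means at least one haplotype contains the variant's site;
    ``functional_only`` restricts it to functional haplotypes (the carriage
    notion the detection phenotype depends on).
    """
    gene = variant.split(" ", 1)[0]
    col = f"{gene.lower()}_diplotype"
    if col not in panel.columns:
        raise UnknownVariantError(f"panel table has no column {col!r} for {variant!r}")
    per_panelist = panel.drop_duplicates("panelist_id")[["panelist_id", col]]
    test = genotyping.is_functional_carrier if functional_only else genotyping.is_carrier
    carriers = 0
    for dip in per_panelist[col]:
        haps = str(dip).split("|")
        if test(haps, variant):
            carriers += 1
    n = len(per_panelist)
    if n == 0:
        raise InsufficientDataError("no panelists")
    return carriers, round(100.0 * carriers / n, 1)


def trial_summaries(panel: pd.DataFrame, chance_prob: float = TRIANGLE_CHANCE) -> pd.DataFrame:
    """Per-(odorant, amount) correct counts and chi-square vs chance."""
    rows = []
    for (odorant, amount), sub in panel.groupby(["odorant", "amount_ng"]):
        ts = TrialSummary(int(sub["correct"].sum()), len(sub), chance_prob)
        chi2, p = goodness_of_fit(ts)
        rows.append(
            {
                "odorant": odorant,
                "amount_ng": amount,
                "n_correct": ts.n_correct,
                "n_total": ts.n_total,
                "p0": chance_prob,
                "chi2": chi2,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OdorantSpec:
    """An odorant's element composition and derived molar mass (g/mol)."""

    name: str
    formula: dict[str, int]

    def __post_init__(self) -> None:
        if not self.formula:
            raise InvalidConfigError(f"{self.name}: empty formula")
        unknown = set(self.formula) - set(ATOMIC_WEIGHTS)
        if unknown:
            raise InvalidConfigError(f"{self.name}: no atomic weight for {sorted(unknown)}")

    @property
    def molar_mass_g_per_mol(self) -> float:
        return sum(ATOMIC_WEIGHTS[el] * n for el, n in self.formula.items())

    @classmethod
    def named(cls, name: str) -> "OdorantSpec":
        try:
            return cls(name=name, formula=dict(ODORANT_FORMULAS[name]))
        except KeyError:
            raise UnknownVariantError(f"no formula on record for odorant {name!r}")


def ng_per_ml_to_umol_per_L(conc_ng_per_mL: float, spec: OdorantSpec) -> float:
    """Mass concentration (ng/mL == ug/L) to molarity (umol/L)."""
    if conc_ng_per_mL < 0:
        raise InvalidConfigError("concentration must be >= 0")
    return conc_ng_per_mL / spec.molar_mass_g_per_mol


def umol_per_L_to_ng_per_ml(conc_umol_per_L: float, spec: OdorantSpec) -> float:
    """Inverse of :func:`ng_per_ml_to_umol_per_L`."""
    if conc_umol_per_L < 0:
        raise InvalidConfigError("concentration must be >= 0")
    return conc_umol_per_L * spec.molar_mass_g_per_mol
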